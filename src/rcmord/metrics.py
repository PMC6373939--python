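"""Ordination evaluation metrics for simulated data with known structure.

All metrics operate on sample-score matrices (importance-scaled, i.e. the
coordinates actually plotted) and, for the taxon ratio, on the fitted score
triple (psi, R, S) together with the planted differential-abundance mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalReport",
    "silhouette_score",
    "pseudo_F",
    "taxon_ratio",
    "libsize_correlation",
]


@dataclass
class EvalReport:
    silhouette: float
    pseudo_F: float
    taxon_ratio: float
    libsize_cor: np.ndarray

    def as_dict(self) -> dict:
        out = {
            "silhouette": self.silhouette,
            "pseudo_F": self.pseudo_F,
            "taxon_ratio": self.taxon_ratio,
        }
        for m, c in enumerate(np.atleast_1d(self.libsize_cor), start=1):
            out[f"libsize_cor_dim{m}"] = float(c)
        return out


def silhouette_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width of the sample scores against known groups.

    Euclidean distances on the (scaled) score matrix; samples in singleton
    groups contribute a silhouette of 0, with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts == 1):
        warnings.warn(
            "singleton group(s) present; their samples get silhouette 0",
            RuntimeWarning,
            stacklevel=2,
        )
    from sklearn.metrics import silhouette_samples

    vals = silhouette_samples(scores, labels)
    return float(vals.mean())


def pseudo_F(scores: np.ndarray, labels: np.ndarray) -> float:
    """Between/within variance ratio of sample scores across known groups.

    ``(SS_between/(g-1)) / (SS_within/(n-g))`` with squared Euclidean
    distances of score rows to group centroids and the grand centroid.
    Returns ``inf`` (with a warning) when the within-group variance is zero.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, g = scores.shape[0], len(uniq)
    if g < 2:
        raise ValueError("need at least two groups")
    grand = scores.mean(axis=0)
    ss_b = 0.0
    ss_w = 0.0
    for lab in uniq:
        grp = scores[labels == lab]
        cen = grp.mean(axis=0)
        ss_b += len(grp) * float(np.sum((cen - grand) ** 2))
        ss_w += float(np.sum((grp - cen) ** 2))
    if ss_w == 0:
        warnings.warn("zero within-group variance: pseudo-F is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return (ss_b / (g - 1)) / (ss_w / (n - g))


def taxon_ratio(
    psi: np.ndarray,
    R: np.ndarray,
    S: np.ndarray,
    da_mask: np.ndarray,
    group_labels: np.ndarray,
) -> float:
    """DA vs non-DA mean inner-product ratio.

    Numerator: for each DA (taxon, group) pair, the mean over that group's
    samples of ``|<psi * r_i, s_j>|``, averaged over pairs.  Denominator: the
    same construction for non-DA taxa paired with every group.  Values above
    1 mean planted DA taxa contribute more to the sample separation than
    background taxa.  Absolute inner products are used so that sign
    conventions of the ordination do not matter.
    """
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    da_mask = np.asarray(da_mask, dtype=bool)
    labels = np.asarray(group_labels)
    groups = np.unique(labels)
    if da_mask.shape[1] != len(groups):
        raise ValueError("da_mask must have one column per group")
    if not da_mask.any():
        raise ValueError("no DA taxa in the mask")
    non_da = ~da_mask.any(axis=1)
    if not non_da.any():
        raise ValueError("no non-DA taxa in the mask")

    inner = np.abs((R * psi) @ S.T)  # n x p
    group_mean = np.vstack([inner[labels == lab].mean(axis=0) for lab in groups])  # g x p

    num_vals = [group_mean[k, j] for j in range(S.shape[0]) for k in range(len(groups))
                if da_mask[j, k]]
    den_vals = group_mean[:, non_da].ravel()
    num = float(np.mean(num_vals))
    den = float(np.mean(den_vals))
    if den == 0:
        warnings.warn("non-DA taxa have zero scores: taxon ratio is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return num / den


def libsize_correlation(scores: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    """Pearson correlation of each score dimension with log library size.

    Dimensions with constant scores get a correlation of 0 with a warning.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    lib = np.asarray(lib_sizes, dtype=float)
    if np.ptp(lib) == 0:
        raise ValueError("library sizes are constant")
    loglib = np.log(lib)
    out = np.empty(scores.shape[1])
    for m in range(scores.shape[1]):
        col = scores[:, m]
        if np.ptp(col) == 0:
            warnings.warn(
                f"dimension {m + 1} has constant scores; correlation set to 0",
                RuntimeWarning, stacklevel=2,
            )
            out[m] = 0.0
        else:
            out[m] = np.corrcoef(col, loglib)[0, 1]
    return out
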