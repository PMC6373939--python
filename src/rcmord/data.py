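"""Count-table and sample-metadata containers, readers and filtering rules.

The canonical in-memory orientation is samples x taxa (an ``n x p`` integer
matrix); readers convert from taxa-in-rows layouts (the BIOM convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleData",
    "read_counts",
    "write_counts",
    "filter_taxa",
    "read_metadata",
    "encode_metadata",
]


@dataclass
class CountTable:
    """An n x p table of read counts with sample and taxon identifiers."""

    X: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if np.any(self.X < 0):
            i, j = np.argwhere(self.X < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if np.any(self.X != np.floor(self.X)):
            i, j = np.argwhere(self.X != np.floor(self.X))[0]
            raise ValueError(
                f"non-integer count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        self.X = self.X.astype(np.int64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.taxon_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({x for x in ids if ids.count(x) > 1})
                raise ValueError(f"duplicate {name} ids: {dup}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def lib_sizes(self) -> np.ndarray:
        """Row sums: the observed library size (sequencing depth) per sample."""
        return self.X.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.sample_ids, columns=self.taxon_ids)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountTable(n={self.n} samples, p={self.p} taxa)"


def read_counts(
    path,
    orientation: str = "samples-in-rows",
    format: str | None = None,
) -> CountTable:
    """Read a count table from TSV or BIOM into a :class:`CountTable`.

    Parameters
    ----------
    path
        File path.  TSV files need a header row and a first id column.
    orientation
        ``"samples-in-rows"`` or ``"taxa-in-rows"`` (TSV only; BIOM files are
        taxa-in-rows by convention and converted automatically).
    format
        ``"tsv"`` or ``"biom"``; inferred from the file extension when None.
    """
    path = str(path)
    if format is None:
        format = "biom" if path.endswith(".biom") else "tsv"
    if format == "biom":
        try:
            import biom  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "reading BIOM files requires the biom-format package"
            ) from exc
        table = biom.load_table(path)
        # BIOM stores observations (taxa) in rows
        df = table.to_dataframe(dense=True).T
    else:
        if orientation not in ("samples-in-rows", "taxa-in-rows"):
            raise ValueError(f"unknown orientation {orientation!r}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "taxa-in-rows":
            df = df.T
    return CountTable(
        df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str))
    )


def write_counts(ct: CountTable, path) -> None:
    """Write a CountTable as TSV, samples in rows."""
    ct.to_frame().to_csv(path, sep="\t")


def filter_taxa(
    ct: CountTable,
    prevalence_min: float = 0.05,
    totalcount_min_frac: float = 0.10,
) -> CountTable:
    """Drop rare taxa, then empty samples.

    A taxon is removed when its prevalence (fraction of samples with a
    positive count) is below ``prevalence_min`` or its total count is below
    ``totalcount_min_frac * n``.  Defaults are 5% prevalence and a total
    count of 10% of the number of samples.  Idempotent.
    """
    for t in (prevalence_min, totalcount_min_frac):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    n = ct.n
    prev = (ct.X > 0).mean(axis=0)
    total = ct.X.sum(axis=0)
    keep = (prev >= prevalence_min) & (total >= totalcount_min_frac * n)
    if not keep.any():
        raise ValueError("filtering removed every taxon")
    X = ct.X[:, keep]
    taxon_ids = [t for t, k in zip(ct.taxon_ids, keep) if k]
    nonempty = X.sum(axis=1) > 0
    X = X[nonempty]
    sample_ids = [s for s, k in zip(ct.sample_ids, nonempty) if k]
    return CountTable(X, sample_ids, taxon_ids)


@dataclass
class SampleData:
    """Encoded sample metadata with role-tagged columns.

    ``Q`` holds the dummy-coded / standardised design, one row per sample in
    the same order as the matching :class:`CountTable`.  Confounder columns
    form the block ``G`` and constraining columns the block ``C``; both are
    exposed mean-centred, which is the form every fitting routine consumes.
    """

    Q: pd.DataFrame
    column_roles: dict[str, str]
    coding_map: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roles = set(self.column_roles.values())
        if not roles <= {"confounder", "constraining", "unused"}:
            raise ValueError(f"unknown roles: {roles}")

    def _block(self, role: str) -> pd.DataFrame:
        cols = [c for c, r in self.column_roles.items() if r == role]
        block = self.Q[cols].astype(float)
        return block - block.mean(axis=0)

    @property
    def G(self) -> pd.DataFrame:
        """Centred confounder block (n x k)."""
        return self._block("confounder")

    @property
    def C(self) -> pd.DataFrame:
        """Centred constraining block (n x d)."""
        return self._block("constraining")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.Q.index.astype(str))


def read_metadata(path) -> pd.DataFrame:
    """Read a TSV metadata table keyed by sample id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def encode_metadata(
    raw: pd.DataFrame,
    confounders: list[str] = (),
    constraining: list[str] = (),
) -> SampleData:
    """Dummy-code and standardise role-tagged metadata columns.

    Categorical constraining variables expand to one 0/1 column per level
    (full coding: gradient loadings are normalised, not tested, so no
    reference level is needed and every level gets an interpretable loading).
    Categorical confounders use reference coding (first level dropped) so the
    centred confounder block stays full rank for the per-taxon regressions.
    Numeric columns are standardised to mean 0, variance 1.  Columns not
    listed in either role are carried through untouched and tagged unused.
    """
    confounders = list(confounders)
    constraining = list(constraining)
    overlap = set(confounders) & set(constraining)
    if overlap:
        raise ValueError(
            f"columns tagged both confounder and constraining: {sorted(overlap)}"
        )
    for col in confounders + constraining:
        if col not in raw.columns:
            raise ValueError(f"metadata column {col!r} not found")
        if raw[col].isna().any():
            missing = list(raw.index[raw[col].isna()].astype(str))
            raise ValueError(f"missing values in column {col!r} for samples {missing}")

    pieces: list[pd.DataFrame] = []
    roles: dict[str, str] = {}
    coding_map: dict[str, dict] = {}
    for col in raw.columns:
        role = (
            "confounder"
            if col in confounders
            else "constraining"
            if col in constraining
            else "unused"
        )
        series = raw[col]
        if role == "unused":
            pieces.append(series.to_frame())
            roles[col] = role
            continue
        if pd.api.types.is_numeric_dtype(series):
            vals = series.astype(float)
            sd = vals.std(ddof=0)
            if sd == 0:
                raise ValueError(f"column {col!r} is constant")
            enc = ((vals - vals.mean()) / sd).to_frame()
            coding_map[col] = {"kind": "numeric"}
        else:
            drop_first = role == "confounder"
            dummies = pd.get_dummies(series, prefix=col, drop_first=drop_first)
            enc = dummies.astype(float)
            coding_map[col] = {
                "kind": "categorical",
                "levels": [str(v) for v in pd.unique(series)],
                "columns": list(enc.columns),
            }
        pieces.append(enc)
        for c in enc.columns:
            roles[c] = role
    Q = pd.concat(pieces, axis=1)
    Q.index = raw.index
    return SampleData(Q=Q, column_roles=roles, coding_map=coding_map)
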