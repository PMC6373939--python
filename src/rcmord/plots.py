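"""Biplots, triplots and response-curve plots for fitted ordinations.

Every rendered figure writes its data layers (sample points, taxon arrows,
variable loadings, curves) as TSV files next to the image, so all plotted
coordinates can be checked without parsing the image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .constrained import ConstrainedFit, NonparametricResponses, linear_arrow_geometry
from .unconstrained import UnconstrainedFit, biplot_coordinates

__all__ = ["PlotSpec", "render_biplot", "render_triplot", "render_response_curves"]


@dataclass
class PlotSpec:
    dims: tuple[int, int] = (1, 2)
    top_k_taxa: int = 8
    color_by: np.ndarray | None = None  # per-sample values or labels
    annotate_psi: bool = True
    output: str | Path = "ordination.png"
    arrow_scale: float = 1.0  # display-only multiplier for the taxon layer


def _check(fit, spec: PlotSpec) -> None:
    if not all(fit.converged):
        raise ValueError("refusing to plot a non-converged fit")
    d1, d2 = spec.dims
    if not (1 <= d1 <= fit.M and 1 <= d2 <= fit.M):
        raise ValueError(f"dims {spec.dims} out of range for M={fit.M}")
    if spec.top_k_taxa > len(fit.taxon_ids):
        raise ValueError("top_k_taxa exceeds the number of taxa")


def _save_layers(output: Path, layers: dict[str, pd.DataFrame]) -> None:
    for name, df in layers.items():
        df.to_csv(output.with_suffix(f".{name}.tsv"), sep="\t", index=False)


def _scatter(ax, pts, ids, color_by):
    if color_by is not None:
        c = np.asarray(color_by)
        if c.dtype.kind in "OUS":  # categorical labels
            for lab in pd.unique(c):
                sel = c == lab
                ax.scatter(pts[sel, 0], pts[sel, 1], s=18, label=str(lab))
            ax.legend(fontsize=7, frameon=False)
        else:
            sc = ax.scatter(pts[:, 0], pts[:, 1], s=18, c=c, cmap="viridis")
            plt.colorbar(sc, ax=ax, shrink=0.8)
    else:
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color="0.3")


def render_biplot(fit: UnconstrainedFit, spec: PlotSpec) -> Path:
    """Samples at (psi_1 r_i1, psi_2 r_i2); top-k taxa by arrow norm as arrows."""
    _check(fit, spec)
    samples, taxa = biplot_coordinates(fit, spec.dims)
    norms = np.linalg.norm(taxa, axis=1)
    top = np.argsort(-norms)[: spec.top_k_taxa]

    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, samples, fit.sample_ids, spec.color_by)
    for j in top:
        x, y = taxa[j] * spec.arrow_scale
        ax.annotate(
            "", xy=(x, y), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="firebrick", lw=1.2),
        )
        ax.text(x, y, fit.taxon_ids[j], fontsize=7, color="firebrick")
    d1, d2 = spec.dims
    psi = fit.psi
    xlab, ylab = f"Dim {d1}", f"Dim {d2}"
    if spec.annotate_psi and psi[d2 - 1] > 0:
        xlab += f" (psi ratio {psi[d1 - 1] / psi[d2 - 1]:.2f})"
        ylab += " (psi ratio 1.00)"
    ax.set_xlabel(xlab)
    ax.set_ylabel(ylab)
    ax.axhline(0, color="0.85", lw=0.5)
    ax.axvline(0, color="0.85", lw=0.5)
    out = Path(spec.output)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    _save_layers(out, {
        "samples": pd.DataFrame(
            {"sample": fit.sample_ids, "x": samples[:, 0], "y": samples[:, 1]}
        ),
        "taxa": pd.DataFrame(
            {"taxon": [fit.taxon_ids[j] for j in top],
             "x": taxa[top, 0], "y": taxa[top, 1],
             "norm": norms[top]}
        ),
    })
    return out


def render_triplot(fit: ConstrainedFit, spec: PlotSpec) -> Path:
    """Samples at (psi_1 h_i1, psi_2 h_i2), taxon response arrows, variable loadings."""
    if fit.family not in ("linear", "quadratic"):
        raise ValueError("triplots need a linear or quadratic fit; "
                         "use render_response_curves for nonparametric responses")
    _check(fit, spec)
    d1, d2 = spec.dims
    i1, i2 = d1 - 1, d2 - 1
    H = fit.H
    samples = np.column_stack([fit.psi[i1] * H[:, i1], fit.psi[i2] * H[:, i2]])
    slopes = np.column_stack([fit.beta1[:, i1], fit.beta1[:, i2]])
    lengths = np.linalg.norm(slopes, axis=1)
    top = np.argsort(-lengths)[: spec.top_k_taxa]

    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, samples, fit.sample_ids, spec.color_by)
    arrows = []
    for j in top:
        arr = linear_arrow_geometry(
            np.array([fit.beta0[j, i1], fit.beta0[j, i2]]),
            np.array([fit.beta1[j, i1], fit.beta1[j, i2]]),
        )
        arrows.append(arr)
        if arr.degenerate:
            continue
        ox = 0.0 if not np.isfinite(arr.origin[0]) else arr.origin[0]
        oy = 0.0 if not np.isfinite(arr.origin[1]) else arr.origin[1]
        dx, dy = slopes[j] * spec.arrow_scale
        ax.annotate("", xy=(ox + dx, oy + dy), xytext=(ox, oy),
                    arrowprops=dict(arrowstyle="->", color="firebrick", lw=1.2))
        ax.text(ox + dx, oy + dy, fit.taxon_ids[j], fontsize=7, color="firebrick")
    # variable loadings
    scale = np.abs(samples).max() * 0.9 if samples.size else 1.0
    load = np.column_stack([fit.A[:, i1], fit.A[:, i2]])
    for name, (lx, ly) in zip(fit.variable_names, load):
        ax.text(lx * scale, ly * scale, name, fontsize=8, color="navy",
                ha="center", va="center")
    if spec.annotate_psi and fit.psi[i2] > 0:
        ax.set_xlabel(f"Dim {d1} (psi ratio {fit.psi[i1] / fit.psi[i2]:.2f})")
        ax.set_ylabel(f"Dim {d2} (psi ratio 1.00)")
    out = Path(spec.output)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    _save_layers(out, {
        "samples": pd.DataFrame(
            {"sample": fit.sample_ids, "x": samples[:, 0], "y": samples[:, 1]}
        ),
        "taxa": pd.DataFrame(
            {"taxon": [fit.taxon_ids[j] for j in top],
             "slope_x": slopes[top, 0], "slope_y": slopes[top, 1],
             "length": lengths[top]}
        ),
        "variables": pd.DataFrame(
            {"variable": fit.variable_names, "x": load[:, 0], "y": load[:, 1]}
        ),
    })
    return out


def render_response_curves(
    fit: ConstrainedFit,
    responses: NonparametricResponses,
    spec: PlotSpec,
) -> Path:
    """One-dimensional triplot: smooth taxon responses along the first gradient.

    Shows the top-k most responsive taxa (largest curve range), a horizontal
    reference line at zero departure from homogeneity, a rug of sample
    scores, and the variable loadings positioned along the gradient axis.
    """
    if spec.top_k_taxa > responses.curves.shape[0]:
        raise ValueError("top_k_taxa exceeds the number of taxa")
    ranges = responses.curves.max(axis=1) - responses.curves.min(axis=1)
    top = np.argsort(-ranges)[: spec.top_k_taxa]
    fig, ax = plt.subplots(figsize=(7, 5))
    for j in top:
        ax.plot(responses.grid, responses.curves[j], lw=1.2,
                label=responses.taxon_ids[j])
    ax.axhline(0.0, color="0.4", ls=":", lw=1.0)  # homogeneity reference
    ax.plot(responses.h, np.full_like(responses.h, ax.get_ylim()[0]), "|",
            color="0.2", ms=10)
    span = float(np.abs(responses.grid).max())
    for name, a in zip(fit.variable_names, fit.A[:, 0]):
        ax.text(a * span, ax.get_ylim()[1] * 0.95, name, fontsize=8,
                color="navy", ha="center")
    ax.set_xlabel("environmental score (dim 1)")
    ax.set_ylabel("log departure from homogeneity")
    ax.legend(fontsize=7, frameon=False)
    out = Path(spec.output)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    _save_layers(out, {
        "curves": pd.DataFrame(
            responses.curves[top].T,
            columns=[responses.taxon_ids[j] for j in top],
        ).assign(grid=responses.grid),
        "rug": pd.DataFrame({"h": responses.h}),
        "variables": pd.DataFrame(
            {"variable": fit.variable_names, "loading": fit.A[:, 0]}
        ),
    })
    return out
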