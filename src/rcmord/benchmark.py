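"""Replicate benchmarks: scenarios x ordination methods x evaluation metrics."""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Callable

import numpy as np
import pandas as pd

from .data import CountTable, filter_taxa
from .metrics import EvalReport, libsize_correlation, pseudo_F, silhouette_score, taxon_ratio
from .simulate import ScenarioSpec, generate

__all__ = ["rcm_method", "run_benchmark", "aggregate_benchmark"]

#: an ordination method maps a CountTable to (scaled sample scores n x m,
#: taxon scores p x m or None, psi or None)
OrdinationMethod = Callable[[CountTable], tuple[np.ndarray, np.ndarray | None, np.ndarray | None]]


def rcm_method(M: int = 2, **kwargs) -> OrdinationMethod:
    """The package's own unconstrained ordination as a benchmark callable."""
    from .unconstrained import fit_unconstrained

    def method(ct: CountTable):
        fit = fit_unconstrained(ct, M=M, **kwargs)
        return fit.R * fit.psi, fit.S, fit.psi

    method.__name__ = f"RCM_M{M}"
    return method


def evaluate(
    scores: np.ndarray,
    taxon_scores: np.ndarray | None,
    psi: np.ndarray | None,
    sim,
    taxon_index: np.ndarray,
) -> EvalReport:
    """Compute all metrics for one ordination of one simulated dataset."""
    labels = sim.group_labels
    sil = silhouette_score(scores, labels)
    pf = pseudo_F(scores, labels)
    if taxon_scores is not None and sim.da_mask.any():
        m = scores.shape[1]
        psi_u = np.ones(m) if psi is None else np.asarray(psi, dtype=float)
        # scores are already psi-scaled; divide out for the (psi, R, S) triple
        R = np.where(psi_u > 0, scores / np.where(psi_u > 0, psi_u, 1.0), scores)
        tr = taxon_ratio(psi_u, R, taxon_scores, sim.da_mask[taxon_index], labels)
    else:
        tr = float("nan")
    lc = libsize_correlation(scores, sim.counts.lib_sizes)
    return EvalReport(silhouette=sil, pseudo_F=pf, taxon_ratio=tr, libsize_cor=lc)


def run_benchmark(
    specs: list[ScenarioSpec],
    methods: dict[str, OrdinationMethod],
    n_reps: int = 20,
    seed: int = 0,
    prevalence_min: float = 0.05,
    totalcount_min_frac: float = 0.10,
) -> pd.DataFrame:
    """Run every method on ``n_reps`` replicates of every scenario.

    Returns a tidy table with one row per replicate x scenario x method;
    method failures are recorded as missing rows' NaN metrics and the run
    continues.  Replicate seeds derive deterministically from ``seed``.
    """
    rows = []
    for spec in specs:
        for rep in range(n_reps):
            from .simulate import SCENARIOS

            scen_id = SCENARIOS.index(spec.name)
            sim = generate(replace(spec, seed=int(seed) * 100_000 + scen_id * 1000 + rep))
            filtered = filter_taxa(sim.counts, prevalence_min, totalcount_min_frac)
            tindex = np.array(
                [sim.counts.taxon_ids.index(t) for t in filtered.taxon_ids]
            )
            for name, method in methods.items():
                row = {"scenario": spec.name, "rep": rep, "method": name}
                try:
                    scores, taxa, psi = method(filtered)
                    rep_eval = evaluate(scores, taxa, psi, sim, tindex)
                    row.update(rep_eval.as_dict())
                except Exception as exc:  # noqa: BLE001 - record and continue
                    warnings.warn(
                        f"method {name} failed on {spec.name} rep {rep}: {exc}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    row.update({"silhouette": np.nan, "pseudo_F": np.nan,
                                "taxon_ratio": np.nan})
                rows.append(row)
    return pd.DataFrame(rows)


def aggregate_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of every metric per scenario x method."""
    metrics = [c for c in table.columns if c not in ("scenario", "rep", "method")]
    grouped = table.groupby(["scenario", "method"])[metrics]
    med = grouped.median().add_suffix("_median")
    q1 = grouped.quantile(0.25).add_suffix("_q25")
    q3 = grouped.quantile(0.75).add_suffix("_q75")
    return pd.concat([med, q1, q3], axis=1).reset_index()
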