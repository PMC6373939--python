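"""JSON serialisation of fitted ordinations and TSV score exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constrained import ConstrainedFit
from .data import CountTable
from .null import NullFit
from .unconstrained import UnconstrainedFit

__all__ = ["save_fit", "load_fit", "export_scores"]


def _arr(a):
    return np.asarray(a).tolist()


def _null_dict(null: NullFit) -> dict:
    return {
        "u": _arr(null.u), "v": _arr(null.v), "zeta": _arr(null.zeta),
        "phi": _arr(null.phi), "deviance": null.deviance, "G": _arr(null.G),
        "confounder_names": null.confounder_names,
        "iterations": null.iterations, "trace": list(null.trace),
    }


def _null_from(d: dict) -> NullFit:
    return NullFit(
        u=np.array(d["u"]), v=np.array(d["v"]),
        zeta=np.array(d["zeta"]).reshape(len(d["v"]), -1),
        phi=np.array(d["phi"]), deviance=d["deviance"],
        G=np.array(d["G"]).reshape(len(d["u"]), -1),
        confounder_names=list(d["confounder_names"]),
        iterations=d["iterations"], trace=list(d["trace"]),
    )


def save_fit(fit: UnconstrainedFit | ConstrainedFit, path) -> Path:
    """Write a fit (including its count table) as a single JSON document."""
    path = Path(path)
    doc: dict = {
        "M": fit.M, "psi": _arr(fit.psi), "null": _null_dict(fit.null),
        "sample_ids": list(fit.sample_ids), "taxon_ids": list(fit.taxon_ids),
        "converged": [bool(c) for c in fit.converged],
    }
    if fit.counts is not None:
        doc["counts"] = _arr(fit.counts.X)
    if isinstance(fit, ConstrainedFit):
        doc["kind"] = "constrained"
        doc.update({
            "A": _arr(fit.A), "family": fit.family,
            "beta0": _arr(fit.beta0), "beta1": _arr(fit.beta1),
            "beta2": None if fit.beta2 is None else _arr(fit.beta2),
            "common_B": _arr(fit.common_B), "C": _arr(fit.C),
            "variable_names": list(fit.variable_names),
            "lr_trace": [list(t) for t in fit.lr_trace],
        })
    else:
        doc["kind"] = "unconstrained"
        doc.update({
            "R": _arr(fit.R), "S": _arr(fit.S), "deviance": fit.deviance,
            "deviance_traces": [list(t) for t in fit.deviance_traces],
        })
    path.write_text(json.dumps(doc))
    return path


def load_fit(path) -> UnconstrainedFit | ConstrainedFit:
    doc = json.loads(Path(path).read_text())
    null = _null_from(doc["null"])
    counts = None
    if "counts" in doc:
        counts = CountTable(
            np.array(doc["counts"]), doc["sample_ids"], doc["taxon_ids"]
        )
    common = dict(
        M=doc["M"], psi=np.array(doc["psi"]), null=null,
        sample_ids=list(doc["sample_ids"]), taxon_ids=list(doc["taxon_ids"]),
        converged=list(doc["converged"]), counts=counts,
    )
    if doc["kind"] == "constrained":
        return ConstrainedFit(
            A=np.array(doc["A"]), family=doc["family"],
            beta0=np.array(doc["beta0"]), beta1=np.array(doc["beta1"]),
            beta2=None if doc["beta2"] is None else np.array(doc["beta2"]),
            common_B=np.array(doc["common_B"]),
            C=np.array(doc["C"]).reshape(len(doc["sample_ids"]), -1),
            variable_names=list(doc["variable_names"]),
            lr_trace=[list(t) for t in doc["lr_trace"]],
            **common,
        )
    return UnconstrainedFit(
        R=np.array(doc["R"]), S=np.array(doc["S"]), deviance=doc["deviance"],
        deviance_traces=[list(t) for t in doc["deviance_traces"]],
        **common,
    )


def export_scores(fit: UnconstrainedFit | ConstrainedFit, prefix) -> list[Path]:
    """Write sample and taxon score TSVs (and variable loadings if constrained)."""
    prefix = Path(prefix)
    written = []
    if isinstance(fit, ConstrainedFit):
        H = fit.H
        samp = pd.DataFrame(
            H * fit.psi, index=fit.sample_ids,
            columns=[f"dim{m + 1}" for m in range(fit.M)],
        )
        tax = pd.DataFrame(
            fit.beta1, index=fit.taxon_ids,
            columns=[f"slope_dim{m + 1}" for m in range(fit.M)],
        )
        var = pd.DataFrame(
            fit.A, index=fit.variable_names,
            columns=[f"dim{m + 1}" for m in range(fit.M)],
        )
        p = prefix.with_suffix(".variables.tsv")
        var.to_csv(p, sep="\t")
        written.append(p)
    else:
        samp = pd.DataFrame(
            fit.R * fit.psi, index=fit.sample_ids,
            columns=[f"dim{m + 1}" for m in range(fit.M)],
        )
        tax = pd.DataFrame(
            fit.S, index=fit.taxon_ids,
            columns=[f"dim{m + 1}" for m in range(fit.M)],
        )
    p = prefix.with_suffix(".samples.tsv")
    samp.to_csv(p, sep="\t")
    written.append(p)
    p = prefix.with_suffix(".taxa.tsv")
    tax.to_csv(p, sep="\t")
    written.append(p)
    return written
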