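"""Deviance-residual and influence diagnostics for fitted ordinations.

Deviance residuals expose cells, samples or taxa the model fits poorly and
reveal response-function misspecification when plotted against the first
environmental gradient.  Influence values identify samples with a dominant
pull on a chosen gradient coefficient, via a one-step case-deletion
approximation (an exact leave-one-out refit mode exists for validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constrained import ConstrainedFit, fit_constrained
from .data import CountTable, SampleData
from .nb import MU_FLOOR, nb_deviance_residual, nb_working_weights
from .unconstrained import UnconstrainedFit

__all__ = ["DiagnosticsReport", "residual_report", "influence_on_parameter"]


@dataclass
class DiagnosticsReport:
    residuals: np.ndarray  # n x p deviance residuals
    sample_deviance: np.ndarray  # per-sample sum of squared residuals
    taxon_deviance: np.ndarray  # per-taxon sum of squared residuals
    h_order: np.ndarray | None = None  # sample order by first gradient (constrained)
    sample_ids: list[str] | None = None
    taxon_ids: list[str] | None = None

    @property
    def total_deviance(self) -> float:
        return float(np.sum(self.residuals**2))


def residual_report(fit: UnconstrainedFit | ConstrainedFit) -> DiagnosticsReport:
    """Cellwise NB deviance residuals at the fitted means and dispersions.

    Per-sample and per-taxon aggregates both sum to the total model deviance.
    For constrained fits the report carries the sample ordering along the
    first environmental gradient for linearity inspection.
    """
    if not all(fit.converged):
        raise ValueError(
            "fit did not converge in every dimension; inspect the deviance/"
            "criterion traces before computing diagnostics"
        )
    if fit.counts is None:
        raise ValueError("fit does not carry its count table")
    X = fit.counts.X
    Mu = np.maximum(fit.mu, MU_FLOOR)
    phi = fit.null.phi
    res = nb_deviance_residual(X, Mu, phi[None, :])
    h_order = None
    if isinstance(fit, ConstrainedFit):
        h_order = np.argsort(fit.H[:, 0])
    return DiagnosticsReport(
        residuals=res,
        sample_deviance=(res**2).sum(axis=1),
        taxon_deviance=(res**2).sum(axis=0),
        h_order=h_order,
        sample_ids=list(fit.sample_ids),
        taxon_ids=list(fit.taxon_ids),
    )


def _criterion_pieces(fit: ConstrainedFit, m: int = 0):
    """Residuals, weights and derivative terms of the LR criterion in dim m.

    Returns everything the influence linearisation needs: per-cell residual
    and weight matrices for the taxon-specific and common-response models,
    the response designs ``Z`` and ``dZ/dh``, and the per-cell derivatives of
    the linear predictor with respect to the environmental score.
    """
    X = fit.counts.X.astype(float)
    phi = fit.null.phi[None, :]
    h = fit.H[:, m]
    psi = fit.psi[m]
    b1 = psi * fit.beta1[:, m]
    b0 = psi * fit.beta0[:, m]
    base = fit.null.offsets
    # other dimensions' responses stay in the offsets
    full = fit.response_eta()
    this = b0[None, :] + np.outer(h, b1)
    if fit.beta2 is not None:
        b2 = psi * fit.beta2[:, m]
        this = this + np.outer(h**2, b2)
    else:
        b2 = np.zeros_like(b1)
    off = base + (full - this)

    Mu_s = np.exp(off + this)
    r_s = (X - Mu_s) / (1.0 + phi * Mu_s)
    # observed information -d(resid)/d(eta): more faithful case-deletion
    # curvature than the Fisher weights when counts sit far from their means
    w_s = Mu_s * (1.0 + phi * X) / (1.0 + phi * Mu_s) ** 2
    g = fit.common_B[m]
    quad = len(g) > 2
    zc = g[0] + g[1] * h + (g[2] * h**2 if quad else 0.0)
    Mu_c = np.exp(off + zc[:, None])
    r_c = (X - Mu_c) / (1.0 + phi * Mu_c)
    w_c = Mu_c * (1.0 + phi * X) / (1.0 + phi * Mu_c) ** 2
    deta_s = b1[None, :] + 2.0 * np.outer(h, b2)  # d eta_spec / d h
    g2 = g[2] if quad else 0.0
    deta_c = g[1] + 2.0 * g2 * h  # n-vector
    if quad:
        Z = np.column_stack([np.ones_like(h), h, h**2])
        dZ = np.column_stack([np.zeros_like(h), np.ones_like(h), 2.0 * h])
    else:
        Z = np.column_stack([np.ones_like(h), h])
        dZ = np.column_stack([np.zeros_like(h), np.ones_like(h)])
    return r_s, w_s, deta_s, r_c, w_c, deta_c, Z, dZ


def influence_on_parameter(
    fit: ConstrainedFit,
    target: str,
    dim: int = 1,
    exact: bool = False,
    sd: SampleData | None = None,
    **refit_kwargs,
) -> np.ndarray:
    """Per-sample influence on one entry of an environmental gradient.

    Returns, for each sample, the (approximate) change ``alpha_hat -
    alpha_hat_without_sample`` in the targeted coefficient: positive values
    mean the sample pulls the coefficient upward.  The default is a one-step
    case-deletion approximation from the criterion's score and curvature;
    ``exact=True`` performs a full leave-one-out refit per sample (slow,
    validation only; requires ``sd``).
    """
    if target not in fit.variable_names:
        raise ValueError(
            f"unknown target {target!r}; available: {fit.variable_names}"
        )
    lidx = fit.variable_names.index(target)
    m = dim - 1
    if not 0 <= m < fit.M:
        raise ValueError(f"dim {dim} out of range for M={fit.M}")

    if exact:
        if sd is None or fit.counts is None:
            raise ValueError("exact mode needs the SampleData used for the fit")
        ct = fit.counts
        full = fit.A[:, m]
        # hold dispersions at the full-data estimates, as in classical
        # case-deletion diagnostics (the dispersion is a fixed nuisance)
        refit_kwargs.setdefault("fix_phi", fit.null.phi)
        out = np.empty(ct.n)
        for i in range(ct.n):
            keep = [k for k in range(ct.n) if k != i]
            ct_i = CountTable(
                ct.X[keep], [ct.sample_ids[k] for k in keep], ct.taxon_ids
            )
            sd_i = SampleData(
                Q=sd.Q.iloc[keep], column_roles=sd.column_roles,
                coding_map=sd.coding_map,
            )
            refit = fit_constrained(
                ct_i, sd_i, M=fit.M, family=fit.family, **refit_kwargs
            )
            a = refit.A[:, m]
            if a @ full < 0:  # sign indeterminacy across refits
                a = -a
            out[i] = full[lidx] - a[lidx]
        return out

    # The gradient, the per-taxon response coefficients and the common
    # response jointly solve an estimating-equation system; the influence of
    # deleting sample i is the first-order change J^{-1} U_i of that system,
    # reduced to the gradient block by a Schur complement.  Using the joint
    # system (rather than the gradient score alone) accounts for the
    # response coefficients re-adjusting after deletion.
    C = fit.C
    n, d = C.shape
    r_s, w_s, deta_s, r_c, w_c, deta_c, Z, dZ = _criterion_pieces(fit, m)
    p = r_s.shape[1]
    q = Z.shape[1]
    rc_row = r_c.sum(axis=1)  # n
    wc_row = w_c.sum(axis=1)

    # tangent basis for alpha: row space of C minus this and earlier gradients
    _, s, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt[: int(np.sum(s > 1e-10 * s[0]))].T
    Tb = V.copy()
    for k in range(m + 1):
        a = fit.A[:, k]
        Tb = Tb - np.outer(a, a @ Tb)
    Q, Rq = np.linalg.qr(Tb)
    T = Q[:, np.abs(np.diag(Rq)) > 1e-8]  # d x t

    # cross blocks d(score_Bj)/d(alpha) and the alpha-alpha curvature
    M1 = (-w_s * deta_s)[:, :, None] * Z[:, None, :] + r_s[:, :, None] * dZ[:, None, :]
    J_aB = np.einsum("ijq,id->jdq", M1, C)  # p x d x q  (= J_Bj,alpha^T)
    D = -np.einsum("iq,ij,ir->jqr", Z, w_s, Z)  # p x q x q
    D = D - 1e-9 * np.eye(q)[None]
    curv_a = -(w_s * deta_s**2).sum(axis=1) + (w_c * deta_c[:, None] ** 2).sum(axis=1)
    # residual second-order terms (2*beta2 parts) vanish for linear responses
    if fit.beta2 is not None:
        b2 = fit.psi[m] * fit.beta2[:, m]
        g2 = fit.common_B[m][2]
        curv_a = curv_a + 2.0 * (r_s @ b2) - 2.0 * g2 * rc_row
    J_aa = (C * curv_a[:, None]).T @ C  # d x d
    Mc = (-(w_c * deta_c[:, None]))[:, :, None] * Z[:, None, :] \
        + r_c[:, :, None] * dZ[:, None, :]
    J_ag = -np.einsum("ijq,id->dq", Mc, C)  # d x q (common enters with minus)
    D_c = -(Z.T * wc_row) @ Z - 1e-9 * np.eye(q)

    Ta = T.T  # t x d
    t_dim = T.shape[1]
    # per-sample contributions to every curvature block, so the one-step can
    # use the case-deleted curvature J - J_i (the DFBETA leverage correction;
    # without it the influence of high-leverage samples is underestimated)
    ZZ = Z[:, :, None] * Z[:, None, :]  # n x q x q
    D_i = -(w_s.T[:, :, None, None] * ZZ[None])  # p x n x q x q
    J_aB_i = np.einsum("id,ijq->jidq", C, M1)  # p x n x d x q
    J_aa_i = curv_a[:, None, None] * (C[:, :, None] * C[:, None, :])  # n x d x d
    J_ag_i = -np.einsum("id,ijq->idq", C, Mc)  # n x d x q
    Dc_i = -wc_row[:, None, None] * ZZ  # n x q x q

    D_full = D  # p x q x q (already regularised)
    Dc_full = D_c
    J_aa_full = J_aa
    J_aB_full = J_aB  # p x d x q
    J_ag_full = J_ag

    # per-sample scores of the joint system
    U_a = C * ((r_s * deta_s).sum(axis=1) - deta_c * rc_row)[:, None]  # n x d
    U_B = Z[:, None, :] * r_s[:, :, None]  # n x p x q
    U_g = Z * rc_row[:, None]  # n x q

    delta = np.empty(n)
    for i in range(n):
        Dl = D_full - D_i[:, i]  # p x q x q
        Dcl = Dc_full - Dc_i[i]
        Jab = J_aB_full - J_aB_i[:, i]
        Jaa = J_aa_full - J_aa_i[i]
        Jag = J_ag_full - J_ag_i[i]
        K = np.einsum("ts,jsq->jtq", Ta, Jab)
        Dinv = np.linalg.inv(Dl)
        KD = np.einsum("jtq,jqr->jtr", K, Dinv)
        S = Ta @ Jaa @ T - np.einsum("jtq,juq->tu", KD, K)
        Kg = Ta @ Jag
        Dc_inv = np.linalg.inv(Dcl)
        S = S - Kg @ Dc_inv @ (-Jag.T @ T)
        rhs = Ta @ U_a[i] \
            - np.einsum("jtq,jq->t", KD, U_B[i]) \
            - Kg @ Dc_inv @ U_g[i]
        delta_t = np.linalg.solve(S, rhs)  # alpha_(i) - alpha_hat in tangent
        delta[i] = (T @ delta_t)[lidx]
    return -delta
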