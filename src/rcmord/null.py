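"""Independence and extended (confounder-adjusted) null models.

The independence model ``log E(X_ij) = u_i + v_j`` describes the counts under
sample homogeneity: identical taxa composition in every sample, with
``exp(u_i)`` an effective sequencing depth and ``exp(v_j)`` the mean relative
abundance of taxon ``j`` (the identifiability constraint ``sum_j exp(v_j) = 1``
fixes the split).  The extended null model adds per-taxon confounder terms
``sum_l zeta_jl g_il`` so that later interaction terms are free of known
technical effects such as batch or sequencing centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import CountTable, SampleData
from .nb import MU_FLOOR, estimate_dispersions, nb_unit_deviance, nb_working_weights

__all__ = ["NullFit", "ConvergenceError", "fit_independence", "fit_extended_null"]


class ConvergenceError(RuntimeError):
    """Raised when an alternating fit exhausts its iteration budget.

    Carries the deviance trace so the failure can be inspected.
    """

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message} (deviance trace: {trace})")
        self.trace = trace


def table_deviance(X: np.ndarray, Mu: np.ndarray, phi: np.ndarray) -> float:
    """Total NB deviance of a fitted table; ``phi`` is per taxon (length p)."""
    return float(
        np.sum(nb_unit_deviance(X, np.maximum(Mu, MU_FLOOR), phi[None, :], validate=False))
    )


@dataclass
class NullFit:
    """Parameters of the (extended) null model."""

    u: np.ndarray
    v: np.ndarray
    zeta: np.ndarray  # p x k (k = 0 when no confounders)
    phi: np.ndarray
    deviance: float
    G: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    confounder_names: list[str] = field(default_factory=list)
    iterations: int = 0
    trace: list[float] = field(default_factory=list)

    @property
    def offsets(self) -> np.ndarray:
        """n x p log-mean matrix u_i + v_j + sum_l zeta_jl g_il."""
        eta = self.u[:, None] + self.v[None, :]
        if self.zeta.size:
            eta = eta + self.G @ self.zeta.T
        return eta

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.offsets)


def _newton_axis(X, Mu, phi2d, axis):
    """Newton step for the per-sample (axis=1) or per-taxon (axis=0) intercepts."""
    resid = (X - Mu) / (1.0 + phi2d * Mu)
    w = nb_working_weights(Mu, phi2d)
    score = resid.sum(axis=axis)
    info = np.maximum(w.sum(axis=axis), MU_FLOOR)
    return score / info


def _normalize_uv(u, v):
    """Shift so that sum_j exp(v_j) = 1; the scale moves into u."""
    s = logsumexp(v)
    return u + s, v - s


def _halving_sweep(X, phi2d, phi, eta_fn, params, steps, dev_prev, max_halvings=20):
    """Apply additive steps to params, halving until deviance does not increase."""
    scale = 1.0
    for _ in range(max_halvings):
        trial = [p + scale * s for p, s in zip(params, steps)]
        dev = table_deviance(X, np.exp(eta_fn(*trial)), phi)
        if dev <= dev_prev * (1 + 1e-12):
            return trial, dev
        scale *= 0.5
    return params, dev_prev


def _fit_uv(X, phi, u, v, tol, max_iter):
    """Alternating Newton updates of (u, v) at fixed dispersions."""
    phi2d = phi[None, :]
    trace = []
    dev = table_deviance(X, np.exp(u[:, None] + v[None, :]), phi)
    for it in range(max_iter):
        Mu = np.exp(u[:, None] + v[None, :])
        du = _newton_axis(X, Mu, phi2d, axis=1)
        (u,), dev = _halving_sweep(
            X, phi2d, phi, lambda uu: uu[:, None] + v[None, :], [u], [du], dev
        )
        Mu = np.exp(u[:, None] + v[None, :])
        dv = _newton_axis(X, Mu, phi2d, axis=0)
        (v,), dev = _halving_sweep(
            X, phi2d, phi, lambda vv: u[:, None] + vv[None, :], [v], [dv], dev
        )
        trace.append(dev)
        if it > 0 and abs(trace[-2] - dev) <= tol * max(abs(trace[-2]), 1e-12):
            u, v = _normalize_uv(u, v)
            return u, v, dev, it + 1, trace
    raise ConvergenceError("independence model did not converge", trace)


def fit_independence(
    ct: CountTable,
    phi_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    prior_df: float = 10.0,
    estimate_phi: bool = True,
) -> NullFit:
    """Maximum-likelihood fit of the independence model ``u_i + v_j``.

    Starts from the Poisson closed-form solution (``exp(u_i)`` the library
    size, ``exp(v_j)`` the taxon's overall relative abundance), alternates
    Newton updates under the NB likelihood, then re-estimates taxon-wise
    dispersions given the fitted means and refits once.
    """
    X = ct.X.astype(float)
    n, p = X.shape
    lib = X.sum(axis=1)
    col = X.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("empty samples present; run filter_taxa first")
    u = np.log(lib)
    v = np.log(np.maximum(col, 0.5)) - np.log(lib.sum())
    u, v = _normalize_uv(u, v)
    phi = np.zeros(p) if phi_init is None else np.asarray(phi_init, dtype=float)

    u, v, dev, its, trace = _fit_uv(X, phi, u, v, tol, max_iter)
    if estimate_phi:
        phi = estimate_dispersions(X, np.exp(u[:, None] + v[None, :]), prior_df)
        u, v, dev, its2, trace2 = _fit_uv(X, phi, u, v, tol, max_iter)
        its += its2
        trace = trace + trace2
    return NullFit(
        u=u, v=v, zeta=np.zeros((p, 0)), phi=phi, deviance=dev,
        iterations=its, trace=trace,
    )


def _check_confounders(G: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop structurally-zero columns; error on remaining collinearity."""
    nonzero = np.ptp(G, axis=0) > 0
    G = G[:, nonzero]
    names = [nm for nm, keep in zip(names, nonzero) if keep]
    if G.shape[1] == 0:
        return G, names
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[1]:
        # identify dependent columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(G, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        dependent = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        dependent += [names[j] for j in piv[len(diag):]]
        raise ValueError(f"confounder columns are collinear: {sorted(set(dependent))}")
    return G, names


def _zeta_newton(X, Mu, phi2d, G):
    """Batched per-taxon Newton step for the confounder coefficients."""
    resid = (X - Mu) / (1.0 + phi2d * Mu)
    W = nb_working_weights(Mu, phi2d)
    score = G.T @ resid  # k x p
    info = np.einsum("ik,ij,il->jkl", G, W, G)  # p x k x k
    k = G.shape[1]
    info = info + 1e-10 * np.eye(k)[None, :, :]
    return np.linalg.solve(info, score.T[:, :, None])[:, :, 0]  # p x k


def fit_extended_null(
    ct: CountTable,
    sd: SampleData,
    phi_init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    prior_df: float = 10.0,
    estimate_phi: bool = True,
) -> NullFit:
    """Fit ``log E(X_ij) = u_i + v_j + sum_l zeta_jl g_il``.

    Confounder columns are mean-centred (from :attr:`SampleData.G`) so the
    confounder terms average out per taxon; the per-taxon coefficient vectors
    ``zeta_j`` absorb systematic departures driven by the confounders, leaving
    the downstream interaction terms conditioned on them.
    """
    Gdf = sd.G
    G_raw, names = _check_confounders(Gdf.to_numpy(), list(Gdf.columns))
    X = ct.X.astype(float)
    n, p = X.shape
    if G_raw.shape[1] == 0:
        base = fit_independence(ct, phi_init, tol, max_iter, prior_df, estimate_phi)
        return base

    G = G_raw
    k = G.shape[1]
    base = fit_independence(ct, phi_init, tol, max_iter, prior_df, estimate_phi=False)
    u, v = base.u.copy(), base.v.copy()
    zeta = np.zeros((p, k))
    phi = np.zeros(p) if phi_init is None else np.asarray(phi_init, dtype=float)

    def run(u, v, zeta, phi):
        phi2d = phi[None, :]

        def eta(u, v, zeta):
            return u[:, None] + v[None, :] + G @ zeta.T

        trace = []
        dev = table_deviance(X, np.exp(eta(u, v, zeta)), phi)
        for it in range(max_iter):
            Mu = np.exp(eta(u, v, zeta))
            du = _newton_axis(X, Mu, phi2d, axis=1)
            (u,), dev = _halving_sweep(
                X, phi2d, phi, lambda uu: eta(uu, v, zeta), [u], [du], dev
            )
            Mu = np.exp(eta(u, v, zeta))
            dv = _newton_axis(X, Mu, phi2d, axis=0)
            (v,), dev = _halving_sweep(
                X, phi2d, phi, lambda vv: eta(u, vv, zeta), [v], [dv], dev
            )
            Mu = np.exp(eta(u, v, zeta))
            dz = _zeta_newton(X, Mu, phi2d, G)
            (zeta,), dev = _halving_sweep(
                X, phi2d, phi, lambda zz: eta(u, v, zz), [zeta], [dz], dev
            )
            trace.append(dev)
            if it > 0 and abs(trace[-2] - dev) <= tol * max(abs(trace[-2]), 1e-12):
                u, v = _normalize_uv(u, v)
                return u, v, zeta, dev, it + 1, trace
        raise ConvergenceError("extended null model did not converge", trace)

    u, v, zeta, dev, its, trace = run(u, v, zeta, phi)
    if estimate_phi:
        Mu = np.exp(u[:, None] + v[None, :] + G @ zeta.T)
        phi = estimate_dispersions(X, Mu, prior_df)
        u, v, zeta, dev, its2, trace2 = run(u, v, zeta, phi)
        its += its2
        trace = trace + trace2
    return NullFit(
        u=u, v=v, zeta=zeta, phi=phi, deviance=dev, G=G,
        confounder_names=names, iterations=its, trace=trace,
    )
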