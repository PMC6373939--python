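"""Unconstrained RC(M) ordination: negative-binomial row-column interaction fit.

The mean model is

    log E(X_ij) = u_i + v_j [+ sum_l zeta_jl g_il] + sum_m psi_m r_im s_jm

with sample scores ``r``, taxon scores ``s`` and importance parameters
``psi_m >= 0``.  Scores are centred, unit-norm and orthogonal across
dimensions; the overall interaction strength per dimension lives in
``psi_m``.  Dimensions are fitted sequentially (greedily), each by
alternating damped Newton updates of the sample intercepts, taxon
intercepts, taxon scores and sample scores.  Centring is applied as an exact
reparametrisation (score means are absorbed into ``u`` and ``v``), so the
deviance trace is monotone by construction; orthogonality against previously
fitted dimensions is maintained by restricting score update steps to the
orthogonal complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CountTable, SampleData
from .nb import MU_FLOOR, estimate_dispersions, nb_working_weights
from .null import ConvergenceError, NullFit, fit_extended_null, fit_independence, table_deviance

__all__ = ["UnconstrainedFit", "fit_unconstrained", "normalize_scores", "biplot_coordinates"]


@dataclass
class UnconstrainedFit:
    M: int
    psi: np.ndarray
    R: np.ndarray  # n x M sample scores
    S: np.ndarray  # p x M taxon scores
    null: NullFit
    deviance: float
    deviance_traces: list[list[float]] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    taxon_ids: list[str] = field(default_factory=list)
    counts: "CountTable | None" = None

    @property
    def interaction(self) -> np.ndarray:
        """n x p matrix of fitted departures sum_m psi_m r_im s_jm."""
        return (self.R * self.psi) @ self.S.T

    @property
    def offsets(self) -> np.ndarray:
        return self.null.offsets + self.interaction

    @property
    def mu(self) -> np.ndarray:
        return np.exp(self.offsets)


def normalize_scores(
    raw_r: np.ndarray,
    raw_s: np.ndarray,
    previous_R: np.ndarray | None = None,
    previous_S: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Centre, orthogonalise and unit-normalise a raw score pair.

    Returns ``(r, s, scale)`` where ``scale`` (the psi contribution) is the
    product of the norms removed from the two vectors.  The sign convention
    makes the taxon with the largest absolute score positive; both vectors
    flip together so the interaction term is unchanged and the scale stays
    non-negative.
    """
    r = np.asarray(raw_r, dtype=float).copy()
    s = np.asarray(raw_s, dtype=float).copy()
    r -= r.mean()
    s -= s.mean()
    if previous_R is not None and previous_R.size:
        r -= previous_R @ (previous_R.T @ r)
    if previous_S is not None and previous_S.size:
        s -= previous_S @ (previous_S.T @ s)
    nr, ns = np.linalg.norm(r), np.linalg.norm(s)
    if nr < 1e-12 or ns < 1e-12:
        raise ValueError("degenerate (constant or fully projected-out) score vector")
    r /= nr
    s /= ns
    # sign convention: the taxon with the largest |score| ends up positive
    # (ties resolved to the last such taxon)
    lead = len(s) - 1 - int(np.argmax(np.abs(s)[::-1]))
    if s[lead] < 0:
        r, s = -r, -s
    return r, s, float(nr * ns)


def _orth_basis(vectors: list[np.ndarray], size: int) -> np.ndarray:
    if not vectors:
        return np.zeros((size, 0))
    return np.column_stack(vectors)


def _project_out(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    if basis.shape[1] == 0:
        return x
    return x - basis @ (basis.T @ x)


def _init_scores(X, Mu, phi, rng, prev_r, prev_s):
    """First singular pair of the deviance-residual matrix, projected to the
    admissible subspace; seeded jitter if degenerate."""
    from .nb import nb_deviance_residual

    resid = nb_deviance_residual(X, np.maximum(Mu, MU_FLOOR), phi[None, :])
    try:
        U, D, Vt = np.linalg.svd(resid, full_matrices=False)
        a, b = U[:, 0], Vt[0]
    except np.linalg.LinAlgError:  # pragma: no cover - rare
        a = rng.standard_normal(X.shape[0])
        b = rng.standard_normal(X.shape[1])
    a = _project_out(a - a.mean(), prev_r)
    b = _project_out(b - b.mean(), prev_s)
    if np.linalg.norm(a) < 1e-8 or np.linalg.norm(b) < 1e-8:
        a = _project_out(rng.standard_normal(a.size), prev_r)
        b = _project_out(rng.standard_normal(b.size), prev_s)
        a -= a.mean()
        b -= b.mean()
    a /= np.linalg.norm(a)
    b /= np.linalg.norm(b)
    return a, b


def _fit_dimension(X, phi, u, v, fixed_part, prev_r, prev_s, rng, tol, max_iter,
                   psi_guard=None):
    """Fit one interaction dimension a b^T on top of the fixed linear part.

    ``fixed_part`` is the n x p matrix of confounder terms plus previously
    fitted dimensions.  Returns updated (u, v, a, b, trace, converged).

    With zero-heavy tables the interaction likelihood can have a supremum at
    infinite parameters (zero cells reward pushing their means to 0 without
    bound — a separation-type degeneracy).  The score *direction* stabilises
    while the scale keeps growing, so when the interaction scale passes
    ``psi_guard`` the dimension is terminated with a warning and the current
    (finite) parameters are kept.
    """
    n, p = X.shape
    if psi_guard is None:
        psi_guard = 30.0 * np.sqrt(n * p)
    phi2d = phi[None, :]

    def eta(u, v, a, b):
        return u[:, None] + v[None, :] + fixed_part + np.outer(a, b)

    def dev(u, v, a, b):
        return table_deviance(X, np.exp(eta(u, v, a, b)), phi)

    dev_null = dev(u, v, np.zeros(n), np.zeros(p))
    a0, b0 = _init_scores(X, np.exp(u[:, None] + v[None, :] + fixed_part), phi, rng, prev_r, prev_s)
    # scale the initial guess down until it does not increase the deviance
    scale = 0.5
    for _ in range(25):
        if dev(u, v, scale * a0, b0) <= dev_null:
            break
        scale *= 0.5
    else:
        # no descent direction: dimension carries no signal
        return u, v, np.zeros(n), np.zeros(p), [dev_null], False
    a, b = scale * a0, b0.copy()
    cur = dev(u, v, a, b)
    trace = [cur]

    def halved(update, cur):
        """Line search on the step scale: halve until the deviance does not
        increase; if the unit step is accepted, try doubling while it helps
        (accelerates the zigzag of alternating descent on flat surfaces)."""
        cand = update(1.0)
        d = dev(*cand)
        if d <= cur * (1 + 1e-12):
            t = 2.0
            for _ in range(6):
                cand2 = update(t)
                d2 = dev(*cand2)
                if d2 < d:
                    cand, d, t = cand2, d2, t * 2.0
                else:
                    break
            return cand, d
        step = 0.5
        for _ in range(24):
            cand = update(step)
            d = dev(*cand)
            if d <= cur * (1 + 1e-12):
                return cand, d
            step *= 0.5
        return (u, v, a, b), cur

    def joint_step(resid, w, covar, axis):
        """Batched 2x2 Newton step for (intercept, score) pairs along one axis.

        axis=1: per-sample (u_i, a_i) with covariate b; axis=0: per-taxon
        (v_j, b_j) with covariate a.  Solving the pair jointly avoids the
        slow ridge between intercepts and scores.
        """
        if axis == 1:
            s0 = resid.sum(axis=1)
            s1 = resid @ covar
            w0 = w.sum(axis=1)
            w1 = w @ covar
            w2 = w @ covar**2
        else:
            s0 = resid.sum(axis=0)
            s1 = covar @ resid
            w0 = w.sum(axis=0)
            w1 = covar @ w
            w2 = (covar**2) @ w
        det = np.maximum(w0 * w2 - w1**2, MU_FLOOR)
        d_int = (w2 * s0 - w1 * s1) / det
        d_sc = (w0 * s1 - w1 * s0) / det
        return d_int, d_sc

    for it in range(max_iter):
        u_p, v_p, a_p, b_p = u.copy(), v.copy(), a.copy(), b.copy()
        # per-sample joint update of (u_i, a_i) given the taxon scores
        Mu = np.exp(eta(u, v, a, b))
        resid = (X - Mu) / (1.0 + phi2d * Mu)
        w = nb_working_weights(Mu, phi2d)
        du, da = joint_step(resid, w, b, axis=1)
        da = _project_out(da, prev_r)
        (u, v, a, b), cur = halved(lambda t: (u + t * du, v, a + t * da, b), cur)
        abar = a.mean()
        v, a = v + abar * b, a - abar  # exact reparametrisation: recentre a

        # per-taxon joint update of (v_j, b_j) given the sample scores
        Mu = np.exp(eta(u, v, a, b))
        resid = (X - Mu) / (1.0 + phi2d * Mu)
        w = nb_working_weights(Mu, phi2d)
        dv, db = joint_step(resid, w, a, axis=0)
        db = _project_out(db, prev_s)
        (u, v, a, b), cur = halved(lambda t: (u, v + t * dv, a, b + t * db), cur)
        bbar = b.mean()
        u, b = u + bbar * a, b - bbar  # recentre b into the sample intercepts

        # sweep-level extrapolation along the total displacement: alternating
        # block updates zigzag on flat ridges, and all score constraints are
        # linear, so over-stepping the combined direction is feasible
        Du, Dv, Da, Db = u - u_p, v - v_p, a - a_p, b - b_p
        kappa = 1.0
        for _ in range(8):
            cand = (u_p + 2 * kappa * Du, v_p + 2 * kappa * Dv,
                    a_p + 2 * kappa * Da, b_p + 2 * kappa * Db)
            d = dev(*cand)
            if d < cur:
                (u, v, a, b), cur, kappa = cand, d, 2 * kappa
            else:
                break

        # rebalance the scale split between the two score vectors
        na, nb_ = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-10 or nb_ < 1e-10:
            return u, v, np.zeros(n), np.zeros(p), trace + [cur], False
        g = np.sqrt(nb_ / na)
        a, b = a * g, b / g

        trace.append(cur)
        if abs(trace[-2] - cur) <= tol * max(abs(trace[-2]), 1e-12):
            return u, v, a, b, trace, True
        if na * nb_ > psi_guard:
            warnings.warn(
                "interaction scale exceeded the divergence guard "
                f"({na * nb_:.3g} > {psi_guard:.3g}): the likelihood supremum "
                "is not attained (zero-cell separation); keeping the current "
                "finite parameters",
                RuntimeWarning,
                stacklevel=2,
            )
            return u, v, a, b, trace, True
    raise ConvergenceError("interaction dimension did not converge", trace)


def fit_unconstrained(
    ct: CountTable,
    sd: SampleData | None = None,
    M: int = 2,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 200,
    prior_df: float = 10.0,
    refresh_phi: bool = True,
    fix_phi: np.ndarray | None = None,
) -> UnconstrainedFit:
    """Fit the unconstrained RC(M) ordination.

    When ``sd`` carries confounder columns the extended null model is fitted
    first and its confounder terms are held in the offsets, so the estimated
    interaction is conditioned on them.  Dispersions are estimated after the
    null fit and refreshed after each fitted dimension.  ``seed`` only
    affects the fallback jitter used when the deterministic initialisation
    (singular vectors of the null-model Pearson residuals) is degenerate.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    has_conf = sd is not None and any(
        r == "confounder" for r in sd.column_roles.values()
    )
    null_kwargs: dict = {"prior_df": prior_df}
    if fix_phi is not None:
        fix_phi = np.asarray(fix_phi, dtype=float)
        null_kwargs.update(phi_init=fix_phi, estimate_phi=False)
        refresh_phi = False
    null = (
        fit_extended_null(ct, sd, **null_kwargs)
        if has_conf
        else fit_independence(ct, **null_kwargs)
    )
    X = ct.X.astype(float)
    n, p = X.shape
    u, v = null.u.copy(), null.v.copy()
    conf_part = null.G @ null.zeta.T if null.zeta.size else np.zeros((n, p))
    phi = null.phi.copy()

    psi = np.zeros(M)
    R = np.zeros((n, M))
    S = np.zeros((p, M))
    traces: list[list[float]] = []
    converged: list[bool] = []
    for m in range(M):
        prev_r = _orth_basis([R[:, k] for k in range(m) if psi[k] > 0], n)
        prev_s = _orth_basis([S[:, k] for k in range(m) if psi[k] > 0], p)
        fixed = conf_part + (R[:, :m] * psi[:m]) @ S[:, :m].T
        u, v, a, b, trace, ok = _fit_dimension(
            X, phi, u, v, fixed, prev_r, prev_s, rng, tol, max_iter
        )
        traces.append(trace)
        converged.append(ok)
        scale = np.linalg.norm(a) * np.linalg.norm(b)
        if scale < 1e-8:
            warnings.warn(
                f"dimension {m + 1}: interaction strength collapsed to zero; "
                "reported as a null dimension",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        r, s, scale = normalize_scores(a, b, prev_r, prev_s)
        psi[m], R[:, m], S[:, m] = scale, r, s
        if refresh_phi:
            Mu = np.exp(u[:, None] + v[None, :] + fixed + np.outer(a, b))
            phi = estimate_dispersions(X, Mu, prior_df)

    # order dimensions by decreasing importance
    order = np.argsort(-psi, kind="stable")
    psi, R, S = psi[order], R[:, order], S[:, order]
    converged = [converged[k] for k in order]
    traces = [traces[k] for k in order]

    from .null import _normalize_uv

    u, v = _normalize_uv(u, v)
    final_eta = u[:, None] + v[None, :] + conf_part + (R * psi) @ S.T
    final_dev = table_deviance(X, np.exp(final_eta), phi)
    null_out = NullFit(
        u=u, v=v, zeta=null.zeta, phi=phi, deviance=null.deviance,
        G=null.G, confounder_names=null.confounder_names,
        iterations=null.iterations, trace=null.trace,
    )
    return UnconstrainedFit(
        M=M, psi=psi, R=R, S=S, null=null_out, deviance=final_dev,
        deviance_traces=traces, converged=converged,
        sample_ids=ct.sample_ids, taxon_ids=ct.taxon_ids, counts=ct,
    )


def biplot_coordinates(
    fit: UnconstrainedFit, dims: tuple[int, int] = (1, 2)
) -> tuple[np.ndarray, np.ndarray]:
    """Sample points ``psi_m r_im`` and taxon arrows ``s_jm`` for two dimensions.

    The inner product of a taxon arrow with a sample point recovers the
    plotted log-scale departure from homogeneity of that taxon in that
    sample, summed over the two displayed dimensions.
    """
    d1, d2 = dims
    if not (1 <= d1 <= fit.M and 1 <= d2 <= fit.M):
        raise ValueError(f"requested dims {dims} exceed fitted M={fit.M}")
    idx = [d1 - 1, d2 - 1]
    samples = fit.R[:, idx] * fit.psi[idx]
    taxa = fit.S[:, idx]
    return samples, taxa
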