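"""Independent brute-force reference implementations.

These exist to validate the fast alternating-Newton fitting routines and the
evaluation metrics: each function recomputes a quantity by a generic method
(unconstrained quasi-Newton optimisation over an explicit constraint basis,
grid search, naive enumeration) that shares no code with the production path.
They are slow and intended only for small problems.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import nbinom, poisson


def _logpmf(x, mu, phi):
    """NB log-pmf via scipy.stats, Poisson at phi == 0."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), np.broadcast(x, mu).shape)
    out = np.empty(np.broadcast(x, mu).shape)
    z = phi < 1e-12
    if z.any():
        out[z] = poisson.logpmf(np.broadcast_to(x, out.shape)[z],
                                np.broadcast_to(mu, out.shape)[z])
    nz = ~z
    if nz.any():
        k = 1.0 / phi[nz]
        mub = np.broadcast_to(mu, out.shape)[nz]
        out[nz] = nbinom.logpmf(np.broadcast_to(x, out.shape)[nz], k, k / (k + mub))
    return out


def _centered_basis(n: int) -> np.ndarray:
    """Orthonormal basis of the zero-sum subspace of R^n."""
    from scipy.linalg import null_space

    return null_space(np.ones((1, n)))


def brute_force_unconstrained(
    X: np.ndarray,
    phi: np.ndarray,
    n_starts: int = 4,
    seed: int = 123,
) -> dict:
    """Maximum likelihood for the one-dimension row-column interaction model.

    Optimises ``log mu = u + v + a b^T`` over sample effects ``u``, taxon
    effects ``v`` and centred score vectors ``a``, ``b`` (parametrised in an
    explicit zero-sum basis so the centring constraints hold exactly) with
    L-BFGS from several random starts.  Returns the best deviance and the
    saturated log-likelihood used.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    phi = np.asarray(phi, dtype=float)
    Zn = _centered_basis(n)
    Zp = _centered_basis(p)
    lib = X.sum(axis=1)
    col = X.sum(axis=0)

    def unpack(theta):
        u = theta[:n]
        v = theta[n : n + p]
        a = Zn @ theta[n + p : n + p + n - 1]
        b = Zp @ theta[n + p + n - 1 :]
        return u, v, a, b

    def negll_grad(theta):
        u, v, a, b = unpack(theta)
        eta = u[:, None] + v[None, :] + np.outer(a, b)
        mu = np.exp(np.clip(eta, -700, 700))
        ll = float(np.sum(_logpmf(X, np.maximum(mu, 1e-12), phi[None, :])))
        resid = (X - mu) / (1.0 + phi[None, :] * mu)
        g = np.concatenate([
            resid.sum(axis=1),
            resid.sum(axis=0),
            Zn.T @ (resid @ b),
            Zp.T @ (resid.T @ a),
        ])
        return -ll, -g

    rng = np.random.default_rng(seed)
    best = None
    u0 = np.log(np.maximum(lib, 1.0)) - 0.5 * np.log(X.sum())
    v0 = np.log(np.maximum(col, 0.5)) - 0.5 * np.log(X.sum())
    for s in range(n_starts):
        th0 = np.concatenate([
            u0, v0,
            0.1 * rng.standard_normal(n - 1),
            0.1 * rng.standard_normal(p - 1),
        ])
        res = minimize(negll_grad, th0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 5000, "ftol": 1e-14, "gtol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    ll = -best.fun
    # saturated log-likelihood at mu = x (limit 0 contribution at x = 0)
    sat = 0.0
    pos = X > 0
    sat = float(np.sum(_logpmf(X[pos], X[pos],
                               np.broadcast_to(phi[None, :], X.shape)[pos])))
    return {"loglik": ll, "deviance": 2.0 * (sat - ll), "result": best}


def _fit_glm_nb(x, Z, offset, phi, q):
    """Small NB regression by direct likelihood optimisation (BFGS)."""

    def negll(beta):
        eta = offset + Z @ beta
        mu = np.exp(np.clip(eta, -700, 700))
        return -float(np.sum(_logpmf(x, np.maximum(mu, 1e-12), phi)))

    res = minimize(negll, np.zeros(q), method="BFGS",
                   options={"maxiter": 2000, "gtol": 1e-9})
    res2 = minimize(negll, res.x, method="Nelder-Mead",
                    options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12})
    return -min(res.fun, res2.fun)


def constrained_criterion(alpha, X, offsets, phi, C):
    """LR criterion at a given gradient: taxon-specific minus common linear fits."""
    alpha = np.asarray(alpha, dtype=float)
    alpha = alpha / np.linalg.norm(alpha)
    h = C @ alpha
    Z = np.column_stack([np.ones_like(h), h])
    n, p = X.shape
    ll_spec = sum(
        _fit_glm_nb(X[:, j], Z, offsets[:, j], phi[j], 2) for j in range(p)
    )
    # common response: one coefficient pair shared by all taxa
    Zc = np.repeat(Z, p, axis=0)
    ll_com = _fit_glm_nb(
        X.ravel(), Zc, offsets.ravel(),
        np.broadcast_to(phi[None, :], X.shape).ravel(), 2,
    )
    return ll_spec - ll_com


def brute_force_constrained(X, offsets, phi, C, n_grid: int = 36) -> dict:
    """Best likelihood-ratio criterion over all unit gradients for d = 2.

    Scans the half-circle on a grid (alpha and -alpha give the same
    criterion) and refines the best angle by bounded scalar optimisation.
    """
    if C.shape[1] != 2:
        raise ValueError("the exhaustive gradient search supports d = 2 only")

    def crit_theta(theta):
        return constrained_criterion(
            np.array([np.cos(theta), np.sin(theta)]), X, offsets, phi, C
        )

    thetas = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    vals = [crit_theta(t) for t in thetas]
    i = int(np.argmax(vals))
    span = np.pi / n_grid
    res = minimize_scalar(
        lambda t: -crit_theta(t),
        bounds=(thetas[i] - span, thetas[i] + span),
        method="bounded",
        options={"xatol": 1e-6},
    )
    best_theta = res.x if -res.fun > vals[i] else thetas[i]
    best_val = max(-res.fun, vals[i])
    return {
        "criterion": best_val,
        "alpha": np.array([np.cos(best_theta), np.sin(best_theta)]),
        "grid": np.array(vals),
    }


def profile_dispersion_interval(x, mu, level_drop: float = 1.92):
    """Profile-likelihood MLE and ~95% interval for the NB dispersion by grid search."""
    grid = np.exp(np.linspace(np.log(1e-4), np.log(50.0), 600))
    ll = np.array([float(np.sum(_logpmf(x, mu, g))) for g in grid])
    i = int(np.argmax(ll))
    inside = ll >= ll[i] - level_drop
    return grid[i], (grid[inside].min(), grid[inside].max())


# ----------------------------------------------------------------------------
# naive metric implementations (pure-python enumeration)

def naive_silhouette(scores, labels):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    n = scores.shape[0]
    dist = np.array([[np.sqrt(np.sum((scores[i] - scores[k]) ** 2))
                      for k in range(n)] for i in range(n)])
    vals = []
    for i in range(n):
        own = [k for k in range(n) if labels[k] == labels[i] and k != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([dist[i, k] for k in own])
        bs = []
        for lab in np.unique(labels):
            if lab == labels[i]:
                continue
            others = [k for k in range(n) if labels[k] == lab]
            bs.append(np.mean([dist[i, k] for k in others]))
        b = min(bs)
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def naive_pseudo_F(scores, labels):
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    labels = np.asarray(labels)
    uniq = list(np.unique(labels))
    n, g = scores.shape[0], len(uniq)
    grand = scores.mean(axis=0)
    ssb = ssw = 0.0
    for lab in uniq:
        grp = scores[labels == lab]
        cen = grp.mean(axis=0)
        ssb += len(grp) * np.sum((cen - grand) ** 2)
        ssw += np.sum((grp - cen) ** 2)
    return (ssb / (g - 1)) / (ssw / (n - g))


def naive_taxon_ratio(psi, R, S, da_mask, labels):
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    R = np.atleast_2d(np.asarray(R, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    labels = np.asarray(labels)
    groups = list(np.unique(labels))
    num, den = [], []
    for j in range(S.shape[0]):
        for k, lab in enumerate(groups):
            members = np.flatnonzero(labels == lab)
            val = np.mean([
                abs(sum(psi[m] * R[i, m] * S[j, m] for m in range(len(psi))))
                for i in members
            ])
            if da_mask[j].any():
                if da_mask[j, k]:
                    num.append(val)
            else:
                den.append(val)
    return float(np.mean(num)) / float(np.mean(den))


def naive_pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
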