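"""Negative-binomial likelihood machinery shared by all fitting routines.

The NB(2) parameterisation is used throughout: a count ``x`` with mean ``mu``
and taxon-wise dispersion ``phi`` has variance ``mu + phi * mu**2``.  The
size (shape) parameter of the classical NB pmf is ``1/phi``; ``phi = 0``
recovers the Poisson distribution exactly, which is the limit used for
near-zero dispersions to keep every quantity continuous at the boundary.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

__all__ = [
    "nb_loglik",
    "nb_unit_deviance",
    "nb_deviance_residual",
    "nb_working_weights",
    "estimate_dispersions",
]

#: below this dispersion the Poisson limit is evaluated instead of the NB pmf
_POISSON_PHI = 1e-10

#: numerical floor for fitted means
MU_FLOOR = 1e-10

#: search range for the dispersion optimiser
PHI_RANGE = (1e-8, 1e3)


def _validate(x, mu, phi):
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")
    if np.any(phi < 0):
        raise ValueError("phi must be non-negative")
    return x, mu, phi


def nb_loglik(x, mu, phi, *, validate: bool = True):
    """Log-density of the negative binomial with mean ``mu``, dispersion ``phi``.

    Broadcasts over array inputs.  ``phi = 0`` (and any ``phi`` below 1e-10)
    evaluates the Poisson log-density, the continuous limit of the NB family.
    """
    if validate:
        x, mu, phi = _validate(x, mu, phi)
    else:
        x, mu, phi = (np.asarray(a, dtype=float) for a in (x, mu, phi))
    x, mu, phi = np.broadcast_arrays(x, mu, phi)
    out = np.empty(x.shape, dtype=float)
    pois = phi < _POISSON_PHI
    if np.any(pois):
        xm, mm = x[pois], mu[pois]
        out[pois] = xm * np.log(mm) - mm - gammaln(xm + 1.0)
    nb = ~pois
    if np.any(nb):
        xm, mm, k = x[nb], mu[nb], 1.0 / phi[nb]
        out[nb] = (
            gammaln(xm + k)
            - gammaln(k)
            - gammaln(xm + 1.0)
            + k * np.log(k / (k + mm))
            + xm * np.log(mm / (k + mm))
        )
    return out if out.shape else float(out)


def nb_unit_deviance(x, mu, phi, *, validate: bool = True):
    """Unit deviance 2*(l_saturated - l_fitted); non-negative, 0 iff x == mu."""
    if validate:
        x, mu, phi = _validate(x, mu, phi)
    else:
        x, mu, phi = (np.asarray(a, dtype=float) for a in (x, mu, phi))
    x, mu, phi = np.broadcast_arrays(x, mu, phi)
    # x*log(x/mu) with the 0*log(0) = 0 convention
    with np.errstate(divide="ignore", invalid="ignore"):
        xlogxm = np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0) / mu), 0.0)
    pois = phi < _POISSON_PHI
    d = np.empty(x.shape, dtype=float)
    if np.any(pois):
        d[pois] = 2.0 * (xlogxm[pois] - (x[pois] - mu[pois]))
    nb = ~pois
    if np.any(nb):
        k = 1.0 / phi[nb]
        d[nb] = 2.0 * (
            xlogxm[nb]
            - (x[nb] + k) * np.log((x[nb] + k) / (mu[nb] + k))
        )
    d = np.maximum(d, 0.0)  # clip tiny negative rounding noise
    return d if d.shape else float(d)


def nb_deviance_residual(x, mu, phi):
    """Signed deviance residual sign(x - mu) * sqrt(unit deviance)."""
    x, mu, phi = _validate(x, mu, phi)
    d = nb_unit_deviance(x, mu, phi, validate=False)
    r = np.sign(np.asarray(x, dtype=float) - mu) * np.sqrt(d)
    return r if np.ndim(r) else float(r)


def nb_working_weights(mu, phi):
    """IRLS weights for the log link: w = mu / (1 + phi * mu).

    These are the Fisher information contributions per cell for any linear
    predictor entering through ``log(mu)``.
    """
    mu = np.asarray(mu, dtype=float)
    return mu / (1.0 + np.asarray(phi, dtype=float) * mu)


def _cr_apl(phi: float, x: np.ndarray, mu: np.ndarray) -> float:
    """Cox-Reid adjusted profile log-likelihood for one taxon.

    The adjustment -0.5*log(sum of working weights) accounts for the single
    mean-model parameter estimated per taxon (intercept-like adjustment).
    """
    ll = float(np.sum(nb_loglik(x, mu, phi, validate=False)))
    w = float(np.sum(nb_working_weights(mu, phi)))
    return ll - 0.5 * np.log(max(w, MU_FLOOR))


def _maximize_apl(x: np.ndarray, mu: np.ndarray) -> float:
    from scipy.optimize import minimize_scalar

    lo, hi = np.log(PHI_RANGE[0]), np.log(PHI_RANGE[1])
    res = minimize_scalar(
        lambda t: -_cr_apl(np.exp(t), x, mu),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    # compare with the Poisson boundary: APL is evaluated at the floor
    phi_hat = float(np.exp(res.x))
    if -res.fun < _cr_apl(PHI_RANGE[0], x, mu):
        phi_hat = PHI_RANGE[0]
    return phi_hat


def estimate_dispersions(
    X: np.ndarray,
    Mu: np.ndarray,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-taxon NB dispersions by Cox-Reid adjusted profile likelihood.

    Parameters
    ----------
    X
        n x p count matrix.
    Mu
        n x p fitted means (conformable with ``X``).
    prior_df
        Strength of empirical-Bayes shrinkage of ``log(phi)`` toward the
        across-taxon mean-dispersion trend, in pseudo-samples.  ``0`` returns
        the raw per-taxon maximisers.

    Returns
    -------
    numpy.ndarray
        Length-p vector of dispersions, all >= 0.  Taxa with a single positive
        observation get a boundary estimate and trigger a warning; all-zero
        taxa raise (they must be removed by filtering upstream).
    """
    X = np.asarray(X, dtype=float)
    Mu = np.maximum(np.asarray(Mu, dtype=float), MU_FLOOR)
    if X.shape != Mu.shape:
        raise ValueError("X and Mu must be conformable")
    n, p = X.shape
    npos = (X > 0).sum(axis=0)
    if np.any(npos == 0):
        bad = np.flatnonzero(npos == 0)
        raise ValueError(
            f"all-zero taxa at columns {bad.tolist()}: dispersion undefined; "
            "filter them out first"
        )
    if np.any(npos == 1):
        warnings.warn(
            f"{int((npos == 1).sum())} taxa have a single positive count; "
            "their dispersion estimates sit on the boundary and are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    phi_raw = np.array([_maximize_apl(X[:, j], Mu[:, j]) for j in range(p)])

    if prior_df <= 0:
        return phi_raw

    # mean-dispersion trend: linear fit of log(phi) on log(mean count),
    # then shrink each taxon toward its trend value on the log scale with
    # weight prior_df against n observed samples.
    logm = np.log(np.maximum(X.mean(axis=0), MU_FLOOR))
    logphi = np.log(phi_raw)
    interior = phi_raw > PHI_RANGE[0] * 10
    if interior.sum() >= 2 and np.ptp(logm[interior]) > 0:
        coef = np.polyfit(logm[interior], logphi[interior], 1)
        trend = np.polyval(coef, logm)
    else:
        trend = np.full(p, logphi.mean())
    shrunk = (n * logphi + prior_df * trend) / (n + prior_df)
    return np.exp(shrunk)
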