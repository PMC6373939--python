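"""Synthetic microbiome count tables with planted group structure.

Scenarios emulate the benchmark conditions used to probe count-based
ordination methods: 60 samples in four groups of 15, 1000 taxa, and either
planted differential abundance (10% of taxa per group at a fold change of 5)
under NB, correlated-NB, phylogenetically-clustered-NB, Dirichlet-multinomial
or zero-inflated-NB sampling, or no biological signal with group-wise
library-size or dispersion multipliers (technical structure an ordination
should ignore).

Parameter pools are built-in parametric stand-ins for pools estimated from
large reference surveys: log-normal library sizes and mean abundances, gamma
taxon dispersions, beta zero-inflation fractions, log-normal Dirichlet
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CountTable

__all__ = [
    "ParameterPools",
    "ScenarioSpec",
    "SimulatedDataset",
    "BatchDataset",
    "ModelDataset",
    "generate",
    "generate_batch_dataset",
    "generate_rcm_dataset",
    "generate_constrained_dataset",
    "SCENARIOS",
]

SCENARIOS = ("NB", "NBcor", "NBphy", "DM", "ZINB", "nosignal-lib", "nosignal-disp")


@dataclass
class ParameterPools:
    """Parametric pools from which sample- and taxon-level parameters are drawn."""

    lib_meanlog: float = 9.0
    lib_sdlog: float = 0.7
    abund_meanlog: float = 0.0
    abund_sdlog: float = 2.0
    disp_shape: float = 2.0
    disp_scale: float = 0.25
    zi_a: float = 2.0
    zi_b: float = 8.0
    dm_conc_meanlog: float = float(np.log(50.0))
    dm_conc_sdlog: float = 0.5


@dataclass
class ScenarioSpec:
    name: str = "NB"
    n: int = 60
    p: int = 1000
    groups: int = 4
    group_sizes: tuple[int, ...] | None = None
    da_fraction: float = 0.10
    fold_change: float = 5.0
    lib_multipliers: tuple[float, ...] = (0.2, 1.0, 5.0, 10.0)
    disp_multipliers: tuple[float, ...] = (0.2, 1.0, 2.0, 5.0)
    pools: ParameterPools = field(default_factory=ParameterPools)
    n_tree_clusters: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if self.group_sizes is None:
            if self.n % self.groups:
                raise ValueError("n must divide evenly into groups or give group_sizes")
            self.group_sizes = (self.n // self.groups,) * self.groups
        if sum(self.group_sizes) != self.n:
            raise ValueError(
                f"group sizes {self.group_sizes} do not sum to n={self.n}"
            )
        if not 0.0 <= self.da_fraction <= 1.0:
            raise ValueError("da_fraction must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


@dataclass
class SimulatedDataset:
    counts: CountTable
    group_labels: np.ndarray
    da_mask: np.ndarray  # p x groups indicator of planted DA
    true_lib_sizes: np.ndarray


def _random_coalescent_linkage(p: int, rng: np.random.Generator) -> np.ndarray:
    """Random binary (coalescent-style) tree as a scipy linkage matrix."""
    active = list(range(p))
    sizes = {i: 1 for i in range(p)}
    Z = np.zeros((p - 1, 4))
    height = 0.0
    nxt = p
    for step in range(p - 1):
        k = len(active)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        Z[step] = [a, b, height, sizes[a] + sizes[b]]
        sizes[nxt] = sizes[a] + sizes[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Z


def _da_mask(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """p x groups boolean mask of planted differentially abundant taxa."""
    p, g = spec.p, spec.groups
    mask = np.zeros((p, g), dtype=bool)
    if spec.name.startswith("nosignal"):
        return mask
    if spec.name == "NBphy":
        from scipy.cluster.hierarchy import fcluster

        Z = _random_coalescent_linkage(p, rng)
        clusters = fcluster(Z, t=spec.n_tree_clusters, criterion="maxclust")
        ids = rng.permutation(np.unique(clusters))[:g]
        for k in range(g):
            mask[clusters == ids[k], k] = True
        return mask
    n_da = int(round(spec.da_fraction * p))
    for k in range(g):
        mask[rng.choice(p, size=n_da, replace=False), k] = True
    return mask


def _nb_draw(rng, mu, phi):
    """Gamma-Poisson draw; phi may be scalar, per-taxon or per-cell."""
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi < 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nbm = ~pois
    if nbm.any():
        lam = rng.gamma(shape=1.0 / phi[nbm], scale=phi[nbm] * mu[nbm])
        out[nbm] = rng.poisson(lam)
    return out


def generate(spec: ScenarioSpec) -> SimulatedDataset:
    """Draw one synthetic dataset for a scenario; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    pools = spec.pools
    n, p, g = spec.n, spec.p, spec.groups
    labels = np.repeat(np.arange(g), spec.group_sizes)

    lib = rng.lognormal(pools.lib_meanlog, pools.lib_sdlog, n)
    if spec.name == "nosignal-lib":
        if len(spec.lib_multipliers) != g:
            raise ValueError("lib_multipliers must have one entry per group")
        lib = lib * np.asarray(spec.lib_multipliers)[labels]

    # one base composition for all groups, then group-wise DA multipliers
    base = rng.lognormal(pools.abund_meanlog, pools.abund_sdlog, p)
    base = base / base.sum()
    mask = _da_mask(spec, rng)
    comp = np.tile(base, (g, 1))  # groups x p
    comp[mask.T] *= spec.fold_change

    phi = rng.gamma(pools.disp_shape, pools.disp_scale, p)
    Mu = lib[:, None] * comp[labels]  # n x p

    if spec.name in ("NB", "NBphy", "nosignal-lib"):
        X = _nb_draw(rng, Mu, phi[None, :])
    elif spec.name == "nosignal-disp":
        if len(spec.disp_multipliers) != g:
            raise ValueError("disp_multipliers must have one entry per group")
        phi_cell = phi[None, :] * np.asarray(spec.disp_multipliers)[labels][:, None]
        X = _nb_draw(rng, Mu, phi_cell)
    elif spec.name == "NBcor":
        X = _copula_nb(rng, Mu, phi)
    elif spec.name == "DM":
        conc = rng.lognormal(pools.dm_conc_meanlog, pools.dm_conc_sdlog)
        X = np.empty((n, p), dtype=np.int64)
        for i in range(n):
            props = comp[labels[i]] / comp[labels[i]].sum()
            pr = rng.dirichlet(conc * props)
            X[i] = rng.multinomial(int(round(lib[i])), pr)
    elif spec.name == "ZINB":
        X = _nb_draw(rng, Mu, phi[None, :])
        zi = rng.beta(pools.zi_a, pools.zi_b, p)
        X = X * (rng.random((n, p)) >= zi[None, :])
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(spec.name)

    ct = CountTable(
        X,
        [f"S{i + 1}" for i in range(n)],
        [f"T{j + 1}" for j in range(p)],
    )
    return SimulatedDataset(
        counts=ct, group_labels=labels, da_mask=mask, true_lib_sizes=lib
    )


@dataclass
class ModelDataset:
    """Counts drawn from the row-column interaction model with known truth."""

    counts: CountTable
    R_true: np.ndarray | None = None  # n x M sample scores
    S_true: np.ndarray | None = None  # p x M taxon scores
    psi_true: np.ndarray | None = None
    alpha_true: np.ndarray | None = None  # d x M gradients (constrained)
    C: np.ndarray | None = None  # n x d constraining design (constrained)
    beta1_true: np.ndarray | None = None


def _orthonormal_centered(rng, n, M):
    """M random centred orthonormal vectors of length n."""
    A = rng.standard_normal((n, M + 1))
    A[:, 0] = 1.0
    Q, _ = np.linalg.qr(A)
    return Q[:, 1 : M + 1]


def _null_params(rng, pools, n, p):
    lib = rng.lognormal(pools.lib_meanlog, pools.lib_sdlog, n)
    base = rng.lognormal(pools.abund_meanlog, pools.abund_sdlog, p)
    base = base / base.sum()
    return np.log(lib), np.log(base)


def generate_rcm_dataset(
    n: int = 60,
    p: int = 200,
    M: int = 2,
    psi: tuple[float, ...] | None = None,
    interaction_sd: float = 0.7,
    pools: ParameterPools | None = None,
    seed: int = 0,
) -> ModelDataset:
    """NB counts from ``log mu = u + v + sum_m psi_m r_m s_m^T`` with known scores.

    Scores are random centred orthonormal vectors.  Because unit-norm score
    products have magnitude ~1/sqrt(n p) per cell, ``psi`` defaults to
    ``interaction_sd * 0.7**m * sqrt(n p)`` so the leading dimension perturbs
    log-means with a standard deviation of about ``interaction_sd`` — the
    order of a four-to-five-fold abundance shift, a clearly present but
    realistic community signal.
    """
    rng = np.random.default_rng(seed)
    pools = pools or ParameterPools()
    u, v = _null_params(rng, pools, n, p)
    R = _orthonormal_centered(rng, n, M)
    S = _orthonormal_centered(rng, p, M)
    if psi is None:
        psi = tuple(interaction_sd * np.sqrt(n * p) * 0.7**m for m in range(M))
    psi_arr = np.asarray(psi, dtype=float)
    eta = u[:, None] + v[None, :] + (R * psi_arr) @ S.T
    phi = rng.gamma(pools.disp_shape, pools.disp_scale, p)
    X = _nb_draw(rng, np.exp(eta), phi[None, :])
    ct = CountTable(X, [f"S{i + 1}" for i in range(n)], [f"T{j + 1}" for j in range(p)])
    return ModelDataset(counts=ct, R_true=R, S_true=S, psi_true=psi_arr)


def generate_constrained_dataset(
    n: int = 60,
    p: int = 150,
    d: int = 3,
    M: int = 1,
    psi: tuple[float, ...] = (8.0,),
    pools: ParameterPools | None = None,
    seed: int = 0,
) -> ModelDataset:
    """NB counts from the constrained model with linear responses and known gradients.

    The constraining design ``C`` is standard-normal (standardised columns),
    gradients are random orthonormal ``d``-vectors, slopes ``beta1`` are unit
    norm per dimension, and intercepts keep each taxon's average departure
    near zero.
    """
    rng = np.random.default_rng(seed)
    pools = pools or ParameterPools()
    u, v = _null_params(rng, pools, n, p)
    C = rng.standard_normal((n, d))
    C = (C - C.mean(axis=0)) / C.std(axis=0)
    A, _ = np.linalg.qr(rng.standard_normal((d, M)))
    H = C @ A
    B1 = rng.standard_normal((p, M))
    B1 /= np.linalg.norm(B1, axis=0)
    psi_arr = np.asarray(psi, dtype=float)
    eta = u[:, None] + v[None, :] + (H * psi_arr) @ B1.T
    phi = rng.gamma(pools.disp_shape, pools.disp_scale, p)
    X = _nb_draw(rng, np.exp(eta), phi[None, :])
    ct = CountTable(X, [f"S{i + 1}" for i in range(n)], [f"T{j + 1}" for j in range(p)])
    return ModelDataset(
        counts=ct, psi_true=psi_arr, alpha_true=A, C=C, beta1_true=B1
    )


@dataclass
class BatchDataset:
    """NB counts with an independent biological signal plus a planted batch effect."""

    counts: CountTable
    group_labels: np.ndarray  # biological groups
    batch_labels: np.ndarray  # 2-level technical batch, crossed with groups
    zeta_true: np.ndarray  # per-taxon log-fold batch effect
    da_mask: np.ndarray


def generate_batch_dataset(
    n: int = 60,
    p: int = 150,
    bio_groups: int = 2,
    da_fraction: float = 0.10,
    fold_change: float = 5.0,
    batch_fraction: float = 0.30,
    batch_logfold: float = 1.0,
    batch_bio_correlation: float = 0.0,
    pools: ParameterPools | None = None,
    seed: int = 0,
) -> BatchDataset:
    """Counts where a 2-level batch shifts a taxon subset on top of real signal.

    By default the batch is assigned in alternation within each biological
    group (crossed with, not confounded by, the biology) and multiplies the
    means of a random ``batch_fraction`` of taxa by ``exp(batch_logfold)``.
    With ``batch_bio_correlation`` in (0, 1], each sample's batch label is
    instead aligned with its group parity with that probability, producing a
    batch that correlates with the biological contrast.  Useful for probing
    conditioning: batch structure should vanish from an ordination that
    treats the batch as a confounder.
    """
    rng = np.random.default_rng(seed)
    pools = pools or ParameterPools()
    labels = np.repeat(np.arange(bio_groups), -(-n // bio_groups))[:n]
    batch = np.zeros(n, dtype=int)
    for g in range(bio_groups):
        idx = np.flatnonzero(labels == g)
        batch[idx[1::2]] = 1
    if batch_bio_correlation > 0:
        align = rng.random(n) < batch_bio_correlation
        batch = np.where(align, labels % 2, rng.integers(0, 2, n))
    lib = rng.lognormal(pools.lib_meanlog, pools.lib_sdlog, n)
    base = rng.lognormal(pools.abund_meanlog, pools.abund_sdlog, p)
    base = base / base.sum()
    mask = np.zeros((p, bio_groups), dtype=bool)
    n_da = int(round(da_fraction * p))
    comp = np.tile(base, (bio_groups, 1))
    for g in range(bio_groups):
        sel = rng.choice(p, size=n_da, replace=False)
        mask[sel, g] = True
        comp[g, sel] *= fold_change
    zeta = np.zeros(p)
    zeta[rng.choice(p, size=int(round(batch_fraction * p)), replace=False)] = batch_logfold
    phi = rng.gamma(pools.disp_shape, pools.disp_scale, p)
    Mu = lib[:, None] * comp[labels] * np.exp(np.outer(batch, zeta))
    X = _nb_draw(rng, Mu, phi[None, :])
    ct = CountTable(
        X, [f"S{i + 1}" for i in range(n)], [f"T{j + 1}" for j in range(p)]
    )
    return BatchDataset(
        counts=ct, group_labels=labels, batch_labels=batch,
        zeta_true=zeta, da_mask=mask,
    )


def _copula_nb(rng, Mu, phi):
    """NB marginals coupled through a block-equicorrelated Gaussian copula."""
    from scipy.stats import nbinom, norm

    n, p = Mu.shape
    Z = np.empty((n, p))
    j = 0
    while j < p:
        size = int(rng.integers(5, 21))
        size = min(size, p - j)
        rho = rng.uniform(0.3, 0.7)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, size))
        Z[:, j : j + size] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        j += size
    U = norm.cdf(Z)
    k = 1.0 / phi[None, :]
    prob = k / (k + Mu)
    X = nbinom.ppf(np.clip(U, 1e-12, 1 - 1e-12), k, prob)
    return X.astype(np.int64)
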