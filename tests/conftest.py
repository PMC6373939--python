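import warnings

import numpy as np
import pandas as pd
import pytest

from rcmord import CountTable, encode_metadata, filter_taxa

# dispersion warnings from boundary taxa are expected noise in small fixtures
warnings.filterwarnings("ignore", category=RuntimeWarning, module="rcmord")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def positive_table_6x8():
    """Strictly positive 6x8 count table with a planted rank-1 interaction.

    All counts positive keeps the interaction maximum-likelihood problem
    well-posed (zero cells push interaction terms toward infinity).
    """
    rng = np.random.default_rng(7)
    mu = np.outer(rng.lognormal(3.2, 0.3, 6), rng.lognormal(0, 0.5, 8)) / 3
    inter = 0.8 * np.outer(rng.standard_normal(6), rng.standard_normal(8))
    X = rng.poisson(mu * np.exp(np.clip(inter, -1.5, 1.5))) + 1
    return CountTable(X, [f"s{i}" for i in range(6)], [f"t{j}" for j in range(8)])


@pytest.fixture()
def constrained_fixture_8x6():
    """8x6 table with two standardised constraining covariates, one active."""
    rng = np.random.default_rng(11)
    n, p = 8, 6
    mu = np.outer(rng.lognormal(3.2, 0.3, n), rng.lognormal(0, 0.5, p)) / 3
    c1 = rng.standard_normal(n)
    c2 = rng.standard_normal(n)
    slopes = rng.standard_normal(p)
    X = rng.poisson(mu * np.exp(np.clip(0.5 * np.outer(c1, slopes), -1.5, 1.5))) + 1
    ct = CountTable(X, [f"s{i}" for i in range(n)], [f"t{j}" for j in range(p)])
    meta = pd.DataFrame({"c1": c1, "c2": c2}, index=ct.sample_ids)
    sd = encode_metadata(meta, constraining=["c1", "c2"])
    return ct, sd


def align_samples(sim_counts, filtered):
    """Indices of the filtered table's samples within the original table."""
    return [sim_counts.sample_ids.index(s) for s in filtered.sample_ids]


def align_taxa(sim_counts, filtered):
    return np.array([sim_counts.taxon_ids.index(t) for t in filtered.taxon_ids])


@pytest.fixture()
def filtered_nb_sim():
    """A moderate DA scenario dataset, filtered, with alignment helpers."""
    from rcmord.simulate import ScenarioSpec, generate

    sim = generate(ScenarioSpec(name="NB", n=40, p=120, seed=1))
    ct = filter_taxa(sim.counts)
    return sim, ct, align_samples(sim.counts, ct), align_taxa(sim.counts, ct)
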