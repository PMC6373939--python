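"""Unconstrained ordination: score normalisation, fitting, biplot geometry."""

import numpy as np
import pytest

from rcmord import (
    biplot_coordinates,
    filter_taxa,
    fit_unconstrained,
    normalize_scores,
)
from rcmord.simulate import ScenarioSpec, generate, generate_rcm_dataset


class TestNormalizeScores:
    def test_centering_and_scaling_closed_form(self):
        raw_r = np.array([2.0, 4.0, 6.0])
        raw_s = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)  # already unit, centred
        r, s, scale = normalize_scores(raw_r, raw_s)
        np.testing.assert_allclose(r, [-1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
                                   atol=1e-12)
        assert scale == pytest.approx(np.sqrt(8.0), rel=1e-12)

    def test_already_orthogonal_vectors_unchanged_up_to_scale(self, rng):
        prev = np.array([[-1.0, 0.0, 1.0]]).T / np.sqrt(2.0)
        raw = np.array([1.0, -2.0, 1.0])  # centred, orthogonal to prev
        r, s, _ = normalize_scores(raw, raw.copy(), previous_R=prev,
                                   previous_S=prev)
        np.testing.assert_allclose(np.abs(r), np.abs(raw) / np.linalg.norm(raw),
                                   atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_scores(np.ones(4), np.arange(4.0))


class TestBiplotCoordinates:
    def _fake_fit(self):
        from rcmord.null import NullFit
        from rcmord.unconstrained import UnconstrainedFit

        psi = np.array([2.0, 1.0])
        R = np.array([[0.5, 0.0], [-0.5, 0.0]])
        S = np.array([[0.3, 0.9], [-0.3, -0.9]])
        null = NullFit(u=np.zeros(2), v=np.zeros(2), zeta=np.zeros((2, 0)),
                       phi=np.zeros(2), deviance=0.0)
        return UnconstrainedFit(M=2, psi=psi, R=R, S=S, null=null, deviance=0.0,
                                converged=[True, True],
                                sample_ids=["a", "b"], taxon_ids=["x", "y"])

    def test_sample_points_are_psi_scaled_scores(self):
        fit = self._fake_fit()
        samples, taxa = biplot_coordinates(fit)
        np.testing.assert_allclose(samples[0], [1.0, 0.0])
        np.testing.assert_allclose(taxa[0], [0.3, 0.9])
        # projection of arrow on sample point = plotted departure
        assert samples[0] @ taxa[0] == pytest.approx(0.3)

    def test_projection_equals_direct_sum(self, rng):
        fit = self._fake_fit()
        samples, taxa = biplot_coordinates(fit)
        direct = np.einsum("m,im,jm->ij", fit.psi, fit.R, fit.S)
        np.testing.assert_allclose(samples @ taxa.T, direct, atol=1e-12)

    def test_out_of_range_dims_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            biplot_coordinates(self._fake_fit(), dims=(1, 3))


class TestFitUnconstrained:
    def test_matches_brute_force_optimizer(self, positive_table_6x8):
        from rcmord._reference import brute_force_unconstrained

        phi = np.full(8, 0.2)
        fit = fit_unconstrained(positive_table_6x8, M=1, seed=0, fix_phi=phi,
                                tol=1e-9, max_iter=2000)
        oracle = brute_force_unconstrained(positive_table_6x8.X, phi)
        assert fit.deviance == pytest.approx(oracle["deviance"], rel=1e-4)

    def test_no_interaction_psi_within_permutation_null(self, rng):
        # data obeying the independence model: the leading interaction
        # strength should be indistinguishable from column-permuted refits
        lib = rng.lognormal(8.0, 0.5, 40)
        comp = rng.lognormal(0.0, 1.5, 100)
        comp /= comp.sum()
        X = rng.poisson(np.outer(lib, comp))
        from rcmord import CountTable

        ct = filter_taxa(CountTable(
            X, [f"s{i}" for i in range(40)], [f"t{j}" for j in range(100)]))
        psi_obs = fit_unconstrained(ct, M=1, seed=0).psi[0]
        perm_psis = []
        for k in range(19):
            Xp = np.column_stack([rng.permutation(ct.X[:, j])
                                  for j in range(ct.p)])
            ctp = CountTable(Xp, ct.sample_ids, ct.taxon_ids)
            perm_psis.append(fit_unconstrained(ctp, M=1, seed=k).psi[0])
        assert psi_obs <= np.quantile(perm_psis, 0.95) * 1.05

    def test_recovers_known_sample_scores(self):
        simd = generate_rcm_dataset(n=60, p=200, M=2, seed=42)
        ct = filter_taxa(simd.counts)
        keep = [simd.counts.sample_ids.index(s) for s in ct.sample_ids]
        fit = fit_unconstrained(ct, M=2, seed=0)
        cor = abs(np.corrcoef(fit.R[:, 0], simd.R_true[keep, 0])[0, 1])
        assert cor > 0.9

    def test_identifiability_invariants(self, filtered_nb_sim):
        _, ct, _, _ = filtered_nb_sim
        fit = fit_unconstrained(ct, M=2, seed=0)
        for m in range(2):
            assert fit.R[:, m].sum() == pytest.approx(0.0, abs=1e-8)
            assert fit.S[:, m].sum() == pytest.approx(0.0, abs=1e-8)
            assert np.linalg.norm(fit.R[:, m]) == pytest.approx(1.0, rel=1e-8)
            assert np.linalg.norm(fit.S[:, m]) == pytest.approx(1.0, rel=1e-8)
        assert fit.R[:, 0] @ fit.R[:, 1] == pytest.approx(0.0, abs=1e-8)
        assert fit.S[:, 0] @ fit.S[:, 1] == pytest.approx(0.0, abs=1e-8)
        assert fit.psi[0] >= fit.psi[1] >= 0

    def test_monotone_deviance_within_dimensions(self, filtered_nb_sim):
        _, ct, _, _ = filtered_nb_sim
        fit = fit_unconstrained(ct, M=2, seed=0)
        for trace in fit.deviance_traces:
            t = np.asarray(trace)
            assert np.all(np.diff(t) <= 1e-8 * np.abs(t[:-1]) + 1e-10)

    def test_deviance_explained_nests_in_M(self, filtered_nb_sim):
        _, ct, _, _ = filtered_nb_sim
        from rcmord import fit_independence

        phi = fit_independence(ct).phi
        devs = [fit_unconstrained(ct, M=m, seed=0, fix_phi=phi).deviance
                for m in (1, 2, 3)]
        assert devs[0] >= devs[1] - 1e-6
        assert devs[1] >= devs[2] - 1e-6

    def test_seed_invariance_up_to_sign(self, filtered_nb_sim):
        _, ct, _, _ = filtered_nb_sim
        f1 = fit_unconstrained(ct, M=2, seed=1)
        f2 = fit_unconstrained(ct, M=2, seed=99)
        for m in range(2):
            sgn = np.sign(f1.R[:, m] @ f2.R[:, m])
            assert np.max(np.abs(f1.R[:, m] - sgn * f2.R[:, m])) < 1e-4

    def test_conditioning_removes_batch_structure(self):
        import pandas as pd

        from rcmord import encode_metadata
        from rcmord.simulate import generate_batch_dataset

        sim = generate_batch_dataset(n=40, p=120, batch_logfold=1.5, seed=17)
        ct = filter_taxa(sim.counts)
        batch = sim.batch_labels[[sim.counts.sample_ids.index(s)
                                  for s in ct.sample_ids]]
        raw = pd.DataFrame({"batch": [f"b{b}" for b in batch]},
                           index=ct.sample_ids)
        sd = encode_metadata(raw, confounders=["batch"])
        un = fit_unconstrained(ct, None, M=2, seed=0)
        co = fit_unconstrained(ct, sd, M=2, seed=0)

        def batch_cor(fit):
            return max(abs(np.corrcoef(fit.R[:, m], batch)[0, 1])
                       for m in range(2))

        assert batch_cor(co) < 0.5 * batch_cor(un)
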