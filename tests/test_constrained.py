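"""Constrained ordination: gradients, response functions, triplot geometry."""

import numpy as np
import pandas as pd
import pytest

from rcmord import (
    CountTable,
    encode_metadata,
    filter_taxa,
    fit_constrained,
    fit_nonparametric_responses,
    fit_unconstrained,
    linear_arrow_geometry,
    quadratic_vertex,
)
from rcmord.simulate import ParameterPools, generate_constrained_dataset


def _constrained_sim(n=60, p=150, d=3, seed=0, **kw):
    simd = generate_constrained_dataset(n=n, p=p, d=d, M=1, seed=seed, **kw)
    ct = filter_taxa(simd.counts)
    keep = [simd.counts.sample_ids.index(s) for s in ct.sample_ids]
    meta = pd.DataFrame(simd.C[keep], columns=[f"x{k}" for k in range(d)],
                        index=ct.sample_ids)
    sd = encode_metadata(meta, constraining=list(meta.columns))
    return simd, ct, sd


class TestFitConstrained:
    def test_binary_variable_forces_two_point_gradient(self, rng):
        n, p = 20, 30
        grp = np.repeat(["lo", "hi"], n // 2)
        mu = np.outer(rng.lognormal(3.0, 0.3, n), rng.lognormal(0.0, 0.6, p)) / 4
        effect = np.where(grp == "hi", 1.0, 0.0)
        slopes = rng.standard_normal(p)
        X = rng.poisson(mu * np.exp(0.6 * np.outer(effect, slopes))) + 1
        ct = CountTable(X, [f"s{i}" for i in range(n)],
                        [f"t{j}" for j in range(p)])
        meta = pd.DataFrame({"grp": grp}, index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["grp"])
        fit = fit_constrained(ct, sd, M=1, family="linear", seed=0)
        # with one (dummy-coded, centred) binary variable the environmental
        # score takes exactly two values
        h = fit.H[:, 0]
        assert len(np.unique(np.round(h, 10))) == 2
        np.testing.assert_allclose(np.linalg.norm(fit.A[:, 0]), 1.0, rtol=1e-10)

    def test_matches_brute_force_criterion(self, constrained_fixture_8x6):
        from rcmord._reference import brute_force_constrained

        ct, sd = constrained_fixture_8x6
        phi = np.full(ct.p, 0.2)
        fit = fit_constrained(ct, sd, M=1, family="linear", seed=0,
                              fix_phi=phi, tol=1e-9, max_iter=300)
        oracle = brute_force_constrained(ct.X, fit.null.offsets, phi,
                                         sd.C.to_numpy())
        assert fit.lr_trace[0][-1] == pytest.approx(oracle["criterion"],
                                                    rel=1e-3)

    def test_recovers_known_gradient(self):
        simd, ct, sd = _constrained_sim(seed=4)
        fit = fit_constrained(ct, sd, M=1, family="linear", seed=0)
        assert abs(fit.A[:, 0] @ simd.alpha_true[:, 0]) > 0.9

    def test_criterion_trace_non_decreasing(self):
        _, ct, sd = _constrained_sim(n=30, p=60, d=2, seed=8)
        fit = fit_constrained(ct, sd, M=2, family="linear", seed=0)
        for trace in fit.lr_trace:
            t = np.asarray(trace)
            assert np.all(np.diff(t) >= -1e-8 * np.maximum(np.abs(t[:-1]), 1.0))

    def test_gradient_invariants(self):
        _, ct, sd = _constrained_sim(n=40, p=80, d=3, seed=2)
        fit = fit_constrained(ct, sd, M=2, family="linear", seed=0)
        A = fit.A
        np.testing.assert_allclose(np.linalg.norm(A, axis=0), 1.0, rtol=1e-8)
        assert A[:, 0] @ A[:, 1] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.H, sd.C.to_numpy() @ A, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(fit.beta1, axis=0), 1.0,
                                   rtol=1e-8)

    def test_duplicated_constraining_column_rejected(self, rng):
        n = 12
        z = rng.standard_normal(n)
        X = rng.poisson(5.0, size=(n, 8)) + 1
        ct = CountTable(X, [f"s{i}" for i in range(n)],
                        [f"t{j}" for j in range(8)])
        meta = pd.DataFrame({"a": z, "b": z}, index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["a", "b"])
        with pytest.raises(ValueError, match="collinear"):
            fit_constrained(ct, sd, M=1)

    def test_saturated_design_approaches_unconstrained(self, rng):
        # one dummy per sample spans every centred score vector, so the
        # constrained fit should reproduce the unconstrained ordination
        simd = generate_constrained_dataset(n=25, p=60, d=2, M=1, psi=(10.0,),
                                            seed=31)
        ct = filter_taxa(simd.counts)
        meta = pd.DataFrame({"id": ct.sample_ids}, index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["id"])
        con = fit_constrained(ct, sd, M=1, family="linear", seed=0)
        unc = fit_unconstrained(ct, M=1, seed=0)
        cor = abs(np.corrcoef(con.H[:, 0], unc.R[:, 0])[0, 1])
        assert cor > 0.95

    def test_conditioning_reduces_batch_gradient_correlation(self, rng):
        # biology independent of the batch; a biologically inert covariate
        # proxies the batch.  Unconditioned, the gradient chases the batch
        # effect through that proxy; conditioning removes it.
        from rcmord.simulate import generate_batch_dataset

        sim = generate_batch_dataset(n=60, p=120, fold_change=2.0,
                                     batch_logfold=2.0, seed=23)
        ct = filter_taxa(sim.counts)
        sidx = [sim.counts.sample_ids.index(s) for s in ct.sample_ids]
        g, b = sim.group_labels[sidx], sim.batch_labels[sidx]
        xvar = b + rng.normal(0, 0.3, len(b))
        raw = pd.DataFrame({
            "grp": [f"g{x}" for x in g], "x": xvar,
            "batch": [f"b{x}" for x in b],
        }, index=ct.sample_ids)
        sd_raw = encode_metadata(raw, constraining=["grp", "x"])
        sd_cond = encode_metadata(raw, confounders=["batch"],
                                  constraining=["grp", "x"])
        f_raw = fit_constrained(ct, sd_raw, M=1, family="linear", seed=0)
        f_cond = fit_constrained(ct, sd_cond, M=1, family="linear", seed=0)
        c_raw = abs(np.corrcoef(f_raw.H[:, 0], b)[0, 1])
        c_cond = abs(np.corrcoef(f_cond.H[:, 0], b)[0, 1])
        assert c_cond <= 0.5 * c_raw


class TestArrowGeometry:
    def test_closed_form_origin_slope_length(self):
        arrow = linear_arrow_geometry(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert arrow.origin == pytest.approx((-0.5, -0.5))
        assert arrow.slope == pytest.approx(1.0)
        assert arrow.length == pytest.approx(np.sqrt(8.0))

    def test_horizontal_arrow(self):
        arrow = linear_arrow_geometry(np.array([0.7, 0.0]), np.array([1.0, 0.0]))
        assert arrow.origin[0] == pytest.approx(-0.7)
        assert arrow.slope == pytest.approx(0.0)

    def test_vertical_and_degenerate_flags(self):
        assert linear_arrow_geometry(np.zeros(2), np.array([0.0, 1.0])).vertical
        assert linear_arrow_geometry(np.zeros(2), np.zeros(2)).degenerate


class TestQuadraticResponses:
    def test_vertex_closed_form_and_concavity(self):
        h, concave = quadratic_vertex(2.0, -1.0)
        assert h == pytest.approx(1.0)
        assert concave
        _, concave2 = quadratic_vertex(1.0, 0.5)
        assert not concave2  # convex niches are suspicious and flagged

    def test_zero_curvature_directs_to_linear(self):
        with pytest.raises(ValueError, match="linear"):
            quadratic_vertex(1.0, 0.0)

    def test_recovers_planted_peak(self):
        # a sparse set of unimodal responders (responses shared by every
        # taxon would be absorbed into the sample intercepts); the tracked
        # taxon peaks at h* = 0.7
        rng = np.random.default_rng(0)
        n, p = 100, 40
        c = rng.standard_normal(n)
        c = (c - c.mean()) / c.std()
        u = rng.lognormal(4.0, 0.3, n)
        v = rng.lognormal(0.0, 0.4, p)
        peaks = rng.uniform(-1.0, 1.0, p)
        peaks[0] = 0.7
        curv = np.zeros(p)
        responders = rng.choice(p, 8, replace=False)
        responders[0] = 0
        curv[responders] = rng.uniform(0.7, 1.1, 8)
        curv[0] = 0.9
        eta = np.log(np.outer(u, v)) - curv[None, :] * (c[:, None] - peaks[None, :]) ** 2
        X = rng.poisson(np.exp(eta))
        ct = filter_taxa(CountTable(X, [f"s{i}" for i in range(n)],
                                    [f"t{j}" for j in range(p)]))
        meta = pd.DataFrame({"c": [c[int(s[1:])] for s in ct.sample_ids]},
                            index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["c"])
        fit = fit_constrained(ct, sd, M=1, family="quadratic", seed=0)
        j = ct.taxon_ids.index("t0")
        vertex, concave = quadratic_vertex(fit.beta1[j, 0], fit.beta2[j, 0])
        # alpha may flip the gradient axis
        assert concave
        assert abs(np.sign(fit.A[0, 0]) * vertex - 0.7) < 0.2


class TestNonparametricResponses:
    def _linear_truth_fit(self, seed=6):
        pools = ParameterPools(lib_meanlog=10.0, disp_shape=2.0,
                               disp_scale=0.02)
        simd = generate_constrained_dataset(n=150, p=30, d=2, M=1, psi=(6.0,),
                                            pools=pools, seed=seed)
        ct = filter_taxa(simd.counts)
        keep = [simd.counts.sample_ids.index(s) for s in ct.sample_ids]
        meta = pd.DataFrame(simd.C[keep], columns=["x0", "x1"],
                            index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["x0", "x1"])
        fit = fit_constrained(ct, sd, M=1, family="linear", seed=0)
        return simd, ct, fit

    def test_linear_truth_recovered_by_splines(self):
        simd, ct, fit = self._linear_truth_fit()
        resp = fit_nonparametric_responses(fit)
        # compare the smooth curve of a strongly responding taxon with the
        # linear fit's own response line on the interior of the h-grid
        j = int(np.argmax(np.abs(fit.beta1[:, 0])))
        grid = resp.grid
        inner = (grid > np.quantile(resp.h, 0.05)) & (grid < np.quantile(resp.h, 0.95))
        line = fit.psi[0] * (fit.beta0[j, 0] + fit.beta1[j, 0] * grid)
        rmse = np.sqrt(np.mean((resp.curves[j][inner] - line[inner]) ** 2))
        assert rmse < 0.1

    def test_constant_response_is_flat_with_unit_edf(self, rng):
        simd, ct, fit = self._linear_truth_fit(seed=12)
        # replace one taxon's counts with draws independent of the gradient
        X = ct.X.copy()
        X[:, 3] = rng.poisson(np.exp(fit.null.offsets[:, 3]))
        ct2 = CountTable(X, ct.sample_ids, ct.taxon_ids)
        from dataclasses import replace

        fit2 = replace(fit, counts=ct2)
        resp = fit_nonparametric_responses(fit2)
        # the second-difference penalty leaves a constant+linear null space,
        # so a flat response bottoms out near 2 effective df
        assert resp.edf[3] < 2.5
        assert np.ptp(resp.curves[3]) < 0.5

    def test_unimodal_response_peak_located(self, rng):
        n, p = 120, 25
        c = np.linspace(-1.6, 1.6, n)
        u = rng.lognormal(4.0, 0.2, n)
        v = rng.lognormal(0.0, 0.3, p)
        # only a few unimodal responders, so the niche shapes are not
        # absorbed into the sample intercepts; tracked taxon peaks at 0.7
        peaks = rng.uniform(-1.0, 1.0, p)
        peaks[0] = 0.7
        curv = np.zeros(p)
        responders = rng.choice(p, 6, replace=False)
        responders[0] = 0
        curv[responders] = rng.uniform(0.8, 1.2, 6)
        curv[0] = 1.0
        eta = np.log(np.outer(u, v)) - curv[None, :] * (c[:, None] - peaks[None, :]) ** 2
        X = rng.poisson(np.exp(eta))
        ct = filter_taxa(CountTable(X, [f"s{i}" for i in range(n)],
                                    [f"t{j}" for j in range(p)]))
        meta = pd.DataFrame({"c": [c[int(s[1:])] for s in ct.sample_ids]},
                            index=ct.sample_ids)
        sd = encode_metadata(meta, constraining=["c"])
        fit = fit_constrained(ct, sd, M=1, family="linear", seed=0)
        resp = fit_nonparametric_responses(fit)
        j = ct.taxon_ids.index("t0")
        # undo the standardisation of c and the sign freedom of the gradient
        cv = meta["c"].to_numpy()
        h_of_peak = (0.7 - cv.mean()) / cv.std() * np.sign(fit.A[0, 0])
        peak = resp.grid[np.argmax(resp.curves[j])]
        assert abs(peak - h_of_peak) < 0.25
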