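"""Kernel estimator: weights, sampling, anchored fits and oracle equivalence."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from stiidil.core import Coalition, coalition_value
from stiidil.exact import explain_exact
from stiidil.kernel import (
    IllPosedFitError,
    build_design,
    default_lambda_lasso,
    explain_kernel,
    fit_random_forest_surrogate,
    fit_weighted_lasso,
    pair_column_index,
    sample_coalitions,
    shapley_kernel_weight,
)
from stiidil.synthetic import ground_truth_stii, random_pairwise_model

from .conftest import make_lab_patient, linear_vf


class TestKernelWeight:
    @pytest.mark.parametrize("d,z,expected", [(4, 1, 0.25), (4, 2, 0.125), (4, 3, 0.25)])
    def test_direct_formula_values(self, d, z, expected):
        assert shapley_kernel_weight(d, z) == pytest.approx(expected)

    @pytest.mark.parametrize("d", range(2, 21))
    def test_symmetric_in_coalition_size(self, d):
        for z in range(1, d):
            assert shapley_kernel_weight(d, z) == pytest.approx(
                shapley_kernel_weight(d, d - z)
            )

    @pytest.mark.parametrize("z", [0, 4])
    def test_anchor_sizes_rejected(self, z):
        with pytest.raises(ValueError, match="anchor"):
            shapley_kernel_weight(4, z)


class TestSampling:
    def test_exhaustive_count(self):
        samples = sample_coalitions(3, 0, scheme="exhaustive")
        assert len(samples) == 2**3 - 2
        assert all(1 <= s.z <= 2 for s in samples)

    def test_deterministic_given_seed(self):
        a = sample_coalitions(10, 300, seed=42)
        b = sample_coalitions(10, 300, seed=42)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.mask, sb.mask)
            assert sa.weight == sb.weight

    def test_weights_normalized_and_positive(self):
        for scheme in ("exhaustive", "kernel_prop", "uniform_z"):
            samples = sample_coalitions(8, 200, seed=1, scheme=scheme)
            w = np.array([s.weight for s in samples])
            assert np.all(w > 0)
            assert w.sum() == pytest.approx(1.0)

    def test_residual_level_mass_matches_kernel_proportions(self):
        # enumerated levels carry their exact kernel mass; sampled levels
        # share the residual mass, so per-level totals track the kernel
        d, M = 12, 4000
        samples = sample_coalitions(d, M, seed=0, scheme="kernel_prop")
        mass = {}
        for s in samples:
            mass[s.z] = mass.get(s.z, 0.0) + s.weight
        from scipy.special import comb

        expected = np.array(
            [comb(d, z, exact=True) * shapley_kernel_weight(d, z) for z in range(1, d)]
        )
        expected /= expected.sum()
        got = np.array([mass.get(z, 0.0) for z in range(1, d)])
        # enumerated levels are exact; sampled ones statistical
        assert np.abs(got - expected).max() < 0.05

    def test_small_budget_warns_underdetermined(self):
        with pytest.warns(UserWarning, match="underdetermined"):
            sample_coalitions(10, 20, seed=0, scheme="uniform_z")

    def test_exhaustive_cap_enforced(self):
        with pytest.raises(ValueError, match="capped"):
            sample_coalitions(20, 0, scheme="exhaustive")


class TestWeightedFit:
    def _design(self, d):
        samples = sample_coalitions(d, 0, scheme="exhaustive")
        masks = np.array([s.mask for s in samples])
        w = np.array([s.weight for s in samples])
        return build_design(masks, d), masks, w

    def test_additive_model_recovers_deltas(self):
        d = 4
        wvec = np.array([1.0, -2.0, 0.5, 3.0])
        x = make_lab_patient(d, seed=0, baseline=np.zeros(d))
        f = linear_vf(wvec)
        design, masks, w = self._design(d)
        y = np.array([coalition_value(f, x, Coalition(np.flatnonzero(m))) for m in masks])
        co = fit_weighted_lasso(design, y, w, v0=0.0, vN=float(wvec @ x.values))
        np.testing.assert_allclose(co.main, wvec * x.values, atol=1e-6)
        np.testing.assert_allclose(co.pair, 0.0, atol=1e-6)

    def test_strong_l1_removes_sign_cancellation(self):
        # the efficiency anchor fixes sum(alpha) = v(N) - v(0), so the
        # large-L1 limit is the minimum-norm face ||alpha||_1 = |v(N)-v(0)|
        # (all coefficients share the sign of the total); the data fit has
        # strictly larger L1 mass whenever signs cancel
        d = 4
        model = random_pairwise_model(d, seed=1)
        x = make_lab_patient(d, seed=1)
        f = model.to_value_function()
        delta = abs(f(x.values) - f(x.baseline))
        iu = np.triu_indices(d, 1)
        small = explain_kernel(f, x, scheme="exhaustive", lambda_lasso=1e-4)
        big = explain_kernel(f, x, scheme="exhaustive", lambda_lasso=1e4)
        l1_small = np.abs(np.concatenate([small.main, small.pair[iu]])).sum()
        l1_big = np.abs(np.concatenate([big.main, big.pair[iu]])).sum()
        assert l1_small > delta * 1.05
        assert l1_big == pytest.approx(delta, rel=1e-3)

    def test_underdetermined_unpenalized_fit_raises(self):
        d = 6
        with pytest.warns(UserWarning, match="underdetermined"):
            samples = sample_coalitions(d, 10, seed=3, scheme="uniform_z")
        masks = np.array([s.mask for s in samples])
        w = np.array([s.weight for s in samples])
        design = build_design(masks, d)
        y = np.zeros(len(samples))
        with pytest.raises(IllPosedFitError, match="lambda_lasso"):
            fit_weighted_lasso(design, y, w, v0=0.0, vN=1.0, lambda_lasso=0.0)

    def test_default_lambda_rule(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert default_lambda_lasso(y, "exhaustive") == 0.0
        assert default_lambda_lasso(y, "kernel_prop") == pytest.approx(1e-3 * 1.0)


class TestExplainKernel:
    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_equals_exact_on_pairwise_models(self, seed):
        d = 6
        model = random_pairwise_model(d, seed=seed)
        x = make_lab_patient(d, seed=seed + 100)
        f = model.to_value_function()
        exact = explain_exact(f, x)
        est = explain_kernel(f, x, scheme="exhaustive", lambda_lasso=0.0)
        np.testing.assert_allclose(est.main, exact.main, atol=1e-6)
        np.testing.assert_allclose(est.pair, exact.pair, atol=1e-6)

    def test_same_seed_bitwise_identical(self):
        d = 8
        model = random_pairwise_model(d, seed=5)
        x = make_lab_patient(d, seed=5)
        f = model.to_value_function()
        a = explain_kernel(f, x, M=256, seed=7)
        b = explain_kernel(f, x, M=256, seed=7)
        assert np.array_equal(a.main, b.main) and np.array_equal(a.pair, b.pair)

    def test_anchored_efficiency_exact_for_sampled_fits(self):
        d = 9
        model = random_pairwise_model(d, seed=2)
        x = make_lab_patient(d, seed=2)
        f = model.to_value_function()
        co = explain_kernel(f, x, M=300, seed=1)
        vN = f(x.values)
        v0 = f(x.baseline)
        assert co.total() == pytest.approx(vN - v0, abs=1e-9)
        assert co.intercept == pytest.approx(v0)

    def test_sampling_error_decays_with_budget(self):
        d = 10
        errs = {M: [] for M in (128, 512, 2048)}
        for seed in range(8):
            model = random_pairwise_model(d, seed=seed)
            x = make_lab_patient(d, seed=seed + 20)
            f = model.to_value_function()
            gt = ground_truth_stii(model, x)
            iu = np.triu_indices(d, k=1)
            truth = np.concatenate([gt.main, gt.pair[iu]])
            for M in errs:
                est = explain_kernel(f, x, M=M, seed=seed)
                a = np.concatenate([est.main, est.pair[iu]])
                errs[M].append(np.sqrt(np.mean((a - truth) ** 2)))
        means = [np.mean(errs[M]) for M in (128, 512, 2048)]
        assert means[0] >= means[1] >= means[2]

    def test_sampled_recovery_rank_correlation(self):
        # dense ground truth so the magnitude ranking is fully identified
        d = 15
        rhos = []
        for seed in range(5):
            model = random_pairwise_model(d, seed=seed, pair_density=1.0)
            x = make_lab_patient(d, seed=seed + 40)
            f = model.to_value_function()
            gt = ground_truth_stii(model, x)
            est = explain_kernel(f, x, M=2048, seed=seed)
            iu = np.triu_indices(d, k=1)
            rhos.append(
                spearmanr(
                    np.abs(np.concatenate([est.main, est.pair[iu]])),
                    np.abs(np.concatenate([gt.main, gt.pair[iu]])),
                ).statistic
            )
        assert min(rhos) >= 0.9


class TestDesign:
    def test_pair_column_values_are_mask_ands(self, rng):
        d = 5
        masks = rng.random((20, d)) < 0.5
        design = build_design(masks, d)
        for col, spec in enumerate(design.columns):
            kind, tgt = spec
            if kind == "pair":
                i, j = tgt
                np.testing.assert_array_equal(
                    design.X[:, col], (masks[:, i] & masks[:, j]).astype(float)
                )
                assert pair_column_index(d, i, j) == col


class TestRandomForestStage:
    def _fit_setup(self, f, x, d, M=400, seed=0):
        samples = sample_coalitions(d, M, seed=seed)
        masks = np.array([s.mask for s in samples])
        w = np.array([s.weight for s in samples])
        y = np.array([coalition_value(f, x, Coalition(np.flatnonzero(m))) for m in masks])
        return build_design(masks, d), y, w

    def test_dominant_additive_feature_tops_importance(self):
        d = 6
        wvec = np.zeros(d)
        wvec[2] = 10.0
        x = make_lab_patient(d, seed=0, values=np.ones(d), baseline=np.zeros(d))
        design, y, w = self._fit_setup(linear_vf(wvec), x, d)
        imp = fit_random_forest_surrogate(design, y, w, seed=0)
        assert int(np.argmax(imp)) == 2

    def test_pure_noise_importances_near_uniform(self):
        d = 5
        x = make_lab_patient(d, seed=1)
        design, _, w = self._fit_setup(linear_vf(np.zeros(d)), x, d)
        rng = np.random.default_rng(0)
        hi, lo = [], []
        for seed in range(10):
            y = rng.normal(size=design.X.shape[0])
            imp = fit_random_forest_surrogate(design, y, w, seed=seed, n_estimators=300)
            hi.append(imp.max() / imp.mean())
            lo.append(imp.min() / imp.mean())
        assert np.median(hi) < 3.0
        assert np.median(lo) > 0.2

    def test_deterministic_given_seed(self):
        d = 5
        model = random_pairwise_model(d, seed=3)
        x = make_lab_patient(d, seed=3)
        design, y, w = self._fit_setup(model.to_value_function(), x, d)
        a = fit_random_forest_surrogate(design, y, w, seed=11)
        b = fit_random_forest_surrogate(design, y, w, seed=11)
        np.testing.assert_array_equal(a, b)
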