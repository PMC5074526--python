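"""Maxent fitting: closed forms, KKT optimality, oracle equivalence on
small instances, and prediction semantics."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from invrisk.grids import ClimateStack, GridSpec, Layer
from invrisk.sdm_maxent import (
    FeatureExpansion,
    MaxentError,
    MaxentModel,
    fit_maxent,
    predict_suitability,
    sample_background,
)


class IdentityExpansion(FeatureExpansion):
    """Features = raw covariates, for closed-form instances."""

    def transform(self, X):
        return np.asarray(X, dtype=float)

    @property
    def feature_names(self):
        return list(self.variables)


def identity_expansion(m):
    return IdentityExpansion(
        variables=[f"f{j}" for j in range(m)], mins=np.zeros(m), maxs=np.ones(m)
    )


def penalized_objective(lam, Fp, Fb, beta):
    return float(logsumexp(Fb @ lam) - Fp.mean(axis=0) @ lam + beta @ np.abs(lam))


class TestFit:
    def test_single_binary_feature_closed_form(self):
        # background: 10 cells, 5 with f=1; presence mean 0.8; beta = 0
        # moment matching: 5 e^lam / (5 e^lam + 5) = 0.8  =>  lam = log 4
        bg = np.array([[1.0]] * 5 + [[0.0]] * 5)
        pres = np.array([[1.0]] * 4 + [[0.0]] * 1)
        model = fit_maxent(
            pres, bg, expansion=identity_expansion(1), reg_multiplier=0.0, tol=1e-12
        )
        assert model.lam[0] == pytest.approx(np.log(4.0), abs=1e-4)

    def test_huge_regularization_zeroes_all_weights(self, small_stack):
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(50, 3))
        pres = rng.normal(size=(10, 3)) + 1.0
        model = fit_maxent(pres, bg, reg_multiplier=1e6)
        np.testing.assert_array_equal(model.lam, np.zeros(6))

    @pytest.mark.parametrize("seed", range(10))
    def test_kkt_box_constraint_at_convergence(self, seed):
        rng = np.random.default_rng(seed)
        bg = rng.normal(size=(200, 3))
        pres = rng.normal(loc=0.5, size=(40, 3))
        model = fit_maxent(pres, bg, reg_multiplier=1.0, tol=1e-9)
        assert model.kkt_violation() <= 1e-4

    def test_q_sums_to_one_over_background(self):
        rng = np.random.default_rng(1)
        bg = rng.normal(size=(100, 2))
        pres = rng.normal(loc=0.3, size=(20, 2))
        model = fit_maxent(pres, bg, tol=1e-9)
        q = model.raw_density(bg)
        assert q.sum() == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_numeric_oracle_on_two_features(self, seed):
        # independent oracle: smooth reformulation lam = a - b with a, b >= 0
        # solved by L-BFGS-B; objectives must agree to 1e-5
        rng = np.random.default_rng(seed)
        bg = rng.normal(size=(40, 2))
        pres = rng.normal(loc=0.4, size=(12, 2))
        exp = identity_expansion(2)
        model = fit_maxent(pres, bg, expansion=exp, reg_multiplier=1.0, tol=1e-12)
        Fp, Fb, beta = pres, bg, model.beta

        def split_obj(z):
            lam = z[:2] - z[2:]
            return float(
                logsumexp(Fb @ lam) - Fp.mean(axis=0) @ lam + beta @ (z[:2] + z[2:])
            )

        res = minimize(
            split_obj,
            np.zeros(4),
            method="L-BFGS-B",
            bounds=[(0, None)] * 4,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 20000},
        )
        ours = penalized_objective(model.lam, Fp, Fb, beta)
        assert ours == pytest.approx(res.fun, abs=1e-5)

    def test_l1_norm_monotone_in_regularization(self):
        rng = np.random.default_rng(4)
        bg = rng.normal(size=(150, 3))
        pres = rng.normal(loc=0.6, size=(30, 3))
        norms = [
            np.abs(fit_maxent(pres, bg, reg_multiplier=mult, tol=1e-10).lam).sum()
            for mult in (0.5, 1.0, 2.0)
        ]
        assert norms[0] >= norms[1] >= norms[2]

    def test_input_validation(self):
        with pytest.raises(MaxentError):
            fit_maxent(np.empty((0, 2)), np.ones((5, 2)))
        with pytest.raises(MaxentError):
            fit_maxent(np.ones((3, 2)), np.ones((1, 2)))
        with pytest.raises(MaxentError):
            fit_maxent(np.ones((3, 2)), np.ones((5, 2)), reg_multiplier=-1.0)

    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(5)
        bg = np.column_stack([rng.normal(size=80), np.full(80, 2.5)])
        pres = np.column_stack([rng.normal(loc=0.5, size=15), np.full(15, 2.5)])
        model = fit_maxent(pres, bg, tol=1e-10)
        # scaled constant feature is identical in presence and background:
        # nothing to match, so its weights stay 0
        assert model.lam[1] == pytest.approx(0.0, abs=1e-6)


class TestSerialization:
    def test_json_round_trip_reproduces_predictions(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(60, 2))
        pres = rng.normal(loc=0.4, size=(12, 2))
        model = fit_maxent(pres, bg, seed=123)
        clone = MaxentModel.from_json(model.to_json())
        X = rng.normal(size=(20, 2))
        np.testing.assert_allclose(clone.logistic(X), model.logistic(X), rtol=1e-12)
        assert clone.seed == 123


class TestBackgroundSampling:
    def test_requesting_more_than_valid_uses_all_and_warns(self, small_stack):
        n_valid = int(small_stack.joint_valid_mask().sum())
        with pytest.warns(UserWarning, match="using all"):
            rows, cols = sample_background(small_stack, n_valid + 1000, seed=0)
        assert len(rows) == n_valid

    def test_seed_reproducible(self, small_stack):
        a = sample_background(small_stack, 50, seed=7)
        b = sample_background(small_stack, 50, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_masked_cells_never_sampled(self, small_spec):
        vals = np.ones((30, 30))
        vals[:, :15] = np.nan
        stack = ClimateStack.from_layers([Layer(small_spec, "v", vals)])
        rows, cols = sample_background(stack, 100, seed=1)
        assert (cols >= 15).all()

    def test_distinct_cells(self, small_stack):
        rows, cols = sample_background(small_stack, 200, seed=3)
        assert len({(r, c) for r, c in zip(rows, cols)}) == 200


class TestPrediction:
    def test_zero_weight_model_predicts_half_everywhere(self, small_stack):
        rng = np.random.default_rng(7)
        rows, cols = sample_background(small_stack, 100, seed=0)
        bg = small_stack.extract(rows, cols, ["BIO1", "BIO12"])
        pres = bg[:10]
        model = fit_maxent(pres, bg, variables=["BIO1", "BIO12"], reg_multiplier=1e9)
        suit = predict_suitability(model, small_stack)
        valid = suit.valid_mask
        np.testing.assert_allclose(suit.values[valid], 0.5, atol=1e-12)

    def test_prediction_in_unit_interval(self, small_stack):
        rows, cols = sample_background(small_stack, 300, seed=1)
        bg = small_stack.extract(rows, cols, ["BIO1", "BIO12"])
        model = fit_maxent(bg[:40] * 1.01, bg, variables=["BIO1", "BIO12"])
        suit = predict_suitability(model, small_stack)
        vals = suit.values[suit.valid_mask]
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_missing_covariate_layer_named(self, small_stack):
        rng = np.random.default_rng(8)
        bg = rng.normal(size=(50, 1))
        model = fit_maxent(bg[:5], bg, variables=["NOPE"])
        with pytest.raises(MaxentError, match="NOPE"):
            predict_suitability(model, small_stack)

    def test_features_clamped_outside_background_range(self):
        exp = FeatureExpansion(variables=["v"], mins=np.array([0.0]), maxs=np.array([1.0]))
        F = exp.transform(np.array([[-5.0], [0.5], [99.0]]))
        assert F.min() >= 0.0 and F.max() <= 1.0
        np.testing.assert_allclose(F[0], [0.0, 0.0])
        np.testing.assert_allclose(F[2], [1.0, 1.0])

    def test_scaled_features_lie_in_unit_box_on_background(self):
        rng = np.random.default_rng(9)
        bg = rng.normal(size=(100, 3)) * 40 - 7
        exp = FeatureExpansion.fit(bg, ["a", "b", "c"])
        F = exp.transform(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0
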