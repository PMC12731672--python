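"""Shapley axioms on the full 9-feature enumeration; LIME surrogate recovery."""

import itertools
import math

import numpy as np
import pytest

from fedecg.explain import (
    ExactShapleyExplainer,
    LimeExplainer,
    exact_shapley,
    lime_explain,
    shap_summary,
)
from fedecg.lstm import build_network


class LinearModel:
    """Test double: p(class 1 | x) = w . x + b (not normalised; the
    explainers only read one output column)."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, float)
        self.b = b

    def predict_proba(self, X):
        out = np.zeros((len(X), 3))
        out[:, 1] = X @ self.w + self.b
        return out


def _background(seed=0, n=25):
    return np.random.default_rng(seed).normal(size=(n, 9))


class TestShapley:
    def test_constant_model_has_zero_attributions(self):
        model = LinearModel(np.zeros(9), b=0.7)
        att = exact_shapley(model, np.ones(9), _background(), target_class=1)
        np.testing.assert_allclose(att.phi, 0.0, atol=1e-12)
        assert att.base_value == pytest.approx(0.7)
        assert att.fx == pytest.approx(0.7)

    def test_linear_model_closed_form(self):
        """For f(x) = w.x the interventional Shapley value is
        w_i (x_i - mean background_i), exactly."""
        rng = np.random.default_rng(1)
        w = rng.normal(size=9)
        bg = _background(2)
        x = rng.normal(size=9)
        att = exact_shapley(LinearModel(w), x, bg, target_class=1)
        np.testing.assert_allclose(att.phi, w * (x - bg.mean(axis=0)),
                                   atol=1e-10)

    def test_efficiency_axiom_on_network(self):
        """sum(phi) = f(x) - E[f(background)] for the actual LSTM."""
        clf, _ = build_network(seed=5)
        bg = _background(3, n=30)
        x = np.random.default_rng(4).normal(size=9)
        for cls in range(3):
            att = exact_shapley(clf, x, bg, target_class=cls)
            assert att.efficiency_gap() < 1e-6

    def test_dummy_feature_gets_exact_zero(self):
        w = np.array([1.0, 0.0, 2.0, 0.0, 0.0, 0.0, 0.0, 0.0, -1.0])
        att = exact_shapley(LinearModel(w), np.ones(9) * 2, _background(5),
                            target_class=1)
        for j in np.flatnonzero(w == 0):
            assert att.phi[j] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_features_get_equal_values(self):
        class SymModel:
            def predict_proba(self, X):
                out = np.zeros((len(X), 3))
                out[:, 1] = np.tanh(X[:, 0] + X[:, 1])
                return out

        bg = _background(6)
        bg[:, 1] = bg[:, 0]  # exchangeable background
        x = np.zeros(9)
        x[0] = x[1] = 1.3
        att = exact_shapley(SymModel(), x, bg, target_class=1)
        assert att.phi[0] == pytest.approx(att.phi[1], abs=1e-9)

    def test_matches_permutation_average_oracle(self):
        """Enumeration vs a direct average of marginal contributions over
        all orderings of a 4-feature game (features 4..8 are dummies)."""
        rng = np.random.default_rng(7)

        class ToyModel:
            def predict_proba(self, X):
                out = np.zeros((len(X), 3))
                out[:, 1] = (X[:, 0] * X[:, 1] + np.sin(X[:, 2])
                             + 0.5 * X[:, 3] ** 2)
                return out

        model = ToyModel()
        bg = np.zeros((6, 9))
        bg[:, :4] = rng.normal(size=(6, 4))
        x = rng.normal(size=9)

        att = exact_shapley(model, x, bg, target_class=1)

        def v(S):  # interventional value over the active 4-feature game
            Z = bg.copy()
            for j in S:
                Z[:, j] = x[j]
            return model.predict_proba(Z)[:, 1].mean()

        active = [0, 1, 2, 3]
        phi_oracle = np.zeros(4)
        perms = list(itertools.permutations(active))
        for perm in perms:
            S = []
            for j in perm:
                before = v(tuple(S))
                S.append(j)
                phi_oracle[j] += v(tuple(S)) - before
        phi_oracle /= len(perms)
        np.testing.assert_allclose(att.phi[:4], phi_oracle, atol=1e-10)
        np.testing.assert_allclose(att.phi[4:], 0.0, atol=1e-12)

    def test_weights_sum_to_one_over_chain(self):
        """The factorial weights sum to 1 along any feature's coalitions."""
        ex = ExactShapleyExplainer(LinearModel(np.ones(9)), _background())
        total = sum(
            math.comb(8, s) * ex.weights_by_size_[s] for s in range(9)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ExactShapleyExplainer(LinearModel(np.ones(9)), np.empty((0, 9)))


class TestShapSummary:
    def test_singleton_equals_row_attribution(self):
        w = np.random.default_rng(8).normal(size=9)
        bg = _background(9)
        x = np.random.default_rng(10).normal(size=(1, 9))
        summary = shap_summary(LinearModel(w), x, bg, target_class=1)
        att = exact_shapley(LinearModel(w), x[0], bg, target_class=1)
        merged = summary.set_index("feature")
        from fedecg.features import FEATURE_NAMES
        for j, name in enumerate(FEATURE_NAMES):
            assert merged.loc[name, "mean_phi"] == pytest.approx(att.phi[j])

    def test_duplicated_rows_leave_summary_unchanged(self):
        w = np.random.default_rng(11).normal(size=9)
        bg = _background(12)
        X = np.random.default_rng(13).normal(size=(4, 9))
        a = shap_summary(LinearModel(w), X, bg, target_class=1)
        b = shap_summary(LinearModel(w), np.vstack([X, X]), bg, target_class=1)
        np.testing.assert_allclose(a["mean_phi"], b["mean_phi"], atol=1e-12)

    def test_single_active_feature_ranks_first(self):
        """w = e_ST: the ST column dominates the ranking; others are ~0."""
        from fedecg.features import FEATURE_NAMES
        w = np.zeros(9)
        w[FEATURE_NAMES.index("ST")] = 1.0
        X = np.random.default_rng(14).normal(size=(5, 9))
        summary = shap_summary(LinearModel(w), X, _background(15), target_class=1)
        assert summary.iloc[0]["feature"] == "ST"
        assert np.all(summary.iloc[1:]["mean_abs_phi"] < 1e-10)


class TestLime:
    def test_linear_recovery(self):
        """Wide kernel, no sparsity cap: coefficients within 5% and
        fidelity >= 0.99."""
        rng = np.random.default_rng(16)
        w = rng.normal(size=9) + np.sign(rng.normal(size=9)) * 0.5
        model = LinearModel(w, b=0.3)
        x = rng.normal(size=9)
        exp = lime_explain(model, x, target_class=1, kernel_width=50.0, seed=0)
        np.testing.assert_allclose(exp.coefficients, w, rtol=0.05)
        assert exp.fidelity >= 0.99

    def test_constant_model(self):
        exp = lime_explain(LinearModel(np.zeros(9), b=0.4), np.zeros(9),
                           target_class=1, seed=1)
        np.testing.assert_allclose(exp.coefficients, 0.0, atol=1e-9)
        assert exp.intercept == pytest.approx(0.4, abs=1e-9)

    def test_sparsity_cap_enforced(self):
        rng = np.random.default_rng(17)
        model = LinearModel(rng.normal(size=9))
        exp = lime_explain(model, rng.normal(size=9), target_class=1,
                           sparsity_cap=2, seed=2)
        assert np.count_nonzero(exp.coefficients) <= 2

    def test_narrow_kernel_tracks_local_gradient(self):
        """On f(x) = x_0^3 the surrogate slope carries a curvature bias of
        3 sigma_eff^2 that shrinks with the kernel width, so a narrower
        kernel lands closer to the true local gradient 3 x_0^2."""

        class Cubic:
            def predict_proba(self, X):
                out = np.zeros((len(X), 3))
                out[:, 1] = X[:, 0] ** 3
                return out

        x = np.zeros(9)
        x[0] = 1.5
        true_grad = 3 * x[0] ** 2
        wide = lime_explain(Cubic(), x, 1, kernel_width=5.0, seed=3,
                            n_samples=4000)
        narrow = lime_explain(Cubic(), x, 1, kernel_width=0.4, seed=3,
                              n_samples=4000)
        assert (abs(narrow.coefficients[0] - true_grad)
                < abs(wide.coefficients[0] - true_grad))

    def test_seeded_determinism(self):
        model = LinearModel(np.arange(9, dtype=float))
        a = lime_explain(model, np.ones(9), 1, seed=5)
        b = lime_explain(model, np.ones(9), 1, seed=5)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.fidelity == b.fidelity

    def test_sample_budget_guard(self):
        with pytest.raises(ValueError, match="n_samples"):
            LimeExplainer(LinearModel(np.ones(9)), n_samples=50, sparsity_cap=9)

    def test_report_serialisable(self):
        import json
        exp = lime_explain(LinearModel(np.ones(9)), np.zeros(9), 1, seed=6)
        text = json.dumps(exp.to_dict())
        assert "kernel_width" in text
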