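"""Post-hoc attribution for the global model: exact Shapley values by full
coalition enumeration, and LIME kernel-weighted local linear surrogates.

Shapley values use the interventional value function: the "model output when
only coalition S is available" is the model's mean output over a background
sample with the out-of-coalition features replaced by the background row's
values.  With 9 features the 2^9 = 512 coalitions are enumerated exactly —
no sampling approximation — and the marginal contributions are combined with
the factorial weights |S|! (|F|-|S|-1)! / |F|!.  The explained output is the
softmax probability of the target class, so a positive value pushes that
class's probability up.

LIME draws Gaussian perturbations of the instance in standardised feature
space, weights them with the RBF kernel pi_x(z) = exp(-d(x,z)^2 / width^2),
and fits a weighted least-squares linear surrogate; sparsity is enforced by
refitting on the top-k coefficients.  Local fidelity is the kernel-weighted
R^2 of the surrogate against the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, N_FEATURES, FeatureMatrix

__all__ = [
    "ShapAttribution", "LimeExplanation", "ExactShapleyExplainer",
    "LimeExplainer", "exact_shapley", "shap_summary", "lime_explain",
]


def _predict_fn(model):
    """Normalise a model-ish argument to a callable (n, 9) -> (n, k)."""
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    return model.predict_proba


@dataclass
class ShapAttribution:
    """Per-instance Shapley attribution for one target class."""

    x: np.ndarray
    target_class: int
    phi: np.ndarray
    base_value: float
    fx: float

    def efficiency_gap(self) -> float:
        """|sum(phi) - (f(x) - base)|; zero up to float error by the
        efficiency axiom."""
        return float(abs(self.phi.sum() - (self.fx - self.base_value)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": FEATURE_NAMES, "phi": self.phi, "abs_phi": np.abs(self.phi)}
        )


@dataclass
class LimeExplanation:
    """Local linear surrogate around one instance for one target class."""

    x: np.ndarray
    target_class: int
    coefficients: np.ndarray
    intercept: float
    kernel_width: float
    n_samples: int
    fidelity: float
    sparsity_cap: int
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def top_features(self, k: int | None = None) -> list[tuple[str, float]]:
        order = np.argsort(-np.abs(self.coefficients))
        if k is not None:
            order = order[:k]
        return [(self.feature_names[i], float(self.coefficients[i]))
                for i in order if self.coefficients[i] != 0.0]

    def to_dict(self) -> dict:
        return {
            "target_class": int(self.target_class),
            "intercept": float(self.intercept),
            "coefficients": dict(zip(self.feature_names,
                                     map(float, self.coefficients))),
            "kernel_width": float(self.kernel_width),
            "n_samples": int(self.n_samples),
            "fidelity": float(self.fidelity),
            "sparsity_cap": int(self.sparsity_cap),
        }


class ExactShapleyExplainer:
    """Exact Shapley attribution over all feature coalitions.

    Parameters
    ----------
    model:
        Anything with ``predict_proba`` (or a bare callable returning class
        probabilities).
    background:
        Reference sample defining the interventional value function; at most
        ``max_background`` rows are kept (seeded subsample).
    """

    def __init__(self, model, background: FeatureMatrix | np.ndarray,
                 max_background: int = 100, random_state: int = 0):
        self._f = _predict_fn(model)
        B = (background.values if isinstance(background, FeatureMatrix)
             else np.asarray(background, float))
        if B.ndim != 2 or B.shape[1] != N_FEATURES:
            raise ValueError(f"background must be (m, {N_FEATURES})")
        if B.shape[0] == 0:
            raise ValueError("background must be non-empty")
        if B.shape[0] > max_background:
            rng = np.random.default_rng(random_state)
            B = B[rng.choice(B.shape[0], max_background, replace=False)]
        self.background_ = B
        d = N_FEATURES
        # coalition masks as bits; masks_[s, j] = feature j in coalition s
        self.masks_ = (
            (np.arange(2 ** d)[:, None] >> np.arange(d)) & 1
        ).astype(bool)
        sizes = self.masks_.sum(axis=1)
        fact = np.array([factorial(i) for i in range(d + 1)], dtype=float)
        # weight attached to a coalition S (not containing i): |S|!(d-|S|-1)!/d!
        self.weights_by_size_ = np.array(
            [fact[s] * fact[d - s - 1] / fact[d] for s in range(d)]
        )
        self.sizes_ = sizes

    def coalition_values(self, x: np.ndarray, target_class: int) -> np.ndarray:
        """v(S) for every coalition: mean model output over the background
        with features in S taken from x."""
        x = np.asarray(x, float).reshape(N_FEATURES)
        m = self.background_.shape[0]
        n_coal = self.masks_.shape[0]
        # (n_coal, m, d): background with x substituted inside the coalition
        synth = np.where(
            self.masks_[:, None, :], x[None, None, :],
            self.background_[None, :, :],
        )
        probs = self._f(synth.reshape(-1, N_FEATURES))[:, target_class]
        return probs.reshape(n_coal, m).mean(axis=1)

    def explain(self, x: np.ndarray, target_class: int) -> ShapAttribution:
        x = np.asarray(x, float).reshape(N_FEATURES)
        v = self.coalition_values(x, target_class)
        d = N_FEATURES
        phi = np.zeros(d)
        coal_ids = np.arange(2 ** d)
        for j in range(d):
            without = (coal_ids & (1 << j)) == 0
            s_ids = coal_ids[without]
            w = self.weights_by_size_[self.sizes_[s_ids]]
            phi[j] = np.sum(w * (v[s_ids | (1 << j)] - v[s_ids]))
        return ShapAttribution(
            x=x, target_class=int(target_class), phi=phi,
            base_value=float(v[0]), fx=float(v[-1]),
        )


def exact_shapley(model, x, background, target_class: int,
                  max_background: int = 100, seed: int = 0) -> ShapAttribution:
    """Functional wrapper: exact Shapley values of ``x`` for one class."""
    return ExactShapleyExplainer(
        model, background, max_background=max_background, random_state=seed
    ).explain(x, target_class)


def shap_summary(model, X: FeatureMatrix | np.ndarray, background,
                 target_class: int, max_background: int = 100,
                 seed: int = 0) -> pd.DataFrame:
    """Cohort-level attribution summary: per-feature mean signed Shapley
    value and mean |value|, ranked by the latter."""
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    if Xv.shape[0] == 0:
        raise ValueError("X must be non-empty")
    explainer = ExactShapleyExplainer(
        model, background, max_background=max_background, random_state=seed
    )
    phis = np.stack(
        [explainer.explain(row, target_class).phi for row in Xv]
    )
    out = pd.DataFrame({
        "feature": FEATURE_NAMES,
        "mean_phi": phis.mean(axis=0),
        "mean_abs_phi": np.abs(phis).mean(axis=0),
    })
    return out.sort_values("mean_abs_phi", ascending=False,
                           kind="mergesort").reset_index(drop=True)


class LimeExplainer:
    """LIME with Gaussian perturbations and an RBF proximity kernel."""

    def __init__(self, model, kernel_width: float = 0.75 * np.sqrt(N_FEATURES),
                 n_samples: int = 1000, sparsity_cap: int = N_FEATURES,
                 feature_scales: np.ndarray | None = None,
                 random_state: int = 0):
        if kernel_width <= 0:
            raise ValueError("kernel_width must be > 0")
        if not (1 <= sparsity_cap <= N_FEATURES):
            raise ValueError(f"sparsity_cap must be in 1..{N_FEATURES}")
        if n_samples < 10 * sparsity_cap:
            raise ValueError("n_samples must be >= 10 * sparsity_cap")
        self._f = _predict_fn(model)
        self.kernel_width = kernel_width
        self.n_samples = n_samples
        self.sparsity_cap = sparsity_cap
        self.feature_scales = (
            np.ones(N_FEATURES) if feature_scales is None
            else np.asarray(feature_scales, float)
        )
        if np.any(self.feature_scales <= 0):
            raise ValueError("feature_scales must be positive")
        self.random_state = random_state

    def explain(self, x: np.ndarray, target_class: int) -> LimeExplanation:
        x = np.asarray(x, float).reshape(N_FEATURES)
        rng = np.random.default_rng(self.random_state)
        # perturb in standardised space, map back to model-input units
        eps = rng.normal(size=(self.n_samples, N_FEATURES))
        Z = x + eps * self.feature_scales
        if np.allclose(Z.std(axis=0), 0):
            raise ValueError("degenerate perturbations: zero variance")
        d2 = np.sum(eps ** 2, axis=1)  # distances in standardised space
        w = np.exp(-d2 / self.kernel_width ** 2)
        target = self._f(Z)[:, target_class]

        Zs = (Z - x) / self.feature_scales  # regress in standardised units
        coef_s, intercept = self._wls(Zs, target, w)
        if self.sparsity_cap < N_FEATURES:
            keep = np.argsort(-np.abs(coef_s))[: self.sparsity_cap]
            coef_s = np.zeros(N_FEATURES)
            coef_sub, intercept = self._wls(Zs[:, keep], target, w)
            coef_s[keep] = coef_sub
        pred = Zs @ coef_s + intercept
        wmean = np.average(target, weights=w)
        ss_res = np.sum(w * (target - pred) ** 2)
        ss_tot = np.sum(w * (target - wmean) ** 2)
        fidelity = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return LimeExplanation(
            x=x, target_class=int(target_class),
            coefficients=coef_s / self.feature_scales,  # model-input units
            intercept=float(intercept),
            kernel_width=self.kernel_width, n_samples=self.n_samples,
            fidelity=float(fidelity), sparsity_cap=self.sparsity_cap,
        )

    @staticmethod
    def _wls(Z: np.ndarray, y: np.ndarray, w: np.ndarray):
        sw = np.sqrt(w)
        A = np.column_stack([Z, np.ones(len(Z))]) * sw[:, None]
        sol, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        return sol[:-1], float(sol[-1])


def lime_explain(model, x, target_class: int, n_samples: int = 1000,
                 kernel_width: float = 0.75 * np.sqrt(N_FEATURES),
                 sparsity_cap: int = N_FEATURES,
                 feature_scales: np.ndarray | None = None,
                 seed: int = 0) -> LimeExplanation:
    """Functional wrapper around :class:`LimeExplainer`."""
    return LimeExplainer(
        model, kernel_width=kernel_width, n_samples=n_samples,
        sparsity_cap=sparsity_cap, feature_scales=feature_scales,
        random_state=seed,
    ).explain(x, target_class)
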