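# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the simulation shows.

## Problem setting

The package classifies single heartbeats into three cardiac states —
arrhythmic, healthy, ischemic — from nine fiducial features of the
P–QRS–T cycle: heart rate (HR, beats/min), R-wave and P-wave heights
(R-H, P-H, mV), PR interval (PRQ), QT interval, rate-corrected QT (QTC),
RR interval (RR-I), QRS duration (all ms), and the ST-segment level (ST,
mV, signed relative to the isoelectric line). The training data are held
by simulated institutions that never share records; only model parameters
(and 18 scalar standardisation statistics) cross the client boundary.

## Synthetic cohort generator

Real multi-institution fiducial datasets cannot be redistributed, so the
generator is a first-class, tested component rather than a fixture. Each
class draws feature vectors from a multivariate normal with a documented
location/scale table (diagonal covariance; positive-support features
truncated at 1e-3). The defaults encode textbook electrophysiology:

* **ischemic** — depressed ST (−0.10 ± 0.09 mV vs +0.02 ± 0.035 healthy)
  and prolonged QTc (455 ± 32 ms vs 410 ± 15);
* **arrhythmic** — strongly dispersed RR intervals (scale multiplied by
  the `rr_jitter_arrhythmic = 4.0` factor, i.e. ±360 ms vs ±40 healthy),
  elevated and variable heart rate, reduced P-wave height
  (0.10 ± 0.055 mV vs 0.15 ± 0.03);
* **healthy** — tight dispersion on every feature (stable sinus rhythm).

Records come in subject blocks (20 beats/subject) sharing an additive
random effect on HR (σ = 4 bpm) and RR-I (σ = 25 ms), so subject-level
splitting is meaningful and leakage checks have something to detect.

The class overlap was calibrated once, before the test suite was frozen,
to a stated design target: a multinomial logistic baseline reaches the
mid-80s% accuracy on the default 4500-record cohort while quadratic
discriminant analysis (which can exploit the class-specific dispersion)
reaches ≈ 94–95%. Much of the class signal is therefore *variance*
structure — exactly the kind of cue (RR irregularity) a linear model
cannot use but the LSTM can, which makes the nonlinear classifier's gain
observable. What passing tests show is that the pipeline learns and
explains this structure; they do not certify performance on real ECGs,
whose feature distributions are heavier-tailed, correlated, and
device-dependent.

## Non-IID sharding

Client sizes are drawn from Dirichlet(`size_skew`, default 5.0); within
each class, records are split across clients proportionally to the size
weight times a per-class Dirichlet(`label_skew`, default 0.5) draw, with
largest-remainder rounding so the shards are an exact partition and every
shard is non-empty. Low `label_skew` yields dominant-class institutions
("arrhythmia-dominant", "ischemia-dominant"); as it grows the shards
approach the IID limit, which the suite checks at `label_skew = 1e4`.

## Client model and training

The classifier feeds the 9 features as a length-9 sequence of scalars in
canonical order through three stacked LSTM layers (64/32/16 units; first
two return sequences), ReLU on each layer's output, dropout 0.2 after
each, and a softmax-3 dense head — 32,499 parameters. Cells are standard
single-bias LSTM cells (sigmoid gates, tanh activations); the ReLU acts
on the output passed to the next layer, not inside the recurrence. The
sequence framing is a documented design choice rather than a claim that
the features are a time series; predictions depend on the registry order,
which is therefore immutable package-wide.

Training is mini-batch (B = 32) sparse categorical cross-entropy for
E = 15 local epochs per round at lr 0.001. Adam is the default optimizer;
`optimizer="sgd"` gives the plain θ ← θ − ηΔθ update. Gradients come
from full backpropagation through time, pinned by a finite-difference
check in the suite. Initialisation is Glorot-uniform kernels with zero
biases except the forget-gate slice at 1. Every stochastic element
(init, dropout, shuffling) draws from seeded generators; per-client seeds
are derived from the global seed, the client id, and the round index, so
runs are bit-reproducible on a fixed single-threaded BLAS (the test suite
and the acceptance script pin BLAS threading to 1 for this reason).

Optimizer state is local to a round: each client re-initialises Adam
moments when it receives the broadcast parameters, the standard choice in
federated averaging.

## Federation

All N = 10 clients train in every round; the server aggregates with the
uniform parameter mean by default (`size_weighted` gives the
|D_i|/|D|-weighted mean; both are one flag apart because the pseudocode
mean and the size-weighted objective imply different weightings). The
round/epoch schedule is R communication rounds × E local epochs, both
configurable, defaults R = 15, E = 15. The global model is evaluated on
the central held-out test set after every aggregation.

SMOTE runs *inside each client* on its private shard, after sharding and
after the train/test split, because rebalancing the merged dataset would
contradict the privacy premise; classes with fewer than two local records
are left as-is. Per-client z-score standardisation is fitted on the local
(post-SMOTE) shard; the server's evaluation scaler is the size-weighted
average of the client statistics — 18 scalars, the same privacy footprint
as exchanging parameters.

Federated k-fold cross-validation groups folds by subject (a subject
never straddles folds), re-shards the remaining data each fold, and
reports per-fold final metrics with mean ± sd.

## Metric conventions

Per-class TP/TN/FP/FN come from one-vs-rest reduction of the 3×3
confusion matrix. Headline precision/recall/F1 are support-weighted —
the convention under which weighted recall is algebraically identical to
accuracy, an identity the suite asserts for every matrix. MC rate is
exactly 1 − accuracy. FNR/FPR are macro-averaged by default (micro is a
flag; micro-FNR collapses to 1 − accuracy). Zero-denominator cells
resolve to 0 with a flag so degenerate early-round predictors never crash
the history. AUC is the pairwise-concordance / Mann–Whitney statistic
(ties count ½), checked against an independent rank-statistic
implementation.

## Explainers

The Shapley value function is interventional: v(S) is the model's mean
target-class probability over a background sample with out-of-coalition
features replaced by background values. With 9 features the 512
coalitions are enumerated exactly (default background: 100 seeded rows),
so the axioms are testable rather than approximate: efficiency to 1e-6
(observed ~1e-16), exact zeros for dummy features, and agreement with a
permutation-average oracle on small games. The explained output is the
softmax probability of a chosen class, so φ > 0 pushes that class up.
The summary table reports both signed means and mean absolute values.

LIME perturbs the instance with unit Gaussians in standardised feature
space, weights by exp(−d²/w²) with the common default width
w = 0.75·√9 = 2.25, fits weighted least squares, and enforces the
complexity cap by refitting on the top-k coefficients. Fidelity is the
kernel-weighted R². On a linear model the coefficients are recovered
within 5% with fidelity ≥ 0.99; on the trained LSTM over this default
(wide) neighbourhood the linear surrogate's fidelity is genuinely modest
— that is a property of explaining a deep model with a linear one, and it
is reported, not hidden. A narrower kernel tracks the local gradient more
closely (asserted on a cubic test double).

## Problem sizes

The reference simulation uses 1500 records per class (4500 total; ≈ 3000
train / 1500 test after the 67/33 subject split), 10 clients, 15 rounds —
sizes chosen so the full pipeline, including the from-scratch LSTM, runs
in minutes on a single CPU while still showing the federated trajectory:
held-out accuracy rises from ≈ 0.5 in round 1 to ≥ 0.90 by round 15.
Unit tests use miniature cohorts and narrow networks.

## Known limitations

* The generator's diagonal-Gaussian law omits feature correlations
  (e.g. HR–RR-I are deterministic inverses in real ECGs), heavy tails,
  and device effects; conclusions about real data require real data.
* The three post-rebalancing class counts of the reference merged
  dataset (111,659 / 284,849 / 705,983 of 1,102,491) do not correspond
  to any standard SMOTE target ratio (the majority class grows), so that
  exact resampling recipe is not reconstructable; the package implements
  standard minority oversampling with `target="balance"` or explicit
  per-class targets.
* A degenerate all-one-class predictor reporting FNR 0 and FPR 1
  simultaneously matches no standard 3-class averaging; this package's
  macro averaging reports its own consistent values instead.
* Client dropout, stragglers, communication latency, secure aggregation
  and differential privacy are out of scope.
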