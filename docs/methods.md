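# Methods

This note documents the modelling and numerical choices behind
`pdresnet`: what each stage assumes, which parameters matter, what the
synthetic cohort does and does not emulate, and where the design was
genuinely open.

## The synthetic cohort generator

`pdresnet.cohort` emulates a per-subject gait feature table, not raw
inertial-sensor signals. Each of the three condition blocks (TUG 97,
TURN 7, NARROW 86 features) is an equicorrelated Gaussian built from a
shared block factor:

    x_ij = mu_class,j + noise_sd * (sqrt(rho) z_block + sqrt(1 - rho) eps_ij)

so every gait feature has marginal standard deviation `noise_sd`
(default 1.0) and within-block pairwise correlation `rho` (default 0.3 —
gait features derived from the same walking test are substantially
correlated, but far from collinear). A fraction `shift_fraction`
(default 0.3) of the features in each block, chosen deterministically
from the config seed, carries the class signal: PD rows are shifted by
`effect_size * noise_sd` (default 1.0, a large-but-plausible
standardized group difference for gait speed/variability measures in
moderate PD), and moderate-to-advanced rows by an additional
`subgroup_effect * noise_sd` (default 0.75), encoding the Hoehn–Yahr
ordering HC < early < moderate-to-advanced as a pure location shift.
Demographics are sex ~ Bernoulli(0.5), age ~ N(65, 8) years, thigh
length ~ N(45, 3) cm, lower-leg length ~ N(38, 3) cm, identical across
classes — the reference cohort is age-matched, and an un-shifted
demographic block keeps it that way.

Default group sizes are the study design: 296 PD (230 early + 66
moderate-to-advanced) and 161 HC, 194 feature columns.

What the generator does **not** emulate: heavy-tailed or skewed feature
distributions, cross-block correlation, missingness, medication-state
(ON/OFF) effects, site or device drift, and any nonlinear or
interaction-structured class signal. Passing tests therefore demonstrate
that the pipeline recovers a linear-in-features location signal under
Gaussian noise at realistic sample sizes — they do not certify clinical
accuracy on real gait tables.

## Preprocessing

* **SMOTE** is implemented exactly as the interpolation rule
  `x + u (x_nn - x)` over the k = 5 Euclidean nearest minority
  neighbours (k is the canonical default; the neighbour search uses
  scikit-learn's `NearestNeighbors`). Synthetic rows are flagged in a
  `synthetic` column and inherit their seed row's labels.
* **Order of operations.** The default pipeline balances the *whole*
  table and then splits 70/30, which reproduces the reference test-set
  size (592 × 0.3 → 178) but leaks minority-interpolation structure into
  the test partition. `preprocessing.split_first = True` gives the
  leak-free variant: split the raw table, balance the training side
  only. The null-calibration check in the acceptance suite uses the
  leak-free order — under the leaky order a classifier genuinely detects
  synthetic-ness of test rows (~70% null accuracy was observed), which
  is a property of the evaluation protocol, not of the features.
* **Normalization** is per-feature min–max to [0, 1], fitted on the
  training partition only (scikit-learn `MinMaxScaler(clip=True)`):
  constant features map to 0 and out-of-range test values clip. It runs
  *before* polynomial elevation so that products of features stay in
  [0, 1] instead of compounding raw scales.
* **Polynomial elevation** emits originals, squares, then pairwise
  products (i, j) in lexicographic order, i < j. For 194 features this
  is 19 109 terms, more than 117² = 13 689, so the vector is truncated
  to the first 13 689 terms (zero-padded in the opposite case). The
  fixed term order makes the truncation reproducible; which cross terms
  survive is arbitrary but deterministic.
* **Resize** is bilinear with corner-aligned sampling
  (`i (n−1)/(m−1)`), so corners are preserved and constant images stay
  constant. It is verified in tests against an independently coded
  two-pass 1-D interpolation.
* **Random erasing** uses the original recipe's defaults: probability
  0.5, area ratio (0.02, 0.33), aspect ratio (0.3, 3.3),
  uniform-random fill on the normalized intensity scale, rejection
  sampling with 100 attempts. It is applied online, per training batch
  only — evaluation images are never erased.
* **Split sizes** use nearest-integer rounding of `n * test_fraction`
  (592 × 0.3 → 178) with stratification; batches are 23 with the last
  batch short (592 → 25 × 23 + 17).

## The network

The residual unit is conv(3×3)–BN–ReLU–conv(3×3)–BN plus a shortcut
(identity when shape-preserving, else strided 1×1 projection + BN), with
ReLU after the addition. Zeroing the branch parameters makes the unit an
exact pass-through of non-negative inputs, which the tests use to verify
the additive identity; the same zeroing applied to the whole backbone
reduces it to the stem-plus-projections chain.

The default plan is stem 1→64 (1×1 convolution), layers 64→128→256→512
with two units per layer and stride-2 first units (112 → 56 → 28 → 14),
global average pooling to the 512-value descriptor, and a 2-neuron
sigmoid head — about 11.0 M parameters. The two output neurons are
trained with complementary labels (neuron 1 = positive class), which
makes the scalar positive probability `p₊` well defined for both the
loss and the ≥ 0.5 decision rule.

Initialization is Kaiming fan-in normal for convolutions and the head,
unit gain / zero shift for batch norm, all drawn from a single seeded
generator so two builds with equal seeds are bit-identical. The engine
computes in float32 by default (float64 is available and is used for
finite-difference gradient verification, which agrees with
backpropagation to ~1e-10 relative error).

## Loss family

Natural logarithms throughout. `p' = 0` is clamped to machine epsilon
before the log for CE and FL (the clamp is logged at debug level); IFL
is identically zero on `[0, tau)` — the boundary `p' = tau` uses the
formula, since the zero branch is a strict inequality. The analytic
gradient of IFL, `2 p' log p' − (1 − p'²)/p'`, is exercised both in unit
tests (against central differences, 1e-6) and in training: a batch whose
every sample lies below `tau` produces an exactly zero parameter update.
One terminological note: the coefficients `(1 − p')²` and `(1 − p'²)`
are referred to by their shapes on (0, 1) — what matters operationally
is that `(1 − p')² < 1 − p'² < 1` there, giving the strict ordering
FL < IFL < CE that the tests assert.

## Training protocol

RMSprop with smoothing constant 0.99 and epsilon 1e-8, no momentum, no
weight decay. Learning rate `1e-3 × 0.2^floor((epoch−1)/10)`. Early
stopping monitors held-out loss with patience 5 and restores the best
recorded state (parameters *and* batch-norm running statistics);
`max_epochs` defaults to 100. By default the held-out set is a
validation split carved from the training partition
(`val_fraction = 0.15`), because monitoring the test set during training
is itself a mild leak; `preprocessing.paper_faithful = True` monitors
the test partition instead, reproducing the reference protocol.

Seeding: one master seed per experiment is expanded through
`numpy.random.SeedSequence` into independent sub-seeds for cohort
generation, SMOTE, the outer split, the validation split, weight
initialization and the training loop, so a full run is bit-reproducible
(`metrics.json` is byte-identical across reruns) while no two stages
share a stream.

## Evaluation

Metrics follow the four-cell confusion matrix with PD (or the
task-specific positive class) as positive. Percentages are kept at full
precision internally and rounded to 2 d.p. for reporting. A metric with
a zero denominator is reported as undefined (`None`/JSON `null`), never
as 0 or 100. AUC is the trapezoidal area under the threshold-swept ROC
curve, equal to the concordant-pair probability with ties counted half
(verified against an O(n²) oracle).

## Desk-scale evaluation preset

`ExperimentConfig.compact()` keeps the full topology (three residual
layers, two units each, stem + projection shortcuts, SMOTE → elevation →
image → resize chain) but uses elevation side 24 → image side 20 and the
channel plan 8→16→32→64 (173 874 parameters), with 25 training epochs.
On one CPU a complete 457-subject experiment takes roughly 15–20
seconds, which is what makes the end-to-end acceptance checks (signal
recovery at effect size 2.0 across three seeds; null calibration at
effect size 0 with the leak-free split, judged against the binomial 95%
band at the realized test-set size) practical as ordinary tests. The
full-scale default configuration is intended for real use, not for the
test suite.

## Known limitations

* The 190 gait features are anonymous block members; no public list of
  the real feature names exists, so per-feature realism (units, skew,
  detection limits) is out of scope.
* Degree-2 truncation to 13 689 terms discards most pairwise products of
  the later feature columns; a feature-importance-aware selection might
  do better but would not be reproducible from the stated design.
* The NumPy engine is single-threaded apart from BLAS matmuls; the
  full-scale network trains in hours, not minutes, on one CPU.
* Multi-class severity staging, calibration analysis and comparator
  models (SVM, gradient boosting, transfer-learned CNNs) are
  deliberately out of scope.
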