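# Methods

## The hybrid neuro-fuzzy classifier (HNFC)

The classifier composes three stages.

**Fuzzification.** For every (class, feature) pair a generalized bell
membership function `mf(y; p, q, r) = 1/(1 + ((y−r)/p)^(2q))` is fitted:
`r` is the class-conditional mean of the feature, `p` the class-conditional
sample standard deviation (the n−1 convention; a single-sample class or a
constant feature gets the floor ε = 1e−6 so the bell stays valid), and `q`
is a global shape exponent, default 2. The fitting scheme is this package's
design: centers and widths are the only class-conditional location/scale
information available at training time, and the bell at (mean, std)
generalises the class-conditional Gaussian with heavier shoulders.

A pattern's memberships can be laid out two ways, both supported because
the aggregation the original formulation intends is ambiguous:

- `flattened` (default): one column per (class, feature) degree, J×(I·k),
  leaving the network free to learn its own aggregation;
- `aggregated`: one column per class, features combined by a t-norm-style
  product (default; matching the product used for Sugeno firing strengths)
  or mean.

**Learning.** The membership matrix feeds a one-hidden-layer perceptron.
Defaults, all configurable:

| parameter | default | why |
|---|---|---|
| hidden width L | round((k + M)·⅔), half-away-from-zero, min 1 | the two-thirds sizing rule for k features, M classes |
| hidden activation | tanh | the stated transfer function of both layers |
| output activation | logistic | the printed output-unit form; the two statements conflict, so both layers are configurable |
| learning rate η | 0.01 | conventional stable default for per-sample updates on inputs in (0,1] |
| momentum | 0.9 | classic heavy-ball default |
| epochs | 500 | budget; training also stops when the epoch SSE changes by < 1e−6 |
| weight init | uniform [−0.5, 0.5], seeded | small arbitrary weights |

Updates are per-sample (stochastic) in a freshly shuffled seeded order each
epoch; each parameter update adds `momentum × previous update − η × gradient`.
The gradient of the half-SSE loss is exact backpropagation, verified in the
suite against centered finite differences to 1e−6 relative error. A
non-finite epoch loss raises a divergence error naming η.

**Defuzzification.** Argmax over output activations, ties to the lowest
class index.

## ANFIS

First-order Sugeno network with grid partitioning: each feature gets
`mfs_per_feature` (default 2) bell functions with centers evenly spaced
over the observed range and widths of half the center spacing; the rule
base is the full Cartesian product, capped at 256 rules (the cap exists
because grid rule counts grow as mᵏ; for the 9-feature fixture the
comparisons use one membership function per feature, i.e. a single rule,
which reduces ANFIS to a globally linear Sugeno model — the honest choice
at 286 samples, where a 512-rule grid could not be estimated anyway).

Hybrid training per epoch: with premises fixed, the consequents enter the
output linearly, so they are solved exactly by least squares on the
normalised-strength-weighted design matrix (ridge-regularised with
λ = 1e−8, with a warning, when the system is singular or has fewer samples
than parameters); then every premise parameter takes one gradient step
(default rate 0.01) against the summed squared error, with widths and
shapes floored at ε to stay positive. The premise gradient is analytic and
finite-difference-verified to 1e−5. The premise step is omitted after the
final epoch's consequent solve, so the returned consequents are always
optimal for the returned premises; the recorded loss trace never increases
at a consequent step (the solve is optimal by construction).

Classification wraps one Sugeno output per class trained against one-hot
targets, argmax prediction. Gaussian membership functions are available
alongside bells; they are what makes the RBFN equivalence exact.

Degenerate inputs whose total firing strength underflows to zero raise an
error rather than returning an arbitrary normalisation.

## RBFN

Two-stage training, standard and deterministic given the seed: centers by
k-means (seeded, single init, empty-cluster retries with derived seeds);
width of each field = distance to its nearest other center (overall feature
standard deviation when there is a single field), floored at ε; output
weights by least squares against one-hot targets, computed in whichever
output mode is configured. The normalised `weighted_average` mode is the
default because it is the form equivalent to a zero-order Sugeno system
with the same Gaussian fields and constant rule outputs — the suite asserts
the identity numerically to 1e−12 across random models.

## Preparation pipeline

Fixed order: encode categoricals → impute → select features → split →
normalise. Two deliberate choices:

- **Normalisation after splitting.** The affine map of each feature onto
  [−1, +1] is fitted on the training part only, so test values may exceed
  the bounds (clipping is optional). A `paper_literal_order` flag restores
  transformation-before-splitting for auditing, at the cost of leakage.
- **Recall = tp/(tp+fn).** The printed source formula for the tp-rate uses
  tn in the denominator, which contradicts the accuracy identity
  (micro-averaged one-vs-rest recall must equal overall accuracy — asserted
  in the suite); the standard form is the default and the printed form is
  available behind `paper_literal=True`.

Correlation pruning drops, from every feature pair with |Pearson r| ≥ 0.95
(threshold configurable), the member less |correlated| with the class
labels, later column on ties; scanning pairs in column order with survivors
checked first guarantees the two members of a pair are never both dropped.
Zero-variance features have undefined Pearson r; they are treated as
uncorrelated (retained) except against an exact duplicate of themselves.
Stratified splitting rounds `fraction × n_c` half-away-from-zero per class,
so a 90/10 mix at n = 100 and fraction 0.7 yields exactly 63 + 7 training
samples.

Undefined metrics (zero denominators) are reported as NaN, never as 0;
macro averages skip NaN entries.

## Synthetic data

The generator draws class-conditional Gaussian features — the minimal
structure under which fitting bell memberships from class means and stds is
meaningful — with a single separation parameter controlling overlap,
uniform missingness injection, and redundant features as noisy copies of
existing columns. Two named recipes:

- `make_separable`: two balanced classes whose centers are `separation`
  pooled standard deviations apart (default 6, n = 500) — a floor test any
  working classifier must pass at ≥ 95% test accuracy.
- `make_breast_cancer_like`: 286 rows, 9 predictors named after the
  recurrence benchmark's attributes, 201/85 class mix, ~1.2-std mean shift
  per feature (moderate overlap), 1% missingness.

What passing on this data does **not** show: real clinical tables have
discrete/ordinal categories, correlated features, non-Gaussian class
conditionals and structured (not uniform) missingness, so accuracy levels
here do not transfer to real benchmarks; the synthetic results validate the
machinery, not clinical performance. Published benchmark accuracies on the
real UCI tables are likewise not comparable to numbers computed on these
generators.

## Problem sizes

The test suite and the acceptance script run the full pipeline at n = 500
(separable benchmark) and n = 286 (overlapping fixture), with training
budgets of 100–500 epochs for the perceptron and 5 epochs for the hybrid
ANFIS training — past which both are converged on these data sizes.

## Known limitations

- A single hidden layer, fixed η, no regularisation: faithful to the method
  being implemented, not a modern MLP.
- Grid-partitioned ANFIS is practical only for small feature counts; no
  clustering-based rule generation is provided.
- The bell-parameter estimation (class mean/std) is a design choice of this
  package; other estimators (quantile-based widths, tuned q) may classify
  better.
- `random_state` on `ANFISClassifier` exists for API symmetry; the
  algorithm is deterministic.
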