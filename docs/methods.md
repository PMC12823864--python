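# Methods

## Connectome construction

For series x_u, x_v of length T and lag τ, the lagged Pearson correlation
is the ordinary Pearson correlation between x_u on steps 1..T−τ and x_v on
steps τ+1..T, with window-wise sample means and sample standard deviations
(divisor T−τ−1). The default τ = 1 is the shortest delay and targets direct
lag-1 interactions. The diagonal of the connectome stores each region's
lagged autocorrelation but is excluded from every downstream edge set and
from the vectorized-connectome feature: a quasimetric requires zero
self-distance, and a self-edge has no meaning in the homology. Constant
windows raise an error naming the region — silent NaN propagation would
poison every downstream stage. Round-off excursions of |ρ| beyond 1 are
clipped (tolerance 1e−12) because the dissimilarity transform requires
ρ ∈ [−1, 1].

## Quasimetric transform

d̃ = sqrt((1 − ρ)/2) maps similarity to dissimilarity on [0, 1]; the square
root makes the quantity behave like a distance derived from the cosine
interpretation of correlation rather than a squared one. The transform is
implemented exactly in this form, with no variants. Shortest-path closure
(per-source heap-based search over the directed graph) then enforces the
triangle inequality; it is idempotent and entrywise non-increasing by
construction. Two deliberate non-repairs:

* off-diagonal zeros (perfectly correlated regions) violate identity of
  indiscernibles; they are logged and reported by `check_quasimetric` but
  never floored to an epsilon — homology keys tuples on node identity, not
  distance, so the computation stays well-defined and the data unaltered;
* on non-strongly-connected toy digraphs, unreachable pairs keep infinite
  distance, matching the convention that absent edges have infinite weight.

## Chain complex and Betti numbers

Chains are spanned by k-paths (consecutive-distinct node tuples) with
length = sum of consecutive distances; the blurred flavour takes length ≤ ℓ,
the strict flavour length = ℓ. The boundary operator drops nodes with
alternating signs; a drop contributes only when the resulting tuple is a
member of the lower basis (finite hops, level constraint,
consecutive-distinct). Degenerate drops (producing a repeated consecutive
node) contribute zero, the standard convention.

**Basis rule for blurred 2-paths.** A triple (v0, v1, v2) enters the
blurred basis only if, additionally, its middle-drop pair (v0, v2) is
degenerate (v0 = v2) or itself a basis member. On a closed quasimetric
space this is implied by the triangle inequality, so the rule changes
nothing there. On toy digraphs with absent edges it is the only reading
that keeps δ₁∘δ₂ = 0 (without it, the middle term of the boundary is
missing and the composite is nonzero) and it reproduces the worked
example's accounting, where only triples whose shortcut edge exists count
as deformations. The chain property is asserted on every constructed pair
of boundary matrices in the tests.

β₀ = dim BMC₀ − rank δ₁ and β₁ = dim BMC₁ − rank δ₁ − rank δ₂. Only
k ≤ 2 is implemented — β₀ and β₁ are what the featurization uses — and
higher degrees fail explicitly. Ranks are exact over ℚ: sparse Gaussian
elimination preferring ±1 pivots (entries stay integer; signed incidence
matrices essentially always provide one) with an exact-fraction fallback,
so no floating tolerance enters a Betti number. A floating SVD rank
(tolerance 1e−8) and a union-find weak-component count serve as
independent cross-checks in the tests, never as the implementation.

Strict-equality comparisons of float path lengths use a relative tolerance
of 1e−9 (exact comparison would almost never fire on float sums); exact
fixture weights compare exactly.

## Betti curves and subnetworks

Grids are inclusive and evenly spaced: [0, 1] for β₀ (the range of d̃) and
[0, 2] for β₁ (the range of two-hop sums), default T = 256 points. Curve
evaluation enumerates paths once at the top of the grid and filters per
level; a test asserts equality with naive per-level recomputation.

Whole-connectome homology is expensive, so curves are computed per
functional subnetwork, nine of them in the fixed order BGN, CEREN, DAN,
DMN, FPN, LN, SMN, VAN, VN, giving 18 curves (β₀ and β₁ each). The
quasimetric closure is applied *after* restriction to a subnetwork:
computing curves "separately per subnetwork" would be contradicted by
shortcuts routed through other subnetworks. Region→subnetwork assignments
ship as an editable two-column CSV; the package provides a synthetic
generator (`default_partition`) used throughout the tests, and no external
atlas table is required. Each subnetwork must contain at least three
regions for non-trivial homology.

## Classifier

Two backbones — a 128-unit ReLU layer each for the vectorized off-diagonal
connectome (N·(N−1) values, row-major) and for the 18-curve vector — feed a
concatenated embedding into a dropout(0.5) + linear head with two-logit
softmax and cross-entropy, trained by Adam with decoupled weight decay.
The network, its backward pass and the optimizer are implemented in NumPy;
having the gradients in hand is what the importance analysis
differentiates. Default hyperparameters (hidden 128, lr 1e−5, weight decay
1e−5, 50 epochs, dropout 0.5 on the head only) are the configuration tuned
for a many-hundred-subject cohort. Betti inputs are standardized per
dimension with training statistics before their backbone (integer counts
and correlations live on incompatible scales); this can be disabled in
`NetConfig`. The connectome branch stays on its native [−1, 1] scale.

Evaluation scans all midpoints of sorted unique scores plus {0, 1}, picks
the threshold maximizing F-score on the validation sample (ties toward the
lower threshold) and reports F-score, accuracy, precision and sensitivity
at that threshold. A validation set with no positive labels raises rather
than silently reporting 0. A stratified 5-fold × 5-seed harness
(`cross_validate`) mirrors the full protocol.

**Subnetwork importance.** Per (seed, split): the gradient of the
positive-class probability with respect to every Betti input is computed
on each validation subject; per-input importance is the mean absolute
gradient over subjects; a subnetwork's importance is the sum over its 2T
inputs; aggregation over (seed, split) pairs is mean ± sd. Gradients are
taken at the standardized Betti inputs the backbone actually consumes —
attributing through the scaler would reweight dimensions by 1/sd and
confound importance with variance.

**Group curve comparison.** Independent two-sample t-tests at every grid
point of all 18 curves; Holm correction is applied jointly across all
18·T tests (one family-wise analysis). Grid points with zero variance in
both groups are flagged undefined and excluded from correction.

## Synthetic data

`var1_timeseries` simulates x_t = Cᵀ x_{t−1} + ε with Gaussian noise,
100-step burn-in, and a stationarity check (spectral radius < 1). Cohorts
place directed couplings only within subnetworks, with per-class edge
density; defaults: 36 regions (9 subnetworks × 4), T = 150 timepoints,
noise sd 1.0, coupling strength 0.45 (±20% jitter), diagonal decay 0.2,
class densities 0.15 vs 0.55, 20 subjects per class. A coupling matrix
drifting toward instability is rescaled to spectral radius 0.9. These
cohorts carry exactly the statistical structure the lagged correlation is
designed to detect — directed lag-1 dependence — and none of the features
of real BOLD data (haemodynamic convolution, noise autocorrelation
structure, site/scanner effects, atlas misregistration). Passing tests
therefore demonstrate correctness of the machinery and detectability of
directed coupling, not clinical performance.

The worked five-node example digraph is reconstructed from its printed
threshold subgraphs with canonical weights 0.1/0.2/0.3 (right endpoints of
the admissible intervals, chosen for readability). A perturbation test
resamples weights within those intervals — subject to the census
constraint that the single valid ordered triple stays longer than 0.4 —
and asserts identical Betti vectors.

## Experiment scales

The synthetic experiments in the test suite use 40-subject cohorts at grid
size 256, training with lr 1e−3 for 150 epochs (batch 8): at 30 training
subjects the reference learning rate of 1e−5 moves the weights by far
too little to fit anything, so the desk-scale experiments use the larger
step size as their own configuration, while `NetConfig` defaults keep the
reference values. The label-permutation control retrains the identical
architecture on permuted labels; gradient importance is validated by
injecting the class-density difference into a single subnetwork and
checking it ranks first in median importance over 10 seeds.

## Known limitations

* Path enumeration is cubic in subnetwork size per level and rank
  elimination is pure Python; fine for subnetwork-scale matrices (tens of
  nodes), intractable for whole large atlases — the motivation for the
  subnetwork split.
* Only β₀/β₁ (k ≤ 2) are available.
* The exact-rank path assumes entries stay small (signed incidence plus
  limited fill-in); the Fraction fallback guarantees correctness at some
  speed cost in pathological cases.
* `evaluate` selects its threshold on the same validation sample it
  reports, mirroring the reference protocol; metrics are therefore
  optimistic relative to a held-out test set.
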