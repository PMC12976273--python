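# Methods

## Problem

Given a link-prediction model on an attributed directed graph — a function
returning the probability that an edge exists from node `v` to node `u` —
we want a feature-effect explanation: how does the value of one node
feature change the predicted probability of that node forming links? The
package adapts accumulated local effects (ALE) to this setting and
quantifies the error introduced by the fast, batched variant of the
estimator.

## Accumulated local effects for link prediction

The feature's support is divided into `H` bins with edges
`z_0 < z_1 < ... < z_H`. For a modified node `v` whose feature value falls
in bin `h`, the local effect is the difference between the model's
prediction with `v`'s feature set to `z_h` and set to `z_{h-1}`, averaged
over a fixed target set `U` of `k` nodes (excluding `v` itself) and over
the sampled nodes of the bin. Accumulating the per-bin average differences
from the lowest bin upward gives the uncentered ALE curve, evaluated at
each bin's right edge and implicitly anchored at 0 at `z_0`. Curves are
left uncentered throughout; `center_profile` (subtract the
bin-count-weighted mean) exists but is never applied by default.

Two estimators:

- **Exact** (`ale_exact`): one node's feature is modified per forward
  pass; `2m` passes for `m` sampled nodes. Modified nodes can never
  influence one another.
- **Approximate** (`ale_approximate`): all sampled nodes of a bin are set
  to the bin edge simultaneously, one forward pass per bin edge (`2H`
  passes plus at most one shared clean pass), independent of `m`. Nodes
  within each other's receptive fields (L message-passing layers = L hops)
  contaminate each other's predictions. This disturbance is the object of
  study and is not corrected.

Both estimators draw the modified-node sample and `U` identically from the
seed, so exact and approximate runs are paired. A target that happens to be
in the modified sample is always scored with its *clean* embedding — the
explained perturbation belongs to the source side only — so with `m = 1`,
or with a predictor that has no message passing, the two estimators
coincide to machine precision.

### Normalization modes

`per_bin` (default) divides each bin's summed prediction differences by the
number of differences the bin received — standard ALE, and the convention
used when pooling runs ("divide by the number of all predictions in the
interval"). `global` divides every bin by the total budget `m·k`, the
algebra under which run-weighted averaging of curves is exactly additive.
Profiles always store raw `bin_sums` and `bin_counts`, so either value set
is recomputable and aggregation is exact in both modes.

### Aggregation

`aggregate_profiles` sums `bin_sums` and `bin_counts` elementwise across
runs sharing a bin grid. Because the stored quantities are the sufficient
statistics of the estimator, pooling reproduces, up to float-summation
grouping, the profile a single run over the union of the samples would
have produced; summation is sequential in input order so re-grouping is
bitwise stable. The pooled curve equals the `k_i·m_i`-weighted average of
the member curves in global mode.

## Curve statistics

- `chi2_curve_test`: statistic `Σ_h (ȳA_h − ȳB_h)² / (s²A_h + s²B_h)` over
  the `H` curve points, with group means and variances weighted by each
  run's per-bin prediction counts; degrees of freedom equal `H` (df = 5 and
  α = 0.05 give the 11.07 critical value). Singleton-vs-singleton
  comparisons fall back to unit variances and are flagged. With group
  variances estimated from few curves the statistic is only approximately
  chi-square; the calibration test holds it to a generous band around the
  nominal level.
- `permutation_test`: observed statistic is the RMSE between the two
  groups' aggregated profiles; group labels are permuted (sizes preserved,
  default 10,000 draws) and the p-value is the plain proportion of permuted
  statistics at least as large (a +1-smoothed option exists). Permutations
  are drawn over a canonical ordering of the pooled profiles so the
  p-value is invariant to input order given the seed. Random (rather than
  enumerated) permutations mean the attainable p-value floor is about
  `2/C(n_a+n_b, n_a)`.
- `rmse_to_reference`: RMSE over the curve points against a reference
  profile or the analytic ground-truth curve, both taken uncentered and
  anchored at 0 at the first bin edge (`align="mean"` subtracts each
  curve's mean instead).

## Synthetic generator

Nodes carry 5 i.i.d. N(0,1) noise features and one Uniform[−1,1] signal
feature. Each source node receives `ceil(sparsity·(n−1))` candidate
targets sampled uniformly without replacement (no self-loops; a pair may
exist in both directions); each candidate pair becomes a directed edge
independently with probability `p = (x_u + x_v + 2)/4` of the endpoint
signal values. Expected density is about `sparsity/2`. The true local
effect of the signal feature is the constant 1/4 per endpoint, giving the
ground-truth curve `(z − z_0)/4`. Defaults: `n_nodes = 1000` (large enough
for stable bins at the default budgets, small enough for minutes-scale
runs), `sparsity = 0.01`, bins quantile with `H = 5`.

What the generator does not emulate: community structure, degree
heavy-tails, feature correlations, categorical features, temporal
dynamics. Passing tests show estimator correctness and the
contamination mechanism under a known, homogeneous feature-edge law; they
do not certify behavior on real graphs with structured confounding.

## Models and training

The predictor is a 2-5 layer GCN or GAT encoder (64-dimensional layers by
default; single-head additive attention for GAT; batch normalization after
every layer; ReLU/ELU between layers) with a dot-product-plus-sigmoid
decoder, trained with binary cross-entropy, Adam, batch size 1024, and
fresh 1:1 negative sampling each epoch. Depth variants keep a comparable
neuron budget via `total_neurons` (per-layer width `round(total/depth)`).
Layers are implemented on a small in-repo reverse-mode autodiff engine
(dense/sparse matmul, gather/scatter message passing, segment softmax),
gradient-checked against finite differences.

Training hyperparameters were chosen once for stable convergence at the
synthetic scale: learning rate 5e-3 for both architectures, halved every
50 epochs, up to 200 epochs with early stopping (patience 30) on
validation AUROC. Optional regularizers (feature dropout, edge dropout,
weight decay, supervision-edge masking, candidate-pool negatives,
configurable GCN self-loop weight) are off by default.

Conventions that matter and were genuinely open:

- **Propagation at serving time.** Training propagates messages over the
  training edges only. At inference (including evaluation and
  explanation) the encoder propagates over the full known edge set — the
  transductive deployment convention. Because a scored pair that is itself
  an edge then participates in propagation, evaluation metrics are higher
  than a strictly inductive protocol would give; `propagation="train"`
  selects the inductive convention. Validation scoring during early
  stopping follows the serving convention (validation edges present in
  propagation), so checkpoint selection optimizes the deployed metric.
- **Negative sampling.** Uniform over ordered non-adjacent pairs, for
  training (resampled each epoch) and for the fixed evaluation negatives.
  `negative_source="candidates"` draws hard negatives from the generator's
  candidate pool instead; at a 1:1 ratio this makes the Bayes-optimal
  sigmoid output equal the generating probability itself.
- **Decoder threshold** for F1 is 0.5; AUROC is threshold-free.

## Numerical choices

Bin assignment is half-open `(z_{h-1}, z_h]` with the minimum going to the
first bin; quantile bin edges collapse duplicates (reducing `H`); empty
bins contribute a zero increment and a logged warning. Exact-estimator
accumulation is ordered canonically by (bin, node id), so permuting the
modified-node sample leaves the output bit-identical. `m` and `k` are
clipped to the available node counts with a warning. Sigmoid inputs are
clipped at ±500. Profile JSON serializes floats via `repr` for round-trip
exactness.

## Known limitations

- At the default synthetic scale the trained encoders' response to the
  signal feature is far weaker than the generating slope (message passing
  mixes a node's own features with ~10 neighbors' noise, and structural
  shortcuts — adjacency of the scored pair under the serving convention,
  degree — absorb most of the training signal). The learned ALE curves are
  therefore much flatter than the ground truth, and the distance of a
  profile to the *aggregated exact explanation* is the informative error
  measure for comparing estimators; the study table reports both this
  (`rmse_exact_aggregate`) and the ground-truth distance
  (`rmse_ground_truth`). The divergence of the approximate from the exact
  estimator grows with `m` (the contamination mechanism), which the test
  suite demonstrates with a fixed-weight message-passing predictor; for an
  under-sloped trained model that same contamination can move the curve
  *toward* the ground truth, so ground-truth RMSE need not increase with
  `m` at this scale.
- The chi-square curve test's null distribution is approximate for small
  groups.
- Runtime is logged in profiles and manifests but never asserted; the
  exact estimator's cost scales linearly with `m` (2m forward passes), the
  approximate estimator's with the number of bins only.
- Categorical features, interaction (second-order) effects, PDP/ICE
  baselines and temporal graphs are out of scope.
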