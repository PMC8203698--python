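# Methods

`carepath` predicts the total healthcare cost of a patient's treatment
from the — possibly still incomplete — sequence of clinical actions
recorded so far.  An *action* is an (activity, cost) pair: one billed
clinical event (a consultation, a lab panel, a surgery, ...) together
with the money it cost.  A patient's *treatment sequence* is the
time-ordered list of their actions; only the order of visits is used,
never the calendar spacing.

## Cost discretization ("modified cost")

Raw costs are continuous, so the joint (activity, cost) vocabulary would
be infinite.  Training costs are therefore cut at the empirical
i/n_s-quantiles (i = 1 … n_s−1, linear interpolation) and every cost is
replaced by the mean of the training costs in its segment.  Default
n_s = 8, giving the ascending segment levels VVL, VL, L, ML, MH, H, VH,
VVH and a roughly equal share of training cost elements per segment.
Numerical conventions:

* intervals are half-open [b_{i−1}, b_i), the last closed above; values
  below/above the training range clamp to the first/last segment, so
  quantization is a total, idempotent map onto the segment means;
* heavily tied costs can duplicate quantile boundaries; the resulting
  empty segments are merged into their lower neighbour and the effective
  segment count is recorded.

Quantization quality is summarized by the normalized quantization error,
NQE = mean|c − c_m| / (max c − min c).  The `fit` CLI prints NQE for
n_s = 2 … 12; on synthetic cost data the curve flattens around n_s = 8.
The grids for different n_s are not nested, so NQE is only empirically —
not provably — decreasing in n_s.

## Treatment Pattern Difference (TPD)

TPD is a cost-aware edit distance between action sequences.  An edit
script converts one sequence into the other by inserting, deleting or
substituting actions, or by aligning two actions of the same activity;
its price is

    w1 · ( Σ_ins y + Σ_del y + Σ_sub (|y_i − y_j| + ε) )
  + w2 · Σ_match |y_i − y_j|

and TPD is the minimum over all monotone scripts, computed by dynamic
programming in O(|P1|·|P2|).  Defaults w1 = 0.7 > w2 = 0.3: changing the
activity mix is penalized more than spending a different amount on the
same activity.  Choices worth noting:

* the substitution price is symmetrized as |y_i − y_j| + ε (the additive
  ε guarantees a strictly positive price even for equally priced
  activities); ε defaults to 10⁻³ × the median segment mean, i.e. it is
  scale-relative and survives currency changes;
* distances are computed on modified (quantized) costs inside the
  pipeline, matching the rest of the model; raw-cost use is possible;
* TPD is *not* a metric — the weighted prices break the triangle
  inequality — and no metric property is relied on anywhere;
* an exhaustive edit-script oracle (`tpd_bruteforce_oracle`, lengths ≤ 5)
  exists purely to cross-check the dynamic program.

A consequence users should know: TPD scales with absolute cost, so a
group of expensive patients is intrinsically more spread out than a
group of cheap ones at the same relative variability.

## Clustering

Patient groups are recovered by hierarchical DBSCAN on the precomputed
TPD matrix (scikit-learn's `HDBSCAN`, `metric="precomputed"`, default
stability-based flat extraction; no global density threshold is chosen).
`min_cluster_size` defaults to 5 and is the only tunable.  Because the
predictor averages over *all* groups, points the hierarchy labels as
noise are re-assigned to the cluster of their nearest clustered
neighbour (ties to the lower cluster index); if everything is noise the
data collapse to a single cluster with a warning.

## Per-group Markov chains

Each group is summarized by a first-order chain over the finite
(activity, segment-mean) vocabulary: empirical transition probabilities
and an initial-action distribution, both with additive smoothing beta
(default 0.5; beta = 0 reproduces raw maximum-likelihood counts, with
never-left states given uniform rows).  A query sequence P is scored by
log λ_l(P) = log p_l(a_1) + Σ log p_l(a_{i+1}|a_i); the per-group scores
are normalized into mixture weights λ̂_l with a log-sum-exp softmax.
Unseen query actions are mapped to the same-activity vocabulary action
with the nearest cost; a completely unseen activity contributes the
uniform floor 1/N per step.  λ_l is length-biased (longer prefixes score
lower everywhere); no per-length normalization is applied, because the
weights are only ever compared across groups at a fixed query.

## Prediction

For a query P, every group l produces an inverse-distance-weighted k-NN
estimate ĉ_l(P) = Σ w_j c_j / Σ w_j over the k members nearest in TPD
(ties by member index), with w = 1/(TPD + δ) and δ defaulting to
10⁻⁶ × the median pairwise training TPD; c_j is the neighbour's total
*raw* cost over its *full* sequence — the quantity actually being
predicted.  The final prediction is the convex blend
c̄(P) = Σ_l λ̂_l(P) ĉ_l(P), so every prediction lies within the range of
training totals, and every ĉ_l within its own cluster's totals.  Early
prediction truncates the query to its first ⌈p/100 · n⌉ actions
(minimum 1) and compares against the full-sequence total.

## Evaluation

The aggregate error measure is the cost-weighted MAPE,
(Σ|c − c̄| / Σ c) × 100 — total absolute error over total true cost, not
the per-patient mean of percentage errors.  `cross_validate` re-fits the
*entire* pipeline (quantiles, TPD matrix, clusters, chains) inside each
training fold, so held-out costs never leak into any fitted quantity;
folds come from a seeded shuffle and differ in size by at most one.

## Rank-based comparison of predictors

`carepath.stats` implements the Friedman/Bonferroni–Dunn/Hochberg chain
for any algorithms × datasets error matrix (lower = better): within-column
ranks with average ties, mean ranks R̄_j, the chi-square statistic
χ²_F = 12n/(k(k+1)) · (Σ R̄_j² − k(k+1)²/4) with df = k−1, the critical
difference CD = q · √(k(k+1)/(6n)) with q the standard-normal upper
quantile at α/(2(k−1)), z-scores against a control, two-sided normal
p-values and Hochberg's step-up adjustment.  A published 4 × 9 benchmark
matrix of MAPE values ships with the package; the chain reproduces that
analysis's printed mean ranks, critical value (7.815), CD (1.457),
z-scores and adjusted p-values exactly.  One exception: the Friedman
statistic printed alongside that analysis (14.133) is not what the
standard mean-rank formula yields on those ranks (19.53); this package
reports the standard value.

## Synthetic-data generator

`carepath.simgen` emulates the structure the method assumes: a mixture of
patient groups, each a first-order Markov chain over clinical activities;
log-normal per-activity costs (medians from ~45 to ~2500 currency units
across ten common activity codes); sequence lengths from a shifted
negative binomial.  Each group concentrates (probability `separation`)
on a random cycle through its own *preferred activity block* — by
default the blocks partition the alphabet into price-sorted runs, the
way an outpatient-style pathway and a surgical/inpatient pathway diverge
in real logs — and otherwise moves uniformly.  Defaults: 2 groups × 200
patients, separation 0.85, lengths 5–40 (min 5, mean 15, dispersion 5),
seed-reproducible to the byte.

`SimConfig.well_separated()` is the configuration used by the recovery
experiments: separation 0.95, lengths 10–16, cost σ 0.25 with
within-block price ranges kept below the between-block gap, 100 patients
per group, paired with min_cluster_size 20.  It is constructed so that
within-group TPD stays well below between-group TPD — the premise the
recovery checks are about.

What the generator does *not* emulate, and hence what passing tests do
not show: real alphabets are larger and actions much sparser (dozens of
codes, most (activity, segment) pairs unobserved); real group structure
is not block-disjoint and group counts are unknown; real costs have
heavier tails and within-patient correlation; visit timing carries
information this model discards.  Recovery results on the generator
demonstrate internal correctness of the pipeline, not expected accuracy
on hospital data.

## Problem sizes and runtimes

Chosen so the full suite runs comfortably on one CPU: cluster-recovery
checks use 200 patients (~4 s including the 19 900-pair TPD matrix);
the earliness trend uses 10 simulations of 100 patients with 25% held
out (~15 s); Markov recovery uses 2 000 sequences of length 12.  The
TPD dynamic program is row-vectorized with numpy; a 400-patient matrix
(79 800 pairs, mean length 15) takes ~10 s.

## Known limitations

* TPD's absolute-cost scaling makes density-based clustering sensitive
  to spending level; a scale-normalized variant is deliberately out of
  scope (it would change the published distance).
* k-NN estimates compare a truncated query against *full* member
  sequences, so short prefixes are biased toward short (cheap) members;
  this is the designed behaviour of the method, and is the main source
  of the large MAPE at 20% prefixes.
* The Friedman machinery assumes independent datasets (columns); applied
  to prefix lengths of one cohort, the columns are correlated — as in
  the published analysis it reproduces.
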