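# carepath

Early prediction of a patient's **total healthcare cost** from the
sequence of clinical actions recorded so far.

Hospitals bill a patient's care as an ordered log of *actions* — pairs of
a clinical activity (consultation, lab work, radiology, surgery, ...) and
the cost it incurred.  Identifying patients who will become high-cost
*before* most of their record exists lets care organizations allocate
resources proactively.  `carepath` implements a sequence-based pipeline
for exactly that, aimed at health-economics and clinical data-science
teams working with administrative event logs.

## The method

**Learning.** Training sequences are quantized (each cost replaced by
the mean of its n_s-quantile segment, default n_s = 8), compared with the
**Treatment Pattern Difference** — a cost-aware edit distance

    TPD(P1, P2) = min over edit scripts of
        w1·(Σ_ins y + Σ_del y + Σ_sub (|y_i − y_j| + ε)) + w2·Σ_match |y_i − y_j|

with w1 = 0.7 > w2 = 0.3 — and clustered with hierarchical DBSCAN on the
pairwise TPD matrix.  Each group G_l is then summarized by a first-order
Markov chain (transition matrix M_l, initial distribution p_l) over the
finite (activity, cost-segment) vocabulary.

**Prediction.** For a new (possibly truncated) sequence P:

1. each group estimates ĉ_l(P) as the inverse-distance-weighted mean of
   the total raw costs of P's k nearest members (w = 1/(TPD+δ), k = 3);
2. each group scores the chain likelihood
   λ_l(P) = p_l(a_1)·Π p_l(a_{i+1}|a_i), normalized across groups into
   weights λ̂_l (computed in log space);
3. the prediction is the convex blend  c̄(P) = Σ_l λ̂_l(P)·ĉ_l(P).

**Evaluation.** Earliness is measured by truncating held-out sequences
to their first p% of actions and scoring the aggregate
MAPE = (Σ|c − c̄| / Σ c) × 100 under cross-validation that re-fits the
whole pipeline per fold.  `carepath.stats` adds the rank-based machinery
for comparing predictors across settings (Friedman mean ranks and
chi-square, Bonferroni–Dunn critical difference, Hochberg-adjusted
z-test p-values).

## Worked example

Simulate a synthetic cohort (two patient groups with their own Markov
chains and log-normal activity costs), fit the pipeline, and predict:

```bash
$ carepath simulate --seed 5 --patients-per-cluster 30 --out events.csv
wrote 60 patients to events.csv

$ carepath fit --input events.csv --model model.json --nqe-table
n_segments      NQE
2       0.0468
...
8       0.0171
...
12      0.0132
fitted 2 cluster(s); model saved to model.json
  cluster 0: n_p=22, L=7-32
  cluster 1: n_p=38, L=7-37

$ carepath predict --model model.json --input events.csv --output preds.csv
$ head -2 preds.csv
patient_id,predicted_cost,top_cluster,top_cluster_weight
p00000,6560.3732300038,0,0.9999999996852722
```

The NQE column is the normalized quantization error — mean absolute
cost distortion over the cost range — which flattens around 8 segments.
The cluster report lists each recovered group's size (n_p) and
sequence-length range (L).  Each prediction comes with the most likely
group and the chain-likelihood weight it received.

The same pipeline is scriptable from Python:

```python
from carepath import SimConfig, simulate_dataset, fit_ensemble, predict_cost

dataset, truth, chains = simulate_dataset(SimConfig(seed=5))
ensemble = fit_ensemble(dataset)
result = predict_cost(dataset.sequences[0], ensemble)
print(result.final_cost, result.cluster_weights)
```

Comparing predictors over multiple settings (here the shipped benchmark
matrix of four cost predictors at nine observed-sequence fractions):

```bash
$ carepath stats --matrix reference_mape_matrix.tsv --control proposed
mean ranks:
  proposed      1.222
  GB    2.000
  ANN   3.111
  EN    3.667
Friedman chi2 = 19.533 (df=3, critical 7.815 at alpha=0.05) -> reject null
Bonferroni-Dunn CD = 1.457 (control: proposed)
        z  p_unadjusted  p_hochberg
GB  1.278        0.2012      0.2012
ANN 3.104      0.001911    0.003822
EN  4.017     5.904e-05   0.0001771
```

Only ANN and EN differ from the control by more than the critical
difference, and their Hochberg-adjusted p-values fall below 0.05; GB
does not.

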