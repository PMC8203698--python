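"""Earliness evaluation: prefix truncation, aggregate MAPE, cross-validation.

Early-prediction quality is measured by truncating each held-out sequence
to its first p% of actions, predicting the *full* total cost from that
prefix, and summarizing with the aggregate mean absolute percentage error

    MAPE = ( sum_i |c(P_i) - c_hat(P_i)| / sum_i c(P_i) ) * 100

i.e. total absolute error over total true cost — a cost-weighted form, not
the per-patient mean of percentage errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .core import Dataset, TreatmentSequence
from .discretize import quantize_dataset
from .markov import normalize_likelihoods, sequence_loglik
from .predict import cluster_distances, fit_ensemble, knn_estimate

__all__ = ["EvaluationReport", "truncate_prefix", "mape", "cross_validate"]


@dataclass
class EvaluationReport:
    """MAPE (%) per (k, prefix %) averaged over folds, plus the fold layout."""

    mape_by_setting: pd.DataFrame  # rows: k, columns: prefix percent
    fold_assignments: np.ndarray
    n_folds: int
    seed: int


def truncate_prefix(p: TreatmentSequence, percent: float) -> TreatmentSequence:
    """First ceil(percent/100 * n) actions, never fewer than one."""
    if not (0 < percent <= 100):
        raise ValueError(f"percent must be in (0, 100], got {percent}")
    n_keep = max(1, int(np.ceil(percent / 100 * len(p))))
    return TreatmentSequence(p.patient_id, p.actions[:n_keep])


def mape(true_costs, predicted_costs) -> float:
    """Aggregate MAPE in percent (total |error| over total true cost)."""
    c = np.asarray(true_costs, dtype=float)
    ch = np.asarray(predicted_costs, dtype=float)
    if c.shape != ch.shape or c.size < 1:
        raise ValueError("true and predicted costs must have equal length >= 1")
    denom = c.sum()
    if denom <= 0:
        raise ValueError("sum of true costs must be positive")
    return float(np.abs(c - ch).sum() / denom * 100.0)


def _fold_indices(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded shuffle into folds whose sizes differ by at most one."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        folds[chunk] = f
    return folds


def cross_validate(
    dataset: Dataset,
    config: PipelineConfig | None = None,
    k_grid=(3,),
    percent_grid=(20, 30, 40, 50, 60, 70, 80, 90, 100),
    n_folds: int = 10,
    seed: int = 0,
) -> EvaluationReport:
    """k-fold cross-validation over the k-NN size and the prefix length.

    For every fold the entire pipeline — discretizer, TPD matrix, clusters,
    chains — is re-fit on the training part only, so held-out costs never
    leak into the quantiles.  Each held-out patient is predicted from its
    truncated prefix (raw costs, quantized with the fold's discretizer)
    while the target stays the raw total of the full sequence.  The
    reported MAPE per setting is the mean of the per-fold MAPEs.
    """
    config = config or PipelineConfig()
    n = len(dataset)
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    folds = _fold_indices(n, n_folds, seed)

    per_fold = np.full((len(k_grid), len(percent_grid), n_folds), np.nan)
    for f in range(n_folds):
        train_idx = np.where(folds != f)[0]
        test_idx = np.where(folds == f)[0]
        train = dataset.subset(train_idx)
        if len(train) < 2 * config.min_cluster_size:
            raise ValueError(
                f"fold {f}: training part has {len(train)} sequences, fewer than "
                f"the {2 * config.min_cluster_size} required by "
                f"min_cluster_size={config.min_cluster_size}"
            )
        ensemble = fit_ensemble(train, config)

        true_totals = np.array([dataset.sequences[i].total_cost for i in test_idx])
        # TPDs and likelihoods do not depend on k: compute once per prefix
        preds = np.empty((len(k_grid), len(percent_grid), len(test_idx)))
        for pi, percent in enumerate(percent_grid):
            for ti, i in enumerate(test_idx):
                prefix = truncate_prefix(dataset.sequences[i], percent)
                pq = quantize_dataset(Dataset([prefix]), ensemble.discretizer).sequences[0]
                dists = [
                    cluster_distances(pq, c, ensemble.tpd_params) for c in ensemble.clusters
                ]
                weights = normalize_likelihoods(
                    [sequence_loglik(pq, c.chain) for c in ensemble.clusters]
                )
                for ki, k in enumerate(k_grid):
                    ests = [
                        knn_estimate(
                            pq, c, k, ensemble.tpd_params,
                            ensemble.knn_weight_delta, distances=d,
                        )[0]
                        for c, d in zip(ensemble.clusters, dists)
                    ]
                    preds[ki, pi, ti] = float(np.dot(weights, ests))
        for ki in range(len(k_grid)):
            for pi in range(len(percent_grid)):
                per_fold[ki, pi, f] = mape(true_totals, preds[ki, pi])

    table = pd.DataFrame(
        per_fold.mean(axis=2), index=list(k_grid), columns=list(percent_grid)
    )
    table.index.name = "k"
    table.columns.name = "prefix_percent"
    return EvaluationReport(
        mape_by_setting=table, fold_assignments=folds, n_folds=n_folds, seed=seed
    )
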