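"""Cost prediction: per-group k-NN estimates blended by chain likelihoods.

Given a (possibly partial) treatment sequence P:

1. in every patient group, the k member sequences nearest to P under TPD
   are found and their *total raw costs* are averaged with weights
   inversely proportional to distance, w = 1/(TPD + delta);
2. P's likelihood under every group's Markov chain is computed and
   normalized into mixture weights;
3. the final predicted cost is the likelihood-weighted sum of the
   per-group estimates — a convex combination, so every prediction lies
   within the range of training totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import cluster_sequences, resolve_noise
from .config import PipelineConfig
from .core import Dataset, TreatmentSequence
from .discretize import CostDiscretizer, fit_quantiles, quantize_dataset
from .markov import (
    ClusterModel,
    MarkovModel,
    VocabAction,
    fit_markov,
    normalize_likelihoods,
    sequence_loglik,
)
from .tpd import TPDParams, tpd_distance, tpd_matrix

__all__ = ["PredictionResult", "PredictorEnsemble", "knn_estimate", "predict_cost", "fit_ensemble"]

DEFAULT_KNN_DELTA_FRACTION = 1e-6
DEFAULT_EPSILON_FRACTION = 1e-3


@dataclass(frozen=True)
class PredictionResult:
    patient_id: str
    final_cost: float
    per_cluster_estimates: np.ndarray
    cluster_weights: np.ndarray
    neighbor_ids: tuple[tuple[str, ...], ...]

    @property
    def top_cluster(self) -> int:
        return int(np.argmax(self.cluster_weights))


@dataclass
class PredictorEnsemble:
    """Everything learned in the training phase."""

    discretizer: CostDiscretizer
    tpd_params: TPDParams
    clusters: list[ClusterModel]
    knn_k: int
    knn_weight_delta: float
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def __post_init__(self) -> None:
        if len(self.clusters) < 1:
            raise ValueError("ensemble needs at least one cluster")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.knn_weight_delta <= 0:
            raise ValueError("knn_weight_delta must be > 0")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "knn_k": self.knn_k,
            "knn_weight_delta": self.knn_weight_delta,
            "tpd_params": {
                "w1": self.tpd_params.w1,
                "w2": self.tpd_params.w2,
                "epsilon": self.tpd_params.epsilon,
            },
            "discretizer": {
                "n_segments": self.discretizer.n_segments,
                "boundaries": self.discretizer.boundaries.tolist(),
                "segment_means": self.discretizer.segment_means.tolist(),
                "segment_labels": list(self.discretizer.segment_labels),
            },
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "member_ids": list(c.member_ids),
                    "member_sequences": [
                        [[a.activity, a.cost] for a in s.actions] for s in c.member_sequences
                    ],
                    "member_total_costs": c.member_total_costs.tolist(),
                    "chain": {
                        "action_vocab": [[a, c_] for a, c_ in c.chain.action_vocab],
                        "initial_probs": c.chain.initial_probs.tolist(),
                        "transition_matrix": c.chain.transition_matrix.tolist(),
                        "smoothing_beta": c.chain.smoothing_beta,
                    },
                }
                for c in self.clusters
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorEnsemble":
        from .core import Action  # local to avoid import noise at module top

        disc = CostDiscretizer(
            n_segments=d["discretizer"]["n_segments"],
            boundaries=np.array(d["discretizer"]["boundaries"], dtype=float),
            segment_means=np.array(d["discretizer"]["segment_means"], dtype=float),
            segment_labels=tuple(d["discretizer"]["segment_labels"]),
        )
        clusters = []
        for c in d["clusters"]:
            chain = MarkovModel(
                action_vocab=tuple((a, float(y)) for a, y in c["chain"]["action_vocab"]),
                initial_probs=np.array(c["chain"]["initial_probs"], dtype=float),
                transition_matrix=np.array(c["chain"]["transition_matrix"], dtype=float),
                smoothing_beta=float(c["chain"]["smoothing_beta"]),
            )
            seqs = [
                TreatmentSequence(
                    pid, tuple(Action(a, float(y)) for a, y in actions)
                )
                for pid, actions in zip(c["member_ids"], c["member_sequences"])
            ]
            clusters.append(
                ClusterModel(
                    cluster_id=int(c["cluster_id"]),
                    member_ids=list(c["member_ids"]),
                    member_sequences=seqs,
                    member_total_costs=np.array(c["member_total_costs"], dtype=float),
                    chain=chain,
                )
            )
        return cls(
            discretizer=disc,
            tpd_params=TPDParams(**d["tpd_params"]),
            clusters=clusters,
            knn_k=int(d["knn_k"]),
            knn_weight_delta=float(d["knn_weight_delta"]),
            config=PipelineConfig(**d["config"]),
        )


def cluster_distances(p: TreatmentSequence, cluster: ClusterModel, params: TPDParams) -> np.ndarray:
    """TPD from a quantized query to every member of a cluster."""
    return np.array([tpd_distance(p, m, params) for m in cluster.member_sequences])


def knn_estimate(
    p: TreatmentSequence,
    cluster: ClusterModel,
    k: int,
    params: TPDParams,
    delta: float,
    distances: np.ndarray | None = None,
) -> tuple[float, tuple[str, ...]]:
    """Inverse-distance-weighted k-NN estimate of total cost within one group.

    Neighbours are ranked by TPD ascending with ties broken by member
    index; weights are 1/(TPD + delta).  ``distances`` may be supplied to
    reuse precomputed TPDs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if delta <= 0:
        raise ValueError(f"delta must be > 0, got {delta}")
    d = cluster_distances(p, cluster, params) if distances is None else np.asarray(distances)
    order = np.argsort(d, kind="stable")[: min(k, len(d))]
    w = 1.0 / (d[order] + delta)
    estimate = float(np.dot(w, cluster.member_total_costs[order]) / w.sum())
    return estimate, tuple(cluster.member_ids[i] for i in order)


def predict_cost(p: TreatmentSequence, ensemble: PredictorEnsemble) -> PredictionResult:
    """Predict the total cost of a treatment sequence (raw costs).

    The query is quantized with the ensemble's discretizer, scored by every
    group, and the per-group k-NN estimates are blended by the normalized
    chain likelihoods.
    """
    if len(p) < 1:
        raise ValueError("cannot predict from an empty sequence")
    pq = quantize_dataset(Dataset([p]), ensemble.discretizer).sequences[0]

    estimates, neighbors, logliks = [], [], []
    for cluster in ensemble.clusters:
        est, ids = knn_estimate(
            pq, cluster, ensemble.knn_k, ensemble.tpd_params, ensemble.knn_weight_delta
        )
        estimates.append(est)
        neighbors.append(ids)
        logliks.append(sequence_loglik(pq, cluster.chain))

    weights = normalize_likelihoods(logliks)
    final = float(np.dot(weights, estimates))
    return PredictionResult(
        patient_id=p.patient_id,
        final_cost=final,
        per_cluster_estimates=np.array(estimates),
        cluster_weights=weights,
        neighbor_ids=tuple(neighbors),
    )


def fit_ensemble(dataset: Dataset, config: PipelineConfig | None = None) -> PredictorEnsemble:
    """Run the full learning phase on a training dataset.

    Fits the cost discretizer, quantizes, computes the pairwise TPD matrix,
    clusters with hierarchical DBSCAN (noise resolved to nearest cluster),
    and fits one smoothed Markov chain per group over the global action
    vocabulary.
    """
    config = config or PipelineConfig()
    all_costs = np.concatenate([s.costs for s in dataset])
    disc = fit_quantiles(all_costs, config.n_segments)

    eps = config.epsilon
    if eps is None:
        eps = DEFAULT_EPSILON_FRACTION * float(np.median(disc.segment_means))
        eps = max(eps, 1e-9)  # all-zero-cost corner case
    params = TPDParams(w1=config.w1, w2=config.w2, epsilon=eps)

    quantized = quantize_dataset(dataset, disc)
    dmat = tpd_matrix(quantized, params)

    delta = config.knn_weight_delta
    if delta is None:
        off_diag = dmat[np.triu_indices_from(dmat, k=1)]
        delta = DEFAULT_KNN_DELTA_FRACTION * float(np.median(off_diag))
        delta = max(delta, 1e-12)

    assignment = resolve_noise(
        cluster_sequences(dmat, config.min_cluster_size), dmat
    )

    vocab: list[VocabAction] = sorted(
        {(a.activity, float(a.cost)) for s in quantized for a in s.actions}
    )
    raw_totals = dataset.total_costs()
    clusters = []
    for cid in sorted(set(assignment.labels.tolist())):
        idx = np.where(assignment.labels == cid)[0]
        members = [quantized.sequences[i] for i in idx]
        chain = fit_markov(members, vocab, beta=config.smoothing_beta)
        clusters.append(
            ClusterModel(
                cluster_id=int(cid),
                member_ids=[dataset.sequences[i].patient_id for i in idx],
                member_sequences=members,
                member_total_costs=raw_totals[idx],
                chain=chain,
            )
        )
    return PredictorEnsemble(
        discretizer=disc,
        tpd_params=params,
        clusters=clusters,
        knn_k=config.knn_k,
        knn_weight_delta=delta,
        config=config,
    )
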