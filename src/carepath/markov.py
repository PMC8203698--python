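"""First-order Markov chains over (activity, modified-cost) actions.

Each patient group is summarized by the empirical transition probabilities
between its actions plus an initial-action distribution.  A new sequence is
scored against every group by the chain likelihood

    lambda_l(P) = p_l(a_1) * prod_i p_l(a_{i+1} | a_i)

computed in log space, and the per-group likelihoods are normalized into
mixture weights with a log-sum-exp softmax.

Additive (pseudo-count) smoothing with ``beta`` keeps a single unseen
transition from annihilating a whole group's likelihood; ``beta = 0``
reproduces the raw maximum-likelihood counts, with all-zero transition
rows replaced by the uniform distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import logsumexp

from .core import TreatmentSequence

__all__ = [
    "MarkovModel",
    "ClusterModel",
    "fit_markov",
    "sequence_loglik",
    "normalize_likelihoods",
]

VocabAction = tuple[str, float]  # (activity, modified cost)

DEFAULT_BETA = 0.5


@dataclass(frozen=True)
class MarkovModel:
    action_vocab: tuple[VocabAction, ...]
    initial_probs: np.ndarray      # length N, sums to 1
    transition_matrix: np.ndarray  # N x N row-stochastic
    smoothing_beta: float

    @property
    def n_actions(self) -> int:
        return len(self.action_vocab)

    @cached_property
    def _index(self) -> dict[VocabAction, int]:
        return {a: i for i, a in enumerate(self.action_vocab)}

    @cached_property
    def _by_activity(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, (act, _) in enumerate(self.action_vocab):
            out.setdefault(act, []).append(i)
        return out

    def action_index(self, action: VocabAction) -> int | None:
        """Vocabulary index of an action, applying the unseen-action rule.

        An unseen (activity, cost) pair is mapped to the vocabulary action
        with the same activity and nearest cost; if the activity itself is
        unseen, ``None`` is returned and the caller scores the step with
        the uniform floor 1/N.
        """
        idx = self._index.get(action)
        if idx is not None:
            return idx
        act, cost = action
        same_act = self._by_activity.get(act)
        if not same_act:
            return None
        costs = np.array([self.action_vocab[i][1] for i in same_act])
        return same_act[int(np.argmin(np.abs(costs - cost)))]


@dataclass
class ClusterModel:
    """One patient group: its member sequences, their raw totals, and its chain."""

    cluster_id: int
    member_ids: list[str]
    member_sequences: list[TreatmentSequence]  # quantized costs
    member_total_costs: np.ndarray             # raw (un-quantized) totals
    chain: MarkovModel

    def __post_init__(self) -> None:
        if len(self.member_sequences) < 1:
            raise ValueError("a cluster must have at least one member")
        if len(self.member_total_costs) != len(self.member_sequences):
            raise ValueError("member_total_costs misaligned with member_sequences")


def _as_vocab_action(a) -> VocabAction:
    return (a.activity, float(a.cost))


def fit_markov(
    sequences: list[TreatmentSequence],
    vocab: list[VocabAction],
    beta: float = DEFAULT_BETA,
) -> MarkovModel:
    """Fit transition and initial probabilities from observed sequences.

    Transition (i, j) = (count(i->j) + beta) / (outgoing(i) + N*beta);
    initial i = (starts(i) + beta) / (n_sequences + N*beta).  With
    ``beta = 0`` rows with no outgoing transitions are uniform.
    """
    if len(sequences) < 1:
        raise ValueError("need at least one sequence")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    index = {a: i for i, a in enumerate(vocab)}
    n = len(vocab)
    trans = np.zeros((n, n))
    init = np.zeros(n)
    for seq in sequences:
        try:
            ids = [index[_as_vocab_action(a)] for a in seq.actions]
        except KeyError as exc:
            raise ValueError(f"action {exc.args[0]!r} not in vocabulary") from None
        init[ids[0]] += 1
        for i, j in zip(ids[:-1], ids[1:]):
            trans[i, j] += 1

    row_sums = trans.sum(axis=1, keepdims=True)
    if beta > 0:
        trans_p = (trans + beta) / (row_sums + n * beta)
        init_p = (init + beta) / (len(sequences) + n * beta)
    else:
        with np.errstate(invalid="ignore"):
            trans_p = np.where(row_sums > 0, trans / np.where(row_sums > 0, row_sums, 1), 1.0 / n)
        init_p = init / init.sum()
    return MarkovModel(
        action_vocab=tuple(vocab),
        initial_probs=init_p,
        transition_matrix=trans_p,
        smoothing_beta=float(beta),
    )


def _log(p: float) -> float:
    return float(np.log(p)) if p > 0 else -np.inf


def sequence_loglik(p: TreatmentSequence, model: MarkovModel) -> float:
    """Log-likelihood of a (quantized) sequence under a group's chain.

    Steps involving an activity absent from the vocabulary contribute the
    uniform floor log(1/N).  May be -inf only when ``smoothing_beta = 0``.
    """
    if len(p) < 1:
        raise ValueError("cannot score an empty sequence")
    n = model.n_actions
    floor = _log(1.0 / n)
    ids = [model.action_index(_as_vocab_action(a)) for a in p.actions]

    ll = floor if ids[0] is None else _log(float(model.initial_probs[ids[0]]))
    for i, j in zip(ids[:-1], ids[1:]):
        if i is None or j is None:
            ll += floor
        else:
            ll += _log(float(model.transition_matrix[i, j]))
    return ll


def normalize_likelihoods(logliks) -> np.ndarray:
    """Normalize per-group log-likelihoods into mixture weights.

    Computed stably via log-sum-exp; if every group has zero likelihood
    the weights fall back to uniform with a warning.
    """
    ll = np.asarray(logliks, dtype=float)
    if ll.size < 1:
        raise ValueError("need at least one log-likelihood")
    if np.all(np.isneginf(ll)):
        warnings.warn(
            "all groups assign zero likelihood; using uniform weights",
            UserWarning,
            stacklevel=2,
        )
        return np.full(ll.shape, 1.0 / ll.size)
    return np.exp(ll - logsumexp(ll))
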