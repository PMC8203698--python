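"""Treatment Pattern Difference (TPD).

A cost-aware edit distance between two action sequences.  Edit operations
are priced by the money involved rather than unit costs:

* inserting or deleting an action costs its healthcare cost ``y``;
* substituting one activity by a different one costs ``|y_i - y_j| + eps``
  (``eps > 0`` so that substitution is never free);
* aligning two actions with the *same* activity is not free either — it is
  penalized by their cost gap ``|y_i - y_j|``, weighted separately.

The distance is the minimum over all monotone edit scripts of

    w1 * (inserts + deletes + substitutions) + w2 * (same-activity gaps)

with ``w1 > w2 > 0`` so that changing the activity mix is penalized more
than spending a different amount on the same activity.  TPD is not a
metric (the triangle inequality can fail); it is only used as a pairwise
dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .core import Dataset, TreatmentSequence

__all__ = ["TPDParams", "EMPTY", "tpd_distance", "tpd_matrix", "tpd_bruteforce_oracle"]

DEFAULT_W1 = 0.7
DEFAULT_W2 = 0.3


class _EmptySequence:
    """Zero-length stand-in accepted by the TPD functions.

    A valid :class:`~carepath.core.TreatmentSequence` always has at least
    one action, but the edit distance itself is defined down to the empty
    sequence (TPD(P, empty) = w1 * total cost of P); this sentinel lets
    that boundary be exercised directly.
    """

    patient_id = "<empty>"
    actions: tuple = ()

    @property
    def costs(self) -> np.ndarray:
        return np.zeros(0)

    def __len__(self) -> int:
        return 0


EMPTY = _EmptySequence()


@dataclass(frozen=True)
class TPDParams:
    """Weights of the TPD edit operations.

    ``epsilon`` is the floor penalty for substituting between different
    activities of equal cost; it should be small relative to typical
    modified costs (a scale-relative default is chosen at ensemble-fit
    time: 1e-3 times the median segment mean).
    """

    w1: float = DEFAULT_W1
    w2: float = DEFAULT_W2
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.w1 > self.w2 > 0):
            raise ValueError(f"require w1 > w2 > 0, got w1={self.w1}, w2={self.w2}")
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def _encode(seq: TreatmentSequence, codebook: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    acts = np.array([codebook[a.activity] for a in seq.actions], dtype=np.int64)
    return acts, seq.costs


def _tpd_arrays(x1, y1, x2, y2, w1: float, w2: float, eps: float) -> float:
    """Row-vectorized dynamic program over the (n+1) x (m+1) alignment grid."""
    n, m = len(x1), len(x2)
    ins_cum = np.concatenate(([0.0], w1 * np.cumsum(y2)))
    prev = ins_cum.copy()  # row 0: build p2 prefix by insertions
    for i in range(1, n + 1):
        diag = np.where(
            x1[i - 1] == x2,
            w2 * np.abs(y1[i - 1] - y2),
            w1 * (np.abs(y1[i - 1] - y2) + eps),
        )
        cur = np.empty(m + 1)
        cur[0] = prev[0] + w1 * y1[i - 1]
        cur[1:] = np.minimum(prev[:-1] + diag, prev[1:] + w1 * y1[i - 1])
        # left-to-right insertion recurrence via a prefix-minimum transform:
        # cur[j] = min(cur[j], cur[j-1] + w1*y2[j-1])
        cur = np.minimum.accumulate(cur - ins_cum) + ins_cum
        prev = cur
    return float(prev[m])


def tpd_distance(p1: TreatmentSequence, p2: TreatmentSequence, params: TPDParams) -> float:
    """Minimum-cost edit distance between two action sequences.

    Sequences are expected to carry modified (quantized) costs when used
    inside the pipeline, but the function itself accepts any costs.
    """
    codebook: dict[str, int] = {}
    for a in (*p1.actions, *p2.actions):
        codebook.setdefault(a.activity, len(codebook))
    x1, y1 = _encode(p1, codebook)
    x2, y2 = _encode(p2, codebook)
    return _tpd_arrays(x1, y1, x2, y2, params.w1, params.w2, params.epsilon)


def tpd_matrix(dataset: Dataset, params: TPDParams) -> np.ndarray:
    """Symmetric pairwise TPD matrix over a dataset (zero diagonal)."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    codebook: dict[str, int] = {}
    for act in sorted(dataset.activity_alphabet):
        codebook[act] = len(codebook)
    encoded = [_encode(s, codebook) for s in dataset]

    n = len(dataset)
    mat = np.zeros((n, n))
    for i in range(n):
        xi, yi = encoded[i]
        for j in range(i + 1, n):
            xj, yj = encoded[j]
            d = _tpd_arrays(xi, yi, xj, yj, params.w1, params.w2, params.epsilon)
            mat[i, j] = mat[j, i] = d
    return mat


_ORACLE_MAX_LEN = 5


def tpd_bruteforce_oracle(p1: TreatmentSequence, p2: TreatmentSequence, params: TPDParams) -> float:
    """Exhaustive minimum over all monotone alignments (test support only).

    Enumerates every pair of equal-size increasing index subsets of the two
    sequences; aligned pairs are matches or substitutions, everything else
    is deleted from ``p1`` or inserted from ``p2``.  Exponential — refuses
    sequences longer than 5.
    """
    if len(p1) > _ORACLE_MAX_LEN or len(p2) > _ORACLE_MAX_LEN:
        raise ValueError(f"oracle limited to length <= {_ORACLE_MAX_LEN}")
    a1, a2 = p1.actions, p2.actions
    n, m = len(a1), len(a2)
    w1, w2, eps = params.w1, params.w2, params.epsilon
    total1 = sum(a.cost for a in a1)
    total2 = sum(a.cost for a in a2)

    best = np.inf
    for r in range(min(n, m) + 1):
        for idx1 in combinations(range(n), r):
            for idx2 in combinations(range(m), r):
                cost = w1 * (total1 + total2)
                for i, j in zip(idx1, idx2):
                    u, v = a1[i], a2[j]
                    cost -= w1 * (u.cost + v.cost)  # not deleted/inserted
                    if u.activity == v.activity:
                        cost += w2 * abs(u.cost - v.cost)
                    else:
                        cost += w1 * (abs(u.cost - v.cost) + eps)
                best = min(best, cost)
    return float(best)
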