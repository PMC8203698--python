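"""Quantile discretization of healthcare costs.

Raw costs are replaced by *modified costs*: the range of observed costs is
cut at the 1/n_s, 2/n_s, ... empirical quantiles and every cost falling in
a segment is replaced by the mean of the training costs of that segment.
This reduces the (activity, cost) action vocabulary to a finite set while
keeping roughly equal numbers of cost elements per segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Action, Dataset, TreatmentSequence

__all__ = ["CostDiscretizer", "fit_quantiles", "quantize", "quantize_dataset", "nqe"]

# Ascending segment names used when the effective number of segments is 8:
# very-very-low ... very-very-high.
_EIGHT_LABELS = ["VVL", "VL", "L", "ML", "MH", "H", "VH", "VVH"]


@dataclass(frozen=True)
class CostDiscretizer:
    """Quantile boundaries plus per-segment training means.

    ``boundaries`` has one entry fewer than ``segment_means``; segment ``i``
    covers the half-open interval [boundaries[i-1], boundaries[i]), with the
    first segment open below and the last closed above.
    """

    n_segments: int          # requested number of segments
    boundaries: np.ndarray   # strictly ascending, len = n_effective - 1
    segment_means: np.ndarray
    segment_labels: tuple[str, ...] = field(default=())

    @property
    def n_effective(self) -> int:
        return len(self.segment_means)


def fit_quantiles(costs, n_segments: int) -> CostDiscretizer:
    """Fit a cost discretizer on training costs.

    Boundaries are the empirical i/n_segments quantiles (linear
    interpolation) for i = 1..n_segments-1.  Segments emptied by duplicated
    quantiles (heavily tied costs) are merged into their lower neighbour, so
    the effective number of segments may be smaller than requested.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.size == 0:
        raise ValueError("cannot fit a discretizer on an empty cost list")
    if n_segments < 1:
        raise ValueError(f"n_segments must be >= 1, got {n_segments}")

    qs = np.arange(1, n_segments) / n_segments
    boundaries = np.unique(np.quantile(costs, qs)) if n_segments > 1 else np.array([])
    labels = np.searchsorted(boundaries, costs, side="right")

    # drop segments with no training mass, keeping the separating boundary
    # at the left edge of the next populated segment
    present = np.unique(labels)
    means = np.array([costs[labels == s].mean() for s in present])
    kept_boundaries = np.array([boundaries[s - 1] for s in present[1:]])

    n_eff = len(present)
    names = tuple(_EIGHT_LABELS) if n_eff == 8 else tuple(f"S{i+1}" for i in range(n_eff))
    return CostDiscretizer(
        n_segments=n_segments,
        boundaries=kept_boundaries,
        segment_means=means,
        segment_labels=names,
    )


def quantize(cost: float, d: CostDiscretizer) -> float:
    """Map a raw cost to its segment mean (total on non-negative costs)."""
    idx = int(np.searchsorted(d.boundaries, cost, side="right"))
    return float(d.segment_means[idx])


def quantize_array(costs, d: CostDiscretizer) -> np.ndarray:
    costs = np.asarray(costs, dtype=float)
    idx = np.searchsorted(d.boundaries, costs, side="right")
    return d.segment_means[idx]


def quantize_dataset(dataset: Dataset, d: CostDiscretizer) -> Dataset:
    """Replace every action's cost by its modified (segment-mean) cost.

    The action vocabulary of the result is a subset of
    activities x effective segments.
    """
    out = []
    for seq in dataset:
        qcosts = quantize_array(seq.costs, d)
        actions = tuple(
            Action(a.activity, float(c)) for a, c in zip(seq.actions, qcosts)
        )
        out.append(TreatmentSequence(seq.patient_id, actions))
    return Dataset(out)


def nqe(true_costs, modified_costs) -> float:
    """Normalized quantization error.

    Mean absolute difference between true and modified costs, divided by
    the range of the true costs.  Lies in [0, 1] when the modified costs
    are segment means of the true costs.
    """
    c = np.asarray(true_costs, dtype=float)
    cm = np.asarray(modified_costs, dtype=float)
    if c.shape != cm.shape:
        raise ValueError("true and modified cost lists must have equal length")
    if c.size < 2:
        raise ValueError("need at least 2 cost elements")
    rng = c.max() - c.min()
    if rng == 0:
        raise ZeroDivisionError("NQE undefined: all true costs are equal (zero range)")
    return float(np.mean(np.abs(c - cm)) / rng)
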