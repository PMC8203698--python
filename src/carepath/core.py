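"""Domain types and event-log / model I/O.

A patient's treatment is an ordered sequence of *actions*, each pairing a
clinical activity code (consultation, surgery, lab work, ...) with the
monetary cost it incurred at that visit.  Calendar time is used only to
order the actions; the models downstream are order-based.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

__all__ = [
    "Action",
    "TreatmentSequence",
    "Dataset",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "save_model",
    "load_model",
]


class EventLogError(ValueError):
    """Raised for malformed or invalid event logs."""


@dataclass(frozen=True)
class Action:
    """One (activity, cost) event of a patient's treatment."""

    activity: str
    cost: float

    def __post_init__(self) -> None:
        if not self.activity:
            raise ValueError("activity must be a non-empty string")
        if not np.isfinite(self.cost) or self.cost < 0:
            raise ValueError(f"cost must be finite and >= 0, got {self.cost!r}")


@dataclass(frozen=True)
class TreatmentSequence:
    """Time-ordered actions of one patient."""

    patient_id: str
    actions: tuple[Action, ...]

    def __post_init__(self) -> None:
        if len(self.actions) < 1:
            raise ValueError(f"patient {self.patient_id!r}: sequence must have length >= 1")

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def activities(self) -> tuple[str, ...]:
        return tuple(a.activity for a in self.actions)

    @property
    def costs(self) -> np.ndarray:
        return np.array([a.cost for a in self.actions], dtype=float)

    @property
    def total_cost(self) -> float:
        return float(self.costs.sum())


@dataclass
class Dataset:
    """A collection of treatment sequences with a data-driven activity alphabet."""

    sequences: list[TreatmentSequence]

    def __post_init__(self) -> None:
        ids = [s.patient_id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient ids: {dupes}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @property
    def activity_alphabet(self) -> set[str]:
        return {a.activity for s in self.sequences for a in s.actions}

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.sequences]

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset([self.sequences[i] for i in indices])

    def total_costs(self) -> np.ndarray:
        return np.array([s.total_cost for s in self.sequences], dtype=float)


_REQUIRED_COLUMNS = ("patient_id", "visit_time", "activity", "cost")


def read_event_log(path: str | Path) -> Dataset:
    """Read a CSV event log into a :class:`Dataset`.

    The file must have columns ``patient_id,visit_time,activity,cost``.
    Rows are grouped by patient and stably sorted by ``visit_time`` within
    each patient, so ties keep file order.  Patients appear in order of
    first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise EventLogError(f"event log not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "activity": str})
    except pd.errors.EmptyDataError:
        raise EventLogError(f"empty event log: {path}") from None
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EventLogError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise EventLogError(f"event log has no rows: {path}")

    costs = pd.to_numeric(df["cost"], errors="coerce")
    if costs.isna().any():
        row = int(costs.index[costs.isna()][0])
        raise EventLogError(f"non-numeric cost at row {row}: {df['cost'].iloc[row]!r}")
    if (costs < 0).any():
        row = int(costs.index[costs < 0][0])
        raise EventLogError(f"negative cost at row {row}: {costs.iloc[row]}")
    df = df.assign(cost=costs.astype(float))

    # visit_time may be numeric or a timestamp; only its order matters
    vt = pd.to_numeric(df["visit_time"], errors="coerce")
    if vt.isna().any():
        vt = pd.to_datetime(df["visit_time"], errors="coerce", format="mixed")
        if vt.isna().any():
            vt = df["visit_time"].astype(str)
    df = df.assign(_vt=vt)

    sequences = []
    for pid in df["patient_id"].drop_duplicates():
        sub = df[df["patient_id"] == pid].sort_values("_vt", kind="stable")
        actions = tuple(Action(r.activity, r.cost) for r in sub.itertuples())
        sequences.append(TreatmentSequence(str(pid), actions))
    return Dataset(sequences)


def write_event_log(dataset: Dataset, path: str | Path, decimals: int | None = None) -> None:
    """Write a dataset as a CSV event log.

    ``visit_time`` is emitted as the 0-based visit index.  When ``decimals``
    is given, costs are rounded to that precision and a warning is issued if
    any value changes (lossy round trip).
    """
    rows = []
    lossy = False
    for seq in dataset:
        for i, a in enumerate(seq.actions):
            cost = a.cost
            if decimals is not None:
                rounded = round(cost, decimals)
                if rounded != cost:
                    lossy = True
                cost = rounded
            rows.append((seq.patient_id, i, a.activity, cost))
    if lossy:
        warnings.warn(
            f"costs rounded to {decimals} decimal(s); round trip is lossy",
            UserWarning,
            stacklevel=2,
        )
    df = pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS))
    df.to_csv(path, index=False)


def save_model(ensemble, path: str | Path) -> None:
    """Serialize a fitted :class:`~carepath.predict.PredictorEnsemble` to JSON."""
    doc = {"schema_version": SCHEMA_VERSION, "model": ensemble.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`."""
    from .predict import PredictorEnsemble  # deferred: predict imports core

    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise EventLogError(f"corrupted model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise EventLogError(f"not a model file (no schema_version): {path}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise EventLogError(
            f"model schema version {doc['schema_version']} not supported "
            f"(expected {SCHEMA_VERSION})"
        )
    return PredictorEnsemble.from_dict(doc["model"])
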