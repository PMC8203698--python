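"""Rank-based comparison of competing predictors over multiple settings.

Given a matrix of error scores (algorithms x datasets, lower is better),
the Friedman test ranks the algorithms within each dataset and tests
whether the mean ranks differ.  Post-hoc, a control algorithm (typically
the best-ranked one) is compared against each contender with the
Bonferroni–Dunn critical difference and with z-score p-values adjusted by
Hochberg's step-up procedure.

A reference benchmark matrix — published mean MAPE values of four cost
predictors at nine observed-sequence fractions — ships with the package
(``load_reference_matrix``) so the whole chain can be run on printed
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ErrorMatrix",
    "ComparisonReport",
    "friedman_ranks",
    "friedman_statistic",
    "bonferroni_dunn_cd",
    "pairwise_z",
    "hochberg_adjust",
    "compare_algorithms",
    "load_reference_matrix",
]


@dataclass(frozen=True)
class ErrorMatrix:
    """k algorithms x n datasets matrix of error scores (lower = better)."""

    algorithms: tuple[str, ...]
    datasets: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.algorithms), len(self.datasets)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.algorithms)} algorithms x {len(self.datasets)} datasets"
            )
        if not np.isfinite(v).all():
            raise ValueError("error matrix contains missing or non-finite entries")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ErrorMatrix":
        return cls(
            algorithms=tuple(str(i) for i in df.index),
            datasets=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ComparisonReport:
    algorithms: tuple[str, ...]
    mean_ranks: np.ndarray
    friedman_stat: float
    df: int
    critical_value: float
    reject_null: bool
    cd: float
    control: str
    pairwise: pd.DataFrame  # index: contender; columns: z, p_unadjusted, p_hochberg


def friedman_ranks(m: ErrorMatrix) -> np.ndarray:
    """Mean rank per algorithm (rank 1 = lowest error; ties averaged)."""
    k, n = m.values.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 algorithms and 2 datasets")
    ranks = np.apply_along_axis(sps.rankdata, 0, m.values)
    return ranks.mean(axis=1)


def friedman_statistic(
    mean_ranks, n: int, k: int, alpha: float = 0.05
) -> tuple[float, int, float]:
    """Friedman chi-square statistic, its degrees of freedom, and the
    upper-alpha critical value.

    chi2_F = 12n / (k(k+1)) * (sum R_j^2 - k(k+1)^2 / 4), df = k - 1.
    """
    r = np.asarray(mean_ranks, dtype=float)
    stat = 12.0 * n / (k * (k + 1)) * (np.sum(r**2) - k * (k + 1) ** 2 / 4.0)
    dof = k - 1
    crit = float(sps.chi2.ppf(1 - alpha, dof))
    return float(stat), dof, crit


def bonferroni_dunn_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Bonferroni–Dunn critical difference between mean ranks.

    CD = q * sqrt(k(k+1)/(6n)) with q the standard-normal upper quantile
    at alpha/(2(k-1)), i.e. a two-sided bound corrected for the k-1
    comparisons against the control.
    """
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 algorithms and n >= 1 datasets")
    q = float(sps.norm.ppf(1 - alpha / (2 * (k - 1))))
    return q * float(np.sqrt(k * (k + 1) / (6.0 * n)))


def pairwise_z(mean_ranks, control_index: int, n: int, k: int) -> np.ndarray:
    """z-score of each non-control algorithm's mean rank vs the control's.

    z_j = (R_j - R_control) / sqrt(k(k+1)/(6n)); returned in algorithm
    order with the control position omitted.
    """
    r = np.asarray(mean_ranks, dtype=float)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    z = (r - r[control_index]) / se
    return np.delete(z, control_index)


def hochberg_adjust(p_values) -> np.ndarray:
    """Hochberg step-up adjusted p-values, in the input order.

    With p_(1) <= ... <= p_(m): adjusted_(m) = p_(m) and
    adjusted_(i) = min(adjusted_(i+1), (m - i + 1) * p_(i)).
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj = np.empty(m)
    adj[m - 1] = sorted_p[m - 1]
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i + 1], (m - i) * sorted_p[i])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def compare_algorithms(
    m: ErrorMatrix, control: str | None = None, alpha: float = 0.05
) -> ComparisonReport:
    """Full comparison chain: ranks, Friedman test, CD, adjusted p-values.

    ``control`` defaults to the best-ranked (lowest mean rank) algorithm.
    Unadjusted p-values are two-sided normal tail probabilities of the
    z-scores.
    """
    k, n = m.values.shape
    mean_ranks = friedman_ranks(m)
    stat, dof, crit = friedman_statistic(mean_ranks, n, k, alpha)
    cd = bonferroni_dunn_cd(k, n, alpha)

    if control is None:
        control_index = int(np.argmin(mean_ranks))
    else:
        try:
            control_index = m.algorithms.index(control)
        except ValueError:
            raise ValueError(f"unknown control algorithm {control!r}") from None
    control_name = m.algorithms[control_index]

    z = pairwise_z(mean_ranks, control_index, n, k)
    p_raw = 2 * sps.norm.sf(np.abs(z))
    p_adj = hochberg_adjust(p_raw)
    contenders = [a for i, a in enumerate(m.algorithms) if i != control_index]
    pairwise = pd.DataFrame(
        {"z": z, "p_unadjusted": p_raw, "p_hochberg": p_adj}, index=contenders
    )
    return ComparisonReport(
        algorithms=m.algorithms,
        mean_ranks=mean_ranks,
        friedman_stat=stat,
        df=dof,
        critical_value=crit,
        reject_null=stat > crit,
        cd=cd,
        control=control_name,
        pairwise=pairwise,
    )


def read_error_matrix(path) -> ErrorMatrix:
    """Read an algorithms x datasets TSV (first column = algorithm names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ErrorMatrix.from_frame(df)


def load_reference_matrix() -> ErrorMatrix:
    """The shipped benchmark MAPE matrix (4 algorithms x 9 prefix lengths)."""
    ref = resources.files("carepath").joinpath("data/reference_mape_matrix.tsv")
    with resources.as_file(ref) as path:
        return read_error_matrix(path)
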