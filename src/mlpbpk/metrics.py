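"""Prediction-accuracy statistics on positive PK quantities.

Fold error FE_i = predicted_i / observed_i; the summary statistics are the
geometric-mean fold error AFE = 10^(mean log10 FE), the geometric-mean
absolute fold error AAFE = 10^(mean |log10 FE|), the percentages of
predictions within 2-fold and 3-fold, and the squared Pearson correlation of
the log10-transformed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AccuracyReport", "fold_error_stats", "r2_log"]


@dataclass
class AccuracyReport:
    n: int
    fold_errors: np.ndarray
    afe: float
    aafe: float
    pct_within_2fold: float
    pct_within_3fold: float
    r2_log: float | None
    n_within_2fold: int
    n_within_3fold: int

    def summary(self) -> dict[str, float | int | None]:
        return {
            "n": self.n,
            "afe": self.afe,
            "aafe": self.aafe,
            "pct_within_2fold": self.pct_within_2fold,
            "pct_within_3fold": self.pct_within_3fold,
            "r2_log": self.r2_log,
        }


def _check_positive(predicted: np.ndarray, observed: np.ndarray) -> None:
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    for name, v in (("predicted", predicted), ("observed", observed)):
        bad = np.flatnonzero(~(v > 0))
        if bad.size:
            raise ValueError(f"{name} has non-positive value at index {bad[0]}")


def pct_within_fold(fold_errors: np.ndarray, k: float,
                    inclusive: bool = True) -> tuple[float, int]:
    if inclusive:
        within = (fold_errors >= 1.0 / k) & (fold_errors <= k)
    else:
        within = (fold_errors > 1.0 / k) & (fold_errors < k)
    n_within = int(within.sum())
    return 100.0 * n_within / fold_errors.size, n_within


def fold_error_stats(predicted, observed,
                     inclusive_bounds: bool = True) -> AccuracyReport:
    """Fold-error accuracy report of predictions against observations.

    Fold bounds are inclusive by default (FE exactly 2.0 counts as within
    2-fold); pass ``inclusive_bounds=False`` for strict bounds.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    _check_positive(predicted, observed)
    fe = predicted / observed
    log_fe = np.log10(fe)
    afe = float(10.0 ** log_fe.mean())
    aafe = float(10.0 ** np.abs(log_fe).mean())
    p2, n2 = pct_within_fold(fe, 2.0, inclusive_bounds)
    p3, n3 = pct_within_fold(fe, 3.0, inclusive_bounds)
    return AccuracyReport(
        n=fe.size, fold_errors=fe, afe=afe, aafe=aafe,
        pct_within_2fold=p2, pct_within_3fold=p3,
        r2_log=r2_log(predicted, observed) if fe.size >= 3 else None,
        n_within_2fold=n2, n_within_3fold=n3,
    )


def r2_log(predicted, observed) -> float | None:
    """Squared Pearson correlation of log10(predicted) vs log10(observed).

    Returns None when either vector has zero variance on the log scale.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    _check_positive(predicted, observed)
    if predicted.size < 3:
        raise ValueError("need at least 3 pairs")
    x, y = np.log10(predicted), np.log10(observed)
    if math.isclose(float(np.var(x)), 0.0) or math.isclose(float(np.var(y)), 0.0):
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r
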