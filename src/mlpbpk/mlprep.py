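"""Model-agnostic ML data-engineering pipeline.

Reusable building blocks for QSAR-style property modelling: dataset curation
(invalid structures, molecular-weight cap, cross-source duplicate
reconciliation), variance/correlation feature filtering, seeded 8:1:1
train/validation/test splitting, Boruta all-relevant feature selection and
plain regression metrics.  Model training itself is out of scope; Boruta
takes any fitted-importance provider (a random-forest importance by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "CurationLedger",
    "curate_records",
    "filter_features",
    "split_811",
    "BorutaResult",
    "boruta_select",
    "eval_regression",
]

MW_THRESHOLD = 900.0       # Da
DUPLICATE_FOLD_LIMIT = 2.0


@dataclass
class CurationLedger:
    """Accounting of every record removed during curation."""

    removed: list[dict] = field(default_factory=list)

    def add(self, record_id, reason: str) -> None:
        self.removed.append({"id": record_id, "reason": reason})

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for entry in self.removed:
            out[entry["reason"]] = out.get(entry["reason"], 0) + 1
        return out


def curate_records(records: pd.DataFrame,
                   source_priority: Sequence[str] | None = None,
                   mw_threshold: float = MW_THRESHOLD,
                   fold_limit: float = DUPLICATE_FOLD_LIMIT,
                   ) -> tuple[pd.DataFrame, CurationLedger]:
    """Apply the dataset curation filters; returns (kept, ledger).

    Expects columns ``id``, ``source``, ``smiles_valid``, ``mw``, ``value``.
    Rules: drop invalid structures, missing values, mw > threshold; for
    cross-source duplicates, drop both when the value ratio exceeds
    ``fold_limit``, otherwise keep the record from the highest-priority
    source (``source_priority`` order, first = preferred).
    """
    required = {"id", "source", "smiles_valid", "mw", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    ledger = CurationLedger()
    df = records.copy()

    bad = ~df["smiles_valid"].astype(bool)
    for rid in df.loc[bad, "id"]:
        ledger.add(rid, "invalid_smiles")
    df = df[~bad]

    bad = df["value"].isna()
    for rid in df.loc[bad, "id"]:
        ledger.add(rid, "missing_value")
    df = df[~bad]

    bad = df["mw"] > mw_threshold
    for rid in df.loc[bad, "id"]:
        ledger.add(rid, f"mw>{mw_threshold:g}")
    df = df[~bad]

    priority = {s: i for i, s in enumerate(source_priority or [])}
    keep_rows = []
    for rid, group in df.groupby("id", sort=False):
        if len(group) == 1:
            keep_rows.append(group.index[0])
            continue
        values = group["value"].astype(float)
        if values.max() / values.min() > fold_limit:
            for _ in range(len(group)):
                ledger.add(rid, f"duplicate_ratio>{fold_limit:g}")
            continue
        ranked = group.assign(
            _rank=group["source"].map(lambda s: priority.get(s, len(priority)))
        ).sort_values("_rank", kind="stable")
        keep_rows.append(ranked.index[0])
        for _ in range(len(group) - 1):
            ledger.add(rid, "duplicate_resolved")
    kept = df.loc[sorted(keep_rows)].reset_index(drop=True)
    return kept, ledger


def filter_features(features: pd.DataFrame, var_threshold: float = 0.05,
                    corr_threshold: float = 0.9,
                    ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Variance then pairwise-correlation feature filter.

    Drops features with variance < ``var_threshold``; then, scanning columns
    in order, drops the later member of any pair with |r| > ``corr_threshold``
    (earlier column wins).  Returns (reduced table, ledger of dropped names).
    """
    dropped: dict[str, list[str]] = {"low_variance": [], "correlated": []}
    variances = features.var(axis=0, ddof=1)
    low = variances[variances < var_threshold].index.tolist()
    dropped["low_variance"] = low
    reduced = features.drop(columns=low)

    if reduced.shape[1] > 1:
        corr = reduced.corr().abs().to_numpy()
        cols = list(reduced.columns)
        keep: list[int] = []
        removed: set[int] = set()
        for j in range(len(cols)):
            if j in removed:
                continue
            keep.append(j)
            for k in range(j + 1, len(cols)):
                if k not in removed and corr[j, k] > corr_threshold:
                    removed.add(k)
                    dropped["correlated"].append(cols[k])
        reduced = reduced.iloc[:, keep]
    if reduced.shape[1] == 0:
        import warnings
        warnings.warn("all features removed by filtering")
    return reduced, dropped


def split_811(table: pd.DataFrame, seed: int,
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Seeded random 8:1:1 train/validation/test partition.

    Sizes are floor(0.8 n) / floor(0.1 n) / remainder; the three parts are
    disjoint and exhaustive.
    """
    n = len(table)
    if n < 10:
        raise ValueError(f"need at least 10 rows to split 8:1:1, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(0.8 * n))
    n_valid = int(np.floor(0.1 * n))
    idx_train = order[:n_train]
    idx_valid = order[n_train:n_train + n_valid]
    idx_test = order[n_train + n_valid:]
    return (table.iloc[idx_train], table.iloc[idx_valid], table.iloc[idx_test])


@dataclass
class BorutaResult:
    confirmed: list[str]
    rejected: list[str]
    tentative: list[str]
    hits: dict[str, int]
    n_iter: int


def _rf_importance(x: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
    rf = RandomForestRegressor(n_estimators=100, max_depth=7,
                               random_state=seed, n_jobs=1)
    rf.fit(x, y)
    return rf.feature_importances_


def boruta_select(features: pd.DataFrame, target, n_iter: int = 50,
                  seed: int = 0, alpha: float = 0.05,
                  importance: Callable[[np.ndarray, np.ndarray, int], np.ndarray]
                  | None = None) -> BorutaResult:
    """Boruta all-relevant feature selection.

    Each iteration appends a shuffled "shadow" copy of every feature, fits
    the importance provider, and scores a hit for each real feature whose
    importance beats the best shadow importance.  After ``n_iter`` rounds a
    two-sided binomial test (p = 0.5) at level ``alpha`` confirms features
    with significantly more hits than chance and rejects symmetric losers;
    the rest stay tentative.
    """
    names = list(features.columns)
    x = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    imp = importance or _rf_importance
    hits = {name: 0 for name in names}
    if np.var(y) == 0 or n_iter == 0:
        return BorutaResult([], [], names, hits, 0)
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        shadow = x.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        both = np.hstack([x, shadow])
        importances = imp(both, y, int(rng.integers(0, 2 ** 31 - 1)))
        max_shadow = importances[x.shape[1]:].max()
        for j, name in enumerate(names):
            if importances[j] > max_shadow:
                hits[name] += 1
    confirmed, rejected, tentative = [], [], []
    for name in names:
        p_hi = binomtest(hits[name], n_iter, 0.5, alternative="greater").pvalue
        p_lo = binomtest(hits[name], n_iter, 0.5, alternative="less").pvalue
        if p_hi < alpha / 2:
            confirmed.append(name)
        elif p_lo < alpha / 2:
            rejected.append(name)
        else:
            tentative.append(name)
    return BorutaResult(confirmed, rejected, tentative, hits, n_iter)


def eval_regression(predicted, observed) -> tuple[float | None, float]:
    """Coefficient of determination and root-mean-square error.

    R2 = 1 - SS_res/SS_tot (None when the observed variance is zero).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return None, rmse
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
    return r2, rmse
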