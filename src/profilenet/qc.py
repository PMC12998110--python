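"""Data-quality screening, descriptives, reliability and sample-size rules.

Quality filters mirror standard online-survey hygiene: drop questionnaires
completed implausibly fast, rows failing user-supplied logical-consistency
predicates, straight-lined ("regular") response patterns, and duplicate
respondent keys.  Rules are applied in a fixed precedence order
(too_fast → logic_error → regularity → duplicate) and each excluded row is
counted once, under the first rule it violates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import ResponseDataset, check_partition

__all__ = [
    "QCRules",
    "ExclusionReport",
    "DescriptivesReport",
    "apply_quality_filters",
    "response_rate",
    "descriptives",
    "cronbach_alpha",
    "min_sample_size",
]


@dataclass
class QCRules:
    """Configuration of the exclusion rules.

    min_duration_seconds: rows faster than this are dropped (None disables).
    logic_checks: predicates row -> bool, True meaning *violation*.
    regularity_run: drop rows whose longest identical-response run is at
        least this long, or whose responses have zero variance (None disables).
    dedupe: drop repeat submissions of the same respondent key (keep first).
    """

    min_duration_seconds: float | None = 180.0
    logic_checks: Sequence[Callable[[pd.Series], bool]] = ()
    regularity_run: int | None = 24
    dedupe: bool = True


@dataclass
class ExclusionReport:
    n_distributed: int
    too_fast: int = 0
    logic_error: int = 0
    regularity: int = 0
    duplicate_key: int = 0

    @property
    def n_excluded(self) -> int:
        return self.too_fast + self.logic_error + self.regularity + self.duplicate_key

    @property
    def n_retained(self) -> int:
        return self.n_distributed - self.n_excluded

    @property
    def response_rate_percent(self) -> float:
        return response_rate(self.n_distributed, self.n_retained)

    def to_dict(self) -> dict:
        return {
            "n_distributed": self.n_distributed,
            "too_fast": self.too_fast,
            "logic_error": self.logic_error,
            "regularity": self.regularity,
            "duplicate_key": self.duplicate_key,
            "n_retained": self.n_retained,
            "response_rate_percent": self.response_rate_percent,
        }


def _longest_run(row: np.ndarray) -> int:
    best = cur = 1
    for a, b in zip(row[:-1], row[1:]):
        cur = cur + 1 if a == b else 1
        best = max(best, cur)
    return best


def apply_quality_filters(
    raw: ResponseDataset, rules: QCRules | None = None
) -> tuple[ResponseDataset, ExclusionReport]:
    """Screen a raw dataset; returns the retained data and an itemized report."""
    if rules is None:
        rules = QCRules()
    report = ExclusionReport(n_distributed=raw.n)
    reason = np.full(raw.n, "", dtype=object)

    if rules.min_duration_seconds is not None:
        if raw.durations is None:
            raise ValueError("too-fast rule enabled but no duration_seconds column")
        fast = raw.durations.to_numpy() < rules.min_duration_seconds
        reason[fast & (reason == "")] = "too_fast"

    for check in rules.logic_checks:
        flags = raw.table.apply(check, axis=1).to_numpy(dtype=bool)
        reason[flags & (reason == "")] = "logic_error"

    if rules.regularity_run is not None:
        X = raw.item_matrix()
        zero_var = X.std(axis=1) == 0
        runs = np.array([_longest_run(r) for r in X])
        reg = zero_var | (runs >= rules.regularity_run)
        reason[reg & (reason == "")] = "regularity"

    if rules.dedupe:
        if raw.respondent_ids.isna().any():
            raise ValueError("dedupe rule enabled but respondent keys missing")
        dup = raw.respondent_ids.duplicated(keep="first").to_numpy()
        reason[dup & (reason == "")] = "duplicate_key"

    report.too_fast = int((reason == "too_fast").sum())
    report.logic_error = int((reason == "logic_error").sum())
    report.regularity = int((reason == "regularity").sum())
    report.duplicate_key = int((reason == "duplicate_key").sum())
    retained = raw.subset(reason == "")
    return retained, report


def response_rate(n_distributed: int, n_retained: int) -> float:
    """Effective response rate, percent, one decimal."""
    if n_distributed <= 0:
        raise ValueError("n_distributed must be positive")
    if not (0 <= n_retained <= n_distributed):
        raise ValueError("n_retained must be in [0, n_distributed]")
    return round(100.0 * n_retained / n_distributed, 1)


def min_sample_size(P: int) -> int:
    """Minimum n for a P-node network: P thresholds + P(P-1)/2 pairwise terms."""
    if P < 1:
        raise ValueError("P must be >= 1")
    return P + P * (P - 1) // 2


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Internal-consistency reliability α = k/(k-1) · (1 - Σ var_i / var_total).

    Sample variances (n-1 denominator).  Undefined (raises) when the total
    score has zero variance.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items and 2 respondents")
    k = X.shape[1]
    var_items = X.var(axis=0, ddof=1)
    var_total = X.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1.0 - var_items.sum() / var_total))


@dataclass
class DescriptivesReport:
    item_stats: pd.DataFrame  # index item, columns mean/sd/dimension
    dimension_stats: pd.DataFrame  # index dimension, columns mean/sd
    total_mean: float
    total_sd: float
    cronbach_alpha: float
    categorical: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form table of all numeric descriptives."""
        rows = [
            {"level": "item", "name": it, "mean": r["mean"], "sd": r["sd"]}
            for it, r in self.item_stats.iterrows()
        ]
        rows += [
            {"level": "dimension", "name": d, "mean": r["mean"], "sd": r["sd"]}
            for d, r in self.dimension_stats.iterrows()
        ]
        rows.append(
            {"level": "total", "name": "total", "mean": self.total_mean,
             "sd": self.total_sd}
        )
        return pd.DataFrame(rows)


def descriptives(
    data: ResponseDataset, item_map: Mapping[str, Sequence[str]]
) -> DescriptivesReport:
    """Per-item and per-dimension means/SDs, total score, alpha, categoricals."""
    check_partition(data.item_labels, item_map)
    items = data.items
    item_stats = pd.DataFrame(
        {"mean": items.mean(), "sd": items.std(ddof=1)}
    )
    dim_of = {it: d for d, its in item_map.items() for it in its}
    item_stats["dimension"] = [dim_of[it] for it in item_stats.index]

    dim_rows = {}
    for dim, its in item_map.items():
        tot = items[list(its)].sum(axis=1)
        dim_rows[dim] = {"mean": tot.mean(), "sd": tot.std(ddof=1)}
    dimension_stats = pd.DataFrame(dim_rows).T

    total = data.total_scores()
    try:
        alpha = cronbach_alpha(items)
    except ValueError:
        alpha = float("nan")  # zero total variance: reliability undefined
    categorical = {}
    for col in data.demographic_columns():
        counts = data.table[col].value_counts()
        categorical[col] = pd.DataFrame(
            {"n": counts, "percent": 100.0 * counts / counts.sum()}
        )
    return DescriptivesReport(
        item_stats=item_stats,
        dimension_stats=dimension_stats,
        total_mean=float(total.mean()),
        total_sd=float(total.std(ddof=1)),
        cronbach_alpha=alpha,
        categorical=categorical,
    )
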