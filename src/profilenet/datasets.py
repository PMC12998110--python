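"""Containers for questionnaire response data.

The package is written around the SE-NNC instrument (Self-Efficacy Scale for
Nursing Nutrition Care): 27 five-point Likert items in three dimensions —
nutritional care knowledge (NCK, 6 items), assessment and evidence
utilization (AEU, 15 items) and care delivery (CD, 6 items), total score
27–135.  Nothing below is specific to that instrument beyond the default
item map, so other Likert scales can be analysed by passing their own item
labels and dimension assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

# Default instrument layout: item label -> dimension.
SENNC_ITEMS: tuple[str, ...] = tuple(
    [f"NCK{i}" for i in range(1, 7)]
    + [f"AEU{i}" for i in range(7, 22)]
    + [f"CD{i}" for i in range(22, 28)]
)

SENNC_DIMENSIONS: dict[str, tuple[str, ...]] = {
    "NCK": tuple(f"NCK{i}" for i in range(1, 7)),
    "AEU": tuple(f"AEU{i}" for i in range(7, 22)),
    "CD": tuple(f"CD{i}" for i in range(22, 28)),
}

LIKERT_MIN = 1
LIKERT_MAX = 5

_RESERVED = ("respondent_id", "duration_seconds", "true_class")


@dataclass
class ResponseDataset:
    """Respondent-by-item Likert matrix with optional metadata.

    Parameters
    ----------
    table : pandas.DataFrame
        One row per respondent.  Must contain the item columns; may contain
        ``respondent_id``, ``duration_seconds``, ``true_class`` and arbitrary
        categorical demographic columns.
    item_labels : sequence of str, optional
        Which columns are the instrument items (default: SE-NNC layout).
    """

    table: pd.DataFrame
    item_labels: tuple[str, ...] = SENNC_ITEMS
    likert_levels: int = LIKERT_MAX

    def __post_init__(self) -> None:
        self.item_labels = tuple(self.item_labels)
        missing = [c for c in self.item_labels if c not in self.table.columns]
        if missing:
            raise ValueError(f"item columns missing from table: {missing}")
        if "respondent_id" not in self.table.columns:
            self.table = self.table.copy()
            self.table.insert(0, "respondent_id", np.arange(len(self.table)))

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    @property
    def items(self) -> pd.DataFrame:
        """The n × P item response block."""
        return self.table[list(self.item_labels)]

    def item_matrix(self) -> np.ndarray:
        return self.items.to_numpy(dtype=float)

    @property
    def respondent_ids(self) -> pd.Series:
        return self.table["respondent_id"]

    @property
    def durations(self) -> pd.Series | None:
        if "duration_seconds" in self.table.columns:
            return self.table["duration_seconds"]
        return None

    @property
    def true_class(self) -> pd.Series | None:
        if "true_class" in self.table.columns:
            return self.table["true_class"]
        return None

    def demographic_columns(self) -> list[str]:
        return [
            c
            for c in self.table.columns
            if c not in self.item_labels and c not in _RESERVED
        ]

    def total_scores(self) -> pd.Series:
        return self.items.sum(axis=1)

    def subset(self, mask) -> "ResponseDataset":
        return ResponseDataset(
            self.table.loc[mask].reset_index(drop=True),
            item_labels=self.item_labels,
            likert_levels=self.likert_levels,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Raise if item responses are missing or off the Likert scale."""
        block = self.items
        if block.isna().any().any():
            raise ValueError("missing item responses (all items are mandatory)")
        vals = block.to_numpy()
        if (vals < LIKERT_MIN).any() or (vals > self.likert_levels).any():
            raise ValueError(
                f"item responses outside [{LIKERT_MIN}, {self.likert_levels}]"
            )
        if self.respondent_ids.duplicated().any():
            raise ValueError("respondent ids are not unique")

    # -- IO ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        item_labels: Sequence[str] = SENNC_ITEMS,
        likert_levels: int = LIKERT_MAX,
    ) -> "ResponseDataset":
        return cls(pd.read_csv(path), tuple(item_labels), likert_levels)


def dimension_map(
    dimensions: Mapping[str, Sequence[str]] = SENNC_DIMENSIONS,
) -> dict[str, tuple[str, ...]]:
    """Return a copy of a dimension -> item-label assignment."""
    return {k: tuple(v) for k, v in dimensions.items()}


def check_partition(
    item_labels: Sequence[str], dimensions: Mapping[str, Sequence[str]]
) -> None:
    """Raise unless ``dimensions`` partitions ``item_labels`` exactly."""
    pooled: list[str] = []
    for labels in dimensions.values():
        pooled.extend(labels)
    if sorted(pooled) != sorted(item_labels) or len(pooled) != len(set(pooled)):
        raise ValueError("dimension assignment is not a partition of the items")
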