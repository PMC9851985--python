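"""Clinical rating-scale definitions, sum scores, score mapping, and reliability.

The SARA (Scale for the Assessment and Rating of Ataxia) has eight ordinal
items with maxima (8, 6, 4, 6, 4, 4, 4, 4) and a total of 0-40.  The f-SARA
is a four-item functional variant (gait, stance, sitting, speech), each item
rescaled to 0-4, total 0-16.  A :class:`MappingTable` converts SARA item
levels to f-SARA item levels; the shipped default collapses source levels
proportionally while fixing both endpoints, and can be replaced by any
user-supplied monotone table (JSON).

Internal consistency is quantified by Cronbach's alpha with a subject-level
bootstrap percentile confidence interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ScaleDefinition",
    "MappingTable",
    "ReliabilityResult",
    "SARA",
    "FSARA",
    "DEFAULT_FSARA_MAPPING",
    "sum_score",
    "map_to_fsara",
    "cronbach_alpha",
    "alpha_if_deleted",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered multi-item ordinal scale.

    Parameters
    ----------
    name : str
        Human-readable scale name, e.g. ``"SARA"``.
    items : sequence of (str, int)
        Ordered (item name, maximum level) pairs.  Levels run from 0 to the
        item maximum inclusive.
    column_prefix : str
        Prefix used for CSV columns (``sara`` -> ``sara_1`` .. ``sara_8``).
    """

    name: str
    items: tuple[tuple[str, int], ...]
    column_prefix: str = "item"

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a scale needs at least one item")
        for item_name, maximum in self.items:
            if maximum < 1:
                raise ValueError(f"item {item_name!r} has non-positive maximum {maximum}")

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.items)

    @property
    def maxima(self) -> tuple[int, ...]:
        return tuple(m for _, m in self.items)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def total_maximum(self) -> int:
        return sum(self.maxima)

    @property
    def columns(self) -> tuple[str, ...]:
        """CSV column names, ``<prefix>_1`` .. ``<prefix>_K``."""
        return tuple(f"{self.column_prefix}_{i}" for i in range(1, self.n_items + 1))

    def maximum_of(self, item: str) -> int:
        for name, m in self.items:
            if name == item:
                return m
        raise KeyError(f"unknown item {item!r} for scale {self.name}")


#: The eight-item SARA: total score 0-40.
SARA = ScaleDefinition(
    name="SARA",
    items=(
        ("gait", 8),
        ("stance", 6),
        ("sitting", 4),
        ("speech", 6),
        ("finger_chase", 4),
        ("finger_nose", 4),
        ("hand_fast", 4),
        ("heel_shin", 4),
    ),
    column_prefix="sara",
)

#: The four-item functional f-SARA: total score 0-16.
FSARA = ScaleDefinition(
    name="f-SARA",
    items=(
        ("gait", 4),
        ("stance", 4),
        ("sitting", 4),
        ("speech", 4),
    ),
    column_prefix="fsara",
)


@dataclass(frozen=True)
class MappingTable:
    """Total, monotone per-item level mapping between two scales.

    ``tables[item][source_level] -> target_level``.  Each per-item table must
    cover every source level, be monotone non-decreasing, and fix both
    endpoints (0 -> 0, source maximum -> target maximum).
    """

    source: ScaleDefinition
    target: ScaleDefinition
    tables: Mapping[str, Mapping[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, target_max in self.target.items:
            if item not in self.tables:
                raise ValueError(f"mapping table missing target item {item!r}")
            table = self.tables[item]
            source_max = self.source.maximum_of(item)
            for level in range(source_max + 1):
                if level not in table:
                    raise ValueError(f"mapping for {item!r} missing source level {level}")
            levels = [table[level] for level in range(source_max + 1)]
            if levels[0] != 0:
                raise ValueError(f"mapping for {item!r} must send 0 to 0")
            if levels[-1] != target_max:
                raise ValueError(
                    f"mapping for {item!r} must send source maximum {source_max} "
                    f"to target maximum {target_max}"
                )
            if any(b < a for a, b in zip(levels, levels[1:])):
                raise ValueError(f"mapping for {item!r} is not monotone non-decreasing")
            if any(not (0 <= v <= target_max) for v in levels):
                raise ValueError(f"mapping for {item!r} leaves the target range")

    def map_level(self, item: str, level: int) -> int:
        table = self.tables[item]
        if level not in table:
            raise KeyError(f"no mapping for item {item!r} level {level}")
        return table[level]

    def to_json(self) -> str:
        payload = {
            item: {str(k): v for k, v in sorted(table.items())}
            for item, table in self.tables.items()
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(
        cls, text: str, source: ScaleDefinition, target: ScaleDefinition
    ) -> "MappingTable":
        raw = json.loads(text)
        tables = {item: {int(k): int(v) for k, v in tab.items()} for item, tab in raw.items()}
        return cls(source=source, target=target, tables=tables)


def _proportional_collapse(groups: Sequence[Sequence[int]]) -> dict[int, int]:
    table: dict[int, int] = {}
    for target_level, sources in enumerate(groups):
        for s in sources:
            table[s] = target_level
    return table


#: Default SARA -> f-SARA mapping: proportional collapse of source levels with
#: both endpoints fixed.  Gait 0 / 1-2 / 3-4 / 5-6 / 7-8 -> 0..4; stance and
#: speech 0 / 1-2 / 3-4 / 5 / 6 -> 0..4; sitting is the identity.
DEFAULT_FSARA_MAPPING = MappingTable(
    source=SARA,
    target=FSARA,
    tables={
        "gait": _proportional_collapse([[0], [1, 2], [3, 4], [5, 6], [7, 8]]),
        "stance": _proportional_collapse([[0], [1, 2], [3, 4], [5], [6]]),
        "sitting": _proportional_collapse([[0], [1], [2], [3], [4]]),
        "speech": _proportional_collapse([[0], [1, 2], [3, 4], [5], [6]]),
    },
)


def sum_score(scores: Sequence[object], scale: ScaleDefinition) -> int | None:
    """Total score of one visit, or ``None`` if any item is missing.

    ``scores`` holds one entry per scale item in order; ``None`` or NaN marks
    a missing item.  Raises ``ValueError`` for out-of-range levels.
    """
    if len(scores) != scale.n_items:
        raise ValueError(
            f"expected {scale.n_items} item scores for {scale.name}, got {len(scores)}"
        )
    total = 0
    for (name, maximum), value in zip(scale.items, scores):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        level = int(value)
        if level != value or not (0 <= level <= maximum):
            raise ValueError(
                f"score {value!r} out of range for item {name!r} (maximum {maximum})"
            )
        total += level
    return total


def map_to_fsara(
    scores: Sequence[object],
    mapping: MappingTable = DEFAULT_FSARA_MAPPING,
) -> list[int | None]:
    """Map one SARA visit (eight item levels) to f-SARA levels (four items).

    SARA items 5-8 are dropped.  Missing source levels propagate to missing
    target levels.
    """
    if len(scores) != mapping.source.n_items:
        raise ValueError(
            f"expected {mapping.source.n_items} source scores, got {len(scores)}"
        )
    out: list[int | None] = []
    for item, value in zip(mapping.source.item_names, scores):
        if item not in mapping.target.item_names:
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            out.append(None)
        else:
            out.append(mapping.map_level(item, int(value)))
    return out


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha with a bootstrap percentile confidence interval."""

    alpha: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_rows_used: int
    n_rows_dropped: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _alpha_from_matrix(matrix: np.ndarray) -> float:
    # K/(K-1) * (1 - sum of item variances / variance of row sums), ddof=1
    n_items = matrix.shape[1]
    total_var = np.var(matrix.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of total scores; alpha undefined")
    item_var = np.var(matrix, axis=0, ddof=1).sum()
    return n_items / (n_items - 1) * (1.0 - item_var / total_var)


def _complete_rows(item_matrix: np.ndarray) -> tuple[np.ndarray, int]:
    matrix = np.asarray(item_matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional (subjects x items)")
    keep = ~np.isnan(matrix).any(axis=1)
    return matrix[keep], int((~keep).sum())


def cronbach_alpha(
    item_matrix: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> ReliabilityResult:
    """Cronbach's alpha of a subjects-by-items matrix with bootstrap CI.

    Rows containing missing items are excluded (their count is reported).
    The confidence interval is the percentile interval over ``n_boot``
    resamples of rows (subjects) with replacement; deterministic given
    ``seed``.
    """
    matrix, n_dropped = _complete_rows(item_matrix)
    if matrix.shape[1] < 2:
        raise ValueError("Cronbach's alpha requires at least 2 items")
    if matrix.shape[0] < 3:
        raise ValueError("Cronbach's alpha requires at least 3 complete rows")
    alpha = _alpha_from_matrix(matrix)

    rng = np.random.default_rng(seed)
    n = matrix.shape[0]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = matrix[idx]
        try:
            boot[b] = _alpha_from_matrix(sample)
        except ValueError:  # degenerate resample (constant totals)
            boot[b] = np.nan
    boot = boot[~np.isnan(boot)]
    if boot.size == 0:
        ci_low = ci_high = alpha
    else:
        tail = (1.0 - ci_level) / 2.0
        ci_low, ci_high = np.quantile(boot, [tail, 1.0 - tail])
    return ReliabilityResult(
        alpha=float(alpha),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        n_rows_used=n,
        n_rows_dropped=n_dropped,
    )


def alpha_if_deleted(item_matrix: np.ndarray) -> np.ndarray:
    """Cronbach's alpha recomputed with each item removed in turn.

    Returns a vector of length K; entry k is the alpha of the K-1 remaining
    items.  A well-behaved scale loses consistency whichever item is dropped;
    a pure-noise item yields the largest entry.
    """
    matrix, _ = _complete_rows(item_matrix)
    n_items = matrix.shape[1]
    if n_items < 3:
        raise ValueError("alpha-if-deleted requires at least 3 items")
    out = np.empty(n_items)
    for k in range(n_items):
        out[k] = _alpha_from_matrix(np.delete(matrix, k, axis=1))
    return out
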