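"""EQ-5D-5L data model and value-set scoring.

The EQ-5D-5L instrument describes health on five dimensions — mobility
(MO), self-care (SC), usual activities (UA), pain/discomfort (PD) and
anxiety/depression (AD) — each at five response levels (1 = no problems
… 5 = extreme problems), plus a visual analogue scale (VAS) from 0
(worst imaginable health) to 100 (best).  A country-specific *value set*
converts each of the 5^5 = 3125 possible health states into a single
utility score anchored at 1 (full health) and 0 (dead); states worse
than death score negative.

Value sets here are additive decrement tables: the utility of a state
is ``1 − Σ_dim decrement(dim, level)``, with every level-1 decrement
equal to zero.  They are data, not code, and are loaded from CSV
(columns ``dimension,level,decrement``); the England value set is
packaged as a fixture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "DIMENSIONS",
    "DIMENSION_LABELS",
    "LEVELS",
    "HealthState",
    "ValueSet",
    "ProblemCategory",
    "apply_value_set",
    "enumerate_states",
    "collapse_level",
]

#: Dimension codes, in instrument order.
DIMENSIONS: tuple[str, ...] = ("MO", "SC", "UA", "PD", "AD")

#: Human-readable dimension names keyed by code.
DIMENSION_LABELS: dict[str, str] = {
    "MO": "mobility",
    "SC": "self-care",
    "UA": "usual activities",
    "PD": "pain/discomfort",
    "AD": "anxiety/depression",
}

#: Valid response levels.
LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)


class ProblemCategory(str, Enum):
    """Collapsed response category used for group comparisons.

    Levels 1–2 are pooled as "no and slight problems", level 3 stands
    alone as "moderate", and levels 4–5 are pooled as "severe and
    extreme problems".
    """

    NO_SLIGHT = "no_slight"
    MODERATE = "moderate"
    SEVERE_EXTREME = "severe_extreme"


def collapse_level(level: int) -> ProblemCategory:
    """Collapse a 1–5 response level into its three-way category."""
    if level in (1, 2):
        return ProblemCategory.NO_SLIGHT
    if level == 3:
        return ProblemCategory.MODERATE
    if level in (4, 5):
        return ProblemCategory.SEVERE_EXTREME
    raise ValueError(f"response level must be in 1..5, got {level!r}")


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-5L response: five dimension levels plus an optional VAS.

    Parameters
    ----------
    mo, sc, ua, pd, ad
        Response level (1–5) for mobility, self-care, usual activities,
        pain/discomfort and anxiety/depression respectively.
    vas
        Self-rated health on the 0–100 visual analogue scale, or
        ``None`` when not recorded.  The VAS never enters utility
        scoring.
    """

    mo: int
    sc: int
    ua: int
    pd: int
    ad: int
    vas: int | None = None

    def __post_init__(self) -> None:
        for code, value in zip(DIMENSIONS, self.levels):
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(
                    f"{DIMENSION_LABELS[code]} level must be an integer, got {value!r}"
                )
            if value not in LEVELS:
                raise ValueError(
                    f"{DIMENSION_LABELS[code]} level must be in 1..5, got {value}"
                )
        if self.vas is not None and not 0 <= self.vas <= 100:
            raise ValueError(f"VAS must lie in [0, 100], got {self.vas}")

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        """Dimension levels in instrument order (MO, SC, UA, PD, AD)."""
        return (self.mo, self.sc, self.ua, self.pd, self.ad)

    def level(self, dimension: str) -> int:
        """Response level for a dimension code (``MO``/``SC``/``UA``/``PD``/``AD``)."""
        try:
            return self.levels[DIMENSIONS.index(dimension.upper())]
        except ValueError:
            raise KeyError(f"unknown dimension {dimension!r}") from None

    def collapsed(self, dimension: str) -> ProblemCategory:
        """Three-way problem category for one dimension."""
        return collapse_level(self.level(dimension))

    def label(self) -> str:
        """Compact state label, e.g. ``'21345'``."""
        return "".join(str(v) for v in self.levels)


class ValueSet:
    """Additive decrement table mapping (dimension, level) to a utility loss.

    ``decrements[(dim, level)]`` is the utility lost relative to full
    health when that dimension sits at that level; level 1 always costs
    nothing.  Decrements must be non-negative and non-decreasing in
    level within each dimension, so the best state 11111 scores exactly
    1 and the worst state 55555 scores the set's *floor*,
    ``1 − Σ_dim decrement(dim, 5)``.
    """

    def __init__(self, name: str, decrements: Mapping[tuple[str, int], float]):
        self.name = name
        self._dec: dict[tuple[str, int], float] = {}
        for dim in DIMENSIONS:
            prev = 0.0
            for lvl in LEVELS:
                key = (dim, lvl)
                if key not in decrements:
                    raise ValueError(
                        f"value set {name!r} is missing an entry for "
                        f"({DIMENSION_LABELS[dim]}, level {lvl})"
                    )
                d = float(decrements[key])
                if lvl == 1 and d != 0.0:
                    raise ValueError(
                        f"value set {name!r}: level-1 decrement for "
                        f"{DIMENSION_LABELS[dim]} must be 0, got {d}"
                    )
                if d < 0:
                    raise ValueError(
                        f"value set {name!r}: negative decrement {d} for ({dim}, {lvl})"
                    )
                if d < prev:
                    raise ValueError(
                        f"value set {name!r}: decrements must be non-decreasing in "
                        f"level ({dim}: level {lvl} = {d} < level {lvl - 1} = {prev})"
                    )
                self._dec[key] = d
                prev = d
        if self.floor < -1:
            raise ValueError(
                f"value set {name!r}: floor {self.floor:.3f} below -1 is not a "
                "valid utility anchor"
            )

    def decrement(self, dimension: str, level: int) -> float:
        """Utility decrement for one (dimension, level) pair."""
        key = (dimension.upper(), level)
        if key not in self._dec:
            raise KeyError(f"no decrement for ({dimension!r}, level {level!r})")
        return self._dec[key]

    @property
    def floor(self) -> float:
        """Minimum achievable utility (score of state 55555)."""
        return 1.0 - sum(self._dec[(dim, 5)] for dim in DIMENSIONS)

    def utility(self, state: HealthState) -> float:
        """Utility of a health state under this value set."""
        return apply_value_set(state, self)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str) -> "ValueSet":
        required = {"dimension", "level", "decrement"}
        if not required.issubset(df.columns):
            missing = required - set(df.columns)
            raise ValueError(f"value-set table is missing columns {sorted(missing)}")
        dec = {
            (str(row.dimension).upper(), int(row.level)): float(row.decrement)
            for row in df.itertuples()
        }
        return cls(name, dec)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "ValueSet":
        """Load a value set from CSV (``dimension,level,decrement``).

        Lines starting with ``#`` are treated as comments.
        """
        path = Path(path)
        df = pd.read_csv(path, comment="#")
        return cls.from_frame(df, name or path.stem)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": dim, "level": lvl, "decrement": self._dec[(dim, lvl)]}
            for dim in DIMENSIONS
            for lvl in LEVELS
        ]
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ValueSet({self.name!r}, floor={self.floor:.3f})"


def apply_value_set(state: HealthState, vs: ValueSet) -> float:
    """Score a health state under a value set.

    Returns ``1 − Σ_dim decrement(dim, level)``; the result lies in
    ``[vs.floor, 1]``.  No rounding is applied — round only at
    presentation.
    """
    total = 0.0
    for dim, lvl in zip(DIMENSIONS, state.levels):
        total += vs.decrement(dim, lvl)
    return 1.0 - total


def enumerate_states(vas: int | None = None) -> list[HealthState]:
    """All 3125 EQ-5D-5L health states (5 levels across 5 dimensions)."""
    return [
        HealthState(*combo, vas=vas)
        for combo in itertools.product(LEVELS, repeat=len(DIMENSIONS))
    ]


def count_by_category(levels: Iterable[int]) -> dict[ProblemCategory, int]:
    """Tally collapsed categories over a vector of response levels."""
    counts = {cat: 0 for cat in ProblemCategory}
    for lvl in levels:
        counts[collapse_level(int(lvl))] += 1
    return counts
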