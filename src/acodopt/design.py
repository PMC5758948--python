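"""Taguchi orthogonal-array designs for the codigestion screening study.

The experiment screens four three-level process factors with an L9(3^4)
orthogonal array instead of the 81-run full factorial:

========  ==============================  ==================
symbol    factor                          levels (1, 2, 3)
========  ==============================  ==================
A         ORWW portion in digester (%)    33, 44, 55
B         process temperature (°C)        36, 46, 56
C         sonication pretreatment (min)   15, 30, 0
D         total-solids level (%)          6, 11, 18
========  ==============================  ==================

Level order is the assignment order of the study, *not* sorted: level 3 of
the sonication factor is the 0-min (untreated) control, so the designation
``C3`` means "no sonication".
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "Formulation",
    "InvalidDesignError",
    "DEFAULT_FACTORS",
    "L9_ROWS",
    "build_l9",
    "designation",
    "parse_designation",
]


class InvalidDesignError(ValueError):
    """Raised when factors or a design table violate the L9 contract."""


#: Canonical L9 row layout (run 1..9), one tuple of level indices per run.
#: This is the row order the downstream factor-effect analysis assumes.
L9_ROWS: tuple[tuple[int, int, int, int], ...] = (
    (1, 1, 1, 1),
    (2, 1, 2, 3),
    (2, 2, 3, 1),
    (1, 2, 2, 2),
    (3, 3, 2, 1),
    (3, 2, 1, 3),
    (1, 3, 3, 3),
    (2, 3, 1, 2),
    (3, 1, 3, 2),
)


@dataclass(frozen=True)
class FactorSpec:
    """One three-level experimental factor.

    Parameters
    ----------
    name
        Single-letter factor symbol ("A".."D").
    description
        Human-readable factor description including units.
    levels
        The three physical settings in assignment order (not sorted).
    unit
        Unit string for the physical values.
    """

    name: str
    description: str
    levels: tuple[float, float, float]
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise InvalidDesignError(
                f"factor {self.name!r} needs exactly 3 levels, got {len(self.levels)}"
            )
        if len(set(self.levels)) != 3:
            raise InvalidDesignError(f"factor {self.name!r} has duplicate levels")

    def physical(self, level: int) -> float:
        if level not in (1, 2, 3):
            raise InvalidDesignError(f"level index {level} out of range 1..3")
        return self.levels[level - 1]


DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("A", "ORWW portion in digester (%)", (33.0, 44.0, 55.0), "%"),
    FactorSpec("B", "temperature (°C)", (36.0, 46.0, 56.0), "°C"),
    FactorSpec("C", "sonication time (min)", (15.0, 30.0, 0.0), "min"),
    FactorSpec("D", "TS level in digester (%)", (6.0, 11.0, 18.0), "%"),
)


@dataclass(frozen=True)
class Formulation:
    """A factor-level combination, e.g. levels ``(2, 1, 2, 1)`` = A2B1C2D1."""

    levels: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.levels) != 4 or any(l not in (1, 2, 3) for l in self.levels):
            raise InvalidDesignError(f"invalid formulation levels {self.levels}")

    @property
    def designation(self) -> str:
        return designation(self.levels)


def designation(levels: Sequence[int], letters: str = "ABCD") -> str:
    """Render level indices as the compact run label, e.g. ``A2B1C2D1``."""
    if len(levels) != len(letters):
        raise InvalidDesignError(f"expected {len(letters)} levels, got {len(levels)}")
    for l in levels:
        if l not in (1, 2, 3):
            raise InvalidDesignError(f"level index {l} out of range 1..3")
    return "".join(f"{c}{l}" for c, l in zip(letters, levels))


def parse_designation(text: str, letters: str = "ABCD") -> tuple[int, ...]:
    """Inverse of :func:`designation`; raises on malformed labels."""
    m = re.fullmatch("".join(f"{c}([123])" for c in letters), text)
    if not m:
        raise InvalidDesignError(f"malformed designation {text!r}")
    return tuple(int(g) for g in m.groups())


@dataclass(frozen=True)
class DesignTable:
    """An L9(3^4) design: 9 runs binding each of 4 factors to a level index."""

    factors: tuple[FactorSpec, ...] = DEFAULT_FACTORS
    rows: tuple[tuple[int, int, int, int], ...] = L9_ROWS

    def __post_init__(self) -> None:
        validate_l9(self.rows, n_factors=len(self.factors))

    @property
    def run_ids(self) -> range:
        return range(1, len(self.rows) + 1)

    def levels(self, run: int) -> tuple[int, ...]:
        if run not in self.run_ids:
            raise KeyError(f"unknown run id {run}; expected 1..{len(self.rows)}")
        return self.rows[run - 1]

    def designation(self, run: int) -> str:
        return designation(self.levels(run), "".join(f.name for f in self.factors))

    def physical_values(self, run: int) -> Mapping[str, float]:
        """Resolve one run's level indices to physical factor settings."""
        lv = self.levels(run)
        return {f.name: f.physical(l) for f, l in zip(self.factors, lv)}

    def runs_at(self, factor: str, level: int) -> list[int]:
        """Run ids holding ``factor`` at ``level`` (always 3 for an L9)."""
        col = self._column(factor)
        return [r for r in self.run_ids if self.rows[r - 1][col] == level]

    def _column(self, factor: str) -> int:
        for i, f in enumerate(self.factors):
            if f.name == factor:
                return i
        raise KeyError(f"unknown factor {factor!r}")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: level indices, designation and physical values."""
        recs = []
        for run in self.run_ids:
            rec: dict[str, object] = {"run_id": run}
            for f, l in zip(self.factors, self.levels(run)):
                rec[f"{f.name}_level"] = l
            rec["designation"] = self.designation(run)
            for f, l in zip(self.factors, self.levels(run)):
                rec[f"{f.name}_value"] = f.physical(l)
            recs.append(rec)
        return pd.DataFrame(recs)


def validate_l9(rows: Sequence[Sequence[int]], n_factors: int = 4) -> None:
    """Check balance and pairwise orthogonality of an L9 layout.

    Balance: each level index 1..3 appears exactly 3 times in every column.
    Orthogonality: for each pair of columns all 9 ordered level pairs occur
    exactly once.  Violations raise :class:`InvalidDesignError`.
    """
    if n_factors != 4:
        raise InvalidDesignError(f"L9(3^4) needs exactly 4 factors, got {n_factors}")
    if len(rows) != 9 or any(len(r) != 4 for r in rows):
        raise InvalidDesignError("L9 requires 9 rows of 4 level indices")
    for c in range(4):
        counts = {l: sum(1 for r in rows if r[c] == l) for l in (1, 2, 3)}
        if any(v != 3 for v in counts.values()):
            raise InvalidDesignError(f"column {c} unbalanced: {counts}")
    for c1, c2 in itertools.combinations(range(4), 2):
        pairs = {(r[c1], r[c2]) for r in rows}
        if len(pairs) != 9:
            raise InvalidDesignError(f"columns {c1},{c2} are not orthogonal")


def build_l9(factors: Sequence[FactorSpec] = DEFAULT_FACTORS) -> DesignTable:
    """Construct the canonical L9(3^4) design for four three-level factors.

    The row order is fixed to the study's run numbering so that factor-effect
    tables computed downstream line up with the published run ids.
    """
    factors = tuple(factors)
    if len(factors) != 4:
        raise InvalidDesignError(f"expected 4 factors, got {len(factors)}")
    return DesignTable(factors=factors, rows=L9_ROWS)
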