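"""Small self-contained study statistics: 2x2 chi-square and tumor volume.

The metastasis-incidence comparison is a Pearson chi-square on a 2x2 table
without continuity correction, computed from the closed form

    X^2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))

with an upper-tail chi-square(1) p-value. Tumor volume uses the standard
caliper ellipsoid approximation 0.52 * length * width^2 (mm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ContingencyTable2x2", "TumorMeasurement", "chi_square_2x2", "tumor_volume"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows are groups, columns outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_rows(cls, rows: list[list[int]]) -> "ContingencyTable2x2":
        (a, b), (c, d) = rows
        return cls(a, b, c, d)


def chi_square_2x2(table: ContingencyTable2x2 | list[list[int]]) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2x2 table.

    Returns (statistic, two-sided p from the chi-square(1) upper tail). A zero
    row or column margin leaves the test undefined and raises.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2.from_rows(table)
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        raise ValueError("zero margin: chi-square test undefined")
    n = table.total
    statistic = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), pvalue


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper length and width in mm; length >= width by convention."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if self.length < 0 or self.width < 0:
            raise ValueError("measurements must be non-negative")
        if self.width > self.length:
            warnings.warn(
                "width exceeds length; swapping to keep length >= width",
                stacklevel=3,
            )
            length, width = self.width, self.length
            object.__setattr__(self, "length", length)
            object.__setattr__(self, "width", width)


def tumor_volume(measurement: TumorMeasurement | tuple[float, float]) -> float:
    """Ellipsoid caliper volume 0.52 * length * width^2 in mm^3."""
    if not isinstance(measurement, TumorMeasurement):
        measurement = TumorMeasurement(*measurement)
    return 0.52 * measurement.length * measurement.width**2
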