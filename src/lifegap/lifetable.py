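"""Standard life tables: annual death probabilities by age, sex and calendar year.

A life table supplies the baseline mortality of the general population.  Matched
reference survival curves are built from it by the monthly recursion in
:mod:`lifegap.reference`, and the synthetic cohort generator uses it as the
baseline hazard on which exposure-linked excess mortality acts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_AGE = 110

SEXES = ("F", "M")


class LifeTableRangeError(KeyError):
    """Lookup outside the (age, sex, year) range the table declares."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``q(age, sex, year)``.

    Internally a dense array indexed ``[sex, year - year0, age]`` covering ages
    ``0..MAX_AGE`` and a contiguous span of calendar years.  ``q`` at
    ``MAX_AGE`` is 1 by construction: no one survives past the table cap.
    """

    year0: int
    q: np.ndarray = field(repr=False)  # shape (2, n_years, MAX_AGE + 1)

    def __post_init__(self) -> None:
        arr = np.asarray(self.q, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != 2 or arr.shape[2] != MAX_AGE + 1:
            raise ValueError("q must have shape (2, n_years, MAX_AGE + 1)")
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("all q must lie in [0, 1]")
        if not np.allclose(arr[:, :, MAX_AGE], 1.0):
            raise ValueError(f"q at age {MAX_AGE} must equal 1")
        object.__setattr__(self, "q", arr)

    @property
    def years(self) -> range:
        return range(self.year0, self.year0 + self.q.shape[1])

    def _sex_index(self, sex: str) -> int:
        try:
            return SEXES.index(sex)
        except ValueError:
            raise LifeTableRangeError(f"unknown sex code {sex!r}") from None

    def annual_q(self, age: int, sex: str, year: int) -> float:
        """Probability of dying before ``age + 1`` for someone aged ``age``."""
        si = self._sex_index(sex)
        yi = int(year) - self.year0
        if not (0 <= yi < self.q.shape[1]):
            raise LifeTableRangeError(f"year {year} outside {self.years}")
        if not (0 <= age <= MAX_AGE):
            raise LifeTableRangeError(f"age {age} outside 0..{MAX_AGE}")
        return float(self.q[si, yi, int(age)])

    def annual_q_path(self, age: int, sex: str, year: int, n_years: int) -> np.ndarray:
        """q along the diagonal (age+k, year+k), k = 0..n_years-1, capped at MAX_AGE.

        Ages past ``MAX_AGE`` return q = 1; years past the table end reuse the
        final year (mortality frozen at the last projected year).
        """
        si = self._sex_index(sex)
        ages = np.minimum(int(age) + np.arange(n_years), MAX_AGE)
        yi = np.minimum(int(year) - self.year0 + np.arange(n_years), self.q.shape[1] - 1)
        if int(year) < self.year0 or int(age) < 0:
            raise LifeTableRangeError(f"({age}, {sex}, {year}) before table start")
        return self.q[si, yi, ages]

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for si, sex in enumerate(SEXES):
            for yi, year in enumerate(self.years):
                recs.append(
                    pd.DataFrame(
                        {
                            "age": np.arange(MAX_AGE + 1),
                            "sex": sex,
                            "year": year,
                            "qx": self.q[si, yi],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        years = np.sort(df["year"].unique())
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise ValueError("life table years must be contiguous")
        arr = np.ones((2, len(years), MAX_AGE + 1))
        piv = df.pivot_table(index=["sex", "year"], columns="age", values="qx")
        for si, sex in enumerate(SEXES):
            for yi, year in enumerate(years):
                row = piv.loc[(sex, year)]
                arr[si, yi, row.index.to_numpy()] = row.to_numpy()
        return cls(year0=int(years[0]), q=arr)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))


def make_life_table(
    level: dict[str, float] | float = 0.01,
    slope: float = 0.085,
    annual_improvement: float = 0.99,
    anchor_age: int = 60,
    year_range: tuple[int, int] = (2000, 2115),
    year0_anchor: int | None = None,
) -> LifeTable:
    """Build a Gompertz life table with calendar-time mortality improvement.

    The annual hazard for sex ``s`` aged ``a`` in calendar year ``y`` is

        h(a, s, y) = h0_s * exp(slope * (a - anchor_age)) * improvement**(y - y0)

    and ``q = 1 - exp(-h)``, clipped to [0, 1], with ``q(MAX_AGE) = 1`` forced.
    ``level`` gives ``q(anchor_age, s, y0)`` per sex (scalar = both sexes).  A
    Gompertz baseline keeps hazards exactly proportional across ages and sexes,
    which makes proportional-hazards excess mortality exactly well-specified
    for the synthetic cohorts.
    """
    if slope < 0:
        raise ValueError("slope must be >= 0")
    if not 0 < annual_improvement <= 1.5:
        raise ValueError("annual_improvement must be positive")
    if isinstance(level, dict):
        levels = {s: float(level[s]) for s in SEXES}
    else:
        levels = {s: float(level) for s in SEXES}
    y_lo, y_hi = year_range
    if y_hi < y_lo:
        raise ValueError("empty year range")
    y0 = year0_anchor if year0_anchor is not None else y_lo
    years = np.arange(y_lo, y_hi + 1)
    ages = np.arange(MAX_AGE + 1)
    arr = np.empty((2, len(years), MAX_AGE + 1))
    for si, sex in enumerate(SEXES):
        qa = levels[sex]
        if not 0 < qa < 1:
            raise ValueError("level must be a probability in (0, 1)")
        h0 = -np.log1p(-qa)  # annual hazard at the anchor age
        haz = (
            h0
            * np.exp(slope * (ages[None, :] - anchor_age))
            * annual_improvement ** (years[:, None] - y0)
        )
        arr[si] = np.clip(-np.expm1(-haz), 0.0, 1.0)
    arr[:, :, MAX_AGE] = 1.0
    return LifeTable(year0=int(y_lo), q=arr)
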