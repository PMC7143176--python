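"""Survival curves on a uniform monthly grid from t = 0."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GridMismatchError(ValueError):
    """Two curves that must share a grid do not."""


@dataclass(frozen=True)
class SurvivalCurve:
    """Survival probabilities ``s`` at month indices ``0..T``.

    Invariants: ``s[0] == 1``, ``s`` nonincreasing, all values in [0, 1].
    """

    s: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.s, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("s must be a 1-d array with at least one point")
        if not np.isclose(arr[0], 1.0):
            raise ValueError("survival must start at 1")
        if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(arr) > 1e-9):
            raise ValueError("survival must be nonincreasing")
        object.__setattr__(self, "s", np.clip(arr, 0.0, 1.0))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.s.size)

    @property
    def horizon(self) -> int:
        """Last month index of the grid."""
        return self.s.size - 1

    def __len__(self) -> int:
        return self.s.size

    def at(self, t: float) -> float:
        """Survival at (possibly fractional) month ``t``, linearly interpolated."""
        if t < 0 or t > self.horizon:
            raise GridMismatchError(f"t={t} outside [0, {self.horizon}]")
        return float(np.interp(t, self.t, self.s))

    def truncated(self, horizon: int) -> "SurvivalCurve":
        if horizon > self.horizon:
            raise GridMismatchError("cannot truncate beyond the curve's horizon")
        return SurvivalCurve(self.s[: horizon + 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_month": self.t, "survival": self.s})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCurve":
        df = pd.read_csv(path)
        return cls(df["survival"].to_numpy())


def restricted_mean(curve: SurvivalCurve, horizon: int | None = None) -> float:
    """Area under the survival curve up to ``horizon``, in months (trapezoid)."""
    s = curve.s if horizon is None else curve.truncated(horizon).s
    return float(np.trapezoid(s, dx=1.0))


def align_horizon(a: SurvivalCurve, b: SurvivalCurve) -> int:
    """Common horizon of two monthly-grid curves."""
    return min(a.horizon, b.horizon)
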