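"""Matched reference survival curves.

Two reference populations are built for a cohort:

* the *general* reference — a hypothetical population matched on sex, age at
  start and start calendar year whose mortality follows the standard life
  table, with survival obtained by the monthly recursion
  ``SG(t) = SG(t-1) * (1 - q)^(1/12)``;
* the *healthy* reference — a reference guaranteed to dominate the cohort's
  observed survival everywhere.  When the general reference already dominates,
  it is used as-is.  Otherwise each participant with observed follow-up
  ``tobs`` is matched to a referent whose survival time is drawn by the
  two-stage uniform scheme r ~ U(0, SG(tobs)), v ~ U(0, r),
  tref = SG^{-1}(v), which guarantees tref >= tobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import GridMismatchError, SurvivalCurve
from .lifetable import MAX_AGE, LifeTable


@dataclass(frozen=True)
class HealthyDraw:
    """Audit record for one healthy-referent draw."""

    participant_id: int
    tobs: float
    p: float
    r: float
    v: float
    tref: float


def monthly_survival_factors(
    table: LifeTable,
    sex: str,
    age: int,
    start_year: int,
    n_months: int,
    log_excess: float = 0.0,
) -> np.ndarray:
    """Conditional one-month survival probabilities for months 1..n_months.

    Annual q is converted to a monthly factor ``(1-q)^(1/12)`` (constant hazard
    within the year).  ``log_excess`` multiplies the hazard by
    ``exp(log_excess)``, i.e. the factor becomes ``(1-q)^(exp(log_excess)/12)``.
    """
    n_years = -(-n_months // 12)
    q = table.annual_q_path(age, sex, start_year, n_years)
    monthly = np.where(q >= 1.0, 0.0, (1.0 - q) ** (np.exp(log_excess) / 12.0))
    return np.repeat(monthly, 12)[:n_months]


def sg_individual(
    table: LifeTable,
    sex: str,
    age: int,
    start_year: int,
    n_months: int,
    log_excess: float = 0.0,
) -> SurvivalCurve:
    """Matched life-table survival curve SG(t | s, a, y) on months 0..n_months."""
    factors = monthly_survival_factors(table, sex, age, start_year, n_months, log_excess)
    s = np.empty(n_months + 1)
    s[0] = 1.0
    np.cumprod(factors, out=s[1:])
    return SurvivalCurve(s)


def cohort_profiles(cohort) -> pd.DataFrame:
    """Distinct (sex, age_at_start, start_year) profiles with counts."""
    df = cohort.to_frame() if hasattr(cohort, "to_frame") else pd.DataFrame(cohort)
    return (
        df.groupby(["sex", "age_start", "start_year"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )


def default_horizon(cohort) -> int:
    """Grid end: month at which the youngest profile reaches the table cap."""
    df = cohort.to_frame()
    return int((MAX_AGE - df["age_start"].min()) * 12 + 12)


def cohort_reference_curve(
    cohort,
    table: LifeTable,
    n_months: int | None = None,
    log_excess: float = 0.0,
) -> SurvivalCurve:
    """General-reference survival Sg(t): the participant-mix average of SG curves.

    Computed as the exact expectation over the cohort's (sex, age, start-year)
    profiles rather than by simulating referent deaths; the expectation of the
    generated referent population is the same curve, without Monte-Carlo noise.
    """
    if n_months is None:
        n_months = default_horizon(cohort)
    prof = cohort_profiles(cohort)
    total = prof["n"].sum()
    acc = np.zeros(n_months + 1)
    for row in prof.itertuples(index=False):
        curve = sg_individual(table, row.sex, int(row.age_start), int(row.start_year), n_months, log_excess)
        acc += row.n * curve.s
    return SurvivalCurve(acc / total)


def is_healthier(
    sg: SurvivalCurve, s_obs: SurvivalCurve, horizon: int | None = None
) -> bool:
    """True iff Sg(t) >= S(t) at every grid point in (0, horizon].

    Ties count as healthier: relative survival W = S/Sg then equals 1 and is
    clamped just below 1 before the logit downstream.
    """
    if horizon is None:
        horizon = s_obs.horizon
    if sg.horizon < horizon or s_obs.horizon < horizon:
        raise GridMismatchError("curves do not cover the comparison horizon")
    return bool(np.all(sg.s[1 : horizon + 1] >= s_obs.s[1 : horizon + 1] - 1e-12))


def _invert_sg(s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Monotone linear-interpolation inverse of a nonincreasing curve.

    For values below the curve's final point the last grid time is returned
    (the curve reaches 0 at the life-table cap, so this affects only v == 0
    edge cases).  Ties broken toward the later time.
    """
    t = np.arange(s.size)
    # np.interp needs increasing x; reverse both axes.  With ties (flat
    # stretches of s) the reversed order makes interp pick the later time.
    return np.interp(v, s[::-1], t[::-1].astype(float))


def draw_healthy_reference(
    cohort,
    table: LifeTable,
    n_months: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SurvivalCurve, list[HealthyDraw]]:
    """Healthy-reference survival Sh(t) from the two-stage uniform draws.

    One referent per participant.  Each referent's survival time satisfies
    ``tref >= tobs`` by construction, so the empirical curve of the tref values
    (all treated as deaths) dominates the cohort's observed survival.  Beyond
    the last drawn time, Sh continues along the general-reference shape
    rescaled for continuity.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_months is None:
        n_months = default_horizon(cohort)
    df = cohort.to_frame()
    tref = np.empty(len(df))
    p_all = np.empty(len(df))
    r_all = np.empty(len(df))
    v_all = np.empty(len(df))
    for key, idx in df.groupby(["sex", "age_start", "start_year"]).groups.items():
        sex, age, year = key
        sg = sg_individual(table, sex, int(age), int(year), n_months)
        tobs = df.loc[idx, "follow_months"].to_numpy(dtype=float)
        if np.any(tobs > sg.horizon):
            raise GridMismatchError("observed time beyond reference curve support")
        p = np.interp(tobs, sg.t, sg.s)
        r = rng.uniform(0.0, p)
        v = rng.uniform(0.0, r)
        tref[idx] = _invert_sg(sg.s, v)
        p_all[idx], r_all[idx], v_all[idx] = p, r, v
    grid = np.arange(n_months + 1)
    sh = (tref[None, :] > grid[:, None]).mean(axis=1)
    sh[0] = 1.0
    # continue beyond the draw support along the Sg shape, rescaled
    alive = np.nonzero(sh > 0)[0]
    t_last = alive[-1]
    if t_last < n_months:
        sgc = cohort_reference_curve(cohort, table, n_months)
        if sgc.s[t_last] > 0:
            tail = sh[t_last] * sgc.s[t_last + 1 :] / sgc.s[t_last]
            sh[t_last + 1 :] = np.minimum(tail, sh[t_last])
    sh = np.minimum.accumulate(sh)
    draws = [
        HealthyDraw(int(pid), float(to), float(p), float(r), float(v), float(tr))
        for pid, to, p, r, v, tr in zip(
            df["id"], df["follow_months"], p_all, r_all, v_all, tref
        )
    ]
    return SurvivalCurve(sh), draws


def draws_to_frame(draws: list[HealthyDraw]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [d.participant_id for d in draws],
            "tobs": [d.tobs for d in draws],
            "p": [d.p for d in draws],
            "r": [d.r for d in draws],
            "v": [d.v for d in draws],
            "tref": [d.tref for d in draws],
        }
    )
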