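"""Synthetic multi-area cohort generator with known ground truth.

Emulates the study design the pipeline targets: 63 small areas, cohorts of
60-79-year-olds followed for 16 years under administrative censoring, monthly
PM2.5/PM10 series with a downward trend and strong inter-pollutant
correlation, and spatially clustered area covariates.  Mortality follows the
standard life table, multiplied by an exposure-linked proportional excess
hazard, so every downstream estimate has a computable truth.

Generative model
----------------
A participant of sex s aged a at the start has monthly conditional survival

    (1 - q(a+k, s, y+k)) ** (exp(eta_i) / 12)

where ``eta_i = excess_coeff * (A_i - hazard_center) + sum_j gamma_j (X_ji - X̄_j)``
is the area's log excess hazard: A_i is the area's true lifetime-weighted
PM2.5 and the X_ji are area covariates that act as genuine confounders when
their hazard coefficients are nonzero.  Because the life table is Gompertz,
the model is an exactly specified proportional-hazards model in age, sex and
exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .curves import SurvivalCurve
from .exposure import ExposureSeries
from .lifetable import MAX_AGE, LifeTable, make_life_table
from .reference import monthly_survival_factors

REGIONS = ("north", "central", "south", "east")

# 2006-level mean PM2.5 by region (µg/m³) and planar region centres (km)
_REGION_PM_BASE = {"north": 28.0, "central": 36.0, "south": 43.0, "east": 17.0}
_REGION_CENTRES = {
    "north": (120.0, 300.0),
    "central": (80.0, 180.0),
    "south": (60.0, 40.0),
    "east": (180.0, 120.0),
}
_REGION_WEIGHTS = {"north": 0.33, "central": 0.27, "south": 0.30, "east": 0.10}


class ScenarioConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Area:
    """One small study area: location, exposure level and covariates."""

    area_id: str
    region: str
    x_km: float
    y_km: float
    pm25_2006: float  # area mean PM2.5 in 2006, µg/m³
    covariates: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Cohort:
    """Participant records for one area."""

    area_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        required = {"id", "sex", "age_start", "start_year", "follow_months", "event"}
        if df.empty:
            raise ValueError("cohort must be nonempty")
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort frame missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Nonparametric bootstrap resample (ids renumbered to stay unique)."""
        idx = rng.integers(0, len(self.frame), size=len(self.frame))
        df = self.frame.iloc[idx].reset_index(drop=True)
        df = df.assign(id=np.arange(len(df)))
        return Cohort(self.area_id, df)

    def to_csv(self, path) -> None:
        self.frame.assign(area_id=self.area_id).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path)
        area = str(df["area_id"].iloc[0]) if "area_id" in df else ""
        return cls(area, df.drop(columns=["area_id"], errors="ignore"))


@dataclass(frozen=True)
class SimScenario:
    """Configuration of one synthetic study.

    Defaults mirror the emulated design: 63 areas, start year 2001, 16-year
    administrative follow-up, ages 60-79 with mean near 68, 54% women, PM2.5
    declining from a 2006 cross-area spread of roughly 15-50 µg/m³ toward the
    10 µg/m³ guideline, and a log excess hazard of 0.0242 per µg/m³ of
    lifetime average PM2.5.  ``n_per_area`` is deliberately modest; studies at
    claims-registry scale simply pass a larger value.
    """

    n_areas: int = 63
    n_per_area: int = 2000
    start_year: int = 2001
    admin_horizon_years: float = 16.0
    annual_loss_rate: float = 0.005  # loss to follow-up, per year
    age_range: tuple[int, int] = (60, 79)
    age_decay: float = 0.95  # P(age) ∝ age_decay**(age - 60); mean ≈ 68
    female_prop: float = 0.54
    excess_coeff: float = 0.0242  # log hazard per µg/m³ lifetime PM2.5
    hazard_center: float = 25.0  # µg/m³ at which the excess multiplier is 1
    covariate_hazard: dict = field(
        default_factory=lambda: {"hospitalization_pct": 0.030, "college_pct": -0.020}
    )
    pm_decline_frac: float = 0.38  # fractional decline 2006 -> 2018
    pm_seasonal_frac: float = 0.15
    pm_noise_frac: float = 0.08
    pm10_alpha: float = 8.0
    pm10_beta: float = 1.7
    pm_floor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_areas < 2:
            raise ScenarioConfigError("n_areas must be >= 2")
        if self.admin_horizon_years <= 0:
            raise ScenarioConfigError("admin horizon must be positive")
        if not np.isfinite(self.excess_coeff):
            raise ScenarioConfigError("excess_coeff must be finite")

    @property
    def admin_horizon_months(self) -> int:
        return int(round(self.admin_horizon_years * 12))

    @property
    def cap_months(self) -> int:
        return (MAX_AGE - self.age_range[0]) * 12 + 12

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 is stable across processes (unlike hash()), keeping cohorts
        # bit-for-bit reproducible for a given (seed, stream) pair
        import zlib

        tag = zlib.crc32(stream.encode())
        return np.random.default_rng(
            np.random.SeedSequence([self.seed % (2**31), tag % (2**31)])
        )

    # -- population structure -------------------------------------------

    def age_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        ages = np.arange(self.age_range[0], self.age_range[1] + 1)
        w = self.age_decay ** (ages - ages[0])
        return ages, w / w.sum()

    def profile_mix(self) -> pd.DataFrame:
        """Expected (sex, age) mix with weights; start year fixed."""
        ages, w = self.age_distribution()
        rows = []
        for sex, ps in (("F", self.female_prop), ("M", 1 - self.female_prop)):
            for a, wa in zip(ages, w):
                rows.append({"sex": sex, "age_start": int(a), "weight": ps * wa})
        return pd.DataFrame(rows)


def default_life_table(scenario: SimScenario | None = None) -> LifeTable:
    """Gompertz life table spanning the scenario's full extrapolation range."""
    start = scenario.start_year if scenario else 2001
    cap_years = MAX_AGE - (scenario.age_range[0] if scenario else 60) + 2
    return make_life_table(
        level={"F": 0.008, "M": 0.013},
        slope=0.085,
        annual_improvement=0.99,
        anchor_age=60,
        year_range=(start - 1, start + cap_years),
        year0_anchor=start,
    )


def make_areas(scenario: SimScenario) -> list[Area]:
    """Areas with region-clustered coordinates, exposure levels and covariates.

    Covariates mirror the kinds of area descriptors such studies adjust for
    (hospitalization %, college %, living-with-partner %, share of over-60s,
    hospital counts).  Several correlate with region — and hence with
    exposure — so they act as spatial confounders.
    """
    rng = scenario.rng("areas")
    regions = list(_REGION_WEIGHTS)
    probs = np.array([_REGION_WEIGHTS[r] for r in regions])
    n = scenario.n_areas
    labels = regions * (n // len(regions))  # guarantee every region appears
    labels += list(rng.choice(regions, size=n - len(labels), p=probs))
    rng.shuffle(labels)
    areas = []
    for i, region in enumerate(labels[:n]):
        cx, cy = _REGION_CENTRES[region]
        x = cx + rng.normal(0, 25)
        y = cy + rng.normal(0, 25)
        pm = max(12.0, _REGION_PM_BASE[region] + rng.normal(0, 5.0))
        north_ses = 1.0 if region == "north" else 0.0
        cov = {
            "hospitalization_pct": float(np.clip(14.5 + rng.normal(0, 1.8), 10, 22)),
            "college_pct": float(np.clip(2.0 + 4.0 * north_ses + rng.gamma(2.0, 1.0), 0.3, 25)),
            "partner_pct": float(np.clip(72.5 + rng.normal(0, 2.5), 64, 78)),
            "age60plus_pct": float(np.clip(11.5 + rng.normal(0, 3.0), 5, 19)),
            "n_hospitals_20km": float(np.clip(rng.poisson(25 * (1 + north_ses)), 0, 70)),
        }
        areas.append(Area(f"A{i:02d}", region, float(x), float(y), float(pm), cov))
    return areas


def area_distance_matrix(areas: list[Area]) -> np.ndarray:
    xy = np.array([[a.x_km, a.y_km] for a in areas])
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


# -- exposure series -----------------------------------------------------


def simulate_exposure_series(
    scenario: SimScenario,
    area: Area,
    first_month="2000-01",
    last_month=None,
) -> dict[str, ExposureSeries]:
    """True PM2.5 over the whole lifetime window plus the exported slices.

    Returns ``{"true": ..., "pm25_obs": ..., "pm10": ...}`` where the observed
    PM2.5 slice covers 2006-2018, PM10 covers 2001-2018, and ``true`` runs from
    ``first_month`` to ``last_month`` (default: the extrapolation cap).

    The underlying level declines linearly from the area's 2006 mean and is
    floored; a winter-peaking seasonal cycle, AR(1) noise and the PM10 linear
    link (monthly correlation ≈ 0.9 by construction) are added on top.
    """
    rng = scenario.rng(f"exposure:{area.area_id}")
    first = pd.Period(first_month, freq="M")
    if last_month is None:
        last = pd.Period(f"{scenario.start_year}-01", freq="M") + scenario.cap_months
    else:
        last = pd.Period(last_month, freq="M")
    n = (last - first).n + 1
    if n < 1:
        raise ScenarioConfigError("empty month range")
    t = np.arange(n)
    anchor = (pd.Period("2006-01", freq="M") - first).n  # trend anchored at 2006
    slope = scenario.pm_decline_frac * area.pm25_2006 / 144.0  # per month
    level = np.maximum(scenario.pm_floor, area.pm25_2006 - slope * (t - anchor))
    month_of_year = ((first.month - 1 + t) % 12) + 1
    seasonal = scenario.pm_seasonal_frac * area.pm25_2006 * np.cos(
        2 * np.pi * (month_of_year - 1) / 12
    )
    eps = np.empty(n)
    sd = scenario.pm_noise_frac * area.pm25_2006
    phi = 0.5
    eps[0] = rng.normal(0, sd)
    innov = rng.normal(0, sd * np.sqrt(1 - phi**2), size=n)
    for k in range(1, n):
        eps[k] = phi * eps[k - 1] + innov[k]
    pm25 = np.maximum(1.0, level + seasonal + eps)
    if np.any(level + seasonal <= 0):
        raise ScenarioConfigError("exposure parameters yield nonpositive means")
    # PM10 linked linearly; noise scaled so the monthly correlation over the
    # monitored window (not the flat far future) is near 0.9
    win = slice(max(anchor, 0), min(anchor + 156, n))
    sigma25 = pm25[win].std() if pm25[win].size > 1 else pm25.std()
    sd10 = 0.484 * scenario.pm10_beta * sigma25
    pm10 = np.maximum(
        1.0, scenario.pm10_alpha + scenario.pm10_beta * pm25 + rng.normal(0, sd10, size=n)
    )
    true = ExposureSeries(area.area_id, first, pm25, np.full(n, "observed"))
    # monitored slices, clipped to the generated range: PM2.5 from 2006,
    # PM10 from 2000 (the PM10 network predates PM2.5 monitoring)
    obs_start = max(first, pd.Period("2006-01", freq="M"))
    obs_end = min(last, pd.Period("2018-12", freq="M"))
    out = {"true": true}
    if obs_end >= obs_start:
        i, j = true.index_of(obs_start), true.index_of(obs_end)
        out["pm25_obs"] = ExposureSeries(area.area_id, obs_start, pm25[i : j + 1])
        p10_start = max(first, pd.Period("2000-01", freq="M"))
        p10_i = true.index_of(p10_start)
        out["pm10"] = ExposureSeries(area.area_id, p10_start, pm10[p10_i : j + 1])
    return out


def true_lifetime_exposure(
    scenario: SimScenario, table: LifeTable, series: ExposureSeries
) -> float:
    """Ground-truth lifetime-weighted average PM2.5 for an area.

    Weights are the expected matched-reference survival of the scenario's
    (sex, age) mix — the generative analogue of E = Σ S(t)C(t)/LE.
    """
    from .exposure import lifetime_weighted_exposure

    s = _mix_survival(scenario, table, 0.0)
    origin = pd.Period(f"{scenario.start_year}-01", freq="M")
    return lifetime_weighted_exposure(s, series, origin).E


# -- cohorts -------------------------------------------------------------


def area_log_excess(scenario: SimScenario, area: Area, lifetime_pm25: float) -> float:
    """Log excess hazard eta_i for an area (exposure + covariate terms)."""
    eta = scenario.excess_coeff * (lifetime_pm25 - scenario.hazard_center)
    centers = {
        "hospitalization_pct": 14.5,
        "college_pct": 3.5,
        "partner_pct": 72.5,
        "age60plus_pct": 11.5,
        "n_hospitals_20km": 29.0,
    }
    for name, gamma in scenario.covariate_hazard.items():
        eta += gamma * (area.covariates[name] - centers.get(name, 0.0))
    return float(eta)


def simulate_cohort(
    scenario: SimScenario,
    table: LifeTable,
    area_id: str,
    log_excess: float,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Draw one cohort from the discrete-time hazard model.

    Death months come from the life-table monthly hazard multiplied by
    ``exp(log_excess)``; censoring is administrative at the horizon plus an
    independent exponential loss process.
    """
    if n is None:
        n = scenario.n_per_area
    if n < 1:
        raise ScenarioConfigError("cohort size must be >= 1")
    if rng is None:
        rng = scenario.rng(f"cohort:{area_id}")
    ages, w = scenario.age_distribution()
    age = rng.choice(ages, size=n, p=w)
    sex = np.where(rng.random(n) < scenario.female_prop, "F", "M")
    death = np.empty(n, dtype=int)
    u = 1.0 - rng.random(n)  # in (0, 1]; guarantees death by the table cap
    for a in np.unique(age):
        for sx in ("F", "M"):
            mask = (age == a) & (sex == sx)
            if not mask.any():
                continue
            n_months = (MAX_AGE - int(a)) * 12 + 12
            f = monthly_survival_factors(
                table, sx, int(a), scenario.start_year, n_months, log_excess
            )
            surv = np.cumprod(f)  # S(1..T); S(T) = 0 at the table cap
            # death month m: S(m-1) >= u > S(m); surv is nonincreasing
            death[mask] = np.searchsorted(-surv, -u[mask], side="right") + 1
    horizon = scenario.admin_horizon_months
    if scenario.annual_loss_rate > 0:
        loss = np.ceil(
            rng.exponential(12.0 / scenario.annual_loss_rate, size=n)
        ).astype(int)
    else:
        loss = np.full(n, np.iinfo(np.int32).max)
    censor = np.minimum(loss, horizon)
    event = (death <= censor).astype(int)
    follow = np.minimum(death, censor)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_start": age.astype(int),
            "start_year": scenario.start_year,
            "follow_months": follow,
            "event": event,
        }
    )
    return Cohort(area_id, df)


# -- ground truth --------------------------------------------------------


def true_life_expectancy(
    table: LifeTable,
    sex: str,
    age: int,
    start_year: int,
    log_excess: float = 0.0,
    n_months: int | None = None,
) -> float:
    """Exact LE (months) under the generative hazard, by the survival recursion.

    Trapezoidal sum of the monthly survival curve, matching the integration
    rule used by the estimation pipeline.
    """
    if n_months is None:
        n_months = (MAX_AGE - age) * 12 + 12
    f = monthly_survival_factors(table, sex, age, start_year, n_months, log_excess)
    s = np.concatenate([[1.0], np.cumprod(f)])
    return float(np.trapezoid(s, dx=1.0))


def _mix_survival(
    scenario: SimScenario, table: LifeTable, log_excess: float
) -> SurvivalCurve:
    mix = scenario.profile_mix()
    acc = np.zeros(scenario.cap_months + 1)
    for row in mix.itertuples(index=False):
        n_m = scenario.cap_months
        f = monthly_survival_factors(
            table, row.sex, int(row.age_start), scenario.start_year, n_m, log_excess
        )
        acc += row.weight * np.concatenate([[1.0], np.cumprod(f)])
    return SurvivalCurve(acc)


def true_mix_life_expectancy(
    scenario: SimScenario, table: LifeTable, log_excess: float = 0.0
) -> float:
    """Expected LE (months) of the scenario's (sex, age) mix."""
    return float(np.trapezoid(_mix_survival(scenario, table, log_excess).s, dx=1.0))


def true_sled_slope(
    scenario: SimScenario, table: LifeTable, excess_coeff: float | None = None
) -> float:
    """d(SLED)/d(lifetime PM2.5) in years per µg/m³ at the hazard centre.

    Central finite difference of the mix LE with respect to the exposure
    level entering the log excess hazard.
    """
    b = scenario.excess_coeff if excess_coeff is None else excess_coeff
    h = 2.0  # µg/m³
    hi = true_mix_life_expectancy(scenario, table, b * h)
    lo = true_mix_life_expectancy(scenario, table, -b * h)
    return float((hi - lo) / (2 * h) / 12.0)


def calibrate_excess_coeff(
    scenario: SimScenario, table: LifeTable, target_slope: float
) -> float:
    """Excess-hazard coefficient giving a chosen true SLED-vs-exposure slope.

    Solves ``true_sled_slope(b) = target_slope`` (years per µg/m³, negative
    for harmful exposure) by bracketing on b.
    """
    if target_slope >= 0:
        raise ValueError("target_slope must be negative (exposure shortens life)")

    def g(b: float) -> float:
        return true_sled_slope(scenario, table, b) - target_slope

    return float(brentq(g, 1e-5, 0.5, xtol=1e-7))


def scenario_truth(scenario: SimScenario, table: LifeTable) -> dict:
    """Reference quantities of the generative model, for tests and reports."""
    return {
        "mix_le_years": true_mix_life_expectancy(scenario, table) / 12.0,
        "sled_slope_years_per_ug": true_sled_slope(scenario, table),
        "log_hr_per_ug": scenario.excess_coeff,
    }


def with_slope(scenario: SimScenario, table: LifeTable, target_slope: float) -> SimScenario:
    """Scenario variant whose excess coefficient yields ``target_slope``."""
    b = calibrate_excess_coeff(scenario, table, target_slope)
    return replace(scenario, excess_coeff=b)
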