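"""Individual-level proportional-hazards analysis of mortality on lifetime
average PM2.5, with individual and area-level covariate adjustment.

Time origin is the start of follow-up; age at start enters as a covariate.
Ties are handled by Efron's method (the monthly grid creates heavy ties;
Breslow would bias toward the null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import ExposureSeries, individual_lifetime_average


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class HazardFit:
    """Cox model fit: hazard ratio per 1 µg/m³ of lifetime average PM2.5."""

    hr: float
    ci_low: float
    ci_high: float
    coef_table: pd.DataFrame = field(repr=False)
    n: int = 0
    events: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the hazard ratio")


def build_individual_design(
    cohorts: list,
    exposures: dict[str, ExposureSeries],
    area_covariates: pd.DataFrame | None = None,
    start_month: str = "2001-01",
    area_exposure: dict[str, float] | None = None,
) -> pd.DataFrame:
    """One row per participant across all cohorts.

    Columns: area_id, follow_months, event, exposure, age_start, sex
    indicator, plus any comorbidity flags already present in the cohort
    frames and any merged area-level covariates.

    The default exposure is the individual lifetime average: the mean monthly
    concentration from 12 months before the start date through the month
    follow-up ended.  Note that this window ends at the survival time itself,
    so under a declining pollution trend the covariate is endogenous —
    longer-lived participants mechanically average over cleaner years.
    Passing ``area_exposure`` (area id -> µg/m³) instead assigns every
    participant their area's fixed lifetime-average level, the appropriate
    covariate for parameter-recovery experiments.
    """
    rows = []
    for cohort in cohorts:
        if cohort.area_id not in exposures:
            raise DesignError(f"no exposure series for area {cohort.area_id}")
        series = exposures[cohort.area_id]
        df = cohort.to_frame().copy()
        if df["id"].duplicated().any():
            raise DesignError(f"duplicate participant ids within area {cohort.area_id}")
        start = pd.Period(start_month, freq="M")
        if area_exposure is not None:
            df["exposure"] = float(area_exposure[cohort.area_id])
        else:
            need_end = start + int(df["follow_months"].max())
            if start - 12 < series.start or need_end > series.end:
                raise DesignError(
                    f"exposure series for {cohort.area_id} does not cover "
                    f"{start - 12}..{need_end}"
                )
            # windowed means, vectorised with a cumulative sum over the series
            csum = np.concatenate([[0.0], np.cumsum(series.values)])
            i0 = series.index_of(start - 12)
            fm = df["follow_months"].to_numpy(dtype=int)
            j = i0 + 12 + fm  # inclusive end index
            mean_expo = (csum[j + 1] - csum[i0]) / (j + 1 - i0)
            df["exposure"] = mean_expo
        df["area_id"] = cohort.area_id
        rows.append(df)
    design = pd.concat(rows, ignore_index=True)
    design["female"] = (design["sex"] == "F").astype(int)
    if area_covariates is not None:
        design = design.merge(area_covariates, on="area_id", how="left")
        extra = [c for c in area_covariates.columns if c != "area_id"]
        if design[extra].isna().any().any():
            raise DesignError("area covariates missing for some areas")
    return design


def fit_proportional_hazards(
    design: pd.DataFrame,
    exposure_col: str = "exposure",
    covariate_cols: list[str] | None = None,
    cluster_by_area: bool = False,
) -> HazardFit:
    """Efron-tie Cox partial-likelihood fit on the monthly time scale.

    ``covariate_cols`` defaults to age, sex and every numeric column that is
    not an identifier or outcome.  ``cluster_by_area`` switches to
    cluster-robust (sandwich) standard errors by area.
    """
    from lifelines import CoxPHFitter

    if design["event"].sum() < 1:
        raise DesignError("no events in the design table")
    if covariate_cols is None:
        skip = {"id", "area_id", "sex", "follow_months", "event", "start_year", exposure_col}
        covariate_cols = [
            c
            for c in design.columns
            if c not in skip and pd.api.types.is_numeric_dtype(design[c])
        ]
    cols = [exposure_col] + covariate_cols
    for c in cols:
        if np.ptp(design[c].to_numpy(dtype=float)) < 1e-12:
            raise DesignError(f"constant column {c!r} in the design")
    # drop covariates that are collinear with what is already in the model
    # (common when several area-level descriptors are shared by few areas)
    kept = [exposure_col]
    for c in covariate_cols:
        M = np.column_stack(
            [np.ones(len(design))] + [design[k].to_numpy(dtype=float) for k in kept + [c]]
        )
        if np.linalg.matrix_rank(M) == M.shape[1]:
            kept.append(c)
        else:
            import warnings

            warnings.warn(f"dropping collinear covariate {c!r} from the Cox design")
    cols = kept
    keep = cols + ["follow_months", "event"] + (["area_id"] if cluster_by_area else [])
    df = design[keep].copy()
    # a zero-duration row carries no partial-likelihood information; nudge it
    df["follow_months"] = df["follow_months"].astype(float)
    df.loc[df["follow_months"] <= 0, "follow_months"] = 0.5
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="follow_months",
        event_col="event",
        cluster_col="area_id" if cluster_by_area else None,
    )
    summ = cph.summary
    hr = float(np.exp(summ.loc[exposure_col, "coef"]))
    lo = float(np.exp(summ.loc[exposure_col, "coef lower 95%"]))
    hi = float(np.exp(summ.loc[exposure_col, "coef upper 95%"]))
    return HazardFit(
        hr=hr,
        ci_low=lo,
        ci_high=hi,
        coef_table=summ,
        n=len(df),
        events=int(design["event"].sum()),
    )
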