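"""Lifetime survival extrapolation via logit relative survival.

The estimator follows four steps:

1. estimate the cohort's survival S(t) over the observed follow-up by the
   product-limit (Kaplan-Meier) method on the monthly grid;
2. form the relative survival W(t) = S(t) / Sh(t) against a healthy reference
   Sh that dominates S everywhere, so W lies in (0, 1]; under an excess
   constant hazard, logit W(t) is approximately linear after an initial
   period;
3. extrapolate logit W one month at a time with a restricted cubic spline
   fitted over a sliding fixed-length window, treating each one-step-ahead
   prediction as observed (the "rolling" step);
4. back-transform and compose S(t) = expit(logit W(t)) * Sh(t) out to the
   life-table cap, then integrate for life expectancy.

SLED (standardized life expectancy deviation) is the cohort's LE minus the LE
of its matched general reference population; standard errors come from a
nonparametric bootstrap over participants that reruns the whole chain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .curves import GridMismatchError, SurvivalCurve, restricted_mean
from .lifetable import LifeTable
from .reference import (
    cohort_reference_curve,
    default_horizon,
    draw_healthy_reference,
    is_healthier,
)

logger = logging.getLogger(__name__)


class DegenerateCohortError(ValueError):
    pass


@dataclass(frozen=True)
class ExtrapolationConfig:
    """Tuning knobs of the extrapolation chain.

    epsilon      clamp applied to W before the logit (keeps it finite)
    knot_counts  restricted-cubic-spline knot candidates, chosen per window
                 by AIC of the least-squares fit
    window       sliding-window length in months; None = the full initial
                 observed period, held fixed while sliding
    cap_months   extrapolation end; None = the life-table cap for the cohort
    bootstrap_b  bootstrap replicates for the standard errors
    """

    epsilon: float = 1e-4
    knot_counts: tuple[int, ...] = (3, 5, 8, 12, 15)
    window: int | None = None
    cap_months: int | None = None
    bootstrap_b: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 0.01:
            raise ValueError("epsilon must lie in (0, 0.01]")
        if self.window is not None and self.window < 24:
            raise ValueError("window must be at least 24 months")
        if self.bootstrap_b < 1:
            raise ValueError("bootstrap_b must be >= 1")


@dataclass(frozen=True)
class RelativeSurvival:
    """W(t) = S(t)/Sh(t) with its clamped logit."""

    t: np.ndarray = field(repr=False)
    w: np.ndarray = field(repr=False)
    logit_w: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class LifetimeEstimate:
    le_years: float
    le_se: float
    sled_years: float
    sled_se: float
    curve: SurvivalCurve = field(repr=False)
    n_bootstrap_ok: int = 0
    used_healthy_draw: bool = False


# -- step 1: product-limit estimate --------------------------------------


def km_estimate(cohort, horizon: int | None = None) -> SurvivalCurve:
    """Kaplan-Meier survival of the cohort on the monthly grid 0..max follow-up."""
    from lifelines import KaplanMeierFitter

    df = cohort.to_frame()
    t_max = int(np.ceil(df["follow_months"].max())) if horizon is None else horizon
    if t_max < 1:
        raise DegenerateCohortError("no follow-up time observed")
    kmf = KaplanMeierFitter()
    kmf.fit(df["follow_months"], event_observed=df["event"], timeline=np.arange(t_max + 1))
    s = kmf.survival_function_.iloc[:, 0].to_numpy()
    return SurvivalCurve(np.minimum.accumulate(np.clip(s, 0, 1)))


# -- step 2: relative survival -------------------------------------------


def relative_survival(
    s_obs: SurvivalCurve, sh: SurvivalCurve, epsilon: float = 1e-4
) -> RelativeSurvival:
    """W = S/Sh clamped to [epsilon, 1 - epsilon], with its logit."""
    T = s_obs.horizon
    if sh.horizon < T:
        raise GridMismatchError("healthy reference does not cover the observed range")
    sh_obs = sh.s[: T + 1]
    if np.any(sh_obs <= 0):
        raise ZeroDivisionError("healthy reference reaches 0 within the observed range")
    w = np.clip(s_obs.s / sh_obs, epsilon, 1 - epsilon)
    return RelativeSurvival(t=np.arange(T + 1), w=w, logit_w=logit(w))


# -- restricted cubic spline (natural spline, linear tails) ---------------

def knot_quantiles(k: int) -> np.ndarray:
    """Equally spaced quantile positions with 2.5% boundary offsets."""
    if k < 3:
        raise ValueError("need at least 3 knots")
    return np.linspace(0.025, 0.975, k)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline design matrix (truncated-power form).

    Columns: intercept, x, and k-2 nonlinear terms that are constrained to be
    linear beyond the boundary knots — which is what makes one-step-ahead
    extrapolation beyond the data a linear continuation.
    """
    x = np.asarray(x, dtype=float)
    k = knots
    if len(k) < 3:
        raise ValueError("need at least 3 knots")
    tau = (k[-1] - k[0]) ** 2
    cols = [np.ones_like(x), x]
    for j in range(len(k) - 2):
        term = (
            np.clip(x - k[j], 0, None) ** 3
            - np.clip(x - k[-2], 0, None) ** 3 * (k[-1] - k[j]) / (k[-1] - k[-2])
            + np.clip(x - k[-1], 0, None) ** 3 * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(term / tau)
    return np.column_stack(cols)


def _fit_predict_window(
    ts: np.ndarray, ys: np.ndarray, t_next: float, knot_counts
) -> float:
    """Best-AIC restricted-cubic-spline fit over the window; predict t_next.

    Degenerate windows (constant response or singular basis) fall back to a
    linear least-squares fit.
    """
    n = ts.size
    if np.ptp(ys) < 1e-12:
        return float(ys[-1])
    best_aic, best_pred = np.inf, None
    for k in knot_counts:
        if k > n // 8:  # keep several points per knot interval
            continue
        knots = np.quantile(ts, knot_quantiles(k))
        if np.unique(knots).size < 3:
            continue
        X = rcs_basis(ts, knots)
        beta, res, rank, _ = np.linalg.lstsq(X, ys, rcond=None)
        if rank < X.shape[1]:
            continue
        rss = float(res[0]) if res.size else float(np.sum((ys - X @ beta) ** 2))
        rss = max(rss, 1e-300)
        aic = n * np.log(rss / n) + 2 * (X.shape[1] + 1)
        if aic < best_aic:
            best_aic = aic
            best_pred = float((rcs_basis(np.array([t_next]), knots) @ beta)[0])
    if best_pred is None:
        logger.debug("spline fit singular; falling back to linear fit")
        coef = np.polyfit(ts, ys, 1)
        best_pred = float(np.polyval(coef, t_next))
    return best_pred


def rolling_extrapolate(
    rel: RelativeSurvival, cfg: ExtrapolationConfig, cap_months: int
) -> np.ndarray:
    """Extend logit W(t) to ``cap_months`` by rolling one-step-ahead prediction.

    Each month the best-AIC restricted cubic spline over the current
    fixed-length window predicts the next point; the prediction is appended as
    observed and the window slides forward one month.

    Because the grid is uniform, each window's quantile knots are the previous
    window's knots shifted by one month, so in window-relative coordinates the
    design matrix never changes; one QR factorization per knot count serves
    every step.
    """
    obs = rel.logit_w
    window = cfg.window if cfg.window is not None else obs.size
    if obs.size < window:
        raise ValueError("observed segment shorter than the rolling window")
    if cap_months < obs.size - 1:
        raise ValueError("cap precedes the observed range")
    x = np.arange(window, dtype=float)
    models = []
    for k in cfg.knot_counts:
        if k > window // 8:  # keep several points per knot interval
            continue
        knots = np.quantile(x, knot_quantiles(k))
        if np.unique(knots).size < 3:
            continue
        X = rcs_basis(x, knots)
        q, r = np.linalg.qr(X)
        if np.min(np.abs(np.diag(r))) < 1e-10:
            continue
        pred_row = rcs_basis(np.array([float(window)]), knots)[0]
        models.append((X.shape[1], q, r, X, pred_row))
    full = np.empty(cap_months + 1)
    full[: obs.size] = obs
    for t_next in range(obs.size, cap_months + 1):
        ys = full[t_next - window : t_next]
        if np.ptp(ys) < 1e-12:
            full[t_next] = ys[-1]
            continue
        best_aic, best_pred = np.inf, None
        for p, q, r, X, pred_row in models:
            beta = solve_triangular_qr(r, q.T @ ys)
            rss = max(float(np.sum((ys - X @ beta) ** 2)), 1e-300)
            aic = window * np.log(rss / window) + 2 * (p + 1)
            if aic < best_aic:
                best_aic = aic
                best_pred = float(pred_row @ beta)
        if best_pred is None:
            logger.debug("spline fits singular; falling back to linear fit")
            coef = np.polyfit(np.arange(window, dtype=float), ys, 1)
            best_pred = float(np.polyval(coef, float(window)))
        full[t_next] = best_pred
    return full


def solve_triangular_qr(r: np.ndarray, qty: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    return solve_triangular(r, qty, lower=False)


# -- steps 3-4: compose, integrate ---------------------------------------


def compose_survival(full_logit_w: np.ndarray, sh_full: SurvivalCurve) -> SurvivalCurve:
    """S(t) = expit(logit W(t)) * Sh(t), with monotonicity enforced."""
    if sh_full.s.size != full_logit_w.size:
        raise GridMismatchError("logit W and Sh grids differ")
    s = expit(full_logit_w) * sh_full.s
    s[0] = 1.0
    return SurvivalCurve(np.minimum.accumulate(np.clip(s, 0, 1)))


def life_expectancy(curve: SurvivalCurve, warn_tail: float = 1e-3) -> float:
    """LE in years: trapezoidal integral of S over the monthly grid / 12."""
    if curve.s[-1] > warn_tail:
        warnings.warn(
            f"survival at the grid end is {curve.s[-1]:.4f} > {warn_tail}; "
            "LE integral may be truncated"
        )
    return restricted_mean(curve) / 12.0


def sled(s_full: SurvivalCurve, sg_full: SurvivalCurve) -> float:
    """Standardized life expectancy deviation in years: LE(S) - LE(Sg)."""
    T = min(s_full.horizon, sg_full.horizon)
    return (
        restricted_mean(s_full.truncated(T)) - restricted_mean(sg_full.truncated(T))
    ) / 12.0


# -- full chain -----------------------------------------------------------


def extrapolate_cohort(
    cohort,
    table: LifeTable,
    cfg: ExtrapolationConfig,
    rng: np.random.Generator,
) -> tuple[SurvivalCurve, SurvivalCurve, bool]:
    """Run steps 1-4 for one cohort.

    Returns (extrapolated cohort curve, general-reference curve to the cap,
    whether the two-stage healthy draw was needed).
    """
    cap = cfg.cap_months if cfg.cap_months is not None else default_horizon(cohort)
    s_obs = km_estimate(cohort)
    sg_full = cohort_reference_curve(cohort, table, cap)
    healthy_draw = not is_healthier(sg_full, s_obs, s_obs.horizon)
    if healthy_draw:
        sh_full, _ = draw_healthy_reference(cohort, table, cap, rng)
        # domination can still fail on a few grid points through MC noise;
        # enforce it so W stays in (0, 1]
        sh_full = SurvivalCurve(
            np.minimum.accumulate(np.maximum(sh_full.s, np.pad(s_obs.s, (0, cap - s_obs.horizon))))
        )
    else:
        sh_full = sg_full
    rel = relative_survival(s_obs, sh_full, cfg.epsilon)
    full_lw = rolling_extrapolate(rel, cfg, cap)
    s_full = compose_survival(full_lw, sh_full)
    return s_full, sg_full, healthy_draw


def estimate_cohort(
    cohort,
    table: LifeTable,
    cfg: ExtrapolationConfig | None = None,
    rng: np.random.Generator | None = None,
    bootstrap: bool = True,
) -> LifetimeEstimate:
    """LE and SLED with bootstrap standard errors for one cohort.

    Each bootstrap replicate resamples participants with replacement and
    reruns the full reference + extrapolation chain.  Replicates that fail on
    a degenerate resample are skipped; at least 80% must succeed.
    """
    if cfg is None:
        cfg = ExtrapolationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    s_full, sg_full, used_draw = extrapolate_cohort(cohort, table, cfg, rng)
    le = life_expectancy(s_full)
    sl = sled(s_full, sg_full)
    le_se = sled_se = float("nan")
    n_ok = 0
    if bootstrap and cfg.bootstrap_b >= 2:
        les, sls = [], []
        for _ in range(cfg.bootstrap_b):
            try:
                boot = cohort.resample(rng)
                s_b, sg_b, _ = extrapolate_cohort(boot, table, cfg, rng)
                les.append(life_expectancy(s_b))
                sls.append(sled(s_b, sg_b))
            except (DegenerateCohortError, ValueError, ZeroDivisionError) as exc:
                logger.warning("bootstrap replicate failed: %s", exc)
        n_ok = len(les)
        if n_ok < 0.8 * cfg.bootstrap_b:
            raise DegenerateCohortError(
                f"only {n_ok}/{cfg.bootstrap_b} bootstrap replicates succeeded"
            )
        le_se = float(np.std(les, ddof=1))
        sled_se = float(np.std(sls, ddof=1))
    return LifetimeEstimate(
        le_years=le,
        le_se=le_se,
        sled_years=sl,
        sled_se=sled_se,
        curve=s_full,
        n_bootstrap_ok=n_ok,
        used_healthy_draw=used_draw,
    )
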