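"""Individual-level Cox model of mortality on lifetime average PM2.5.

Simulates cohorts whose hazard carries a known log-HR of 0.0242 per µg/m³
of area lifetime-average PM2.5 and recovers it with the proportional-hazards
fit, adjusted for age and sex.
"""

import dataclasses

import numpy as np

from lifegap import SimScenario, default_life_table
from lifegap.hazard import build_individual_design, fit_proportional_hazards
from lifegap.synthetic import (
    make_areas,
    simulate_cohort,
    simulate_exposure_series,
    true_lifetime_exposure,
)

scenario = dataclasses.replace(
    SimScenario(n_areas=6, n_per_area=3000, seed=21), covariate_hazard={}
)
table = default_life_table(scenario)
b = 0.0242

cohorts, series, area_levels = [], {}, {}
for area in make_areas(scenario):
    sim = simulate_exposure_series(scenario, area)
    A = true_lifetime_exposure(scenario, table, sim["true"])
    eta = b * (A - scenario.hazard_center)
    cohorts.append(simulate_cohort(scenario, table, area.area_id, eta))
    series[area.area_id] = sim["true"]
    area_levels[area.area_id] = A

design = build_individual_design(cohorts, series, area_exposure=area_levels)
fit = fit_proportional_hazards(design)
print(f"n = {fit.n}, events = {fit.events}")
print(f"HR per 1 µg/m³: {fit.hr:.4f} (95% CI {fit.ci_low:.4f}-{fit.ci_high:.4f})")
print(f"generative HR : {np.exp(b):.4f}")
print("\nNote: the windowed per-participant exposure (the default when no")
print("area_exposure is given) ends at the survival time itself; with a")
print("declining trend that covariate is endogenous and overstates the HR.")
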