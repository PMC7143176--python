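"""Area-level model: stepwise selection, spatial GLS, years of life lost.

Simulates SLED outcomes from the area model itself (known slope -0.034
years per µg/m³, spatial range 50 km), fits the two-stage procedure and
converts the fitted slope into expected years of life lost for the
worst-exposed area.
"""

import numpy as np
import pandas as pd

from lifegap.arealevel import fit_area_model, simulate_area_model, years_lost

rng = np.random.default_rng(0)
n = 63
table = pd.DataFrame(
    {
        "area_id": [f"A{i:02d}" for i in range(n)],
        "sled_se": rng.uniform(0.05, 0.2, n),
        "exposure": rng.uniform(12, 38, n),
        "x_km": rng.uniform(0, 300, n),
        "y_km": rng.uniform(0, 300, n),
        "college_pct": rng.gamma(2.0, 1.5, n),
        "noise_cov": rng.normal(0, 1, n),
    }
)
sim = simulate_area_model(
    table,
    {"const": 0.5, "exposure": -0.034, "college_pct": 0.06},
    delta_km=50.0,
    sigma=1.0,
    rng=rng,
)
fit, selected = fit_area_model(sim)
b1, se = fit.params["exposure"], fit.bse["exposure"]
print(f"selected covariates: {selected}")
print(f"exposure slope: {b1:.4f} (SE {se:.4f}) years per µg/m³  [truth -0.034]")
print(f"spatial range delta: {fit.delta_km:.0f} km; adjusted R²: {fit.adj_r2:.2f}")

excess = sim["exposure"].max() - 10.0  # above the 10 µg/m³ guideline baseline
out = years_lost(b1, excess, reference_le=16.0)
print(f"worst area: {excess:.1f} µg/m³ excess -> {out['years_lost']:.2f} years lost "
      f"({out['relative_loss_pct']:.1f}% of a 16-year LE)")
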