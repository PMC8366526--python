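"""Estimate the terrapin effective detection radius from point counts.

Simulates radial sighting distances from visual point-transect surveys
with a known half-normal detection process, truncates the farthest 5%,
fits half-normal and hazard-rate keys with series expansions, selects
by AIC subject to goodness-of-fit, and reports the effective detection
radius with a bootstrap CI.
"""

import math

from marshequiv import (
    TerrapinSimSpec,
    candidate_fits,
    edr_half_normal,
    effective_radius,
    select_model,
    simulate_terrapin_distances,
    truncate_distances,
)

spec = TerrapinSimSpec(key="half-normal", sigma=20.0, w=60.0, density=15)
sightings = simulate_terrapin_distances(spec, 60, seed=7)
print(f"simulated sightings: {len(sightings)}")

kept = truncate_distances(sightings["distance_m"].to_numpy())
print(f"retained after 5% truncation: {kept.size}")

fits = candidate_fits(kept, w=60.0)
best = select_model(fits)
print(f"selected: {best.key} key + {best.n_adj} {best.adjustment} "
      f"adjustment term(s); AIC {best.aic:.1f}, GoF p = {best.gof_p:.2f}")

er = effective_radius(best, n_boot=99, seed=8)
print(f"effective radius = {er.rho:.1f} m "
      f"(95% CI [{er.ci_low:.1f}, {er.ci_high:.1f}])")
print(f"closed-form radius at the true scale: "
      f"{edr_half_normal(20.0, 60.0):.1f} m")
# Inside the effective radius an observer misses as many animals as it
# detects beyond it; counts within it give comparable per-site effort.
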