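"""Locating the source area of pollen richness by radius scanning.

Pollen richness per site is regressed against cumulative plant richness at
every radius of the scan grid; the radius with the highest adjusted R^2 is
the estimated source area. On the strong-signal synthetic landscape the
dispersal kernel is built so 85% of the pollen load originates within 150 m
— the scan should recover that radius.
"""

from pollendiv import fit_scaling_regressions, rarefy_dataset
from pollendiv.synthetic_data import effective_source_radius, preset_config, \
    simulate_study

cfg = preset_config("strong-signal")
pollen, survey, ppe, truth = simulate_study(cfg, seed=1)

richness = rarefy_dataset(pollen, depth=943, n_reps=100, rng_seed=1)
scan = fit_scaling_regressions(richness.as_mapping(), survey)

print(f"planted effective source radius: "
      f"{effective_source_radius(cfg.dispersal_lambda):.0f} m")
print(f"estimated source area:           {scan.source_area_m:g} m")
print("radius (m)   adj R^2   p-value")
for s in scan.summaries:
    flag = " *" if s.significant else ""
    print(f"  {s.radius:7.1f}   {s.adj_r2:7.3f}   {s.p_value:.4f}{flag}")
print("The adjusted R^2 profile peaks where the plant survey radius matches")
print("the spatial footprint of the pollen rain; * marks p < 0.05.")
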