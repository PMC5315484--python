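"""Light-dependent ingestion and growth curves for the two species presets.

Reproduces the classic laboratory designs: steady-state ingestion versus
irradiance at saturating prey, and growth versus irradiance in unfed
(monoculture) versus fed cultures, both in nitrogen-replete medium.
"""

import numpy as np

from mixotroph import (
    K_ARMIGER,
    K_VENEFICUM,
    growth_vs_light_curve,
    ingestion_vs_light_curve,
)

light = np.array([0.0, 10.0, 40.0, 100.0, 200.0, 400.0])

print("specific ingestion (1/d) at saturating prey:")
print(f"{'X_L':>6} {'K. armiger':>11} {'K. veneficum':>13}")
arm = ingestion_vs_light_curve(K_ARMIGER, light)
ven = ingestion_vs_light_curve(K_VENEFICUM, light)
for x, a, v in zip(light, arm.ingestion, ven.ingestion):
    print(f"{x:6.0f} {a:11.3f} {v:13.3f}")
print("-> ingestion is zero in darkness (feeding runs on photosynthate) and")
print("   the heavier phagotroph ingests roughly twice as much when light-saturated.")

print()
print("net growth (1/d), unfed monocultures vs fed cultures:")
print(f"{'X_L':>6} {'arm unfed':>10} {'arm fed':>9} {'ven unfed':>10} {'ven fed':>9}")
au = growth_vs_light_curve(K_ARMIGER, light, fed=False)
af = growth_vs_light_curve(K_ARMIGER, light, fed=True)
vu = growth_vs_light_curve(K_VENEFICUM, light, fed=False)
vf = growth_vs_light_curve(K_VENEFICUM, light, fed=True)
for x, a, b, c, d in zip(light, au.g, af.g, vu.g, vf.g):
    print(f"{x:6.0f} {a:10.3f} {b:9.3f} {c:10.3f} {d:9.3f}")
print("-> K. armiger (no nitrogen uptake) never grows without prey; K. veneficum")
print("   does, and both need light even with plenty of food.")
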