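"""Seasonal succession of trophic strategy in idealized surface waters.

Runs the two species presets and a fully plastic optimal strategy through a
coastal-temperate annual cycle (light peaking midsummer, nutrients depleted
in summer, prey peaking in late summer).  The competitive prediction is the
ordering of growth rates: K. veneficum leads in spring and autumn (dissolved
nitrogen available), K. armiger takes over in midsummer (nitrogen depleted,
prey moderate), and the optimal strategy grows all year.
"""

from mixotroph import SeasonalForcingConfig, seasonal_surface_forcing, succession_run

forcing = seasonal_surface_forcing(SeasonalForcingConfig(n_time=13))
run = succession_run(forcing)

print(f"{'day':>4} {'X_L':>6} {'X_N':>6} {'X_F':>6} | "
      f"{'g_arm':>7} {'g_ven':>7} {'g_opt':>6} | {'phiL*':>5} {'phiF*':>5} {'phiN*':>5}")
for _, r in run.iterrows():
    leader = "armiger" if r.g_K_armiger > r.g_K_veneficum else "veneficum"
    print(f"{r.t:4.0f} {r.X_L:6.1f} {r.X_N:6.1f} {r.X_F:6.1f} | "
          f"{r.g_K_armiger:7.3f} {r.g_K_veneficum:7.3f} {r.g_opt:6.3f} | "
          f"{r.phi_L_opt:5.2f} {r.phi_F_opt:5.2f} {r.phi_N_opt:5.2f}  {leader}")
print()
print("Winner flips veneficum -> armiger -> veneficum over the season, and the")
print("optimal strategy shifts from photoautotrophy (high phiL*, phiN*) in")
print("spring to phagotrophy (high phiF*) in summer, with g_opt > 0 throughout.")
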