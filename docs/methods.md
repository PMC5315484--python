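# Methods

## The model

`mixotroph` implements a flux-budget model of a unicellular constitutive
mixotroph — an organism that builds and maintains its own chloroplasts and
combines photoautotrophy with phagotrophy, motivated by the dinoflagellates
*Karlodinium armiger* and *K. veneficum*.  The cell's biomass is split into
structure `V` (µg C) and three machinery pools `φ_L·V`, `φ_F·V`, `φ_N·V`
for light harvesting, phagotrophy and dissolved inorganic nitrogen (DIN)
uptake; the traits `φ_i` are dimensionless investments relative to
structural mass, constrained to `φ_i ≥ 0`, `Σφ_i ≤ 1`.  Total cell mass is
`(1 + Σφ)·V`.

Each investment buys two things:

* an **affinity** `A_i = A_max,i · α_i φ_i V / (α_i φ_i V + A_max,i)` —
  increasing but saturating (packaging of pigments, diffusion limitation of
  transporters, prey-encounter geometry);
* a **maximum uptake capacity** `Jmax_i = M_i φ_i V` — exactly linear
  (processing machinery scales with the amount of machinery).

Uptake of each resource `X_i` follows a Holling type II functional
response, `Jpot_i = Jmax_i · A_i X_i / (A_i X_i + Jmax_i)`, with the
convention `0/0 = 0`.

**Energetics.**  Respiration runs on photosynthate only.  Basal
maintenance `J_R = r_0 (1 + Σφ) V` (structure included; an
investments-only variant is available as an option) is paid first; the
remaining photosynthate `(1 − β_L) J_L − J_R` pays the respiratory costs of
running the uptake pathways, `β_N J_N + β_F J_F`.  When it cannot cover the
cost of the *potential* uptakes, both are throttled by a single pooled
light-energy factor

```
ρ = clip( ((1 − β_L) J_L − J_R) / (β_N Jpot_N + β_F Jpot_F), 0, 1 )
```

with `ρ = 1` when the denominator is zero (nothing to throttle).  This one
assumption produces the observed obligate light dependence of feeding:
ingestion is zero in darkness and every strategy shrinks at
`g = −r_0 − m` in the dark.

**Synthesis.**  Ingested carbon feeds synthesis in full while its
processing cost is paid from photosynthate, so

```
C_syn = (1 − β_L) J_L − J_R − β_N J_N − β_F J_F + J_F
N_syn = J_N + J_F / c_CN
J_tot = min(C_syn, c_CN · N_syn)          (Liebig's law, fixed C:N)
μ     = J_tot / ((1 + Σφ) V),   g = μ − m
```

The excess of the non-limiting element is excreted (`excreted_C`,
`excreted_N` in the `FluxBudget`); there is no downregulation of uptake to
demand, no reserves, no variable stoichiometry, and no distinction between
nitrogen species — growth rate is the terminal output, with no population
dynamics.  A negative `C_syn` propagates into `J_tot` (the cell shrinks;
`g < −m` is not clipped), which is what produces negative growth at low
light even with plentiful food.

### Parameters

All defaults are the published reference values: `V = 6.5e-5` µg C,
`A_max,L = 4.07e-6` µg C (µmol photons m⁻² s⁻¹)⁻¹, `A_max,N = 1e-6` L d⁻¹,
`A_max,F = 4.65e-7` L d⁻¹, `α_N = 0.30`, `α_F = 0.16` (per µg C invested),
`M_L = 5.01` d⁻¹, `M_N = 1.00` µg N µg C⁻¹ d⁻¹, `M_F = 14.10` d⁻¹,
`β_L = 0.35`, `β_F = 0.50` (dimensionless), `β_N = 3.00` µg C µg N⁻¹,
`r_0 = 0.05` d⁻¹, `m = 0.12` d⁻¹, `c_CN = 5.68` µg C µg N⁻¹.  Species
presets: *K. armiger* `{φ_L, φ_F, φ_N} = {0.45, 0.16, 0.00}`,
*K. veneficum* `{0.45, 0.08, 0.10}`.

`α_L` is not available from the published table.  The default
`α_L = 9 · A_max,L / (0.9 · V) ≈ 0.626` is calibrated so light affinity
reaches 90% of its maximum at the saturation investment `φ* = 0.9` — the
same ratio implied by the printed `(α_F, φ* = 0.4, A_max,F)` triplet
(`0.16 · 0.4 · 6.5e-5 ≈ 9 · 4.65e-7`).  The value is configurable and a
provenance notice is logged whenever a run uses the reconstructed default.

The feeding-efficiency factor (0.7) and the Q10 (2.5) are
data-normalization helpers used when comparing model rates with published
laboratory rates; they are not fluxes inside the budget.

## Optimization

`optimize_traits` maximizes `g` over the feasible simplex.  The landscape
is smooth but carries wide, nearly flat ridges — a broad set of trait
combinations performs within 5% of the optimum — so the method is a
deterministic multistart scheme: a vectorized enumeration of the simplex at
step 0.02 (23 426 points) ranks starting points, up to four
diversity-filtered starts (pairwise L∞ distance ≥ 0.2) are refined with
SLSQP under bounds `[0, 1]` and the constraint `Σφ ≤ 1`, and ties within
1e-9 d⁻¹ are broken toward the smallest `Σφ` (parsimony).  There is no
randomness; a `seed` argument exists only for interface stability.

Validation against an exhaustive 0.01-step simplex enumeration
(176 851 points) is *one-sided*: the optimizer must attain at least the
grid's best growth minus 1e-3 d⁻¹ (observed worst deficit ~1e-4).  The
continuous optimizer routinely exceeds the grid's best by the grid's own
discretization error (up to ~7e-3 d⁻¹ where gradients approach 1 d⁻¹ per
unit φ), and on flat ridges the argmax *location* is not identifiable to
any useful tolerance — which is itself a finding: selection on these traits
is weak, so a cloud of strategies coexists near the optimum.  The
near-optimal region reported by `OptimizationResult` makes this explicit:
all simplex samples (step 0.02) with `g ≥ tolerance · g_opt`, by default
within 95% of optimum, summarized per trait as `[lo95, hi95]` bands.  It is
defined only where `g_opt > 0`.

A consequence of fixed traits worth noting: `g` is monotone in light and
food but **not** in DIN.  A carbon-limited cell keeps paying the `β_N`
carbon cost for nitrogen it must excrete, so more DIN can lower the growth
of a fixed strategy; after re-optimizing the traits, optimal growth is
monotone in all three resources.  This is real model behaviour (uptake is
not downregulated to demand), not a numerical artifact.

## Scenarios and the synthetic forcing

The laboratory-curve builders evaluate the presets on fixed environments
mimicking the experimental designs: ingestion vs irradiance at saturating
prey (≥1000 µg C L⁻¹, default 1500) and nitrogen-replete medium
(838 µM ≈ 1.17e4 µg N L⁻¹); growth vs irradiance in unfed monocultures or
fed cultures in the same medium.

The constant-environment scan baselines and the seasonal forcing
magnitudes are not printed in the source material; they are idealized
coastal-temperate choices, fixed once in `scenarios.py` and exposed in the
run configuration:

* scan baselines — high light 200 µmol photons m⁻² s⁻¹ (saturation is
  above ~180), low DIN 1 µg N L⁻¹, high DIN 100 µg N L⁻¹, limited food
  5 µg C L⁻¹;
* surface season (day 0 = midwinter, period 365 d) — light 40→400 µmol
  photons m⁻² s⁻¹ as `sin²(πt/365)`; DIN 70→0.5 µg N L⁻¹, depleted in
  summer with a cubed shape so spring stays nutrient-rich; prey
  5→150 µg C L⁻¹, squared shape lagged 30 d so it peaks in late summer.
  Winter surface light of 40 µmol photons m⁻² s⁻¹ is the lowest value at
  which an optimally investing cell still achieves positive growth in the
  nutrient-rich winter mixed layer, which the succession prediction
  (optimal growth positive year-round) requires;
* depth extension — exponential light decay with constant extinction
  `k = ln(400/13)/80 ≈ 0.0428 m⁻¹`, calibrated so the summer compensation
  depth sits at ≈80 m (the model's compensation irradiance at deep-water
  nutrient levels, found numerically, is ≈13 µmol photons m⁻² s⁻¹); a fixed
  pycnocline at 50 m with DIN ramping back to winter levels over 20 m below
  it; a Gaussian prey maximum centred at 35 m (width 12 m) whose amplitude
  follows the surface prey cycle.

What the synthetic forcing does *not* emulate: weather-band variability,
storms and mixed-layer deepening events, self-shading, prey dynamics
responding to grazing, or any feedback of the plankton on the resources
(forcing is imposed, not simulated).  Passing succession tests therefore
demonstrate that the *physiology* module orders strategies correctly along
realistic resource gradients — not that the forcing reproduces any
particular year or station.  Succession claims are deliberately tested as
sign/ordering properties (who wins when; growth positive or negative),
never as absolute rates.

`succession_run` evaluates the presets and the optimizer at every grid
point.  Default problem sizes keep desk-scale runtimes: test-suite
succession runs use 25–37 time points (surface) and 8×6 (depth); the CLI
defaults to 365 daily steps and 1 m depth bins to 100 m (a full 365×101
depth-season run is tens of minutes on one core; reduce `n_time`/`n_depth`
for quick looks).

## Numerical conventions

* `0/0 ≡ 0` in functional responses; `ρ ≡ 1` with no potential uptake.
* Feasibility tolerance on `Σφ ≤ 1` is 1e-9; SLSQP results are clipped to
  the simplex before re-evaluation.
* Budget evaluations are vectorized (numpy broadcasting) for grids and
  scans, with an equivalent plain-float path used inside the optimizer's
  refinement loop; the two are cross-checked in the test suite to 1e-12
  relative tolerance.
* Carbon and nitrogen ledgers close by construction; the test suite checks
  both to 1e-12 relative tolerance on 10⁴ random evaluations.
* CSV outputs use `%.12g` floats; identical configuration reproduces
  result tables byte for byte.

## Known limitations

* Fixed stoichiometry and a single DIN pool; no reserves, acclimation
  dynamics, or dark-survival heterotrophy — strategies are compared at
  steady state, instantaneously per environment.
* No mortality closure beyond the constant `m`; no grazing risk or other
  trait-dependent losses, so the optimum only reflects resource harvest.
* The `α_L` reconstruction and the forcing amplitudes are modelling
  choices (documented above); quantitative outputs that depend on them
  (e.g. absolute seasonal growth rates) should be read as illustrative,
  while trade-off-driven results (trait optima, orderings, crossovers) are
  robust to them within the tested ranges.
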