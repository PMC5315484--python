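"""Carbon/nitrogen flux budget of a single mixotrophic cell.

The model organism is a unicellular plankter (motivated by the mixotrophic
dinoflagellates *Karlodinium armiger* and *K. veneficum*) that divides its
biomass between structure ``V`` and three resource-harvesting investments,
expressed as fractions of structural carbon:

* ``phi_L`` — light harvesting (pigments, carbon-fixation enzymes),
* ``phi_F`` — phagotrophy (feeding apparatus, food vacuoles, digestion),
* ``phi_N`` — dissolved inorganic nitrogen uptake (transporters, reductases).

Each investment buys an *affinity* (a saturating, diminishing-returns
function of the investment) and a *maximum uptake capacity* (linear in the
investment).  Uptake of each resource follows a Holling type II functional
response shaped by the affinity and the capacity.

Carbon for respiration comes from photosynthesis only: basal maintenance
``J_R`` is paid first, and whatever photosynthate remains fuels the
respiratory costs of nutrient and food uptake.  When photosynthate is
insufficient, those uptakes are throttled by the light-energy factor
``rho`` in [0, 1] — this is what makes feeding obligately light dependent.
Carbon and nitrogen left after costs are combined into new biomass under
Liebig's law of the minimum at a fixed cellular C:N mass ratio; the excess
of the non-limiting element is excreted.

All fluxes are per cell (µg C d⁻¹ or µg N d⁻¹); specific rates divide by
the total cell mass ``(1 + phi_L + phi_F + phi_N) · V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TraitSet",
    "Environment",
    "ModelParams",
    "FluxBudget",
    "FluxBudgetError",
    "ALPHA_L_DEFAULT",
    "ALPHA_L_NOTE",
    "affinity",
    "max_uptake",
    "potential_uptake",
    "basal_respiration",
    "light_energy_factor",
    "compute_budget",
    "growth_rate",
    "growth_rate_arrays",
    "budget_frame",
]

#: Affinity gained per unit investment in photosynthesis.  The printed value
#: is unreadable in the source table; this default makes the light affinity
#: reach 90% of A_max_L at the saturation investment phi* = 0.9, the same
#: ratio implied by the printed (alpha_F, phi*=0.4, A_max_F) triplet.
ALPHA_L_DEFAULT = 9.0 * 4.07e-6 / (0.9 * 6.5e-5)

ALPHA_L_NOTE = (
    "alpha_L is not available from the published parameter table; using the "
    f"reconstructed default {ALPHA_L_DEFAULT:.4g} ug C (umol photons m-2 s-1)-1 "
    "(ug C)-1, calibrated so light affinity reaches 90% of A_max_L at an "
    "investment of 0.9. Override via the 'alpha_L' parameter key if needed."
)

_SUM_TOL = 1e-9


class FluxBudgetError(ArithmeticError):
    """A flux-budget evaluation produced a non-finite intermediate."""


@dataclass(frozen=True)
class TraitSet:
    """Dimensionless investments in the three resource-harvesting systems.

    Each ``phi_i`` is machinery mass relative to structural mass; the total
    investment cannot exceed the structural mass (``sum(phi) <= 1``), which
    is also the optimizer's feasible set.
    """

    phi_L: float
    phi_F: float
    phi_N: float

    def __post_init__(self) -> None:
        for name in ("phi_L", "phi_F", "phi_N"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.total > 1.0 + _SUM_TOL:
            raise ValueError(
                f"total investment {self.total:.6g} exceeds structural mass "
                "(phi_L + phi_F + phi_N must be <= 1)"
            )

    @property
    def total(self) -> float:
        return self.phi_L + self.phi_F + self.phi_N

    def as_array(self) -> np.ndarray:
        return np.array([self.phi_L, self.phi_F, self.phi_N], dtype=float)

    def replace(self, **changes: float) -> "TraitSet":
        return replace(self, **changes)


@dataclass(frozen=True)
class Environment:
    """Resource triple experienced by the cell.

    ``X_L`` irradiance (µmol photons m⁻² s⁻¹), ``X_N`` dissolved inorganic
    nitrogen (µg N L⁻¹), ``X_F`` prey carbon (µg C L⁻¹).
    """

    X_L: float
    X_N: float
    X_F: float

    def __post_init__(self) -> None:
        for name in ("X_L", "X_N", "X_F"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def replace(self, **changes: float) -> "Environment":
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelParams:
    """Physiological parameter registry (published reference values).

    Defaults are the general, species-independent constants of the model;
    species differ only through their :class:`TraitSet`.  Units:

    * ``V`` structural mass, µg C
    * ``A_max_L`` µg C (µmol photons m⁻² s⁻¹)⁻¹; ``A_max_N``, ``A_max_F`` L d⁻¹
    * ``alpha_i`` affinity gained per µg C invested
    * ``M_L``, ``M_F`` d⁻¹; ``M_N`` µg N µg C⁻¹ d⁻¹ (max uptake per investment)
    * ``beta_L``, ``beta_F`` µg C per µg C of flux; ``beta_N`` µg C per µg N
    * ``r_0`` basal respiration d⁻¹; ``m`` mortality d⁻¹
    * ``c_CN`` C:N mass ratio of cell, investments and food (Redfield-like)
    """

    V: float = 6.5e-5
    A_max_L: float = 4.07e-6
    A_max_N: float = 1.0e-6
    A_max_F: float = 4.65e-7
    alpha_L: float = ALPHA_L_DEFAULT
    alpha_N: float = 0.30
    alpha_F: float = 0.16
    M_L: float = 5.01
    M_N: float = 1.00
    M_F: float = 14.10
    beta_L: float = 0.35
    beta_N: float = 3.00
    beta_F: float = 0.50
    r_0: float = 0.05
    m: float = 0.12
    c_CN: float = 5.68

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v <= 0.0:
                raise ValueError(f"parameter {f.name} must be finite and > 0, got {v!r}")
        # a dimensionless carbon cost >= 1 would tax away the whole flux
        if self.beta_L >= 1.0:
            raise ValueError(f"beta_L must be < 1, got {self.beta_L!r}")
        if self.beta_F >= 1.0:
            raise ValueError(f"beta_F must be < 1, got {self.beta_F!r}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ModelParams":
        """Build parameters from a symbol->value mapping; unknown keys rejected."""
        known = set(cls.field_names())
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown parameter key(s): {', '.join(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def replace(self, **changes: float) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class FluxBudget:
    """Every per-cell flux from one evaluation of the budget.

    Carbon fluxes in µg C d⁻¹, nitrogen fluxes in µg N d⁻¹; ``mu`` and ``g``
    are specific rates in d⁻¹.  ``C_syn`` may be negative (the cell shrinks
    when photosynthate cannot cover maintenance); ``J_tot`` then inherits the
    deficit, so ``g`` is not clipped at ``-m``.
    """

    A_L: float
    A_N: float
    A_F: float
    Jmax_L: float
    Jmax_N: float
    Jmax_F: float
    J_L: float
    Jpot_N: float
    Jpot_F: float
    rho: float
    J_N: float
    J_F: float
    J_R: float
    C_syn: float
    N_syn: float
    J_tot: float
    mu: float
    g: float
    excreted_C: float
    excreted_N: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _npvalue(x: np.ndarray | float, scalar: bool) -> Any:
    return float(x) if scalar else x


def affinity(phi_i, A_max_i, alpha_i, V):
    """Affinity bought by an investment: ``A_max·αφV / (αφV + A_max)``.

    Strictly increasing and concave in ``phi_i`` with asymptote ``A_max_i``
    (packaging effect for pigments, diffusion limitation for transporters).
    Accepts scalars or arrays.
    """
    phi = np.asarray(phi_i, dtype=float)
    if np.any(phi < 0):
        raise ValueError("investment phi_i must be >= 0")
    for name, v in (("A_max_i", A_max_i), ("alpha_i", alpha_i), ("V", V)):
        if np.any(np.asarray(v) <= 0):
            raise ValueError(f"{name} must be > 0")
    invested = alpha_i * phi * V
    out = A_max_i * invested / (invested + A_max_i)
    return _npvalue(out, phi.ndim == 0)


def max_uptake(phi_i, M_i, V):
    """Maximum uptake capacity, exactly linear in the investment: ``M·φ·V``."""
    phi = np.asarray(phi_i, dtype=float)
    if np.any(phi < 0):
        raise ValueError("investment phi_i must be >= 0")
    return _npvalue(M_i * phi * V, phi.ndim == 0)


def potential_uptake(A_i, Jmax_i, X_i):
    """Holling type II functional response ``Jmax·A·X / (A·X + Jmax)``.

    Defined as 0 whenever the encounter flux and the capacity are both zero
    (0/0 convention), so zero investment or zero resource yields zero uptake.
    """
    A = np.asarray(A_i, dtype=float)
    Jmax = np.asarray(Jmax_i, dtype=float)
    X = np.asarray(X_i, dtype=float)
    enc = A * X
    denom = enc + Jmax
    safe = np.where(denom > 0.0, denom, 1.0)
    out = np.where(denom > 0.0, Jmax * enc / safe, 0.0)
    scalar = A.ndim == 0 and Jmax.ndim == 0 and X.ndim == 0
    return _npvalue(out, scalar)


def basal_respiration(traits: TraitSet, params: ModelParams, *, include_structure: bool = True) -> float:
    """Maintenance respiration ``r_0·(1 + Σφ)·V`` (µg C d⁻¹).

    Structure and the three investments share the same specific maintenance
    cost.  ``include_structure=False`` gives the investments-only variant
    ``r_0·Σφ·V`` for sensitivity analysis.
    """
    base = 1.0 if include_structure else 0.0
    return params.r_0 * (base + traits.total) * params.V


def light_energy_factor(J_L, J_R, Jpot_N, Jpot_F, params: ModelParams):
    """Light-energy throttle on nutrient and food uptake.

    ``rho = clip(((1-beta_L)·J_L - J_R) / (beta_N·Jpot_N + beta_F·Jpot_F), 0, 1)``:
    the photosynthate left after maintenance, relative to the carbon needed to
    pay the respiratory costs of running both uptake pathways at potential.
    With nothing to throttle (zero denominator) the convention is ``rho = 1``.
    """
    J_L = np.asarray(J_L, dtype=float)
    num = (1.0 - params.beta_L) * J_L - np.asarray(J_R, dtype=float)
    denom = params.beta_N * np.asarray(Jpot_N, dtype=float) + params.beta_F * np.asarray(Jpot_F, dtype=float)
    safe = np.where(denom > 0.0, denom, 1.0)
    out = np.where(denom > 0.0, np.clip(num / safe, 0.0, 1.0), 1.0)
    return _npvalue(out, out.ndim == 0)


def _budget_fields(phi_L, phi_F, phi_N, X_L, X_N, X_F, p: ModelParams,
                   *, include_structure_respiration: bool = True) -> dict[str, Any]:
    """Vectorized flux budget; inputs broadcast elementwise."""
    phi_L = np.asarray(phi_L, dtype=float)
    phi_F = np.asarray(phi_F, dtype=float)
    phi_N = np.asarray(phi_N, dtype=float)
    total = phi_L + phi_F + phi_N

    A_L = affinity(phi_L, p.A_max_L, p.alpha_L, p.V)
    A_N = affinity(phi_N, p.A_max_N, p.alpha_N, p.V)
    A_F = affinity(phi_F, p.A_max_F, p.alpha_F, p.V)
    Jmax_L = max_uptake(phi_L, p.M_L, p.V)
    Jmax_N = max_uptake(phi_N, p.M_N, p.V)
    Jmax_F = max_uptake(phi_F, p.M_F, p.V)

    # photosynthesis is never throttled: actual equals potential uptake
    J_L = potential_uptake(A_L, Jmax_L, X_L)
    Jpot_N = potential_uptake(A_N, Jmax_N, X_N)
    Jpot_F = potential_uptake(A_F, Jmax_F, X_F)

    base = 1.0 if include_structure_respiration else 0.0
    J_R = p.r_0 * (base + total) * p.V

    rho = light_energy_factor(J_L, J_R, Jpot_N, Jpot_F, p)
    J_N = rho * Jpot_N
    J_F = rho * Jpot_F

    # ingested carbon feeds synthesis in full; its processing cost beta_F*J_F
    # is paid out of photosynthate (respiration runs on photosynthate only)
    C_syn = (1.0 - p.beta_L) * J_L - J_R - p.beta_N * J_N - p.beta_F * J_F + J_F
    N_syn = J_N + J_F / p.c_CN
    J_tot = np.minimum(C_syn, p.c_CN * N_syn)
    mu = J_tot / ((1.0 + total) * p.V)
    g = mu - p.m
    excreted_C = C_syn - J_tot
    excreted_N = N_syn - J_tot / p.c_CN

    return {
        "A_L": A_L, "A_N": A_N, "A_F": A_F,
        "Jmax_L": Jmax_L, "Jmax_N": Jmax_N, "Jmax_F": Jmax_F,
        "J_L": J_L, "Jpot_N": Jpot_N, "Jpot_F": Jpot_F,
        "rho": rho, "J_N": J_N, "J_F": J_F, "J_R": J_R,
        "C_syn": C_syn, "N_syn": N_syn, "J_tot": J_tot,
        "mu": mu, "g": g,
        "excreted_C": excreted_C, "excreted_N": excreted_N,
    }


def compute_budget(traits: TraitSet, env: Environment, params: ModelParams | None = None,
                   *, include_structure_respiration: bool = True) -> FluxBudget:
    """Evaluate the complete flux budget for one trait set in one environment."""
    p = params if params is not None else ModelParams()
    raw = _budget_fields(traits.phi_L, traits.phi_F, traits.phi_N,
                         env.X_L, env.X_N, env.X_F, p,
                         include_structure_respiration=include_structure_respiration)
    out: dict[str, float] = {}
    for name, v in raw.items():
        v = float(v)
        if not math.isfinite(v):
            raise FluxBudgetError(f"non-finite flux '{name}' for traits={traits}, env={env}")
        out[name] = v
    return FluxBudget(**out)


def growth_rate(traits: TraitSet, env: Environment, params: ModelParams | None = None) -> float:
    """Net per-capita growth rate ``g = mu - m`` (d⁻¹)."""
    return compute_budget(traits, env, params).g


def growth_rate_arrays(phi_L, phi_F, phi_N, X_L, X_N, X_F,
                       params: ModelParams | None = None) -> np.ndarray:
    """Vectorized ``g`` over broadcastable trait and environment arrays.

    No feasibility checks beyond non-negativity are applied; callers sweeping
    the trait simplex are responsible for ``sum(phi) <= 1``.
    """
    p = params if params is not None else ModelParams()
    return np.asarray(_budget_fields(phi_L, phi_F, phi_N, X_L, X_N, X_F, p)["g"], dtype=float)


def _growth_scalar(phi_L: float, phi_F: float, phi_N: float,
                   X_L: float, X_N: float, X_F: float, p: ModelParams) -> float:
    """Plain-float growth evaluation (hot path for the optimizer)."""
    total = phi_L + phi_F + phi_N

    inv = p.alpha_L * phi_L * p.V
    J_L = 0.0
    if inv > 0.0 and X_L > 0.0:
        A = p.A_max_L * inv / (inv + p.A_max_L)
        enc = A * X_L
        Jmax = p.M_L * phi_L * p.V
        J_L = Jmax * enc / (enc + Jmax)

    inv = p.alpha_N * phi_N * p.V
    Jpot_N = 0.0
    if inv > 0.0 and X_N > 0.0:
        A = p.A_max_N * inv / (inv + p.A_max_N)
        enc = A * X_N
        Jmax = p.M_N * phi_N * p.V
        Jpot_N = Jmax * enc / (enc + Jmax)

    inv = p.alpha_F * phi_F * p.V
    Jpot_F = 0.0
    if inv > 0.0 and X_F > 0.0:
        A = p.A_max_F * inv / (inv + p.A_max_F)
        enc = A * X_F
        Jmax = p.M_F * phi_F * p.V
        Jpot_F = Jmax * enc / (enc + Jmax)

    J_R = p.r_0 * (1.0 + total) * p.V
    denom = p.beta_N * Jpot_N + p.beta_F * Jpot_F
    if denom > 0.0:
        rho = ((1.0 - p.beta_L) * J_L - J_R) / denom
        rho = 0.0 if rho < 0.0 else (1.0 if rho > 1.0 else rho)
    else:
        rho = 1.0
    J_N = rho * Jpot_N
    J_F = rho * Jpot_F

    C_syn = (1.0 - p.beta_L) * J_L - J_R - p.beta_N * J_N - p.beta_F * J_F + J_F
    N_syn = J_N + J_F / p.c_CN
    J_tot = min(C_syn, p.c_CN * N_syn)
    return J_tot / ((1.0 + total) * p.V) - p.m


def budget_frame(records: Iterable[tuple[TraitSet, Environment, FluxBudget]]) -> pd.DataFrame:
    """Flatten (traits, environment, budget) evaluations into a tidy table."""
    rows = []
    for traits, env, budget in records:
        row: dict[str, float] = {
            "phi_L": traits.phi_L, "phi_F": traits.phi_F, "phi_N": traits.phi_N,
            "X_L": env.X_L, "X_N": env.X_N, "X_F": env.X_F,
        }
        row.update(budget.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
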