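"""Constrained optimization of the trait triple.

Finds the investment triple ``(phi_L, phi_F, phi_N)`` maximizing the net
per-capita growth rate in a fixed environment, subject to the feasibility
simplex ``phi_i >= 0``, ``sum(phi) <= 1`` (total investment cannot exceed
structural mass).  "Population growth rate" here is the density-independent
per-capita rate ``g``; optimization is instantaneous per environment, with
no adaptive-dynamics time stepping.

The growth landscape is smooth but can carry wide, nearly flat ridges (a
broad band of trait combinations performs within a few percent of the
optimum), so the optimizer is a deterministic multistart scheme: a
vectorized coarse enumeration of the simplex picks diverse high-growth
starting points, each refined by SLSQP.  Ties on plateaus are broken toward
the smallest total investment (parsimony).  The near-optimal region — all
sampled trait sets with ``g >= tolerance * g_opt`` — is characterized by a
dense simplex sample (default step 0.02), mirroring the reported "within
95% of optimal" bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import Environment, ModelParams, TraitSet, growth_rate_arrays
from .core import _growth_scalar

__all__ = [
    "OptimizationResult",
    "simplex_grid",
    "optimize_traits",
    "gradient_scan",
    "compare_species",
    "SCAN_AXES",
]

#: mapping from scan-axis name to the Environment field it varies
SCAN_AXES = {"light": "X_L", "nutrients": "X_N", "food": "X_F"}

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of a constrained trait optimization.

    ``near_optimal_phis`` holds the sampled trait triples whose growth rate
    is at least ``tolerance * g_opt`` (rows ``[phi_L, phi_F, phi_N]``); it is
    empty when the landscape admits no positive growth (``g_opt <= 0``), in
    which case the result is flagged simply by that sign.
    """

    traits_opt: TraitSet
    g_opt: float
    converged: bool
    n_evals: int
    tolerance: float
    near_optimal_phis: np.ndarray

    @property
    def near_optimal(self) -> tuple[TraitSet, ...]:
        return tuple(TraitSet(*row) for row in self.near_optimal_phis)

    def near_optimal_ranges(self) -> dict[str, tuple[float, float]]:
        """Per-trait [min, max] over the near-optimal sample (incl. the optimum)."""
        pts = self.near_optimal_phis
        if pts.size == 0:
            pts = self.traits_opt.as_array()[None, :]
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        return {name: (float(lo[i]), float(hi[i]))
                for i, name in enumerate(("phi_L", "phi_F", "phi_N"))}


@lru_cache(maxsize=8)
def _simplex_grid_cached(n: int) -> np.ndarray:
    idx = np.arange(n + 1)
    i, j = np.meshgrid(idx, idx, indexing="ij")
    mask = (i + j) <= n
    i, j = i[mask], j[mask]
    counts = n - i - j + 1
    ii = np.repeat(i, counts)
    jj = np.repeat(j, counts)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    kk = np.arange(counts.sum()) - offsets
    return np.column_stack([ii, jj, kk]) / float(n)


def simplex_grid(step: float) -> np.ndarray:
    """All triples ``(phi_L, phi_F, phi_N)`` with spacing ``step`` and sum <= 1."""
    if not 0.0 < step <= 1.0:
        raise ValueError(f"step must be in (0, 1], got {step!r}")
    return _simplex_grid_cached(int(round(1.0 / step)))


def _project(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    s = x.sum()
    if s > 1.0:
        x = x / s
    return x


def _better(g_new: float, total_new: float, g_best: float, total_best: float) -> bool:
    if g_new > g_best + _TIE_EPS:
        return True
    return abs(g_new - g_best) <= _TIE_EPS and total_new < total_best - _TIE_EPS


def optimize_traits(env: Environment, params: ModelParams | None = None,
                    tolerance: float = 0.95, *,
                    coarse_step: float = 0.02,
                    near_optimal_step: float | None = 0.02,
                    n_starts: int = 4,
                    seed: int | None = None) -> OptimizationResult:
    """Maximize growth over the feasible trait simplex.

    Parameters
    ----------
    tolerance
        Fraction of the optimal growth rate defining the near-optimal region
        (default 0.95, i.e. within 95% of optimum); must be in (0, 1].
    near_optimal_step
        Simplex sampling step for the near-optimal region, or ``None`` to
        skip that characterization (e.g. inside large scenario sweeps).
    seed
        Accepted for interface stability; the multistart schedule is a fixed
        lattice, so results do not depend on it.
    """
    del seed  # deterministic start schedule
    if not 0.0 < tolerance <= 1.0:
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance!r}")
    p = params if params is not None else ModelParams()

    grid = simplex_grid(coarse_step)
    g_grid = growth_rate_arrays(grid[:, 0], grid[:, 1], grid[:, 2],
                                env.X_L, env.X_N, env.X_F, p)
    n_evals = grid.shape[0]

    # diverse high-growth starts: walk the ranking, keep points far apart
    order = np.lexsort((grid.sum(axis=1), -g_grid))
    starts: list[np.ndarray] = []
    for idx in order:
        x = grid[idx]
        if all(np.max(np.abs(x - s)) >= 0.2 for s in starts):
            starts.append(x)
        if len(starts) >= n_starts:
            break

    def neg_g(x: np.ndarray) -> float:
        return -_growth_scalar(max(x[0], 0.0), max(x[1], 0.0), max(x[2], 0.0),
                               env.X_L, env.X_N, env.X_F, p)

    best_x = grid[order[0]].copy()
    best_g = float(g_grid[order[0]])
    converged = False
    for x0 in starts:
        res = minimize(neg_g, x0, method="SLSQP",
                       bounds=[(0.0, 1.0)] * 3,
                       constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum()}],
                       options={"maxiter": 200, "ftol": 1e-12})
        n_evals += int(res.nfev)
        x = _project(np.asarray(res.x, dtype=float))
        gx = -neg_g(x)
        n_evals += 1
        if _better(gx, x.sum(), best_g, best_x.sum()):
            best_x, best_g = x, gx
        converged = converged or bool(res.success)

    traits_opt = TraitSet(*np.round(best_x, 12))

    if near_optimal_step is not None and best_g > 0.0:
        sample = simplex_grid(near_optimal_step)
        g_sample = growth_rate_arrays(sample[:, 0], sample[:, 1], sample[:, 2],
                                      env.X_L, env.X_N, env.X_F, p)
        n_evals += sample.shape[0]
        keep = sample[g_sample >= tolerance * best_g]
        near = np.vstack([keep, traits_opt.as_array()[None, :]])
    else:
        near = np.empty((0, 3), dtype=float)

    return OptimizationResult(traits_opt=traits_opt, g_opt=best_g,
                              converged=converged, n_evals=n_evals,
                              tolerance=tolerance, near_optimal_phis=near)


def gradient_scan(axis: str, values: Sequence[float], base_env: Environment,
                  params: ModelParams | None = None, tolerance: float = 0.95,
                  *, near_optimal_step: float | None = 0.02) -> pd.DataFrame:
    """Optimal traits along one environmental gradient.

    Returns one row per gradient value with the optimal investments, the
    optimal growth rate, and the per-trait near-optimal bands
    ``phi_i_lo95`` / ``phi_i_hi95`` (NaN where growth is non-positive and
    the near-optimal region is undefined).
    """
    if axis not in SCAN_AXES:
        raise ValueError(f"axis must be one of {sorted(SCAN_AXES)}, got {axis!r}")
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("values must be a non-empty ordered list")
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError("values must be strictly increasing")

    rows = []
    for v in vals:
        env = base_env.replace(**{SCAN_AXES[axis]: v})
        res = optimize_traits(env, params, tolerance, near_optimal_step=near_optimal_step)
        row = {
            "axis": axis,
            "axis_value": v,
            "phi_L_opt": res.traits_opt.phi_L,
            "phi_F_opt": res.traits_opt.phi_F,
            "phi_N_opt": res.traits_opt.phi_N,
            "g_opt": res.g_opt,
        }
        if res.near_optimal_phis.size:
            ranges = res.near_optimal_ranges()
            for name, (lo, hi) in ranges.items():
                row[f"{name}_lo95"] = lo
                row[f"{name}_hi95"] = hi
        else:
            for name in ("phi_L", "phi_F", "phi_N"):
                row[f"{name}_lo95"] = np.nan
                row[f"{name}_hi95"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_species(presets: Iterable, env: Environment,
                    params: ModelParams | None = None) -> pd.DataFrame:
    """Growth rate of each fixed-trait species in a common environment.

    ``presets`` is an iterable of objects with ``label`` and ``traits``
    attributes (see :class:`mixotroph.scenarios.SpeciesPreset`) or of
    ``(label, TraitSet)`` pairs.  The resulting ordering of ``g`` is the
    competitive prediction for that environment.
    """
    p = params if params is not None else ModelParams()
    rows = []
    for preset in presets:
        if isinstance(preset, tuple):
            label, traits = preset
        else:
            label, traits = preset.label, preset.traits
        g = float(growth_rate_arrays(traits.phi_L, traits.phi_F, traits.phi_N,
                                     env.X_L, env.X_N, env.X_F, p))
        rows.append({"label": label,
                     "phi_L": traits.phi_L, "phi_F": traits.phi_F,
                     "phi_N": traits.phi_N, "g": g})
    if not rows:
        raise ValueError("presets must be non-empty")
    return pd.DataFrame(rows)
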