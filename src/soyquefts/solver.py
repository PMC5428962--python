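"""Reverse QUEFTS: balanced uptake requirements for a target yield.

Balanced uptake places every nutrient at the same relative position t
between its dilution-minimal uptake (target/d, nutrient maximally diluted)
and its accumulation-maximal uptake (target/a):

    u_x(t) = r_x + target * ((1 - t) / d_x + t / a_x),      t in [0, 1].

The forward engine's yield is strictly increasing in t, so a single Brent
root-find on t delivers the uptake triple whose predicted yield equals the
target.  In the linear phase t is constant, giving the constant per-tonne
requirements and internal efficiencies of the linear part of the
linear–parabolic–plateau curve; approaching the potential, t climbs to 1
and requirements per tonne rise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

import pandas as pd

from .dataset import NUTRIENTS, NutrientTriple
from .envelope import EnvelopeCoefficients
from .engine import QueftsParams, UptakeVector, combined_yield

#: Relative tolerance on yield for accepting a balanced solution.
YIELD_RTOL = 1e-6

#: Relative tolerance used to delimit the linear phase of the curve.
LINEAR_PHASE_RTOL = 0.005


class ConvergenceError(RuntimeError):
    """The balanced-uptake root-find failed its forward verification."""


@dataclass(frozen=True)
class RequirementRow:
    """Requirements for one target yield (the machine row of the
    requirement table): balanced uptake, per-tonne requirement, implied IE,
    and — once seed removal is attached — the seed share."""

    target_yield: float
    uptake: NutrientTriple
    per_ton: NutrientTriple
    ie: NutrientTriple
    seed_per_ton: NutrientTriple | None = None
    seed_fraction: NutrientTriple | None = None


@dataclass(frozen=True)
class RequirementCurve:
    ymax: float
    rows: tuple[RequirementRow, ...]
    linear_limit: float

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (kg t-1 and %), full precision."""
        recs = []
        for r in self.rows:
            rec = {"target_yield_kg_ha": r.target_yield}
            for x in NUTRIENTS:
                rec[f"{x}_per_ton_kg_t"] = r.per_ton[x]
            for x in NUTRIENTS:
                rec[f"{x}_seed_per_ton_kg_t"] = (
                    None if r.seed_per_ton is None else r.seed_per_ton[x])
            for x in NUTRIENTS:
                rec[f"{x}_seed_fraction_pct"] = (
                    None if r.seed_fraction is None else r.seed_fraction[x])
            recs.append(rec)
        return pd.DataFrame(recs)


def _blend_uptake(t: float, target: float, params: QueftsParams) -> UptakeVector:
    env = params.envelope
    vals = [params.r[x] + target * ((1.0 - t) / env.d[x] + t / env.a[x])
            for x in NUTRIENTS]
    return UptakeVector(NutrientTriple(*vals))


def balanced_uptake(target: float, params: QueftsParams) -> UptakeVector:
    """Componentwise-minimal balanced uptake achieving the target yield.

    Solves combined_yield(u(t)) = target for the balanced position t by
    Brent's method (deterministic; tolerance ``YIELD_RTOL`` relative on
    yield) and verifies the solution by a forward round trip.

    Raises
    ------
    ValueError
        If target is negative or exceeds the yield potential.
    ConvergenceError
        If the root-find cannot bracket or verify a solution.
    """
    if target < 0:
        raise ValueError(f"target yield must be >= 0, got {target}")
    if target > params.ymax * (1 + 1e-12):
        raise ValueError(f"target {target} exceeds yield potential {params.ymax}")
    if target == 0:
        return UptakeVector(NutrientTriple(0.0, 0.0, 0.0))

    def gap(t: float) -> float:
        return combined_yield(_blend_uptake(t, target, params), params) - target

    g0, g1 = gap(0.0), gap(1.0)
    if g0 >= 0.0:
        t_star = 0.0  # dilution bound already reaches the target
    elif g1 <= 0.0:
        # g(1) = 0 identically (accumulation yields all equal the target);
        # anything below is a numerical failure worth surfacing.
        if abs(g1) > YIELD_RTOL * target:
            raise ConvergenceError(
                f"no balanced position reaches target {target:g} "
                f"(gap at t=1: {g1:g})")
        t_star = 1.0
    else:
        t_star = brentq(gap, 0.0, 1.0, xtol=1e-13, rtol=8.9e-16)
    u = _blend_uptake(t_star, target, params)
    achieved = combined_yield(u, params)
    if abs(achieved - target) > max(1e-3 * target, 1e-9):  # 0.1 % round-trip check
        raise ConvergenceError(
            f"round-trip failed: target {target:g} vs achieved {achieved:g}")
    return u


def internal_efficiencies(row: RequirementRow) -> NutrientTriple:
    """IE_x = target_yield / uptake_x = 1000 / per_ton_x (kg kg-1)."""
    if any(row.uptake[x] == 0 for x in NUTRIENTS):
        raise ValueError("internal efficiency undefined at zero uptake")
    return NutrientTriple(*[row.target_yield / row.uptake[x] for x in NUTRIENTS])


def default_grid(ymax: float) -> list[float]:
    """Target-yield grid mirroring the printed requirement table
    (0, then 0.8–3.6 by 0.4, 3.9–4.8 by 0.3, 5.0–6.0 by 0.2 t ha-1),
    rescaled to the requested potential and clipped at ymax."""
    base = ([0.0] + [800 + 400 * i for i in range(8)]
            + [3900 + 300 * i for i in range(4)]
            + [5000 + 200 * i for i in range(6)])
    scale = ymax / 6000.0
    return [round(v * scale, 6) for v in base if v * scale <= ymax + 1e-9]


def fine_grid(ymax: float, n: int = 120) -> list[float]:
    return list(np.linspace(0.0, ymax, n + 1))


def _make_row(target: float, params: QueftsParams) -> RequirementRow:
    u = balanced_uptake(target, params)
    if target == 0:
        zero = NutrientTriple(0.0, 0.0, 0.0)
        return RequirementRow(0.0, zero, zero, zero)
    per_ton = NutrientTriple(*[1000.0 * u.u[x] / target for x in NUTRIENTS])
    ie = NutrientTriple(*[1000.0 / per_ton[x] for x in NUTRIENTS])
    return RequirementRow(target, u.u, per_ton, ie)


def linear_limit(params: QueftsParams, rtol: float = LINEAR_PHASE_RTOL,
                 probe_points: int = 400) -> float:
    """Largest target whose per-tonne N requirement stays within ``rtol`` of
    the small-target (linear-phase) constant."""
    ref_target = 0.05 * params.ymax
    ref = 1000.0 * balanced_uptake(ref_target, params).u.n / ref_target
    targets = np.linspace(params.ymax / probe_points, params.ymax, probe_points)
    limit = targets[0]
    for y in targets:
        per_ton_n = 1000.0 * balanced_uptake(float(y), params).u.n / y
        if abs(per_ton_n / ref - 1.0) <= rtol:
            limit = float(y)
        else:
            break
    return limit


def requirement_curve(params: QueftsParams,
                      grid: Sequence[float] | None = None) -> RequirementCurve:
    """Balanced requirement rows over a target grid, plus the linear limit.

    The linear limit is located on an internal fine probe independent of the
    reporting grid, so coarse grids do not distort it.
    """
    targets = sorted(default_grid(params.ymax) if grid is None else grid)
    if targets and (targets[0] < 0 or targets[-1] > params.ymax * (1 + 1e-12)):
        raise ValueError("grid targets must lie within [0, ymax]")
    rows = tuple(_make_row(float(y), params) for y in targets)
    return RequirementCurve(ymax=params.ymax, rows=rows,
                            linear_limit=linear_limit(params))


def seed_removal(curve: RequirementCurve, seed_envelope: EnvelopeCoefficients,
                 params: QueftsParams) -> RequirementCurve:
    """Attach seed removal to each row via a second balanced solve.

    The seed envelope must be calibrated on seed-based IEs (seed yield per
    kg of nutrient *in the seed*) by the same percentile method.  For every
    row the balanced seed uptake at the row's target yield gives
    seed_per_ton; seed_fraction is its percentage of the above-ground
    requirement.  A seed requirement exceeding the above-ground requirement
    violates mass balance and raises.
    """
    seed_params = replace(params, envelope=seed_envelope)
    new_rows = []
    for row in curve.rows:
        if row.target_yield == 0:
            zero = NutrientTriple(0.0, 0.0, 0.0)
            new_rows.append(replace(row, seed_per_ton=zero, seed_fraction=zero))
            continue
        seed_u = balanced_uptake(row.target_yield, seed_params)
        spt = NutrientTriple(
            *[1000.0 * seed_u.u[x] / row.target_yield for x in NUTRIENTS])
        for x in NUTRIENTS:
            if spt[x] > row.per_ton[x] * (1 + 1e-9):
                raise ValueError(
                    f"seed {x.upper()} requirement {spt[x]:g} kg/t exceeds "
                    f"above-ground requirement {row.per_ton[x]:g} kg/t")
        frac = NutrientTriple(*[100.0 * spt[x] / row.per_ton[x] for x in NUTRIENTS])
        new_rows.append(replace(row, seed_per_ton=spt, seed_fraction=frac))
    return replace(curve, rows=tuple(new_rows))
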