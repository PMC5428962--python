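"""Forward QUEFTS yield engine: uptake triple -> attainable seed yield.

For each nutrient the envelope turns uptake into a yield range
[YA, YD] — the yields at maximum accumulation and maximum dilution — both
capped at the yield potential.  Every ordered nutrient pair (i, j) then
yields a parabolic estimate that rises from j's accumulation yield to i's
dilution yield, expressing that extra j only helps until i becomes
limiting.  The six ordered-pair estimates are averaged and capped at the
potential, producing the characteristic linear–parabolic–plateau response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataset import NUTRIENTS, NutrientTriple
from .envelope import EnvelopeCoefficients

_ORDERED_PAIRS = [(i, j) for i in NUTRIENTS for j in NUTRIENTS if i != j]

_ZERO = NutrientTriple(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class QueftsParams:
    """Envelope, zero-yield uptake offsets r (kg ha-1) and yield potential.

    r defaults to zero: the requirement curve then passes through the
    origin, with constant per-tonne requirements throughout the linear
    phase.  Nonzero offsets are retained for fidelity to the original
    soil-supply formulation.
    """

    envelope: EnvelopeCoefficients
    ymax: float
    r: NutrientTriple = _ZERO

    def __post_init__(self):
        if not self.ymax > 0:
            raise ValueError(f"ymax must be > 0, got {self.ymax}")
        self.r.validate_nonnegative("r")


@dataclass(frozen=True)
class UptakeVector:
    """Above-ground N/P/K uptake, kg ha-1, all components >= 0."""

    u: NutrientTriple

    def __post_init__(self):
        self.u.validate_nonnegative("uptake")

    @classmethod
    def of(cls, n: float, p: float, k: float) -> "UptakeVector":
        return cls(NutrientTriple(n, p, k))


@dataclass(frozen=True)
class YieldBounds:
    """Per-nutrient accumulation (ya) and dilution (yd) yields, kg ha-1."""

    ya: NutrientTriple
    yd: NutrientTriple


def _bounds_one(x: str, u: NutrientTriple, p: QueftsParams) -> tuple[float, float]:
    eff = max(u[x] - p.r[x], 0.0)
    ya = min(p.envelope.a[x] * eff, p.ymax)
    yd = min(p.envelope.d[x] * eff, p.ymax)
    return ya, yd


def yield_bounds(uptake: UptakeVector, params: QueftsParams) -> YieldBounds:
    """ya_x = min(a_x (u_x - r_x), ymax), yd_x likewise, clamped at 0 below."""
    pairs = [_bounds_one(x, uptake.u, params) for x in NUTRIENTS]
    return YieldBounds(ya=NutrientTriple(*(p[0] for p in pairs)),
                       yd=NutrientTriple(*(p[1] for p in pairs)))


def pairwise_yield(i: str, j: str, uptake: UptakeVector, params: QueftsParams) -> float:
    """Yield estimate for the ordered pair (i, j): j limited, i diluting.

    On the ascending branch,

        EY(i,j) = YA_j + 2 (YD_i - YA_j) x / L - (YD_i - YA_j) x^2 / L^2

    with x = (u_j - r_j) - YA_j / d_j and L = YD_i / a_j - YA_j / d_j; the
    vertex (x = L, i.e. u_j - r_j = YD_i / a_j) meets the dilution bound
    YD_i exactly, beyond which the estimate stays at YD_i.  When
    YA_j >= YD_i the parabola is degenerate and the estimate is YD_i.
    The result is clamped to [0, min(YD_i, ymax)].
    """
    if i == j:
        raise ValueError("pairwise_yield requires two distinct nutrients")
    i, j = i.lower(), j.lower()
    u = uptake.u
    ya_j, _ = _bounds_one(j, u, params)
    _, yd_i = _bounds_one(i, u, params)
    if ya_j >= yd_i:
        ey = yd_i
    else:
        a_j = params.envelope.a[j]
        d_j = params.envelope.d[j]
        x = (u[j] - params.r[j]) - ya_j / d_j
        span = yd_i / a_j - ya_j / d_j
        if x >= span:
            ey = yd_i
        else:
            rel = x / span
            ey = ya_j + (yd_i - ya_j) * rel * (2.0 - rel)
    return min(max(ey, 0.0), yd_i, params.ymax)


def combined_yield(uptake: UptakeVector, params: QueftsParams) -> float:
    """Mean of the six ordered pairwise estimates (kg ha-1).

    The average is finally capped at the yield potential and at every
    nutrient's dilution-bound yield: no nutrient can carry the crop past
    its own maximum-dilution line.
    """
    total = sum(pairwise_yield(i, j, uptake, params) for i, j in _ORDERED_PAIRS)
    bounds = yield_bounds(uptake, params)
    return min(total / len(_ORDERED_PAIRS), params.ymax, *bounds.yd)
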