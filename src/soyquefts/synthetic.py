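"""Synthetic field-trial data with the structure the analysis assumes.

No plot-level dataset accompanies the published calibration, so testing the
pipeline end-to-end requires emulating one: plot yields and harvest indices
with the reported moments, per-nutrient internal efficiencies spread
between the accumulation and dilution envelopes, uptakes split between seed
and straw by nutrient harvest indices, and multiplicative measurement
noise.

The nominal envelope is interpreted as the central 95 % band of the IE
distribution — matching how the envelope is *defined* in the calibration
(2.5th/97.5th percentiles of observed IEs, with observed extremes well
outside it) — so Set-I recalibration on generated data recovers the
configured coefficients as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist, truncnorm

from .dataset import (DEFAULT_MOISTURE_FRACTION, NUTRIENTS, NutrientTriple,
                      Observation)
from .envelope import SOYBEAN_SET_I, EnvelopeCoefficients
from .engine import QueftsParams, UptakeVector
from .solver import balanced_uptake
from .validation import PairedSeries

#: Beta(2,2) quantiles mapping the central 95 % band onto the envelope.
_BETA_A, _BETA_B = 2.0, 2.0
_Q_LO = float(beta_dist.ppf(0.025, _BETA_A, _BETA_B))
_Q_HI = float(beta_dist.ppf(0.975, _BETA_A, _BETA_B))


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level generator settings.

    Defaults emulate the 2001-2015 multi-site soybean dataset: yields
    2472 +/- 683 kg ha-1 (truncated to [300, ymax]), HI 0.46 +/- 0.06
    truncated to (0.2, 0.7), seed nutrient shares around 0.84/0.67/0.58 for
    N/P/K, Set-I envelope as the true IE band, and an 8 % CV of
    multiplicative lognormal measurement noise on uptakes.
    """

    n_obs: int = 2200
    true_envelope: EnvelopeCoefficients = SOYBEAN_SET_I
    ymax: float = 6600.0
    yield_mean: float = 2472.0
    yield_sd: float = 683.0
    yield_floor: float = 300.0
    hi_mean: float = 0.46
    hi_sd: float = 0.06
    hi_bounds: tuple[float, float] = (0.2, 0.7)
    seed_nutrient_hi: NutrientTriple = NutrientTriple(0.84, 0.67, 0.58)
    seed_nutrient_hi_sd: NutrientTriple = NutrientTriple(0.04, 0.09, 0.08)
    measurement_noise_cv: float = 0.08
    moisture_fraction: float = DEFAULT_MOISTURE_FRACTION
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_obs < 0:
            raise ValueError("n_obs must be >= 0")
        if not (0 < self.yield_floor < self.ymax):
            raise ValueError("need 0 < yield_floor < ymax")
        lo, hi = self.hi_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"hi_bounds inverted or out of (0,1): {self.hi_bounds}")
        if not (lo <= self.hi_mean <= hi):
            raise ValueError("hi_mean outside hi_bounds")
        if self.measurement_noise_cv < 0:
            raise ValueError("measurement_noise_cv must be >= 0")
        for x in NUTRIENTS:
            if not (0.0 < self.seed_nutrient_hi[x] < 1.0):
                raise ValueError("seed_nutrient_hi components must lie in (0,1)")


def _record_rng(root_seed: int, index: int) -> np.random.Generator:
    # Per-record substream: changing n_obs never reshuffles earlier records.
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(index,)))


def ie_support(cfg: GeneratorConfig, nutrient: str) -> tuple[float, float]:
    """Support of the IE distribution whose central 95 % band is [a, d]."""
    a = cfg.true_envelope.a[nutrient]
    d = cfg.true_envelope.d[nutrient]
    width = (d - a) / (_Q_HI - _Q_LO)
    lo = a - width * _Q_LO
    return max(lo, 1e-6), lo + width


def _draw_ie(rng, cfg: GeneratorConfig, nutrient: str) -> float:
    lo, hi = ie_support(cfg, nutrient)
    return lo + (hi - lo) * rng.beta(_BETA_A, _BETA_B)


def _lognormal_factor(rng, cv: float, size=None):
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    # mean-one lognormal: E[exp(N(-s^2/2, s^2))] = 1
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_observations(cfg: GeneratorConfig) -> list[Observation]:
    """Draw ``cfg.n_obs`` plot records, bitwise-reproducible from rng_seed.

    Per record: yield and HI from truncated normals; per-nutrient IE from
    the rescaled beta; uptake = yield / IE, perturbed by mean-one lognormal
    noise with the configured CV; uptake split into seed/straw by drawn
    nutrient harvest indices; concentrations derived consistently with the
    dry weights, so recomputing uptake from the stored record reproduces
    the noisy uptake exactly.
    """
    out: list[Observation] = []
    for idx in range(cfg.n_obs):
        rng = _record_rng(cfg.rng_seed, idx)
        seed_yield = float(_truncated_normal(rng, cfg.yield_mean, cfg.yield_sd,
                                             cfg.yield_floor, cfg.ymax))
        hi = float(_truncated_normal(rng, cfg.hi_mean, cfg.hi_sd, *cfg.hi_bounds))
        seed_dm = seed_yield * (1.0 - cfg.moisture_fraction)
        straw_dm = seed_dm * (1.0 - hi) / hi

        uptake, conc_seed, conc_straw = {}, {}, {}
        for x in NUTRIENTS:
            ie = _draw_ie(rng, cfg, x)
            u = seed_yield / ie
            u *= float(_lognormal_factor(rng, cfg.measurement_noise_cv))
            nhi = float(_truncated_normal(
                rng, cfg.seed_nutrient_hi[x], cfg.seed_nutrient_hi_sd[x],
                0.05, 0.999))
            uptake[x] = u
            conc_seed[x] = 1000.0 * (u * nhi) / seed_dm
            conc_straw[x] = 1000.0 * (u * (1.0 - nhi)) / straw_dm

        out.append(Observation(
            site_id=f"synth-{idx:05d}", year=2001 + idx % 15,
            treatment="synthetic",
            seed_yield=seed_yield, straw_dm=straw_dm,
            conc_seed=NutrientTriple(**conc_seed),
            conc_straw=NutrientTriple(**conc_straw),
            uptake=NutrientTriple(**uptake),
            hi=seed_dm / (seed_dm + straw_dm),
        ))
    return out


def generate_validation_pairs(cfg: GeneratorConfig, params: QueftsParams,
                              n_sites: int = 20,
                              ) -> dict[str, PairedSeries]:
    """Paired simulated/measured uptakes for an on-farm validation design.

    Each site's attainable yield is drawn as in ``generate_observations``;
    the model's balanced uptake at that yield is the *simulated* value, and
    the *measured* value is the same uptake under multiplicative lognormal
    measurement noise.  With known CV the expected n-RMSE is analytic
    (about 100*cv for small cv), enabling calibration checks.
    """
    sims = {x: [] for x in NUTRIENTS}
    meas = {x: [] for x in NUTRIENTS}
    for idx in range(n_sites):
        rng = _record_rng(cfg.rng_seed ^ 0x5EED, idx)
        y = float(_truncated_normal(rng, cfg.yield_mean, cfg.yield_sd,
                                    cfg.yield_floor, min(cfg.ymax, params.ymax)))
        u = balanced_uptake(y, params)
        for x in NUTRIENTS:
            sims[x].append(u.u[x])
            meas[x].append(u.u[x] * float(_lognormal_factor(
                rng, cfg.measurement_noise_cv)))
    return {x: PairedSeries(np.array(sims[x]), np.array(meas[x])) for x in NUTRIENTS}
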