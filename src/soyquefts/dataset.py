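"""Plot-level field-trial records and derived per-plot quantities.

A record holds seed yield (at commercial moisture), straw dry matter,
seed/straw nutrient concentrations and/or precomputed above-ground N/P/K
uptakes, plus the harvest index.  From these the module derives uptakes,
internal efficiencies (IE, kg seed per kg nutrient) and their reciprocals
(RIE, kg nutrient per tonne of seed), nutrient harvest indices, and
Table-style summary statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("soyquefts")

#: Moisture fraction of commercial seed yield; dry matter = yield * (1 - this).
DEFAULT_MOISTURE_FRACTION = 0.135

#: Harvest-index threshold below which a plot is assumed stressed by
#: factors other than nutrition and excluded from calibration.
DEFAULT_HI_THRESHOLD = 0.4

#: Relative tolerance for declaring stored and recomputed uptakes inconsistent.
UPTAKE_CONSISTENCY_RTOL = 1e-3

NUTRIENTS = ("n", "p", "k")


class InsufficientDataError(ValueError):
    """A derived quantity was requested from a record lacking the inputs."""


class UndefinedEfficiencyError(ValueError):
    """IE/RIE requested where uptake (or yield) makes them undefined."""


@dataclass(frozen=True)
class NutrientTriple:
    """An (N, P, K) value triple; semantics fixed by context.

    Used for uptakes (kg ha-1), concentrations (g kg-1), internal
    efficiencies (kg kg-1) and per-tonne requirements (kg t-1).
    """

    n: float
    p: float
    k: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n, self.p, self.k], dtype=float)

    def __getitem__(self, nutrient: str) -> float:
        return getattr(self, nutrient.lower())

    def __iter__(self):
        return iter((self.n, self.p, self.k))

    @classmethod
    def from_mapping(cls, m) -> "NutrientTriple":
        return cls(float(m["n"]), float(m["p"]), float(m["k"]))

    def validate_nonnegative(self, what: str = "value") -> None:
        for x, v in zip(NUTRIENTS, self):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{what} for {x.upper()} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class NutrientHarvestIndex:
    """Seed nutrient content over total above-ground content, per nutrient."""

    hi_n: float
    hi_p: float
    hi_k: float

    def __post_init__(self):
        for name in ("hi_n", "hi_p", "hi_k"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class Observation:
    """One plot-level record.

    seed_yield is on a 13.5 %-moisture basis (configurable when deriving dry
    matter); straw_dm is oven-dry.  Concentrations are g kg-1 of the
    respective dry matter; uptake, when stored, is total above-ground
    kg ha-1.
    """

    site_id: str
    year: int
    treatment: str = ""
    seed_yield: float | None = None
    straw_dm: float | None = None
    conc_seed: NutrientTriple | None = None
    conc_straw: NutrientTriple | None = None
    uptake: NutrientTriple | None = None
    hi: float | None = None

    def __post_init__(self):
        for name in ("seed_yield", "straw_dm"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.hi is not None and not (0.0 < self.hi < 1.0):
            raise ValueError(f"hi must lie in (0, 1), got {self.hi}")
        for name in ("conc_seed", "conc_straw", "uptake"):
            t = getattr(self, name)
            if t is not None:
                t.validate_nonnegative(name)


@dataclass(frozen=True)
class SummaryStats:
    """Seven-number summary: n, mean, SD (n-1), min, quartiles, max."""

    n_obs: int
    mean: float
    sd: float
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float

    def __post_init__(self):
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        order = (self.minimum, self.q25, self.median, self.q75, self.maximum)
        if any(a > b + 1e-12 for a, b in zip(order, order[1:])):
            raise ValueError("order statistics out of order")


def seed_dry_matter(obs: Observation,
                    moisture_fraction: float = DEFAULT_MOISTURE_FRACTION) -> float:
    """Oven-dry seed mass (kg ha-1) from the moist commercial yield."""
    if obs.seed_yield is None:
        raise InsufficientDataError(f"{obs.site_id}/{obs.year}: seed_yield missing")
    return obs.seed_yield * (1.0 - moisture_fraction)


def compute_uptake(obs: Observation,
                   moisture_fraction: float = DEFAULT_MOISTURE_FRACTION) -> NutrientTriple:
    """Total above-ground uptake (kg ha-1) from concentrations and dry weights.

    uptake_x = conc_seed_x * seed_dm / 1000 + conc_straw_x * straw_dm / 1000,
    with seed dry matter derived from the moist yield.

    Raises
    ------
    InsufficientDataError
        If any concentration or dry weight needed is missing.  Missing data
        are never silently treated as zero.
    """
    if obs.conc_seed is None or obs.conc_straw is None:
        raise InsufficientDataError(
            f"{obs.site_id}/{obs.year}: seed and straw concentrations required")
    if obs.straw_dm is None:
        raise InsufficientDataError(f"{obs.site_id}/{obs.year}: straw_dm missing")
    sdm = seed_dry_matter(obs, moisture_fraction)
    vals = [obs.conc_seed[x] * sdm / 1000.0 + obs.conc_straw[x] * obs.straw_dm / 1000.0
            for x in NUTRIENTS]
    return NutrientTriple(*vals)


def resolve_uptake(obs: Observation,
                   moisture_fraction: float = DEFAULT_MOISTURE_FRACTION) -> NutrientTriple:
    """Stored uptake if present, else recomputed; fail loud on conflict.

    When a record carries both raw concentrations+weights and a stored
    uptake, the two must agree within ``UPTAKE_CONSISTENCY_RTOL`` relative,
    otherwise the record is rejected.
    """
    recomputable = (obs.conc_seed is not None and obs.conc_straw is not None
                    and obs.straw_dm is not None and obs.seed_yield is not None)
    if obs.uptake is not None and recomputable:
        recomputed = compute_uptake(obs, moisture_fraction)
        for x in NUTRIENTS:
            stored, calc = obs.uptake[x], recomputed[x]
            scale = max(abs(stored), abs(calc), 1e-12)
            if abs(stored - calc) / scale > UPTAKE_CONSISTENCY_RTOL:
                raise ValueError(
                    f"{obs.site_id}/{obs.year}: stored uptake_{x}={stored:g} "
                    f"inconsistent with recomputed {calc:g}")
        return obs.uptake
    if obs.uptake is not None:
        return obs.uptake
    if recomputable:
        return compute_uptake(obs, moisture_fraction)
    raise InsufficientDataError(
        f"{obs.site_id}/{obs.year}: neither uptake nor concentrations+weights present")


def compute_ie_rie(obs: Observation,
                   moisture_fraction: float = DEFAULT_MOISTURE_FRACTION,
                   ) -> tuple[NutrientTriple, NutrientTriple]:
    """Internal efficiency and its reciprocal for one record.

    IE_x = seed_yield / uptake_x (kg seed per kg nutrient, yield on the
    commercial-moisture basis); RIE_x = 1000 / IE_x (kg nutrient per tonne
    of seed).  IE * RIE == 1000 identically.

    Zero yield gives IE = (0,0,0) and undefined RIE (NaN).  Zero uptake in
    any nutrient makes IE undefined and raises.
    """
    if obs.seed_yield is None:
        raise InsufficientDataError(f"{obs.site_id}/{obs.year}: seed_yield missing")
    u = resolve_uptake(obs, moisture_fraction)
    if obs.seed_yield == 0:
        logger.warning("%s/%s: zero yield, RIE undefined", obs.site_id, obs.year)
        nan = float("nan")
        return NutrientTriple(0.0, 0.0, 0.0), NutrientTriple(nan, nan, nan)
    zero = [x for x in NUTRIENTS if u[x] == 0]
    if zero:
        raise UndefinedEfficiencyError(
            f"{obs.site_id}/{obs.year}: zero uptake for {','.join(zero).upper()}, IE undefined")
    ie = NutrientTriple(*[obs.seed_yield / u[x] for x in NUTRIENTS])
    rie = NutrientTriple(*[1000.0 / ie[x] for x in NUTRIENTS])
    return ie, rie


def compute_nutrient_hi(obs: Observation,
                        moisture_fraction: float = DEFAULT_MOISTURE_FRACTION,
                        ) -> NutrientHarvestIndex:
    """Nutrient harvest index: seed nutrient content over total content."""
    if obs.conc_seed is None or obs.conc_straw is None or obs.straw_dm is None:
        raise InsufficientDataError(
            f"{obs.site_id}/{obs.year}: concentrations and straw_dm required")
    sdm = seed_dry_matter(obs, moisture_fraction)
    his = []
    for x in NUTRIENTS:
        seed_content = obs.conc_seed[x] * sdm / 1000.0
        total = seed_content + obs.conc_straw[x] * obs.straw_dm / 1000.0
        if total == 0:
            raise UndefinedEfficiencyError(
                f"{obs.site_id}/{obs.year}: zero total {x.upper()} content")
        if seed_content > total * (1 + 1e-12):
            raise ValueError("seed nutrient content exceeds total")
        hi = seed_content / total
        if hi == 0:
            logger.warning("%s/%s: nutrient HI of 0 for %s (no nutrient in seed)",
                           obs.site_id, obs.year, x.upper())
        his.append(min(hi, 1.0))
    return NutrientHarvestIndex(*his)


def filter_by_hi(table: Sequence[Observation],
                 threshold: float = DEFAULT_HI_THRESHOLD,
                 keep_missing: bool = False) -> list[Observation]:
    """Keep records with HI >= threshold ("less than threshold" excluded).

    Records lacking an HI are excluded unless ``keep_missing``; counts of
    removals are logged.  Order-preserving and idempotent.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    kept, n_low, n_missing = [], 0, 0
    for obs in table:
        if obs.hi is None:
            if keep_missing:
                kept.append(obs)
            else:
                n_missing += 1
        elif obs.hi >= threshold:
            kept.append(obs)
        else:
            n_low += 1
    logger.info("HI filter (>= %.2f): kept %d, removed %d low-HI, %d missing-HI",
                threshold, len(kept), n_low, n_missing)
    return kept


def summarize(values: Iterable[float]) -> SummaryStats:
    """Seven-number summary in the layout of the field-trial tables.

    SD is the sample standard deviation (n-1 denominator; 0 for a single
    value by convention).  Quartiles use linear interpolation between order
    statistics at rank p*(n-1) — the convention the envelope calibration
    relies on as well.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("summarize requires finite values")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n_obs=int(arr.size), mean=float(arr.mean()), sd=sd,
        minimum=float(arr.min()), q25=float(q25), median=float(med),
        q75=float(q75), maximum=float(arr.max()))


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "site_id", "year", "treatment", "seed_yield_kg_ha", "straw_dm_kg_ha",
    "n_seed_g_kg", "p_seed_g_kg", "k_seed_g_kg",
    "n_straw_g_kg", "p_straw_g_kg", "k_straw_g_kg",
    "n_uptake_kg_ha", "p_uptake_kg_ha", "k_uptake_kg_ha", "hi",
]


def _triple_from_row(row, fmt: str) -> NutrientTriple | None:
    vals = [row[fmt.format(x)] for x in NUTRIENTS]
    if all(pd.isna(v) for v in vals):
        return None
    if any(pd.isna(v) for v in vals):
        raise ValueError(f"partial nutrient triple in columns {fmt.format('*')}")
    return NutrientTriple(*[float(v) for v in vals])


def read_observations(path) -> list[Observation]:
    """Read plot records from the documented CSV schema (UTF-8, empty=missing)."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(Observation(
            site_id=str(row["site_id"]),
            year=int(row["year"]),
            treatment="" if pd.isna(row["treatment"]) else str(row["treatment"]),
            seed_yield=None if pd.isna(row["seed_yield_kg_ha"]) else float(row["seed_yield_kg_ha"]),
            straw_dm=None if pd.isna(row["straw_dm_kg_ha"]) else float(row["straw_dm_kg_ha"]),
            conc_seed=_triple_from_row(row, "{}_seed_g_kg"),
            conc_straw=_triple_from_row(row, "{}_straw_g_kg"),
            uptake=_triple_from_row(row, "{}_uptake_kg_ha"),
            hi=None if pd.isna(row["hi"]) else float(row["hi"]),
        ))
    return out


def write_observations(table: Sequence[Observation], path) -> None:
    rows = []
    for o in table:
        row = {
            "site_id": o.site_id, "year": o.year, "treatment": o.treatment,
            "seed_yield_kg_ha": o.seed_yield, "straw_dm_kg_ha": o.straw_dm,
            "hi": o.hi,
        }
        for attr, fmt in (("conc_seed", "{}_seed_g_kg"),
                          ("conc_straw", "{}_straw_g_kg"),
                          ("uptake", "{}_uptake_kg_ha")):
            t = getattr(o, attr)
            for x in NUTRIENTS:
                row[fmt.format(x)] = None if t is None else t[x]
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, encoding="utf-8")


def dataset_ies(table: Sequence[Observation],
                moisture_fraction: float = DEFAULT_MOISTURE_FRACTION,
                ) -> dict[str, np.ndarray]:
    """Per-nutrient arrays of IE values over a dataset (records lacking the
    inputs, or with zero yield/uptake, are skipped with a log message)."""
    vals: dict[str, list[float]] = {x: [] for x in NUTRIENTS}
    n_skipped = 0
    for obs in table:
        try:
            ie, _ = compute_ie_rie(obs, moisture_fraction)
        except (InsufficientDataError, UndefinedEfficiencyError):
            n_skipped += 1
            continue
        if obs.seed_yield == 0:
            n_skipped += 1
            continue
        for x in NUTRIENTS:
            vals[x].append(ie[x])
    if n_skipped:
        logger.info("IE extraction: skipped %d records without usable IE", n_skipped)
    return {x: np.asarray(v, dtype=float) for x, v in vals.items()}
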