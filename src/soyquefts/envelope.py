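"""Accumulation/dilution envelope calibration from IE distributions.

The envelope coefficient *a* (maximum accumulation) is the lower percentile
of the observed internal efficiencies and *d* (maximum dilution) the upper
percentile, computed per nutrient after symmetric exclusion of the
distribution tails: 2.5/97.5 % (Set I), 5/95 % (Set II) or 7.5/92.5 %
(Set III).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .dataset import NUTRIENTS, NutrientTriple

#: Minimum IE values per nutrient before a percentile envelope is trusted.
DEFAULT_MIN_OBSERVATIONS = 20


@dataclass(frozen=True)
class EnvelopeCoefficients:
    """Per-nutrient IE bounds, kg seed per kg nutrient (0 < a_x < d_x)."""

    a: NutrientTriple
    d: NutrientTriple

    def __post_init__(self):
        for x in NUTRIENTS:
            if not (0.0 < self.a[x] < self.d[x]):
                raise ValueError(
                    f"invalid envelope for {x.upper()}: need 0 < a < d, "
                    f"got a={self.a[x]}, d={self.d[x]}")

    @classmethod
    def from_pairs(cls, n: tuple[float, float], p: tuple[float, float],
                   k: tuple[float, float]) -> "EnvelopeCoefficients":
        return cls(a=NutrientTriple(n[0], p[0], k[0]),
                   d=NutrientTriple(n[1], p[1], k[1]))


#: Envelope coefficients calibrated on the 2001-2015 China soybean dataset
#: with 2.5/97.5 % exclusion (Set I) — the configuration used for the
#: headline requirement estimates.
SOYBEAN_SET_I = EnvelopeCoefficients.from_pairs(
    n=(13.5, 21.4), p=(60.4, 234.6), k=(27.8, 79.9))


@dataclass(frozen=True)
class PercentileSet:
    """A symmetric percentile-exclusion rule, e.g. Set I = (2.5, 97.5)."""

    label: str
    lower_pct: float
    upper_pct: float

    def __post_init__(self):
        if not (0.0 < self.lower_pct < self.upper_pct < 100.0):
            raise ValueError(
                f"need 0 < lower < upper < 100, got {self.lower_pct}, {self.upper_pct}")


def build_standard_sets() -> list[PercentileSet]:
    """The three standard symmetric exclusions: I, II, III."""
    return [
        PercentileSet("I", 2.5, 97.5),
        PercentileSet("II", 5.0, 95.0),
        PercentileSet("III", 7.5, 92.5),
    ]


def standard_set(label: str) -> PercentileSet:
    for s in build_standard_sets():
        if s.label == label.upper():
            return s
    raise KeyError(f"unknown percentile set {label!r}; expected I, II or III")


def calibrate_envelope(ie_values: Mapping[str, Sequence[float]],
                       pset: PercentileSet,
                       min_observations: int = DEFAULT_MIN_OBSERVATIONS,
                       ) -> EnvelopeCoefficients:
    """Percentile envelope of per-nutrient IE samples.

    a_x is the ``lower_pct``-th and d_x the ``upper_pct``-th percentile of
    the IE_x sample, with linear interpolation between order statistics at
    rank p*(n-1).  Invariant to input order and to duplication of the whole
    sample.

    Raises
    ------
    ValueError
        If a nutrient has fewer than ``min_observations`` values, any value
        is non-positive/non-finite, or the resulting envelope is degenerate
        (a >= d).
    """
    lows, highs = [], []
    for x in NUTRIENTS:
        vals = np.asarray(list(ie_values[x]), dtype=float)
        if vals.size < min_observations:
            raise ValueError(
                f"need at least {min_observations} IE values for {x.upper()}, "
                f"got {vals.size}")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"IE values for {x.upper()} must be positive finite")
        lo, hi = np.percentile(vals, [pset.lower_pct, pset.upper_pct])
        if not lo < hi:
            raise ValueError(
                f"degenerate IE distribution for {x.upper()}: "
                f"{pset.lower_pct}th percentile {lo:g} >= {pset.upper_pct}th {hi:g}")
        lows.append(float(lo))
        highs.append(float(hi))
    return EnvelopeCoefficients(a=NutrientTriple(*lows), d=NutrientTriple(*highs))


# ---------------------------------------------------------------------------
# YAML persistence
# ---------------------------------------------------------------------------

def envelope_to_yaml(env: EnvelopeCoefficients, path, *, set_label: str | None = None,
                     n_used: int | None = None, provenance: bytes | None = None) -> None:
    doc = {
        "a": {x: float(env.a[x]) for x in NUTRIENTS},
        "d": {x: float(env.d[x]) for x in NUTRIENTS},
    }
    if set_label is not None:
        doc["set"] = set_label
    if n_used is not None:
        doc["n"] = int(n_used)
    if provenance is not None:
        doc["input_sha256"] = hashlib.sha256(provenance).hexdigest()
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def envelope_from_yaml(path) -> EnvelopeCoefficients:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return EnvelopeCoefficients(a=NutrientTriple.from_mapping(doc["a"]),
                                d=NutrientTriple.from_mapping(doc["d"]))
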