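"""Agreement statistics between simulated and measured uptakes.

RMSE = sqrt(mean((s_i - m_i)^2)) in the units of the series;
normalized RMSE = 100 * RMSE / mean(measured), in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PairedSeries:
    """Paired simulated/measured values (kg ha-1), equal length, n >= 1."""

    simulated: np.ndarray
    measured: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.simulated, dtype=float)
        m = np.asarray(self.measured, dtype=float)
        if s.ndim != 1 or m.ndim != 1:
            raise ValueError("paired series must be one-dimensional")
        if s.shape != m.shape:
            raise ValueError(f"length mismatch: {s.size} simulated vs {m.size} measured")
        if s.size < 1:
            raise ValueError("paired series require n >= 1")
        object.__setattr__(self, "simulated", s)
        object.__setattr__(self, "measured", m)

    @property
    def n(self) -> int:
        return int(self.simulated.size)

    @property
    def m_bar(self) -> float:
        return float(self.measured.mean())


def rmse(pairs: PairedSeries) -> float:
    """Root mean square error, same units as the inputs."""
    diff = pairs.simulated - pairs.measured
    return float(np.sqrt(np.mean(diff * diff)))


def n_rmse(pairs: PairedSeries) -> float:
    """Normalized RMSE as a percentage of the measured mean.

    Invariant under a common rescaling of both series; undefined (raises)
    when the measured mean is zero.
    """
    if pairs.m_bar == 0:
        raise ValueError("normalized RMSE undefined: measured mean is zero")
    return 100.0 * rmse(pairs) / pairs.m_bar


def paired_summary(series_by_nutrient: dict[str, PairedSeries]) -> pd.DataFrame:
    """Per-nutrient RMSE, n-RMSE, n and mean bias (simulated - measured).

    A descriptive table only; no inferential claims attached.
    """
    rows = []
    for nutrient, pairs in series_by_nutrient.items():
        rows.append({
            "nutrient": nutrient.upper(),
            "n": pairs.n,
            "rmse_kg_ha": rmse(pairs),
            "n_rmse_pct": n_rmse(pairs),
            "mean_bias_kg_ha": float(np.mean(pairs.simulated - pairs.measured)),
        })
    return pd.DataFrame(rows)
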