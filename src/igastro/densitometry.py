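"""Dilution-corrected gel-band quantification and intact-protein kinetics.

Densitometry of SDS-PAGE bands (kappa-casein, alpha-s-casein, beta-casein,
beta-lactoglobulin, alpha-lactalbumin, ...) tracks intact protein over
digestion. Because gastric secretion continuously dilutes the chyme, raw
band intensities understate the intact fraction; each time point is
multiplied by a dilution factor before normalizing to the t = 0 lane:

    residual(band, t) = intensity(band, t) * DF(t) / intensity(band, 0)

DF(t) comes from the simulator's mass ledger (chyme mass over what the
chyme mass would be with the resident secretion removed) or can be supplied
explicitly. Residuals above 1 (noise) are kept, with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulator import GastricTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "BandIntensityTable",
    "dilution_factor",
    "residual_intact",
    "hydrolysis_halftime",
    "HalfTime",
]


@dataclass
class BandIntensityTable:
    """Band x time matrix of densitometry intensities with dilution factors."""

    bands: list[str]
    times: list[float]
    intensities: np.ndarray  # shape (n_bands, n_times)
    dilution_factors: np.ndarray | None = None  # per time; >= 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.bands), len(self.times)):
            raise ValueError("intensities must be shaped (n_bands, n_times)")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if not any(t == 0 for t in self.times):
            raise ValueError("a t = 0 column is required")
        if self.dilution_factors is None:
            self.dilution_factors = np.ones(len(self.times))
        else:
            self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
            if self.dilution_factors.shape != (len(self.times),):
                raise ValueError("one dilution factor per time point required")
            if np.any(self.dilution_factors < 1):
                raise ValueError("dilution factors must be >= 1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "") -> "BandIntensityTable":
        """Build from a tidy table with columns band, time_min, intensity."""
        pivot = df.pivot_table(index="band", columns="time_min", values="intensity")
        return cls(
            bands=list(pivot.index),
            times=[float(t) for t in pivot.columns],
            intensities=pivot.to_numpy(),
            sample_id=sample_id,
        )

    def with_dilution_from(self, ts: GastricTimeSeries) -> "BandIntensityTable":
        factors = np.array([dilution_factor(ts, t) for t in self.times])
        return BandIntensityTable(
            bands=self.bands,
            times=self.times,
            intensities=self.intensities,
            dilution_factors=factors,
            sample_id=self.sample_id,
        )


def dilution_factor(ts: GastricTimeSeries, t: float) -> float:
    """Secretion dilution of the chyme at time ``t``, from the mass ledger.

    Ratio of the chyme mass to the chyme mass with resident secretion
    removed; 1.0 at t = 0 and whenever secretion flows are zero.
    """
    s = ts.state_at(t)
    if s.resident_secretion_g == 0:
        return 1.0
    undiluted = s.chyme_mass_g - s.resident_secretion_g
    if undiluted <= 0:
        raise ValueError(f"no non-secretion mass left in chyme at t = {t} min")
    return s.chyme_mass_g / undiluted


def residual_intact(table: BandIntensityTable) -> pd.DataFrame:
    """Dilution-corrected intact fraction per band and time.

    Bands with zero t = 0 intensity get NaN (undefined, not zero); residuals
    above 1 are retained with a warning.
    """
    times = np.asarray(table.times)
    i0_col = int(np.flatnonzero(times == 0)[0])
    i0 = table.intensities[:, i0_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        residual = table.intensities * table.dilution_factors[None, :] / i0[:, None]
    residual[i0 == 0, :] = np.nan
    if np.any(i0 == 0):
        logger.warning("bands with zero t=0 intensity reported as undefined (NaN)")
    if np.nanmax(residual, initial=0.0) > 1.0:
        logger.warning("residual intact fraction exceeds 1 at some points (noise)")
    return pd.DataFrame(residual, index=table.bands, columns=table.times)


@dataclass(frozen=True)
class HalfTime:
    """First crossing of residual = 0.5, or censored if never reached."""

    band: str
    time_min: float | None
    censored: bool
    at_boundary: bool = False


def hydrolysis_halftime(
    residual: pd.Series | np.ndarray, times=None, band: str = ""
) -> HalfTime:
    """Linear-interpolated first crossing of the 50% intact level.

    A series that never falls below 0.5 within the digestion window is
    censored; one that starts at or below 0.5 crosses at the t = 0 boundary
    and is flagged.
    """
    if isinstance(residual, pd.Series):
        times = np.asarray(residual.index, dtype=float)
        band = band or str(residual.name or "")
        values = residual.to_numpy(dtype=float)
    else:
        values = np.asarray(residual, dtype=float)
        times = np.asarray(times, dtype=float)
    if values[0] <= 0.5:
        return HalfTime(band=band, time_min=float(times[0]), censored=False, at_boundary=True)
    for (t0, t1), (r0, r1) in zip(
        zip(times[:-1], times[1:]), zip(values[:-1], values[1:])
    ):
        if r1 <= 0.5 < r0:
            crossing = t0 + (r0 - 0.5) / (r0 - r1) * (t1 - t0)
            return HalfTime(band=band, time_min=float(crossing), censored=False)
    return HalfTime(band=band, time_min=None, censored=True)
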