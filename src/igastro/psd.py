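"""Particle-size distributions, d4,3, and colloidal destabilization indices.

Laser-diffraction instruments report a volume density over log-spaced
diameter bins. The volume-weighted mean diameter is the moment ratio
d4,3 = sum(n_i d_i^4) / sum(n_i d_i^3), which on a binned volume density
reduces to the volume-weighted mean of the bin midpoint diameters
(geometric midpoints, matching log-spaced binning).

Two dispersant "dialects" are measured: plain water, and SDS (1% w/w) +
EDTA (50 mM) buffer, which dissolves casein micelles and protein-mediated
flocs. Comparing the two separates flocculation from true oil-droplet
coalescence:

* Aggregation Index  AI = (d43_chyme - d43_initial) / d43_initial, on
  water-dispersed measurements (flocculation + coalescence).
* Coalescence Index  CI = same ratio on buffer-dispersed measurements
  (coalescence only; flocs are dissolved before sizing).

Both are relative to the undigested formula at t = 0 and may be slightly
negative with measurement noise (reported as-is, with a warning).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "Dispersant",
    "ParticleSizeDistribution",
    "D43Value",
    "FlowCurveFit",
    "d43",
    "aggregation_index",
    "coalescence_index",
    "FlowCurveModel",
    "fit_flow_curve",
]


class Dispersant(str, enum.Enum):
    water = "water"
    sds_edta = "sds_edta"


@dataclass
class ParticleSizeDistribution:
    """Binned relative volume density over strictly increasing diameter bins."""

    bin_edges_um: np.ndarray
    volume_density: np.ndarray
    dispersant: Dispersant = Dispersant.water
    sample_id: str = ""
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges_um = np.asarray(self.bin_edges_um, dtype=float)
        self.volume_density = np.asarray(self.volume_density, dtype=float)
        self.dispersant = Dispersant(self.dispersant)
        edges, dens = self.bin_edges_um, self.volume_density
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if np.any(edges <= 0) or np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be positive and strictly increasing")
        if dens.shape != (edges.size - 1,):
            raise ValueError("volume_density must have len(bin_edges) - 1 entries")
        if np.any(dens < 0):
            raise ValueError("volume_density must be non-negative")
        total = dens.sum()
        if total <= 0:
            raise ValueError("volume_density must have positive total")
        self.volume_density = dens / total

    @property
    def midpoints_um(self) -> np.ndarray:
        """Geometric bin midpoints (log-spaced binning convention)."""
        return np.sqrt(self.bin_edges_um[:-1] * self.bin_edges_um[1:])


@dataclass(frozen=True)
class D43Value:
    """A volume-weighted mean diameter with its measurement context."""

    value_um: float
    dispersant: Dispersant
    time_min: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.value_um <= 0:
            raise ValueError("d4,3 must be positive")


def d43(psd: ParticleSizeDistribution) -> D43Value:
    """Volume-weighted mean diameter (um) of a binned distribution.

    Equals sum(v_i * d_i) / sum(v_i) over bin midpoints d_i, which is the
    n_i d_i^4 / n_i d_i^3 moment ratio since v_i is proportional to
    n_i d_i^3.
    """
    v, d = psd.volume_density, psd.midpoints_um
    return D43Value(
        value_um=float(np.sum(v * d) / np.sum(v)),
        dispersant=psd.dispersant,
        time_min=psd.time_min,
        sample_id=psd.sample_id,
    )


def _index(chyme: D43Value, initial: D43Value, expect: Dispersant, name: str) -> float:
    if chyme.dispersant != expect or initial.dispersant != expect:
        raise ValueError(
            f"{name} requires both d4,3 values measured in {expect.value} "
            f"(got {chyme.dispersant.value}, {initial.dispersant.value})"
        )
    value = (chyme.value_um - initial.value_um) / initial.value_um
    if value < 0:
        logger.warning("%s is negative (%.3g); reported as-is", name, value)
    return value


def aggregation_index(d43_chyme: D43Value, d43_initial: D43Value) -> float:
    """AI: relative d4,3 increase of water-dispersed chyme over the t=0 formula."""
    return _index(d43_chyme, d43_initial, Dispersant.water, "AI")


def coalescence_index(d43_chyme_buf: D43Value, d43_initial_buf: D43Value) -> float:
    """CI: same relative increase on SDS+EDTA-dispersed measurements."""
    return _index(d43_chyme_buf, d43_initial_buf, Dispersant.sds_edta, "CI")


@dataclass(frozen=True)
class FlowCurveFit:
    """Power-law fit eta = K * gammadot^(n-1) with a rheological class."""

    K_mPas: float
    n: float
    classification: str
    r_squared: float

    def summary(self) -> str:
        return (
            f"Power-law flow curve: K = {self.K_mPas:.4g} mPa.s^n, "
            f"n = {self.n:.3f} ({self.classification}), R^2 = {self.r_squared:.4f}"
        )


class FlowCurveModel:
    """Ordinary least squares on log(eta) = log(K) + (n-1) log(gammadot)."""

    def __init__(self, shear_rates, viscosities_mPas, newtonian_tol: float = 0.05):
        g = np.asarray(shear_rates, dtype=float)
        eta = np.asarray(viscosities_mPas, dtype=float)
        if g.size < 3 or g.shape != eta.shape:
            raise ValueError("need >= 3 paired points")
        if np.any(g <= 0):
            raise ValueError("shear rates must be positive")
        if np.any(eta <= 0):
            raise ValueError("viscosities must be positive")
        self.shear_rates = g
        self.viscosities = eta
        self.newtonian_tol = newtonian_tol

    def fit(self) -> FlowCurveFit:
        res = stats.linregress(np.log(self.shear_rates), np.log(self.viscosities))
        n = 1.0 + res.slope
        if abs(n - 1.0) <= self.newtonian_tol:
            cls = "newtonian"
        elif n < 1.0:
            cls = "shear_thinning"
        else:
            cls = "shear_thickening"
        r2 = 1.0 if np.ptp(np.log(self.viscosities)) == 0 else float(res.rvalue**2)
        return FlowCurveFit(
            K_mPas=float(np.exp(res.intercept)), n=float(n), classification=cls, r_squared=r2
        )


def fit_flow_curve(shear_rates, viscosities_mPas, newtonian_tol: float = 0.05) -> FlowCurveFit:
    """Convenience wrapper around :class:`FlowCurveModel`."""
    return FlowCurveModel(shear_rates, viscosities_mPas, newtonian_tol).fit()
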