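"""Study configuration: formula composition, digestion protocol, buffering.

The dynamic infant gastric simulator (iHGS) protocol is parameterized here
field-for-field: a 100 g reconstituted-formula meal is mixed with 10 g of
basal simulated gastric fluid (SGF, pH 3.0), secretions (1.25x SGF at
0.4 mL/min and an enzyme solution at 0.1 mL/min) run continuously, and 22 g
of gastric content is withdrawn through a 1 mm sieve every 20 min over a
160 min digestion at 37 degC.

All streams are treated as density 1 g/mL, so gram and millilitre figures
are interchangeable throughout.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class ProfileClass(str, enum.Enum):
    """Colloidal profile of a formula, which drives its gastric fate."""

    casein_dominant = "casein_dominant"
    whey_dominant = "whey_dominant"
    biopolymer_whey = "biopolymer_whey"


class Nutrient(str, enum.Enum):
    protein = "protein"
    lipid = "lipid"
    total = "total"


class CurdParams(BaseModel):
    """Time course of the sieve-retained (curd) fraction of one nutrient.

    The curd fraction f(t) is zero before ``onset`` and rises as
    ``plateau * (1 - exp(-rate * (t - onset)))`` afterwards: monotone
    non-decreasing, saturating at ``plateau``. Casein-dominant formulae
    coagulate early with a high plateau; whey-dominant ones late and low.
    """

    model_config = ConfigDict(extra="forbid")

    onset_min: float = Field(0.0, ge=0.0)
    rate_per_min: float = Field(0.0, ge=0.0)
    plateau: float = Field(0.0, ge=0.0, le=1.0)

    def fraction(self, t: float) -> float:
        """Curd fraction at time ``t`` (min), in [0, plateau]."""
        import math

        if t <= self.onset_min or self.rate_per_min == 0.0 or self.plateau == 0.0:
            return 0.0
        return self.plateau * (1.0 - math.exp(-self.rate_per_min * (t - self.onset_min)))


class FormulaSpec(BaseModel):
    """Composition and colloidal profile of one reconstituted infant formula."""

    model_config = ConfigDict(extra="forbid")

    name: str
    protein_frac: float = Field(..., gt=0.0, lt=1.0, description="g protein per g formula")
    fat_frac: float = Field(..., ge=0.0, lt=1.0, description="g fat per g formula")
    whey_casein_ratio: tuple[float, float] = (60.0, 40.0)
    profile: ProfileClass = ProfileClass.whey_dominant
    curd_protein: CurdParams = Field(default_factory=CurdParams)
    curd_lipid: CurdParams = Field(default_factory=CurdParams)

    @model_validator(mode="after")
    def _check_ratio(self) -> "FormulaSpec":
        whey, casein = self.whey_casein_ratio
        if whey < 0 or casein < 0 or abs(whey + casein - 100.0) > 1e-6:
            raise ValueError(
                f"whey:casein parts must be non-negative and sum to 100, got {self.whey_casein_ratio}"
            )
        return self


class DigestionProtocol(BaseModel):
    """Operating parameters of the dynamic gastric digestion run.

    Defaults reproduce the infant protocol: secretion streams sum to
    0.5 mL/min, emptying removes 22 g per 20 min interval, and the sieve
    retains particles above 1000 um (1 mm).
    """

    model_config = ConfigDict(extra="forbid")

    meal_mass_g: float = Field(100.0, gt=0.0)
    basal_sgf_mass_g: float = Field(10.0, ge=0.0)
    sgf_flow_ml_min: float = Field(0.4, ge=0.0)
    enzyme_flow_ml_min: float = Field(0.1, ge=0.0)
    emptying_mass_g: float = Field(22.0, gt=0.0)
    emptying_interval_min: float = Field(20.0, gt=0.0)
    total_time_min: float = Field(160.0, ge=0.0)
    sieve_cutoff_um: float = Field(1000.0, gt=0.0)
    sampling_times_min: tuple[float, ...] = (15.0, 40.0, 80.0, 120.0, 160.0)
    pepsin_activity_u_ml: float = Field(651.0, gt=0.0)
    lipase_activity_u_ml: float = Field(60.0, gt=0.0)
    sgf_ph: float = Field(2.0, gt=0.0)
    basal_sgf_ph: float = Field(3.0, gt=0.0)
    temperature_c: float = Field(37.0, gt=0.0)

    @model_validator(mode="after")
    def _check_sampling(self) -> "DigestionProtocol":
        for t in self.sampling_times_min:
            if not (0.0 <= t <= self.total_time_min):
                raise ValueError(
                    f"sampling time {t} min outside [0, {self.total_time_min}] min"
                )
        return self

    @property
    def secretion_rate_g_min(self) -> float:
        """Total secretion mass flow (g/min), density 1 g/mL."""
        return self.sgf_flow_ml_min + self.enzyme_flow_ml_min

    def emptying_times(self) -> list[float]:
        """Emptying events at t = interval, 2*interval, ... <= total_time."""
        n = int(self.total_time_min / self.emptying_interval_min + 1e-9)
        return [self.emptying_interval_min * (i + 1) for i in range(n)]


class BufferingParams(BaseModel):
    """Simplified linear titration model of chyme pH.

    pH(t) = max(min_ph, initial_ph - acid(t) / (buffer_capacity * protein(t))),
    where acid(t) is the cumulative H+ delivered by the SGF stream. This is a
    deliberate simplification used only for qualitative ordering (a higher
    buffering capacity, as in casein-dominant formulae, keeps pH higher); it
    is never fitted to measured pH data.
    """

    model_config = ConfigDict(extra="forbid")

    buffer_capacity: float = Field(
        1.0, ge=0.0, description="mmol H+ per pH unit per g protein in chyme"
    )
    acid_delivery: float = Field(0.1, ge=0.0, description="mmol H+ per mL SGF")
    min_ph: float = Field(2.0, gt=0.0)
    initial_ph: float = Field(6.8, gt=0.0)


def load_protocol(path: str) -> DigestionProtocol:
    """Read a protocol configuration from a YAML file (unknown keys rejected)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DigestionProtocol(**data)


def load_formula(path: str) -> FormulaSpec:
    """Read a formula specification from a YAML file (unknown keys rejected)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return FormulaSpec(**data)
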