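"""Synthetic study generator for the digestion-analysis pipeline.

Generates complete, schema-valid studies — formula specs, particle-size
distribution (PSD) time courses in both dispersants, retention observations
and gel-band intensity tables — with the statistical structure the analysis
assumes, so every pipeline stage can be exercised and parameter recovery
verified without any measured data.

Three profile templates encode the qualitative behaviours of the formula
classes:

* ``casein_dominant`` — early destabilization (coarsening from 15 min),
  heavy curd, slow emptying (protein kappa ~11e-3/min).
* ``whey_dominant`` — late destabilization (from 80 min), little curd, fast
  emptying (protein kappa ~16e-3/min).
* ``biopolymer_whey`` — thickener-stabilized: multimodal initial PSD that
  persists in SDS+EDTA buffer, fast protein but depressed lipid emptying.

Numeric anchors (onsets, kappa scales, initial d4,3 values) are defaults
and fully overridable. PSD noise is multiplicative log-normal per bin and
renormalized; retention noise is additive Gaussian clamped to [0, 110]%.
All randomness flows from an explicit seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import RetentionCurve, elashoff
from .densitometry import BandIntensityTable
from .protocol import CurdParams, FormulaSpec, ProfileClass
from .psd import Dispersant, ParticleSizeDistribution

__all__ = [
    "PsdMode",
    "CoarseningParams",
    "ProfileTemplate",
    "default_templates",
    "lognormal_bin_weights",
    "calibrated_lognormal_psd",
    "calibrated_bimodal_psd",
    "synth_psd_series",
    "synth_retention",
    "synth_band_table",
    "StudyBundle",
    "synth_study",
]

BANDS = ("kappa_casein", "alpha_s_casein", "beta_casein", "beta_LG", "alpha_LA")

#: lognormal volume-mean factor: mean = median * exp(ln(gsd)^2 / 2)
def _mode_mean(median_um: float, gsd: float) -> float:
    return median_um * math.exp(0.5 * math.log(gsd) ** 2)


@dataclass(frozen=True)
class PsdMode:
    """One lognormal mode of a volume-density distribution."""

    median_um: float
    gsd: float
    volume_frac: float

    @property
    def mean_um(self) -> float:
        return _mode_mean(self.median_um, self.gsd)


@dataclass(frozen=True)
class CoarseningParams:
    """Growth of a coarse mode after a destabilization onset.

    The coarse-mode volume fraction rises as
    ``plateau_frac * (1 - exp(-rate * (t - onset)))`` past the onset — a
    saturating trajectory that, combined with the flat early phase, gives
    index-vs-emptied traces their plateau-then-rise (hinge) shape.
    """

    onset_min: float
    rate_per_min: float
    plateau_frac: float
    coarse_median_um: float
    coarse_gsd: float = 1.8

    def coarse_frac(self, t: float) -> float:
        if t <= self.onset_min or self.rate_per_min == 0 or self.plateau_frac == 0:
            return 0.0
        return self.plateau_frac * (1.0 - math.exp(-self.rate_per_min * (t - self.onset_min)))


@dataclass
class ProfileTemplate:
    """All true parameters of one synthetic formula profile."""

    profile: ProfileClass
    initial_modes: dict[Dispersant, tuple[PsdMode, ...]]
    aggregation: CoarseningParams  # water dialect
    coalescence: CoarseningParams  # SDS+EDTA dialect
    kappa_protein: float  # per min
    kappa_lipid: float
    beta: float = 1.0
    protein_frac: float = 0.017
    fat_frac: float = 0.039
    whey_casein_ratio: tuple[float, float] = (60.0, 40.0)
    curd_protein: CurdParams = field(default_factory=CurdParams)
    curd_lipid: CurdParams = field(default_factory=CurdParams)
    band_decay_per_min: dict[str, float] = field(default_factory=dict)
    band_initial: dict[str, float] = field(default_factory=dict)
    psd_noise_cv: float = 0.05
    retention_sigma_pct: float = 2.0
    intensity_cv: float = 0.05

    def to_formula(self, name: str) -> FormulaSpec:
        return FormulaSpec(
            name=name,
            protein_frac=self.protein_frac,
            fat_frac=self.fat_frac,
            whey_casein_ratio=self.whey_casein_ratio,
            profile=self.profile,
            curd_protein=self.curd_protein,
            curd_lipid=self.curd_lipid,
        )

    def true_params(self) -> dict:
        """Manifest entry for recovery tests."""
        return {
            "profile": self.profile.value,
            "kappa_protein": self.kappa_protein,
            "kappa_lipid": self.kappa_lipid,
            "beta": self.beta,
            "aggregation_onset_min": self.aggregation.onset_min,
            "coalescence_onset_min": self.coalescence.onset_min,
            "band_decay_per_min": dict(self.band_decay_per_min),
            "retention_sigma_pct": self.retention_sigma_pct,
        }


def _median_for_d43(target_um: float, gsd: float) -> float:
    return target_um / math.exp(0.5 * math.log(gsd) ** 2)


def default_templates() -> dict[ProfileClass, ProfileTemplate]:
    """The three profile templates with their default anchors.

    Initial d4,3 anchors: casein-dominant 0.78 um in water / 0.66 um in
    buffer; whey-dominant 0.86 / 0.75 um; biopolymer-stabilized bimodal
    with overall d4,3 near 60 um persisting in buffer (near 55 um).
    Emptying-rate anchors are the per-group means of reported kappa values
    (x1e-3/min): casein 11.0 (protein) / 9.8 (lipid); whey 16.2 / 15.3;
    biopolymer 16.4 / 11.0.
    """
    gsd = 1.5

    def mono(d43_um: float) -> tuple[PsdMode, ...]:
        return (PsdMode(_median_for_d43(d43_um, gsd), gsd, 1.0),)

    def bimodal(d43_um: float, fine_median=1.0, coarse_median=200.0) -> tuple[PsdMode, ...]:
        mean_f = _mode_mean(fine_median, gsd)
        mean_c = _mode_mean(coarse_median, gsd)
        w = (mean_c - d43_um) / (mean_c - mean_f)
        if not 0 < w < 1:
            raise ValueError("target d4,3 outside the bimodal hull")
        return (PsdMode(fine_median, gsd, w), PsdMode(coarse_median, gsd, 1 - w))

    casein = ProfileTemplate(
        profile=ProfileClass.casein_dominant,
        initial_modes={Dispersant.water: mono(0.78), Dispersant.sds_edta: mono(0.66)},
        aggregation=CoarseningParams(onset_min=15, rate_per_min=0.012, plateau_frac=0.95, coarse_median_um=60.0),
        coalescence=CoarseningParams(onset_min=15, rate_per_min=0.008, plateau_frac=0.30, coarse_median_um=15.0),
        kappa_protein=11.0e-3,
        kappa_lipid=9.8e-3,
        fat_frac=0.042,
        whey_casein_ratio=(30.0, 70.0),
        curd_protein=CurdParams(onset_min=15, rate_per_min=0.03, plateau=0.35),
        curd_lipid=CurdParams(onset_min=15, rate_per_min=0.025, plateau=0.28),
        band_decay_per_min={
            "kappa_casein": 0.15,
            "alpha_s_casein": 0.004,
            "beta_casein": 0.004,
            "beta_LG": 0.002,
            "alpha_LA": 0.006,
        },
        band_initial={
            "kappa_casein": 900,
            "alpha_s_casein": 2500,
            "beta_casein": 2600,
            "beta_LG": 700,
            "alpha_LA": 500,
        },
    )
    whey = ProfileTemplate(
        profile=ProfileClass.whey_dominant,
        initial_modes={Dispersant.water: mono(0.86), Dispersant.sds_edta: mono(0.75)},
        aggregation=CoarseningParams(onset_min=80, rate_per_min=0.015, plateau_frac=0.60, coarse_median_um=30.0),
        coalescence=CoarseningParams(onset_min=100, rate_per_min=0.010, plateau_frac=0.15, coarse_median_um=10.0),
        kappa_protein=16.2e-3,
        kappa_lipid=15.3e-3,
        fat_frac=0.038,
        whey_casein_ratio=(60.0, 40.0),
        curd_protein=CurdParams(onset_min=80, rate_per_min=0.02, plateau=0.08),
        curd_lipid=CurdParams(onset_min=100, rate_per_min=0.02, plateau=0.10),
        band_decay_per_min={
            "kappa_casein": 0.15,
            "alpha_s_casein": 0.040,
            "beta_casein": 0.040,
            "beta_LG": 0.015,
            "alpha_LA": 0.045,
        },
        band_initial={
            "kappa_casein": 500,
            "alpha_s_casein": 1200,
            "beta_casein": 1300,
            "beta_LG": 1800,
            "alpha_LA": 1500,
        },
    )
    biopolymer = ProfileTemplate(
        profile=ProfileClass.biopolymer_whey,
        initial_modes={
            Dispersant.water: bimodal(59.65),
            Dispersant.sds_edta: bimodal(54.62),
        },
        aggregation=CoarseningParams(onset_min=40, rate_per_min=0.004, plateau_frac=0.10, coarse_median_um=300.0),
        coalescence=CoarseningParams(onset_min=60, rate_per_min=0.004, plateau_frac=0.08, coarse_median_um=300.0),
        kappa_protein=16.4e-3,
        kappa_lipid=11.0e-3,
        fat_frac=0.036,
        whey_casein_ratio=(65.0, 35.0),
        curd_protein=CurdParams(onset_min=120, rate_per_min=0.01, plateau=0.02),
        curd_lipid=CurdParams(onset_min=60, rate_per_min=0.02, plateau=0.25),
        band_decay_per_min={
            "kappa_casein": 0.15,
            "alpha_s_casein": 0.035,
            "beta_casein": 0.035,
            "beta_LG": 0.012,
            "alpha_LA": 0.040,
        },
        band_initial={
            "kappa_casein": 400,
            "alpha_s_casein": 900,
            "beta_casein": 1000,
            "beta_LG": 1700,
            "alpha_LA": 1400,
        },
    )
    return {t.profile: t for t in (casein, whey, biopolymer)}


def lognormal_bin_weights(
    median_um: float, gsd: float, edges_um: np.ndarray
) -> np.ndarray:
    """Integrated lognormal volume weights over diameter bins."""
    from scipy.stats import norm

    z = (np.log(edges_um) - math.log(median_um)) / math.log(gsd)
    cdf = norm.cdf(z)
    return np.diff(cdf)


def _default_edges(lo=0.01, hi=3000.0, n_bins=120) -> np.ndarray:
    return np.geomspace(lo, hi, n_bins + 1)


def calibrated_lognormal_psd(
    target_d43_um: float,
    gsd: float = 1.5,
    edges_um: np.ndarray | None = None,
    dispersant: Dispersant = Dispersant.water,
    sample_id: str = "",
    time_min: float = 0.0,
) -> ParticleSizeDistribution:
    """Single-mode lognormal PSD whose analytic volume mean is the target.

    The mode median is ``target / exp(ln(gsd)^2 / 2)``, so the binned d4,3
    reproduces the target to discretization error.
    """
    if edges_um is None:
        edges_um = _default_edges(target_d43_um / 50, target_d43_um * 50, 100)
    weights = lognormal_bin_weights(_median_for_d43(target_d43_um, gsd), gsd, edges_um)
    return ParticleSizeDistribution(edges_um, weights, dispersant, sample_id, time_min)


def calibrated_bimodal_psd(
    target_d43_um: float,
    fine_median_um: float = 1.0,
    coarse_median_um: float = 200.0,
    gsd: float = 1.5,
    edges_um: np.ndarray | None = None,
    dispersant: Dispersant = Dispersant.water,
    sample_id: str = "",
    time_min: float = 0.0,
) -> ParticleSizeDistribution:
    """Two-mode lognormal PSD with mode fractions solved analytically so the
    overall volume-weighted mean equals the target."""
    mean_f, mean_c = _mode_mean(fine_median_um, gsd), _mode_mean(coarse_median_um, gsd)
    if not mean_f < target_d43_um < mean_c:
        raise ValueError("target d4,3 must lie between the mode means")
    w = (mean_c - target_d43_um) / (mean_c - mean_f)
    if edges_um is None:
        edges_um = _default_edges(fine_median_um / 50, coarse_median_um * 20, 150)
    weights = w * lognormal_bin_weights(fine_median_um, gsd, edges_um) + (
        1 - w
    ) * lognormal_bin_weights(coarse_median_um, gsd, edges_um)
    return ParticleSizeDistribution(edges_um, weights, dispersant, sample_id, time_min)


def _psd_at(
    template: ProfileTemplate,
    t: float,
    dispersant: Dispersant,
    edges: np.ndarray,
    rng: np.random.Generator | None,
    sample_id: str,
) -> ParticleSizeDistribution:
    coars = (
        template.aggregation if dispersant is Dispersant.water else template.coalescence
    )
    fc = coars.coarse_frac(t)
    weights = np.zeros(edges.size - 1)
    for mode in template.initial_modes[dispersant]:
        weights += (1 - fc) * mode.volume_frac * lognormal_bin_weights(
            mode.median_um, mode.gsd, edges
        )
    if fc > 0:
        weights += fc * lognormal_bin_weights(coars.coarse_median_um, coars.coarse_gsd, edges)
    if rng is not None and template.psd_noise_cv > 0:
        sigma = math.sqrt(math.log(1 + template.psd_noise_cv**2))
        weights = weights * rng.lognormal(-0.5 * sigma**2, sigma, size=weights.size)
    return ParticleSizeDistribution(edges, weights, dispersant, sample_id, t)


def synth_psd_series(
    template: ProfileTemplate,
    times,
    seed: int | None = 0,
    sample_id: str = "",
    edges_um: np.ndarray | None = None,
) -> list[ParticleSizeDistribution]:
    """PSD time course in both dispersants.

    Before the destabilization onset the initial modes are returned (plus
    per-bin multiplicative noise); afterwards a coarse mode grows per the
    template. The buffer dialect sheds flocculation by construction: its
    coarse mode follows the (slower, smaller) coalescence parameters.
    ``seed=None`` disables noise. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    edges = edges_um if edges_um is not None else _default_edges()
    out = []
    for t in times:
        for disp in (Dispersant.water, Dispersant.sds_edta):
            out.append(_psd_at(template, t, disp, edges, rng, sample_id))
    return out


def synth_retention(
    template: ProfileTemplate,
    times,
    sigma_pct: float | None = None,
    seed: int | None = 0,
    sample_id: str = "",
) -> dict[str, RetentionCurve]:
    """Retention observations per nutrient from the true emptying model.

    y(t) = 100 * exp(-(kappa t)^beta) plus i.i.d. Gaussian noise of
    ``sigma_pct`` (default: the template's), clamped to [0, 110]%.
    """
    if sigma_pct is None:
        sigma_pct = template.retention_sigma_pct
    rng = np.random.default_rng(seed) if seed is not None else None
    times = np.asarray(list(times), dtype=float)
    out = {}
    for nutrient, kappa in (("protein", template.kappa_protein), ("lipid", template.kappa_lipid)):
        y = elashoff(times, 100.0, kappa, template.beta)
        if rng is not None and sigma_pct > 0:
            y = y + rng.normal(0.0, sigma_pct, size=times.size)
        y = np.clip(y, 0.0, 110.0)
        out[nutrient] = RetentionCurve(
            times=list(times), retained_pct=list(y), nutrient=nutrient, sample_id=sample_id
        )
    return out


def synth_band_table(
    template: ProfileTemplate,
    times,
    seed: int | None = 0,
    sample_id: str = "",
) -> BandIntensityTable:
    """Gel-band intensities under per-band first-order decay.

    kappa-casein decays fastest in every profile (hydrolysed within the
    first sampling interval); beta-lactoglobulin slowest. Noise is
    multiplicative log-normal with the template's CV; the t = 0 column is
    noise-free so residuals normalize exactly.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    times = [float(t) for t in times]
    bands = list(template.band_decay_per_min)
    inten = np.empty((len(bands), len(times)))
    for i, band in enumerate(bands):
        i0 = template.band_initial.get(band, 1000.0)
        rate = template.band_decay_per_min[band]
        for j, t in enumerate(times):
            val = i0 * math.exp(-rate * t)
            if rng is not None and template.intensity_cv > 0 and t > 0:
                sigma = math.sqrt(math.log(1 + template.intensity_cv**2))
                val *= rng.lognormal(-0.5 * sigma**2, sigma)
            inten[i, j] = val
    return BandIntensityTable(bands=bands, times=times, intensities=inten, sample_id=sample_id)


@dataclass
class StudyBundle:
    """One complete synthetic study, ready for the full pipeline."""

    formulae: list[FormulaSpec]
    templates: dict[str, ProfileTemplate]  # sample -> template
    psds: dict[str, list[ParticleSizeDistribution]]
    retention: dict[str, dict[str, RetentionCurve]]  # sample -> nutrient -> curve
    bands: dict[str, BandIntensityTable]
    groups: dict[str, str]  # sample -> profile label
    seed: int
    manifest: dict = field(default_factory=dict)


PSD_TIMES = (0.0, 15.0, 40.0, 80.0, 120.0, 160.0)
RETENTION_TIMES = tuple(float(t) for t in range(0, 161, 20))


def synth_study(n_per_profile: int = 1, seed: int = 0) -> StudyBundle:
    """Generate a full study: ``n_per_profile`` formulae per profile class.

    Seeds for every sample and data kind are derived deterministically from
    the study seed, so identical seeds give identical bundles.
    """
    if n_per_profile < 1:
        raise ValueError("n_per_profile must be >= 1")
    templates = default_templates()
    formulae, t_map, psds, retention, bands, groups = [], {}, {}, {}, {}, {}
    manifest = {"seed": seed, "n_per_profile": n_per_profile, "samples": {}}
    idx = 0
    for profile, template in templates.items():
        for k in range(n_per_profile):
            name = f"{profile.value}_{k + 1}"
            seeds = {
                "psd": (seed * 1000 + idx * 10 + 1) % (2**31),
                "retention": (seed * 1000 + idx * 10 + 2) % (2**31),
                "bands": (seed * 1000 + idx * 10 + 3) % (2**31),
            }
            formulae.append(template.to_formula(name))
            t_map[name] = template
            psds[name] = synth_psd_series(template, PSD_TIMES, seeds["psd"], name)
            retention[name] = synth_retention(
                template, RETENTION_TIMES, seed=seeds["retention"], sample_id=name
            )
            bands[name] = synth_band_table(template, PSD_TIMES, seeds["bands"], name)
            groups[name] = profile.value
            manifest["samples"][name] = template.true_params() | {"seeds": seeds}
            idx += 1
    return StudyBundle(
        formulae=formulae,
        templates=t_map,
        psds=psds,
        retention=retention,
        bands=bands,
        groups=groups,
        seed=seed,
        manifest=manifest,
    )
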