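"""Synthetic-study generator: determinism, calibration, recovery."""

import numpy as np
import pytest

from igastro import (
    ProfileClass,
    aggregation_index,
    calibrated_bimodal_psd,
    calibrated_lognormal_psd,
    d43,
    default_templates,
    fit_retention,
    residual_intact,
    synth_band_table,
    synth_psd_series,
    synth_retention,
    synth_study,
)
from igastro.psd import Dispersant


@pytest.fixture(scope="module")
def templates():
    return default_templates()


class TestTemplates:
    def test_onset_anchors(self, templates):
        assert templates[ProfileClass.casein_dominant].aggregation.onset_min == 15
        assert templates[ProfileClass.whey_dominant].aggregation.onset_min == 80

    def test_kappa_ordering_whey_above_casein(self, templates):
        assert (
            templates[ProfileClass.whey_dominant].kappa_protein
            > templates[ProfileClass.casein_dominant].kappa_protein
        )

    def test_biopolymer_initial_buffer_d43_stays_large(self, templates):
        t = templates[ProfileClass.biopolymer_whey]
        psd = synth_psd_series(t, [0.0], seed=None)
        buf = [p for p in psd if p.dispersant is Dispersant.sds_edta][0]
        assert d43(buf).value_um > 50.0

    def test_biopolymer_lipid_kappa_depressed(self, templates):
        t = templates[ProfileClass.biopolymer_whey]
        assert t.kappa_lipid < t.kappa_protein


class TestCalibratedPsds:
    def test_lognormal_hits_target_d43(self):
        p = calibrated_lognormal_psd(0.78, gsd=1.5, edges_um=np.geomspace(0.01, 10, 101))
        assert d43(p).value_um == pytest.approx(0.78, abs=0.005)

    def test_bimodal_hits_target_d43(self):
        p = calibrated_bimodal_psd(59.65)
        assert d43(p).value_um == pytest.approx(59.65, rel=0.005)

    def test_bimodal_target_outside_hull_rejected(self):
        with pytest.raises(ValueError):
            calibrated_bimodal_psd(500.0, fine_median_um=1.0, coarse_median_um=200.0)


class TestPsdSeries:
    def test_zero_rates_constant_in_time(self, templates):
        t = templates[ProfileClass.casein_dominant]
        frozen = t.__class__(**{**t.__dict__})
        frozen.aggregation = t.aggregation.__class__(
            onset_min=15, rate_per_min=0.0, plateau_frac=0.0, coarse_median_um=60.0
        )
        psds = synth_psd_series(frozen, [0.0, 160.0], seed=None)
        water = [p for p in psds if p.dispersant is Dispersant.water]
        assert np.allclose(water[0].volume_density, water[1].volume_density)

    def test_casein_ai_grows_after_onset(self, templates):
        t = templates[ProfileClass.casein_dominant]
        psds = synth_psd_series(t, [0.0, 15.0, 160.0], seed=None)
        water = {p.time_min: d43(p) for p in psds if p.dispersant is Dispersant.water}
        ai15 = aggregation_index(water[15.0], water[0.0])
        ai160 = aggregation_index(water[160.0], water[0.0])
        assert ai160 > ai15 >= 0.0

    def test_onset_difference_between_profiles(self, templates):
        def ai_at_40(profile):
            t = templates[profile]
            psds = synth_psd_series(t, [0.0, 40.0], seed=None)
            water = {p.time_min: d43(p) for p in psds if p.dispersant is Dispersant.water}
            return aggregation_index(water[40.0], water[0.0])

        assert ai_at_40(ProfileClass.whey_dominant) == pytest.approx(0.0, abs=0.05)
        assert ai_at_40(ProfileClass.casein_dominant) > 1.0

    def test_seed_determinism(self, templates):
        t = templates[ProfileClass.whey_dominant]
        a = synth_psd_series(t, [0.0, 80.0], seed=5)
        b = synth_psd_series(t, [0.0, 80.0], seed=5)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.volume_density, pb.volume_density)


class TestRetentionGeneration:
    def test_noiseless_matches_model_and_roundtrips(self, templates):
        t = templates[ProfileClass.casein_dominant]
        curves = synth_retention(t, np.arange(0, 161, 20), sigma_pct=0.0, seed=None)
        fit = fit_retention(curves["protein"])
        assert fit.kappa == pytest.approx(t.kappa_protein, rel=1e-6)
        assert fit.beta == pytest.approx(t.beta, rel=1e-6)

    def test_whey_empties_protein_faster_by_80min(self, templates):
        times = [0.0, 40.0, 80.0, 120.0, 160.0]
        whey = synth_retention(templates[ProfileClass.whey_dominant], times, 0.0, None)
        casein = synth_retention(templates[ProfileClass.casein_dominant], times, 0.0, None)
        assert whey["protein"].retained_pct[2] < casein["protein"].retained_pct[2]

    def test_noise_is_seeded_and_clamped(self, templates):
        t = templates[ProfileClass.whey_dominant]
        a = synth_retention(t, np.arange(0, 161, 20), seed=9)
        b = synth_retention(t, np.arange(0, 161, 20), seed=9)
        assert a["protein"].retained_pct == b["protein"].retained_pct
        assert max(a["protein"].retained_pct) <= 110.0


class TestBandTables:
    def test_zero_decay_constant(self, templates):
        t = templates[ProfileClass.whey_dominant]
        frozen = t.__class__(**{**t.__dict__})
        frozen.band_decay_per_min = {b: 0.0 for b in t.band_decay_per_min}
        tab = synth_band_table(frozen, [0.0, 80.0, 160.0], seed=None)
        assert np.allclose(tab.intensities, tab.intensities[:, [0]])

    @pytest.mark.parametrize("profile", list(ProfileClass))
    def test_kappa_casein_mostly_gone_by_15min(self, templates, profile):
        tab = synth_band_table(templates[profile], [0.0, 15.0, 160.0], seed=1)
        res = residual_intact(tab)
        assert res.loc["kappa_casein", 15.0] < 0.2

    def test_casein_profile_betaLG_outlasts_whey_alphaLA(self, templates):
        times = [0.0, 40.0, 80.0, 120.0, 160.0]
        cas = residual_intact(synth_band_table(templates[ProfileClass.casein_dominant], times, 2))
        whey = residual_intact(synth_band_table(templates[ProfileClass.whey_dominant], times, 2))
        assert cas.loc["beta_LG", 160.0] > whey.loc["alpha_LA", 160.0]

    def test_whey_hydrolyses_caseins_faster(self, templates):
        cas = templates[ProfileClass.casein_dominant].band_decay_per_min
        whey = templates[ProfileClass.whey_dominant].band_decay_per_min
        for band in ("alpha_s_casein", "beta_casein", "alpha_LA"):
            assert whey[band] >= cas[band]


class TestStudyBundle:
    def test_three_samples_at_n1(self, study_bundle):
        assert len(study_bundle.formulae) == 3
        assert set(study_bundle.groups.values()) == {p.value for p in ProfileClass}

    def test_determinism_same_seed(self):
        a, b = synth_study(1, seed=7), synth_study(1, seed=7)
        for s in a.retention:
            assert (
                a.retention[s]["protein"].retained_pct
                == b.retention[s]["protein"].retained_pct
            )
            assert np.array_equal(
                a.psds[s][0].volume_density, b.psds[s][0].volume_density
            )

    def test_manifest_records_true_parameters(self, study_bundle):
        entry = study_bundle.manifest["samples"]["whey_dominant_1"]
        assert entry["kappa_protein"] == pytest.approx(16.2e-3)
        assert "seeds" in entry

    def test_n_must_be_positive(self):
        with pytest.raises(ValueError):
            synth_study(0, seed=1)
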