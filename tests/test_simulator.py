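"""Mass-balance simulator: bookkeeping, emptying, curd retention, pH."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igastro import (
    BufferingParams,
    CurdParams,
    DigestionProtocol,
    FormulaSpec,
    init_state,
    nutrient_retention,
    ph_trajectory,
    run_digestion,
)
from igastro.simulator import advance, empty_event


class TestInitState:
    def test_meal_plus_basal_and_nutrient_masses(self, zero_curd_formula, protocol):
        s = init_state(zero_curd_formula, protocol)
        assert s.chyme_mass_g == pytest.approx(110.0)
        assert s.protein_g == pytest.approx(1.70)
        assert s.lipid_g == pytest.approx(3.94)
        assert s.protein_curd_g == 0.0 and s.time == 0.0

    def test_zero_fat_formula_has_zero_lipid(self, protocol):
        f = FormulaSpec(name="skim", protein_frac=0.017, fat_frac=0.0)
        assert init_state(f, protocol).lipid_g == 0.0

    def test_nonpositive_meal_rejected(self, zero_curd_formula):
        with pytest.raises(Exception):
            DigestionProtocol(meal_mass_g=0.0)


class TestAdvance:
    def test_secretion_adds_half_gram_per_minute(self, zero_curd_formula, protocol):
        s0 = init_state(zero_curd_formula, protocol)
        s = advance(s0, 20.0, protocol)
        assert s.chyme_mass_g - s0.chyme_mass_g == pytest.approx(10.0)
        assert s.protein_g == s0.protein_g and s.lipid_g == s0.lipid_g

    def test_linearity_at_tiny_dt(self, zero_curd_formula, protocol):
        s0 = init_state(zero_curd_formula, protocol)
        s = advance(s0, 1e-6, protocol)
        assert s.chyme_mass_g - s0.chyme_mass_g == pytest.approx(5e-7)

    def test_total_secretion_over_run(self, zero_curd_formula, protocol):
        s = init_state(zero_curd_formula, protocol)
        s = advance(s, 160.0, protocol)
        assert s.resident_secretion_g == pytest.approx(80.0)

    def test_dt_must_be_positive(self, zero_curd_formula, protocol):
        with pytest.raises(ValueError):
            advance(init_state(zero_curd_formula, protocol), 0.0, protocol)


class TestEmptyEvent:
    def test_aliquot_is_proportional_to_emptiable_phase(self, zero_curd_formula, protocol):
        s = advance(init_state(zero_curd_formula, protocol), 20.0, protocol)
        assert s.chyme_mass_g == pytest.approx(120.0)
        s2, aliquot = empty_event(s, protocol, zero_curd_formula)
        assert aliquot.mass_g == pytest.approx(22.0)
        assert aliquot.protein_g / aliquot.mass_g == pytest.approx(s.protein_g / s.chyme_mass_g)
        assert s2.chyme_mass_g == pytest.approx(98.0)

    def test_drains_when_less_than_scheduled(self, zero_curd_formula):
        small = DigestionProtocol(meal_mass_g=8.0, basal_sgf_mass_g=2.0)
        s = init_state(zero_curd_formula, small)
        _, aliquot = empty_event(s, small, zero_curd_formula)
        assert aliquot.mass_g == pytest.approx(10.0)

    def test_curd_never_appears_in_aliquot(self, protocol):
        all_curd = FormulaSpec(
            name="curd",
            protein_frac=0.017,
            fat_frac=0.04,
            curd_protein=CurdParams(onset_min=0, rate_per_min=100.0, plateau=1.0),
        )
        s = advance(init_state(all_curd, protocol), 20.0, protocol)
        _, aliquot = empty_event(s, protocol, all_curd)
        assert aliquot.protein_g == pytest.approx(0.0)
        assert aliquot.mass_g > 0  # water and lipid still empty


class TestRunDigestion:
    def test_closed_form_final_chyme_mass(self, zero_curd_formula, protocol):
        ts = run_digestion(zero_curd_formula, protocol)
        # 110 start + 80 secreted - 8 x 22 emptied
        assert ts.state_at(160.0).chyme_mass_g == pytest.approx(14.0)
        assert sum(a.mass_g for a in ts.aliquots) == pytest.approx(176.0)
        assert len(ts.aliquots) == 8

    def test_zero_total_time_is_initial_state(self, zero_curd_formula):
        p = DigestionProtocol(total_time_min=0.0, sampling_times_min=())
        ts = run_digestion(zero_curd_formula, p)
        assert len(ts.states) == 1
        assert ts.states[0].chyme_mass_g == pytest.approx(110.0)

    def test_mass_conservation_default_run(self, curdy_formula, protocol):
        ts = run_digestion(curdy_formula, protocol)
        for t in ts.times:
            assert abs(ts.conservation_error(t)) < 1e-9

    @settings(max_examples=25, deadline=None)
    @given(
        meal=st.floats(50, 150),
        basal=st.floats(0, 20),
        flow=st.floats(0.05, 1.0),
        emp_mass=st.floats(5, 40),
        interval=st.floats(5, 40),
        plateau=st.floats(0, 1),
    )
    def test_mass_conservation_randomized(self, meal, basal, flow, emp_mass, interval, plateau):
        """Conservation holds across the protocol parameter space."""
        protocol = DigestionProtocol(
            meal_mass_g=meal,
            basal_sgf_mass_g=basal,
            sgf_flow_ml_min=flow,
            enzyme_flow_ml_min=flow / 4,
            emptying_mass_g=emp_mass,
            emptying_interval_min=interval,
            sampling_times_min=(),
        )
        f = FormulaSpec(
            name="x",
            protein_frac=0.017,
            fat_frac=0.04,
            curd_protein=CurdParams(onset_min=10, rate_per_min=0.05, plateau=plateau),
        )
        ts = run_digestion(f, protocol)
        assert max(abs(ts.conservation_error(t)) for t in ts.times) < 1e-9


class TestRetention:
    def test_starts_at_100_and_decreases(self, zero_curd_formula, protocol):
        ts = run_digestion(zero_curd_formula, protocol)
        rc = nutrient_retention(ts, "protein")
        assert rc.retained_pct[0] == 100.0
        assert np.all(np.diff(rc.y) <= 1e-12)

    def test_first_event_removes_proportional_share(self, zero_curd_formula, protocol):
        ts = run_digestion(zero_curd_formula, protocol)
        rc = nutrient_retention(ts, "protein", at_times=[0.0, 20.0])
        assert rc.retained_pct[1] == pytest.approx(100.0 * (1 - 22.0 / 120.0))

    def test_zero_curd_protein_equals_lipid_retention(self, zero_curd_formula, protocol):
        ts = run_digestion(zero_curd_formula, protocol)
        p = nutrient_retention(ts, "protein").y
        l = nutrient_retention(ts, "lipid").y
        assert np.allclose(p, l, atol=1e-9)

    def test_full_curd_retains_everything(self, protocol):
        f = FormulaSpec(
            name="locked",
            protein_frac=0.017,
            fat_frac=0.0,
            curd_protein=CurdParams(onset_min=0, rate_per_min=100.0, plateau=1.0),
        )
        ts = run_digestion(f, protocol)
        assert np.allclose(nutrient_retention(ts, "protein").y, 100.0)

    def test_more_curd_never_lowers_retention(self, protocol):
        def run(plateau):
            f = FormulaSpec(
                name="f",
                protein_frac=0.017,
                fat_frac=0.04,
                curd_protein=CurdParams(onset_min=15, rate_per_min=0.05, plateau=plateau),
            )
            return nutrient_retention(run_digestion(f, protocol), "protein").y

        low, high = run(0.1), run(0.6)
        assert np.all(high >= low - 1e-12)

    def test_zero_initial_nutrient_is_an_error(self, protocol):
        f = FormulaSpec(name="skim", protein_frac=0.017, fat_frac=0.0)
        ts = run_digestion(f, protocol)
        with pytest.raises(ValueError):
            nutrient_retention(ts, "lipid")


class TestPh:
    def test_no_acid_keeps_initial_ph(self, zero_curd_formula, protocol):
        buffering = BufferingParams(acid_delivery=0.0)
        ts = run_digestion(zero_curd_formula, protocol, buffering)
        ph = ph_trajectory(ts, buffering)
        assert all(v == pytest.approx(buffering.initial_ph) for _, v in ph)

    def test_infinite_buffering_limit(self, zero_curd_formula, protocol, buffering):
        ts = run_digestion(zero_curd_formula, protocol, buffering)
        huge = BufferingParams(buffer_capacity=1e12, acid_delivery=buffering.acid_delivery)
        ph = ph_trajectory(ts, huge)
        assert ph[-1][1] == pytest.approx(huge.initial_ph, abs=1e-6)

    def test_higher_capacity_gives_pointwise_higher_ph(self, zero_curd_formula, protocol, buffering):
        ts = run_digestion(zero_curd_formula, protocol, buffering)
        low = ph_trajectory(ts, BufferingParams(buffer_capacity=0.5))
        high = ph_trajectory(ts, BufferingParams(buffer_capacity=50.0))
        assert all(h >= l for (_, h), (_, l) in zip(high, low))
        assert high[-1][1] > low[-1][1]

    def test_ph_never_below_floor(self, zero_curd_formula, protocol):
        b = BufferingParams(buffer_capacity=1e-6, acid_delivery=1.0)
        ts = run_digestion(zero_curd_formula, protocol, b)
        assert all(v >= b.min_ph for _, v in ph_trajectory(ts, b))
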