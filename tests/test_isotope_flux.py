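"""Isotope mass-balance equations: worked examples, inversion, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipflux.isotope_flux import (
    IncubationSetup,
    MicrocosmMeasurement,
    atom_percent_excess,
    bottle_potentials,
    co2_oxidation_potential,
    depth_fold_ratios,
    inverse_atom_excess,
    n2_fixation_potential,
    soc_assimilation_potential,
    total_methane_oxidation,
)


def make_meas(**overrides):
    base = dict(
        depth_label="mid_40_60",
        replicate_id="L1",
        treatment="labeled",
        co2_concentration_pct=1.0,
        atom13_co2_day90_pct=10.5,
        atom13_co2_day0_pct=0.5,
        soc_content_pct=5.0,
        atom13_soc_day90_pct=1.09,
        atom13_soc_day0_pct=1.08,
        son_content_pct=0.50,
        atom15_son_day90_pct=0.3715,
        atom15_son_day0_pct=0.3665,
    )
    base.update(overrides)
    return MicrocosmMeasurement(**base)


class TestAtomPercentExcess:
    @pytest.mark.parametrize(
        "day90, day0, expected",
        [(10.5, 0.5, 10.0), (1.08, 1.08, 0.0), (0.5, 1.0, -0.5)],
    )
    def test_examples(self, day90, day0, expected):
        assert atom_percent_excess(day90, day0) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            atom_percent_excess(bad, 1.0)


class TestForwardEquations:
    def test_co2_hand_oracle(self, setup):
        # 0.01 * 0.10 * 0.360 L / 22.4 L/mol * 1e9 nmol/mol / (5 g * 90 d)
        meas = make_meas()
        assert co2_oxidation_potential(meas, setup) == pytest.approx(
            0.01 * 0.10 * 0.360 / 22.4 * 1e9 / 450
        )
        assert co2_oxidation_potential(meas, setup) == pytest.approx(35.71, abs=0.01)

    def test_soc_hand_oracle(self, setup):
        # 0.05 * 5 g * 1e-4 / 13 g/mol * 1e9 / (5 g * 90 d)
        meas = make_meas()
        assert soc_assimilation_potential(meas, setup) == pytest.approx(
            0.05 * 5 * 1e-4 / 13 * 1e9 / 450
        )
        assert soc_assimilation_potential(meas, setup) == pytest.approx(4.274, abs=0.001)

    def test_son_hand_oracle(self, setup):
        # 0.005 * 5 g * 5e-5 / 15 g/mol * 1e9 / (5 g * 90 d)
        meas = make_meas()
        assert n2_fixation_potential(meas, setup) == pytest.approx(
            0.005 * 5 * 5e-5 / 15 * 1e9 / 450
        )
        assert n2_fixation_potential(meas, setup) == pytest.approx(0.1852, abs=0.0001)

    def test_zero_excess_gives_zero(self, setup):
        meas = make_meas(
            atom13_co2_day90_pct=0.5,
            atom13_soc_day90_pct=1.08,
            atom15_son_day90_pct=0.3665,
        )
        assert co2_oxidation_potential(meas, setup) == 0.0
        assert soc_assimilation_potential(meas, setup) == 0.0
        assert n2_fixation_potential(meas, setup) == 0.0

    def test_linearity_in_excess(self, setup):
        one = soc_assimilation_potential(make_meas(), setup)
        two = soc_assimilation_potential(make_meas(atom13_soc_day90_pct=1.10), setup)
        assert two == pytest.approx(2 * one)

    def test_mass_cancellation(self):
        """SOC/SON potentials are invariant to m; the CO2 one scales as 1/m."""
        meas = make_meas()
        s1, s2 = IncubationSetup(dry_mass_g=5.0), IncubationSetup(dry_mass_g=10.0)
        assert soc_assimilation_potential(meas, s1) == pytest.approx(
            soc_assimilation_potential(meas, s2)
        )
        assert n2_fixation_potential(meas, s1) == pytest.approx(
            n2_fixation_potential(meas, s2)
        )
        assert co2_oxidation_potential(meas, s1) == pytest.approx(
            2 * co2_oxidation_potential(meas, s2)
        )

    def test_invalid_setup_rejected(self):
        with pytest.raises(ValueError):
            IncubationSetup(dry_mass_g=0.0)
        with pytest.raises(ValueError):
            IncubationSetup(incubation_days=0.5)


class TestTotalAndPartition:
    @pytest.mark.parametrize(
        "gas, soc, total, fraction",
        [(106.69, 37.48, 144.17, 0.74), (1.0, 1.0, 2.0, 0.5)],
    )
    def test_examples(self, gas, soc, total, fraction):
        t, f = total_methane_oxidation(gas, soc)
        assert t == pytest.approx(total)
        assert f == pytest.approx(fraction, abs=0.005)

    def test_zero_total_is_undefined(self):
        t, f = total_methane_oxidation(0.0, 0.0)
        assert t == 0.0 and math.isnan(f)

    def test_negative_excess_flagged_not_clamped(self, setup):
        res = bottle_potentials(make_meas(atom13_co2_day90_pct=0.4), setup)
        assert res.co2_potential < 0
        assert "negative_excess" in res.flags

    def test_total_is_component_sum(self, setup):
        res = bottle_potentials(make_meas(), setup)
        assert res.total_ch4_oxidation == pytest.approx(
            res.co2_potential + res.soc_potential, rel=1e-12
        )
        assert 0.0 <= res.co2_fraction <= 1.0


class TestFoldRatios:
    def test_printed_ch4_ratios(self):
        ratios = depth_fold_ratios({"top": 57.67, "mid": 144.17, "deep": 120.14})
        assert round(ratios[("mid", "top")], 1) == 2.5
        assert round(ratios[("mid", "deep")], 1) == 1.2

    def test_printed_n2_ratios(self):
        ratios = depth_fold_ratios({"top": 0.41, "mid": 0.57, "deep": 0.13})
        assert round(ratios[("mid", "deep")], 1) == 4.4
        assert round(ratios[("mid", "top")], 1) == 1.4

    def test_identical_means(self):
        ratios = depth_fold_ratios({"a": 3.0, "b": 3.0})
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_zero_denominator_flagged(self):
        ratios = depth_fold_ratios({"a": 3.0, "b": 0.0})
        assert math.isnan(ratios[("a", "b")])


class TestInverseOracle:
    def test_inverts_co2_example(self, setup):
        d_a = inverse_atom_excess(
            0.01 * 0.10 * 0.360 / 22.4 * 1e9 / 450,
            setup, "co2", co2_concentration_pct=1.0,
        )
        assert d_a == pytest.approx(10.0, rel=1e-12)

    def test_zero_target(self, setup):
        assert inverse_atom_excess(0.0, setup, "soc", soc_content_pct=5.0) == 0.0

    def test_zero_pool_rejected(self, setup):
        with pytest.raises(ValueError):
            inverse_atom_excess(1.0, setup, "son", son_content_pct=0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        target=st.floats(1e-6, 1e4),
        pool=st.floats(0.01, 50.0),
        which=st.sampled_from(["co2", "soc", "son"]),
    )
    def test_round_trip(self, target, pool, which):
        """forward(inverse(x)) == x to 1e-9 relative, all three equations."""
        setup = IncubationSetup()
        d_a = inverse_atom_excess(
            target, setup, which,
            co2_concentration_pct=pool, soc_content_pct=pool, son_content_pct=pool,
        )
        day0 = 0.0
        day90 = min(day0 + d_a, 100.0)
        if day90 < day0 + d_a:  # excess beyond the atom-% scale: skip
            return
        meas = make_meas(
            co2_concentration_pct=pool, soc_content_pct=pool, son_content_pct=pool,
            atom13_co2_day90_pct=day90, atom13_co2_day0_pct=day0,
            atom13_soc_day90_pct=day90, atom13_soc_day0_pct=day0,
            atom15_son_day90_pct=day90, atom15_son_day0_pct=day0,
        )
        forward = {
            "co2": co2_oxidation_potential,
            "soc": soc_assimilation_potential,
            "son": n2_fixation_potential,
        }[which]
        assert forward(meas, setup) == pytest.approx(target, rel=1e-9)
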