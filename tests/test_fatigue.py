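"""Gerber correction, Basquin life, Miner accumulation and the pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valvefatigue import (
    MaterialFatigueProperties,
    SubCycle,
    basquin_life,
    constant_amplitude_spectrum,
    cycles_to_duration,
    fatigue_life_pipeline,
    gerber_equivalent_stress,
    spectrum_damage,
    total_life,
)


class TestGerber:
    def test_zero_mean_is_identity(self):
        assert gerber_equivalent_stress(0.3, 0.0, 10.0) == pytest.approx(0.3)

    def test_parabolic_correction(self):
        assert gerber_equivalent_stress(0.3, 5.0, 10.0) == pytest.approx(0.4)

    def test_sign_symmetry_of_squared_term(self):
        pos = gerber_equivalent_stress(0.3, 5.0, 10.0)
        neg = gerber_equivalent_stress(0.3, -5.0, 10.0)
        assert neg == pytest.approx(pos) == pytest.approx(0.4)

    def test_mean_at_ultimate_signals_immediate_failure(self):
        assert math.isinf(gerber_equivalent_stress(0.3, 10.0, 10.0))
        assert math.isinf(gerber_equivalent_stress(0.3, -12.0, 10.0))

    @settings(derandomize=True, max_examples=60)
    @given(
        s_a=st.floats(min_value=0.01, max_value=5.0),
        s_m=st.floats(min_value=-9.0, max_value=9.0),
    )
    def test_snf_bounded_below_by_amplitude_and_grows_with_mean(self, s_a, s_m):
        snf = gerber_equivalent_stress(s_a, s_m, 10.0)
        assert snf >= s_a
        wider = gerber_equivalent_stress(s_a, s_m * 1.05, 10.0)
        assert wider >= snf


class TestBasquin:
    def test_single_cycle_strength_boundary(self, simple_mat):
        assert basquin_life(simple_mat.sigma_f, simple_mat) == 0.5

    def test_closed_form_value(self, simple_mat):
        # sigma_f = 10, beta = -0.1: Nf(5) = 0.5 * 0.5**(-10) = 512
        assert basquin_life(5.0, simple_mat) == pytest.approx(512.0)

    @pytest.mark.parametrize("n", [0.5, 1.0, 7.0, 1e3, 1e8])
    def test_round_trip_inverse(self, simple_mat, n):
        snf = simple_mat.sigma_f * (2 * n) ** simple_mat.beta
        assert basquin_life(snf, simple_mat) == pytest.approx(n, rel=1e-12)

    def test_monotone_decreasing_in_stress(self, simple_mat):
        levels = np.linspace(0.5, 9.5, 30)
        lives = [basquin_life(s, simple_mat) for s in levels]
        assert all(a > b for a, b in zip(lives, lives[1:]))

    def test_above_sigma_f_clamps(self, simple_mat):
        assert basquin_life(50.0, simple_mat) == 0.5

    def test_nonpositive_stress_rejected(self, simple_mat):
        with pytest.raises(ValueError):
            basquin_life(0.0, simple_mat)


class TestMinerAccumulation:
    def test_single_term_sum(self, simple_mat):
        # one cycle at the stress level whose life is known in closed form
        sc = SubCycle(s_max=5.0, s_min=-5.0, count=1.0)  # s_a=5, s_m=0
        assert spectrum_damage([sc], simple_mat) == pytest.approx(1 / 512.0)

    def test_half_cycle_weighting(self, simple_mat):
        full = spectrum_damage([SubCycle(5.0, -5.0, 1.0)], simple_mat)
        half = spectrum_damage([SubCycle(5.0, -5.0, 0.5)], simple_mat)
        assert half == pytest.approx(full / 2)

    def test_empty_and_zero_amplitude_spectra(self, simple_mat):
        assert spectrum_damage([], simple_mat) == 0.0
        assert spectrum_damage([SubCycle(2.0, 2.0, 1.0)], simple_mat) == 0.0

    def test_immediate_failure_subcycle(self, simple_mat):
        # mean beyond ultimate strength: damage = count / 0.5
        sc = SubCycle(s_max=25.0, s_min=5.0, count=1.0)  # s_m = 15 > su
        assert spectrum_damage([sc], simple_mat) == pytest.approx(2.0)

    def test_endurance_limit_option(self, simple_mat):
        sc = SubCycle(1.0, -1.0, 1.0)
        assert spectrum_damage([sc], simple_mat) > 0
        assert spectrum_damage([sc], simple_mat, endurance_limit=1.5) == 0.0

    def test_negative_mean_clamp_option(self, simple_mat):
        sc = SubCycle(1.0, -7.0, 1.0)  # s_a = 4, s_m = -3
        raw = spectrum_damage([sc], simple_mat)
        clamped = spectrum_damage([sc], simple_mat, clamp_negative_mean=True)
        assert clamped < raw  # zeroed mean lowers the equivalent stress

    @settings(derandomize=True, max_examples=40)
    @given(factor=st.floats(min_value=0.1, max_value=10.0))
    def test_miner_linearity(self, simple_mat, factor):
        spectrum = [SubCycle(5.0, -5.0, 1.0), SubCycle(3.0, 0.0, 0.5)]
        base = spectrum_damage(spectrum, simple_mat)
        scaled = spectrum_damage([c.scaled(factor) for c in spectrum], simple_mat)
        assert scaled == pytest.approx(factor * base, rel=1e-12)
        assert total_life(scaled) == pytest.approx(total_life(base) / factor)

    def test_monotone_in_amplitude_and_mean(self, simple_mat):
        def life_of(s_a, s_m):
            sc = SubCycle(s_m + s_a, s_m - s_a, 1.0)
            return total_life(spectrum_damage([sc], simple_mat))

        amp_lives = [life_of(s_a, 1.0) for s_a in (1.0, 2.0, 3.0, 4.0)]
        assert all(a >= b for a, b in zip(amp_lives, amp_lives[1:]))
        mean_lives = [life_of(2.0, abs(m)) for m in (0.0, 2.0, 4.0, 6.0)]
        assert all(a >= b for a, b in zip(mean_lives, mean_lives[1:]))


class TestTotalLifeAndDuration:
    def test_reciprocal(self):
        assert total_life(2.183e-9) == pytest.approx(4.581e8, rel=1e-3)
        assert total_life(1.0) == 1.0

    def test_zero_damage_flags_infinite_life(self):
        assert math.isinf(total_life(0.0))

    def test_negative_damage_rejected(self):
        with pytest.raises(ValueError):
            total_life(-1e-9)

    @pytest.mark.parametrize(
        "cycles, days",
        [
            (4.40e5, 4.3651),   # under a week
            (4.58e8, 4543.65),  # about 12.4 years
            (0.0, 0.0),
        ],
    )
    def test_duration_at_70_bpm(self, cycles, days):
        years, d = cycles_to_duration(cycles, bpm=70.0)
        assert d == pytest.approx(days, rel=1e-4)
        assert years == pytest.approx(d / 365.0, rel=1e-12)


class TestPipeline:
    def test_constant_amplitude_life_equals_basquin(self, simple_mat):
        # pulsatile 0 -> S -> 0 repeated: per-cycle spectrum is one full
        # cycle, so L must equal Nf at the Gerber-corrected stress
        s = 4.0
        h = constant_amplitude_spectrum(s, 0.0, n_cycles=5)
        res = fatigue_life_pipeline(h, simple_mat, rel_tolerance=0.0)
        snf = gerber_equivalent_stress(s / 2, s / 2, simple_mat.su)
        assert res.total_life_cycles == pytest.approx(
            basquin_life(snf, simple_mat), rel=1e-9
        )
        assert res.damage_per_spectrum == pytest.approx(
            sum(r.damage for r in res.breakdown)
        )

    def test_zero_stress_history_has_infinite_life(self, simple_mat):
        import numpy as np

        from valvefatigue import StressHistory

        h = StressHistory(np.arange(5.0), np.zeros(5))
        res = fatigue_life_pipeline(h, simple_mat)
        assert res.infinite_life
        assert res.damage_per_spectrum == 0.0

    def test_parameter_recovery_from_pipeline_lives(self, simple_mat):
        # generate pulsatile spectra at 5 stress levels, compute lives with
        # the pipeline, refit (sigma_f, beta) by log-linear regression
        levels = [2.0, 3.0, 4.0, 5.0, 6.0]
        snf, lives = [], []
        for s in levels:
            h = constant_amplitude_spectrum(s, 0.0, n_cycles=3)
            res = fatigue_life_pipeline(h, simple_mat, rel_tolerance=0.0)
            snf.append(gerber_equivalent_stress(s / 2, s / 2, simple_mat.su))
            lives.append(res.total_life_cycles)
        slope, intercept = np.polyfit(np.log(2 * np.array(lives)), np.log(snf), 1)
        assert slope == pytest.approx(simple_mat.beta, rel=0.01)
        assert math.exp(intercept) == pytest.approx(simple_mat.sigma_f, rel=0.01)

    def test_material_validation(self):
        with pytest.raises(Exception):
            MaterialFatigueProperties(
                su=15, sigma_f=16, beta=0.17,  # positive slope is invalid
                e_modulus=2, hardening_exp=0.15, strength_coeff=20,
                paris_c=1e-6, paris_m=3,
            )
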