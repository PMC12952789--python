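"""Call synthesis, piston directivity, and the propagation equations.

The dB-level operations are checked against independent term-by-term
evaluations of the sonar, Friis, and two-leg equations written out inline.
"""

import numpy as np
import pytest
from scipy.special import j1

from echoroost import acoustics as ac
from echoroost.acoustics import (CallParams, CallEvent, PropagationModel,
                                 atmospheric_absorption, compose_received_scene,
                                 echo_level, masking_call_level, piston_gain,
                                 second_order_echo_level, synthesize_call)
from echoroost.arena import spawn_bats

PK_SEARCH = CallParams(ipi_ms=100, duration_ms=7, terminal_freq_khz=39,
                       bandwidth_khz=8, level_db=120, species="PK")
FS = 250e3


class TestSynthesis:
    def test_pk_search_sweep_band(self):
        wave = synthesize_call(PK_SEARCH, FS, level_db=0.0)
        freqs = np.fft.rfftfreq(len(wave), 1 / FS)
        spec = np.abs(np.fft.rfft(wave))
        band = spec > 0.3 * spec.max()
        lo, hi = freqs[band].min(), freqs[band].max()
        assert 37e3 < lo < 41e3 and 45e3 < hi < 49e3   # 47 -> 39 kHz sweep

    def test_rm_search_sweep_band(self):
        rm = CallParams(ipi_ms=100, duration_ms=12, terminal_freq_khz=26,
                        bandwidth_khz=3, level_db=120, species="RM")
        wave = synthesize_call(rm, FS, level_db=0.0)
        freqs = np.fft.rfftfreq(len(wave), 1 / FS)
        spec = np.abs(np.fft.rfft(wave))
        band = spec > 0.3 * spec.max()
        assert 24.5e3 < freqs[band].min() < 27e3
        assert 27.5e3 < freqs[band].max() < 30.5e3    # 29 -> 26 kHz

    def test_zero_bandwidth_is_a_tone(self):
        tone = CallParams(ipi_ms=100, duration_ms=5, terminal_freq_khz=39,
                          bandwidth_khz=0, level_db=120)
        wave = synthesize_call(tone, FS, level_db=0.0)
        freqs = np.fft.rfftfreq(len(wave), 1 / FS)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(wave)))]
        assert peak == pytest.approx(39e3, rel=0.01)

    def test_amplitude_scaling(self):
        wave = synthesize_call(PK_SEARCH, FS)
        assert np.max(np.abs(wave)) == pytest.approx(10 ** (120 / 20), rel=1e-3)

    def test_undersampling_rejected(self):
        with pytest.raises(ValueError):
            synthesize_call(PK_SEARCH, 80e3)


class TestPiston:
    def test_on_axis_gain_is_one(self):
        assert piston_gain(0.0, 39.0, 0.003) == pytest.approx(1.0)

    def test_even_in_angle(self):
        a = np.linspace(0.01, np.pi, 30)
        assert np.allclose(piston_gain(a, 55.0, 0.007),
                           piston_gain(-a, 55.0, 0.007))

    def test_matches_direct_bessel_evaluation(self):
        # mouth aperture, 39 kHz, 60 degrees off axis
        c, f, a, th = 343.0, 39e3, 0.003, np.deg2rad(60)
        x = 2 * np.pi * f / c * a * np.sin(th)
        expected = (2 * j1(x) / x) ** 2
        assert piston_gain(th, 39.0, 0.003) == pytest.approx(expected, rel=1e-9)

    def test_narrower_beam_at_higher_frequency(self):
        assert piston_gain(0.8, 70.0, 0.007) < piston_gain(0.8, 20.0, 0.007)


class TestAbsorption:
    def test_nonnegative_and_increasing_over_band(self):
        f = np.linspace(10, 80, 30)
        a = np.array([atmospheric_absorption(x) for x in f])
        assert np.all(a >= 0) and np.all(np.diff(a) > 0)

    def test_magnitude_at_40khz(self):
        # ~1.3 dB/m at 20 degC, 50% RH
        assert 1.0 < atmospheric_absorption(40.0) < 1.7


class TestLevels:
    def test_echo_two_way_spreading(self, model):
        flat = PropagationModel()
        flat.alpha = lambda f: 0.0
        l1 = echo_level(120, 1.0, 0, 0, 39, -22.5, flat)
        l2 = echo_level(120, 2.0, 0, 0, 39, -22.5, flat)
        assert l1 - l2 == pytest.approx(40 * np.log10(2), abs=1e-9)

    def test_echo_term_by_term_oracle(self, model):
        # independent evaluation: Pt * Gt*Gr*lambda^2/((4pi)^3 D^4) * sigma,
        # two-way absorption beyond the 0.1 m reference
        Pt, D, f, sigma = 120.0, 1.0, 39.0, -23.0
        lam = 343.0 / (f * 1e3)
        alpha = atmospheric_absorption(f)
        expected = (Pt
                    + 10 * np.log10(lam ** 2 / (4 * np.pi) ** 3 / D ** 4)
                    - 2 * alpha * (D - 0.1) + sigma)
        got = echo_level(Pt, D, 0.0, 0.0, f, sigma, model)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_masking_one_way_spreading(self, model):
        flat = PropagationModel()
        flat.alpha = lambda f: 0.0
        l1 = masking_call_level(120, 1.0, 0, 0, 39, flat)
        l2 = masking_call_level(120, 2.0, 0, 0, 39, flat)
        assert l1 - l2 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_masking_term_by_term_oracle(self, model):
        Pt, D, f = 120.0, 2.5, 39.0
        lam = 343.0 / (f * 1e3)
        expected = (Pt + 20 * np.log10(lam / (4 * np.pi * D))
                    - atmospheric_absorption(f) * (D - 0.1))
        assert masking_call_level(Pt, D, 0, 0, f, model) \
            == pytest.approx(expected, abs=1e-9)

    def test_direct_call_vs_echo_gap_matches_oracles(self, model):
        # at equal distance on axis the direct call exceeds the echo by the
        # difference of the printed Friis and sonar forms
        Pt, D, f, sigma = 120.0, 2.0, 39.0, -22.5
        direct = masking_call_level(Pt, D, 0, 0, f, model)
        echo = echo_level(Pt, D, 0, 0, f, sigma, model)
        lam = 343.0 / (f * 1e3)
        expected_gap = (20 * np.log10(lam / (4 * np.pi * D))
                        - 10 * np.log10(lam ** 2 / (4 * np.pi) ** 3 / D ** 4)
                        - sigma
                        + atmospheric_absorption(f) * (D - 0.1))
        assert direct - echo == pytest.approx(expected_gap, abs=1e-9)

    def test_second_order_symmetric_limit_equals_echo(self, model):
        for D in (0.5, 1.0, 3.0):
            assert second_order_echo_level(120, D, D, 0.2, -0.1, 39, -23, model) \
                == pytest.approx(echo_level(120, D, 0.2, -0.1, 39, -23, model),
                                 abs=1e-9)

    def test_second_order_per_leg_spreading(self, model):
        flat = PropagationModel()
        flat.alpha = lambda f: 0.0
        l1 = second_order_echo_level(120, 1.0, 2.0, 0, 0, 39, -23, flat)
        l2 = second_order_echo_level(120, 2.0, 2.0, 0, 0, 39, -23, flat)
        assert l1 - l2 == pytest.approx(20 * np.log10(2), abs=1e-9)

    def test_reference_distance_enforced(self, model):
        with pytest.raises(ValueError):
            echo_level(120, 0.05, 0, 0, 39, -23, model)


class TestSceneComposition:
    def test_single_bat_scene_kinds(self, arena, model):
        (bat,) = spawn_bats(1, 2, arena)
        call = PK_SEARCH
        scene = compose_received_scene(bat, call, 0.0, arena, [bat], [], model)
        kinds = {c.kind for c in scene.components}
        assert kinds == {"own_call", "own_wall_echo"}

    def test_wall_echo_delay_is_two_way_travel_time(self, arena, model):
        (bat,) = spawn_bats(1, 2, arena)
        scene = compose_received_scene(bat, PK_SEARCH, 0.0, arena, [bat], [],
                                       model)
        for comp in scene.by_kind("own_wall_echo"):
            D = np.linalg.norm(arena.reflectors[comp.reflector_ref]
                               - bat.position)
            assert comp.delay == pytest.approx(2 * D / model.c, abs=1e-12)

    def test_levels_decrease_with_distance(self, arena, model):
        (bat,) = spawn_bats(1, 2, arena)
        scene = compose_received_scene(bat, PK_SEARCH, 0.0, arena, [bat], [],
                                       model)
        on_axis = [c for c in scene.by_kind("own_wall_echo")
                   if abs(c.true_bearing) < np.deg2rad(10)]
        on_axis.sort(key=lambda c: c.distance)
        levels = [c.level_db for c in on_axis]
        assert all(a >= b for a, b in zip(levels, levels[1:]))

    def test_six_kinds_with_conspecifics_near_wall(self, arena, model):
        bats = spawn_bats(3, 4, arena)
        call = PK_SEARCH
        log = [CallEvent(time=-0.001 * b.id, bat_id=b.id, params=call,
                         position=b.position, heading=b.heading)
               for b in bats[1:]]
        scene = compose_received_scene(bats[0], call, 0.0, arena, bats, log,
                                       model)
        kinds = {c.kind for c in scene.components}
        assert kinds == {"own_call", "own_wall_echo", "own_bat_echo",
                         "conspecific_call", "conspecific_wall_echo",
                         "conspecific_bat_echo"}

    def test_masking_off_keeps_only_own_components(self, arena, model):
        bats = spawn_bats(3, 4, arena)
        log = [CallEvent(time=-0.004, bat_id=b.id, params=PK_SEARCH,
                         position=b.position, heading=b.heading)
               for b in bats[1:]]
        scene = compose_received_scene(bats[0], PK_SEARCH, 0.0, arena, bats,
                                       log, model, masking=False)
        kinds = {c.kind for c in scene.components}
        assert kinds <= {"own_call", "own_wall_echo", "own_bat_echo"}

    def test_echoes_after_next_emission_discarded(self, arena, model):
        (bat,) = spawn_bats(1, 2, arena)
        short = CallParams(ipi_ms=5, duration_ms=0.5, terminal_freq_khz=39,
                           bandwidth_khz=20, level_db=120)
        scene = compose_received_scene(bat, short, 0.0, arena, [bat], [],
                                       model)
        assert all(c.delay <= short.ipi_s for c in scene.components)
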