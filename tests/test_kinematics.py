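"""Wave-parameter estimators: recovery, invariances, degenerate inputs."""

import numpy as np
import pytest

from swimtrack.core import MidlineSequence
from swimtrack.errors import (
    IncoherentWaveError,
    InsufficientCyclesError,
    NoNetTravelError,
    NoOscillationError,
    ValidationError,
    WaveNotResolvedError,
)
from swimtrack.kinematics import (
    ExcursionField,
    body_frame,
    compute_wave_kinematics,
    estimate_amplitude,
    estimate_frequency,
    estimate_speed,
    estimate_wave_speed,
    estimate_wavelength,
    steady_state_filter,
    waves_per_body,
)
from swimtrack.synthetic import SwimmerParams, generate_midline_sequence

FPS = 250.0


def _seq(n_frames=400, fps=FPS, **kw):
    defaults = dict(wavelength_bl=0.79, frequency_hz=3.6, amp_pp_tail_bl=0.16,
                    amp_ratio=4.8, speed_bl_s=1.83)
    defaults.update(kw)
    return generate_midline_sequence(SwimmerParams(**defaults), fps, n_frames)


class TestBodyFrame:
    def test_straight_zero_amplitude_gives_flat_field(self):
        sm = _seq(amp_pp_tail_bl=0.0, amp_ratio=1.0, n_frames=100)
        field = body_frame(sm.observed)
        assert np.abs(field.h).max() < 1e-9

    def test_tail_station_sinusoid_at_half_pp(self, fifth_gill_midlines):
        field = body_frame(fifth_gill_midlines.observed)
        i = field.station_index(1.0)
        half_amp = (field.h[i].max() - field.h[i].min()) / 2.0
        assert half_amp == pytest.approx(0.11 / 2.0, rel=0.02)

    def test_rotation_invariance(self):
        a = _seq(heading_deg=0.0, n_frames=300)
        b = _seq(heading_deg=37.0, n_frames=300)
        fa, fb = body_frame(a.observed), body_frame(b.observed)
        assert np.allclose(fa.h, fb.h, atol=1e-6)

    def test_station_holding_has_no_heading(self):
        sm = _seq(speed_bl_s=0.0, n_frames=200)
        with pytest.raises(NoNetTravelError):
            body_frame(sm.observed)


class TestSpeed:
    def test_transected_mean_speed_recovered(self):
        sm = _seq(speed_bl_s=1.12, n_frames=500)
        u = estimate_speed(sm.observed)
        assert u == pytest.approx(1.12, rel=0.01)

    def test_frame_rate_does_not_change_speed(self):
        u1 = estimate_speed(_seq(fps=250.0, n_frames=250).observed)
        u2 = estimate_speed(_seq(fps=500.0, n_frames=500).observed)
        assert u1 == pytest.approx(u2, rel=1e-3)


class TestFrequency:
    def test_sham_frequency_within_half_percent(self, sham_midlines):
        f, _ = estimate_frequency(body_frame(sham_midlines.observed))
        assert f == pytest.approx(3.6, rel=0.005)

    def test_flat_excursion_raises(self):
        sm = _seq(amp_pp_tail_bl=0.0, amp_ratio=1.0, n_frames=200)
        with pytest.raises(NoOscillationError):
            estimate_frequency(body_frame(sm.observed))

    def test_sampling_rate_robust(self):
        f1, _ = estimate_frequency(body_frame(
            _seq(frequency_hz=4.1, fps=1000.0, n_frames=1000).observed))
        f2, _ = estimate_frequency(body_frame(
            _seq(frequency_hz=4.1, fps=250.0, n_frames=250).observed))
        assert f1 == pytest.approx(f2, rel=0.01)

    def test_too_few_cycles(self):
        sm = _seq(n_frames=40)  # 0.16 s < one period
        with pytest.raises(InsufficientCyclesError):
            estimate_frequency(body_frame(sm.observed))


class TestAmplitude:
    def test_sham_peak_to_peak_recovered(self, sham_midlines):
        amp, _, _ = estimate_amplitude(body_frame(sham_midlines.observed))
        assert amp == pytest.approx(0.16, rel=0.02)

    def test_growth_ratio_recovered(self, sham_midlines):
        _, _, ratio = estimate_amplitude(body_frame(sham_midlines.observed))
        assert ratio == pytest.approx(4.8, rel=0.05)

    def test_uniform_envelope_ratio_one(self):
        sm = _seq(amp_ratio=1.0, amp_pp_tail_bl=0.12, n_frames=300)
        _, _, ratio = estimate_amplitude(body_frame(sm.observed))
        assert ratio == pytest.approx(1.0, abs=0.02)


class TestWavelength:
    def test_fifth_gill_wavelength_recovered(self, fifth_gill_midlines):
        lam, fit_based = estimate_wavelength(body_frame(fifth_gill_midlines.observed))
        assert not fit_based
        assert lam == pytest.approx(0.53, rel=0.02)

    def test_long_wave_falls_back_to_fit(self):
        sm = _seq(wavelength_bl=2.0, amp_pp_tail_bl=0.12, amp_ratio=1.0,
                  n_frames=400)
        lam, fit_based = estimate_wavelength(body_frame(sm.observed))
        assert fit_based
        assert lam == pytest.approx(2.0, rel=0.05)

    def test_straight_body_not_resolved(self):
        sm = _seq(amp_pp_tail_bl=0.0, amp_ratio=1.0, n_frames=200)
        with pytest.raises(WaveNotResolvedError):
            estimate_wavelength(body_frame(sm.observed))


class TestWaveSpeed:
    def test_phase_speed_equals_lambda_f(self):
        sm = _seq(wavelength_bl=0.6, frequency_hz=4.0, amp_pp_tail_bl=0.12,
                  amp_ratio=1.5, n_frames=500)
        v = estimate_wave_speed(body_frame(sm.observed))
        assert v == pytest.approx(2.4, rel=0.03)

    def test_internal_consistency_on_sham(self, sham_midlines):
        field = body_frame(sham_midlines.observed)
        f, _ = estimate_frequency(field)
        lam, _ = estimate_wavelength(field)
        v = estimate_wave_speed(field, frequency_hz=f)
        assert v == pytest.approx(lam * f, rel=0.10)

    def test_standing_wave_incoherent(self):
        # two counter-propagating waves: h = A sin(ks) cos(wt)
        s = np.linspace(0, 1, 100)
        t = np.arange(500) / FPS
        h = 0.05 * np.sin(2 * np.pi * s[:, None] / 0.6) * np.cos(
            2 * np.pi * 4.0 * t[None, :]
        )
        field = ExcursionField(
            h=h, s=s, times=t, heading=np.array([1.0, 0.0]),
            com_track=np.column_stack([1.5 * t, np.zeros_like(t)]),
            body_length=1.0,
        )
        with pytest.raises(IncoherentWaveError):
            estimate_wave_speed(field, frequency_hz=4.0)


class TestSteadyState:
    def test_constant_speed_passes(self, sham_midlines):
        res = steady_state_filter(sham_midlines.observed)
        assert res.passed
        assert np.allclose(res.cycle_speeds_bl_s, res.mean_speed_bl_s, rtol=0.02)

    def test_accelerating_clip_fails(self, sham_midlines):
        seq = sham_midlines.observed
        t = seq.times
        # superimpose a ramp: speed doubles over the clip
        extra = 1.83 * t**2 / (2 * t[-1])
        xy = seq.xy.copy()
        xy[..., 0] += extra[:, None]
        ramped = MidlineSequence(xy, seq.frame_rate_hz)
        assert not steady_state_filter(ramped).passed

    def test_small_noise_still_passes(self):
        sm = _seq(noise_sd_bl=0.005, n_frames=500)
        assert steady_state_filter(sm.observed).passed

    def test_single_cycle_insufficient(self):
        sm = _seq(n_frames=80)  # ~1.1 cycles
        with pytest.raises(InsufficientCyclesError):
            steady_state_filter(sm.observed)


class TestWavesPerBody:
    @pytest.mark.parametrize("lam,expected", [(0.53, 1.8868), (1.0, 1.0), (0.5, 2.0)])
    def test_reciprocal(self, lam, expected):
        assert waves_per_body(lam) == pytest.approx(expected, abs=1e-4)

    def test_invalid(self):
        with pytest.raises(ValidationError):
            waves_per_body(0.0)


class TestFullExtraction:
    def test_scale_invariance(self, fifth_gill_midlines):
        seq = fifth_gill_midlines.observed
        scaled = MidlineSequence(seq.xy * 220.0, seq.frame_rate_hz,
                                 pixels_per_bl=220.0)
        wk1 = compute_wave_kinematics(seq)
        wk2 = compute_wave_kinematics(scaled)
        for attr in ("speed_bl_s", "frequency_hz", "amp_pp_bl",
                     "wavelength_bl", "wave_speed_bl_s", "amp_ratio"):
            assert getattr(wk1, attr) == pytest.approx(getattr(wk2, attr), rel=1e-6)

    def test_noise_free_recovery_within_two_percent(self, fifth_gill_midlines):
        wk = compute_wave_kinematics(fifth_gill_midlines.observed)
        assert wk.wavelength_bl == pytest.approx(0.53, rel=0.02)
        assert wk.frequency_hz == pytest.approx(4.1, rel=0.02)
        assert wk.amp_pp_bl == pytest.approx(0.11, rel=0.02)
        assert wk.speed_bl_s == pytest.approx(1.12, rel=0.02)
        assert wk.amp_ratio == pytest.approx(1.7, rel=0.05)
        assert wk.wave_speed_consistent

    def test_noisy_recovery_within_five_percent(self):
        sm = _seq(wavelength_bl=0.61, frequency_hz=3.7, amp_pp_tail_bl=0.13,
                  amp_ratio=1.9, speed_bl_s=1.12, noise_sd_bl=0.005,
                  n_frames=500)
        wk = compute_wave_kinematics(sm.observed)
        assert wk.wavelength_bl == pytest.approx(0.61, rel=0.05)
        assert wk.frequency_hz == pytest.approx(3.7, rel=0.05)
        assert wk.amp_pp_bl == pytest.approx(0.13, rel=0.05)
        assert wk.speed_bl_s == pytest.approx(1.12, rel=0.05)
        assert wk.amp_ratio == pytest.approx(1.9, rel=0.10)
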