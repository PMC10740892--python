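"""Pulse construction: shapes, charge formulas, quantization, PFM trains."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vestibsim.errors import InvalidSpecError
from vestibsim.stimgen import (
    Polarity,
    PulseShape,
    WaveformSpec,
    charge_per_phase,
    pfm_train,
    quantize_current,
    render_waveform,
    spec_from_json,
    spec_to_json,
    waveform_from_csv,
    waveform_grid,
    waveform_to_csv,
)

SLOPES = [15.0, 30.0, 45.0, 60.0]
RAMP_SHAPES = [PulseShape.RAMP_UP, PulseShape.RAMP_DOWN, PulseShape.RAMP_UP_DOWN]


def _spec(shape, slope=None, **kw):
    defaults = dict(phase_us=200.0, amp_uA=240.0)
    defaults.update(kw)
    return WaveformSpec(shape=shape, slope_deg=slope, **defaults)


def _numeric_charge_nC(spec):
    """Independent oracle: fine-grid integration of the rendered envelope."""
    fine = WaveformSpec(
        shape=spec.shape, slope_deg=spec.slope_deg, polarity=spec.polarity,
        phase_us=spec.phase_us, amp_uA=spec.amp_uA, gap_frac=spec.gap_frac,
        dt_us=spec.phase_us / 20000.0, step_uA=0.0,
    )
    w = render_waveform(fine)
    n_phase = int(round(fine.phase_us / fine.dt_us))
    return abs(np.sum(w.i_uA[:n_phase]) * fine.dt_us) / 1e3


class TestRender:
    def test_rect_standard_pulse(self):
        w = render_waveform(_spec(PulseShape.RECT))
        assert np.all(w.i_uA[:100] == -240.0)       # cathodic first phase
        assert np.all(w.i_uA[100:110] == 0.0)       # 10% interphase gap
        assert np.all(w.i_uA[110:210] == 240.0)     # anodic second phase
        assert w.t_us[1] - w.t_us[0] == 2.0

    def test_ramp45_is_pure_triangle_to_amp(self):
        w = render_waveform(_spec(PulseShape.RAMP_UP, 45.0))
        phase = -w.i_uA[:100]  # cathodic-first: negate
        # linear rise from zero reaching the nominal amplitude at phase offset
        assert phase[0] < phase[50] < phase[-1]
        assert np.isclose(phase[-1], 240.0, rtol=0.02)
        ramp_rate = np.diff(phase)
        assert np.allclose(ramp_rate, ramp_rate[0])

    def test_ramp_down_mirrors_ramp_up_in_time(self):
        up = render_waveform(_spec(PulseShape.RAMP_UP, 30.0))
        down = render_waveform(_spec(PulseShape.RAMP_DOWN, 30.0))
        assert np.allclose(up.i_uA[:100], down.i_uA[:100][::-1])

    def test_subunity_slope_peaks_below_amp(self):
        w = render_waveform(_spec(PulseShape.RAMP_UP, 30.0))
        peak = np.abs(w.i_uA).max()
        assert np.isclose(peak, math.tan(math.radians(30.0)) * 240.0, rtol=0.02)

    def test_zero_amplitude_renders_all_zero(self):
        w = render_waveform(_spec(PulseShape.RECT, amp_uA=0.0))
        assert np.all(w.i_uA == 0.0)
        assert len(w.i_uA) == 210

    @pytest.mark.parametrize(
        "kw",
        [dict(phase_us=-5.0), dict(phase_us=200.0, dt_us=-1.0),
         dict(phase_us=1.0, dt_us=2.0), dict(phase_us=200.0, gap_frac=1.0),
         dict(phase_us=200.0, amp_uA=-3.0)],
    )
    def test_invalid_specs_rejected(self, kw):
        base = dict(shape=PulseShape.RECT, amp_uA=240.0)
        base.update(kw)
        with pytest.raises(InvalidSpecError):
            WaveformSpec(**base)

    def test_ramp_without_slope_rejected(self):
        with pytest.raises(InvalidSpecError):
            WaveformSpec(shape=PulseShape.RAMP_UP, phase_us=200, amp_uA=240)
        with pytest.raises(InvalidSpecError):
            _spec(PulseShape.RAMP_UP, 120.0)


class TestCharge:
    def test_printed_rect_and_triangle_values(self):
        assert charge_per_phase(_spec(PulseShape.RECT)) == pytest.approx(48.0)
        # 45-degree ramp is the triangle: half the rectangle's charge
        assert charge_per_phase(_spec(PulseShape.RAMP_UP, 45.0)) == pytest.approx(24.0)

    @pytest.mark.parametrize("shape", [PulseShape.RECT] + RAMP_SHAPES)
    @pytest.mark.parametrize("slope", SLOPES)
    def test_closed_form_matches_numeric_integral(self, shape, slope):
        spec = _spec(shape, None if shape is PulseShape.RECT else slope)
        closed = charge_per_phase(spec)
        numeric = _numeric_charge_nC(spec)
        assert closed == pytest.approx(numeric, rel=1e-3)

    @pytest.mark.parametrize("shape", RAMP_SHAPES)
    def test_charge_monotone_in_slope(self, shape):
        slopes = np.linspace(5.0, 89.0, 40)
        q = [charge_per_phase(_spec(shape, s)) for s in slopes]
        assert np.all(np.diff(q) >= -1e-12)


class TestQuantize:
    def test_full_ramp_has_twelve_levels(self):
        w = render_waveform(_spec(PulseShape.RAMP_UP, 45.0))
        q = quantize_current(w, 20.0)
        levels = np.unique(np.abs(q.i_uA))
        assert np.all(levels % 20.0 == 0)
        assert len(levels[levels > 0]) == 12  # 240 / 20

    def test_step_zero_is_identity(self):
        w = render_waveform(_spec(PulseShape.RAMP_UP, 30.0))
        assert quantize_current(w, 0.0) is w

    def test_round_half_away_from_zero(self):
        w = render_waveform(_spec(PulseShape.RECT, amp_uA=15.0))
        q = quantize_current(w, 20.0)
        assert np.all(np.abs(q.i_uA[:100]) == 20.0)

    def test_negative_step_rejected(self):
        w = render_waveform(_spec(PulseShape.RECT))
        with pytest.raises(InvalidSpecError):
            quantize_current(w, -1.0)


@st.composite
def waveform_specs(draw):
    shape = draw(st.sampled_from(list(PulseShape)))
    slope = None if shape is PulseShape.RECT else draw(
        st.floats(min_value=5.0, max_value=85.0)
    )
    return WaveformSpec(
        shape=shape,
        slope_deg=slope,
        polarity=draw(st.sampled_from(list(Polarity))),
        phase_us=draw(st.floats(min_value=20.0, max_value=1000.0)),
        amp_uA=draw(st.floats(min_value=0.0, max_value=2000.0)),
        gap_frac=draw(st.floats(min_value=0.0, max_value=0.5)),
    )


class TestInvariants:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(waveform_specs())
    def test_charge_balance_and_polarity_mirror(self, spec):
        w = render_waveform(spec)
        # exact charge balance before quantization
        assert abs(w.net_charge_nC()) < 1e-9 * max(spec.amp_uA, 1.0)
        # flipping polarity negates the waveform sample-wise
        flipped = WaveformSpec(
            shape=spec.shape, slope_deg=spec.slope_deg,
            polarity=(Polarity.ANODIC_FIRST if spec.polarity is Polarity.CATHODIC_FIRST
                      else Polarity.CATHODIC_FIRST),
            phase_us=spec.phase_us, amp_uA=spec.amp_uA, gap_frac=spec.gap_frac,
        )
        assert np.array_equal(render_waveform(flipped).i_uA, -w.i_uA)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(waveform_specs())
    def test_quantized_net_charge_bounded(self, spec):
        q = render_waveform(spec, quantize=True)
        # antisymmetric quantization keeps residual below one step-sample
        assert abs(q.net_charge_nC()) <= spec.step_uA * spec.dt_us / 1e3 + 1e-12


class TestPFM:
    def test_unmodulated_train_is_uniform(self, rect200):
        tr = pfm_train(100.0, 0.0, 0.0, 1.0, rect200)
        assert abs(len(tr.pulse_times_s) - 100) <= 1
        ipi = np.diff(tr.pulse_times_s)
        assert np.allclose(ipi, 0.01, rtol=1e-3)

    def test_pulse_count_matches_rate_integral(self, rect200):
        tr = pfm_train(100.0, 2.0, 50.0, 1.0, rect200)
        t = np.linspace(0.0, 1.0, 200001)
        expected = np.trapezoid(100.0 + 50.0 * np.sin(2 * np.pi * 2.0 * t), t)
        assert abs(len(tr.pulse_times_s) - round(expected)) <= 1

    def test_two_hz_modulation_gives_two_ipi_minima(self, rect200):
        tr = pfm_train(100.0, 2.0, 50.0, 1.0, rect200)
        t_mid = 0.5 * (tr.pulse_times_s[1:] + tr.pulse_times_s[:-1])
        ipi = np.diff(tr.pulse_times_s)
        # one IPI minimum per modulation cycle, at each rate peak
        for lo, hi in [(0.0, 0.5), (0.5, 1.0)]:
            half = ipi[(t_mid >= lo) & (t_mid < hi)]
            t_half = t_mid[(t_mid >= lo) & (t_mid < hi)]
            t_min = t_half[np.argmin(half)]
            assert abs(t_min - (lo + 0.125)) < 0.05  # sin peak at cycle/4

    def test_excess_depth_rejected(self, rect200):
        with pytest.raises(InvalidSpecError):
            pfm_train(100.0, 2.0, 150.0, 1.0, rect200)

    def test_deterministic(self, rect200):
        a = pfm_train(180.0, 2.0, 90.0, 0.5, rect200)
        b = pfm_train(180.0, 2.0, 90.0, 0.5, rect200)
        assert np.array_equal(a.pulse_times_s, b.pulse_times_s)


class TestGrid:
    def test_four_shapes_two_polarities_is_eight(self):
        specs = waveform_grid(list(PulseShape), list(Polarity), [30.0])
        assert len(specs) == 8

    def test_rect_collapses_slopes(self):
        specs = waveform_grid([PulseShape.RECT], list(Polarity), [15.0, 30.0])
        assert len(specs) == 2
        assert all(s.slope_deg is None for s in specs)

    def test_single_combination(self):
        specs = waveform_grid([PulseShape.RAMP_UP], [Polarity.CATHODIC_FIRST], [30.0])
        assert len(specs) == 1

    def test_empty_factor_rejected(self):
        with pytest.raises(InvalidSpecError):
            waveform_grid([], list(Polarity), [30.0])


class TestSerialization:
    def test_waveform_csv_roundtrip(self, tmp_path, rect200):
        w = render_waveform(rect200, quantize=True)
        p = tmp_path / "wave.csv"
        waveform_to_csv(w, p)
        w2 = waveform_from_csv(p, spec=rect200)
        assert np.allclose(w.t_us, w2.t_us)
        assert np.allclose(w.i_uA, w2.i_uA)

    def test_spec_json_roundtrip(self, tmp_path):
        spec = WaveformSpec(shape=PulseShape.RAMP_UP_DOWN, slope_deg=60.0,
                            phase_us=120.0, amp_uA=180.0,
                            polarity=Polarity.ANODIC_FIRST)
        p = tmp_path / "spec.json"
        spec_to_json(spec, p)
        assert spec_from_json(p) == spec
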