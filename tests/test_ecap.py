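"""eCAP synthesis, filtering, amplitude metrics and threshold rules."""

import numpy as np
import pytest

from vestibsim.afferents import RecruitmentCurve, SimResult, recruitment_curve
from vestibsim.ecap import (
    ECAPTrace,
    Thresholds,
    add_noise,
    ecap_amplitude,
    ecap_sweep,
    ecap_threshold,
    growth_function,
    lowpass_filter,
    sensory_threshold,
    synthesize_ecap,
)
from vestibsim.errors import AlignmentError, InvalidSpecError
from vestibsim.fields import LeadField
from vestibsim.stimgen import WaveformSpec


def _sim_result(i_m, dt_us=2.0):
    n_t, n_nodes = i_m.shape
    t = np.arange(n_t) * dt_us * 1e-3
    return SimResult(
        t_ms=t, v_m=np.zeros_like(i_m), i_m=i_m,
        spike_times_ms=np.full(n_nodes, np.nan), activated=False,
        dt_us=dt_us, duration_ms=float(t[-1]),
    )


def _trace(v, dt_ms=0.002, stim_end_ms=0.0):
    v = np.asarray(v, dtype=float)
    return ECAPTrace(t_ms=np.arange(len(v)) * dt_ms, v_rec_uV=v,
                     stim_end_ms=stim_end_ms)


class TestSynthesize:
    def test_single_compartment_unit_weight_passthrough(self):
        i_m = np.sin(np.linspace(0, 4 * np.pi, 200))[:, None]
        res = _sim_result(i_m)
        trace = synthesize_ecap([res], [LeadField("rec", np.array([1.0]))])
        assert np.allclose(trace.v_rec_uV, i_m[:, 0])

    def test_zero_weights_zero_trace(self):
        res = _sim_result(np.random.default_rng(0).normal(size=(100, 5)))
        trace = synthesize_ecap([res], [LeadField("rec", np.zeros(5))])
        assert np.all(trace.v_rec_uV == 0.0)

    def test_superposition_over_fibers(self):
        rng = np.random.default_rng(1)
        results = [_sim_result(rng.normal(size=(50, 4))) for _ in range(3)]
        leads = [LeadField("rec", rng.normal(size=4)) for _ in range(3)]
        combined = synthesize_ecap(results, leads)
        parts = [synthesize_ecap([r], [lf]) for r, lf in zip(results, leads)]
        assert np.allclose(combined.v_rec_uV,
                           sum(p.v_rec_uV for p in parts))

    def test_mismatched_time_grids_rejected(self):
        a = _sim_result(np.zeros((50, 3)))
        b = _sim_result(np.zeros((60, 3)))
        with pytest.raises(AlignmentError):
            synthesize_ecap([a, b], [LeadField("rec", np.zeros(3))] * 2)


class TestFilter:
    def test_dc_gain_unity(self):
        tr = lowpass_filter(_trace(np.full(4000, 3.0)))
        assert tr.filtered
        assert tr.v_rec_uV[-1] == pytest.approx(3.0, rel=1e-3)

    def test_half_power_at_cutoff(self):
        # 7.5 kHz sinusoid sampled at 500 kHz -> amplitude must drop to 1/sqrt(2)
        t_ms = np.arange(0, 10.0, 0.002)
        sine = np.sin(2 * np.pi * 7.5 * t_ms)
        tr = lowpass_filter(_trace(sine))
        steady = tr.v_rec_uV[len(t_ms) // 2:]
        assert np.max(np.abs(steady)) == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_stopband_attenuation_at_4fc(self):
        # |H| = 1/sqrt(1 + (f/fc)^(2*order)); 4x cutoff, order 4 -> >= 40 dB
        t_ms = np.arange(0, 10.0, 0.002)
        sine = np.sin(2 * np.pi * 30.0 * t_ms)
        tr = lowpass_filter(_trace(sine), fc_khz=7.5, order=4)
        atten_db = -20 * np.log10(np.max(np.abs(tr.v_rec_uV[len(t_ms) // 2:])))
        assert atten_db >= 40.0

    def test_energy_non_increasing(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=5000)
        tr = lowpass_filter(_trace(v))
        assert np.sum(tr.v_rec_uV**2) <= np.sum(v**2)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidSpecError):
            lowpass_filter(_trace(np.zeros(100)), fc_khz=300.0)

    def test_noise_is_seeded(self):
        tr = _trace(np.zeros(100))
        a = add_noise(tr, 1.0, seed=9)
        b = add_noise(tr, 1.0, seed=9)
        assert np.array_equal(a.v_rec_uV, b.v_rec_uV)
        assert not np.array_equal(a.v_rec_uV, tr.v_rec_uV)


class TestAmplitude:
    def test_peak_to_trough_arithmetic(self):
        v = np.zeros(100)
        v[40], v[60] = 5.0, -3.0
        assert ecap_amplitude(_trace(v)) == pytest.approx(8.0)

    def test_flat_trace_zero(self):
        assert ecap_amplitude(_trace(np.zeros(50))) == 0.0

    def test_dc_offset_invariant(self):
        v = np.sin(np.linspace(0, 6, 200))
        assert ecap_amplitude(_trace(v + 100.0)) == pytest.approx(
            ecap_amplitude(_trace(v))
        )

    def test_window_opens_at_stimulus_end(self):
        v = np.zeros(100)
        v[10] = 50.0   # inside the artifact window: must be ignored
        v[80] = 5.0
        tr = _trace(v, stim_end_ms=0.05)
        assert ecap_amplitude(tr) == pytest.approx(5.0)

    def test_fully_blanked_trace_undefined(self):
        tr = _trace(np.ones(10), stim_end_ms=1e6)
        assert ecap_amplitude(tr) is None


class TestThresholdRules:
    def _curve(self, amps, fracs, branch="LH"):
        return RecruitmentCurve(
            amplitudes_uA=np.asarray(amps, dtype=float),
            fraction_active={branch: np.asarray(fracs, dtype=float)},
            spec=WaveformSpec(shape="rect", phase_us=200.0, amp_uA=240.0),
            stim_label=f"{branch}_stim",
        )

    def test_step_curve_threshold(self):
        curve = self._curve([10, 20, 40, 80], [0.0, 0.0, 0.5, 1.0])
        thr = sensory_threshold(curve)
        assert thr.ST_uA == 40.0

    def test_discomfort_ratio_is_exact(self):
        thr = Thresholds(ST_uA=30.0)
        assert thr.DT_uA == pytest.approx(42.0)
        assert thr.dynamic_range_uA == (30.0, pytest.approx(42.0))

    def test_upper_limit_caps_dynamic_range(self):
        thr = Thresholds(ST_uA=30.0, UL_uA=35.0)
        assert thr.dynamic_range_uA == (30.0, 35.0)

    def test_never_reached_signals_none(self):
        curve = self._curve([10, 20, 40], [0.0, 0.0, 0.0])
        assert sensory_threshold(curve) is None

    def test_facial_branch_sets_upper_limit(self):
        curve = RecruitmentCurve(
            amplitudes_uA=np.array([10.0, 20.0, 40.0, 80.0]),
            fraction_active={
                "LH": np.array([0.0, 0.5, 1.0, 1.0]),
                "FACIAL": np.array([0.0, 0.0, 0.0, 0.1]),
            },
            spec=WaveformSpec(shape="rect", phase_us=200.0, amp_uA=240.0),
            stim_label="LH_stim",
        )
        thr = sensory_threshold(curve)
        assert thr.ST_uA == 20.0 and thr.UL_uA == 80.0


@pytest.fixture(scope="module")
def sweep(anatomy9, rect200, surrogate_model, tissue):
    grid = np.geomspace(10.0, 1000.0, 13)
    amps = ecap_sweep(anatomy9, rect200, grid, surrogate_model, tissue, "LH")
    return grid, amps


class TestECAPThreshold:

    def test_undetectable_criterion_signals_none(self, anatomy9, rect200,
                                                 surrogate_model, tissue, sweep):
        grid, amps = sweep
        thr = ecap_threshold(anatomy9, rect200, detection_uV=10.0 * amps.max(),
                             grid_uA=grid, model=surrogate_model, medium=tissue)
        assert thr is None

    def test_threshold_monotone_in_detection_criterion(self, anatomy9, rect200,
                                                       surrogate_model, tissue, sweep):
        grid, amps = sweep
        lo = ecap_threshold(anatomy9, rect200, detection_uV=1.0, grid_uA=grid,
                            model=surrogate_model, medium=tissue)
        hi = ecap_threshold(anatomy9, rect200, detection_uV=0.8 * amps.max(),
                            grid_uA=grid, model=surrogate_model, medium=tissue)
        assert lo <= hi

    def test_invalid_detection_rejected(self, anatomy9, rect200, surrogate_model, tissue):
        with pytest.raises(InvalidSpecError):
            ecap_threshold(anatomy9, rect200, detection_uV=0.0,
                           model=surrogate_model, medium=tissue)

    def test_agrees_with_recruitment_threshold(self, anatomy30, rect200,
                                               hh_model, tissue):
        """Two threshold routes, one answer: the 1 uV eCAP criterion lands on
        the same grid amplitude as the 10% recruitment rule."""
        grid = np.geomspace(10.0, 1000.0, 25)
        curve = recruitment_curve(anatomy30, rect200, grid, model=hh_model,
                                  medium=tissue, stim_branch="LH")
        st = sensory_threshold(curve, target_branch="LH").ST_uA
        et = ecap_threshold(anatomy30, rect200, detection_uV=1.0, grid_uA=grid,
                            model=hh_model, medium=tissue, branch="LH")
        step = grid[1] / grid[0]
        assert et / st <= step * 1.0001 and st / et <= step * 1.0001


class TestGrowthFunction:
    def test_all_subthreshold_is_flat(self, anatomy9, rect200, surrogate_model, tissue):
        levels = np.linspace(0.1, 1.0, 6)  # far below every fiber threshold
        gf = growth_function(anatomy9, rect200, levels, surrogate_model, tissue)
        assert gf is not None
        assert abs(gf.slope) < 1e-6

    def test_lead_scaling_doubles_slope(self, anatomy9, rect200, surrogate_model, tissue):
        levels = np.geomspace(10.0, 1000.0, 9)
        g1 = growth_function(anatomy9, rect200, levels, surrogate_model, tissue)
        g2 = growth_function(anatomy9, rect200, levels, surrogate_model, tissue,
                             lead_scale=2.0)
        assert g2.slope == pytest.approx(2.0 * g1.slope, rel=1e-6)

    def test_recruitment_drives_positive_slope(self, anatomy9, rect200,
                                               surrogate_model, tissue):
        levels = np.geomspace(10.0, 1000.0, 9)
        gf = growth_function(anatomy9, rect200, levels, surrogate_model, tissue)
        assert gf.slope > 0.0

    def test_too_few_levels_rejected(self, anatomy9, rect200, surrogate_model, tissue):
        with pytest.raises(InvalidSpecError):
            growth_function(anatomy9, rect200, np.array([10.0, 100.0]),
                            surrogate_model, tissue)
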