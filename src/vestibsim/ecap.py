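"""Electrically evoked compound action potentials (eCAPs).

An eCAP is the summed extracellular signature of synchronously firing
fibers seen by a non-stimulating electrode.  By reciprocity, the voltage a
compartment's transmembrane current impresses on a recording electrode
equals the potential a unit current at that electrode would impress at the
compartment, so recording reduces to a weighted sum of compartment
currents with lead-field weights.  Bipolar differential traces subtract a
nearby reference electrode; traces are low-pass filtered (Butterworth,
7.5 kHz cutoff) to emulate recording-chain bandwidth before the P-N
(peak-to-trough) amplitude is measured.

The direct capacitive stimulus artifact is not modeled; instead the
measurement window opens at the pulse offset, mirroring the artifact
blanking real eCAP systems apply.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal

from .afferents import (
    Kinetics,
    MembraneModel,
    SimResult,
    _fiber_drive_unit,
    _integrate_hh,
    _prepare_drive,
    simulate_fiber,
)
from .anatomy import Anatomy
from .errors import AlignmentError, InvalidSpecError
from .fields import LeadField, Medium, lead_field
from .stimgen import WaveformSpec
from .afferents import RecruitmentCurve

__all__ = [
    "ECAPTrace",
    "Thresholds",
    "GrowthFunction",
    "synthesize_ecap",
    "lowpass_filter",
    "add_noise",
    "ecap_amplitude",
    "sensory_threshold",
    "ecap_sweep",
    "ecap_threshold",
    "growth_function",
]

#: default eCAP detection criterion (uV); the choice is a free parameter of
#: the analysis and is configurable everywhere it is used.
DETECTION_UV = 1.0


@dataclass
class ECAPTrace:
    """Recorded eCAP: per-electrode voltage and optional differential."""

    t_ms: np.ndarray
    v_rec_uV: np.ndarray
    v_ref_uV: np.ndarray | None = None
    rec_label: str = ""
    ref_label: str = ""
    filtered: bool = False
    stim_end_ms: float = 0.0  # measurement window opens here

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])

    @property
    def differential_uV(self) -> np.ndarray:
        """Bipolar recording: record minus reference electrode."""
        if self.v_ref_uV is None:
            raise InvalidSpecError("no reference electrode in this trace")
        return self.v_rec_uV - self.v_ref_uV

    @property
    def best_uV(self) -> np.ndarray:
        return self.differential_uV if self.v_ref_uV is not None else self.v_rec_uV


@dataclass
class Thresholds:
    """Sensory threshold, discomfort threshold and facial-nerve upper limit.

    DT is tied to ST by the fixed clinical ratio 1.4; the usable dynamic
    range runs from ST up to the smaller of DT and the facial-nerve limit.
    """

    ST_uA: float
    UL_uA: float | None = None

    @property
    def DT_uA(self) -> float:
        return 1.4 * self.ST_uA

    @property
    def dynamic_range_uA(self) -> tuple[float, float]:
        hi = self.DT_uA if self.UL_uA is None else min(self.DT_uA, self.UL_uA)
        return (self.ST_uA, hi)


@dataclass
class GrowthFunction:
    """eCAP amplitude versus stimulus level with its rising-segment slope."""

    levels: np.ndarray           # abscissa values (uA or nC)
    ecap_amp_uV: np.ndarray
    slope: float                 # uV per abscissa unit
    segment: np.ndarray          # indices used for the slope fit
    abscissa: str = "amplitude"  # "amplitude" (uA) or "charge" (nC)


def synthesize_ecap(
    sim_results: list[SimResult],
    rec_leads: list[LeadField],
    ref_leads: list[LeadField] | None = None,
    stim_end_ms: float = 0.0,
) -> ECAPTrace:
    """Reciprocity-based eCAP: weighted sum of all transmembrane currents.

    ``rec_leads``/``ref_leads`` hold one LeadField per simulated fiber,
    aligned with ``sim_results``; weights are ohms, currents uA, so the
    trace comes out in microvolts.
    """
    if not sim_results:
        raise InvalidSpecError("need at least one simulated fiber")
    t0 = sim_results[0].t_ms
    for r in sim_results[1:]:
        if r.t_ms.shape != t0.shape or not np.allclose(r.t_ms, t0):
            raise AlignmentError("simulation results are on different time grids")
    if len(rec_leads) != len(sim_results):
        raise AlignmentError("one recording lead field per fiber is required")
    v_rec = np.zeros_like(t0)
    for r, lf in zip(sim_results, rec_leads):
        v_rec += r.i_m @ lf.weights
    v_ref = None
    ref_label = ""
    if ref_leads is not None:
        if len(ref_leads) != len(sim_results):
            raise AlignmentError("one reference lead field per fiber is required")
        v_ref = np.zeros_like(t0)
        for r, lf in zip(sim_results, ref_leads):
            v_ref += r.i_m @ lf.weights
        ref_label = ref_leads[0].rec_label
    return ECAPTrace(
        t_ms=t0.copy(),
        v_rec_uV=v_rec,
        v_ref_uV=v_ref,
        rec_label=rec_leads[0].rec_label,
        ref_label=ref_label,
        filtered=False,
        stim_end_ms=stim_end_ms,
    )


def lowpass_filter(
    trace: ECAPTrace,
    fc_khz: float = 7.5,
    order: int = 4,
    zero_phase: bool = False,
) -> ECAPTrace:
    """Butterworth low-pass emulating the recording chain (DC gain 1).

    Causal by default; ``zero_phase`` switches to forward-backward
    filtering (doubling the effective order and removing group delay).
    """
    fs_khz = 1.0 / trace.dt_ms
    if fc_khz <= 0 or fc_khz >= fs_khz / 2.0:
        raise InvalidSpecError(
            f"cutoff {fc_khz} kHz outside (0, Nyquist={fs_khz / 2.0} kHz)"
        )
    sos = signal.butter(order, fc_khz, btype="low", fs=fs_khz, output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    v_rec = np.asarray(filt(sos, trace.v_rec_uV))
    v_ref = None if trace.v_ref_uV is None else np.asarray(filt(sos, trace.v_ref_uV))
    return dc_replace(trace, v_rec_uV=v_rec, v_ref_uV=v_ref, filtered=True)


def add_noise(trace: ECAPTrace, sigma_uV: float, seed: int = 0) -> ECAPTrace:
    """Seeded additive Gaussian noise (for exercising detection logic only)."""
    rng = np.random.default_rng(seed)
    v_rec = trace.v_rec_uV + rng.normal(0.0, sigma_uV, trace.v_rec_uV.shape)
    v_ref = trace.v_ref_uV
    if v_ref is not None:
        v_ref = v_ref + rng.normal(0.0, sigma_uV, v_ref.shape)
    return dc_replace(trace, v_rec_uV=v_rec, v_ref_uV=v_ref)


def ecap_amplitude(trace: ECAPTrace) -> float | None:
    """P-N amplitude: max minus min over the post-stimulus window.

    Returns None when the window is empty (fully blanked trace).
    """
    mask = trace.t_ms >= trace.stim_end_ms
    if not np.any(mask):
        return None
    v = trace.best_uV[mask]
    return float(v.max() - v.min())


def sensory_threshold(
    curve: RecruitmentCurve,
    frac: float = 0.10,
    target_branch: str | None = None,
    facial_branch: str = "FACIAL",
) -> Thresholds | None:
    """Threshold rules applied to a recruitment curve.

    ST is the lowest grid amplitude activating at least ``frac`` of the
    target branch's fibers; DT is fixed at 1.4 x ST; the upper limit UL is
    the lowest amplitude activating any facial-nerve fiber, when a facial
    branch is present.  Returns None when the fraction is never reached.
    """
    if target_branch is None:
        target_branch = curve.stim_label.split("_")[0] if curve.stim_label else None
    if target_branch not in curve.fraction_active:
        raise InvalidSpecError(f"no branch {target_branch!r} in recruitment curve")
    fracs = curve.fraction_active[target_branch]
    idx = np.nonzero(fracs >= frac)[0]
    if idx.size == 0:
        return None
    st = float(curve.amplitudes_uA[idx[0]])
    ul = None
    if facial_branch in curve.fraction_active:
        f_fac = curve.fraction_active[facial_branch]
        jdx = np.nonzero(f_fac > 0)[0]
        if jdx.size:
            ul = float(curve.amplitudes_uA[jdx[0]])
    return Thresholds(ST_uA=st, UL_uA=ul)


# ---------------------------------------------------------------------------
# amplitude sweeps

def _branch_traces_at_amps(
    anatomy: Anatomy,
    spec: WaveformSpec,
    amplitudes: np.ndarray,
    model: MembraneModel,
    medium: Medium,
    branch: str,
    lead_scale: float = 1.0,
) -> list[ECAPTrace]:
    """Filtered differential eCAP of ``branch`` at each amplitude.

    For the cable tier all amplitudes are integrated in one batch per
    fiber; contributions are accumulated fiber by fiber so memory stays
    bounded.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    stim = anatomy.stim_electrode(branch)
    rec_e, ref_e = anatomy.recording_pair(branch)
    fibers = anatomy.branch(branch).fibers
    dt_us = spec.dt_us
    stim_end_ms = spec.duration_us * 1e-3

    wf_ms = None
    v_rec = v_ref = t_ms = None
    for fiber in fibers:
        e_unit = _fiber_drive_unit(fiber, stim, spec, medium)
        if wf_ms is None:
            wf_ms = e_unit.shape[0] * dt_us * 1e-3
        e_pad, _ = _prepare_drive(e_unit, dt_us, None, wf_ms)
        if t_ms is None:
            t_ms = np.arange(e_pad.shape[0]) * dt_us * 1e-3
            v_rec = np.zeros((len(amplitudes), len(t_ms)))
            v_ref = np.zeros((len(amplitudes), len(t_ms)))
        w_rec = lead_field(rec_e, fiber.node_positions_mm, medium).weights * lead_scale
        w_ref = lead_field(ref_e, fiber.node_positions_mm, medium).weights * lead_scale
        if model.kinetics is Kinetics.HH_NODE:
            _, i_full, _, _ = _integrate_hh(
                fiber, e_pad, amplitudes, model, dt_us, keep_traces=True
            )
            # i_full: (n_t, n_nodes, n_amp)
            v_rec += np.einsum("tjs,j->st", i_full, w_rec)
            v_ref += np.einsum("tjs,j->st", i_full, w_ref)
        else:
            for a, amp in enumerate(amplitudes):
                res = simulate_fiber(
                    fiber, e_unit * amp, model, dt_us=dt_us, duration_ms=None
                )
                v_rec[a] += res.i_m @ w_rec
                v_ref[a] += res.i_m @ w_ref
    traces = []
    for a in range(len(amplitudes)):
        tr = ECAPTrace(
            t_ms=t_ms,
            v_rec_uV=v_rec[a],
            v_ref_uV=v_ref[a],
            rec_label=rec_e.label,
            ref_label=ref_e.label,
            stim_end_ms=stim_end_ms,
        )
        traces.append(lowpass_filter(tr))
    return traces


def ecap_sweep(
    anatomy: Anatomy,
    spec: WaveformSpec,
    amplitudes_uA: np.ndarray,
    model: MembraneModel = MembraneModel(),
    medium: Medium = Medium.tissue(),
    branch: str = "LH",
    lead_scale: float = 1.0,
) -> np.ndarray:
    """Filtered differential eCAP P-N amplitude (uV) at each stimulus level."""
    traces = _branch_traces_at_amps(
        anatomy, spec, np.asarray(amplitudes_uA, dtype=float), model, medium,
        branch, lead_scale,
    )
    return np.array([ecap_amplitude(tr) for tr in traces], dtype=float)


def ecap_threshold(
    anatomy: Anatomy,
    spec: WaveformSpec,
    detection_uV: float = DETECTION_UV,
    grid_uA: np.ndarray | None = None,
    model: MembraneModel = MembraneModel(),
    medium: Medium = Medium.tissue(),
    branch: str = "LH",
) -> float | None:
    """Lowest grid amplitude whose eCAP reaches the detection criterion.

    Returns None when no grid amplitude produces a detectable eCAP.
    """
    if detection_uV <= 0:
        raise InvalidSpecError("detection criterion must be positive")
    if grid_uA is None:
        grid_uA = np.logspace(1, 3, 25)
    amps = ecap_sweep(anatomy, spec, grid_uA, model, medium, branch)
    idx = np.nonzero(amps >= detection_uV)[0]
    return float(np.asarray(grid_uA, dtype=float)[idx[0]]) if idx.size else None


def growth_function(
    anatomy: Anatomy,
    spec: WaveformSpec,
    levels_uA: np.ndarray,
    model: MembraneModel = MembraneModel(),
    medium: Medium = Medium.tissue(),
    branch: str = "LH",
    detection_uV: float = DETECTION_UV,
    abscissa: str = "amplitude",
    lead_scale: float = 1.0,
) -> GrowthFunction | None:
    """eCAP growth function and its rising-segment slope.

    The slope is a least-squares fit over the segment from the first
    detectable response up to saturation (within 5 % of the maximum).  With
    no detectable response at any level, the function is flat and the slope
    is fit over all levels (~0).  With 1-2 detectable points the rise
    cannot be characterized and None is returned.  ``abscissa`` chooses
    stimulus current (uA) or charge per phase (nC) as the x axis.
    """
    levels_uA = np.asarray(levels_uA, dtype=float)
    if levels_uA.size < 5:
        raise InvalidSpecError("need at least 5 levels spanning threshold")
    amps = ecap_sweep(anatomy, spec, levels_uA, model, medium, branch, lead_scale)
    if abscissa == "amplitude":
        x = levels_uA
    elif abscissa == "charge":
        from .stimgen import charge_per_phase

        x = np.array([charge_per_phase(spec.with_amp(a)) for a in levels_uA])
    else:
        raise InvalidSpecError(f"unknown abscissa {abscissa!r}")
    supra = amps >= detection_uV
    if supra.sum() == 0:
        segment = np.arange(len(x))
    elif supra.sum() < 3:
        return None
    else:
        rising = supra & (amps <= 0.95 * amps.max())
        segment = np.nonzero(rising)[0]
        if segment.size < 3:
            segment = np.nonzero(supra)[0][:3]
    slope = float(np.polyfit(x[segment], amps[segment], 1)[0])
    return GrowthFunction(
        levels=x, ecap_amp_uV=amps, slope=slope, segment=segment, abscissa=abscissa
    )
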