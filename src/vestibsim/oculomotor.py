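"""VOR-axis prediction, misalignment and the pulse-shape sweep experiment.

The electrically evoked vestibulo-ocular reflex (eVOR) rotates the eye
about an axis that should match the stimulated canal's anatomical axis.
Current spread recruits neighboring ampullary nerves, so the predicted eye
rotation axis is the normalized weighted sum of the canal axes, weighted by
how strongly each nerve is recruited — by default the fraction of its
fibers activated (axial-current weighting can be supplied instead, since
both are computed upstream).  Misalignment is the angle between the
predicted axis and the target canal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afferents import MembraneModel, RecruitmentCurve, recruitment_curve
from .anatomy import Anatomy, canal_axes
from .ecap import DETECTION_UV, Thresholds, ecap_sweep, sensory_threshold
from .errors import InvalidSpecError
from .fields import Medium
from .stimgen import (
    Polarity,
    PulseShape,
    PulseTrain,
    WaveformSpec,
    charge_per_phase,
)

__all__ = [
    "VORPrediction",
    "MisalignmentReport",
    "predict_axis",
    "misalignment",
    "evor_trace",
    "slope_sweep",
]

#: canal-frame component label for each branch
_FRAME_OF_BRANCH = {"LH": "horizontal", "LA": "LARP", "LP": "RALP"}


@dataclass
class VORPrediction:
    axis: np.ndarray             # unit 3-vector
    components: dict[str, float]  # projections onto the canal frame
    magnitude: float             # ||weighted sum|| (arbitrary velocity units)


@dataclass
class MisalignmentReport:
    target_branch: str
    predicted_axis: np.ndarray
    misalignment_deg: float


def predict_axis(
    weights: dict[str, float], axes: dict[str, np.ndarray]
) -> VORPrediction | None:
    """Normalized weighted sum of canal axes; None when all weights vanish."""
    total = np.zeros(3)
    for name, w in weights.items():
        if w < 0:
            raise InvalidSpecError(f"negative recruitment weight for {name}: {w}")
        if name in axes:
            total = total + w * np.asarray(axes[name], dtype=float)
    mag = float(np.linalg.norm(total))
    if mag == 0.0:
        return None
    axis = total / mag
    comps = {
        _FRAME_OF_BRANCH.get(name, name): float(np.dot(axis, np.asarray(ax) / np.linalg.norm(ax)))
        for name, ax in axes.items()
        if name in _FRAME_OF_BRANCH
    }
    return VORPrediction(axis=axis, components=comps, magnitude=mag)


def misalignment(predicted: np.ndarray, target: np.ndarray) -> float:
    """Angle (degrees) between two rotation axes."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(target, dtype=float)
    np_, nt = np.linalg.norm(p), np.linalg.norm(t)
    if np_ == 0 or nt == 0:
        raise InvalidSpecError("misalignment of a zero vector is undefined")
    cosang = np.clip(np.dot(p / np_, t / nt), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def evor_trace(
    train: PulseTrain,
    weights: dict[str, float],
    axes: dict[str, np.ndarray],
    gain: float = 1.0,
    baseline_pps: float | None = None,
    excitatory_sign: float = 1.0,
    fs_hz: float = 1000.0,
) -> pd.DataFrame:
    """Predicted slow-phase eye-velocity components for a PFM train.

    The eye velocity vector is ``gain * (r(t) - baseline)`` along the
    predicted axis; columns are its projections onto the horizontal, LARP
    and RALP canal axes.  ``excitatory_sign`` flips the global sign
    convention (whether excitation counts as positive rotation).
    """
    if baseline_pps is None:
        baseline_pps = train.base_pps  # mid-rate of a symmetric modulation
    t_s = np.arange(0.0, train.duration_s, 1.0 / fs_hz)
    rate = train.rate(t_s)
    pred = predict_axis(weights, axes)
    data = {"t_s": t_s}
    for branch, frame_name in _FRAME_OF_BRANCH.items():
        if pred is None or branch not in axes:
            data[frame_name] = np.zeros_like(t_s)
            continue
        ax = np.asarray(axes[branch], dtype=float)
        ax = ax / np.linalg.norm(ax)
        proj = float(np.dot(pred.axis, ax))
        data[frame_name] = excitatory_sign * gain * (rate - baseline_pps) * proj
    return pd.DataFrame(data)


def slope_sweep(
    anatomy: Anatomy,
    slopes_deg=(15.0, 30.0, 45.0, 60.0),
    shapes=(PulseShape.RAMP_UP,),
    polarity: Polarity = Polarity.CATHODIC_FIRST,
    include_rect: bool = True,
    phase_us: float = 200.0,
    amplitudes_uA: np.ndarray | None = None,
    model: MembraneModel = MembraneModel(),
    medium: Medium = Medium.tissue(),
    branch: str = "LH",
    detection_uV: float = DETECTION_UV,
    st_frac: float = 0.10,
) -> pd.DataFrame:
    """Score pulse shapes: one row per (shape, slope).

    For every spec the sweep computes the eCAP detection threshold and the
    charge per phase at that threshold, the recruitment-based sensory and
    discomfort thresholds, the facial-nerve upper limit (when a facial
    branch exists), the usable dynamic range, and the VOR-axis
    misalignment at the sensory threshold.  Cells are NaN where the
    corresponding threshold was never reached on the grid.
    """
    if amplitudes_uA is None:
        amplitudes_uA = np.logspace(1, 3, 25)
    amplitudes_uA = np.asarray(amplitudes_uA, dtype=float)
    axes = canal_axes(anatomy)
    target_axis = axes[branch]

    specs: list[WaveformSpec] = []
    if include_rect:
        specs.append(
            WaveformSpec(shape=PulseShape.RECT, phase_us=phase_us, amp_uA=240.0,
                         polarity=polarity)
        )
    for shape in shapes:
        shape = PulseShape(shape)
        if shape is PulseShape.RECT:
            continue
        for s in slopes_deg:
            specs.append(
                WaveformSpec(shape=shape, slope_deg=float(s), phase_us=phase_us,
                             amp_uA=240.0, polarity=polarity)
            )

    rows = []
    for spec in specs:
        curve = recruitment_curve(
            anatomy, spec, amplitudes_uA, model=model, medium=medium,
            stim_branch=branch,
        )
        thr = sensory_threshold(curve, frac=st_frac, target_branch=branch)
        ecap_amps = ecap_sweep(anatomy, spec, amplitudes_uA, model, medium, branch)
        det = np.nonzero(ecap_amps >= detection_uV)[0]
        ecap_thr = float(amplitudes_uA[det[0]]) if det.size else np.nan
        charge_thr = (
            charge_per_phase(spec.with_amp(ecap_thr)) if np.isfinite(ecap_thr) else np.nan
        )
        mis = np.nan
        if thr is not None:
            st_idx = int(np.nonzero(amplitudes_uA >= thr.ST_uA)[0][0])
            weights = {
                b.name: float(curve.fraction_active[b.name][st_idx])
                for b in anatomy.scc_branches
            }
            pred = predict_axis(weights, axes)
            if pred is not None:
                mis = misalignment(pred.axis, target_axis)
        rows.append(
            {
                "shape": spec.shape.value,
                "slope_deg": spec.slope_deg if spec.slope_deg is not None else np.nan,
                "polarity": spec.polarity.value,
                "ecap_threshold_uA": ecap_thr,
                "charge_at_ecap_threshold_nC": charge_thr,
                "ST_uA": thr.ST_uA if thr else np.nan,
                "DT_uA": thr.DT_uA if thr else np.nan,
                "UL_uA": (thr.UL_uA if thr and thr.UL_uA is not None else np.nan),
                "dynamic_range_lo_uA": thr.dynamic_range_uA[0] if thr else np.nan,
                "dynamic_range_hi_uA": thr.dynamic_range_uA[1] if thr else np.nan,
                "misalignment_at_ST_deg": mis,
            }
        )
    return pd.DataFrame(rows)
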