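"""Charge-balanced biphasic pulse construction.

Vestibular prostheses encode head velocity as trains of charge-balanced
biphasic current pulses.  This module builds the stimulus side of the
simulator: rectangular and ramped pulse shapes, hardware-style current
quantization, and sinusoidally pulse-frequency-modulated (PFM) trains.

Ramp geometry convention
------------------------
Ramp slopes are quoted in degrees measured on *normalized* axes: one phase
duration maps to 1 on the time axis and the nominal amplitude maps to 1 on
the current axis.  A ramp therefore rises at ``tan(theta)`` in normalized
units until it reaches the nominal amplitude, then plateaus (a trapezoid).
For ``tan(theta) <= 1`` the plateau vanishes and the phase is a pure ramp
that peaks at ``tan(theta) * amp`` at the phase offset; at 45 degrees this
is exactly the triangle that reaches the nominal amplitude at the phase
offset.  Both phases of a pulse carry the same envelope with opposite sign,
so every rendered pulse is charge balanced by construction.
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncompatibleFileError, InvalidSpecError

__all__ = [
    "PulseShape",
    "Polarity",
    "WaveformSpec",
    "SampledWaveform",
    "PulseTrain",
    "render_waveform",
    "charge_per_phase",
    "quantize_current",
    "pfm_train",
    "waveform_grid",
    "waveform_to_csv",
    "waveform_from_csv",
    "spec_to_json",
    "spec_from_json",
]


class PulseShape(str, enum.Enum):
    RECT = "rect"
    RAMP_UP = "ramp_up"
    RAMP_DOWN = "ramp_down"
    RAMP_UP_DOWN = "ramp_up_down"


class Polarity(str, enum.Enum):
    CATHODIC_FIRST = "cathodic_first"
    ANODIC_FIRST = "anodic_first"


#: Nominal ramp slopes (degrees) exercised throughout the package.
STANDARD_SLOPES_DEG = (15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class WaveformSpec:
    """Parametric description of one biphasic pulse.

    Parameters
    ----------
    shape
        Pulse shape; ramped shapes interpret ``slope_deg``.
    slope_deg
        Ramp slope in degrees on normalized axes (see module docstring);
        ``None`` for rectangular pulses, where it is meaningless.
    polarity
        Sign of the first phase (cathodic = negative current).
    phase_us
        Duration of each phase, microseconds.
    amp_uA
        Nominal peak current, microamperes (>= 0).
    gap_frac
        Interphase gap as a fraction of the phase duration (default 10 %).
    step_uA
        Hardware current-quantization step (default 20 uA; 0 disables).
    dt_us
        Sample interval of the emulated pulse generator (default 2 us).
    """

    shape: PulseShape
    phase_us: float
    amp_uA: float
    slope_deg: float | None = None
    polarity: Polarity = Polarity.CATHODIC_FIRST
    gap_frac: float = 0.10
    step_uA: float = 20.0
    dt_us: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", PulseShape(self.shape))
        object.__setattr__(self, "polarity", Polarity(self.polarity))
        if self.shape is PulseShape.RECT:
            # slope is meaningless for rectangles; normalize so that specs
            # differing only in slope compare (and deduplicate) as equal
            object.__setattr__(self, "slope_deg", None)
        else:
            if self.slope_deg is None:
                raise InvalidSpecError(f"{self.shape.value} requires slope_deg")
            if not 0.0 < self.slope_deg <= 90.0:
                raise InvalidSpecError(
                    f"slope_deg must lie in (0, 90], got {self.slope_deg}"
                )
        if self.phase_us <= 0:
            raise InvalidSpecError(f"phase_us must be positive, got {self.phase_us}")
        if self.amp_uA < 0:
            raise InvalidSpecError(f"amp_uA must be non-negative, got {self.amp_uA}")
        if not 0.0 <= self.gap_frac < 1.0:
            raise InvalidSpecError(f"gap_frac must lie in [0, 1), got {self.gap_frac}")
        if self.step_uA < 0:
            raise InvalidSpecError(f"step_uA must be non-negative, got {self.step_uA}")
        if self.dt_us <= 0:
            raise InvalidSpecError(f"dt_us must be positive, got {self.dt_us}")
        if self.dt_us > self.phase_us:
            raise InvalidSpecError(
                f"dt_us ({self.dt_us}) exceeds phase_us ({self.phase_us})"
            )

    @property
    def gap_us(self) -> float:
        return self.gap_frac * self.phase_us

    @property
    def duration_us(self) -> float:
        """Total pulse duration: two phases plus the interphase gap."""
        return 2.0 * self.phase_us + self.gap_us

    @property
    def first_phase_sign(self) -> int:
        return -1 if self.polarity is Polarity.CATHODIC_FIRST else +1

    def with_amp(self, amp_uA: float) -> "WaveformSpec":
        return replace(self, amp_uA=float(amp_uA))


@dataclass
class SampledWaveform:
    """A discretized pulse: uniform sample times (us) and currents (uA).

    ``i_uA[k]`` is the current held over ``[t_us[k], t_us[k] + dt_us)``,
    matching the sample-and-hold output of a pulse generator.
    """

    t_us: np.ndarray
    i_uA: np.ndarray
    spec: WaveformSpec

    @property
    def dt_us(self) -> float:
        return self.spec.dt_us

    @property
    def duration_us(self) -> float:
        return float(len(self.i_uA) * self.dt_us)

    def net_charge_nC(self) -> float:
        """Residual charge over the whole pulse (0 for unquantized pulses)."""
        return float(np.sum(self.i_uA) * self.dt_us) / 1e3

    def phase_charge_nC(self) -> float:
        """Unsigned charge delivered by the first phase, numerically."""
        n_phase = int(round(self.spec.phase_us / self.dt_us))
        return abs(float(np.sum(self.i_uA[:n_phase]) * self.dt_us)) / 1e3


@dataclass
class PulseTrain:
    """Pulse onset times plus the rate function that generated them."""

    pulse_times_s: np.ndarray
    spec: WaveformSpec
    base_pps: float
    mod_hz: float
    depth_pps: float
    duration_s: float

    def rate(self, t_s: np.ndarray) -> np.ndarray:
        """Instantaneous commanded pulse rate r(t), pulses/s."""
        t = np.asarray(t_s, dtype=float)
        return self.base_pps + self.depth_pps * np.sin(2.0 * np.pi * self.mod_hz * t)


def _normalized_envelope(spec: WaveformSpec, tau: np.ndarray) -> np.ndarray:
    """Phase envelope on normalized time tau in [0, 1], in units of amp."""
    if spec.shape is PulseShape.RECT:
        return np.ones_like(tau)
    slope = math.tan(math.radians(spec.slope_deg))
    if spec.shape is PulseShape.RAMP_UP:
        return np.minimum(slope * tau, 1.0)
    if spec.shape is PulseShape.RAMP_DOWN:
        return np.minimum(slope * (1.0 - tau), 1.0)
    # symmetric rise then fall
    return np.minimum.reduce([slope * tau, slope * (1.0 - tau), np.ones_like(tau)])


def render_waveform(spec: WaveformSpec, quantize: bool = False) -> SampledWaveform:
    """Render a spec to a sampled current waveform.

    Samples are taken at segment midpoints so that the discrete sum
    reproduces the continuous charge of piecewise-linear envelopes to high
    accuracy.  The second phase is the exact negation of the first, so the
    unquantized waveform is charge balanced to machine precision.

    Parameters
    ----------
    quantize
        When True, additionally snap currents to ``spec.step_uA``.
    """
    n_phase = max(1, int(round(spec.phase_us / spec.dt_us)))
    n_gap = int(round(spec.gap_us / spec.dt_us))
    tau_mid = (np.arange(n_phase) + 0.5) / n_phase
    phase = spec.amp_uA * _normalized_envelope(spec, tau_mid)
    i = np.concatenate(
        [
            spec.first_phase_sign * phase,
            np.zeros(n_gap),
            -spec.first_phase_sign * phase,
        ]
    )
    t = np.arange(i.size) * spec.dt_us
    w = SampledWaveform(t_us=t, i_uA=i, spec=spec)
    if quantize:
        w = quantize_current(w, spec.step_uA)
    return w


def charge_per_phase(spec: WaveformSpec) -> float:
    """Closed-form charge per phase in nC.

    Rectangle: pulse width times amplitude.  Trapezoid: the rectangular
    plateau's charge plus the triangular ramp's peak charge divided by two.
    Under-peaked ramps (tan(theta) < 1) are pure triangles peaking at
    ``tan(theta) * amp``.
    """
    t = None if spec.slope_deg is None else math.tan(math.radians(spec.slope_deg))
    if spec.shape is PulseShape.RECT:
        q_norm = 1.0
    elif spec.shape in (PulseShape.RAMP_UP, PulseShape.RAMP_DOWN):
        q_norm = 1.0 - 1.0 / (2.0 * t) if t >= 1.0 else t / 2.0
    else:  # RAMP_UP_DOWN: two ramps, possibly a central plateau
        q_norm = 1.0 - 1.0 / t if t >= 2.0 else t / 4.0
    return q_norm * spec.phase_us * spec.amp_uA / 1e3  # uA*us = pC -> nC


def quantize_current(w: SampledWaveform, step_uA: float) -> SampledWaveform:
    """Snap every sample to an integer multiple of ``step_uA``.

    Rounds half away from zero, which keeps quantization symmetric under a
    polarity flip.  ``step_uA = 0`` is the identity.
    """
    if step_uA < 0:
        raise InvalidSpecError(f"step_uA must be non-negative, got {step_uA}")
    if step_uA == 0:
        return w
    q = np.copysign(np.floor(np.abs(w.i_uA) / step_uA + 0.5), w.i_uA) * step_uA
    return SampledWaveform(t_us=w.t_us.copy(), i_uA=q, spec=w.spec)


def pfm_train(
    base_pps: float,
    mod_hz: float,
    depth_pps: float,
    duration_s: float,
    spec: WaveformSpec,
) -> PulseTrain:
    """Sinusoidally pulse-frequency-modulated train.

    The instantaneous rate is ``r(t) = base + depth * sin(2 pi f t)``; a
    pulse is emitted each time the running integral of r crosses an
    integer.  The integral has the closed form
    ``base*t + depth*(1 - cos(2 pi f t)) / (2 pi f)``, so emission times are
    found by inverting a monotone function — fully deterministic, no jitter.
    """
    if base_pps < 0 or duration_s <= 0:
        raise InvalidSpecError("base_pps must be >= 0 and duration_s > 0")
    if depth_pps > base_pps:
        raise InvalidSpecError(
            f"depth_pps ({depth_pps}) exceeds base_pps ({base_pps}): rate would go negative"
        )

    def cum(t: np.ndarray) -> np.ndarray:
        if mod_hz == 0.0:
            return base_pps * t
        w = 2.0 * np.pi * mod_hz
        return base_pps * t + depth_pps * (1.0 - np.cos(w * t)) / w

    # dense monotone grid; integer crossings located by inverse interpolation
    n_grid = max(1000, int(duration_s * 200_000))
    t_grid = np.linspace(0.0, duration_s, n_grid)
    r_grid = cum(t_grid)
    n_pulses = int(np.floor(r_grid[-1] + 1e-9))
    onsets = np.interp(np.arange(1, n_pulses + 1), r_grid, t_grid)
    return PulseTrain(
        pulse_times_s=onsets,
        spec=spec,
        base_pps=base_pps,
        mod_hz=mod_hz,
        depth_pps=depth_pps,
        duration_s=duration_s,
    )


def waveform_grid(
    shapes,
    polarities,
    slopes,
    phase_us: float = 200.0,
    amp_uA: float = 240.0,
    **kwargs,
) -> list[WaveformSpec]:
    """Full factorial of shape x polarity x slope, deduplicated.

    Rectangular pulses ignore slope, so the slope factor collapses to a
    single spec per polarity for RECT.
    """
    shapes = [PulseShape(s) for s in shapes]
    polarities = [Polarity(p) for p in polarities]
    slopes = list(slopes)
    if not shapes or not polarities or not slopes:
        raise InvalidSpecError("shapes, polarities and slopes must be non-empty")
    out: list[WaveformSpec] = []
    seen = set()
    for shape, pol, slope in itertools.product(shapes, polarities, slopes):
        spec = WaveformSpec(
            shape=shape,
            slope_deg=None if shape is PulseShape.RECT else float(slope),
            polarity=pol,
            phase_us=phase_us,
            amp_uA=amp_uA,
            **kwargs,
        )
        if spec not in seen:
            seen.add(spec)
            out.append(spec)
    return out


# ---------------------------------------------------------------------------
# serialization

def waveform_to_csv(w: SampledWaveform, path) -> None:
    pd.DataFrame({"t_us": w.t_us, "i_uA": w.i_uA}).to_csv(path, index=False)


def waveform_from_csv(path, spec: WaveformSpec | None = None) -> SampledWaveform:
    df = pd.read_csv(path)
    if list(df.columns) != ["t_us", "i_uA"]:
        raise IncompatibleFileError(
            f"{path}: expected columns t_us,i_uA, found {list(df.columns)}"
        )
    t = df["t_us"].to_numpy(dtype=float)
    if spec is None:
        dt = float(t[1] - t[0]) if len(t) > 1 else 2.0
        spec = WaveformSpec(
            shape=PulseShape.RECT, phase_us=max(dt, t[-1] / 2 if len(t) else dt),
            amp_uA=float(np.max(np.abs(df["i_uA"]))) if len(df) else 0.0, dt_us=dt,
        )
    return SampledWaveform(t_us=t, i_uA=df["i_uA"].to_numpy(dtype=float), spec=spec)


def spec_to_json(spec: WaveformSpec, path=None) -> str:
    payload = {
        "shape": spec.shape.value,
        "slope_deg": spec.slope_deg,
        "polarity": spec.polarity.value,
        "phase_us": spec.phase_us,
        "amp_uA": spec.amp_uA,
        "gap_frac": spec.gap_frac,
        "step_uA": spec.step_uA,
        "dt_us": spec.dt_us,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def spec_from_json(source) -> WaveformSpec:
    if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise IncompatibleFileError(f"not valid waveform-spec JSON: {exc}") from exc
    try:
        return WaveformSpec(**payload)
    except TypeError as exc:
        raise IncompatibleFileError(f"waveform-spec JSON missing fields: {exc}") from exc
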