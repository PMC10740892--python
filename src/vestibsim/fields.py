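"""Quasistatic volume conductor.

Extracellular potentials are computed analytically for point current
sources in an unbounded homogeneous medium, optionally with axis-aligned
anisotropic conductivity (nerve tissue conducts far better along fibers
than across them).  This closed-form kernel replaces a finite-element
solve of real labyrinth geometry while preserving every property the rest
of the pipeline relies on: linearity in the source current, superposition,
and source/measurement reciprocity.  Any callable with the same signature
can be slotted in as an alternative potential kernel.

Units: positions mm, currents uA, conductivities S/m.  Raw kernels return
volts-per-ampere coefficients (ohms); convenience wrappers return volts or
millivolts as documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import Anatomy, Electrode, FiberTrajectory
from .errors import InvalidSpecError, SingularityError
from .stimgen import SampledWaveform

__all__ = [
    "Medium",
    "LeadField",
    "point_potential",
    "transfer_ohm",
    "drive_matrix",
    "lead_field",
    "current_spread",
]

#: sources closer than this to a field point raise SingularityError (mm)
_R_MIN_MM = 1e-6


@dataclass(frozen=True)
class Medium:
    """Homogeneous conductive medium, isotropic or uniaxially anisotropic.

    When ``sigma_long``/``sigma_trans`` are set, conduction along ``axis``
    uses sigma_long and transverse directions use sigma_trans; otherwise the
    medium is isotropic with ``sigma_iso``.
    """

    sigma_iso: float = 0.3
    sigma_long: float | None = None
    sigma_trans: float | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        sigmas = [self.sigma_iso]
        if (self.sigma_long is None) != (self.sigma_trans is None):
            raise InvalidSpecError("sigma_long and sigma_trans must be set together")
        if self.sigma_long is not None:
            sigmas += [self.sigma_long, self.sigma_trans]
        if any(s <= 0 for s in sigmas):
            raise InvalidSpecError(f"conductivities must be positive: {sigmas}")

    @property
    def anisotropic(self) -> bool:
        return self.sigma_long is not None

    @classmethod
    def saline(cls) -> "Medium":
        """0.9 % NaCl at room temperature (bench-test mode)."""
        return cls(sigma_iso=1.4)

    @classmethod
    def tissue(cls) -> "Medium":
        """Generic soft tissue (labyrinth mode)."""
        return cls(sigma_iso=0.3)

    @classmethod
    def nerve(cls, axis=(0.0, 0.0, 1.0), sigma_long: float = 1.0,
              sigma_trans: float = 0.1) -> "Medium":
        """Anisotropic nerve: 10:1 longitudinal:transverse by default."""
        return cls(sigma_iso=sigma_trans, sigma_long=sigma_long,
                   sigma_trans=sigma_trans, axis=tuple(axis))


@dataclass
class LeadField:
    """Reciprocity weights mapping compartment currents to recorded voltage.

    ``weights[j]`` is the voltage (V) the recording electrode would report
    per ampere of current injected at compartment j — numerically equal, by
    reciprocity, to the potential a unit current at the electrode impresses
    at the compartment.
    """

    rec_label: str
    weights: np.ndarray  # ohms (V/A), one per compartment


def transfer_ohm(displacement_mm: np.ndarray, medium: Medium) -> np.ndarray:
    """Potential-per-unit-current coefficient (ohms) for point sources.

    ``displacement_mm`` is the field-point-minus-source vector (...x3).
    Isotropic: 1/(4 pi sigma r).  Uniaxial anisotropy has the closed form
    1/(4 pi sqrt(sigma_t) sqrt(sigma_t r_par^2 + sigma_l r_perp^2)), which
    reduces continuously to the isotropic expression.
    """
    d = np.asarray(displacement_mm, dtype=float) * 1e-3  # -> meters
    if d.shape[-1] != 3:
        raise InvalidSpecError("displacement must have a trailing dimension of 3")
    r = np.linalg.norm(d, axis=-1)
    if np.any(r < _R_MIN_MM * 1e-3):
        raise SingularityError("field point coincides with a source electrode")
    if not medium.anisotropic:
        return 1.0 / (4.0 * np.pi * medium.sigma_iso * r)
    u = np.asarray(medium.axis, dtype=float)
    u = u / np.linalg.norm(u)
    r_par = d @ u
    r_perp_sq = np.maximum(r**2 - r_par**2, 0.0)
    s_t, s_l = medium.sigma_trans, medium.sigma_long
    denom = 4.0 * np.pi * np.sqrt(s_t) * np.sqrt(s_t * r_par**2 + s_l * r_perp_sq)
    return 1.0 / denom


def point_potential(r_mm, I_uA: float, medium: Medium) -> np.ndarray | float:
    """Extracellular potential in volts at distance/displacement ``r_mm``.

    Scalars are treated as radial distances (isotropic media only);
    3-vectors as displacements, required for anisotropic media.
    """
    r = np.asarray(r_mm, dtype=float)
    if r.ndim == 0 or r.shape[-1] != 3:
        if medium.anisotropic:
            raise InvalidSpecError(
                "anisotropic media need a 3-vector displacement, not a scalar distance"
            )
        if np.any(r <= 0):
            raise SingularityError("distance must be positive")
        coeff = 1.0 / (4.0 * np.pi * medium.sigma_iso * r * 1e-3)
    else:
        coeff = transfer_ohm(r, medium)
    out = coeff * I_uA * 1e-6
    return float(out) if np.ndim(out) == 0 else out


def drive_matrix(
    fiber: FiberTrajectory,
    stim_electrode: Electrode,
    waveform: SampledWaveform,
    medium: Medium,
    return_electrode: Electrode | None = None,
) -> np.ndarray:
    """Extracellular potential at each node over time, millivolts.

    Quasistatic linearity makes the drive separable: a static spatial
    profile (potential per unit current at each node of Ranvier) scaled by
    the stimulus current time series.  The distant return electrode can be
    included as an equal-and-opposite sink; for the default geometry its
    contribution is negligible.
    """
    if fiber.n_nodes < 2:
        raise InvalidSpecError("fiber needs at least 2 nodes")
    disp = fiber.node_positions_mm - stim_electrode.position_mm[None, :]
    coeff = transfer_ohm(disp, medium)  # ohms
    if return_electrode is not None:
        disp_ret = fiber.node_positions_mm - return_electrode.position_mm[None, :]
        coeff = coeff - transfer_ohm(disp_ret, medium)
    # ohms * uA = uV; -> mV
    return np.outer(waveform.i_uA, coeff) * 1e-3


def lead_field(
    rec_electrode: Electrode,
    compartments_mm: np.ndarray,
    medium: Medium,
) -> LeadField:
    """Reciprocity solution for one recording electrode.

    In this homogeneous analytic medium the reciprocal weight of a
    compartment is identical to the forward source-to-electrode transfer
    coefficient, so the lead field is a direct kernel evaluation.
    """
    comps = np.atleast_2d(np.asarray(compartments_mm, dtype=float))
    if comps.size == 0:
        raise InvalidSpecError("compartments must be non-empty")
    disp = comps - rec_electrode.position_mm[None, :]
    return LeadField(rec_label=rec_electrode.label, weights=transfer_ohm(disp, medium))


def current_spread(
    stim_electrode: Electrode,
    sense_electrodes: list[Electrode],
    medium: Medium,
    I_uA: float,
    ref_distance_mm: float = 0.1,
) -> pd.DataFrame:
    """In-silico bench test: potential spread to nearby electrodes.

    Reports the open-circuit potential at each sense site plus a spread
    index normalized to the potential at a fixed reference distance
    (default 0.1 mm) from the stimulating site.
    """
    if not sense_electrodes:
        raise InvalidSpecError("need at least one sense electrode")
    sigma_ref = medium.sigma_trans if medium.anisotropic else medium.sigma_iso
    v_ref = I_uA * 1e-6 / (4.0 * np.pi * sigma_ref * ref_distance_mm * 1e-3)
    rows = []
    for e in sense_electrodes:
        disp = e.position_mm - stim_electrode.position_mm
        v = float(transfer_ohm(disp, medium) * I_uA * 1e-6)
        rows.append(
            {
                "electrode": e.label,
                "distance_mm": float(np.linalg.norm(disp)),
                "potential_mV": v * 1e3,
                "spread_index": v / v_ref if v_ref != 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
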