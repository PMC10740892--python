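"""Procedural synthetic labyrinth.

Real virtual-ear models are built from co-registered CT/micro-MRI
segmentations of an implanted labyrinth.  That imaging pipeline is out of
scope here; this module replaces it with a parametric stand-in that keeps
every quantity downstream code consumes: three ampullary-nerve branches
(left horizontal LH, left anterior LA, left posterior LP) of ~100 model
afferents each, fiber start positions in peripheral/intermediate/central
crista zones, node-of-Ranvier coordinates along each fiber, canal rotation
axes, a monopolar electrode array, and an optional facial-nerve branch used
only to detect the upper stimulation limit.

All coordinates are millimetres in a right-handed frame.  Geometry is fully
deterministic given a seed and round-trips exactly through JSON.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GeometryError, IncompatibleFileError

__all__ = [
    "Zone",
    "ElectrodeRole",
    "FiberTrajectory",
    "NerveBranch",
    "Electrode",
    "Anatomy",
    "build_default_labyrinth",
    "canal_axes",
    "add_facial_branch",
    "anatomy_to_json",
    "anatomy_from_json",
]

ANATOMY_FORMAT = "vestibsim-anatomy/1"

SCC_BRANCHES = ("LH", "LA", "LP")
FACIAL = "FACIAL"

#: crista centers (mm); the nerve branches converge on the origin,
#: standing in for the principal trunk of the vestibular nerve.
_CRISTA_CENTERS = {
    "LH": np.array([3.5, 2.0, 0.5]),
    "LA": np.array([3.0, -1.5, 2.5]),
    "LP": np.array([2.5, 2.0, -2.5]),
}

#: default canal rotation axes in the {horizontal, LARP, RALP} frame:
#: the horizontal canal's axis is superior (+z), the anterior and posterior
#: canal axes lie at +/-45 degrees azimuth in the horizontal plane.
_DEFAULT_AXES = {
    "LH": np.array([0.0, 0.0, 1.0]),
    "LA": np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0]),
    "LP": np.array([np.sqrt(0.5), -np.sqrt(0.5), 0.0]),
}

#: zone split of fiber start positions over the crista surface
_ZONE_SPLIT = {"peripheral": 0.40, "intermediate": 0.30, "central": 0.30}
_ZONE_RADII_MM = {
    "central": (0.0, 0.12),
    "intermediate": (0.12, 0.24),
    "peripheral": (0.24, 0.36),
}


class Zone(str, enum.Enum):
    PERIPHERAL = "peripheral"
    INTERMEDIATE = "intermediate"
    CENTRAL = "central"


class ElectrodeRole(str, enum.Enum):
    STIM = "stim"
    RETURN = "return"
    RECORD = "record"
    REFERENCE = "reference"


@dataclass
class FiberTrajectory:
    """One model afferent: a straight path with nodes of Ranvier on it.

    ``threshold_uA`` is an optional planted activation threshold consumed by
    the surrogate membrane tier; the biophysical tier ignores it.
    """

    zone: Zone
    path_mm: np.ndarray          # (2, 3) polyline endpoints
    node_positions_mm: np.ndarray  # (n_nodes, 3)
    diameter_um: float
    internode_ratio: float = 100.0
    threshold_uA: float | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.node_positions_mm.shape[0])

    @property
    def internode_mm(self) -> float:
        """Node spacing: internode ratio x fiber diameter."""
        return self.internode_ratio * self.diameter_um * 1e-3


@dataclass
class NerveBranch:
    name: str
    fibers: list[FiberTrajectory] = field(default_factory=list)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)


@dataclass
class Electrode:
    position_mm: np.ndarray
    role: ElectrodeRole
    label: str


@dataclass
class Anatomy:
    """Synthetic labyrinth: nerve branches, electrode array, canal axes."""

    branches: list[NerveBranch]
    electrodes: list[Electrode]
    axes: dict[str, np.ndarray]
    frame: tuple[str, str, str] = ("horizontal", "LARP", "RALP")
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, ax in self.axes.items():
            n = np.linalg.norm(ax)
            if n == 0:
                raise GeometryError(f"canal axis for {name} is the zero vector")
            self.axes[name] = np.asarray(ax, dtype=float) / n
        scc = [self.axes[b] for b in SCC_BRANCHES if b in self.axes]
        for i in range(len(scc)):
            for j in range(i + 1, len(scc)):
                cosang = abs(float(np.dot(scc[i], scc[j])))
                if cosang > np.cos(np.radians(30.0)):
                    raise GeometryError(
                        "semicircular canal axes are near-parallel "
                        f"(angle < 30 deg between axes {i} and {j})"
                    )
        returns = [e for e in self.electrodes if e.role is ElectrodeRole.RETURN]
        if len(returns) != 1:
            raise GeometryError(
                f"monopolar configuration requires exactly one return electrode, found {len(returns)}"
            )

    # -- lookups -----------------------------------------------------------
    def branch(self, name: str) -> NerveBranch:
        for b in self.branches:
            if b.name == name:
                return b
        raise KeyError(f"no branch named {name!r}")

    @property
    def scc_branches(self) -> list[NerveBranch]:
        return [b for b in self.branches if b.name in SCC_BRANCHES]

    @property
    def facial_branch(self) -> NerveBranch | None:
        for b in self.branches:
            if b.name == FACIAL:
                return b
        return None

    def electrode(self, label: str) -> Electrode:
        for e in self.electrodes:
            if e.label == label:
                return e
        raise KeyError(f"no electrode labelled {label!r}")

    def stim_electrode(self, branch: str) -> Electrode:
        return self.electrode(f"{branch}_stim")

    def recording_pair(self, branch: str) -> tuple[Electrode, Electrode]:
        return self.electrode(f"{branch}_rec"), self.electrode(f"{branch}_ref")

    @property
    def return_electrode(self) -> Electrode:
        return next(e for e in self.electrodes if e.role is ElectrodeRole.RETURN)


def _zone_counts(n: int) -> dict[str, int]:
    n_per = int(round(_ZONE_SPLIT["peripheral"] * n))
    n_int = int(round(_ZONE_SPLIT["intermediate"] * n))
    n_cen = n - n_per - n_int
    if min(n_per, n_int, n_cen) < 1:
        # tiny populations still get one fiber per zone
        n_per = n_int = 1
        n_cen = n - 2
    return {"peripheral": n_per, "intermediate": n_int, "central": n_cen}


def _orthonormal_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _make_fiber(
    start: np.ndarray,
    end: np.ndarray,
    zone: Zone,
    diameter_um: float,
    internode_ratio: float,
) -> FiberTrajectory:
    vec = end - start
    length = float(np.linalg.norm(vec))
    unit = vec / length
    spacing = internode_ratio * diameter_um * 1e-3  # mm
    n_nodes = int(np.floor(length / spacing)) + 1
    if n_nodes < 11:
        raise GeometryError(
            f"fiber too short for 11 nodes (length {length:.2f} mm, spacing {spacing:.3f} mm)"
        )
    nodes = start[None, :] + np.arange(n_nodes)[:, None] * spacing * unit[None, :]
    return FiberTrajectory(
        zone=zone,
        path_mm=np.stack([start, end]),
        node_positions_mm=nodes,
        diameter_um=float(diameter_um),
        internode_ratio=float(internode_ratio),
    )


def build_default_labyrinth(
    n_per_crista: int = 100,
    seed: int = 0,
    internode_ratio: float = 100.0,
    diameter_mean_um: float = 3.0,
    diameter_sd_um: float = 0.5,
    diameter_bounds_um: tuple[float, float] = (2.0, 4.0),
    stim_offset_mm: float = 0.2,
    axes: dict[str, np.ndarray] | None = None,
) -> Anatomy:
    """Build the default three-canal synthetic labyrinth.

    Each crista carries ``n_per_crista`` afferents whose start positions are
    sampled on a disc at the crista surface (peripheral/intermediate/central
    zones split 40/30/30) and whose straight trajectories converge past the
    common nerve trunk at the origin.  One stimulating electrode sits
    ``stim_offset_mm`` from each crista center, a single distant return
    serves all of them, and each branch gets a nearby recording/reference
    electrode pair for differential eCAPs.

    The stimulating-electrode standoff (default 0.2 mm) is the main
    threshold calibration knob: at 0.2 mm the biophysical tier's thresholds
    fall in the tens of microamperes.
    """
    if n_per_crista < 3:
        raise GeometryError(f"n_per_crista must be >= 3 (one per zone), got {n_per_crista}")
    rng = np.random.default_rng(seed)
    trunk = np.zeros(3)
    branches: list[NerveBranch] = []
    electrodes: list[Electrode] = []
    for name in SCC_BRANCHES:
        center = _CRISTA_CENTERS[name]
        u = (trunk - center) / np.linalg.norm(trunk - center)  # toward trunk
        e1, e2 = _orthonormal_basis(u)
        end = trunk + 1.5 * u  # overshoot past the trunk for node headroom
        fibers: list[FiberTrajectory] = []
        counts = _zone_counts(n_per_crista)
        for zone_name, count in counts.items():
            r_lo, r_hi = _ZONE_RADII_MM[zone_name]
            rho = rng.uniform(r_lo, r_hi, count)
            phi = rng.uniform(0.0, 2.0 * np.pi, count)
            diam = _truncnorm(
                rng, diameter_mean_um, diameter_sd_um, *diameter_bounds_um, size=count
            )
            for k in range(count):
                start = center + rho[k] * (np.cos(phi[k]) * e1 + np.sin(phi[k]) * e2)
                fibers.append(
                    _make_fiber(start, end, Zone(zone_name), diam[k], internode_ratio)
                )
        branches.append(NerveBranch(name=name, fibers=fibers))
        # stimulating electrode on the far side of the crista from the nerve
        electrodes.append(
            Electrode(center - stim_offset_mm * u, ElectrodeRole.STIM, f"{name}_stim")
        )
        # recording pair near the nerve trunk, off the fiber bundle
        t_rec = center + 0.7 * (trunk - center)
        electrodes.append(
            Electrode(t_rec + 0.3 * e1, ElectrodeRole.RECORD, f"{name}_rec")
        )
        electrodes.append(
            Electrode(t_rec + 0.8 * u + 0.3 * e1, ElectrodeRole.REFERENCE, f"{name}_ref")
        )
    electrodes.append(
        Electrode(np.array([15.0, 15.0, 15.0]), ElectrodeRole.RETURN, "return")
    )
    ax = {k: np.array(v, dtype=float) for k, v in (axes or _DEFAULT_AXES).items()}
    return Anatomy(branches=branches, electrodes=electrodes, axes=ax, seed=seed)


def canal_axes(anatomy: Anatomy) -> dict[str, np.ndarray]:
    """Unit rotation axis of each canal in the {horizontal, LARP, RALP} frame."""
    return {
        name: anatomy.axes[name] / np.linalg.norm(anatomy.axes[name])
        for name in anatomy.axes
    }


def add_facial_branch(
    anatomy: Anatomy,
    offset_mm: float = 1.5,
    n_fibers: int = 50,
    seed: int = 1,
) -> Anatomy:
    """Return a copy of the anatomy with a facial-nerve branch appended.

    The facial nerve passes near the labyrinth but farther from every
    stimulating electrode than the target afferents; its activation defines
    the upper limit of usable stimulus amplitude.  The bundle is placed
    ``offset_mm`` beyond the crista belt, on the far side from the nerve
    trunk.
    """
    if offset_mm <= 0:
        raise GeometryError(f"offset_mm must be positive, got {offset_mm}")
    rng = np.random.default_rng(seed)
    centers = np.stack([_CRISTA_CENTERS[n] for n in SCC_BRANCHES])
    centroid = centers.mean(axis=0)
    v = centroid / np.linalg.norm(centroid)  # away from the trunk at the origin
    bundle_center = centroid + (np.max(np.linalg.norm(centers - centroid, axis=1)) + offset_mm) * v
    e1, e2 = _orthonormal_basis(v)
    direction = e1  # bundle runs transverse to the outward direction
    fibers: list[FiberTrajectory] = []
    diam = _truncnorm(rng, 3.0, 0.5, 2.0, 4.0, size=max(n_fibers, 1))
    for k in range(n_fibers):
        rho = rng.uniform(0.0, 0.3)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        start = (
            bundle_center
            - 2.75 * direction
            + rho * (np.cos(phi) * e2 + np.sin(phi) * v)
        )
        fibers.append(
            _make_fiber(start, start + 5.5 * direction, Zone.CENTRAL, diam[k], 100.0)
        )
    branch = NerveBranch(name=FACIAL, fibers=fibers)

    if n_fibers:
        facial_nodes = np.concatenate([f.node_positions_mm for f in fibers])
        for scc in anatomy.scc_branches:
            scc_nodes = np.concatenate([f.node_positions_mm for f in scc.fibers])
            d = np.linalg.norm(
                facial_nodes[:, None, :] - scc_nodes[None, :, :], axis=-1
            ).min()
            if d < 0.05:
                raise GeometryError(
                    f"facial branch overlaps {scc.name} fibers (min distance {d:.3f} mm)"
                )
        for name in SCC_BRANCHES:
            stim = anatomy.stim_electrode(name).position_mm
            d_facial = np.linalg.norm(facial_nodes - stim, axis=1).min()
            d_target = max(
                np.linalg.norm(f.node_positions_mm - stim, axis=1).min()
                for f in anatomy.branch(name).fibers
            )
            if d_facial <= d_target:
                raise GeometryError(
                    f"facial branch closer to {name}_stim ({d_facial:.2f} mm) than "
                    f"its target fibers ({d_target:.2f} mm)"
                )

    return Anatomy(
        branches=list(anatomy.branches) + [branch],
        electrodes=list(anatomy.electrodes),
        axes=dict(anatomy.axes),
        frame=anatomy.frame,
        seed=anatomy.seed,
    )


# ---------------------------------------------------------------------------
# JSON serialization (exact float round-trip via repr-based JSON encoding)

def _read_maybe_path(source) -> str:
    """Accept a path or raw JSON text; JSON text starts with a brace."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if s.lstrip().startswith("{"):
        return s
    return Path(s).read_text()

def _anatomy_to_dict(a: Anatomy) -> dict:
    return {
        "format": ANATOMY_FORMAT,
        "seed": a.seed,
        "frame": list(a.frame),
        "axes": {k: v.tolist() for k, v in a.axes.items()},
        "electrodes": [
            {"label": e.label, "role": e.role.value, "position_mm": e.position_mm.tolist()}
            for e in a.electrodes
        ],
        "branches": [
            {
                "name": b.name,
                "fibers": [
                    {
                        "zone": f.zone.value,
                        "path_mm": f.path_mm.tolist(),
                        "node_positions_mm": f.node_positions_mm.tolist(),
                        "diameter_um": f.diameter_um,
                        "internode_ratio": f.internode_ratio,
                        "threshold_uA": f.threshold_uA,
                    }
                    for f in b.fibers
                ],
            }
            for b in a.branches
        ],
    }


def anatomy_to_json(a: Anatomy, path=None) -> str:
    text = json.dumps(_anatomy_to_dict(a), indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def anatomy_from_json(source) -> Anatomy:
    text = _read_maybe_path(source)
    try:
        d = json.loads(text)
    except json.JSONDecodeError as exc:
        raise IncompatibleFileError(f"not valid anatomy JSON: {exc}") from exc
    if d.get("format") != ANATOMY_FORMAT:
        raise IncompatibleFileError(
            f"unsupported anatomy format {d.get('format')!r}, expected {ANATOMY_FORMAT}"
        )
    branches = [
        NerveBranch(
            name=b["name"],
            fibers=[
                FiberTrajectory(
                    zone=Zone(f["zone"]),
                    path_mm=np.array(f["path_mm"]),
                    node_positions_mm=np.array(f["node_positions_mm"]),
                    diameter_um=f["diameter_um"],
                    internode_ratio=f["internode_ratio"],
                    threshold_uA=f["threshold_uA"],
                )
                for f in b["fibers"]
            ],
        )
        for b in d["branches"]
    ]
    electrodes = [
        Electrode(np.array(e["position_mm"]), ElectrodeRole(e["role"]), e["label"])
        for e in d["electrodes"]
    ]
    axes = {k: np.array(v) for k, v in d["axes"].items()}
    return Anatomy(
        branches=branches,
        electrodes=electrodes,
        axes=axes,
        frame=tuple(d["frame"]),
        seed=d["seed"],
    )
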