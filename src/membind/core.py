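"""Domain types and selection logic shared by all analysis stages.

The package works on labelled particle systems: a :class:`Topology` assigns
every particle a residue index, a name, and a role (protein, lipid head bead,
lipid tail bead, or other), while per-frame geometry lives in :class:`Frame`
and :class:`Trajectory`.  All coordinates are handled in nanometres
internally; ångström appear only at I/O boundaries (fixed factor 10 Å/nm).
Residue indices are 1-based and carried verbatim from input, so reported
interface residues can use conventional protein numbering (e.g. 296-304).
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1

__all__ = [
    "Role",
    "Leaflet",
    "Particle",
    "LipidComposition",
    "Topology",
    "Frame",
    "Trajectory",
    "ReplicaSet",
    "AnalysisConfig",
    "select_particles",
    "validate_trajectory",
    "assign_leaflets",
    "MembindError",
    "SpecificationError",
    "SelectionError",
    "ParameterError",
    "CompositionError",
    "InsufficientDataError",
    "FormatError",
]


class MembindError(Exception):
    """Base class for all package errors."""


class SpecificationError(MembindError, ValueError):
    """A selection spec references an unknown field or role."""


class SelectionError(MembindError, ValueError):
    """A particle selection is invalid for the requested operation."""


class ParameterError(MembindError, ValueError):
    """A parameter value violates its contract."""


class CompositionError(ParameterError):
    """A lipid composition does not sum to one."""


class InsufficientDataError(MembindError, ValueError):
    """Not enough data to perform the requested computation."""


class FormatError(MembindError, ValueError):
    """A file could not be parsed in the declared dialect."""


class Role(str, enum.Enum):
    PROTEIN = "protein"
    LIPID_HEAD = "lipid_head"
    LIPID_TAIL = "lipid_tail"
    OTHER = "other"


class Leaflet(str, enum.Enum):
    UPPER = "upper"
    LOWER = "lower"


@dataclass(frozen=True)
class Particle:
    """One interaction site (bead) of the system.

    Protein particles leave ``lipid_class`` and ``leaflet`` unset; lipid
    particles carry both.
    """

    particle_id: int
    residue_index: int
    residue_name: str
    particle_name: str
    role: Role
    lipid_class: str | None = None
    leaflet: Leaflet | None = None

    def __post_init__(self):
        object.__setattr__(self, "role", Role(self.role))
        if self.leaflet is not None:
            object.__setattr__(self, "leaflet", Leaflet(self.leaflet))

    @property
    def is_lipid(self) -> bool:
        return self.role in (Role.LIPID_HEAD, Role.LIPID_TAIL)


@dataclass(frozen=True)
class LipidComposition:
    """Mole fractions per lipid class; must sum to 1 within 1e-9."""

    fractions: Mapping[str, float]

    def __post_init__(self):
        fractions = dict(self.fractions)
        object.__setattr__(self, "fractions", fractions)
        if not fractions:
            raise CompositionError("composition has no lipid classes")
        for name, f in fractions.items():
            if not (0.0 <= f <= 1.0):
                raise CompositionError(f"fraction of {name} outside [0,1]: {f}")
        total = sum(fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise CompositionError(f"fractions sum to {total!r}, expected 1")

    def __eq__(self, other):
        if not isinstance(other, LipidComposition):
            return NotImplemented
        if set(self.fractions) != set(other.fractions):
            return False
        return all(
            abs(self.fractions[k] - other.fractions[k]) <= 1e-12 for k in self.fractions
        )

    def __hash__(self):
        return hash(tuple(sorted(self.fractions)))


_SELECTION_KEYS = {"role", "residue_range", "particle_name", "lipid_class", "leaflet"}


class Topology:
    """Ordered list of particles plus system-level metadata.

    Caches numpy views of the per-particle fields so selections and
    per-residue reductions are vectorised.
    """

    def __init__(
        self,
        particles: Sequence[Particle],
        lipid_composition: LipidComposition | None = None,
    ):
        self.particles: list[Particle] = list(particles)
        self.lipid_composition = lipid_composition
        n = len(self.particles)
        self._residue_index = np.array([p.residue_index for p in self.particles], dtype=np.int64)
        self._roles = np.array([p.role.value for p in self.particles], dtype=object)
        self._names = np.array([p.particle_name for p in self.particles], dtype=object)
        self._lipid_class = np.array(
            [p.lipid_class or "" for p in self.particles], dtype=object
        )
        self._leaflet = np.array(
            [p.leaflet.value if p.leaflet else "" for p in self.particles], dtype=object
        )
        self._n = n

    def __len__(self) -> int:
        return self._n

    @property
    def n_particles(self) -> int:
        return self._n

    @property
    def n_protein_residues(self) -> int:
        mask = self._roles == Role.PROTEIN.value
        return int(np.unique(self._residue_index[mask]).size)

    def protein_residue_ids(self) -> np.ndarray:
        mask = self._roles == Role.PROTEIN.value
        return np.unique(self._residue_index[mask])

    def residue_names(self, residue_ids: Iterable[int]) -> list[str]:
        lookup = {}
        for p in self.particles:
            lookup.setdefault(p.residue_index, p.residue_name)
        return [lookup.get(int(r), "") for r in residue_ids]

    def indices(
        self,
        role: Role | str | None = None,
        residue_range: tuple[int, int] | None = None,
        particle_name: str | None = None,
        lipid_class: str | None = None,
        leaflet: Leaflet | str | None = None,
    ) -> np.ndarray:
        mask = np.ones(self._n, dtype=bool)
        if role is not None:
            role = Role(role)
            mask &= self._roles == role.value
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self._residue_index >= lo) & (self._residue_index <= hi)
        if particle_name is not None:
            mask &= self._names == particle_name
        if lipid_class is not None:
            mask &= self._lipid_class == lipid_class
        if leaflet is not None:
            leaflet = Leaflet(leaflet)
            mask &= self._leaflet == leaflet.value
        return np.flatnonzero(mask).astype(np.int64)

    def protein_indices(self) -> np.ndarray:
        return self.indices(role=Role.PROTEIN)

    def membrane_indices(self) -> np.ndarray:
        """All lipid beads, head and tail ("any bead of the membrane")."""
        mask = (self._roles == Role.LIPID_HEAD.value) | (self._roles == Role.LIPID_TAIL.value)
        return np.flatnonzero(mask).astype(np.int64)

    def protein_residue_offsets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Protein bead indices, reduceat offsets, and residue ids.

        Requires each protein residue's beads to be contiguous in the
        (ascending-index) protein block, which the topology invariants
        guarantee.
        """
        prot = self.protein_indices()
        if prot.size == 0:
            raise SelectionError("topology has no protein particles")
        resid = self._residue_index[prot]
        boundaries = np.flatnonzero(np.diff(resid) != 0) + 1
        offsets = np.concatenate(([0], boundaries))
        residue_ids = resid[offsets]
        if np.unique(residue_ids).size != residue_ids.size:
            raise SelectionError("protein residues are not contiguous blocks")
        return prot, offsets, residue_ids

    def validate(self) -> list[str]:
        report: list[str] = []
        ids = [p.particle_id for p in self.particles]
        if len(set(ids)) != len(ids):
            report.append("topology: duplicate particle_id")
        for p in self.particles:
            if p.role == Role.PROTEIN and (p.lipid_class or p.leaflet):
                report.append(
                    f"topology: protein particle {p.particle_id} carries lipid fields"
                )
            if p.is_lipid and (p.lipid_class is None or p.leaflet is None):
                report.append(
                    f"topology: lipid particle {p.particle_id} missing lipid_class/leaflet"
                )
        # residue_index non-decreasing within each contiguous role block
        prev_role, prev_res = None, None
        for p in self.particles:
            if p.role == prev_role and p.residue_index < prev_res:
                report.append(
                    f"topology: residue_index decreases within {p.role.value} block at particle {p.particle_id}"
                )
            prev_role, prev_res = p.role, p.residue_index
        if self.lipid_composition is not None:
            known = set(self.lipid_composition.fractions)
            seen = {p.lipid_class for p in self.particles if p.is_lipid}
            missing = seen - known - {None}
            if missing:
                report.append(f"topology: lipid classes absent from composition: {sorted(missing)}")
        return report


@dataclass
class Frame:
    """One time point: box edge lengths (nm, orthorhombic) and coordinates (nm)."""

    time: float  # ps
    box: np.ndarray  # (3,)
    coords: np.ndarray  # (n_particles, 3)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64).reshape(-1)
        self.coords = np.asarray(self.coords, dtype=np.float64)


class Trajectory:
    """A topology plus stacked frame data.

    Coordinates are stored as one ``(n_frames, n_particles, 3)`` array so
    analyses can vectorise across frames.
    """

    def __init__(
        self,
        topology: Topology,
        times: np.ndarray,
        boxes: np.ndarray,
        coords: np.ndarray,
        replica_id: int = 0,
        label: str = "",
    ):
        self.topology = topology
        self.times = np.asarray(times, dtype=np.float64)
        self.boxes = np.asarray(boxes, dtype=np.float64)
        self.coords = np.asarray(coords, dtype=np.float64)
        self.replica_id = int(replica_id)
        self.label = label

    @classmethod
    def from_frames(
        cls,
        topology: Topology,
        frames: Sequence[Frame],
        replica_id: int = 0,
        label: str = "",
    ) -> "Trajectory":
        times = np.array([f.time for f in frames], dtype=np.float64)
        boxes = np.stack([f.box for f in frames])
        coords = np.stack([f.coords for f in frames])
        return cls(topology, times, boxes, coords, replica_id=replica_id, label=label)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), box=self.boxes[i], coords=self.coords[i])

    @property
    def frames(self) -> list[Frame]:
        return [self.frame(i) for i in range(self.n_frames)]

    @property
    def span_ns(self) -> float:
        if self.n_frames == 0:
            return 0.0
        return float(self.times[-1] - self.times[0]) / 1000.0


@dataclass
class ReplicaSet:
    """Independent replicas of one condition sharing a topology schema."""

    trajectories: list[Trajectory]
    label: str = ""

    def __post_init__(self):
        if not self.trajectories:
            return
        ref = self.trajectories[0]
        for t in self.trajectories[1:]:
            if t.topology.n_protein_residues != ref.topology.n_protein_residues:
                raise ParameterError("replicas disagree on n_protein_residues")
            if (
                t.topology.lipid_composition is not None
                and ref.topology.lipid_composition is not None
                and t.topology.lipid_composition != ref.topology.lipid_composition
            ):
                raise ParameterError("replicas disagree on lipid composition")

    def __len__(self) -> int:
        return len(self.trajectories)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds of the analysis pipeline.

    ``bound_threshold`` (default 0.7 nm, comparison ≤) classifies whole-protein
    bound frames; ``residue_contact_cutoff`` (default 0.5 nm, strict <) defines
    per-residue lipid contact.  The two rules are independent by design.
    """

    bound_threshold: float = 0.7
    residue_contact_cutoff: float = 0.5
    kde_bandwidth: str | float = "scott"
    kde_grid: tuple[float, float, int] = (0.0, 5.0, 1001)
    pbc_mode: str = "xyz"
    window_length_ns: float = 20.0
    normalization_mode: str = "per_frame_fraction"
    seed: int = 0

    def __post_init__(self):
        if self.bound_threshold <= 0:
            raise ParameterError("bound_threshold must be positive")
        if self.residue_contact_cutoff <= 0:
            raise ParameterError("residue_contact_cutoff must be positive")
        if self.pbc_mode not in ("xyz", "xy", "none"):
            raise ParameterError(f"unknown pbc_mode {self.pbc_mode!r}")
        if self.normalization_mode not in ("per_frame_fraction", "max_scaled"):
            raise ParameterError(f"unknown normalization_mode {self.normalization_mode!r}")

    def to_dict(self) -> dict:
        return {
            "bound_threshold": self.bound_threshold,
            "residue_contact_cutoff": self.residue_contact_cutoff,
            "kde_bandwidth": self.kde_bandwidth,
            "kde_grid": list(self.kde_grid),
            "pbc_mode": self.pbc_mode,
            "window_length_ns": self.window_length_ns,
            "normalization_mode": self.normalization_mode,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def select_particles(topology: Topology, spec: Mapping[str, object]) -> np.ndarray:
    """Resolve a declarative selection spec to ascending particle indices.

    ``spec`` may combine ``role``, ``residue_range`` (inclusive 2-tuple),
    ``particle_name``, ``lipid_class`` and ``leaflet``.  An empty selection is
    a valid result, not an error; an unknown key or role is a
    :class:`SpecificationError`.
    """
    unknown = set(spec) - _SELECTION_KEYS
    if unknown:
        raise SpecificationError(f"unknown selection fields: {sorted(unknown)}")
    kwargs = dict(spec)
    if "role" in kwargs:
        try:
            kwargs["role"] = Role(kwargs["role"])
        except ValueError as exc:
            raise SpecificationError(f"unknown role {kwargs['role']!r}") from exc
    if "leaflet" in kwargs:
        try:
            kwargs["leaflet"] = Leaflet(kwargs["leaflet"])
        except ValueError as exc:
            raise SpecificationError(f"unknown leaflet {kwargs['leaflet']!r}") from exc
    if "residue_range" in kwargs:
        rr = kwargs["residue_range"]
        if not (isinstance(rr, (tuple, list)) and len(rr) == 2):
            raise SpecificationError("residue_range must be a (lo, hi) pair")
        kwargs["residue_range"] = (int(rr[0]), int(rr[1]))
    return topology.indices(**kwargs)


def validate_trajectory(
    trajectory: Trajectory | Sequence[Frame],
    topology: Topology | None = None,
) -> list[str]:
    """Check frame/topology invariants; returns a list of violations.

    Accepts either a built :class:`Trajectory` or a raw frame sequence plus
    topology (so malformed content can be validated before construction).
    Validation never raises on content.
    """
    if isinstance(trajectory, Trajectory):
        frames: Sequence[Frame] = trajectory.frames
        topo = trajectory.topology
    else:
        frames = trajectory
        if topology is None:
            raise ParameterError("topology required when validating raw frames")
        topo = topology

    report = topo.validate()
    n = topo.n_particles
    prev_time = None
    for i, f in enumerate(frames):
        if f.coords.ndim != 2 or f.coords.shape[1] != 3 or f.coords.shape[0] != n:
            report.append(
                f"frame {i}: coordinate count {f.coords.shape[0] if f.coords.ndim == 2 else '?'}"
                f" does not match topology particle count {n}"
            )
        if f.box.size != 3 or np.any(f.box <= 0):
            report.append(f"frame {i}: box lengths not strictly positive")
        if f.coords.size and not np.all(np.isfinite(f.coords)):
            report.append(f"frame {i}: non-finite coordinates")
        if prev_time is not None and f.time <= prev_time:
            report.append(f"frame {i}: time not strictly increasing")
        prev_time = f.time
    return report


def assign_leaflets(topology: Topology, frame: Frame) -> Topology:
    """Assign upper/lower leaflets from head-bead z versus the membrane midplane.

    The midplane is the mean z of all lipid beads in ``frame``; every bead of
    a lipid residue inherits the leaflet of its head bead (or, lacking one,
    of its own mean z).
    """
    lipid_idx = topology.membrane_indices()
    if lipid_idx.size == 0:
        return topology
    midplane = float(np.mean(frame.coords[lipid_idx, 2]))
    # head-bead z per lipid residue
    residue_z: dict[int, float] = {}
    for i in lipid_idx:
        p = topology.particles[i]
        if p.role == Role.LIPID_HEAD and p.residue_index not in residue_z:
            residue_z[p.residue_index] = float(frame.coords[i, 2])
    new_particles = []
    for i, p in enumerate(topology.particles):
        if p.is_lipid:
            z = residue_z.get(p.residue_index, float(frame.coords[i, 2]))
            leaflet = Leaflet.UPPER if z >= midplane else Leaflet.LOWER
            new_particles.append(replace(p, leaflet=leaflet))
        else:
            new_particles.append(p)
    return Topology(new_particles, topology.lipid_composition)
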