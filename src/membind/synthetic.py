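"""Synthetic bilayer + protein trajectories with exact ground truth.

The generator emulates the geometry that the downstream analyses consume: a
two-leaflet planar bilayer of head/tail beads built on a jittered square
lattice (insane-style), and a compact multi-residue protein bead cloud that
alternates between a membrane-bound pose and an unbound excursion above the
membrane.  Binding is a discrete-time two-state Markov chain, not Langevin
dynamics: the analyses under test consume only geometry, and a chain gives
exact, provable ground-truth occupancy.

Margins are hard guarantees, not probabilistic ones: all positional noise is
clipped at ±3σ, bound-state interface beads are snapped near a head-bead
lattice site so their lipid contact is strictly below the 0.5 nm residue
cutoff, and the unbound altitude floor keeps the global minimum distance
strictly above the 0.7 nm bound threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AnalysisConfig,
    Frame,
    Leaflet,
    LipidComposition,
    ParameterError,
    Particle,
    ReplicaSet,
    Role,
    Topology,
    Trajectory,
)

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "build_bilayer",
    "build_protein",
    "simulate_binding_trajectory",
    "simulate_replicas",
    "simulate_detachment_trajectory",
    "DEFAULT_INTERFACE",
]

# Margins the generator is built to satisfy (match the analysis defaults).
CONTACT_CUTOFF = 0.5  # nm, strict <, per-residue contact
BOUND_THRESHOLD = 0.7  # nm, <=, global bound classification
HALF_THICKNESS = 2.0  # nm, head plane to bilayer midplane (DOPC-like)
TAIL_SPACING = 0.6  # nm between stacked tail beads
NOISE_CLIP_SIGMA = 3.0

# Paper-style numbering: the domain spans residues 284-408 (125 residues);
# its two membrane-binding regions are 296-304 and 378-395.
DEFAULT_FIRST_RESIDUE = 284
DEFAULT_INTERFACE = frozenset(range(296, 305)) | frozenset(range(378, 396))


def _default_composition() -> LipidComposition:
    return LipidComposition({"DOPC": 0.6, "DOPA": 0.4})


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; defaults mirror the simulated study conditions."""

    n_residues: int = 125
    beads_per_residue: int = 1
    first_residue: int = DEFAULT_FIRST_RESIDUE
    interface_residues: frozenset[int] = DEFAULT_INTERFACE
    lipid_composition: LipidComposition = field(default_factory=_default_composition)
    area_per_lipid: float = 0.64  # nm^2, fluid PC bilayer
    box: tuple[float, float, float] = (17.0, 17.0, 25.0)
    start_offset: float = 2.5  # nm above the upper head plane at t0
    p_bind: float = 0.12  # per-frame unbound->bound probability
    p_unbind: float = 0.08  # per-frame bound->unbound probability
    bound_depths: Mapping[int, float] | float = 0.2  # nm below the head plane
    positional_noise_sd: float = 0.05  # nm, per bead per frame, clipped 3 sigma
    rest_altitude: float = 2.5  # nm, unbound mean-reversion level
    reversion_rate: float = 0.1  # per frame
    drift_noise_sd: float = 0.1  # nm
    n_frames: int = 1250  # x 40 ps ~= 50 ns: fits two 20 ns windows
    frame_dt: float = 40.0  # ps
    seed: int = 0
    initial_state: str = "stationary"  # bound | unbound | stationary
    clean_margins: bool = True

    def __post_init__(self):
        if self.n_residues < 1:
            raise ParameterError("n_residues must be >= 1")
        if self.beads_per_residue < 1:
            raise ParameterError("beads_per_residue must be >= 1")
        resid_lo = self.first_residue
        resid_hi = self.first_residue + self.n_residues - 1
        object.__setattr__(self, "interface_residues", frozenset(self.interface_residues))
        bad = [r for r in self.interface_residues if not (resid_lo <= r <= resid_hi)]
        if bad:
            raise ParameterError(
                f"interface residues outside [{resid_lo}, {resid_hi}]: {sorted(bad)}"
            )
        for name, p in (("p_bind", self.p_bind), ("p_unbind", self.p_unbind)):
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"{name} must lie in [0,1], got {p}")
        if self.initial_state not in ("bound", "unbound", "stationary"):
            raise ParameterError(f"unknown initial_state {self.initial_state!r}")
        if self.initial_state == "stationary" and self.p_bind + self.p_unbind == 0:
            raise ParameterError("stationary initial state needs p_bind + p_unbind > 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        sd = self.positional_noise_sd
        floor = self.unbound_floor()
        if self.rest_altitude < floor:
            raise ParameterError(
                "rest altitude too low to guarantee unbound separation: "
                f"rest_altitude={self.rest_altitude} < floor={floor:.3f} "
                f"(= bound threshold {BOUND_THRESHOLD} + margin)"
            )
        # Bound interface beads must register < CONTACT_CUTOFF with 3-sigma noise.
        for r in sorted(self.interface_residues):
            d = self.depth_of(r)
            if d <= 0:
                raise ParameterError(f"bound depth of residue {r} must be positive, got {d}")
            worst = np.hypot(d + NOISE_CLIP_SIGMA * sd, np.sqrt(2) * NOISE_CLIP_SIGMA * sd)
            if worst >= CONTACT_CUTOFF:
                raise ParameterError(
                    f"residue {r}: depth {d} + noise {sd} cannot guarantee contact "
                    f"< {CONTACT_CUTOFF} nm (worst case {worst:.3f})"
                )

    def residue_ids(self) -> np.ndarray:
        return np.arange(self.first_residue, self.first_residue + self.n_residues)

    def depth_of(self, residue: int) -> float:
        if isinstance(self.bound_depths, Mapping):
            return float(self.bound_depths.get(residue, 0.2))
        return float(self.bound_depths)

    def unbound_floor(self) -> float:
        """Minimum altitude of the lowest protein bead above the head plane."""
        k = 4.0 if self.clean_margins else 1.5
        return BOUND_THRESHOLD + k * self.positional_noise_sd

    def stationary_occupancy(self) -> float:
        if self.p_bind + self.p_unbind == 0:
            raise ParameterError("stationary occupancy undefined when both rates are 0")
        return self.p_bind / (self.p_bind + self.p_unbind)


@dataclass
class GroundTruth:
    """Exact generator record used for parameter-recovery tests."""

    state_sequence: np.ndarray  # bool, True = bound
    interface_residues: frozenset[int]
    true_depths: dict[int, float]
    seed: int

    @property
    def true_occupancy(self) -> float:
        return float(np.mean(self.state_sequence))

    def to_json(self) -> str:
        return json.dumps(
            {
                "state_sequence": [int(s) for s in self.state_sequence],
                "true_occupancy": self.true_occupancy,
                "interface_residues": sorted(self.interface_residues),
                "true_depths": {str(k): v for k, v in self.true_depths.items()},
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            state_sequence=np.array(d["state_sequence"], dtype=bool),
            interface_residues=frozenset(d["interface_residues"]),
            true_depths={int(k): float(v) for k, v in d["true_depths"].items()},
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(Path(path).read_text())


def _clipped_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Gaussian noise hard-clipped at ±NOISE_CLIP_SIGMA·sd (keeps margins exact)."""
    if sd == 0:
        return np.zeros(size)
    lim = NOISE_CLIP_SIGMA * sd
    return np.clip(rng.normal(0.0, sd, size), -lim, lim)


def _largest_remainder_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    names = sorted(fractions)
    exact = np.array([fractions[k] * n for k in names])
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    short = n - counts.sum()
    # distribute leftovers by descending remainder, name as deterministic tie-break
    order = sorted(range(len(names)), key=lambda i: (-rem[i], names[i]))
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(names, counts))


@dataclass
class _BilayerGeometry:
    particles: list[Particle]
    coords: np.ndarray
    upper_plane_z: float
    lower_plane_z: float
    upper_head_xy: np.ndarray  # (n_upper, 2) lattice sites of upper head beads
    head_indices_upper: np.ndarray


def _build_bilayer_geometry(
    composition: LipidComposition,
    box: Sequence[float],
    area_per_lipid: float,
    seed: int,
    first_particle_id: int = 1,
    first_residue_index: int = 1,
    n_tail_beads: int = 2,
    jitter_sd: float = 0.01,
) -> _BilayerGeometry:
    bx, by, bz = box
    n_leaflet = int(np.floor(bx * by / area_per_lipid))
    if n_leaflet < 4:
        raise ParameterError(
            f"box cross-section {bx}x{by} with area/lipid {area_per_lipid} "
            f"holds only {n_leaflet} lipids per leaflet (need >= 4)"
        )
    rng = np.random.default_rng(seed)
    mid = bz / 2.0
    n_side = int(np.ceil(np.sqrt(n_leaflet)))
    sx, sy = bx / n_side, by / n_side
    gi, gj = np.divmod(np.arange(n_leaflet), n_side)
    lattice = np.column_stack(((gj + 0.5) * sx, (gi + 0.5) * sy))

    counts = _largest_remainder_counts(composition.fractions, n_leaflet)
    class_pool = np.repeat(
        np.array(sorted(counts), dtype=object),
        [counts[k] for k in sorted(counts)],
    )

    particles: list[Particle] = []
    coords: list[np.ndarray] = []
    upper_head_xy = []
    head_indices_upper = []
    pid = first_particle_id
    resid = first_residue_index
    for leaflet, sign in ((Leaflet.UPPER, 1.0), (Leaflet.LOWER, -1.0)):
        classes = class_pool[rng.permutation(n_leaflet)]
        head_z = mid + sign * HALF_THICKNESS
        for k in range(n_leaflet):
            xy = lattice[k] + _clipped_normal(rng, jitter_sd, 2)
            lipid_class = str(classes[k])
            if leaflet == Leaflet.UPPER:
                upper_head_xy.append(lattice[k])
                head_indices_upper.append(len(coords))
            particles.append(
                Particle(pid, resid, lipid_class, "PO4", Role.LIPID_HEAD, lipid_class, leaflet)
            )
            coords.append(np.array([xy[0], xy[1], head_z]))
            pid += 1
            for t in range(1, n_tail_beads + 1):
                particles.append(
                    Particle(
                        pid, resid, lipid_class, f"C{t}A", Role.LIPID_TAIL, lipid_class, leaflet
                    )
                )
                coords.append(np.array([xy[0], xy[1], head_z - sign * TAIL_SPACING * t]))
                pid += 1
            resid += 1
    return _BilayerGeometry(
        particles=particles,
        coords=np.array(coords),
        upper_plane_z=mid + HALF_THICKNESS,
        lower_plane_z=mid - HALF_THICKNESS,
        upper_head_xy=np.array(upper_head_xy),
        head_indices_upper=np.array(head_indices_upper, dtype=np.int64),
    )


def build_bilayer(
    composition: LipidComposition,
    box: Sequence[float] = (17.0, 17.0, 25.0),
    area_per_lipid: float = 0.64,
    seed: int = 0,
) -> tuple[Topology, Frame]:
    """Deterministic lattice bilayer: two leaflets centred on the box z-midplane.

    Each lipid has one "PO4" head bead and two tail beads; class counts follow
    the composition by largest-remainder rounding (within ±1 lipid per class).
    """
    geo = _build_bilayer_geometry(composition, box, area_per_lipid, seed)
    topo = Topology(geo.particles, composition)
    frame = Frame(time=0.0, box=np.asarray(box, dtype=float), coords=geo.coords)
    return topo, frame


@dataclass
class _ProteinTemplate:
    particles: list[Particle]
    rel_coords: np.ndarray  # (n_beads, 3); z = 0 at the lowest (interface) layer
    bead_residue: np.ndarray  # residue id per bead
    interface_mask: np.ndarray  # bool per bead
    clearance: float  # z offset of the lowest non-interface bead


def _build_protein_template(params: SyntheticParams, seed: int) -> _ProteinTemplate:
    rng = np.random.default_rng(seed)
    resids = params.residue_ids()
    iface = np.array([r in params.interface_residues for r in resids])
    n_iface = int(iface.sum())
    clearance = CONTACT_CUTOFF + 0.05 + NOISE_CLIP_SIGMA * params.positional_noise_sd

    def grid_xy(n: int, spacing: float = 0.5) -> np.ndarray:
        side = max(1, int(np.ceil(np.sqrt(n))))
        gi, gj = np.divmod(np.arange(n), side)
        xy = np.column_stack((gj * spacing, gi * spacing))
        return xy - xy.mean(axis=0)

    # Interface residues form the membrane-facing bottom layer (z=0);
    # the remaining residues stack in layers above a clearance gap.
    positions = np.zeros((params.n_residues, 3))
    if n_iface:
        positions[iface, :2] = grid_xy(n_iface)
        positions[iface, 2] = 0.0
    n_rest = params.n_residues - n_iface
    if n_rest:
        per_layer = max(1, int(np.ceil(np.sqrt(n_rest))))
        rest_xy = grid_xy(n_rest, spacing=0.5)
        layer = np.arange(n_rest) // per_layer
        positions[~iface, :2] = rest_xy
        positions[~iface, 2] = clearance + 0.4 * layer
    positions[:, :2] += _clipped_normal(rng, 0.02, (params.n_residues, 2))

    particles: list[Particle] = []
    rel = []
    bead_residue = []
    bead_iface = []
    pid = 1
    bead_offsets = 0.05 * np.arange(params.beads_per_residue)[:, None] * np.array([[1.0, 0.0, 0.0]])
    for i, r in enumerate(resids):
        for b in range(params.beads_per_residue):
            name = "BB" if b == 0 else f"SC{b}"
            particles.append(Particle(pid, int(r), "DYS", name, Role.PROTEIN))
            rel.append(positions[i] + bead_offsets[b])
            bead_residue.append(int(r))
            bead_iface.append(bool(iface[i]))
            pid += 1
    rel = np.array(rel)
    rel[:, 2] -= rel[:, 2].min()  # anchor the lowest bead at z = 0
    return _ProteinTemplate(
        particles=particles,
        rel_coords=rel,
        bead_residue=np.array(bead_residue),
        interface_mask=np.array(bead_iface),
        clearance=clearance,
    )


def build_protein(params: SyntheticParams, seed: int | None = None) -> tuple[list[Particle], np.ndarray]:
    """Protein bead cloud with its lowest bead exactly ``start_offset`` above
    the upper head-bead plane of the default bilayer geometry."""
    seed = params.seed if seed is None else seed
    tpl = _build_protein_template(params, seed)
    upper_plane = params.box[2] / 2.0 + HALF_THICKNESS
    coords = tpl.rel_coords.copy()
    coords[:, 0] += params.box[0] / 2.0
    coords[:, 1] += params.box[1] / 2.0
    coords[:, 2] += upper_plane + params.start_offset
    return tpl.particles, coords


def _simulate_states(
    params: SyntheticParams, rng: np.random.Generator, schedule: np.ndarray | None
) -> np.ndarray:
    if schedule is not None:
        return np.asarray(schedule, dtype=bool)
    n = params.n_frames
    states = np.empty(n, dtype=bool)
    if params.initial_state == "bound":
        state = True
    elif params.initial_state == "unbound":
        state = False
    else:
        state = rng.random() < params.stationary_occupancy()
    u = rng.random(n)
    for t in range(n):
        states[t] = state
        if state:
            state = u[t] >= params.p_unbind
        else:
            state = u[t] < params.p_bind
    return states


def simulate_binding_trajectory(
    params: SyntheticParams,
    state_schedule: np.ndarray | None = None,
    replica_id: int = 0,
    label: str | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one replica trajectory plus its exact ground truth.

    The hidden bound/unbound state evolves as a two-state Markov chain.  In
    bound frames every interface residue sits at its configured depth below
    the upper head plane, laterally snapped near a head-bead lattice site; in
    unbound frames the rigid cloud rides a mean-reverting altitude excursion
    clamped above the unbound floor.  Lipids jitter laterally only.  All
    randomness flows from ``params.seed`` (optionally a fixed state schedule
    replaces the chain, e.g. for scripted detachment fixtures).
    """
    ss = np.random.SeedSequence(params.seed)
    s_bilayer, s_protein, s_states, s_noise = [
        np.random.default_rng(child) for child in ss.spawn(4)
    ]

    tpl = _build_protein_template(params, params.seed)
    n_prot = len(tpl.particles)
    geo = _build_bilayer_geometry(
        params.lipid_composition,
        params.box,
        params.area_per_lipid,
        seed=int(s_bilayer.integers(2**31)),
        first_particle_id=n_prot + 1,
        first_residue_index=params.first_residue + params.n_residues,
    )
    topology = Topology(tpl.particles + geo.particles, params.lipid_composition)

    states = _simulate_states(params, s_states, state_schedule)
    n_frames = states.size
    plane = geo.upper_plane_z

    # static lateral snap site per interface bead: nearest upper head lattice xy
    prot_xy = tpl.rel_coords[:, :2] + np.array([params.box[0] / 2.0, params.box[1] / 2.0])
    iface_beads = np.flatnonzero(tpl.interface_mask)
    site_xy = np.empty((iface_beads.size, 2))
    for k, b in enumerate(iface_beads):
        d2 = np.sum((geo.upper_head_xy - prot_xy[b]) ** 2, axis=1)
        site_xy[k] = geo.upper_head_xy[np.argmin(d2)]
    depths = np.array([params.depth_of(r) for r in tpl.bead_residue[iface_beads]])

    # unbound altitude: mean-reverting walk clamped at the floor
    floor = params.unbound_floor()
    alt = np.empty(n_frames)
    eta = s_noise.normal(0.0, params.drift_noise_sd, n_frames)
    a = params.start_offset if not states[0] else params.rest_altitude
    for t in range(n_frames):
        if t > 0 and not states[t] and states[t - 1]:
            a = params.rest_altitude  # fresh excursion after release
        a = a + params.reversion_rate * (params.rest_altitude - a) + eta[t]
        a = max(a, floor)
        alt[t] = a

    n_total = topology.n_particles
    coords = np.empty((n_frames, n_total, 3))

    # lipids: static base + lateral jitter
    lipid_block = np.broadcast_to(geo.coords, (n_frames,) + geo.coords.shape).copy()
    lipid_block[:, :, :2] += _clipped_normal(s_noise, 0.01, (n_frames, geo.coords.shape[0], 2))
    coords[:, n_prot:, :] = lipid_block

    # protein block
    noise = _clipped_normal(s_noise, params.positional_noise_sd, (n_frames, n_prot, 3))
    bound_f = np.flatnonzero(states)
    unbound_f = np.flatnonzero(~states)

    if unbound_f.size:
        base = tpl.rel_coords[None, :, :].copy()
        pos = np.repeat(base, unbound_f.size, axis=0)
        pos[:, :, 0] += params.box[0] / 2.0
        pos[:, :, 1] += params.box[1] / 2.0
        pos[:, :, 2] += plane + alt[unbound_f, None]
        coords[unbound_f, :n_prot, :] = pos + noise[unbound_f]

    if bound_f.size:
        pos = np.repeat(tpl.rel_coords[None, :, :], bound_f.size, axis=0)
        pos[:, :, 0] += params.box[0] / 2.0
        pos[:, :, 1] += params.box[1] / 2.0
        # non-interface beads keep the template stack above the plane
        pos[:, :, 2] += plane
        # interface beads: snapped lateral site, configured depth below plane
        pos[:, iface_beads, 0] = site_xy[None, :, 0]
        pos[:, iface_beads, 1] = site_xy[None, :, 1]
        pos[:, iface_beads, 2] = plane - depths[None, :]
        coords[bound_f, :n_prot, :] = pos + noise[bound_f]

    times = np.arange(n_frames) * params.frame_dt
    boxes = np.broadcast_to(np.asarray(params.box, dtype=float), (n_frames, 3)).copy()
    if label is None:
        pa = params.lipid_composition.fractions.get("DOPA", 0.0)
        label = f"{int(round(pa * 100))}% DOPA"
    traj = Trajectory(topology, times, boxes, coords, replica_id=replica_id, label=label)
    truth = GroundTruth(
        state_sequence=states,
        interface_residues=params.interface_residues,
        true_depths={int(r): params.depth_of(int(r)) for r in sorted(params.interface_residues)},
        seed=params.seed,
    )
    return traj, truth


def simulate_replicas(
    params: SyntheticParams, n_replicas: int, base_seed: int | None = None, label: str | None = None
) -> tuple[ReplicaSet, list[GroundTruth]]:
    """Independent replicas; replica ``r`` uses seed ``base_seed + r``."""
    from dataclasses import replace as _replace

    if n_replicas < 1:
        raise ParameterError("n_replicas must be >= 1")
    base_seed = params.seed if base_seed is None else base_seed
    trajectories, truths = [], []
    for r in range(n_replicas):
        p = _replace(params, seed=base_seed + r)
        traj, truth = simulate_binding_trajectory(p, replica_id=r, label=label)
        trajectories.append(traj)
        truths.append(truth)
    return ReplicaSet(trajectories, label=trajectories[0].label), truths


def simulate_detachment_trajectory(
    params: SyntheticParams, detach_fraction: float = 0.5
) -> tuple[Trajectory, GroundTruth]:
    """Scripted fixture: bound for the first part of the run, then released.

    Emulates an interface that is not maintained over time (the unstable
    binding-mode contrast): interface residues flip from inserted to far
    above the membrane surface in the second part of the trajectory.
    """
    if not (0.0 < detach_fraction < 1.0):
        raise ParameterError("detach_fraction must lie in (0,1)")
    n_bound = int(round(params.n_frames * detach_fraction))
    schedule = np.zeros(params.n_frames, dtype=bool)
    schedule[:n_bound] = True
    return simulate_binding_trajectory(params, state_schedule=schedule, label="detachment")
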