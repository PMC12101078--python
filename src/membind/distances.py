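"""Minimum-distance computations between particle groups under periodic
boundaries.

Two production paths exist and must agree: a brute-force broadcast over all
pairs (used below a pair-count threshold, and itself the reference the
accelerated path is tested against) and a k-d tree accelerator with per-axis
periodicity.  The minimum-image convention is applied on the axes active in
``pbc_mode`` ("xyz", "xy" for z-oriented membranes, or "none").  Distances
are computed in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .core import AnalysisConfig, Frame, SelectionError, Topology, Trajectory

__all__ = [
    "MinDistanceTrace",
    "ResidueDistanceMatrix",
    "min_distance_frame",
    "min_distance_trace",
    "min_distance_over_frames",
    "per_residue_min_distance",
]

PBC_AXES = {"xyz": (0, 1, 2), "xy": (0, 1), "none": ()}

# Above this many pairs per frame the k-d tree path takes over.
BRUTE_PAIR_LIMIT = 250_000
_CHUNK_BYTES = 96 * 2**20


@dataclass
class MinDistanceTrace:
    """Per-frame minimum distance between two particle groups (nm)."""

    times: np.ndarray  # ps
    values: np.ndarray  # nm
    group_a: str = "A"
    group_b: str = "B"
    pbc_mode: str = "xyz"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ResidueDistanceMatrix:
    """Per-residue, per-frame minimum distance to the membrane (nm)."""

    residue_indices: np.ndarray
    times: np.ndarray
    values: np.ndarray  # (n_residues, n_frames)

    def global_trace(self, **kwargs) -> MinDistanceTrace:
        """Row-wise minimum; equals the whole-protein minimum-distance trace."""
        return MinDistanceTrace(
            times=self.times, values=self.values.min(axis=0), **kwargs
        )


def _validate_groups(group_a: np.ndarray, group_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(group_a, dtype=np.int64).ravel()
    b = np.asarray(group_b, dtype=np.int64).ravel()
    if a.size == 0 or b.size == 0:
        raise SelectionError("both particle groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise SelectionError("particle groups must be disjoint")
    return a, b


def _pbc_axes(pbc_mode: str) -> tuple[int, ...]:
    try:
        return PBC_AXES[pbc_mode]
    except KeyError:
        raise SelectionError(f"unknown pbc_mode {pbc_mode!r}") from None


def _min_image(disp: np.ndarray, box: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Wrap displacement components on the active axes (in place)."""
    for ax in axes:
        length = box[..., ax]
        disp[..., ax] -= length * np.round(disp[..., ax] / length)
    return disp


def _brute_min(coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray, axes) -> float:
    disp = coords_a[:, None, :] - coords_b[None, :, :]
    _min_image(disp, box, axes)
    return float(np.sqrt(np.einsum("ijk,ijk->ij", disp, disp).min()))


def _tree_min(coords_a: np.ndarray, coords_b: np.ndarray, box: np.ndarray, axes) -> float:
    # shift both groups to non-negative coordinates (distance-invariant),
    # wrap the periodic axes, and use per-axis boxsize (0 = non-periodic)
    pts = np.concatenate([coords_a, coords_b])
    shift = pts.min(axis=0)
    a = coords_a - shift
    b = coords_b - shift
    boxsize = np.zeros(3)
    for ax in axes:
        boxsize[ax] = box[ax]
        a[:, ax] %= box[ax]
        b[:, ax] %= box[ax]
    tree = cKDTree(b, boxsize=boxsize if axes else None)
    d, _ = tree.query(a, k=1)
    return float(d.min())


def min_distance_frame(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    pbc_mode: str = "xyz",
    force: str | None = None,
) -> float:
    """Minimum over all pairs (a in A, b in B) of the minimum-image distance.

    Symmetric in (A, B).  ``force`` pins the implementation to "brute" or
    "tree" regardless of problem size (used to cross-check the two paths).
    """
    a, b = _validate_groups(group_a, group_b)
    axes = _pbc_axes(pbc_mode)
    ca = frame.coords[a]
    cb = frame.coords[b]
    if force == "brute" or (force is None and a.size * b.size <= BRUTE_PAIR_LIMIT):
        return _brute_min(ca, cb, frame.box, axes)
    return _tree_min(ca, cb, frame.box, axes)


def _frame_chunks(n_frames: int, pair_count: int) -> int:
    per_frame = max(1, pair_count) * 3 * 8
    return max(1, min(n_frames, _CHUNK_BYTES // per_frame))


def min_distance_trace(
    trajectory: Trajectory,
    group_a: np.ndarray | None = None,
    group_b: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
    group_a_label: str = "protein",
    group_b_label: str = "membrane",
) -> MinDistanceTrace:
    """Per-frame protein-membrane (or arbitrary group) minimum distance.

    Defaults to protein versus all lipid beads.  Frames are processed in
    chunks so memory stays bounded.
    """
    config = config or AnalysisConfig()
    topo = trajectory.topology
    if group_a is None:
        group_a = topo.protein_indices()
    if group_b is None:
        group_b = topo.membrane_indices()
    a, b = _validate_groups(group_a, group_b)
    axes = _pbc_axes(config.pbc_mode)
    n_frames = trajectory.n_frames
    values = np.empty(n_frames)
    pair_count = a.size * b.size
    if pair_count <= BRUTE_PAIR_LIMIT:
        step = _frame_chunks(n_frames, pair_count)
        for start in range(0, n_frames, step):
            sl = slice(start, min(start + step, n_frames))
            disp = (
                trajectory.coords[sl][:, a, None, :]
                - trajectory.coords[sl][:, None, b, :]
            )
            box = trajectory.boxes[sl][:, None, None, :]
            _min_image(disp, box, axes)
            d2 = np.einsum("fijk,fijk->fij", disp, disp)
            values[sl] = np.sqrt(d2.reshape(d2.shape[0], -1).min(axis=1))
    else:
        for i in range(n_frames):
            values[i] = _tree_min(
                trajectory.coords[i, a], trajectory.coords[i, b], trajectory.boxes[i], axes
            )
    return MinDistanceTrace(
        times=trajectory.times.copy(),
        values=values,
        group_a=group_a_label,
        group_b=group_b_label,
        pbc_mode=config.pbc_mode,
    )


def min_distance_over_frames(
    frames,
    group_a: np.ndarray,
    group_b: np.ndarray,
    pbc_mode: str = "xyz",
) -> MinDistanceTrace:
    """Streaming variant: consumes an iterable of frames one at a time.

    Memory does not grow with frame count, so arbitrarily long trajectories
    can be analysed directly from a file reader generator.
    """
    a, b = _validate_groups(group_a, group_b)
    axes = _pbc_axes(pbc_mode)
    times, values = [], []
    for frame in frames:
        ca, cb = frame.coords[a], frame.coords[b]
        if a.size * b.size <= BRUTE_PAIR_LIMIT:
            d = _brute_min(ca, cb, frame.box, axes)
        else:
            d = _tree_min(ca, cb, frame.box, axes)
        times.append(frame.time)
        values.append(d)
    return MinDistanceTrace(times=np.array(times), values=np.array(values), pbc_mode=pbc_mode)


def per_residue_min_distance(
    trajectory: Trajectory,
    membrane: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> ResidueDistanceMatrix:
    """Minimum distance of each protein residue's beads to any membrane bead.

    The row-wise minimum over residues reproduces the global protein-membrane
    minimum-distance trace by construction.
    """
    config = config or AnalysisConfig()
    topo = trajectory.topology
    prot, offsets, residue_ids = topo.protein_residue_offsets()
    if membrane is None:
        membrane = topo.membrane_indices()
    _, mem = _validate_groups(prot, membrane)
    axes = _pbc_axes(config.pbc_mode)
    n_frames = trajectory.n_frames
    out = np.empty((residue_ids.size, n_frames))
    pair_count = prot.size * mem.size
    step = _frame_chunks(n_frames, pair_count)
    for start in range(0, n_frames, step):
        sl = slice(start, min(start + step, n_frames))
        disp = (
            trajectory.coords[sl][:, prot, None, :]
            - trajectory.coords[sl][:, None, mem, :]
        )
        box = trajectory.boxes[sl][:, None, None, :]
        _min_image(disp, box, axes)
        d = np.sqrt(np.einsum("fijk,fijk->fij", disp, disp)).min(axis=2)  # (f, n_prot_beads)
        out[:, sl] = np.minimum.reduceat(d, offsets, axis=1).T
    return ResidueDistanceMatrix(
        residue_indices=residue_ids.copy(), times=trajectory.times.copy(), values=out
    )
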