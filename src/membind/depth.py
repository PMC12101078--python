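"""Per-residue membrane-insertion depth relative to the head-bead plane.

The membrane surface is the mean z of the phosphate ("PO4") head beads of
the leaflet proximal to the protein, evaluated per frame (a flat reference
plane, not a fitted surface).  Depth is signed: positive = below the surface
(inserted into the membrane), negative = above it (solvated).  Profiles are
time-averaged over a window and typically compared between the first and
last window of a run to quantify binding-mode drift.  Internally nm;
ångström only at the output boundary (×10 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisConfig,
    Frame,
    InsufficientDataError,
    Leaflet,
    Role,
    SelectionError,
    Topology,
    Trajectory,
)

__all__ = [
    "DepthProfile",
    "WindowComparison",
    "membrane_surface_z",
    "residue_insertion_depth",
    "compare_windows",
]


@dataclass
class DepthProfile:
    """Signed per-residue insertion depth (nm) averaged over a time window."""

    residue_indices: np.ndarray
    depth: np.ndarray  # nm; positive = inserted below the surface
    window: tuple[float, float]  # ns
    surface_definition: str = "mean PO4 z of proximal leaflet"
    leaflet: str = Leaflet.UPPER.value

    @property
    def depth_angstrom(self) -> np.ndarray:
        return self.depth * 10.0


@dataclass
class WindowComparison:
    """First-versus-last-window depth profiles and their drift."""

    first: DepthProfile
    last: DepthProfile
    per_residue_drift: np.ndarray  # |last - first| in nm
    max_drift: float  # nm, the binding-mode drift scalar


def _head_indices(topology: Topology, leaflet: Leaflet) -> np.ndarray:
    idx = topology.indices(role=Role.LIPID_HEAD, leaflet=leaflet)
    if idx.size == 0:
        raise SelectionError(f"no head beads in {leaflet.value} leaflet")
    return idx


def membrane_surface_z(
    frame: Frame, topology: Topology, leaflet: Leaflet | str = Leaflet.UPPER
) -> float:
    """Mean z of the head beads of one leaflet (nm)."""
    leaflet = Leaflet(leaflet)
    idx = _head_indices(topology, leaflet)
    return float(np.mean(frame.coords[idx, 2]))


def _check_z_wholeness(trajectory: Trajectory, frame_sel: np.ndarray) -> None:
    """Guard: no z-periodic wrapping is applied, so the membrane must lie
    whole inside the box on every analysed frame."""
    lipids = trajectory.topology.membrane_indices()
    z = trajectory.coords[frame_sel][:, lipids, 2]
    bz = trajectory.boxes[frame_sel][:, 2]
    if np.any(z < 0) or np.any(z > bz[:, None]):
        raise SelectionError(
            "lipid beads cross the z boundary; depth analysis assumes a whole membrane"
        )


def _window_frames(trajectory: Trajectory, window_ns: tuple[float, float]) -> np.ndarray:
    start, end = window_ns
    if not start < end:
        raise InsufficientDataError(f"window start {start} must precede end {end}")
    t_ns = trajectory.times / 1000.0
    sel = np.flatnonzero((t_ns >= start - 1e-9) & (t_ns <= end + 1e-9))
    if sel.size == 0:
        raise InsufficientDataError(
            f"window [{start}, {end}] ns contains no frames "
            f"(trajectory spans [{t_ns[0]:.3f}, {t_ns[-1]:.3f}] ns)"
        )
    return sel


def residue_insertion_depth(
    trajectory: Trajectory,
    window_ns: tuple[float, float],
    config: AnalysisConfig | None = None,
    per_residue: str = "mean",
) -> DepthProfile:
    """Time-averaged signed depth of every protein residue over a window.

    depth(r) = average over window frames of (proximal-surface z − residue z),
    with the sign flipped for a lower-leaflet-proximal protein so positive
    always means inserted.  ``per_residue`` is "mean" (mean bead z, default)
    or "deepest" (the most inserted bead per frame).  The proximal leaflet is
    frozen at the window's first frame to avoid mid-window flapping.
    """
    if per_residue not in ("mean", "deepest"):
        raise InsufficientDataError(f"unknown per_residue mode {per_residue!r}")
    topo = trajectory.topology
    sel = _window_frames(trajectory, window_ns)
    _check_z_wholeness(trajectory, sel)
    prot, offsets, residue_ids = topo.protein_residue_offsets()

    first = trajectory.frame(int(sel[0]))
    centroid_z = float(np.mean(first.coords[prot, 2]))
    dists = {}
    for leaflet in (Leaflet.UPPER, Leaflet.LOWER):
        try:
            dists[leaflet] = abs(membrane_surface_z(first, topo, leaflet) - centroid_z)
        except SelectionError:
            continue
    if not dists:
        raise SelectionError("no leaflet head beads present")
    proximal = min(dists, key=dists.get)
    sign = 1.0 if proximal == Leaflet.UPPER else -1.0

    heads = _head_indices(topo, proximal)
    surface = trajectory.coords[sel][:, heads, 2].mean(axis=1)  # (f,)
    prot_z = trajectory.coords[sel][:, prot, 2]  # (f, n_beads)
    per_bead_depth = sign * (surface[:, None] - prot_z)
    if per_residue == "mean":
        # mean over beads within each residue, then over frames
        sums = np.add.reduceat(per_bead_depth, offsets, axis=1)
        counts = np.diff(np.append(offsets, prot.size))
        res_depth = (sums / counts).mean(axis=0)
    else:
        res_depth = np.maximum.reduceat(per_bead_depth, offsets, axis=1).mean(axis=0)
    return DepthProfile(
        residue_indices=residue_ids.copy(),
        depth=res_depth,
        window=(float(window_ns[0]), float(window_ns[1])),
        leaflet=proximal.value,
    )


def compare_windows(
    trajectory: Trajectory,
    window_length_ns: float | None = None,
    config: AnalysisConfig | None = None,
    per_residue: str = "mean",
) -> WindowComparison:
    """Depth profiles over the first and last window plus the drift scalar.

    A stationary binding mode keeps the per-residue drift near zero; a
    detaching interface produces a large (> membrane-scale) drift.
    """
    config = config or AnalysisConfig()
    if window_length_ns is None:
        window_length_ns = config.window_length_ns
    if window_length_ns <= 0:
        raise InsufficientDataError("window length must be positive")
    t_ns = trajectory.times / 1000.0
    span = float(t_ns[-1] - t_ns[0])
    if span < 2 * window_length_ns:
        raise InsufficientDataError(
            f"trajectory span {span:.3f} ns < 2 x window {window_length_ns} ns"
        )
    first = residue_insertion_depth(
        trajectory, (float(t_ns[0]), float(t_ns[0] + window_length_ns)), config, per_residue
    )
    last = residue_insertion_depth(
        trajectory, (float(t_ns[-1] - window_length_ns), float(t_ns[-1])), config, per_residue
    )
    drift = np.abs(last.depth - first.depth)
    return WindowComparison(
        first=first, last=last, per_residue_drift=drift, max_drift=float(drift.max())
    )
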