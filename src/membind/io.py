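"""Structure/trajectory file I/O and result writers.

GRO is the native fixture format (fixed-column, nm-native, multi-frame by
block concatenation); PDB (multi-MODEL with CRYST1, Å) is supported for
interoperability through MDAnalysis.  Particle roles are inferred from a
configurable residue-name map.  All result files carry a metadata block with
the seed and a configuration hash so results produced under different
thresholds are never silently aggregated.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from . import __version__
from .binding import BindingSummary, KdeCurve
from .core import (
    ANGSTROM_PER_NM,
    NM_PER_ANGSTROM,
    AnalysisConfig,
    FormatError,
    Frame,
    LipidComposition,
    ParameterError,
    Particle,
    Role,
    Topology,
    Trajectory,
    assign_leaflets,
)
from .depth import DepthProfile, WindowComparison
from .distances import MinDistanceTrace, ResidueDistanceMatrix
from .interface import ResidueProfile

__all__ = [
    "ResidueRoleMap",
    "read_structure",
    "read_gro",
    "iter_gro_frames",
    "write_gro",
    "read_pdb",
    "write_pdb",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_residue_matrix_tsv",
    "write_profile_tsv",
    "write_attribute_file",
    "write_binding_summary",
    "write_kde_tsv",
    "write_depth_tsv",
    "write_window_comparison",
    "make_metadata",
    "write_metadata",
    "check_compatible_metadata",
]

_DEFAULT_LIPID_CLASSES = frozenset(
    {"DOPC", "DOPA", "DOPS", "DOPE", "POPC", "POPA", "POPS", "POPE"}
)
_DEFAULT_OTHER = frozenset({"W", "WN", "ION", "NA", "CL", "NA+", "CL-", "SOL", "TIP3"})


@dataclass(frozen=True)
class ResidueRoleMap:
    """Rules mapping residue/particle names to roles at read time."""

    lipid_classes: frozenset[str] = _DEFAULT_LIPID_CLASSES
    head_names: frozenset[str] = frozenset({"PO4"})
    other_resnames: frozenset[str] = _DEFAULT_OTHER

    def classify(self, resname: str, particle_name: str) -> tuple[Role, str | None]:
        if resname in self.lipid_classes:
            role = Role.LIPID_HEAD if particle_name in self.head_names else Role.LIPID_TAIL
            return role, resname
        if resname in self.other_resnames:
            return Role.OTHER, None
        return Role.PROTEIN, None


def _build_topology(
    resids: list[int],
    resnames: list[str],
    names: list[str],
    role_map: ResidueRoleMap,
    composition: LipidComposition | None,
    frame0: Frame,
) -> Topology:
    particles = []
    for i, (resid, resname, name) in enumerate(zip(resids, resnames, names)):
        role, lipid_class = role_map.classify(resname, name)
        particles.append(
            Particle(
                particle_id=i + 1,
                residue_index=resid,
                residue_name=resname,
                particle_name=name,
                role=role,
                lipid_class=lipid_class,
            )
        )
    if composition is None:
        lipid_residues: dict[int, str] = {}
        for p in particles:
            if p.is_lipid:
                lipid_residues.setdefault(p.residue_index, p.lipid_class)
        if lipid_residues:
            counts: dict[str, int] = {}
            for cls in lipid_residues.values():
                counts[cls] = counts.get(cls, 0) + 1
            total = sum(counts.values())
            composition = LipidComposition({k: v / total for k, v in counts.items()})
    topo = Topology(particles, composition)
    return assign_leaflets(topo, frame0)


# ---------------------------------------------------------------------------
# GRO (fixed-column dialect, nm, multi-frame by concatenated blocks)
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"\bt=\s*([-0-9.eE+]+)")


def _parse_gro_box(line: str, lineno: int) -> np.ndarray:
    try:
        vals = [float(v) for v in line.split()]
    except ValueError as exc:
        raise FormatError(f"line {lineno}: unparseable box line {line!r}") from exc
    if len(vals) == 3:
        return np.array(vals)
    if len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise FormatError(f"line {lineno}: triclinic box not supported")
        return np.array(vals[:3])
    raise FormatError(f"line {lineno}: box line needs 3 (or 9) values, got {len(vals)}")


def _parse_gro_block(lines_iter, lineno_start: int, want_labels: bool):
    """Parse one GRO frame block; returns (time, labels|None, coords, box, lineno)."""
    lineno = lineno_start
    title = next(lines_iter, None)
    if title is None:
        return None
    lineno += 1
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    count_line = next(lines_iter, None)
    if count_line is None:
        raise FormatError(f"line {lineno}: truncated file, missing atom count")
    lineno += 1
    try:
        n_atoms = int(count_line.strip())
    except ValueError as exc:
        raise FormatError(f"line {lineno}: bad atom count {count_line!r}") from exc
    coords = np.empty((n_atoms, 3))
    labels = ([], [], []) if want_labels else None
    for i in range(n_atoms):
        line = next(lines_iter, None)
        if line is None:
            raise FormatError(f"line {lineno}: truncated frame, expected {n_atoms} atoms")
        lineno += 1
        try:
            coords[i, 0] = float(line[20:28])
            coords[i, 1] = float(line[28:36])
            coords[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: coordinate parse failure") from exc
        if want_labels:
            labels[0].append(int(line[0:5]))
            labels[1].append(line[5:10].strip())
            labels[2].append(line[10:15].strip())
    box_line = next(lines_iter, None)
    if box_line is None:
        raise FormatError(f"line {lineno}: missing box line")
    lineno += 1
    box = _parse_gro_box(box_line, lineno)
    return time, labels, coords, box, lineno


def iter_gro_frames(path: str | Path) -> Iterator[Frame]:
    """Stream frames from a multi-frame GRO file with bounded memory."""
    with open(path) as fh:
        lines = iter(fh)
        lineno = 0
        index = 0
        while True:
            parsed = _parse_gro_block(lines, lineno, want_labels=False)
            if parsed is None:
                return
            time, _, coords, box, lineno = parsed
            yield Frame(time=time if time is not None else float(index), box=box, coords=coords)
            index += 1


def read_gro(
    path: str | Path,
    role_map: ResidueRoleMap | None = None,
    composition: LipidComposition | None = None,
    replica_id: int = 0,
    label: str = "",
) -> Trajectory:
    """Read a (multi-frame) GRO file into a Trajectory; coordinates in nm."""
    role_map = role_map or ResidueRoleMap()
    frames: list[Frame] = []
    labels0 = None
    with open(path) as fh:
        lines = iter(fh)
        lineno = 0
        index = 0
        while True:
            parsed = _parse_gro_block(lines, lineno, want_labels=labels0 is None)
            if parsed is None:
                break
            time, labels, coords, box, lineno = parsed
            if labels is not None:
                labels0 = labels
            frames.append(
                Frame(time=time if time is not None else float(index), box=box, coords=coords)
            )
            index += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    resids, resnames, names = labels0
    topo = _build_topology(resids, resnames, names, role_map, composition, frames[0])
    for i, f in enumerate(frames):
        if f.coords.shape[0] != topo.n_particles:
            raise FormatError(
                f"{path}: frame {i} has {f.coords.shape[0]} atoms, "
                f"topology has {topo.n_particles}"
            )
    return Trajectory.from_frames(topo, frames, replica_id=replica_id, label=label)


def write_gro(trajectory: Trajectory, path: str | Path, title: str = "membind system") -> None:
    """Write a Trajectory as concatenated fixed-column GRO frame blocks."""
    topo = trajectory.topology
    # labels are constant across frames; format them once
    prefixes = [
        f"{p.residue_index % 100000:5d}{p.residue_name:<5.5s}"
        f"{p.particle_name:>5.5s}{p.particle_id % 100000:5d}"
        for p in topo.particles
    ]
    with open(path, "w") as fh:
        for fi in range(trajectory.n_frames):
            coords = trajectory.coords[fi]
            box = trajectory.boxes[fi]
            fh.write(f"{title} t= {trajectory.times[fi]:.5f}\n")
            fh.write(f"{topo.n_particles:5d}\n")
            fh.writelines(
                f"{pre}{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}\n"
                for pre, c in zip(prefixes, coords)
            )
            fh.write(f"{box[0]:10.5f}{box[1]:10.5f}{box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# PDB (multi-MODEL, Å, CRYST1) via MDAnalysis
# ---------------------------------------------------------------------------


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


_CRYST1_RE = re.compile(
    r"^CRYST1\s*([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)\s+([\d.]+)"
)


def _pdb_box(path: Path) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            m = _CRYST1_RE.match(line)
            if m:
                a, b, c, alpha, beta, gamma = (float(g) for g in m.groups())
                if any(abs(ang - 90.0) > 1e-3 for ang in (alpha, beta, gamma)):
                    raise FormatError("triclinic PDB box not supported")
                return np.array([a, b, c]) * NM_PER_ANGSTROM
    return None


def read_pdb(
    path: str | Path,
    role_map: ResidueRoleMap | None = None,
    composition: LipidComposition | None = None,
    replica_id: int = 0,
    label: str = "",
) -> Trajectory:
    """Read a multi-MODEL PDB as a multi-frame trajectory (Å converted to nm)."""
    mda = _import_mda()
    path = Path(path)
    role_map = role_map or ResidueRoleMap()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        fallback_box = _pdb_box(path)
        frames = []
        for ts in u.trajectory:
            if ts.dimensions is not None and ts.dimensions[:3].any():
                dims = np.asarray(ts.dimensions, dtype=float)
                if any(abs(a - 90.0) > 1e-3 for a in dims[3:]):
                    raise FormatError("triclinic PDB box not supported")
                box = dims[:3] * NM_PER_ANGSTROM
            elif fallback_box is not None:
                box = fallback_box
            else:
                raise FormatError(f"{path}: missing CRYST1 box")
            frames.append(
                Frame(
                    time=float(ts.time),
                    box=box,
                    coords=ts.positions.astype(np.float64) * NM_PER_ANGSTROM,
                )
            )
        resids = [int(r) for r in u.atoms.resids]
        resnames = [str(r) for r in u.atoms.resnames]
        names = [str(n) for n in u.atoms.names]
    topo = _build_topology(resids, resnames, names, role_map, composition, frames[0])
    return Trajectory.from_frames(topo, frames, replica_id=replica_id, label=label)


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as a multi-MODEL PDB (nm converted to Å)."""
    mda = _import_mda()
    topo = trajectory.topology
    resids = [p.residue_index for p in topo.particles]
    unique_res = sorted(set(resids))
    res_of = {r: i for i, r in enumerate(unique_res)}
    resindex = [res_of[r] for r in resids]
    resname_of: dict[int, str] = {}
    for p in topo.particles:
        resname_of.setdefault(p.residue_index, p.residue_name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            topo.n_particles, n_residues=len(unique_res), atom_resindex=resindex, trajectory=True
        )
        u.add_TopologyAttr("names", [p.particle_name for p in topo.particles])
        u.add_TopologyAttr("resnames", [resname_of[r] for r in unique_res])
        u.add_TopologyAttr("resids", unique_res)
        with mda.Writer(str(path), multiframe=True) as writer:
            for fi in range(trajectory.n_frames):
                frame = trajectory.frame(fi)
                u.atoms.positions = frame.coords * ANGSTROM_PER_NM
                dims = np.concatenate([frame.box * ANGSTROM_PER_NM, [90.0, 90.0, 90.0]])
                u.trajectory.ts.dimensions = dims
                writer.write(u.atoms)


def read_structure(path: str | Path, format: str | None = None, **kwargs) -> Trajectory:
    """Dispatch to the GRO or PDB reader by declared format or file suffix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gro":
        return read_gro(path, **kwargs)
    if fmt == "pdb":
        return read_pdb(path, **kwargs)
    raise FormatError(f"unknown structure format {fmt!r}")


# ---------------------------------------------------------------------------
# Result writers (TSV/JSON with metadata blocks)
# ---------------------------------------------------------------------------


def make_metadata(
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    inputs: dict | None = None,
    **extra,
) -> dict:
    config = config or AnalysisConfig()
    meta = {
        "tool": "membind",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed if seed is None else seed,
    }
    if inputs:
        meta["inputs"] = inputs
    meta.update(extra)
    return meta


def write_metadata(meta: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def check_compatible_metadata(metas: list[dict], force: bool = False) -> None:
    """Refuse to aggregate results produced under different configurations."""
    hashes = {m.get("config_hash") for m in metas}
    if len(hashes) > 1 and not force:
        raise ParameterError(
            f"refusing to aggregate results with differing config hashes {sorted(hashes)}; "
            "pass force=True to override"
        )


def _meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {json.dumps(v, sort_keys=True)}\n" for k, v in sorted(meta.items()))


def write_trace_tsv(trace: MinDistanceTrace, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("time_ps\tmin_distance_nm\n")
        for t, v in zip(trace.times, trace.values):
            fh.write(f"{t:.4f}\t{v:.6f}\n")


def read_trace_tsv(path: str | Path) -> tuple[MinDistanceTrace, dict]:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(": ")
            if value:
                try:
                    meta[key] = json.loads(value)
                except json.JSONDecodeError:
                    meta[key] = value
    df = pd.read_csv(path, sep="\t", comment="#")
    return (
        MinDistanceTrace(times=df["time_ps"].to_numpy(), values=df["min_distance_nm"].to_numpy()),
        meta,
    )


def write_residue_matrix_tsv(
    matrix: ResidueDistanceMatrix, path: str | Path, meta: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write("residue_index\t" + "\t".join(f"{t:.4f}" for t in matrix.times) + "\n")
        for r, row in zip(matrix.residue_indices, matrix.values):
            fh.write(f"{r}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_profile_tsv(profile: ResidueProfile, path: str | Path, meta: dict | None = None) -> None:
    names = profile.residue_names or [""] * profile.residue_indices.size
    raw = profile.raw_fraction
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write(f"# normalization_mode: {profile.normalization_mode}\n")
        fh.write(f"# cutoff_nm: {profile.cutoff}\n")
        fh.write(f"# n_frames_total: {profile.n_frames_total}\n")
        fh.write("residue_index\tresidue_name\tfrequency\traw_fraction\n")
        for i, (r, name, f) in enumerate(
            zip(profile.residue_indices, names, profile.frequency)
        ):
            rf = raw[i] if raw is not None else f
            fh.write(f"{r}\t{name}\t{f:.6f}\t{rf:.6f}\n")


def write_attribute_file(profile: ResidueProfile, path: str | Path) -> None:
    """Plain residue<TAB>value table consumable by molecular viewers."""
    with open(path, "w") as fh:
        for r, f in zip(profile.residue_indices, profile.frequency):
            fh.write(f"{r}\t{f:.6f}\n")


def write_binding_summary(
    summary: BindingSummary, json_path: str | Path, tsv_path: str | Path | None = None,
    meta: dict | None = None,
) -> None:
    payload = summary.to_dict()
    if meta:
        payload["metadata"] = meta
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(_meta_header(meta))
            fh.write("condition\treplica\tfraction\tmean_pct\tse_pct\n")
            for i, f in enumerate(summary.per_replica_fraction):
                fh.write(
                    f"{summary.condition_label}\t{i}\t{f:.6f}\t"
                    f"{summary.mean_percentage:.4f}\t{summary.standard_error:.4f}\n"
                )


def write_kde_tsv(curve: KdeCurve, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write(f"# bandwidth_nm: {curve.bandwidth}\n")
        fh.write("distance_nm\tdensity\n")
        for x, y in zip(curve.grid, curve.density):
            fh.write(f"{x:.6f}\t{y:.8f}\n")


def write_depth_tsv(profile: DepthProfile, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        fh.write(f"# surface_definition: {profile.surface_definition}\n")
        fh.write(f"# proximal_leaflet: {profile.leaflet}\n")
        fh.write(
            "residue_index\tdepth_nm\tdepth_angstrom\twindow_start_ns\twindow_end_ns\n"
        )
        for r, d in zip(profile.residue_indices, profile.depth):
            fh.write(
                f"{r}\t{d:.6f}\t{d * ANGSTROM_PER_NM:.5f}\t"
                f"{profile.window[0]:.3f}\t{profile.window[1]:.3f}\n"
            )


def write_window_comparison(
    comparison: WindowComparison, json_path: str | Path, meta: dict | None = None
) -> None:
    payload = {
        "window_first_ns": list(comparison.first.window),
        "window_last_ns": list(comparison.last.window),
        "max_drift_nm": comparison.max_drift,
        "per_residue_drift_nm": {
            int(r): float(d)
            for r, d in zip(comparison.first.residue_indices, comparison.per_residue_drift)
        },
    }
    if meta:
        payload["metadata"] = meta
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
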