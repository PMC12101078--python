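"""Per-residue lipid-contact frequency and binding-region segmentation.

A residue counts as lipid-contacting in a frame when the minimum distance
between any of its beads and any membrane bead is strictly below the contact
cutoff (default 0.5 nm).  Contact frames are counted across all replicas of
a condition and normalized by the total frame count (``per_frame_fraction``);
an optional ``max_scaled`` mode divides by the maximum frequency, as heatmap
figures often do.  Ranking and contiguous-run segmentation turn the profile
into an interface map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AnalysisConfig,
    InsufficientDataError,
    ParameterError,
    ReplicaSet,
)
from .distances import per_residue_min_distance

__all__ = [
    "ResidueProfile",
    "residue_contact_frequency",
    "rank_binding_residues",
    "contiguous_binding_regions",
]


@dataclass
class ResidueProfile:
    """Per-residue lipid-interaction frequency over pooled replica frames."""

    residue_indices: np.ndarray
    frequency: np.ndarray  # in [0, 1]
    normalization_mode: str
    cutoff: float  # nm
    n_frames_total: int
    residue_names: list[str] = field(default_factory=list)
    raw_fraction: np.ndarray | None = None  # frames-fraction before max scaling

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=np.int64)
        self.frequency = np.asarray(self.frequency, dtype=np.float64)
        if self.residue_indices.shape != self.frequency.shape:
            raise ValueError("residue_indices and frequency lengths differ")

    def as_mapping(self) -> dict[int, float]:
        return {int(r): float(f) for r, f in zip(self.residue_indices, self.frequency)}


def residue_contact_frequency(
    replicas: ReplicaSet,
    membrane: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> ResidueProfile:
    """Fraction of pooled frames in which each residue contacts the membrane.

    frequency(r) = (# frames across all replicas with residue-r min distance
    < cutoff) / (total frames across all replicas); strict comparison.
    Replica concatenation order cannot change the result.
    """
    config = config or AnalysisConfig()
    if len(replicas) == 0:
        raise InsufficientDataError("empty replica set")
    cutoff = config.residue_contact_cutoff
    counts = None
    residue_ids = None
    names: list[str] = []
    n_total = 0
    for traj in replicas.trajectories:
        mat = per_residue_min_distance(traj, membrane=membrane, config=config)
        bound = (mat.values < cutoff).sum(axis=1)
        if counts is None:
            counts = bound.astype(np.int64)
            residue_ids = mat.residue_indices
            names = traj.topology.residue_names(residue_ids)
        else:
            if not np.array_equal(residue_ids, mat.residue_indices):
                raise ParameterError("replicas disagree on protein residue indices")
            counts += bound
        n_total += mat.values.shape[1]
    raw = counts / n_total
    if config.normalization_mode == "max_scaled":
        peak = raw.max()
        freq = raw / peak if peak > 0 else raw.copy()
    else:
        freq = raw.copy()
    return ResidueProfile(
        residue_indices=residue_ids,
        frequency=freq,
        normalization_mode=config.normalization_mode,
        cutoff=cutoff,
        n_frames_total=n_total,
        residue_names=names,
        raw_fraction=raw,
    )


def rank_binding_residues(profile: ResidueProfile, k: int) -> list[int]:
    """Top-k residues by descending contact frequency.

    Ties break by ascending residue index (deterministic).  ``k`` larger
    than the residue count is clipped with a warning.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    n = profile.residue_indices.size
    if k > n:
        warnings.warn(f"k={k} exceeds residue count {n}; clipping", stacklevel=2)
        k = n
    order = sorted(
        range(n), key=lambda i: (-profile.frequency[i], profile.residue_indices[i])
    )
    return [int(profile.residue_indices[i]) for i in order[:k]]


def contiguous_binding_regions(
    profile: ResidueProfile, level: float = 0.5
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residues with frequency ≥ level·max.

    Returns inclusive (start, end) residue ranges in the profile's own
    numbering.  An all-zero profile yields an empty list.
    """
    if not (0.0 < level <= 1.0):
        raise ParameterError(f"level must lie in (0, 1], got {level}")
    peak = float(profile.frequency.max()) if profile.frequency.size else 0.0
    if peak == 0.0:
        return []
    mask = profile.frequency >= level * peak
    selected = [int(r) for r, m in zip(profile.residue_indices, mask) if m]
    runs: list[list[int]] = []
    for r in selected:
        if runs and r == runs[-1][1] + 1:
            runs[-1][1] = r
        else:
            runs.append([r, r])
    return [(a, b) for a, b in runs]
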