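"""Liposome-flotation bound-fraction quantification.

In a sucrose-gradient flotation assay, liposome-bound protein floats with
the vesicles to the top of the gradient.  Four fractions are collected from
the top of the tube; the bound fraction of a measurement is the band
intensity of the top fraction divided by the total intensity across all
four.  Densitometry (gel image → intensity) is upstream of this module;
input is a per-fraction intensity table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import InsufficientDataError, ParameterError

__all__ = [
    "FlotationMeasurement",
    "bound_fraction_flotation",
    "summarize_flotation",
    "read_flotation_table",
]

N_FRACTIONS = 4  # collected top (1) to bottom (4)


@dataclass(frozen=True)
class FlotationMeasurement:
    """Band intensities of the four gradient fractions for one lane."""

    sample_label: str
    intensities: tuple[float, float, float, float]
    replicate_id: int = 0

    def __post_init__(self):
        vals = tuple(float(v) for v in self.intensities)
        if len(vals) != N_FRACTIONS:
            raise ParameterError(
                f"expected {N_FRACTIONS} fraction intensities, got {len(vals)}"
            )
        if any(v < 0 for v in vals):
            raise ParameterError(f"negative intensity in {self.sample_label!r}: {vals}")
        object.__setattr__(self, "intensities", vals)


def bound_fraction_flotation(measurement: FlotationMeasurement) -> float:
    """Top-fraction intensity over total intensity; in [0, 1].

    Scale-invariant: multiplying all intensities by a positive constant
    leaves the result unchanged.  All-zero lanes are unquantifiable.
    """
    total = sum(measurement.intensities)
    if total <= 0:
        raise InsufficientDataError(
            f"measurement {measurement.sample_label!r} has zero total intensity"
        )
    return measurement.intensities[0] / total


def summarize_flotation(measurements: list[FlotationMeasurement]) -> pd.DataFrame:
    """Per-sample mean bound percentage and SD across replicates.

    SD is the sample standard deviation (n−1); a single replicate reports
    SD = 0 with ``n = 1`` so it is visibly unreplicated.
    """
    if not measurements:
        raise InsufficientDataError("no measurements")
    rows = []
    by_label: dict[str, list[float]] = {}
    for m in measurements:
        by_label.setdefault(m.sample_label, []).append(bound_fraction_flotation(m))
    for label, fracs in by_label.items():
        arr = np.array(fracs)
        sd = float(100.0 * arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(
            {
                "sample_label": label,
                "n": arr.size,
                "mean_bound_pct": float(100.0 * arr.mean()),
                "sd_pct": sd,
            }
        )
    return pd.DataFrame(rows)


def read_flotation_table(path: str | Path) -> list[FlotationMeasurement]:
    """Read a TSV/CSV with columns sample_label, replicate, f1..f4.

    f1 is the top fraction (first collected), f4 the bottom.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"sample_label", "f1", "f2", "f3", "f4"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"flotation table missing columns: {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        out.append(
            FlotationMeasurement(
                sample_label=str(row["sample_label"]),
                intensities=(row["f1"], row["f2"], row["f3"], row["f4"]),
                replicate_id=int(row["replicate"]) if "replicate" in df.columns else int(i),
            )
        )
    return out
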