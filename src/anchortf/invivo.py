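"""Axon-growth quantification arithmetic: fiber index and branch frequency.

These are the fixed formulas used to quantify cross-midline sprouting of
corticospinal axons after pyramidotomy. Counting is manual and blinded in
the source experiments; this module pins down only the auditable
arithmetic: extrapolation of total labeled axons in the medullary pyramid
from sampled virtual lines, the per-distance fiber index, and the branch
frequency per traced millimetre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


def medulla_total(
    line_counts: Sequence[float],
    sampled_area: float,
    pyramid_area: float,
) -> float:
    """Total axons extrapolated from virtual-line counts by the area ratio.

    Counts from the sampled virtual lines (seven 10-um lines in the source
    protocol) are summed and scaled by pyramid_area / sampled_area.
    """
    if sampled_area <= 0:
        raise ValueError("sampled_area must be positive")
    if pyramid_area < sampled_area:
        raise ValueError("pyramid_area must be >= sampled_area")
    if any(c < 0 for c in line_counts):
        raise ValueError("counts must be >= 0")
    return float(sum(line_counts)) * (pyramid_area / sampled_area)


@dataclass
class AxonCountTable:
    """Per-animal axon counts: sections x midline distances, plus medulla lines.

    ``section_counts`` maps distance (um from midline) to the per-section
    counts (four replicate sections in the source protocol).
    """

    section_counts: Mapping[float, Sequence[float]]
    line_counts: Sequence[float]
    sampled_area: float
    pyramid_area: float

    def __post_init__(self) -> None:
        if self.sampled_area <= 0 or self.pyramid_area < self.sampled_area:
            raise ValueError("need pyramid_area >= sampled_area > 0")
        for d, counts in self.section_counts.items():
            if any(c < 0 for c in counts):
                raise ValueError(f"negative count at distance {d}")


def fiber_index(table: AxonCountTable) -> dict[float, float]:
    """FI(d) = mean section count at distance d / extrapolated medulla total."""
    total = medulla_total(table.line_counts, table.sampled_area, table.pyramid_area)
    if total <= 0:
        raise ValueError("medulla total is 0; fiber index undefined")
    return {
        float(d): float(sum(counts) / len(counts) / total)
        for d, counts in table.section_counts.items()
    }


@dataclass
class BranchTraceSet:
    """Traced axon segments with branch counts.

    Segments shorter than ``min_segment_um`` (100 um) are rejected; a total
    below ``min_total_um`` (5 mm) triggers a warning but is still computed.
    """

    segments: Sequence[tuple[float, int]]  # (traced_length_um, branch_count)
    min_segment_um: float = 100.0
    min_total_um: float = 5000.0


def branch_frequency(traces: BranchTraceSet) -> float:
    """Branches per millimetre of accepted traced length."""
    accepted = [
        (length, branches)
        for length, branches in traces.segments
        if length >= traces.min_segment_um
    ]
    total_um = sum(length for length, _ in accepted)
    if total_um <= 0:
        raise ValueError("no accepted traced length")
    if total_um < traces.min_total_um:
        warnings.warn(
            f"total traced length {total_um:.0f} um below the "
            f"{traces.min_total_um:.0f} um sampling minimum"
        )
    total_branches = sum(branches for _, branches in accepted)
    return total_branches / (total_um / 1000.0)


def read_axon_tables(
    counts_tsv: str | Path,
    medulla_tsv: str | Path,
    include_only: bool = True,
) -> dict[str, AxonCountTable]:
    """Load per-animal tables from the two TSV shapes.

    ``counts_tsv`` columns: animal, section, distance, count[, include]
    (``include`` encodes the lesion-completeness exclusion criterion);
    ``medulla_tsv`` columns: animal, line, count, sampled_area, pyramid_area.
    """
    counts = pd.read_csv(counts_tsv, sep="\t")
    med = pd.read_csv(medulla_tsv, sep="\t")
    if include_only and "include" in counts.columns:
        counts = counts[counts["include"].astype(bool)]
    out: dict[str, AxonCountTable] = {}
    for animal, sub in counts.groupby("animal"):
        m = med[med["animal"] == animal]
        if m.empty:
            warnings.warn(f"animal {animal}: no medulla rows; skipped")
            continue
        out[str(animal)] = AxonCountTable(
            section_counts={
                float(d): list(g["count"]) for d, g in sub.groupby("distance")
            },
            line_counts=list(m["count"]),
            sampled_area=float(m["sampled_area"].iloc[0]),
            pyramid_area=float(m["pyramid_area"].iloc[0]),
        )
    return out


def fiber_index_table(tables: Mapping[str, AxonCountTable]) -> pd.DataFrame:
    rows = []
    for animal, table in tables.items():
        for d, fi in fiber_index(table).items():
            rows.append({"animal": animal, "distance": d, "fiber_index": fi})
    return pd.DataFrame(rows, columns=["animal", "distance", "fiber_index"])
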