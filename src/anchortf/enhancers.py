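"""Candidate-element calling and activity-by-contact (ABC) enhancer-gene pairing.

The ABC model scores each candidate element for each gene as

    score_ij = A_i * C_ij / sum_k A_k * C_kj

where A is element activity (geometric mean of accessibility and H3K27ac
signal) and C the Hi-C contact between the element and the gene's TSS,
power-law scaled with distance. Scores for a gene sum to 1 over all
candidate elements within the window; pairs at or above the threshold
(default 0.01) are retained.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

Region = tuple[str, int, int]


@dataclass
class CoverageTrack:
    """Sorted, non-overlapping (chrom, start, end, value) coverage intervals."""

    intervals: list[tuple[str, int, int, float]]
    assay: str = "accessibility"

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv[0], iv[1]))
        prev: dict[str, int] = {}
        for chrom, start, end, value in self.intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            if value < 0:
                raise ValueError("coverage values must be >= 0")
            if chrom in prev and start < prev[chrom]:
                raise ValueError(f"overlapping intervals on {chrom} at {start}")
            prev[chrom] = end
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {iv[0] for iv in self.intervals}:
            ivs = [iv for iv in self.intervals if iv[0] == chrom]
            self._by_chrom[chrom] = (
                np.array([iv[1] for iv in ivs]),
                np.array([iv[2] for iv in ivs]),
                np.array([iv[3] for iv in ivs]),
            )


def count_signal(region: Region, track: CoverageTrack) -> float:
    """Sum of value x overlap length between the region and the track."""
    chrom, start, end = region
    if end <= start:
        raise ValueError("region end must exceed start")
    if chrom not in track._by_chrom:
        return 0.0
    starts, ends, values = track._by_chrom[chrom]
    lo = bisect_right(ends.tolist(), start)
    hi = bisect_left(starts.tolist(), end)
    if lo >= hi:
        return 0.0
    ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
    return float((values[lo:hi] * np.clip(ov, 0, None)).sum())


def select_strongest_regions(
    track: CoverageTrack, n: int, width: int = 500
) -> list[Region]:
    """Greedy strongest-window selector (simplified stand-in for peak calling).

    Windows of ``width`` bp at step width/2 are scored by summed signal;
    the top-scoring non-overlapping windows are kept greedily, book-ended
    survivors merged, and the top ``n`` merged regions returned. Ties break
    by (chrom, start) ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if width < 50:
        raise ValueError("width must be >= 50 bp")
    step = max(1, width // 2)
    windows: list[tuple[float, str, int]] = []
    for chrom, (starts, ends, values) in sorted(track._by_chrom.items()):
        span_lo = int(starts.min())
        span_hi = int(ends.max())
        w_starts = np.arange(span_lo, max(span_lo + 1, span_hi - width + 1), step)
        scores = np.zeros(len(w_starts))
        # each track interval contributes value * overlap to the windows it touches
        for s, e, v in zip(starts, ends, values):
            first = max(0, int(np.searchsorted(w_starts, s - width, side="right")) - 1)
            last = int(np.searchsorted(w_starts, e, side="left"))
            for wi in range(first, min(last, len(w_starts))):
                ov = min(e, w_starts[wi] + width) - max(s, w_starts[wi])
                if ov > 0:
                    scores[wi] += v * ov
        for ws, sc in zip(w_starts, scores):
            if sc > 0:
                windows.append((float(sc), chrom, int(ws)))
    if not windows:
        warnings.warn("flat-zero track: no windows selected")
        return []
    windows.sort(key=lambda t: (-t[0], t[1], t[2]))
    chosen: dict[str, list[tuple[int, int, float]]] = {}
    for sc, chrom, ws in windows:
        lst = chosen.setdefault(chrom, [])
        if all(ws + width <= s or ws >= e for s, e, _ in lst):
            lst.append((ws, ws + width, sc))
    merged: list[tuple[float, str, int, int]] = []
    for chrom, lst in chosen.items():
        lst.sort()
        cur_s, cur_e, cur_sc = lst[0]
        for s, e, sc in lst[1:]:
            if s == cur_e:  # book-ended
                cur_e, cur_sc = e, cur_sc + sc
            else:
                merged.append((cur_sc, chrom, cur_s, cur_e))
                cur_s, cur_e, cur_sc = s, e, sc
        merged.append((cur_sc, chrom, cur_s, cur_e))
    merged.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [(chrom, s, e) for _, chrom, s, e in merged[:n]]


def element_activity(atac: float, h3k27ac: float) -> float:
    """Geometric mean of the two assay read counts."""
    if atac < 0 or h3k27ac < 0:
        raise ValueError("activity inputs must be >= 0")
    return math.sqrt(atac * h3k27ac)


@dataclass
class CandidateElement:
    region: Region
    atac_count: float
    h3k27ac_count: float
    is_promoter: bool = False
    gene_id: str | None = None  # for promoter elements: the owning gene

    @property
    def activity(self) -> float:
        return element_activity(self.atac_count, self.h3k27ac_count)

    @property
    def midpoint(self) -> int:
        return (self.region[1] + self.region[2]) // 2


@dataclass
class HiCContacts:
    """Sparse symmetric Hi-C contacts at a fixed resolution.

    With no entries the object operates in power-law-only mode, returning
    the distance curve (resolution / max(d, resolution))^gamma directly.
    With entries, counts are rescaled so the distance-binned mean matches
    the power-law curve (the "scale by power law" convention).
    """

    resolution: int = 5000
    entries: list[tuple[str, int, int, float]] = field(default_factory=list)
    gamma: float = 0.87
    pseudocount: float = 0.3

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self._lookup: dict[tuple[str, int, int], float] = {}
        dist_sum: dict[int, float] = {}
        dist_n: dict[int, int] = {}
        for chrom, bi, bj, count in self.entries:
            if count < 0:
                raise ValueError("Hi-C counts must be >= 0")
            key = (chrom, min(bi, bj), max(bi, bj))
            self._lookup[key] = self._lookup.get(key, 0.0) + count
        for (chrom, bi, bj), count in self._lookup.items():
            d = bj - bi
            dist_sum[d] = dist_sum.get(d, 0.0) + count
            dist_n[d] = dist_n.get(d, 0) + 1
        self._scale = {
            d: self._powerlaw(d * self.resolution) / (dist_sum[d] / dist_n[d])
            for d in dist_sum
            if dist_sum[d] > 0
        }

    def _powerlaw(self, distance_bp: float) -> float:
        return (self.resolution / max(abs(distance_bp), self.resolution)) ** self.gamma


def contact_value(
    hic: HiCContacts,
    pos_a: int,
    pos_b: int,
    chrom: str = "chr1",
    chrom_b: str | None = None,
) -> float:
    """Power-law-scaled contact between two positions on one chromosome."""
    if chrom_b is not None and chrom_b != chrom:
        warnings.warn("cross-chromosome contact queried; returning 0")
        return 0.0
    bi, bj = pos_a // hic.resolution, pos_b // hic.resolution
    d_bins = abs(bi - bj)
    powerlaw = hic._powerlaw(d_bins * hic.resolution)
    if not hic.entries:
        return powerlaw
    count = hic._lookup.get((chrom, min(bi, bj), max(bi, bj)), 0.0)
    scale = hic._scale.get(d_bins)
    if scale is None:
        # no data at this distance: fall back to the calibrated curve
        return powerlaw
    return (count + hic.pseudocount) * scale


@dataclass(frozen=True)
class ABCPair:
    gene_id: str
    element: CandidateElement
    contact: float
    score: float
    distance_to_tss: int


def abc_scores(
    gene: Mapping,
    elements: Sequence[CandidateElement],
    hic: HiCContacts,
    window: int = 5_000_000,
    threshold: float = 0.01,
    keep_all: bool = False,
) -> list[ABCPair]:
    """Score elements against one gene and keep pairs with score >= threshold.

    ``gene`` needs keys ``id``, ``tss``, ``chrom``. Promoter elements count
    in the normalizing denominator but are excluded from the retained
    enhancer report (the report is the enhancer compartment). ``keep_all``
    returns every in-window pair regardless of threshold or promoter status
    (scores then sum to 1).
    """
    tss, chrom, gid = int(gene["tss"]), gene["chrom"], gene["id"]
    in_win = [
        el
        for el in elements
        if el.region[0] == chrom and abs(el.midpoint - tss) <= window
    ]
    if not in_win:
        warnings.warn(f"gene {gid}: no candidate elements in window")
        return []
    acts = np.array([el.activity for el in in_win])
    contacts = np.array([contact_value(hic, tss, el.midpoint, chrom) for el in in_win])
    ac = acts * contacts
    total = ac.sum()
    if total <= 0:
        warnings.warn(f"gene {gid}: zero total activity x contact; no pairs")
        return []
    scores = ac / total
    pairs = [
        ABCPair(
            gene_id=gid,
            element=el,
            contact=float(c),
            score=float(s),
            distance_to_tss=abs(el.midpoint - tss),
        )
        for el, c, s in zip(in_win, contacts, scores)
    ]
    pairs.sort(key=lambda p: -p.score)
    if keep_all:
        return pairs
    return [p for p in pairs if p.score >= threshold and not p.element.is_promoter]


class PairSummary(NamedTuple):
    per_gene_counts: dict[str, int]
    mean_count: float
    min_count: int
    max_count: int
    band_fraction: float


def pair_summary(
    pairs: Sequence[ABCPair],
    band: tuple[int, int] = (10_000, 1_500_000),
) -> PairSummary:
    """Per-gene enhancer-count distribution and the distance-band fraction.

    The band defaults to 10 kb - 1500 kb from the TSS, the interval used to
    describe where the bulk of enhancer-gene pairs fall.
    """
    if not pairs:
        return PairSummary({}, float("nan"), 0, 0, float("nan"))
    counts: dict[str, int] = {}
    in_band = 0
    for p in pairs:
        counts[p.gene_id] = counts.get(p.gene_id, 0) + 1
        if band[0] <= p.distance_to_tss <= band[1]:
            in_band += 1
    vals = list(counts.values())
    return PairSummary(
        per_gene_counts=counts,
        mean_count=float(np.mean(vals)),
        min_count=min(vals),
        max_count=max(vals),
        band_fraction=in_band / len(pairs),
    )


def pairs_to_frame(pairs: Sequence[ABCPair]) -> pd.DataFrame:
    """Enhancer-gene pair table with genomic coordinates, one row per pair."""
    return pd.DataFrame(
        [
            {
                "gene": p.gene_id,
                "chrom": p.element.region[0],
                "start": p.element.region[1],
                "end": p.element.region[2],
                "activity": p.element.activity,
                "contact": p.contact,
                "abc_score": p.score,
                "distance_to_tss": p.distance_to_tss,
                "is_promoter": p.element.is_promoter,
            }
            for p in pairs
        ]
    )
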