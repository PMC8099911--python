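"""Anchored motif co-occupancy analysis over promoters and enhancers.

The analysis scans each regulatory sequence for the anchor TF's motif
(Klf6-style GC box in the original application), takes the DNA within D bp
of each anchor site (minus the anchor footprints) as the searchable
foreground, and asks whether a partner TF's motif occurs there more often
than in a background. Over-representation is summarized by a binomial
Z-score,

    u = bg_hits / bg_nt,  mu = u * fg_nt,  sigma = sqrt(fg_nt u (1 - u)),
    z = (fg_hits - mu) / sigma,

with partners called at z >= 10 and sorted into promoter-only,
enhancer-only, or both categories across the two compartments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .motifs import (
    MotifHit,
    PFMModel,
    information_content,
    reverse_complement,
    scan_sequence,
    scan_sequences,
)

Interval = tuple[int, int]

CATEGORIES = ("promoter_only", "enhancer_only", "both", "none")


def _merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    ivs = sorted((s, e) for s, e in ivs if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract_intervals(ivs: list[Interval], minus: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in ivs:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


@dataclass
class AnchoredWindowSet:
    """Searchable DNA near anchor hits, per sequence.

    ``windows`` maps seq_id to disjoint sorted intervals: the union of
    [anchor_start - D, anchor_end + D) flanks minus the anchor footprints,
    clipped to the sequence.
    """

    windows: dict[str, list[Interval]] = field(default_factory=dict)
    footprints: dict[str, list[Interval]] = field(default_factory=dict)
    anchor_absent: bool = False

    @property
    def searchable_nt(self) -> int:
        return sum(e - s for ivs in self.windows.values() for s, e in ivs)

    def contains(self, seq_id: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.windows.get(seq_id, []))


def anchored_windows(
    anchor_hits: Sequence[MotifHit],
    D: int,
    seq_lengths: Mapping[str, int],
) -> AnchoredWindowSet:
    """Union of +/- D flanks around anchor hits, minus the anchors themselves."""
    if D < 1:
        raise ValueError("inter-binding distance D must be >= 1")
    by_seq: dict[str, list[MotifHit]] = {}
    for h in anchor_hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    if not by_seq:
        warnings.warn("no anchor hits in any sequence")
        return AnchoredWindowSet(anchor_absent=True)
    ws = AnchoredWindowSet()
    for seq_id, hits in by_seq.items():
        L = seq_lengths[seq_id]
        flanks = _merge_intervals(
            (max(0, h.start - D), min(L, h.end + D)) for h in hits
        )
        feet = _merge_intervals((h.start, h.end) for h in hits)
        ws.windows[seq_id] = _subtract_intervals(flanks, feet)
        ws.footprints[seq_id] = feet
    return ws


def anchored_hit_count(
    partner_hits: Sequence[MotifHit], windows: AnchoredWindowSet
) -> int:
    """Partner hits whose start lies inside a window; hits overlapping an
    anchor footprint are excluded."""
    n = 0
    for h in partner_hits:
        if not windows.contains(h.seq_id, h.start):
            continue
        feet = windows.footprints.get(h.seq_id, [])
        if any(h.start < fe and h.end > fs for fs, fe in feet):
            continue
        n += 1
    return n


def enrichment_z(fg_hits: float, fg_nt: float, bg_hits: float, bg_nt: float) -> float:
    """Binomial Z for the foreground hit count against the background rate."""
    if fg_nt <= 0 or bg_nt <= 0:
        raise ValueError("fg_nt and bg_nt must be positive")
    u = bg_hits / bg_nt
    mu = u * fg_nt
    if u <= 0:
        if fg_hits > 0:
            warnings.warn("background rate is 0 with foreground hits; z is +inf")
            return math.inf
        return 0.0
    if u >= 1:
        return 0.0 if fg_hits == mu else -math.inf
    sigma = math.sqrt(fg_nt * u * (1.0 - u))
    return (fg_hits - mu) / sigma


def fisher_enrichment(fg_pos: int, fg_neg: int, bg_pos: int, bg_neg: int) -> float:
    """One-tailed (upper) Fisher exact p on the 2x2 sequence-count table."""
    for v in (fg_pos, fg_neg, bg_pos, bg_neg):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    total = fg_pos + fg_neg + bg_pos + bg_neg
    if total == 0:
        return 1.0
    return float(hypergeom.sf(fg_pos - 1, total, fg_pos + bg_pos, fg_pos + fg_neg))


@dataclass(frozen=True)
class EnrichmentResult:
    tf_name: str
    fg_hits: int
    fg_nt: int
    bg_hits: int
    bg_nt: int
    z: float
    fisher_p: float | None = None

    @property
    def bg_rate(self) -> float:
        return self.bg_hits / self.bg_nt if self.bg_nt else float("nan")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    succ: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        succ.setdefault(a, []).append(b)
    last = seq[-1]
    verts = list(succ)
    # choose a random "last edge" per vertex such that they form a tree into `last`
    while True:
        last_edge = {
            v: succ[v][rng.integers(len(succ[v]))] for v in verts if v != last
        }
        ok = True
        for v in last_edge:
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v, lst in succ.items():
        lst = list(lst)
        if v in last_edge:
            lst.remove(last_edge[v])
        order = rng.permutation(len(lst))
        lst = [lst[i] for i in order]
        if v in last_edge:
            lst.append(last_edge[v])
        shuffled[v] = lst
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def make_promoters(
    gene_table: pd.DataFrame,
    upstream: int,
    downstream: int,
    genome: Mapping[str, str],
) -> dict[str, dict]:
    """Strand-aware promoter windows around each TSS, with sequences.

    On the + strand the interval is [TSS - upstream, TSS + downstream); on
    the - strand it mirrors to [TSS - downstream, TSS + upstream) and the
    extracted sequence is reverse-complemented. Intervals are clipped to
    the contig; genes on missing contigs are skipped with a warning.
    """
    out: dict[str, dict] = {}
    for row in gene_table.itertuples():
        chrom, tss, strand = row.chrom, int(row.tss), row.strand
        if chrom not in genome:
            warnings.warn(f"gene {row.id}: contig {chrom} absent; skipped")
            continue
        L = len(genome[chrom])
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        else:
            start, end = tss - downstream, tss + upstream
        start, end = max(0, start), min(L, end)
        if end <= start:
            warnings.warn(f"gene {row.id}: promoter off contig; skipped")
            continue
        seq = genome[chrom][start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        out[str(row.id)] = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "seq": seq,
        }
    return out


def anchored_enrichment(
    seqs: Mapping[str, str],
    anchor: PFMModel,
    partners: Sequence[PFMModel],
    D: int = 100,
    rel_threshold: float = 0.9,
    min_ic: float = 8.0,
    background: str = "shuffle",
    bg_seqs: Mapping[str, str] | None = None,
    seed: int | None = 0,
    with_fisher: bool = False,
) -> list[EnrichmentResult]:
    """Anchored over-representation of each partner motif near anchor sites.

    Background modes:
      * ``"shuffle"``  - seeded per-sequence dinucleotide shuffle of the
        foreground sequences; the background rate is the partner hit
        density over the shuffled sequences (default, self-contained).
      * ``"outside"``  - partner hit density in the parts of the same
        sequences outside the anchor windows and footprints (rate-matched
        when occurrences arise from a common per-nucleotide process).
      * ``"regions"``  - user-supplied background sequences in ``bg_seqs``.

    Partners with information content below ``min_ic`` bits are excluded.
    Results are sorted by z descending.
    """
    if background not in ("shuffle", "outside", "regions"):
        raise ValueError(f"unknown background mode {background!r}")
    if background == "regions" and not bg_seqs:
        raise ValueError("background='regions' requires bg_seqs")
    seqs = dict(seqs)
    seq_lengths = {k: len(v) for k, v in seqs.items()}
    anchor_hits = scan_sequences(seqs, anchor, rel_threshold)
    windows = anchored_windows(anchor_hits, D, seq_lengths) if anchor_hits else AnchoredWindowSet(anchor_absent=True)
    fg_nt = windows.searchable_nt

    if background == "shuffle":
        rng = np.random.default_rng(seed)
        bg = {k: dinucleotide_shuffle(v, rng) for k, v in seqs.items()}
        bg_nt = sum(len(v) for v in bg.values())
    elif background == "regions":
        bg = dict(bg_seqs)
        bg_nt = sum(len(v) for v in bg.values())
    else:  # outside
        bg = None
        blocked = {
            k: _merge_intervals(
                windows.windows.get(k, []) + windows.footprints.get(k, [])
            )
            for k in seqs
        }
        bg_nt = sum(
            seq_lengths[k] - sum(e - s for s, e in blocked[k]) for k in seqs
        )

    results: list[EnrichmentResult] = []
    for pfm in partners:
        if information_content(pfm) < min_ic:
            warnings.warn(f"{pfm.tf_name}: below {min_ic}-bit specificity; skipped")
            continue
        partner_hits = scan_sequences(seqs, pfm, rel_threshold)
        fg_hits = anchored_hit_count(partner_hits, windows) if fg_nt else 0
        if background == "outside":
            bg_hits = sum(
                1
                for h in partner_hits
                if not windows.contains(h.seq_id, h.start)
                and not any(
                    h.start < fe and h.end > fs
                    for fs, fe in windows.footprints.get(h.seq_id, [])
                )
            )
        else:
            bg_hits = len(scan_sequences(bg, pfm, rel_threshold))
        z = (
            enrichment_z(fg_hits, fg_nt, bg_hits, bg_nt)
            if fg_nt > 0 and bg_nt > 0
            else float("nan")
        )
        fisher_p = None
        if with_fisher and fg_nt > 0:
            fg_seqids = {h.seq_id for h in partner_hits if windows.contains(h.seq_id, h.start)}
            fg_pos = len(fg_seqids)
            fg_neg = len(seqs) - fg_pos
            if background == "outside":
                bg_ids = {h.seq_id for h in partner_hits if not windows.contains(h.seq_id, h.start)}
                bg_pos, bg_neg = len(bg_ids), len(seqs) - len(bg_ids)
            else:
                bg_ids = {h.seq_id for h in scan_sequences(bg, pfm, rel_threshold)}
                bg_pos, bg_neg = len(bg_ids), len(bg) - len(bg_ids)
            fisher_p = fisher_enrichment(fg_pos, fg_neg, bg_pos, bg_neg)
        results.append(
            EnrichmentResult(
                tf_name=pfm.tf_name,
                fg_hits=fg_hits,
                fg_nt=fg_nt,
                bg_hits=bg_hits,
                bg_nt=bg_nt,
                z=z,
                fisher_p=fisher_p,
            )
        )
    results.sort(key=lambda r: (-(r.z if np.isfinite(r.z) else -np.inf), r.tf_name))
    return results


def motif_enrichment(
    seqs: Mapping[str, str],
    motifs: Sequence[PFMModel],
    rel_threshold: float = 0.9,
    min_ic: float = 8.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Un-anchored motif over-representation of whole sequences against a
    seeded dinucleotide-shuffle background (used for per-subnetwork batches)."""
    rng = np.random.default_rng(seed)
    bg = {k: dinucleotide_shuffle(v, rng) for k, v in seqs.items()}
    fg_nt = sum(len(v) for v in seqs.values())
    bg_nt = sum(len(v) for v in bg.values())
    rows = []
    for pfm in motifs:
        if information_content(pfm) < min_ic:
            continue
        fg_hits = len(scan_sequences(dict(seqs), pfm, rel_threshold))
        bg_hits = len(scan_sequences(bg, pfm, rel_threshold))
        rows.append(
            {
                "tf": pfm.tf_name,
                "fg_hits": fg_hits,
                "bg_hits": bg_hits,
                "z": enrichment_z(fg_hits, fg_nt, bg_hits, bg_nt),
            }
        )
    df = pd.DataFrame(rows, columns=["tf", "fg_hits", "bg_hits", "z"])
    return df.sort_values("z", ascending=False, ignore_index=True)


def categorize_tfs(
    promoter_results: Sequence[EnrichmentResult],
    enhancer_results: Sequence[EnrichmentResult],
    z_threshold: float = 10.0,
) -> dict[str, str]:
    """Sort TFs into promoter_only / enhancer_only / both / none by
    whether z >= threshold in each compartment (ties at the threshold count)."""
    zp = {r.tf_name: r.z for r in promoter_results}
    ze = {r.tf_name: r.z for r in enhancer_results}
    cats: dict[str, str] = {}
    for tf in sorted(set(zp) | set(ze)):
        if tf not in zp or tf not in ze:
            warnings.warn(f"{tf}: missing from one compartment; treated as z=-inf there")
        p_hit = zp.get(tf, -math.inf) >= z_threshold
        e_hit = ze.get(tf, -math.inf) >= z_threshold
        cats[tf] = (
            "both"
            if p_hit and e_hit
            else "promoter_only"
            if p_hit
            else "enhancer_only"
            if e_hit
            else "none"
        )
    return cats


def results_to_frame(
    results: Sequence[EnrichmentResult],
    compartment: str,
    categories: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rows = [
        {
            "tf": r.tf_name,
            "compartment": compartment,
            "fg_hits": r.fg_hits,
            "bg_rate": r.bg_rate,
            "z": r.z,
            "fisher_p": r.fisher_p,
            "category": categories.get(r.tf_name, "") if categories else "",
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["tf", "compartment", "fg_hits", "bg_rate", "z", "fisher_p", "category"],
    )
    return df.sort_values("z", ascending=False, ignore_index=True)
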