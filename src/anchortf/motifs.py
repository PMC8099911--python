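"""Position frequency matrices, JASPAR parsing, and relative-score scanning.

Scanning follows the "matrix score threshold" convention: each window's
log-odds score is rescaled to (score - min)/(max - min), where min and max
are the lowest and highest scores attainable under the matrix, and windows
at or above the relative threshold (default 0.9, i.e. a 90% matrix score)
are reported on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PFMModel:
    """Position frequency matrix with rows in A, C, G, T order."""

    tf_name: str
    counts: np.ndarray  # shape (4, w)
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix (rows A,C,G,T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every column needs at least one positive count")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount) / (col_tot + 4 * self.pseudocount)

    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities() / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PFMModel":
        return PFMModel(
            tf_name=self.tf_name,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )


def information_content(pfm: PFMModel) -> float:
    """Total information content in bits relative to a uniform background.

    IC = sum_j (2 + sum_i p_ij log2 p_ij) with pseudocounted probabilities;
    motifs below the specificity floor (8 bits by convention here) are
    excluded from candidate scans.
    """
    p = pfm.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float((2.0 + plogp.sum(axis=0)).sum())


_JASPAR_ROW = re.compile(r"^([ACGTacgt])\s*\[?\s*([-0-9.\s]*?)\s*\]?\s*$")


def read_jaspar(pfm_text: str | Path) -> list[PFMModel]:
    """Parse JASPAR-format PFM text (path or raw text) into models.

    Accepts the post-2016 format: a ``>`` header line followed by four
    labelled base rows (any row order; counts optionally bracketed).
    Ragged or negative rows raise with the offending line.
    """
    from .io import slurp

    text = slurp(pfm_text)
    models: list[PFMModel] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = set(BASES) - set(rows)
        if missing:
            raise ValueError(f"record {header!r}: missing rows for {sorted(missing)}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"record {header!r}: ragged rows (widths {sorted(widths)})")
        counts = np.array([rows[b] for b in BASES])
        name = header.split()[-1] if len(header.split()) > 1 else header
        models.append(PFMModel(tf_name=name, counts=counts))
        header, rows = None, {}

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        m = _JASPAR_ROW.match(line)
        if not m:
            raise ValueError(f"line {lineno}: unparsable PFM row: {line!r}")
        base = m.group(1).upper()
        try:
            vals = [float(x) for x in m.group(2).split()]
        except ValueError as exc:
            raise ValueError(f"line {lineno}: bad count in {line!r}") from exc
        if any(v < 0 for v in vals):
            raise ValueError(f"line {lineno}: negative count in {line!r}")
        if base in rows:
            raise ValueError(f"line {lineno}: duplicate {base} row")
        rows[base] = vals
    flush()
    if not models:
        raise ValueError("no PFM records found")
    return models


def write_jaspar(path: str | Path, models: Iterable[PFMModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.tf_name} {m.tf_name}\n")
            for b, row in zip(BASES, m.counts):
                fh.write(f"{b}  [ " + "  ".join(f"{v:g}" for v in row) + " ]\n")


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based, forward-strand coordinates
    strand: str  # '+' or '-'
    score: float
    rel_score: float
    width: int
    tf_name: str = ""

    @property
    def end(self) -> int:
        return self.start + self.width


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to 4."""
    idx = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for base, i in _BASE_INDEX.items():
        idx[arr == ord(base)] = i
    return idx


def scan_sequence(
    seq: str,
    pfm: PFMModel,
    rel_threshold: float = 0.9,
    seq_id: str = "seq",
    mask: np.ndarray | None = None,
) -> list[MotifHit]:
    """Scan both strands, emitting hits with relative score >= threshold.

    Windows containing N are skipped. Hits are reported in forward
    coordinates sorted by (start, strand), '+' before '-'. ``mask`` is an
    optional per-base boolean (e.g. a conservation mask >= 0.40): a window
    is scanned only when every base is unmasked.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must lie in (0, 1]")
    w = pfm.width
    n = len(seq)
    if n < w:
        return []
    idx = encode_sequence(seq)
    lo = pfm.log_odds()
    s_min = lo.min(axis=0).sum()
    s_max = lo.max(axis=0).sum()
    span = s_max - s_min
    if span <= 0:
        return []
    # pad the log-odds with a row for N so gather never fails, then invalidate
    lo_pad = np.vstack([lo, np.full((1, w), np.nan)])
    lo_rc = lo[::-1, ::-1]
    lo_rc_pad = np.vstack([lo_rc, np.full((1, w), np.nan)])
    win = np.lib.stride_tricks.sliding_window_view(idx, w)
    cols = np.arange(w)
    fwd = lo_pad[win, cols].sum(axis=1)
    rev = lo_rc_pad[win, cols].sum(axis=1)
    valid = ~np.isnan(fwd)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != n:
            raise ValueError("mask length must equal sequence length")
        mwin = np.lib.stride_tricks.sliding_window_view(mask, w).all(axis=1)
        valid &= mwin
    hits: list[MotifHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        rel = (scores - s_min) / span
        for start in np.nonzero(valid & (rel >= rel_threshold))[0]:
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=int(start),
                    strand=strand,
                    score=float(scores[start]),
                    rel_score=float(rel[start]),
                    width=w,
                    tf_name=pfm.tf_name,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_sequences(
    seqs: dict[str, str],
    pfm: PFMModel,
    rel_threshold: float = 0.9,
    masks: dict[str, np.ndarray] | None = None,
) -> list[MotifHit]:
    hits: list[MotifHit] = []
    for seq_id, seq in seqs.items():
        m = masks.get(seq_id) if masks else None
        hits.extend(scan_sequence(seq, pfm, rel_threshold, seq_id=seq_id, mask=m))
    return hits


def pfm_from_consensus(
    tf_name: str, consensus: str, strength: float = 85.0, total: float = 100.0
) -> PFMModel:
    """Build a near-one-hot PFM from a consensus string (fixture helper)."""
    consensus = consensus.upper()
    w = len(consensus)
    off = (total - strength) / 3.0
    counts = np.full((4, w), off)
    for j, b in enumerate(consensus):
        counts[_BASE_INDEX[b], j] = strength
    return PFMModel(tf_name=tf_name, counts=counts)
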