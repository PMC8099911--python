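"""Plain-text format readers and writers shared across the pipeline.

All genomic coordinates are 0-based half-open. FASTA goes through Biopython;
the tabular formats (BED, bedGraph, GMT, sparse Hi-C TSV, gene tables) are
simple enough to stream directly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{seq_id: sequence}`` (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[tuple]:
    """Read BED3/BED4+ as ``(chrom, start, end[, name])`` tuples."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if end <= start:
            raise ValueError(f"empty/negative BED interval: {line!r}")
        out.append((chrom, start, end, *parts[3:4]))
    return out


def write_bed(path: str | Path, regions: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for reg in regions:
            fh.write("\t".join(str(x) for x in reg) + "\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read bedGraph lines as ``(chrom, start, end, value)``."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, value = line.split("\t")[:4]
        out.append((chrom, int(start), int(end), float(value)))
    return out


def write_bedgraph(path: str | Path, intervals: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: ``name <TAB> description <TAB> gene1 ...``."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs name, description, >=1 gene: {line!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(path: str | Path, sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a gene table TSV with columns ``id, chrom, tss, strand``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "strand": str})
    missing = {"id", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df["tss"] = df["tss"].astype(int)
    return df


def read_hic_tsv(path: str | Path) -> list[tuple[str, int, int, float]]:
    """Read sparse Hi-C contacts: ``chrom <TAB> bin_i <TAB> bin_j <TAB> count``."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chrom, bi, bj, count = line.split("\t")[:4]
        out.append((chrom, int(bi), int(bj), float(count)))
    return out


def write_hic_tsv(path: str | Path, entries: Iterable[tuple]) -> None:
    with open(path, "w") as fh:
        for chrom, bi, bj, count in entries:
            fh.write(f"{chrom}\t{bi}\t{bj}\t{count:g}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an interaction edge list TSV (``node_a <TAB> node_b [<TAB> evidence]``)."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"edge line needs two columns: {line!r}")
        edges.append((parts[0], parts[1]))
    return edges


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def slurp(path_or_text: str | Path) -> str:
    """Accept either a path to a file or raw text content."""
    p = Path(str(path_or_text))
    try:
        if p.exists():
            return p.read_text()
    except OSError:
        pass
    return str(path_or_text)
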