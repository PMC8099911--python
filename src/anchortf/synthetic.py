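"""Seeded synthetic-fixture generators for every pipeline stage.

Each generator is a pure function of a :class:`FixtureSpec` and emulates
the statistical structure its consumer assumes: block-correlated,
developmentally decaying expression modules; a toy genome whose growth-gene
promoters and enhancers carry planted anchor and partner motif
co-occurrences; coverage peaks over regulatory elements; distance-decaying
Hi-C with boosted loops at true enhancer-gene pairs; and TF target sets
with a planted, interconnected core plus a held-out anchor-like TF that
only joins the network through interaction-based expansion.

Scales are kept desk-sized (a few megabases, tens to hundreds of genes) so
end-to-end runs finish in minutes while preserving the planted effects the
analysis stages are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .enhancers import CandidateElement, CoverageTrack, HiCContacts, count_signal
from .geneselect import ExpressionMatrix
from .motifs import PFMModel, pfm_from_consensus

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ANCHOR_NAME = "ANCHOR"
PARTNER_PLAN = {
    "PARTNER_BOTH": ("promoter", "enhancer"),
    "PARTNER_PROM": ("promoter",),
    "PARTNER_ENH": ("enhancer",),
    "PARTNER_NULL": (),
}
_CONSENSI = {
    ANCHOR_NAME: "GGGGCGGGG",
    "PARTNER_BOTH": "TGACCTTGA",
    "PARTNER_PROM": "CATTGCATG",
    "PARTNER_ENH": "GACGCAATC",
    "PARTNER_NULL": "ACCTGAGTC",
}


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic study conditions (seeded, reproducible)."""

    seed: int = 0
    # expression time course
    n_genes: int = 120
    n_modules: int = 2
    module_size: int = 40
    n_down_modules: int = 1
    time_labels: tuple[str, ...] = ("P1", "P7", "P14", "P21")
    replicates: int = 3
    latent_sd: float = 0.3
    noise_sd: float = 0.05
    down_log2_drop: float = 3.0  # 8-fold early->late, well past the 2-fold gate
    # regulatory genome
    genome_length: int = 4_000_000
    n_growth_genes: int = 40
    promoter_upstream: int = 1500
    promoter_downstream: int = 300
    enhancer_width: int = 1500
    enhancers_per_gene: int = 2
    decoys_per_gene: int = 2
    anchors_per_promoter: int = 1
    enhancer_offset_range: tuple[int, int] = (10_000, 45_000)
    planting_rate: float = 1.0 / 1500.0  # partner instances per searchable nt
    planting_multiplier: float = 10.0
    inter_binding_distance: int = 100
    # coverage tracks and Hi-C
    track_bin: int = 100
    peak_height: float = 50.0
    track_noise: float = 1.0
    hic_resolution: int = 5000
    hic_gamma: float = 0.87
    hic_base_count: float = 200.0
    loop_boost: float = 10.0
    # TF target sets
    tf_set_count: int = 12
    core_tf_count: int = 4
    shared_pool_size: int = 40
    peripheral_targets: int = 3
    anchor_links: int = 12

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_modules, self.module_size, self.genome_length,
            self.n_growth_genes, self.enhancer_width, self.tf_set_count,
            self.core_tf_count, self.replicates, self.track_bin,
            self.hic_resolution,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.planting_multiplier < 1:
            raise ValueError("planting_multiplier must be >= 1")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        if self.core_tf_count > self.tf_set_count:
            raise ValueError("core_tf_count must be <= tf_set_count")


def default_motifs() -> dict[str, PFMModel]:
    """The planted anchor (GC-box, Klf6-style) and partner PFMs (>=8 bits)."""
    return {name: pfm_from_consensus(name, cons) for name, cons in _CONSENSI.items()}


class ExpressionFixture(NamedTuple):
    matrix: ExpressionMatrix
    true_labels: dict[str, str]  # gene -> planted module ("B1", ...) or "bg"


def sim_expression(spec: FixtureSpec) -> ExpressionFixture:
    """Block-correlated modules over a developmental time course.

    Genes in a module share a per-sample latent factor (correlation ~0.9);
    designated "down" modules ride a latent trend that falls
    ``down_log2_drop`` log2 units from the first to the last time label,
    clearing the 2-fold gate by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n_t = len(spec.time_labels)
    sample_ids = [
        f"{t}_r{r + 1}" for t in spec.time_labels for r in range(spec.replicates)
    ]
    sample_time = [t for t in spec.time_labels for _ in range(spec.replicates)]
    n_samples = len(sample_ids)
    t_of_sample = np.repeat(np.arange(n_t), spec.replicates)

    values = np.empty((spec.n_genes, n_samples))
    labels: dict[str, str] = {}
    gene_ids = [f"gene{i:04d}" for i in range(spec.n_genes)]
    g = 0
    prev_axes: list[np.ndarray] = []  # orthonormal, centered module profiles
    for m in range(spec.n_modules):
        if m < spec.n_down_modules:
            trend = np.linspace(8.0, 8.0 - spec.down_log2_drop, n_t)
        else:
            trend = np.full(n_t, 8.0)
        latent = trend[t_of_sample] + rng.normal(0, spec.latent_sd, n_samples)
        # modules are statistically independent processes; with few samples
        # chance cross-module correlation is non-negligible, so project each
        # centered profile off the earlier ones to make independence exact
        centered = latent - latent.mean()
        for ax in prev_axes:
            centered -= (centered @ ax) * ax
        latent = latent.mean() + centered
        prev_axes.append(centered / np.linalg.norm(centered))
        for _ in range(spec.module_size):
            values[g] = latent + rng.normal(0, spec.noise_sd, n_samples)
            labels[gene_ids[g]] = f"B{m + 1}"
            g += 1
    while g < spec.n_genes:
        values[g] = rng.normal(8.0, 0.5, n_samples)
        labels[gene_ids[g]] = "bg"
        g += 1
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=values,
        sample_time=sample_time,
        log_scale=True,
    )
    return ExpressionFixture(matrix, labels)


def coherent_expression(spec: FixtureSpec, growth_ids: list[str]) -> ExpressionFixture:
    """Expression fixture whose down-module genes carry the growth-gene ids.

    Makes the expression time course and the regulatory genome describe one
    coherent study: the genes the selection stage recovers are exactly the
    genes whose promoters and enhancers the downstream stages analyse.
    """
    fx = sim_expression(spec)
    down = sorted(g for g, lab in fx.true_labels.items() if lab == "B1")
    rename = dict(zip(down, growth_ids))
    matrix = ExpressionMatrix(
        gene_ids=[rename.get(g, g) for g in fx.matrix.gene_ids],
        sample_ids=fx.matrix.sample_ids,
        values=fx.matrix.values,
        sample_time=fx.matrix.sample_time,
        log_scale=fx.matrix.log_scale,
    )
    labels = {rename.get(g, g): lab for g, lab in fx.true_labels.items()}
    return ExpressionFixture(matrix, labels)


class RegulatoryGenome(NamedTuple):
    genome: dict[str, str]
    gene_table: pd.DataFrame  # id, chrom, tss, strand
    promoters: dict[str, dict]  # gene -> {chrom,start,end,strand,seq}
    enhancers: dict[str, dict]  # enh_id -> {chrom,start,end,gene,seq}
    decoys: list[tuple[str, int, int]]
    motifs: dict[str, PFMModel]
    plan: dict[str, tuple[str, ...]]
    true_pairs: list[tuple[str, str]]  # (gene, enh_id)


def _plant(arr: np.ndarray, pos: int, motif: str, occupied: list) -> bool:
    end = pos + len(motif)
    if any(pos < oe and end > os_ for os_, oe in occupied):
        return False
    arr[pos:end] = np.frombuffer(motif.encode(), dtype=np.uint8)
    occupied.append((pos, end))
    return True


def sim_regulatory_genome(spec: FixtureSpec) -> RegulatoryGenome:
    """Toy genome with planted anchor+partner motif co-occurrences.

    Anchor consensus sites are planted in every growth-gene promoter and
    enhancer. Each partner is planted as a per-nucleotide Poisson process
    at ``planting_rate`` outside anchor windows and at
    ``planting_multiplier`` times that rate inside windows of its planned
    compartments (rate unchanged in unplanned compartments), so a
    multiplier of 1 is an exact null against the outside-window rate.
    """
    rng = np.random.default_rng(spec.seed + 1)
    motifs = default_motifs()
    anchor_motif = motifs[ANCHOR_NAME].consensus
    wa = len(anchor_motif)
    D = spec.inter_binding_distance
    L = spec.genome_length
    arr = BASES[rng.integers(0, 4, L)].copy()

    spacing = L // (spec.n_growth_genes + 1)
    if spacing < 3 * (spec.promoter_upstream + spec.promoter_downstream):
        raise ValueError("genome too short for the requested gene count")
    genes = []
    placed: list[tuple[int, int]] = []  # global registry of region intervals
    for i in range(spec.n_growth_genes):
        tss = (i + 1) * spacing + int(rng.integers(-2000, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"growth{i:03d}"
        if strand == "+":
            ps, pe = tss - spec.promoter_upstream, tss + spec.promoter_downstream
        else:
            ps, pe = tss - spec.promoter_downstream, tss + spec.promoter_upstream
        genes.append({"id": gid, "chrom": "chr1", "tss": tss, "strand": strand,
                      "pstart": ps, "pend": pe})
        placed.append((ps, pe))

    enhancers: dict[str, dict] = {}
    true_pairs: list[tuple[str, str]] = []
    lo_off, hi_off = spec.enhancer_offset_range
    for gene in genes:
        for k in range(spec.enhancers_per_gene):
            for _ in range(50):  # rejection-sample a free slot
                off = int(rng.integers(lo_off, hi_off)) * (1 if rng.random() < 0.5 else -1)
                es = gene["tss"] + off
                ee = es + spec.enhancer_width
                if es < 0 or ee > L:
                    continue
                if all(es >= pe or ee <= ps for ps, pe in placed):
                    break
            else:
                raise RuntimeError("could not place enhancer; genome too crowded")
            eid = f"{gene['id']}_e{k + 1}"
            enhancers[eid] = {"chrom": "chr1", "start": es, "end": ee,
                              "gene": gene["id"]}
            true_pairs.append((gene["id"], eid))
            placed.append((es, ee))

    decoys: list[tuple[str, int, int]] = []
    for _ in range(spec.decoys_per_gene * spec.n_growth_genes):
        for _ in range(50):
            ds = int(rng.integers(0, L - spec.enhancer_width))
            de = ds + spec.enhancer_width
            if all(ds >= pe or de <= ps for ps, pe in placed):
                break
        else:
            raise RuntimeError("could not place decoy element")
        decoys.append(("chr1", ds, de))
        placed.append((ds, de))

    # plant anchors, record footprints, then plant partners relative to windows
    def plant_region(start: int, end: int, compartment: str) -> None:
        occupied: list[tuple[int, int]] = []
        n_anchors = spec.anchors_per_promoter if compartment == "promoter" else 1
        anchor_feet = []
        for _ in range(n_anchors):
            for _ in range(20):
                pos = int(rng.integers(start, end - wa))
                if _plant(arr, pos, anchor_motif, occupied):
                    anchor_feet.append((pos, pos + wa))
                    break
        # mirror the analysis windows exactly: merged flank union minus feet
        from .cooccupancy import _merge_intervals, _subtract_intervals

        feet = _merge_intervals(anchor_feet)
        flanks = _merge_intervals(
            (max(start, fs - D), min(end, fe + D)) for fs, fe in anchor_feet
        )
        window_iv = _subtract_intervals(flanks, feet)
        win_nt = sum(e - s for s, e in window_iv)
        seg_len = np.array([e - s for s, e in window_iv])
        seg_cum = np.concatenate([[0], np.cumsum(seg_len)])
        out_nt = (end - start) - win_nt - sum(fe - fs for fs, fe in anchor_feet)
        for name, compartments in PARTNER_PLAN.items():
            motif = motifs[name].consensus
            w = len(motif)
            rate_in = spec.planting_rate * (
                spec.planting_multiplier if compartment in compartments else 1.0
            )
            n_in = rng.poisson(rate_in * win_nt)
            for _ in range(n_in):
                for _ in range(10):  # retry collisions so realized counts match
                    off = int(rng.integers(win_nt))  # length-weighted position
                    k = int(np.searchsorted(seg_cum, off, side="right")) - 1
                    pos = window_iv[k][0] + (off - int(seg_cum[k]))
                    if pos + w <= end and _plant(arr, pos, motif, occupied):
                        break
            n_out = rng.poisson(spec.planting_rate * max(out_nt, 0))
            for _ in range(n_out):
                for _ in range(10):
                    pos = int(rng.integers(start, end - w))
                    in_win = any(s <= pos < e for s, e in window_iv)
                    in_foot = any(pos < fe and pos + w > fs for fs, fe in anchor_feet)
                    if not in_win and not in_foot:
                        _plant(arr, pos, motif, occupied)
                        break

    for gene in genes:
        plant_region(gene["pstart"], gene["pend"], "promoter")
    for enh in enhancers.values():
        plant_region(enh["start"], enh["end"], "enhancer")

    genome = {"chr1": arr.tobytes().decode()}
    gene_table = pd.DataFrame(
        [{k: g[k] for k in ("id", "chrom", "tss", "strand")} for g in genes]
    )
    from .cooccupancy import make_promoters

    promoters = make_promoters(
        gene_table, spec.promoter_upstream, spec.promoter_downstream, genome
    )
    for enh in enhancers.values():
        enh["seq"] = genome["chr1"][enh["start"]:enh["end"]]
    return RegulatoryGenome(
        genome=genome,
        gene_table=gene_table,
        promoters=promoters,
        enhancers=enhancers,
        decoys=decoys,
        motifs=motifs,
        plan=dict(PARTNER_PLAN),
        true_pairs=true_pairs,
    )


class TracksAndHiC(NamedTuple):
    atac: CoverageTrack
    h3k27ac: CoverageTrack
    hic: HiCContacts
    elements: list[CandidateElement]


def sim_tracks_and_hic(spec: FixtureSpec, reg: RegulatoryGenome) -> TracksAndHiC:
    """Coverage peaks over regulatory elements and distance-decaying Hi-C.

    Both assays get Poisson peaks over promoters, true enhancers and decoy
    elements on a low Poisson background; Hi-C counts follow
    ``base * (res / max(d, res))^gamma`` with ``loop_boost`` applied at
    true enhancer-gene bin pairs only.
    """
    rng = np.random.default_rng(spec.seed + 2)
    L = len(reg.genome["chr1"])
    nb = L // spec.track_bin
    starts = np.arange(nb) * spec.track_bin

    regions: list[tuple[int, int]] = []
    regions += [(p["start"], p["end"]) for p in reg.promoters.values()]
    regions += [(e["start"], e["end"]) for e in reg.enhancers.values()]
    regions += [(s, e) for _, s, e in reg.decoys]

    def make_track(assay: str) -> CoverageTrack:
        vals = rng.poisson(spec.track_noise, nb).astype(float)
        for s, e in regions:
            b0, b1 = s // spec.track_bin, -(-e // spec.track_bin)
            vals[b0:b1] += rng.poisson(spec.peak_height, b1 - b0)
        ivs = [
            ("chr1", int(st), int(st) + spec.track_bin, float(v))
            for st, v in zip(starts, vals)
        ]
        return CoverageTrack(intervals=ivs, assay=assay)

    atac = make_track("accessibility")
    h3k = make_track("acetylation")

    res = spec.hic_resolution
    boosted = {
        (reg.gene_table.set_index("id").loc[g, "tss"] // res,
         (reg.enhancers[e]["start"] + reg.enhancers[e]["end"]) // 2 // res)
        for g, e in reg.true_pairs
    }
    boosted |= {(b, a) for a, b in boosted}
    tss_bins = sorted({int(t) // res for t in reg.gene_table["tss"]})
    elem_bins = sorted(
        {(s + e) // 2 // res for _, s, e in reg.decoys}
        | {(d["start"] + d["end"]) // 2 // res for d in reg.enhancers.values()}
        | {(p["start"] + p["end"]) // 2 // res for p in reg.promoters.values()}
    )
    entries: dict[tuple[int, int], float] = {}
    for tb in tss_bins:
        for eb in elem_bins:
            key = (min(tb, eb), max(tb, eb))
            if key in entries:
                continue
            d = abs(tb - eb) * res
            lam = spec.hic_base_count * (res / max(d, res)) ** spec.hic_gamma
            if (tb, eb) in boosted:
                lam *= spec.loop_boost
            entries[key] = float(rng.poisson(lam))
    hic = HiCContacts(
        resolution=res,
        entries=[("chr1", bi, bj, c) for (bi, bj), c in sorted(entries.items())],
        gamma=spec.hic_gamma,
    )

    elements: list[CandidateElement] = []
    for gid, p in reg.promoters.items():
        region = ("chr1", p["start"], p["end"])
        elements.append(
            CandidateElement(
                region=region,
                atac_count=count_signal(region, atac),
                h3k27ac_count=count_signal(region, h3k),
                is_promoter=True,
                gene_id=gid,
            )
        )
    for eid, e in reg.enhancers.items():
        region = ("chr1", e["start"], e["end"])
        elements.append(
            CandidateElement(
                region=region,
                atac_count=count_signal(region, atac),
                h3k27ac_count=count_signal(region, h3k),
            )
        )
    for region in reg.decoys:
        elements.append(
            CandidateElement(
                region=region,
                atac_count=count_signal(region, atac),
                h3k27ac_count=count_signal(region, h3k),
            )
        )
    return TracksAndHiC(atac, h3k, hic, elements)


class TFSetFixture(NamedTuple):
    sets: dict[str, set[str]]
    interactions: list[tuple[str, str]]
    core_tfs: list[str]
    peripheral_tfs: list[str]
    anchor: str


def sim_tf_target_sets(spec: FixtureSpec) -> TFSetFixture:
    """Target sets with an interconnected planted core and a held-out anchor.

    Core TFs all target a shared pool and each other (high connectivity);
    peripheral TFs get small disjoint target sets. The anchor-like TF
    appears only in the interaction list, wired to ``anchor_links`` shared
    targets, so one-level expansion pulls it into the network core.
    """
    rng = np.random.default_rng(spec.seed + 3)
    shared = [f"T{j:03d}" for j in range(spec.shared_pool_size)]
    core = [f"CORE{j + 1}" for j in range(spec.core_tf_count)]
    n_per = spec.tf_set_count - spec.core_tf_count
    peripheral = [f"PERI{j + 1}" for j in range(n_per)]
    sets: dict[str, set[str]] = {}
    for tf in core:
        sets[tf] = set(shared) | {c for c in core if c != tf}
    nxt = 0
    for tf in peripheral:
        sets[tf] = {f"U{nxt + j:03d}" for j in range(spec.peripheral_targets)}
        nxt += spec.peripheral_targets
    linked = rng.choice(spec.shared_pool_size, size=min(spec.anchor_links, spec.shared_pool_size), replace=False)
    interactions = [(ANCHOR_NAME, shared[j]) for j in sorted(linked)]
    return TFSetFixture(sets, interactions, core, peripheral, ANCHOR_NAME)


def write_fixture_files(spec: FixtureSpec, out_dir) -> dict[str, str]:
    """Generate one full fixture set and write it in the standard formats.

    Returns a mapping of logical input names to the written paths; the
    files round-trip through the package readers without loss.
    """
    from pathlib import Path

    from . import io as aio
    from .motifs import write_jaspar

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    reg = sim_regulatory_genome(spec)
    expr = coherent_expression(spec, list(reg.gene_table["id"]))
    df = pd.DataFrame(
        expr.matrix.values, index=expr.matrix.gene_ids, columns=expr.matrix.sample_ids
    )
    paths["expression"] = str(out / "expression.tsv")
    df.to_csv(paths["expression"], sep="\t", index_label="gene")
    paths["sample_times"] = str(out / "sample_times.tsv")
    pd.DataFrame(
        {"sample": expr.matrix.sample_ids, "time": expr.matrix.sample_time}
    ).to_csv(paths["sample_times"], sep="\t", index=False)

    paths["genome"] = str(out / "genome.fa")
    aio.write_fasta(paths["genome"], reg.genome)
    paths["gene_table"] = str(out / "genes.tsv")
    reg.gene_table.to_csv(paths["gene_table"], sep="\t", index=False)
    paths["motifs"] = str(out / "motifs.jaspar")
    write_jaspar(paths["motifs"], reg.motifs.values())
    paths["promoters_bed"] = str(out / "promoters.bed")
    aio.write_bed(
        paths["promoters_bed"],
        [(p["chrom"], p["start"], p["end"], g) for g, p in reg.promoters.items()],
    )
    paths["enhancers_bed"] = str(out / "enhancers.bed")
    aio.write_bed(
        paths["enhancers_bed"],
        [(e["chrom"], e["start"], e["end"], eid) for eid, e in reg.enhancers.items()],
    )

    tracks = sim_tracks_and_hic(spec, reg)
    paths["atac"] = str(out / "atac.bedgraph")
    aio.write_bedgraph(paths["atac"], tracks.atac.intervals)
    paths["h3k27ac"] = str(out / "h3k27ac.bedgraph")
    aio.write_bedgraph(paths["h3k27ac"], tracks.h3k27ac.intervals)
    paths["hic"] = str(out / "hic.tsv")
    aio.write_hic_tsv(paths["hic"], tracks.hic.entries)

    tfs = sim_tf_target_sets(spec)
    paths["target_sets"] = str(out / "target_sets.gmt")
    aio.write_gmt(paths["target_sets"], tfs.sets)
    paths["interactions"] = str(out / "interactions.tsv")
    with open(paths["interactions"], "w") as fh:
        for a, b in tfs.interactions:
            fh.write(f"{a}\t{b}\tcurated\n")
    return paths
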