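"""Config-driven orchestration of the discovery stages.

``run_discovery`` executes gene selection -> promoter/enhancer assembly
(ABC) -> anchored co-occupancy -> categorization -> (optional) network
ranking, writing plain-text TSV outputs plus a machine-readable run
manifest. A failing stage aborts the run with the stage named; partial
outputs stay on disk next to a FAILED marker.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, io as aio
from .config import config_hash, validate_config
from .cooccupancy import (
    anchored_enrichment,
    categorize_tfs,
    make_promoters,
    results_to_frame,
)
from .enhancers import (
    ABCPair,
    CandidateElement,
    CoverageTrack,
    HiCContacts,
    abc_scores,
    count_signal,
    pair_summary,
    pairs_to_frame,
    select_strongest_regions,
)
from .geneselect import (
    ExpressionMatrix,
    SelectionConfig,
    compute_adjacency,
    compute_tom,
    detect_modules,
    module_fold_change,
    preprocess_expression,
)
from .motifs import read_jaspar
from .synthetic import (
    FixtureSpec,
    coherent_expression,
    sim_regulatory_genome,
    sim_tf_target_sets,
    sim_tracks_and_hic,
)
from .tfnetwork import expand_network, merge_networks, node_table, rank_shells


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _selection_config(cfg: dict[str, Any]) -> SelectionConfig:
    return SelectionConfig(
        soft_power=int(cfg["soft_power"]),
        min_module_size=int(cfg["min_module_size"]),
        cut_height_frac=float(cfg["cut_height_frac"]),
        max_missing_frac=float(cfg["max_missing_frac"]),
        downreg_fold=float(cfg["downreg_fold"]),
        alpha=float(cfg["alpha"]),
        fdr=float(cfg["fdr"]),
    )


def _select_down_genes(matrix: ExpressionMatrix, scfg: SelectionConfig):
    """Module detection plus the fold-change gate; returns (genes, table)."""
    pre = preprocess_expression(matrix, scfg)
    adj = compute_adjacency(pre.matrix, scfg.soft_power)
    tom = compute_tom(adj)
    det = detect_modules(tom, scfg, pre.matrix.gene_ids)
    early = pre.matrix.sample_time[0]
    late = pre.matrix.sample_time[-1]
    rows = []
    selected: set[str] = set()
    for mod in det.modules:
        fc = module_fold_change(mod, pre.matrix, early, late)
        down = fc >= scfg.downreg_fold
        if down:
            selected |= set(mod.gene_ids)
        for g in sorted(mod.gene_ids):
            rows.append({"gene": g, "module": mod.label, "fold_change": fc,
                         "downregulated": down})
    for g in sorted(det.unassigned):
        rows.append({"gene": g, "module": "unassigned", "fold_change": np.nan,
                     "downregulated": False})
    table = pd.DataFrame(rows, columns=["gene", "module", "fold_change", "downregulated"])
    return selected, table


def _load_real_inputs(cfg: dict[str, Any]) -> dict[str, Any]:
    inp = cfg["inputs"]
    data: dict[str, Any] = {}
    data["genome"] = aio.read_fasta(inp["genome"])
    data["gene_table"] = aio.read_gene_table(inp["gene_table"])
    motifs = {m.tf_name: m for m in read_jaspar(inp["motifs"])}
    if cfg["anchor"] not in motifs:
        raise ValueError(f"anchor motif {cfg['anchor']!r} absent from motif file")
    data["motifs"] = motifs
    if "expression" in inp:
        data["expression"] = ExpressionMatrix.from_tsv(
            inp["expression"], inp["sample_times"]
        )
    if "atac" in inp:
        data["atac"] = CoverageTrack(aio.read_bedgraph(inp["atac"]), "accessibility")
        data["h3k27ac"] = CoverageTrack(aio.read_bedgraph(inp["h3k27ac"]), "acetylation")
    if "hic" in inp:
        data["hic"] = HiCContacts(
            resolution=int(cfg["hic_resolution"]),
            entries=aio.read_hic_tsv(inp["hic"]),
            gamma=float(cfg["hic_gamma"]),
            pseudocount=float(cfg["hic_pseudocount"]),
        )
    if "target_sets" in inp:
        data["target_sets"] = aio.read_gmt(inp["target_sets"])
        data["interactions"] = (
            aio.read_edge_list(inp["interactions"]) if "interactions" in inp else []
        )
    return data


def _elements_from_tracks(
    cfg: dict[str, Any],
    atac: CoverageTrack,
    h3k: CoverageTrack,
    promoters: dict[str, dict],
) -> list[CandidateElement]:
    """Strongest-window candidate elements plus promoter elements."""
    regions = select_strongest_regions(
        atac, n=int(cfg["n_strongest"]), width=int(cfg["peak_width"])
    )
    prom_iv = {(p["chrom"], p["start"], p["end"]): g for g, p in promoters.items()}
    elements = []
    for region in regions:
        overlaps_prom = any(
            region[0] == c and region[1] < e and region[2] > s
            for (c, s, e) in prom_iv
        )
        if overlaps_prom:
            continue
        elements.append(
            CandidateElement(
                region=region,
                atac_count=count_signal(region, atac),
                h3k27ac_count=count_signal(region, h3k),
            )
        )
    for g, p in promoters.items():
        region = (p["chrom"], p["start"], p["end"])
        elements.append(
            CandidateElement(
                region=region,
                atac_count=count_signal(region, atac),
                h3k27ac_count=count_signal(region, h3k),
                is_promoter=True,
                gene_id=g,
            )
        )
    return elements


def run_discovery(cfg: dict[str, Any] | str | Path) -> dict[str, Any]:
    """Run the full discovery pipeline; returns a report with output paths."""
    if not isinstance(cfg, dict):
        cfg, errors = validate_config(cfg)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"outputs": {}, "stages": []}
    failed_marker = out_dir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        scfg = _selection_config(cfg)
        seed = int(cfg["seed"])
        if cfg["simulate"]:
            spec = FixtureSpec(
                seed=seed,
                inter_binding_distance=int(cfg["inter_binding_distance"]),
                promoter_upstream=int(cfg["promoter_upstream"]),
                promoter_downstream=int(cfg["promoter_downstream"]),
                hic_resolution=int(cfg["hic_resolution"]),
                hic_gamma=float(cfg["hic_gamma"]),
            )
            reg = sim_regulatory_genome(spec)
            expr = coherent_expression(spec, list(reg.gene_table["id"]))
            matrix = expr.matrix
            tracks = sim_tracks_and_hic(spec, reg)
            atac, h3k, hic = tracks.atac, tracks.h3k27ac, tracks.hic
            genome, gene_table, motifs = reg.genome, reg.gene_table, reg.motifs
            tf_fixture = sim_tf_target_sets(spec)
            target_sets, interactions = tf_fixture.sets, tf_fixture.interactions
            elements = tracks.elements
        else:
            data = _load_real_inputs(cfg)
            genome, gene_table, motifs = (
                data["genome"], data["gene_table"], data["motifs"],
            )
            matrix = data.get("expression")
            atac, h3k = data.get("atac"), data.get("h3k27ac")
            hic = data.get("hic")
            target_sets = data.get("target_sets")
            interactions = data.get("interactions", [])
            elements = None

        stage = "geneselect"
        if matrix is not None:
            selected, module_table = _select_down_genes(matrix, scfg)
            selected &= set(gene_table["id"])
        else:
            selected = set(gene_table["id"])
            module_table = pd.DataFrame(
                columns=["gene", "module", "fold_change", "downregulated"]
            )
        module_path = out_dir / "modules.tsv"
        aio.write_tsv(module_path, module_table)
        report["outputs"]["modules"] = str(module_path)
        report["n_selected_genes"] = len(selected)
        report["stages"].append(stage)
        if not selected:
            raise ValueError("no downregulated genes selected")

        stage = "enhancers"
        sel_table = gene_table[gene_table["id"].isin(selected)]
        promoters = make_promoters(
            sel_table,
            int(cfg["promoter_upstream"]),
            int(cfg["promoter_downstream"]),
            genome,
        )
        pairs: list[ABCPair] = []
        if hic is not None and atac is not None:
            if elements is None:
                elements = _elements_from_tracks(cfg, atac, h3k, promoters)
            for row in sel_table.itertuples():
                pairs.extend(
                    abc_scores(
                        {"id": row.id, "tss": row.tss, "chrom": row.chrom},
                        elements,
                        hic,
                        window=int(cfg["abc_window"]),
                        threshold=float(cfg["abc_threshold"]),
                    )
                )
        pair_path = out_dir / "enhancer_gene_pairs.tsv"
        aio.write_tsv(pair_path, pairs_to_frame(pairs))
        report["outputs"]["pairs"] = str(pair_path)
        report["n_pairs"] = len(pairs)
        if pairs:
            summ = pair_summary(pairs)
            report["mean_enhancers_per_gene"] = summ.mean_count
            report["distance_band_fraction"] = summ.band_fraction
        report["stages"].append(stage)

        stage = "cooccupancy"
        anchor = motifs[cfg["anchor"]]
        partners = [m for name, m in motifs.items() if name != cfg["anchor"]]
        prom_seqs = {g: p["seq"] for g, p in promoters.items()}
        enh_seqs = {
            f"{p.gene_id}_{p.element.region[1]}": genome[p.element.region[0]][
                p.element.region[1]:p.element.region[2]
            ]
            for p in pairs
        }
        common = dict(
            D=int(cfg["inter_binding_distance"]),
            rel_threshold=float(cfg["rel_score_threshold"]),
            min_ic=float(cfg["min_ic_bits"]),
            background=cfg["background"],
            seed=seed,
        )
        prom_res = anchored_enrichment(prom_seqs, anchor, partners, **common)
        enh_res = (
            anchored_enrichment(enh_seqs, anchor, partners, **common)
            if enh_seqs
            else []
        )
        cats = categorize_tfs(prom_res, enh_res, float(cfg["z_threshold"]))
        cand = pd.concat(
            [
                results_to_frame(prom_res, "promoter", cats),
                results_to_frame(enh_res, "enhancer", cats),
            ],
            ignore_index=True,
        )
        cand_path = out_dir / "candidate_tfs.tsv"
        aio.write_tsv(cand_path, cand)
        report["outputs"]["candidates"] = str(cand_path)
        report["categories"] = cats
        report["n_candidates"] = sum(1 for c in cats.values() if c != "none")
        report["stages"].append(stage)

        if cfg["run_network"] and target_sets:
            stage = "tfnetwork"
            net = merge_networks(target_sets)
            net = expand_network(net, interactions, int(cfg["min_links"]))
            ranking = rank_shells(net, int(cfg["n_shells"]), query_tfs=[cfg["anchor"]])
            nodes_path = out_dir / "network_nodes.tsv"
            aio.write_tsv(nodes_path, node_table(ranking.graph))
            report["outputs"]["network_nodes"] = str(nodes_path)
            report["anchor_in_core"] = bool(ranking.core_report.get(cfg["anchor"]))
            report["stages"].append(stage)

        stage = "manifest"
        manifest = {
            "config_hash": config_hash(cfg),
            "seed": seed,
            "version": __version__,
            "outputs": report["outputs"],
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        report["outputs"]["manifest"] = str(manifest_path)
        report["stages"].append(stage)
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n")
        raise StageError(stage, exc) from exc
    return report
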