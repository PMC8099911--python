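"""Selection of developmentally downregulated, growth-relevant genes.

The selection path mirrors weighted co-expression network analysis: a
pairwise Pearson correlation matrix is raised to a soft power (unsigned
adjacency), smoothed into a topological overlap matrix (TOM), clustered by
average linkage on 1 - TOM, and cut into modules with a minimum-size rule.
Modules whose mean expression falls at least ``downreg_fold``-fold from the
earliest to the latest time label are retained, and a hypergeometric GO
gate keeps the growth-relevant members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, false_discovery_control, hypergeom


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with an ordered time label per sample.

    ``values`` may contain NaN for missing entries; ``log_scale`` records
    whether values are log2 (fold changes are always reported on the linear
    scale).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    sample_time: list[str]
    log_scale: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.sample_time) != len(self.sample_ids):
            raise ValueError("sample_time must label every sample")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_time)) < 2:
            raise ValueError("need >=2 distinct time levels")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def linear_values(self) -> np.ndarray:
        return np.exp2(self.values) if self.log_scale else self.values

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = set(genes)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx],
        )

    @classmethod
    def from_tsv(cls, path, time_path, log_scale: bool = True) -> "ExpressionMatrix":
        """Load from TSV (first column gene id) plus a sample->time sidecar TSV."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        times = pd.read_csv(time_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            sample_time=[str(times[s]) for s in df.columns],
            log_scale=log_scale,
        )


@dataclass(frozen=True)
class GeneModule:
    label: str
    gene_ids: frozenset[str]
    fold_change: float | None = None

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SelectionConfig:
    soft_power: int = 10
    min_module_size: int = 30
    cut_height_frac: float = 0.95
    max_missing_frac: float = 0.2
    downreg_fold: float = 2.0
    alpha: float = 0.05
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be a positive integer")
        if not 0 < self.cut_height_frac <= 1:
            raise ValueError("cut_height_frac must lie in (0, 1]")
        for name in ("max_missing_frac", "alpha", "fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.downreg_fold <= 0:
            raise ValueError("downreg_fold must be positive")


class PreprocessResult(NamedTuple):
    matrix: ExpressionMatrix
    removed_genes: list[str]
    removed_samples: list[str]
    n_imputed: int


def _leaf_merge_heights(Z: np.ndarray, n: int) -> np.ndarray:
    """Height at which each original leaf first merges into a cluster."""
    heights = np.zeros(n)
    for row in Z:
        for child in (int(row[0]), int(row[1])):
            if child < n:
                heights[child] = row[2]
    return heights


def preprocess_expression(m: ExpressionMatrix, cfg: SelectionConfig) -> PreprocessResult:
    """Drop high-missingness genes, impute remaining gaps by gene mean, and
    drop outlier samples by their average-linkage merge height.

    A sample is an outlier when the height at which it first merges in an
    average-linkage dendrogram of samples exceeds mean + 2 sd of all merge
    heights.
    """
    if m.n_samples < 3:
        raise ValueError("need >=3 samples")
    if m.n_genes < 2:
        raise ValueError("need >=2 genes")

    missing_frac = np.isnan(m.values).mean(axis=1)
    keep = missing_frac <= cfg.max_missing_frac
    removed_genes = [g for g, k in zip(m.gene_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all genes removed by the missingness filter")
    vals = m.values[keep].copy()
    gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]

    n_imputed = int(np.isnan(vals).sum())
    if n_imputed:
        row_means = np.nanmean(vals, axis=1)
        nan_r, nan_c = np.nonzero(np.isnan(vals))
        vals[nan_r, nan_c] = row_means[nan_r]

    # sample outliers via first-merge heights of the sample dendrogram; the
    # mean + 2 sd rule runs on the per-sample heights themselves so one
    # extreme sample cannot mask itself through the internal merge heights
    Z = linkage(vals.T, method="average", metric="euclidean")
    leaf_h = _leaf_merge_heights(Z, m.n_samples)
    thresh = leaf_h.mean() + 2.0 * leaf_h.std()
    sample_keep = leaf_h <= thresh
    removed_samples = [s for s, k in zip(m.sample_ids, sample_keep) if not k]
    if sample_keep.sum() < 2:
        raise ValueError("fewer than 2 samples remain after outlier removal")
    out = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[s for s, k in zip(m.sample_ids, sample_keep) if k],
        values=vals[:, sample_keep],
        sample_time=[t for t, k in zip(m.sample_time, sample_keep) if k],
        log_scale=m.log_scale,
    )
    return PreprocessResult(out, removed_genes, removed_samples, n_imputed)


def compute_adjacency(m: ExpressionMatrix, soft_power: int = 10) -> np.ndarray:
    """Unsigned soft-threshold adjacency ``|pearson|^beta`` with unit diagonal.

    Zero-variance genes get correlation 0 to every partner (flagged by a
    warning rather than raising).
    """
    if np.isnan(m.values).any():
        raise ValueError("adjacency requires a complete matrix; run preprocessing")
    if m.n_samples < 3:
        raise ValueError("need >=3 samples for correlation")
    sd = m.values.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s); correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(m.values)
    cor[np.isnan(cor)] = 0.0
    cor[flat, :] = 0.0
    cor[:, flat] = 0.0
    adj = np.abs(cor) ** soft_power
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity sum excluding the diagonal; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency values must lie in [0, 1]")
    n = A.shape[0]
    k = A.sum(axis=1) - np.diag(A)
    # (A @ A)_ij includes the u=i and u=j terms a_ii*a_ij + a_ij*a_jj
    shared = A @ A - np.diag(A)[:, None] * A - A * np.diag(A)[None, :]
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


class ModuleDetection(NamedTuple):
    modules: list[GeneModule]
    unassigned: frozenset[str]
    labels: dict[str, str]


def detect_modules(
    tom: np.ndarray,
    cfg: SelectionConfig,
    gene_ids: Sequence[str] | None = None,
) -> ModuleDetection:
    """Cut the average-linkage dendrogram of 1 - TOM into gene modules.

    Static-height variant of dynamic tree cutting: the tree is cut at
    ``cut_height_frac`` of the maximum merge height and clusters smaller
    than ``min_module_size`` go to the unassigned pool. Output modules are
    labelled M1, M2, ... in decreasing size (ties by smallest member id).
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    if n < cfg.min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return ModuleDetection([], frozenset(gene_ids), {g: "unassigned" for g in gene_ids})
    dissim = 1.0 - tom
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(np.clip(dissim, 0.0, None), checks=False), method="average")
    max_h = Z[:, 2].max()
    if max_h <= 0:  # all genes identical
        flat = np.ones(n, dtype=int)
    else:
        flat = fcluster(Z, t=cfg.cut_height_frac * max_h, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(gene_ids, flat):
        clusters.setdefault(int(c), []).append(g)
    big = [v for v in clusters.values() if len(v) >= cfg.min_module_size]
    big.sort(key=lambda v: (-len(v), min(v)))
    modules = [GeneModule(label=f"M{i + 1}", gene_ids=frozenset(v)) for i, v in enumerate(big)]
    assigned = set().union(*(mod.gene_ids for mod in modules)) if modules else set()
    unassigned = frozenset(g for g in gene_ids if g not in assigned)
    labels = {g: "unassigned" for g in unassigned}
    for mod in modules:
        for g in mod.gene_ids:
            labels[g] = mod.label
    return ModuleDetection(modules, unassigned, labels)


def module_fold_change(
    module: GeneModule,
    m: ExpressionMatrix,
    early_label: str,
    late_label: str,
) -> float:
    """Linear-scale ratio mean(early)/mean(late) over the module's genes.

    A ratio > 1 means the module is downregulated with maturation.
    """
    for lab in (early_label, late_label):
        if lab not in m.sample_time:
            raise ValueError(f"time label {lab!r} absent from matrix")
    gidx = [i for i, g in enumerate(m.gene_ids) if g in module.gene_ids]
    if not gidx:
        raise ValueError("module genes absent from matrix")
    lin = m.linear_values()[gidx]
    early = [j for j, t in enumerate(m.sample_time) if t == early_label]
    late = [j for j, t in enumerate(m.sample_time) if t == late_label]
    late_mean = lin[:, late].mean()
    if late_mean <= 0:
        raise ValueError("late mean <= 0 on the linear scale; ratio undefined")
    return float(lin[:, early].mean() / late_mean)


def timecourse_de(m: ExpressionMatrix, cfg: SelectionConfig) -> pd.DataFrame:
    """Per-gene one-way F-test across time groups with BH correction.

    Returns a frame with columns ``gene, p, q, fold_change, direction,
    called_down``; ``fold_change`` is the linear early/late ratio and a gene
    is called down when q < fdr, p < alpha and fold_change >= downreg_fold.
    """
    order = list(dict.fromkeys(m.sample_time))
    if len(order) < 2:
        raise ValueError("need >=2 time groups")
    groups_idx = [[j for j, t in enumerate(m.sample_time) if t == lab] for lab in order]
    if any(len(g) < 2 for g in groups_idx):
        raise ValueError(
            "each time group needs >=2 replicates for the F-test; "
            "use module_fold_change for fold-change-only selection"
        )
    logv = m.values if m.log_scale else np.log2(np.clip(m.values, 1e-12, None))
    ps = np.ones(m.n_genes)
    for i in range(m.n_genes):
        samples = [logv[i, g] for g in groups_idx]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            ps[i] = 1.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p = f_oneway(*samples)
        ps[i] = 1.0 if np.isnan(p) else float(p)
    qs = false_discovery_control(ps, method="bh")
    lin = m.linear_values()
    early_mean = lin[:, groups_idx[0]].mean(axis=1)
    late_mean = lin[:, groups_idx[-1]].mean(axis=1)
    with np.errstate(divide="ignore"):
        fc = np.where(late_mean > 0, early_mean / late_mean, np.inf)
    direction = np.where(
        fc >= cfg.downreg_fold, "down", np.where(fc <= 1.0 / cfg.downreg_fold, "up", "flat")
    )
    called = (qs < cfg.fdr) & (ps < cfg.alpha) & (fc >= cfg.downreg_fold)
    return pd.DataFrame(
        {
            "gene": m.gene_ids,
            "p": ps,
            "q": qs,
            "fold_change": fc,
            "direction": direction,
            "called_down": called,
        }
    )


def normalize_gene_id(gene: str, synonyms: Mapping[str, str] | None = None) -> str:
    g = gene.strip().casefold()
    if synonyms:
        g = {k.casefold(): v.casefold() for k, v in synonyms.items()}.get(g, g)
    return g


def intersect_down(
    set_a: Iterable[str],
    set_b: Iterable[str],
    synonyms: Mapping[str, str] | None = None,
) -> set[str]:
    """Case-fold (and optionally synonym-map) gene ids, then intersect."""
    syn = {k.casefold(): v.casefold() for k, v in (synonyms or {}).items()}
    norm = lambda g: syn.get(g.strip().casefold(), g.strip().casefold())
    a = {norm(g) for g in set_a}
    b = {norm(g) for g in set_b}
    out = a & b
    if not out:
        warnings.warn("empty intersection between the two downregulated gene sets")
    return out


class GoSelection(NamedTuple):
    selected_genes: set[str]
    term_table: pd.DataFrame


def go_enrich_select(
    genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    whitelist: Sequence[str],
    cfg: SelectionConfig = SelectionConfig(),
) -> GoSelection:
    """Hypergeometric term enrichment with a mandatory user whitelist.

    Each term gets an upper-tail hypergeometric p for its overlap with the
    query inside the universe, BH-corrected across tested terms. The
    selected genes are the query members of whitelisted terms with q < fdr
    (the whitelist plays the role of the curated growth-relevant term list).
    """
    if not whitelist:
        raise ValueError("term whitelist is mandatory (curated relevant terms)")
    universe = set(universe)
    query = set(genes) & universe
    rows = []
    terms = sorted(annotation)
    for term in terms:
        members = set(annotation[term]) & universe
        if not members:
            continue
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(query)))
        rows.append({"term": term, "overlap": k, "term_size": len(members), "p": p})
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
    if len(table):
        table["q"] = false_discovery_control(table["p"].to_numpy(), method="bh")
    else:
        table["q"] = pd.Series(dtype=float)
    wl = {t for t in whitelist}
    hits = table[(table["term"].isin(wl)) & (table["q"] < cfg.fdr)]
    selected: set[str] = set()
    for term in hits["term"]:
        selected |= set(annotation[term]) & query
    return GoSelection(selected, table.sort_values("p", ignore_index=True))
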