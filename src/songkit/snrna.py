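"""snRNA-seq QC, clustering contracts and dopamine-receptor classification.

This module implements the single-nucleus arm of the pipeline for songbird
striatal tissue (Area X): post-alignment quality control, log-normalization,
a clustering contract (variable genes -> covariate regression -> PCA ->
graph community detection), marker-based cluster typing, the exclusive
dopamine-receptor/FoxP2 classification of medium spiny neurons (MSNs),
direct-like vs indirect-like pathway differential expression, per-receptor
Welch tests between conditions, and bootstrap-supported dendrograms of
cluster profiles.

Data live in :class:`anndata.AnnData` objects with cells as rows and genes
as columns (the scanpy convention); ``adata.layers["counts"]`` retains raw
UMI counts once normalization has run.

Conventions fixed here:

* QC removes cells with *more than* 10,000 UMIs (doublet proxy) or *more
  than* 5% mitochondrial UMIs (damage proxy); boundary cells are retained.
* Normalized value = ln(1 + count / cell_total * 10,000).
* A gene counts as "expressed" in a cell iff its normalized value is
  positive, i.e. at least one raw UMI; the threshold is exposed for
  sensitivity analyses.
* Receptor classes partition MSNs: D1/5-only (Drd1 or Drd5, no Drd2),
  D2-only, both, none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scanpy as sc
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats

__all__ = [
    "QCConfig",
    "MARKER_TABLE",
    "RECEPTOR_GENES",
    "RECEPTOR_CLASSES",
    "PathwayGrouping",
    "load_10x",
    "read_dense_counts",
    "flag_mito",
    "mito_fraction",
    "qc_filter",
    "log_normalize",
    "cluster_cells",
    "marker_summary",
    "assign_cell_types",
    "receptor_classes",
    "receptor_class",
    "coexpression_summary",
    "infer_pathway_grouping",
    "pathway_de",
    "receptor_shift_test",
    "bootstrap_dendrogram",
    "Dendrogram",
]

RECEPTOR_GENES = ("Drd1", "Drd5", "Drd2")
FOXP2_GENE = "FoxP2"
RECEPTOR_CLASSES = ("D1/5-only", "D2-only", "both", "none")

#: Marker genes -> functional identity (zebra-finch-established markers
#: flagged with True).
MARKER_TABLE: dict[str, tuple[str, bool]] = {
    "Gad2": ("GABAergic", False),
    "Slc17a6": ("Glutamatergic", False),
    "Lhx6": ("MGE-derived", False),
    "Pvalb": ("Interneuron", True),
    "Sst": ("Interneuron", True),
    "Npy": ("Interneuron", True),
    "Nos1": ("Interneuron", True),
    "Chat": ("Interneuron", True),
    "Penk": ("PN", True),
    "Tshz1": ("PN", True),
    "Lrig1": ("Astrocyte", False),
    "Meis2": ("LGE-derived", False),
    "Ppp1r1b": ("MSN", True),
    "FoxP1": ("MSN", True),
    "FoxP2": ("MSN", True),
    "Tac1": ("MSN", True),
    "Csf1r": ("Microglia", False),
    "Flt1": ("Endothelial", False),
    "Mbp": ("Oligodendrocyte", False),
    "Pdgfra": ("Oligodendrocyte Precursor", False),
}


@dataclass
class QCConfig:
    """Cell-level QC thresholds (strict '>' removes)."""

    umi_max: float = 10_000
    mito_pct_max: float = 5.0

    def __post_init__(self) -> None:
        if self.umi_max <= 0 or self.mito_pct_max <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class PathwayGrouping:
    """Cluster ids grouped into putative direct-like and indirect-like pathways."""

    direct_like: frozenset[int] = frozenset({1, 5})
    indirect_like: frozenset[int] = frozenset({2, 3, 4})

    def __post_init__(self) -> None:
        if set(self.direct_like) & set(self.indirect_like):
            raise ValueError("pathway groupings must be disjoint")


# ---------------------------------------------------------------------------
# I/O and QC
# ---------------------------------------------------------------------------


def load_10x(path, mito_prefix: str = "MT-") -> AnnData:
    """Read a 10x-convention Matrix Market triplet directory.

    Compressed Cell Ranger v3 directories go through scanpy; uncompressed
    ``matrix.mtx`` + ``features.tsv``/``genes.tsv`` + ``barcodes.tsv``
    triplets are assembled directly.
    """
    from pathlib import Path

    path = Path(path)
    if (path / "matrix.mtx.gz").exists():
        adata = sc.read_10x_mtx(path)
    else:
        from scipy.io import mmread

        matrix = sp.csr_matrix(mmread(path / "matrix.mtx")).T  # genes x cells on disk
        feat_file = next(
            p for n in ("features.tsv", "genes.tsv") if (p := path / n).exists()
        )
        features = pd.read_csv(feat_file, sep="\t", header=None)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)
        names = features[1] if features.shape[1] > 1 else features[0]
        adata = AnnData(
            X=matrix,
            obs=pd.DataFrame(index=pd.Index(barcodes[0].astype(str), name="barcode")),
            var=pd.DataFrame(index=pd.Index(names.astype(str), name="gene")),
        )
        adata.var_names_make_unique()
    return flag_mito(adata, prefix=mito_prefix)


def read_dense_counts(path, mito_prefix: str = "MT-", sep: str = "\t") -> AnnData:
    """Read a dense gene-by-cell TSV (genes as rows) into AnnData."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    adata = AnnData(
        X=sp.csr_matrix(df.to_numpy().T.astype(np.float32)),
        obs=pd.DataFrame(index=df.columns.astype(str)),
        var=pd.DataFrame(index=df.index.astype(str)),
    )
    return flag_mito(adata, prefix=mito_prefix)


def _counts(adata: AnnData) -> sp.csr_matrix:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sp.csr_matrix(X)


def flag_mito(
    adata: AnnData,
    mito_genes: Sequence[str] | None = None,
    prefix: str = "MT-",
) -> AnnData:
    """Annotate mitochondrial genes and per-cell QC covariates.

    Sets ``var['mt']``, ``obs['total_counts']`` and ``obs['pct_counts_mt']``
    from raw counts.  Mito genes are named explicitly or by prefix.
    """
    if mito_genes is not None:
        missing = set(mito_genes) - set(adata.var_names)
        if missing:
            raise KeyError(f"mito genes not in matrix: {sorted(missing)}")
        mt = adata.var_names.isin(mito_genes)
    else:
        mt = adata.var_names.str.upper().str.startswith(prefix.upper())
    adata.var["mt"] = np.asarray(mt)
    counts = _counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    mito = np.asarray(counts[:, np.asarray(mt)].sum(axis=1)).ravel()
    adata.obs["total_counts"] = totals
    with np.errstate(invalid="ignore", divide="ignore"):
        adata.obs["pct_counts_mt"] = np.where(totals > 0, 100.0 * mito / np.where(totals == 0, 1, totals), 0.0)
    return adata


def mito_fraction(adata: AnnData, cell: str) -> float:
    """Percent of a cell's UMIs from mitochondrial genes."""
    if "mt" not in adata.var:
        raise KeyError("run flag_mito() first")
    i = adata.obs_names.get_loc(cell)
    counts = _counts(adata)
    total = counts[i].sum()
    if total == 0:
        raise ValueError(f"cell {cell} has zero total counts")
    mito = counts[i, np.asarray(adata.var["mt"])].sum()
    return 100.0 * float(mito) / float(total)


def qc_filter(
    adata: AnnData, cfg: QCConfig | None = None
) -> tuple[AnnData, pd.DataFrame]:
    """Remove probable doublets and damaged cells.

    Retains exactly the cells with total UMI <= ``umi_max`` AND mito% <=
    ``mito_pct_max``.  Returns the filtered copy and a report listing each
    removed barcode with its reason.
    """
    cfg = cfg or QCConfig()
    if "pct_counts_mt" not in adata.obs:
        adata = flag_mito(adata.copy())
    totals = adata.obs["total_counts"].to_numpy()
    mito_pct = adata.obs["pct_counts_mt"].to_numpy()
    high_umi = totals > cfg.umi_max
    high_mito = mito_pct > cfg.mito_pct_max
    removed = high_umi | high_mito
    if removed.all():
        raise ValueError("QC removed every cell")
    reasons = np.where(
        high_umi & high_mito,
        "high_umi+high_mito",
        np.where(high_umi, "high_umi", "high_mito"),
    )
    report = pd.DataFrame(
        {
            "barcode": adata.obs_names[removed],
            "total_counts": totals[removed],
            "pct_counts_mt": mito_pct[removed],
            "reason": reasons[removed],
        }
    ).reset_index(drop=True)
    return adata[~removed].copy(), report


def log_normalize(adata: AnnData, scale_factor: float = 1e4) -> AnnData:
    """Library-size normalize and log-transform in place.

    value = ln(1 + count / cell_total * scale_factor).  Raw counts are kept
    in ``layers['counts']``; zero-total cells are an error (QC first).
    """
    counts = _counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError(
            f"{int((totals == 0).sum())} cells have zero total counts"
        )
    adata.layers["counts"] = counts.copy()
    adata.X = counts.astype(np.float64)
    sc.pp.normalize_total(adata, target_sum=scale_factor)
    sc.pp.log1p(adata)
    adata.uns["scale_factor"] = scale_factor
    return adata


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def _regress_out(X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residualize every gene on the covariates in one vectorized OLS."""
    design = np.column_stack([np.ones(len(X)), covariates])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    return X - design @ beta


def elbow_n_pcs(variance_ratio: np.ndarray) -> int:
    """Pick the PC count at the elbow of the explained-variance curve.

    Automates the visual "last noticeable drop" criterion as the point of
    maximum distance to the chord joining the first and last PCs.
    """
    v = np.asarray(variance_ratio, dtype=float)
    n = len(v)
    if n < 3:
        return n
    x = np.arange(n, dtype=float)
    chord = v[0] + (v[-1] - v[0]) * x / (n - 1)
    dist = np.abs(v - chord)
    return int(np.argmax(dist)) + 1


def cluster_cells(
    adata: AnnData,
    n_top_genes: int = 2000,
    n_pcs: int | None = None,
    resolution: float = 0.8,
    regress_covariates: bool = True,
    seed: int = 0,
    cluster_key: str = "cluster",
) -> AnnData:
    """Variable genes -> covariate regression -> PCA -> graph clustering.

    Writes 1-based cluster ids, renumbered by decreasing size (1 =
    largest), to ``obs[cluster_key]``.  Deterministic for a fixed seed.
    ``adata`` must be log-normalized; covariate regression removes linear
    dependence on total UMI count and mito%.
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    work = adata.copy()
    n_top = min(n_top_genes, work.n_vars)
    sc.pp.highly_variable_genes(work, n_top_genes=n_top, flavor="seurat")
    work = work[:, work.var["highly_variable"]].copy()
    X = np.asarray(work.X.todense() if sp.issparse(work.X) else work.X, dtype=float)
    if not (X.std(axis=0) > 1e-12).any():
        raise ValueError("degenerate expression matrix (no gene varies across cells)")
    if regress_covariates:
        cov = np.column_stack(
            [
                adata.obs["total_counts"].to_numpy(dtype=float),
                adata.obs["pct_counts_mt"].to_numpy(dtype=float),
            ]
        )
        X = _regress_out(X, cov)
    # unit-variance scaling with clipping, as in standard workflows
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - X.mean(axis=0)) / sd, -10, 10)
    work.X = X
    n_comps = int(min(50, work.n_vars - 1, work.n_obs - 1))
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    ratio = work.uns["pca"]["variance_ratio"]
    use_pcs = n_pcs if n_pcs is not None else max(2, elbow_n_pcs(ratio))
    use_pcs = int(min(use_pcs, n_comps))
    sc.pp.neighbors(work, n_pcs=use_pcs, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        key_added="_raw_cluster",
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    raw = work.obs["_raw_cluster"]
    order = raw.value_counts().index  # decreasing size
    mapping = {old: new for new, old in enumerate(order, start=1)}
    adata.obs[cluster_key] = raw.map(mapping).astype(int).to_numpy()
    adata.uns["pca_variance_ratio"] = np.asarray(ratio)
    adata.uns["n_pcs_used"] = use_pcs
    return adata


# ---------------------------------------------------------------------------
# Marker summaries and typing
# ---------------------------------------------------------------------------


def _gene_vector(adata: AnnData, gene: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise KeyError(f"gene '{gene}' not in matrix")
    col = adata[:, gene].X
    return np.asarray(col.todense() if sp.issparse(col) else col).ravel()


def marker_summary(
    adata: AnnData, gene: str, cluster_key: str = "cluster"
) -> pd.DataFrame:
    """Percent of cells expressing and mean normalized expression per cluster.

    "Expressing" means normalized value > 0; the mean includes zeros.
    """
    values = _gene_vector(adata, gene)
    clusters = adata.obs[cluster_key]
    rows = []
    for cid, idx in clusters.groupby(clusters, observed=True).groups.items():
        v = values[adata.obs_names.get_indexer(idx)]
        rows.append(
            {
                "cluster": cid,
                "pct_expressing": 100.0 * float((v > 0).mean()),
                "mean_expression": float(v.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("cluster").sort_index()


def assign_cell_types(
    adata: AnnData,
    cluster_key: str = "cluster",
    markers: Mapping[str, tuple[str, bool]] | None = None,
    min_pct: float = 40.0,
    relative_to_max: float = 0.5,
) -> dict[int, str]:
    """Rule-based functional identity per cluster from marker enrichment.

    A marker is *enriched* in a cluster when at least ``min_pct`` percent of
    the cluster's cells express it and its mean expression reaches
    ``relative_to_max`` of the highest cluster mean for that gene (a
    scale-free criterion that tolerates markers shared across sibling
    clusters, e.g. Gad2 across all MSN clusters).  MSN identity requires
    joint enrichment of Gad2, Ppp1r1b and FoxP1; pallidal-like (PN)
    requires Penk or Tshz1; interneuron and glial identities follow their
    single markers; clusters matching no rule are "unassigned" (or
    "GABAergic" when only Gad2 is enriched).
    """
    markers = dict(markers if markers is not None else MARKER_TABLE)
    if not markers:
        raise ValueError("empty marker table")
    clusters = np.asarray(adata.obs[cluster_key])
    ids = sorted(pd.unique(clusters))
    enriched: dict[int, set[str]] = {cid: set() for cid in ids}
    for gene in markers:
        if gene not in adata.var_names:
            continue
        v = _gene_vector(adata, gene)
        means = {cid: float(v[clusters == cid].mean()) for cid in ids}
        top = max(means.values())
        if top <= 0:
            continue
        for cid in ids:
            inside = clusters == cid
            pct = 100.0 * float((v[inside] > 0).mean())
            if pct >= min_pct and means[cid] >= relative_to_max * top:
                enriched[cid].add(gene)

    def call(genes: set[str]) -> str:
        if {"Gad2", "Ppp1r1b", "FoxP1"} <= genes:
            return "MSN"
        if "Penk" in genes or "Tshz1" in genes:
            return "PN"
        for g in ("Pvalb", "Sst", "Npy", "Nos1", "Chat"):
            if g in genes:
                return "Interneuron"
        if "Slc17a6" in genes:
            return "Glutamatergic"
        for g, (identity, _) in markers.items():
            if g in genes and identity in {
                "Astrocyte",
                "Oligodendrocyte",
                "Oligodendrocyte Precursor",
                "Microglia",
                "Endothelial",
            }:
                return identity
        if "Gad2" in genes:
            return "GABAergic"
        return "unassigned"

    return {cid: call(genes) for cid, genes in enriched.items()}


# ---------------------------------------------------------------------------
# Receptor classification
# ---------------------------------------------------------------------------


def receptor_classes(
    adata: AnnData,
    receptor_genes: Sequence[str] = RECEPTOR_GENES,
    foxp2_gene: str = FOXP2_GENE,
    min_value: float = 0.0,
) -> pd.DataFrame:
    """Exclusive dopamine-receptor class and FoxP2 status per cell.

    D1/5-only: (Drd1 or Drd5) without Drd2; D2-only: Drd2 without Drd1/5;
    both: Drd1/5 and Drd2; none: neither.  Expression means normalized
    value > ``min_value`` (default 0, i.e. >= 1 raw UMI).
    """
    d1, d5, d2 = (_gene_vector(adata, g) > min_value for g in receptor_genes)
    foxp2 = _gene_vector(adata, foxp2_gene) > min_value
    d15 = d1 | d5
    cls = np.where(
        d15 & ~d2, "D1/5-only", np.where(d2 & ~d15, "D2-only", np.where(d15 & d2, "both", "none"))
    )
    return pd.DataFrame(
        {
            "receptor_class": pd.Categorical(cls, categories=list(RECEPTOR_CLASSES)),
            "foxp2_positive": foxp2,
        },
        index=adata.obs_names,
    )


def receptor_class(adata: AnnData, cell: str) -> tuple[str, bool]:
    """Receptor class and FoxP2 status of a single cell."""
    row = receptor_classes(adata[[cell]]).iloc[0]
    return str(row["receptor_class"]), bool(row["foxp2_positive"])


def coexpression_summary(
    adata: AnnData,
    msn_clusters: Sequence[int],
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Receptor-class composition of MSNs and FoxP2 co-expression per class.

    Returns one row per receptor class with ``pct_of_msns`` (sums to 100)
    and ``pct_foxp2_positive`` within the class.
    """
    mask = adata.obs[cluster_key].isin(list(msn_clusters)).to_numpy()
    if not mask.any():
        raise ValueError("no cells in the given MSN clusters")
    classes = receptor_classes(adata[mask])
    n = len(classes)
    rows = []
    for cls in RECEPTOR_CLASSES:
        sub = classes[classes["receptor_class"] == cls]
        rows.append(
            {
                "receptor_class": cls,
                "n_cells": len(sub),
                "pct_of_msns": 100.0 * len(sub) / n,
                "pct_foxp2_positive": (
                    100.0 * float(sub["foxp2_positive"].mean()) if len(sub) else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("receptor_class")


def infer_pathway_grouping(
    adata: AnnData,
    msn_clusters: Sequence[int],
    cluster_key: str = "cluster",
    drd2_threshold: float = 0.25,
) -> PathwayGrouping:
    """Split MSN clusters into direct-like and indirect-like pathways.

    Clusters whose fraction of Drd2-expressing cells exceeds
    ``drd2_threshold`` are grouped as indirect-like; the rest as
    direct-like (Drd1/FoxP2-dominated).
    """
    d2 = _gene_vector(adata, "Drd2") > 0
    clusters = np.asarray(adata.obs[cluster_key])
    direct, indirect = set(), set()
    for cid in msn_clusters:
        frac = float(d2[clusters == cid].mean())
        (indirect if frac > drd2_threshold else direct).add(int(cid))
    if not direct or not indirect:
        raise ValueError("could not split MSN clusters into two pathways")
    return PathwayGrouping(frozenset(direct), frozenset(indirect))


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def pathway_de(
    adata: AnnData,
    grouping: PathwayGrouping,
    cluster_key: str = "cluster",
    min_pct: float = 0.1,
    logfc_threshold: float = 0.25,
    max_cells_per_ident: int = 200,
    seed: int = 0,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between direct-like and indirect-like MSNs.

    Genes are pre-filtered to those expressed in at least ``min_pct`` of
    either group with |log fold change| >= ``logfc_threshold`` (difference
    of mean ln-normalized expression); each group is subsampled to
    ``max_cells_per_ident`` cells (seeded); p-values are Bonferroni-adjusted
    over the genes tested.  ``direction`` labels genes enriched in the
    direct-like or indirect-like group at adjusted p < ``alpha``.
    """
    clusters = np.asarray(adata.obs[cluster_key])
    rng = np.random.default_rng(seed)

    def take(ids) -> np.ndarray:
        idx = np.flatnonzero(np.isin(clusters, list(ids)))
        if len(idx) == 0:
            raise ValueError(f"empty pathway group {sorted(ids)}")
        if len(idx) > max_cells_per_ident:
            idx = rng.choice(idx, size=max_cells_per_ident, replace=False)
        return np.sort(idx)

    ia, ib = take(grouping.direct_like), take(grouping.indirect_like)
    X = adata.X
    Xa = np.asarray(X[ia].todense() if sp.issparse(X) else X[ia], dtype=float)
    Xb = np.asarray(X[ib].todense() if sp.issparse(X) else X[ib], dtype=float)
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    logfc = Xa.mean(axis=0) - Xb.mean(axis=0)
    keep = np.flatnonzero(
        ((pct_a >= min_pct) | (pct_b >= min_pct)) & (np.abs(logfc) >= logfc_threshold)
    )
    rows = []
    n_tests = len(keep)
    for j in keep:
        a, b = Xa[:, j], Xb[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_adj = min(1.0, p * n_tests)
        rows.append(
            {
                "gene": adata.var_names[j],
                "log_fc": float(logfc[j]),
                "pct_direct": float(pct_a[j]),
                "pct_indirect": float(pct_b[j]),
                "p_value": p,
                "p_adjusted": p_adj,
                "direction": (
                    ("direct-like" if logfc[j] > 0 else "indirect-like")
                    if p_adj < alpha
                    else "ns"
                ),
            }
        )
    return (
        pd.DataFrame(
            rows,
            columns=[
                "gene",
                "log_fc",
                "pct_direct",
                "pct_indirect",
                "p_value",
                "p_adjusted",
                "direction",
            ],
        )
        .sort_values("p_adjusted")
        .reset_index(drop=True)
    )


def receptor_shift_test(
    adata_a: AnnData,
    adata_b: AnnData,
    gene: str = "Drd1",
    receptor_genes: Sequence[str] = RECEPTOR_GENES,
    foxp2_gene: str = FOXP2_GENE,
    restrict_foxp2: bool = True,
) -> pd.DataFrame:
    """Welch's t-test of receptor expression between two conditions.

    Cells (FoxP2+ by default) are grouped by their exact receptor
    combination (e.g. ``D1+``, ``D1+/D5+``); within each group in which the
    tested gene is expressed, normalized expression of ``gene`` is compared
    between condition a and condition b with an unequal-variance t-test.
    """

    def combos(adata: AnnData) -> pd.Series:
        pos = {g: _gene_vector(adata, g) > 0 for g in receptor_genes}
        names = {"Drd1": "D1", "Drd5": "D5", "Drd2": "D2"}
        labels = []
        for i in range(adata.n_obs):
            on = [names.get(g, g) + "+" for g in receptor_genes if pos[g][i]]
            labels.append("/".join(on) if on else "none")
        return pd.Series(labels, index=adata.obs_names)

    frames = []
    for adata, cond in ((adata_a, "a"), (adata_b, "b")):
        mask = np.ones(adata.n_obs, dtype=bool)
        if restrict_foxp2:
            mask &= _gene_vector(adata, foxp2_gene) > 0
        sub = adata[mask]
        frames.append(
            pd.DataFrame(
                {
                    "group": combos(sub),
                    "value": _gene_vector(sub, gene),
                    "condition": cond,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    short = {"Drd1": "D1", "Drd5": "D5", "Drd2": "D2"}.get(gene, gene)
    rows = []
    for group, g in data.groupby("group"):
        if short + "+" not in group and group != "none":
            continue
        if group == "none":
            continue
        a = g.loc[g["condition"] == "a", "value"].to_numpy()
        b = g.loc[g["condition"] == "b", "value"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"receptor group '{group}' has fewer than 2 cells")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "group": group,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": float(t),
                "p_value": float(p),
                "direction": "a>b" if a.mean() > b.mean() else ("a<b" if a.mean() < b.mean() else "equal"),
            }
        )
    if not rows:
        raise ValueError(f"no receptor group expresses {gene} in both conditions")
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Bootstrap dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage tree over cluster profiles with bootstrap supports."""

    linkage: np.ndarray
    labels: list[str]
    supports: dict[frozenset, float] = field(default_factory=dict)
    genes: list[str] = field(default_factory=list)

    def newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return str(self.labels[node.id])
            left, right = walk(node.left), walk(node.right)
            clade = frozenset(self._leaves(node))
            support = self.supports.get(clade)
            tag = f"{support:.2f}" if support is not None else ""
            return f"({left},{right}){tag}:{node.dist:.6g}"

        return walk(tree) + ";"

    def _leaves(self, node) -> list[str]:
        return [self.labels[i] for i in node.pre_order(lambda n: n.id)]


def _clades(Z: np.ndarray, labels: Sequence[str]) -> set[frozenset]:
    tree = sch.to_tree(Z)
    out: set[frozenset] = set()

    def walk(node):
        leaves = frozenset(labels[i] for i in node.pre_order(lambda n: n.id))
        if len(leaves) > 1:
            out.add(leaves)
        if not node.is_leaf():
            walk(node.left)
            walk(node.right)

    walk(tree)
    return out


def _correlation_linkage(profiles: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    from scipy.spatial.distance import squareform

    return sch.linkage(squareform(dist, checks=False), method="average")


def top_foldchange_genes(
    adata: AnnData, cluster_key: str = "cluster", top_n: int = 50
) -> list[str]:
    """Union over clusters of the ``top_n`` genes by log fold change vs rest."""
    clusters = np.asarray(adata.obs[cluster_key])
    X = adata.X
    Xd = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    genes: set[int] = set()
    for cid in pd.unique(clusters):
        inside = clusters == cid
        fc = Xd[inside].mean(axis=0) - Xd[~inside].mean(axis=0)
        genes.update(np.argsort(fc)[::-1][:top_n].tolist())
    return [adata.var_names[j] for j in sorted(genes)]


def bootstrap_dendrogram(
    adata: AnnData,
    cluster_key: str = "cluster",
    top_n_genes: int = 50,
    n_boot: int = 100,
    seed: int = 0,
) -> Dendrogram:
    """Hierarchical clustering of cluster-mean profiles with gene bootstrap.

    Profiles are cluster means of normalized expression over the union of
    each cluster's ``top_n_genes`` by fold change; distance is
    1 - Pearson correlation with average-linkage agglomeration.  Support of
    each internal node is the fraction of ``n_boot`` gene-resampled
    replicates whose tree contains the same leaf set.
    """
    clusters = np.asarray(adata.obs[cluster_key])
    ids = sorted(pd.unique(clusters))
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters for a dendrogram")
    genes = top_foldchange_genes(adata, cluster_key, top_n_genes)
    sub = adata[:, genes]
    Xd = np.asarray(sub.X.todense() if sp.issparse(sub.X) else sub.X, dtype=float)
    profiles = np.vstack([Xd[clusters == cid].mean(axis=0) for cid in ids])
    labels = [str(cid) for cid in ids]
    Z = _correlation_linkage(profiles)
    observed = _clades(Z, labels)
    counts = {clade: 0 for clade in observed}
    rng = np.random.default_rng(seed)
    n_genes = profiles.shape[1]
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        Zb = _correlation_linkage(profiles[:, idx])
        for clade in _clades(Zb, labels) & observed:
            counts[clade] += 1
    supports = {clade: c / n_boot for clade, c in counts.items()}
    return Dendrogram(Z, labels, supports, list(genes))
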