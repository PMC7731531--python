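"""Engineered gene features for SM/GM classification.

Derives the classifier's feature matrix from precursor tables that upstream
tools produce: an expression matrix (FPKM-like), a differential-expression
table (logFC + p per contrast), homology/orthogroup tables with dN/dS,
gene coordinates, paralog pairs with synteny flags, and a binary
protein-domain matrix.  Feature categories: domain, expression,
coexpression, evolution, duplication.

The module also harmonizes the features shared between two species:
continuous shared columns are z-scored within each species so values are
comparable across species; binary columns pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.covariance import LedoitWolf
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORIES = ("domain", "expression", "coexpression", "evolution", "duplication")


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureTable:
    """Gene x feature numeric matrix plus per-feature metadata.

    ``values``: DataFrame indexed by gene id, one column per feature (binary
    features coded 0/1).  ``meta``: DataFrame indexed by feature name with
    columns ``category``, ``kind`` ("binary"/"continuous") and ``shared``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(values=self.values[names].copy(), meta=self.meta.loc[names].copy())

    @staticmethod
    def concat(tables: list["FeatureTable"]) -> "FeatureTable":
        values = pd.concat([t.values for t in tables], axis=1)
        meta = pd.concat([t.meta for t in tables], axis=0)
        return FeatureTable(values=values, meta=meta)

    def to_tsv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep="")
        self.meta.to_csv(meta_path, sep="\t")

    @staticmethod
    def from_tsv(values_path, meta_path) -> "FeatureTable":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return FeatureTable(values=values, meta=meta)


def _meta(names, category: str, kind: str, shared: bool = False) -> pd.DataFrame:
    return pd.DataFrame(
        {"category": category, "kind": kind, "shared": shared}, index=pd.Index(names, name="feature")
    )


@dataclass
class ExpressionMatrix:
    """Non-negative expression values (genes x samples) with a sample ->
    dataset-group map (e.g. development, hormone, stress, circadian)."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group assignment: {missing}")

    def group_names(self) -> list[str]:
        return sorted(self.groups.loc[self.values.columns].unique())

    def samples_in(self, group: str | None) -> list[str]:
        if group is None:
            return list(self.values.columns)
        return [s for s in self.values.columns if self.groups[s] == group]


# ---------------------------------------------------------------------------
# expression summaries and DE breadth


def _mad(x: np.ndarray, axis=1) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def expression_summaries(expr: ExpressionMatrix) -> FeatureTable:
    """Median, maximum and variation of expression per gene.

    Computed per dataset group and for all groups combined ("all").
    Variation is the (unscaled) median absolute deviation.
    """
    if expr.values.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    blocks, names = [], []
    for group in expr.group_names() + [None]:
        label = group if group is not None else "all"
        samples = expr.samples_in(group)
        if not samples:
            raise ValueError(f"expression group {label!r} has no samples")
        x = expr.values[samples].to_numpy(float)
        blocks.extend([np.median(x, axis=1), np.max(x, axis=1), _mad(x)])
        names.extend([f"expr_{label}_median", f"expr_{label}_max", f"expr_{label}_mad"])
    values = pd.DataFrame(np.column_stack(blocks), index=expr.values.index, columns=names)
    return FeatureTable(values=values, meta=_meta(names, "expression", "continuous"))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DETable:
    """Long-format differential-expression results.

    ``table`` columns: gene, contrast, group, logFC, p.  ``p_adjusted``
    states whether p already went through multiple-testing correction
    upstream; when False, BH adjustment is applied per contrast (across
    genes) before thresholding.
    """

    table: pd.DataFrame
    p_adjusted: bool = False

    def __post_init__(self) -> None:
        required = {"gene", "contrast", "group", "logFC", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns: {sorted(missing)}")
        p = self.table["p"].to_numpy(float)
        if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
            raise ValueError("p-values must lie in [0, 1]")


def de_breadth(
    de: DETable, logfc_threshold: float = 1.0, alpha: float = 0.05
) -> FeatureTable:
    """Breadth of differential expression per gene.

    A gene is counted as upregulated in a contrast when logFC > 1 and the
    adjusted p < 0.05, and downregulated when logFC < -1 and adjusted
    p < 0.05.  Counts are tallied per dataset group and over all contrasts
    combined ("all").
    """
    t = de.table.copy()
    if de.p_adjusted:
        t["p_adj"] = t["p"]
    else:
        t["p_adj"] = np.nan
        for _, idx in t.groupby("contrast").groups.items():
            t.loc[idx, "p_adj"] = bh_adjust(t.loc[idx, "p"])
    t["up"] = (t["logFC"] > logfc_threshold) & (t["p_adj"] < alpha)
    t["down"] = (t["logFC"] < -logfc_threshold) & (t["p_adj"] < alpha)
    genes = pd.Index(sorted(t["gene"].unique()), name="gene_id")
    cols = {}
    for group in sorted(t["group"].unique()):
        sub = t[t["group"] == group]
        cols[f"de_{group}_n_up"] = sub.groupby("gene")["up"].sum()
        cols[f"de_{group}_n_down"] = sub.groupby("gene")["down"].sum()
    cols["de_all_n_up"] = t.groupby("gene")["up"].sum()
    cols["de_all_n_down"] = t.groupby("gene")["down"].sum()
    values = pd.DataFrame(cols, index=genes).fillna(0).astype(int)
    return FeatureTable(values=values.astype(float), meta=_meta(values.columns, "expression", "continuous"))


# ---------------------------------------------------------------------------
# co-expression


def _correlation_matrix(x: np.ndarray, method: str) -> np.ndarray:
    """Gene x gene correlation across samples. x: genes x samples."""
    if method == "pearson":
        with np.errstate(invalid="ignore"):
            return np.corrcoef(x)
    if method == "spearman":
        ranks = scipy.stats.rankdata(x, axis=1)
        with np.errstate(invalid="ignore"):
            return np.corrcoef(ranks)
    if method == "partial":
        return _partial_correlation(x)
    raise ValueError(f"unknown correlation method {method!r}")


def _partial_correlation(x: np.ndarray) -> np.ndarray:
    """Shrinkage-regularized partial correlation between genes.

    The covariance of the standardized sample x gene matrix is estimated
    with Ledoit-Wolf shrinkage (well-conditioned even when genes outnumber
    samples), inverted, and the precision matrix is rescaled to partial
    correlations: pcor_ij = -theta_ij / sqrt(theta_ii * theta_jj).
    """
    z = x.T.astype(float)  # samples x genes
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=0)) / sd
    lw = LedoitWolf(assume_centered=True).fit(z)
    theta = lw.precision_
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def coexpression_class_features(
    expr: ExpressionMatrix,
    labels: pd.Series,
    method: str = "pearson",
    classes: tuple[str, ...] = ("SM", "GM", "DF"),
    per_group: bool = True,
) -> FeatureTable:
    """Median/maximum co-expression of each gene with each annotated class.

    For every gene (annotated or not) the correlation with every annotated
    gene of each class is computed, self-correlation excluded, and the
    median and maximum are recorded — per dataset group and over all
    samples combined.  An empty class after self-exclusion yields a missing
    value (never zero).
    """
    if expr.values.shape[1] < 3:
        raise ValueError("co-expression requires at least 3 samples")
    genes = expr.values.index
    groups: list[str | None] = ([*expr.group_names()] if per_group else []) + [None]
    blocks = []
    for group in groups:
        glabel = group if group is not None else "all"
        samples = expr.samples_in(group)
        if len(samples) < 3:
            raise ValueError(f"group {glabel!r} has fewer than 3 samples")
        corr = _correlation_matrix(expr.values[samples].to_numpy(float), method)
        np.fill_diagonal(corr, np.nan)  # self-exclusion
        cols = {}
        for cls in classes:
            members = labels.index[labels == cls]
            pos = genes.get_indexer(members.intersection(genes))
            pos = pos[pos >= 0]
            if len(pos) == 0:
                med = np.full(len(genes), np.nan)
                mx = np.full(len(genes), np.nan)
            else:
                sub = corr[:, pos]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    med = np.nanmedian(sub, axis=1)
                    mx = np.nanmax(
                        np.where(np.isnan(sub), -np.inf, sub), axis=1
                    )
                    mx[np.isinf(mx)] = np.nan
            cols[f"coexp_{method}_{glabel}_{cls}_median"] = med
            cols[f"coexp_{method}_{glabel}_{cls}_max"] = mx
        blocks.append(pd.DataFrame(cols, index=genes))
    values = pd.concat(blocks, axis=1)
    return FeatureTable(values=values, meta=_meta(values.columns, "coexpression", "continuous"))


CLUSTER_METHODS = ("kmeans", "cmeans", "hier_complete", "hier_average", "hier_ward")


def _fuzzy_cmeans(x: np.ndarray, k: int, rng: np.random.Generator, m: float = 2.0,
                  max_iter: int = 300, tol: float = 1e-6) -> np.ndarray:
    """Plain fuzzy c-means; returns hard assignments by argmax membership."""
    n = x.shape[0]
    u = rng.dirichlet(np.ones(k), size=n)  # n x k memberships
    for _ in range(max_iter):
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d = np.maximum(
            np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2), 1e-12
        )
        inv = d ** (-2.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return np.argmax(u, axis=1)


def cluster_module_features(
    expr: ExpressionMatrix, method: str, k: int, seed: int = 0
) -> FeatureTable:
    """Cluster genes into co-expression modules; emit 0/1 membership columns.

    Methods: k-means, fuzzy c-means (hardened to argmax membership), and
    complete/average/Ward hierarchical clustering on Euclidean distances.
    Each gene belongs to exactly one module per method/run.
    """
    if method not in CLUSTER_METHODS:
        raise ValueError(f"unknown clustering method {method!r}; choose from {CLUSTER_METHODS}")
    n = expr.values.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} genes")
    x = expr.values.to_numpy(float)
    if k == 1:
        assign = np.zeros(n, dtype=int)
    elif method == "kmeans":
        assign = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    elif method == "cmeans":
        assign = _fuzzy_cmeans(x, k, np.random.default_rng(seed))
    else:
        linkage = {"hier_complete": "complete", "hier_average": "average", "hier_ward": "ward"}[method]
        z = sch.linkage(pdist(x), method=linkage)
        assign = sch.fcluster(z, t=k, criterion="maxclust") - 1
    names = [f"mod_{method}_k{k}_{j:03d}" for j in range(k)]
    values = pd.DataFrame(0.0, index=expr.values.index, columns=names)
    for j in range(k):
        values.iloc[assign == j, j] = 1.0
    return FeatureTable(values=values, meta=_meta(names, "coexpression", "binary"))


def select_top_modules(
    modules: FeatureTable,
    train_labels: pd.Series,
    n: int = 200,
    mode: str = "ensemble_importance",
    seed: int = 0,
) -> FeatureTable:
    """Keep the top-n module columns best separating SM from GM training genes.

    ``ensemble_importance`` ranks modules by random-forest impurity
    importance fit on the training genes; ``fisher_score`` ranks by the
    per-column Fisher's exact test p-value of the 2x2 membership x class
    table (ascending).  Ties preserve input column order.  Ranking uses the
    supplied (training) labels only.
    """
    y = train_labels[train_labels.isin(["SM", "GM"])]
    if y.empty:
        raise ValueError("no SM/GM training labels supplied")
    x = modules.values.loc[y.index]
    if n >= x.shape[1]:
        return modules.subset(modules.feature_names)
    if mode == "ensemble_importance":
        rf = RandomForestClassifier(n_estimators=250, random_state=seed)
        rf.fit(x.to_numpy(), (y == "SM").to_numpy(int))
        score = -rf.feature_importances_  # ascending sort => most important first
    elif mode == "fisher_score":
        is_sm = (y == "SM").to_numpy()
        score = np.empty(x.shape[1])
        for j, col in enumerate(x.columns):
            member = x[col].to_numpy() > 0
            table = [
                [int((member & is_sm).sum()), int((member & ~is_sm).sum())],
                [int((~member & is_sm).sum()), int((~member & ~is_sm).sum())],
            ]
            score[j] = scipy.stats.fisher_exact(table)[1]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    order = np.argsort(score, kind="stable")[:n]
    keep = [modules.feature_names[j] for j in sorted(order)]
    return modules.subset(keep)


# ---------------------------------------------------------------------------
# genomic clustering and duplication


@dataclass
class GeneCoordinates:
    """Gene coordinates: chromosome, 1-based inclusive start/end, and the
    gene's rank index along its chromosome (consistent with start order)."""

    table: pd.DataFrame  # index: gene_id; columns: chrom, start, end, rank

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in coordinates")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise ValueError(f"start > end for genes: {self.table.index[bad].tolist()}")

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "GeneCoordinates":
        """Build from a frame with gene_id, chrom, start, end; ranks are
        assigned by start order within each chromosome."""
        t = df.set_index("gene_id")[["chrom", "start", "end"]].copy()
        t["rank"] = t.groupby("chrom")["start"].rank(method="first").astype(int) - 1
        return GeneCoordinates(t)


def genomic_cluster_counts(
    coords: GeneCoordinates,
    labels: pd.Series,
    window_bp: int = 10_000,
    window_genes: int = 10,
) -> FeatureTable:
    """Count annotated SM and GM neighbours in the same genomic cluster.

    Genes X and Y cluster together when they sit on the same chromosome, the
    gap between their nearest boundaries is <= ``window_bp`` (overlapping
    genes gap 0), AND their rank distance is <= ``window_genes``.  For each
    gene the qualifying neighbours annotated SM and GM are tallied
    separately.
    """
    t = coords.table
    genes = t.index
    out = pd.DataFrame(0.0, index=genes, columns=["cluster_n_SM", "cluster_n_GM"])
    lab = labels.reindex(genes)
    for _, sub in t.groupby("chrom"):
        sub = sub.sort_values("rank")
        ids = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        ranks = sub["rank"].to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ranks[j] - ranks[i] > window_genes:
                    break
                gap = max(0, max(starts[i], starts[j]) - min(ends[i], ends[j]))
                if gap > window_bp:
                    continue
                for a, b in ((i, j), (j, i)):
                    lb = lab.get(ids[b])
                    if lb == "SM":
                        out.loc[ids[a], "cluster_n_SM"] += 1
                    elif lb == "GM":
                        out.loc[ids[a], "cluster_n_GM"] += 1
    return FeatureTable(values=out, meta=_meta(out.columns, "duplication", "continuous"))


@dataclass
class ParalogTable:
    """Unordered within-species paralog pairs with optional upstream
    mechanism flags (syntenic/dispersed) and per-pair dN/dS."""

    table: pd.DataFrame  # columns: gene_a, gene_b, [syntenic, dispersed, dn_ds, pseudogene]

    def __post_init__(self) -> None:
        if (self.table["gene_a"] == self.table["gene_b"]).any():
            raise ValueError("self-pairs are not allowed in the paralog table")


def duplication_features(pairs: ParalogTable, coords: GeneCoordinates) -> FeatureTable:
    """Per-gene binary duplication-mechanism flags.

    ``tandem``: some paralog at rank distance 1 on the same chromosome.
    ``proximal``: some paralog at rank distance <= 10 on the same
    chromosome that is not tandem.  ``syntenic``/``dispersed``/
    ``pseudogene_paralog`` are passed through from upstream flags (a gene is
    flagged when any of its pairs is flagged).
    """
    t = coords.table
    genes = t.index
    cols = ["dup_tandem", "dup_proximal", "dup_syntenic", "dup_dispersed", "dup_pseudogene_paralog"]
    out = pd.DataFrame(0.0, index=genes, columns=cols)
    for row in pairs.table.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a not in genes or b not in genes:
            raise ValueError(f"paralog pair references unknown gene: ({a}, {b})")
        same_chrom = t.loc[a, "chrom"] == t.loc[b, "chrom"]
        dist = abs(int(t.loc[a, "rank"]) - int(t.loc[b, "rank"])) if same_chrom else None
        for g in (a, b):
            if same_chrom and dist == 1:
                out.loc[g, "dup_tandem"] = 1.0
            elif same_chrom and dist is not None and dist <= 10:
                out.loc[g, "dup_proximal"] = 1.0
            for flag, col in (
                ("syntenic", "dup_syntenic"),
                ("dispersed", "dup_dispersed"),
                ("pseudogene", "dup_pseudogene_paralog"),
            ):
                if flag in pairs.table.columns and bool(getattr(row, flag)):
                    out.loc[g, col] = 1.0
    return FeatureTable(values=out, meta=_meta(cols, "duplication", "binary"))


# ---------------------------------------------------------------------------
# evolutionary summaries


@dataclass
class HomologyTable:
    """Cross-species homolog rows and per-gene orthogroup membership.

    ``pairs``: rows of (gene, species, dn_ds) — one row per homolog
    comparison; rows whose species equals the focal species are paralog
    comparisons.  ``orthogroup``: focal-species gene -> orthogroup id.
    ``node``: optional per-gene most-recent duplication node index (0..24).
    ``pseudogene_paralog``: optional per-gene 0/1 flag.
    """

    pairs: pd.DataFrame
    orthogroup: pd.Series
    node: pd.Series | None = None
    pseudogene_paralog: pd.Series | None = None
    node_range: tuple[int, int] = (0, 24)

    def __post_init__(self) -> None:
        if (self.pairs["dn_ds"] < 0).any():
            raise ValueError("dN/dS must be non-negative")
        if self.node is not None:
            lo, hi = self.node_range
            bad = ~self.node.dropna().between(lo, hi)
            if bad.any():
                raise ValueError(f"duplication node outside {self.node_range}")


def evolutionary_summaries(hom: HomologyTable, focal_species: str) -> FeatureTable:
    """Per-gene evolutionary features.

    For each non-focal species: a homolog-presence flag and the median and
    max dN/dS to that species' homologs (missing when no homolog exists).
    Rows against the focal species itself summarize paralog dN/dS.  Family
    size is the number of focal-species genes sharing the gene's orthogroup.
    The most-recent duplication node and pseudogene-paralog flags pass
    through when provided.
    """
    genes = pd.Index(sorted(hom.orthogroup.index), name="gene_id")
    blocks = {}
    for sp, sub in hom.pairs.groupby("species"):
        agg = sub.groupby("gene")["dn_ds"].agg(["median", "max"])
        prefix = "paralog" if sp == focal_species else f"homolog_{sp}"
        if sp != focal_species:
            blocks[f"{prefix}_presence"] = pd.Series(1.0, index=agg.index).reindex(genes).fillna(0.0)
        blocks[f"{prefix}_dnds_median"] = agg["median"].reindex(genes)
        blocks[f"{prefix}_dnds_max"] = agg["max"].reindex(genes)
    fam = hom.orthogroup.map(hom.orthogroup.value_counts())
    blocks["family_size"] = fam.reindex(genes).astype(float)
    if hom.node is not None:
        blocks["duplication_node"] = hom.node.reindex(genes).astype(float)
    if hom.pseudogene_paralog is not None:
        blocks["pseudogene_paralog"] = hom.pseudogene_paralog.reindex(genes).astype(float)
    values = pd.DataFrame(blocks, index=genes)
    kinds = {
        name: "binary" if name.endswith("_presence") or name == "pseudogene_paralog" else "continuous"
        for name in values.columns
    }
    meta = pd.DataFrame(
        {"category": "evolution", "kind": pd.Series(kinds), "shared": False}
    )
    meta.index.name = "feature"
    return FeatureTable(values=values, meta=meta.loc[values.columns])


# ---------------------------------------------------------------------------
# missing values and cross-species harmonization


def impute_missing(
    table: FeatureTable, train_genes: pd.Index | None = None
) -> FeatureTable:
    """Fill missing values: binary -> 0; continuous -> median of the column
    computed on training genes only (leakage-safe)."""
    values = table.values.copy()
    ref = values.loc[train_genes] if train_genes is not None else values
    for name in values.columns:
        if table.meta.loc[name, "kind"] == "binary":
            values[name] = values[name].fillna(0.0)
        else:
            med = ref[name].median()
            values[name] = values[name].fillna(0.0 if pd.isna(med) else med)
    return FeatureTable(values=values, meta=table.meta.copy())


def harmonize_shared_features(
    table_a: FeatureTable, table_b: FeatureTable, shared_names
) -> tuple[FeatureTable, FeatureTable]:
    """Restrict two species' tables to the shared features and normalize.

    Continuous shared columns are z-scored within each species independently
    (population standard deviation) so values are comparable across species;
    binary columns pass through.  Both outputs carry the shared columns in
    identical order and are tagged ``harmonized`` so downstream model
    application can verify its input.  A constant continuous column becomes
    all zeros with a logged warning.
    """
    shared_names = list(shared_names)
    for side, table in (("A", table_a), ("B", table_b)):
        missing = [n for n in shared_names if n not in table.values.columns]
        if missing:
            raise KeyError(f"shared features missing in table {side}: {missing}")
    for name in shared_names:
        ka = table_a.meta.loc[name, "kind"]
        kb = table_b.meta.loc[name, "kind"]
        if ka != kb:
            raise ValueError(f"feature {name!r} kind mismatch: {ka} vs {kb}")
    out = []
    for table in (table_a, table_b):
        sub = table.subset(shared_names)
        values = sub.values
        for name in shared_names:
            if sub.meta.loc[name, "kind"] != "continuous":
                continue
            col = values[name].to_numpy(float)
            sd = np.std(col)
            if sd == 0 or np.isnan(sd):
                logger.warning("constant continuous shared feature %r set to zeros", name)
                values[name] = 0.0
            else:
                values[name] = (col - np.mean(col)) / sd
        values.attrs["harmonized"] = True
        out.append(FeatureTable(values=values, meta=sub.meta))
    return out[0], out[1]
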