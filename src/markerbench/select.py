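"""Native marker-gene selection strategies.

Each method maps (log-normalized matrix, cluster assignment) to a ranked
MarkerTable with a controllable number of genes per cluster:

* ``wilcoxon_markers``  — one-vs-rest Wilcoxon rank-sum (Seurat-style DE)
* ``kruskal_markers``   — all-cluster Kruskal–Wallis (SC3-style DE)
* ``cosg_markers``      — cosine similarity to the cluster indicator, with a
  cross-cluster penalty (COSG-style)
* ``scmarker_markers``  — bimodality (mixture-BIC) + co-/mutual-exclusion
  filtering, then per-cluster assignment by mean expression (SCMarker-style)
* ``hgt_markers``       — minimal hypergeometric enrichment over expression
  cuts with BH correction (COMET-style, single genes only)
* ``hvg_baseline``      — globally highly variable genes as a non-specific
  control
* ``run_plugin``        — external command producing a standard markers.csv

All methods consume log-normalized (not scaled) expression and break ranking
ties by gene list order (stable sort), so results are reproducible.
"""

from __future__ import annotations

import logging
import os
import subprocess
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, PluginError, ValidationError
from .io import ClusterAssignment, MarkerTable, read_marker_csv
from .prepare import NormMatrix, hvg_dispersion, select_hvg

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "wilcoxon_markers",
    "kruskal_markers",
    "cosg_markers",
    "scmarker_markers",
    "hgt_markers",
    "hvg_baseline",
    "run_plugin",
    "pooled_unique_genes",
    "METHODS",
]

_P_FLOOR = 1e-300  # avoid -log10(0) in scores


@dataclass
class SelectionConfig:
    """Shared and method-specific selection hyperparameters."""

    n_per_cluster: int = 10
    cosg_mu: float = 1.0          # cross-cluster penalty weight
    hgt_fdr: float = 0.05         # BH threshold for the hypergeometric method
    scm_bic_margin: float = 10.0  # required BIC gain of 2- over 1-component fit
    scm_min_partners: int = 5     # co-occurrence partners required to survive
    logfc_floor: float = 0.0      # minimum mean log difference (wilcoxon/kruskal)

    def __post_init__(self):
        if self.n_per_cluster < 1:
            raise ValidationError("n_per_cluster must be >= 1")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _membership(norm: NormMatrix, clusters: ClusterAssignment) -> np.ndarray:
    """Boolean cells x clusters matrix following cluster_order."""
    missing = [b for b in norm.barcodes if b not in clusters.labels]
    if missing:
        raise ValidationError(
            f"{len(missing)} barcodes lack a cluster assignment (e.g. {missing[0]!r})"
        )
    codes = clusters.as_codes(norm.barcodes)
    k = len(clusters.cluster_order)
    member = np.zeros((len(norm.barcodes), k), dtype=bool)
    member[np.arange(len(codes)), codes] = True
    return member


def _require_multi(clusters: ClusterAssignment) -> None:
    if len(clusters.cluster_order) < 2:
        raise ValidationError("one-vs-rest selection requires at least two clusters")


def _tie_term(X: np.ndarray) -> np.ndarray:
    """Per-gene sum of t^3 - t over tied groups (for rank-test variances)."""
    n, g = X.shape
    out = np.zeros(g)
    Xs = np.sort(X, axis=0)
    for j in range(g):
        _, counts = np.unique(Xs[:, j], return_counts=True)
        t = counts[counts > 1].astype(float)
        out[j] = np.sum(t**3 - t)
    return out


def _table(cluster_order, per_cluster: dict[str, list[tuple[str, float]]]) -> MarkerTable:
    recs = []
    for cl in cluster_order:
        for rank, (gene, score) in enumerate(per_cluster.get(cl, []), start=1):
            recs.append((cl, rank, gene, score))
    df = pd.DataFrame(recs, columns=["cluster", "rank", "gene", "score"])
    return MarkerTable(df)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# rank-based DE methods
# ---------------------------------------------------------------------------

def wilcoxon_markers(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """One-vs-rest two-sided Wilcoxon rank-sum markers per cluster.

    Uses the normal approximation with tie and continuity corrections. Genes
    with positive in-minus-rest mean log difference are ranked by ascending
    p, then descending mean difference; score is -log10(p).
    """
    _require_multi(clusters)
    X = norm.values
    n, _ = X.shape
    member = _membership(norm, clusters)
    ranks = stats.rankdata(X, axis=0)
    ties = _tie_term(X)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        ingrp = member[:, ki]
        n1 = int(ingrp.sum())
        n2 = n - n1
        W = ranks[ingrp].sum(axis=0)
        mu = n1 * (n + 1) / 2.0
        var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1.0)))
        diff = W - mu
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        p = np.clip(p, _P_FLOOR, 1.0)
        lfc = X[ingrp].mean(axis=0) - X[~ingrp].mean(axis=0)
        cand = np.flatnonzero(lfc > cfg.logfc_floor)
        order = cand[np.lexsort((cand, -lfc[cand], p[cand]))]
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [(norm.genes[j], -np.log10(p[j])) for j in top]
    return _table(clusters.cluster_order, per_cluster)


def kruskal_markers(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """Kruskal–Wallis markers: test across all clusters, assign by max mean.

    Per gene the tie-corrected H statistic is referred to a chi-square with
    k-1 degrees of freedom; each gene goes to the cluster with the highest
    mean expression and clusters rank their genes by ascending p.
    """
    _require_multi(clusters)
    X = norm.values
    n, _ = X.shape
    member = _membership(norm, clusters)
    sizes = member.sum(axis=0).astype(float)
    ranks = stats.rankdata(X, axis=0)
    mean_ranks = (member.T.astype(float) @ ranks) / sizes[:, None]  # k x genes
    H = 12.0 / (n * (n + 1)) * (sizes[:, None] * (mean_ranks - (n + 1) / 2.0) ** 2).sum(axis=0)
    correction = 1.0 - _tie_term(X) / (n**3 - n)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(correction > 0, H / np.where(correction > 0, correction, 1.0), 0.0)
    dof = len(clusters.cluster_order) - 1
    p = np.clip(stats.chi2.sf(H, dof), _P_FLOOR, 1.0)
    p[H == 0] = 1.0

    means = (member.T.astype(float) @ X) / sizes[:, None]  # k x genes
    assigned = means.argmax(axis=0)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        cand = np.flatnonzero(assigned == ki)
        if cand.size:
            ingrp = member[:, ki]
            lfc = X[np.ix_(ingrp, cand)].mean(axis=0) - X[np.ix_(~ingrp, cand)].mean(axis=0)
            cand = cand[lfc > cfg.logfc_floor]
        order = cand[np.lexsort((cand, p[cand]))]
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [(norm.genes[j], -np.log10(p[j])) for j in top]
    return _table(clusters.cluster_order, per_cluster)


# ---------------------------------------------------------------------------
# cosine-similarity method
# ---------------------------------------------------------------------------

def cosine_to_clusters(norm: NormMatrix, clusters: ClusterAssignment) -> np.ndarray:
    """cos(x_g, one-hot cluster indicator) for every gene and cluster (k x genes)."""
    X = norm.values
    member = _membership(norm, clusters).astype(float)
    sizes = member.sum(axis=0)
    gene_norm = np.linalg.norm(X, axis=0)
    dots = member.T @ X  # k x genes: sum of expression inside each cluster
    denom = np.sqrt(sizes)[:, None] * gene_norm[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    return cos


def cosg_markers(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """Penalized cosine-similarity markers.

    The raw affinity of gene g for cluster k is the cosine between the gene's
    expression vector and the one-hot indicator of the cluster; the score
    down-weights genes that also resemble other clusters:

        score_gk = cos_gk * cos_gk^2 / (cos_gk^2 + mu * sum_{k'!=k} cos_gk'^2)

    At mu = 0 the score reduces exactly to the raw cosine; keeping the cosine
    magnitude in the numerator prevents genes expressed in a handful of
    cluster-exclusive cells (zero penalty term) from saturating the score.
    Remaining ties fall back to the raw cosine, then gene order.
    """
    _require_multi(clusters)
    cos = cosine_to_clusters(norm, clusters)
    c2 = cos**2
    total = c2.sum(axis=0)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        denom = c2[ki] + cfg.cosg_mu * (total - c2[ki])
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(denom > 0, cos[ki] * c2[ki] / np.where(denom > 0, denom, 1.0), 0.0)
        order = np.lexsort((np.arange(len(score)), -cos[ki], -score))
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [(norm.genes[j], score[j]) for j in top]
    return _table(clusters.cluster_order, per_cluster)


# ---------------------------------------------------------------------------
# bimodality / co-exclusion method
# ---------------------------------------------------------------------------

def _bimodal_candidates(X: np.ndarray, bic_margin: float) -> list[int]:
    from sklearn.mixture import GaussianMixture

    cands = []
    for j in range(X.shape[1]):
        v = X[:, j : j + 1]
        if len(np.unique(v)) < 2:
            continue
        gm1 = GaussianMixture(1, random_state=0).fit(v)
        gm2 = GaussianMixture(2, random_state=0, n_init=1).fit(v)
        if gm1.bic(v) - gm2.bic(v) >= bic_margin:
            cands.append(j)
    return cands


def _binarize_bimodal(X: np.ndarray, cands: list[int]) -> np.ndarray:
    """1 = cell assigned to the higher-mean mixture component."""
    from sklearn.mixture import GaussianMixture

    B = np.zeros((X.shape[0], len(cands)), dtype=bool)
    for c, j in enumerate(cands):
        v = X[:, j : j + 1]
        gm = GaussianMixture(2, random_state=0).fit(v)
        hi = int(np.argmax(gm.means_.ravel()))
        B[:, c] = gm.predict(v) == hi
    return B


def _cooccurrence_partners(B: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Count, per candidate, partners with a significant 2x2 association."""
    n, c = B.shape
    Bf = B.astype(float)
    n11 = Bf.T @ Bf
    s = Bf.sum(axis=0)
    n10 = s[:, None] - n11
    n01 = s[None, :] - n11
    n00 = n - n11 - n10 - n01
    row = s[:, None] * (n - s)[:, None]
    col = s[None, :] * (n - s)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(
            (row > 0) & (col > 0),
            n * (n11 * n00 - n10 * n01) ** 2 / np.where((row > 0) & (col > 0), row * col, 1.0),
            0.0,
        )
    pvals = stats.chi2.sf(chi2, df=1)
    np.fill_diagonal(pvals, 1.0)
    return (pvals < alpha).sum(axis=1)


def scmarker_markers(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """Bimodal, co-expression-supported markers assigned by top expression.

    Stage 1 keeps genes whose two-component Gaussian mixture beats the
    one-component fit by at least ``scm_bic_margin`` BIC. Stage 2 binarizes
    each candidate at its mixture decision boundary and keeps candidates with
    at least ``scm_min_partners`` other candidates showing a chi-square
    2x2 association at p < 0.01 (co-occurrence or mutual exclusion). Stage 3
    hands each cluster its ``n_per_cluster`` surviving genes with the highest
    in-cluster mean expression.
    """
    X = norm.values
    member = _membership(norm, clusters)
    cands = _bimodal_candidates(X, cfg.scm_bic_margin)
    if cands:
        B = _binarize_bimodal(X, cands)
        partners = _cooccurrence_partners(B)
        survivors = [j for j, k in zip(cands, partners) if k >= cfg.scm_min_partners]
    else:
        survivors = []
    if not survivors:
        logger.warning("scmarker_markers: no candidate genes survived filtering")
        return _table(clusters.cluster_order, {})
    surv = np.array(survivors)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        means = X[np.ix_(member[:, ki], surv)].mean(axis=0)
        order = np.lexsort((surv, -means))
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [(norm.genes[surv[j]], means[j]) for j in top]
    return _table(clusters.cluster_order, per_cluster)


# ---------------------------------------------------------------------------
# minimal hypergeometric method
# ---------------------------------------------------------------------------

def min_hypergeom_p(values: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Minimal hypergeometric enrichment p over expression cuts, per cluster.

    For each distinct expression value the cells strictly above that cut form
    the drawn sample; the upper-tail hypergeometric p measures enrichment of
    the cluster among them. The all-cells cut (p = 1) is always included, so
    a constant gene scores exactly 1.
    """
    n = len(values)
    order = np.argsort(-values, kind="stable")
    v = values[order]
    boundary = np.flatnonzero(v[:-1] > v[1:]) + 1  # prefix lengths at value changes
    m = np.concatenate([boundary, [n]])
    cums = np.cumsum(member[order].astype(np.int64), axis=0)  # n x k
    k_above = cums[m - 1]  # cuts x k
    K = member.sum(axis=0)
    p = stats.hypergeom.sf(k_above - 1, n, K[None, :], m[:, None])
    return p.min(axis=0)


def hgt_markers(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """Minimal-hypergeometric markers with per-cluster BH correction.

    Each gene's score for a cluster is its minimal hypergeometric enrichment
    p over expression cuts; within each cluster the p-values are BH-adjusted
    across genes, genes at adjusted p <= hgt_fdr are kept, and the top
    ``n_per_cluster`` by ascending adjusted p are reported with score
    -log10(adjusted p).
    """
    X = norm.values
    member = _membership(norm, clusters)
    g = X.shape[1]
    k = member.shape[1]
    pmat = np.empty((g, k))
    for j in range(g):
        pmat[j] = min_hypergeom_p(X[:, j], member)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        padj = _bh(pmat[:, ki])
        cand = np.flatnonzero(padj <= cfg.hgt_fdr)
        order = cand[np.lexsort((cand, padj[cand]))]
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [
            (norm.genes[j], -np.log10(max(padj[j], _P_FLOOR))) for j in top
        ]
    return _table(clusters.cluster_order, per_cluster)


# ---------------------------------------------------------------------------
# baseline, plugin, pooling
# ---------------------------------------------------------------------------

def hvg_baseline(
    norm: NormMatrix, clusters: ClusterAssignment, cfg: SelectionConfig = SelectionConfig()
) -> MarkerTable:
    """Globally highly variable genes as a non-specific control method.

    Selects n_per_cluster x #clusters top HVGs, assigns each to the cluster
    with the highest mean expression, and re-ranks within cluster by
    standardized dispersion.
    """
    member = _membership(norm, clusters)
    sizes = member.sum(axis=0).astype(float)
    k = len(clusters.cluster_order)
    pool = select_hvg(norm, cfg.n_per_cluster * k)
    disp = hvg_dispersion(norm)
    means = (member.T.astype(float) @ norm.values[:, pool]) / sizes[:, None]
    assigned = means.argmax(axis=0)
    per_cluster: dict[str, list[tuple[str, float]]] = {}
    for ki, cl in enumerate(clusters.cluster_order):
        cand = pool[assigned == ki]
        order = cand[np.lexsort((cand, -disp[cand]))]
        top = order[: cfg.n_per_cluster]
        per_cluster[cl] = [(norm.genes[j], disp[j]) for j in top]
    return _table(clusters.cluster_order, per_cluster)


def run_plugin(
    command_template: str, norm_path: str, clusters_path: str, out_path: str
) -> MarkerTable:
    """Run an external selection command and parse its markers.csv output.

    The template may reference {norm}, {clusters} and {out}. A nonzero exit
    or missing/unparseable output raises PluginError carrying the captured
    stderr; structurally invalid tables raise ValidationError like built-ins.
    """
    cmd = command_template.format(norm=norm_path, clusters=clusters_path, out=out_path)
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise PluginError(
            f"plugin exited with status {proc.returncode}: {cmd}", stderr=proc.stderr
        )
    if not os.path.exists(out_path):
        raise PluginError(f"plugin produced no output at {out_path}", stderr=proc.stderr)
    try:
        return read_marker_csv(out_path)
    except FormatError as exc:
        raise PluginError(f"plugin output malformed: {exc}", stderr=proc.stderr) from exc


def pooled_unique_genes(table: MarkerTable) -> tuple[set[str], int]:
    """Non-redundant union of marker genes across clusters, with its size."""
    genes = set(table.df["gene"])
    return genes, len(genes)


METHODS = {
    "wilcoxon": wilcoxon_markers,
    "kruskal": kruskal_markers,
    "cosg": cosg_markers,
    "scmarker": scmarker_markers,
    "hgt": hgt_markers,
    "hvg": hvg_baseline,
}
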