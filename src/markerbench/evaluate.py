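"""Marker evaluation: re-clustering agreement metrics and precision/recall.

The central object is the contingency table n_ij between an observed
partition C^o (obtained by re-clustering the cells on the selected marker
genes alone) and an expected partition C^E (the reference cluster labels).
From it the report computes ARI, a best-match mean Jaccard index, purity,
NMI and the Fowlkes–Mallows index; if known marker genes are supplied,
per-cluster and pooled precision/recall are added.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ClusterAssignment, KnownMarkerSet, MarkerTable
from .prepare import NormMatrix, scale_genes
from .select import pooled_unique_genes

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "PairCounts",
    "InformationTerms",
    "EvalReport",
    "build_contingency",
    "pair_counts",
    "adjusted_rand_index",
    "jaccard_pair",
    "jaccard_overall",
    "nmi",
    "information_terms",
    "fmi",
    "purity",
    "recluster",
    "marker_precision_recall",
    "standard_scale_matrix",
    "evaluate_markers",
]


# ---------------------------------------------------------------------------
# contingency table and pair counts
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Cell counts n_ij by (observed cluster i, expected cluster j)."""

    n_ij: np.ndarray
    obs_labels: list[str] = field(default_factory=list)
    exp_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.n_ij = np.asarray(self.n_ij, dtype=np.int64)
        if self.n_ij.ndim != 2 or (self.n_ij < 0).any():
            raise ValidationError("contingency table must be 2-D and non-negative")
        if not self.obs_labels:
            self.obs_labels = [str(i) for i in range(self.n_ij.shape[0])]
        if not self.exp_labels:
            self.exp_labels = [str(j) for j in range(self.n_ij.shape[1])]

    @property
    def row_margins(self) -> np.ndarray:  # n_i.
        return self.n_ij.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:  # n_.j
        return self.n_ij.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.n_ij.sum())


@dataclass
class PairCounts:
    """Unordered cell pairs cross-classified by same/different cluster."""

    TP: int
    FP: int
    FN: int
    TN: int


@dataclass
class InformationTerms:
    mutual_info: float  # nats
    entropy_obs: float
    entropy_exp: float


def build_contingency(obs: ClusterAssignment, exp: ClusterAssignment) -> ContingencyTable:
    """Exact cross-tabulation of two partitions over the same barcodes."""
    if set(obs.labels) != set(exp.labels):
        raise ValidationError("observed and expected partitions cover different barcodes")
    barcodes = obs.barcodes
    oi = obs.as_codes(barcodes)
    ej = exp.as_codes(barcodes)
    k_o = len(obs.cluster_order)
    k_e = len(exp.cluster_order)
    table = np.bincount(oi * k_e + ej, minlength=k_o * k_e).reshape(k_o, k_e)
    return ContingencyTable(table, list(obs.cluster_order), list(exp.cluster_order))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def pair_counts(t: ContingencyTable) -> PairCounts:
    """Derive TP/FP/FN/TN pair counts from the contingency table."""
    tp = _comb2(t.n_ij).sum()
    same_obs = _comb2(t.row_margins).sum()
    same_exp = _comb2(t.col_margins).sum()
    total = _comb2(np.array([t.n])).sum()
    fp = same_obs - tp
    fn = same_exp - tp
    tn = total - tp - fp - fn
    return PairCounts(int(tp), int(fp), int(fn), int(tn))


# ---------------------------------------------------------------------------
# partition metrics
# ---------------------------------------------------------------------------

def adjusted_rand_index(t: ContingencyTable) -> float:
    """Adjusted Rand index of the two partitions.

    (sum_ij C(n_ij,2) - E) / (max - E) with E the chance expectation
    C(n_i.,2)-by-C(n_.j,2) products over C(n,2). Can be negative for
    worse-than-chance agreement; not clamped.
    """
    n = t.n
    if n < 2:
        raise ValidationError("ARI undefined for fewer than 2 cells")
    index = _comb2(t.n_ij).sum()
    sum_rows = _comb2(t.row_margins).sum()
    sum_cols = _comb2(t.col_margins).sum()
    expected = sum_rows * sum_cols / _comb2(np.array([n]))[0]
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial or chance-saturated
        return 1.0 if index == expected else 0.0
    return float((index - expected) / (max_index - expected))


def jaccard_pair(t: ContingencyTable, i: int, j: int) -> float:
    """Jaccard index of observed cluster i vs expected cluster j."""
    nij = t.n_ij[i, j]
    union = t.row_margins[i] + t.col_margins[j] - nij
    return float(nij / union) if union > 0 else 0.0


def jaccard_overall(t: ContingencyTable, matching: str = "best") -> float:
    """Mean cluster-wise Jaccard index.

    ``best`` (default): each expected cluster contributes the Jaccard index
    of its best-matching observed cluster. ``all_pairs``: plain mean over
    every (i, j) pair (vanishes with cluster count; kept as an option).
    """
    ji = np.zeros(t.n_ij.shape)
    for i in range(t.n_ij.shape[0]):
        for j in range(t.n_ij.shape[1]):
            ji[i, j] = jaccard_pair(t, i, j)
    if matching == "best":
        return float(ji.max(axis=0).mean())
    if matching == "all_pairs":
        return float(ji.mean())
    raise ValueError(f"unknown matching rule {matching!r}")


def information_terms(t: ContingencyTable) -> InformationTerms:
    """Mutual information and marginal entropies (natural log, 0·log0 = 0)."""
    n = t.n
    pij = t.n_ij / n
    pi = t.row_margins / n
    pj = t.col_margins / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = pij * np.log(pij / (pi[:, None] * pj[None, :]))
    mi = float(np.nansum(terms))
    h_obs = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h_exp = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    return InformationTerms(mutual_info=max(mi, 0.0), entropy_obs=h_obs, entropy_exp=h_exp)


def nmi(t: ContingencyTable) -> float:
    """Normalized mutual information I / sqrt(H_obs * H_exp)."""
    info = information_terms(t)
    denom = math.sqrt(info.entropy_obs * info.entropy_exp)
    if denom == 0:
        logger.warning("nmi: a partition is trivial (zero entropy); defined as 0")
        return 0.0
    return float(min(info.mutual_info / denom, 1.0))


def fmi(t: ContingencyTable) -> float:
    """Fowlkes–Mallows index: geometric mean of pairwise precision and recall."""
    pc = pair_counts(t)
    if pc.TP == 0 or (pc.TP + pc.FP) == 0 or (pc.TP + pc.FN) == 0:
        return 0.0
    return float(math.sqrt(pc.TP / (pc.TP + pc.FP) * pc.TP / (pc.TP + pc.FN)))


def purity(t: ContingencyTable) -> float:
    """Fraction of cells in their observed cluster's dominant expected label."""
    return float(t.n_ij.max(axis=1).sum() / t.n)


# ---------------------------------------------------------------------------
# re-clustering
# ---------------------------------------------------------------------------

def recluster(
    norm: NormMatrix,
    markers: MarkerTable,
    seed: int = 0,
    resolution: float = 0.8,
    n_neighbors: int = 20,
    n_components: int = 30,
) -> ClusterAssignment:
    """Leiden community detection on a kNN graph over the marker genes.

    The scaled matrix is restricted to the pooled unique marker genes; when
    more than ``n_components`` markers remain, PCA reduces to that many
    directions before the Euclidean kNN graph (k = min(n_neighbors, n-1)) is
    built. Modularity communities are found with a fixed seed, so identical
    inputs yield identical partitions.
    """
    import igraph
    import leidenalg
    from sklearn.decomposition import PCA
    from sklearn.neighbors import NearestNeighbors

    genes, _ = pooled_unique_genes(markers)
    index = {g: i for i, g in enumerate(norm.genes)}
    present = sorted((index[g] for g in genes if g in index))
    missing = sorted(g for g in genes if g not in index)
    if not present:
        raise ValidationError(f"no marker gene found in matrix; missing: {missing}")
    if missing:
        logger.warning("recluster: %d marker genes absent from matrix", len(missing))

    scaled = norm.scaled if norm.scaled is not None else scale_genes(norm).scaled
    X = scaled[:, present]
    n = X.shape[0]
    if X.shape[1] > n_components:
        X = PCA(
            n_components=min(n_components, n - 1), svd_solver="full", random_state=seed
        ).fit_transform(X)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(a, b), max(a, b)) for a, row in enumerate(idx) for b in row if a != b}
    graph = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = {bc: str(m) for bc, m in zip(norm.barcodes, part.membership)}
    return ClusterAssignment(labels=labels)


# ---------------------------------------------------------------------------
# known-marker precision / recall and reporting
# ---------------------------------------------------------------------------

def marker_precision_recall(
    predicted: MarkerTable, known: KnownMarkerSet
) -> tuple[dict[str, float], dict[str, float], float | None, float | None]:
    """Per-cluster and pooled precision/recall of predicted vs known markers.

    Gene symbols are compared case-sensitively. Clusters with an empty known
    set are excluded from the per-cluster maps; the pooled scores use the
    unions of predicted and known genes over all clusters.
    """
    if len(predicted) == 0:
        logger.warning("marker_precision_recall: empty predicted table; precision undefined")
        return {}, {}, None, None
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for cl, kn in known.items():
        if not kn:
            continue
        pred = set(predicted.genes_for(cl))
        hits = len(pred & set(kn))
        if pred:
            precision[cl] = hits / len(pred)
        recall[cl] = hits / len(kn)
    pred_union = set(predicted.df["gene"])
    known_union = set().union(*known.values()) if known else set()
    overall_p = len(pred_union & known_union) / len(pred_union) if pred_union else None
    overall_r = len(pred_union & known_union) / len(known_union) if known_union else None
    return precision, recall, overall_p, overall_r


def standard_scale_matrix(
    norm: NormMatrix, clusters: ClusterAssignment, markers: MarkerTable
) -> pd.DataFrame:
    """Min–max standardized cluster-mean expression of the marker genes.

    Rows are marker genes (pooled, in first-appearance order), columns are
    clusters; each row is shifted by its minimum and divided by the resulting
    maximum, so non-constant rows span exactly [0, 1] and constant rows are 0.
    """
    genes = list(dict.fromkeys(markers.df["gene"]))
    index = {g: i for i, g in enumerate(norm.genes)}
    rows = []
    codes = clusters.as_codes(norm.barcodes)
    for g in genes:
        if g not in index:
            raise ValidationError(f"marker gene {g!r} absent from matrix")
        v = norm.values[:, index[g]]
        means = np.array(
            [v[codes == ki].mean() for ki in range(len(clusters.cluster_order))]
        )
        shifted = means - means.min()
        rows.append(shifted / shifted.max() if shifted.max() > 0 else shifted * 0.0)
    return pd.DataFrame(rows, index=genes, columns=clusters.cluster_order)


@dataclass
class EvalReport:
    """Full benchmark report for one marker selection."""

    ari: float
    jaccard_overall: float
    purity: float
    nmi: float
    fmi: float
    per_cluster_precision: dict[str, float] | None = None
    per_cluster_recall: dict[str, float] | None = None
    overall_precision: float | None = None
    overall_recall: float | None = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "ari": self.ari,
            "jaccard_overall": self.jaccard_overall,
            "purity": self.purity,
            "nmi": self.nmi,
            "fmi": self.fmi,
        }
        if self.overall_precision is not None or self.per_cluster_precision is not None:
            out["per_cluster_precision"] = self.per_cluster_precision
            out["per_cluster_recall"] = self.per_cluster_recall
            out["overall_precision"] = self.overall_precision
            out["overall_recall"] = self.overall_recall
        out["metadata"] = self.metadata
        return out


def evaluate_markers(
    norm: NormMatrix,
    markers: MarkerTable,
    reference_clusters: ClusterAssignment,
    known: KnownMarkerSet | None = None,
    seed: int = 0,
    resolution: float = 0.8,
) -> EvalReport:
    """Re-cluster on the markers and score agreement with the reference.

    Runs recluster -> contingency -> ARI/Jaccard/purity/NMI/FMI, plus
    precision/recall when known markers are supplied. Fully deterministic
    given the seed.
    """
    observed = recluster(norm, markers, seed=seed, resolution=resolution)
    table = build_contingency(observed, reference_clusters)
    _, n_pooled = pooled_unique_genes(markers)
    report = EvalReport(
        ari=adjusted_rand_index(table),
        jaccard_overall=jaccard_overall(table),
        purity=purity(table),
        nmi=nmi(table),
        fmi=fmi(table),
        metadata={
            "n_pooled_genes": n_pooled,
            "n_observed_clusters": len(observed.cluster_order),
            "n_expected_clusters": len(reference_clusters.cluster_order),
            "seed": seed,
            "resolution": resolution,
        },
    )
    if known is not None:
        pc_p, pc_r, ov_p, ov_r = marker_precision_recall(markers, known)
        report.per_cluster_precision = pc_p
        report.per_cluster_recall = pc_r
        report.overall_precision = ov_p
        report.overall_recall = ov_r
    return report
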