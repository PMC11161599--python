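import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from markerbench.errors import PluginError, ValidationError
from markerbench.io import ClusterAssignment, MarkerTable
from markerbench.prepare import NormMatrix
from markerbench.select import (
    METHODS,
    SelectionConfig,
    cosg_markers,
    cosine_to_clusters,
    hgt_markers,
    hvg_baseline,
    kruskal_markers,
    min_hypergeom_p,
    pooled_unique_genes,
    run_plugin,
    scmarker_markers,
    wilcoxon_markers,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y):
    """Two-sided exact Wilcoxon rank-sum p by enumerating all group splits."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1 = len(x)
    mu = n1 * (len(combined) + 1) / 2.0
    w_obs = ranks[: n1].sum()
    hits = total = 0
    for subset in itertools.combinations(range(len(combined)), n1):
        total += 1
        if abs(ranks[list(subset)].sum() - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def kruskal_h_oracle(groups):
    """H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2, tie-corrected."""
    combined = np.concatenate(groups)
    ranks = stats.rankdata(combined)
    n = len(combined)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(combined, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction if correction > 0 else 0.0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _norm_from_groups(groups):
    """One-gene matrix whose cells are the concatenated group values."""
    values = np.concatenate(groups)[:, None]
    barcodes = [f"c{i}" for i in range(len(values))]
    labels = {}
    start = 0
    for gi, g in enumerate(groups):
        for i in range(start, start + len(g)):
            labels[barcodes[i]] = chr(ord("A") + gi)
        start += len(g)
    norm = NormMatrix(values, barcodes, ["g0"])
    return norm, ClusterAssignment(labels)


def _score_of(table: MarkerTable, cluster, gene):
    row = table.df[(table.df.cluster == cluster) & (table.df.gene == gene)]
    assert len(row) == 1
    return float(row.score.iloc[0])


# ---------------------------------------------------------------------------
# wilcoxon
# ---------------------------------------------------------------------------

def test_wilcoxon_worked_example_exact_p():
    assert exact_ranksum_p([4, 5, 6], [1, 2, 3]) == pytest.approx(0.1)


def test_wilcoxon_identical_multiset_p_one():
    norm, clusters = _norm_from_groups([[1.0, 2.0, 3.0], [2.0, 3.0, 1.0]])
    table = wilcoxon_markers(norm, clusters, SelectionConfig(n_per_cluster=1))
    assert len(table) == 0  # no positive mean difference on either side


def test_wilcoxon_approx_close_to_exact():
    norm, clusters = _norm_from_groups([[4.0, 5.0, 6.0], [1.0, 2.0, 3.0]])
    table = wilcoxon_markers(norm, clusters, SelectionConfig(n_per_cluster=1))
    p_impl = 10 ** -_score_of(table, "A", "g0")
    assert abs(p_impl - 0.1) <= 0.02


@pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 5), (4, 3)])
def test_wilcoxon_matches_scipy_mannwhitney(n1, n2):
    rng = np.random.default_rng(n1 * 10 + n2)
    x = np.round(rng.uniform(0, 4, n1), 1) + 1.0  # +1 keeps the mean diff positive
    y = np.round(rng.uniform(0, 4, n2), 1)
    norm, clusters = _norm_from_groups([x, y])
    table = wilcoxon_markers(norm, clusters, SelectionConfig(n_per_cluster=1))
    p_impl = 10 ** -_score_of(table, "A", "g0")
    p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert p_impl == pytest.approx(p_scipy, rel=1e-9)


def test_wilcoxon_single_cluster_is_error(two_block_norm):
    norm, _ = two_block_norm
    only = ClusterAssignment({b: "A" for b in norm.barcodes})
    with pytest.raises(ValidationError):
        wilcoxon_markers(norm, only)


def test_wilcoxon_recovers_planted_marker(sim_small):
    norm, clusters, truth = sim_small
    table = wilcoxon_markers(norm, clusters)
    for cl in clusters.cluster_order:
        top = set(table.genes_for(cl))
        assert len(top & truth.known_markers[cl]) >= 8


# ---------------------------------------------------------------------------
# kruskal
# ---------------------------------------------------------------------------

def test_kruskal_h_oracle_value():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    h = kruskal_h_oracle(groups)
    assert h == pytest.approx(4.5714, abs=1e-4)
    norm, clusters = _norm_from_groups(groups)
    table = kruskal_markers(norm, clusters, SelectionConfig(n_per_cluster=1))
    # gene assigned to max-mean cluster C, score = -log10(chi2 sf of H)
    assert table.genes_for("C") == ["g0"]
    p_expect = stats.chi2.sf(h, df=2)
    assert _score_of(table, "C", "g0") == pytest.approx(-np.log10(p_expect), abs=1e-6)


def test_kruskal_all_equal_gene_dropped():
    norm, clusters = _norm_from_groups([[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]])
    table = kruskal_markers(norm, clusters)
    assert len(table) == 0  # H = 0, p = 1, and no positive mean contrast


def test_kruskal_matches_scipy():
    rng = np.random.default_rng(5)
    groups = [rng.normal(loc, 1, 7) for loc in (0.0, 0.5, 2.0)]
    groups = [np.abs(g) for g in groups]
    norm, clusters = _norm_from_groups(groups)
    table = kruskal_markers(norm, clusters, SelectionConfig(n_per_cluster=1))
    p_scipy = stats.kruskal(*groups).pvalue
    cl = table.df.cluster.iloc[0]
    assert 10 ** -_score_of(table, cl, "g0") == pytest.approx(p_scipy, rel=1e-9)


# ---------------------------------------------------------------------------
# cosg
# ---------------------------------------------------------------------------

def test_cosg_parallel_vector_has_unit_cosine(two_block_norm):
    norm, clusters = two_block_norm
    cos = cosine_to_clusters(norm, clusters)
    assert cos[0, 0] == pytest.approx(1.0)  # g0 constant exactly on cluster A


def test_cosg_uniform_gene_cosine_is_sqrt_fraction():
    X = np.ones((12, 1))
    barcodes = [f"c{i}" for i in range(12)]
    labels = {b: ("A" if i < 3 else "B") for i, b in enumerate(barcodes)}
    norm = NormMatrix(X, barcodes, ["g0"])
    cos = cosine_to_clusters(norm, ClusterAssignment(labels))
    assert cos[0, 0] == pytest.approx(np.sqrt(3 / 12))  # = 0.5


def test_cosg_mu_zero_ranks_by_raw_cosine(sim_small):
    norm, clusters, _ = sim_small
    cos = cosine_to_clusters(norm, clusters)
    table = cosg_markers(norm, clusters, SelectionConfig(n_per_cluster=8, cosg_mu=0.0))
    for ki, cl in enumerate(clusters.cluster_order):
        by_cos = np.lexsort((np.arange(cos.shape[1]), -cos[ki]))[:8]
        assert table.genes_for(cl) == [norm.genes[j] for j in by_cos]


def test_cosg_zero_gene_scores_zero():
    X = np.zeros((6, 1))
    barcodes = [f"c{i}" for i in range(6)]
    labels = {b: ("A" if i < 3 else "B") for i, b in enumerate(barcodes)}
    norm = NormMatrix(X, barcodes, ["g0"])
    table = cosg_markers(norm, ClusterAssignment(labels), SelectionConfig(n_per_cluster=1))
    assert set(table.df.score) == {0.0}


# ---------------------------------------------------------------------------
# scmarker
# ---------------------------------------------------------------------------

def _bimodal_block(n_cells=60, n_bimodal=8, seed=4):
    """Half the cells express a block of co-occurring bimodal genes."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 0.3, size=(n_cells, n_bimodal + 2))
    on = np.arange(n_cells) < n_cells // 2
    for j in range(n_bimodal):
        X[on, j] = 5.0 + rng.uniform(-0.1, 0.1, on.sum())
    X[:, n_bimodal] = 1.0  # constant gene: must fail the bimodality stage
    barcodes = [f"c{i}" for i in range(n_cells)]
    labels = {b: ("A" if on[i] else "B") for i, b in enumerate(barcodes)}
    norm = NormMatrix(X, barcodes, [f"g{j}" for j in range(n_bimodal + 2)])
    return norm, ClusterAssignment(labels), n_bimodal


def test_scmarker_constant_gene_fails_and_block_survives():
    norm, clusters, n_bimodal = _bimodal_block()
    table = scmarker_markers(norm, clusters, SelectionConfig(n_per_cluster=5))
    picked = set(table.df.gene)
    assert f"g{n_bimodal}" not in picked  # constant gene filtered at stage 1
    assert picked <= {f"g{j}" for j in range(n_bimodal)}  # only the bimodal block
    assert table.genes_for("A")  # the expressing cluster got markers


def test_scmarker_emits_exactly_n_per_cluster():
    norm, clusters, n_bimodal = _bimodal_block(n_bimodal=9)
    cfg = SelectionConfig(n_per_cluster=4)
    table = scmarker_markers(norm, clusters, cfg)
    for cl in clusters.cluster_order:
        assert len(table.genes_for(cl)) == 4


def test_scmarker_no_candidates_warns_empty(two_block_norm, caplog):
    norm, clusters = two_block_norm
    flat = NormMatrix(np.ones_like(norm.values), norm.barcodes, norm.genes)
    with caplog.at_level("WARNING"):
        table = scmarker_markers(flat, clusters)
    assert len(table) == 0
    assert any("no candidate" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# hgt
# ---------------------------------------------------------------------------

def test_hgt_exact_extreme_p():
    member = np.zeros((20, 1), dtype=bool)
    member[:5, 0] = True
    values = np.zeros(20)
    values[:5] = 2.0  # expressed exactly in the cluster
    p = min_hypergeom_p(values, member)
    assert p[0] == pytest.approx(1.0 / 15504, rel=1e-10)  # 1/C(20,5) = 6.4499e-5


def test_hgt_all_expressing_gene_p_one():
    member = np.zeros((10, 1), dtype=bool)
    member[:4, 0] = True
    p = min_hypergeom_p(np.full(10, 3.0), member)
    assert p[0] == pytest.approx(1.0)


def test_hgt_marker_table_ranked_by_adjusted_p(sim_small):
    norm, clusters, truth = sim_small
    table = hgt_markers(norm, clusters)
    for cl in clusters.cluster_order:
        assert len(set(table.genes_for(cl)) & truth.known_markers[cl]) >= 8
        scores = table.df[table.df.cluster == cl].sort_values("rank").score.to_numpy()
        assert np.all(np.diff(scores) <= 1e-9)


# ---------------------------------------------------------------------------
# hvg baseline, pooling
# ---------------------------------------------------------------------------

def test_hvg_baseline_pool_bounded_and_nonconstant(sim_small):
    norm, clusters, _ = sim_small
    table = hvg_baseline(norm, clusters, SelectionConfig(n_per_cluster=10))
    _, count = pooled_unique_genes(table)
    assert count <= 10 * len(clusters.cluster_order)
    variances = norm.values.var(axis=0)
    gene_var = {g: v for g, v in zip(norm.genes, variances)}
    assert all(gene_var[g] > 0 for g in table.df.gene)


def test_pooled_unique_genes_union():
    table = MarkerTable(pd.DataFrame(
        [("A", 1, "g1", 2.0), ("A", 2, "g2", 1.0), ("B", 1, "g2", 3.0), ("B", 2, "g3", 1.0)],
        columns=["cluster", "rank", "gene", "score"]))
    genes, count = pooled_unique_genes(table)
    assert genes == {"g1", "g2", "g3"} and count == 3


# ---------------------------------------------------------------------------
# invariances shared by all methods
# ---------------------------------------------------------------------------

# hvg is excluded: its global pool is split by max-mean assignment, so a
# cluster can legitimately receive fewer than n_per_cluster genes
@pytest.mark.parametrize("method", ["wilcoxon", "kruskal", "cosg", "hgt"])
def test_exactly_n_per_cluster_with_large_pool(sim_small, method):
    norm, clusters, _ = sim_small
    table = METHODS[method](norm, clusters, SelectionConfig(n_per_cluster=7))
    for cl in clusters.cluster_order:
        assert len(table.genes_for(cl)) == 7


@pytest.mark.parametrize("method", ["wilcoxon", "kruskal", "cosg", "hgt"])
def test_cell_permutation_invariance(two_block_norm, method):
    norm, clusters = two_block_norm
    base = METHODS[method](norm, clusters, SelectionConfig(n_per_cluster=3))
    rng = np.random.default_rng(9)
    perm = rng.permutation(len(norm.barcodes))
    shuffled = NormMatrix(
        norm.values[perm], [norm.barcodes[i] for i in perm], norm.genes
    )
    again = METHODS[method](shuffled, clusters, SelectionConfig(n_per_cluster=3))
    pd.testing.assert_frame_equal(base.df, again.df)


@pytest.mark.parametrize("method", ["wilcoxon", "kruskal", "cosg", "hgt"])
def test_cluster_relabel_equivariance(two_block_norm, method):
    norm, clusters = two_block_norm
    base = METHODS[method](norm, clusters, SelectionConfig(n_per_cluster=3))
    renamed = ClusterAssignment(
        {b: {"A": "x9", "B": "y7"}[c] for b, c in clusters.labels.items()},
        cluster_order=["x9", "y7"],
    )
    again = METHODS[method](norm, renamed, SelectionConfig(n_per_cluster=3))
    mapped = again.df.assign(cluster=again.df.cluster.map({"x9": "A", "y7": "B"}))
    pd.testing.assert_frame_equal(base.df, mapped)


# ---------------------------------------------------------------------------
# plugin contract
# ---------------------------------------------------------------------------

def test_plugin_copy_round_trip(tmp_path):
    fixture = tmp_path / "fixture.csv"
    fixture.write_text("cluster,rank,gene,score\nA,1,g1,2.0\nA,2,g2,1.0\n")
    out = tmp_path / "out.csv"
    table = run_plugin(f"cp {fixture} {{out}}", "unused", "unused", str(out))
    assert table.genes_for("A") == ["g1", "g2"]


def test_plugin_nonzero_exit_raises(tmp_path):
    out = tmp_path / "out.csv"
    with pytest.raises(PluginError) as err:
        run_plugin("python -c 'import sys; sys.stderr.write(\"boom\"); sys.exit(1)'",
                   "n", "c", str(out))
    assert "boom" in err.value.stderr


def test_plugin_missing_output_raises(tmp_path):
    with pytest.raises(PluginError, match="no output"):
        run_plugin("true", "n", "c", str(tmp_path / "absent.csv"))


def test_plugin_duplicate_rows_are_validation_error(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("cluster,rank,gene,score\nA,1,g1,2.0\nA,2,g1,1.0\n")
    with pytest.raises(ValidationError):
        run_plugin(f"cp {bad} {{out}}", "n", "c", str(tmp_path / "out.csv"))
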