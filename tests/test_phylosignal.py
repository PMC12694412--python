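import math

import dendropy
import networkx as nx
import numpy as np
import pytest
from scipy import integrate, stats

from viralphenology import phylosignal as phy
from viralphenology.clustering import ClusterSolution
from viralphenology.core_io import RegularSeries
from viralphenology.synthetic import SimConfig, simulate_tree

from conftest import make_series


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


# ------------------------------------------------------------ patristic
def test_patristic_two_and_three_tips():
    d2 = phy.patristic_matrix(_tree("(A:0.1,B:0.2);"))
    assert d2.matrix[0, 1] == pytest.approx(0.3)

    d3 = phy.patristic_matrix(_tree("((A:0.1,B:0.1):0.05,C:0.2);"))
    i = {t: k for k, t in enumerate(d3.taxa)}
    assert d3.matrix[i["A"], i["B"]] == pytest.approx(0.2)
    assert d3.matrix[i["A"], i["C"]] == pytest.approx(0.35)


def _graph_path_oracle(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Independent oracle: tree as weighted graph, Dijkstra tip-to-tip paths."""
    G = nx.Graph()
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            G.add_edge(id(node), id(child), weight=child.edge.length or 0.0)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    out = {}
    for a in leaves:
        lengths = nx.single_source_dijkstra_path_length(G, leaves[a])
        for b in leaves:
            out[(a, b)] = lengths[leaves[b]]
    return out


@pytest.mark.parametrize("seed", range(10))
def test_patristic_matches_graph_oracle_on_random_trees(seed):
    tree = simulate_tree(SimConfig(n_taxa=5 + 2 * seed, seed=seed))
    d = phy.patristic_matrix(tree)
    oracle = _graph_path_oracle(tree)
    for i, a in enumerate(d.taxa):
        for j, b in enumerate(d.taxa):
            assert d.matrix[i, j] == pytest.approx(oracle[(a, b)], rel=1e-9)


def test_patristic_triangle_inequality():
    tree = simulate_tree(SimConfig(n_taxa=30, seed=2))
    M = phy.patristic_matrix(tree).matrix
    n = M.shape[0]
    rng = np.random.default_rng(0)
    for _ in range(2000):
        i, j, k = rng.choice(n, size=3, replace=False)
        assert M[i, j] <= M[i, k] + M[k, j] + 1e-12


# ------------------------------------------------------------ kendall
def _tau_b_enumeration(x, y) -> float:
    """O(n^2) concordant/discordant pair counting with tie correction."""
    n = len(x)
    c = d = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                c += 1
            else:
                d += 1
    n0 = n * (n - 1) / 2
    return (c - d) / math.sqrt((n0 - tx) * (n0 - ty))


def _series_dict(arrays, start_month=1):
    return {
        f"t{i}": make_series(a, start_month=start_month, taxon_id=f"t{i}")
        for i, a in enumerate(arrays)
    }


def test_kendall_identity_and_reversal():
    x = np.arange(14.0)
    series = _series_dict([x, -x])
    _, T = phy.kendall_matrix(series)
    assert T[0, 0] == 1.0
    assert T[0, 1] == pytest.approx(-1.0)


def test_kendall_small_example_and_enumeration_oracle():
    # hand example: one discordant pair among six
    assert _tau_b_enumeration([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(2 / 3)
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.integers(0, 6, size=20).astype(float)  # ties included
        y = rng.integers(0, 6, size=20).astype(float)
        got = stats.kendalltau(x, y).statistic
        assert got == pytest.approx(_tau_b_enumeration(x, y), rel=1e-9)
    series = _series_dict([rng.normal(size=30) for _ in range(4)])
    taxa, T = phy.kendall_matrix(series)
    for i in range(4):
        for j in range(i + 1, 4):
            expect = _tau_b_enumeration(series[taxa[i]].values, series[taxa[j]].values)
            assert T[i, j] == pytest.approx(expect, rel=1e-9)


def test_kendall_monotone_invariance():
    rng = np.random.default_rng(6)
    x = rng.normal(size=24)
    y = rng.normal(size=24)
    _, T1 = phy.kendall_matrix(_series_dict([x, y]))
    _, T2 = phy.kendall_matrix(_series_dict([np.exp(x), y**3]))
    assert T1[0, 1] == pytest.approx(T2[0, 1])


def test_kendall_uses_overlapping_months_only():
    a = make_series(np.arange(24.0), start_month=1, taxon_id="a")
    b = make_series(np.arange(18.0), start_month=7, taxon_id="b")  # offset start
    taxa, T = phy.kendall_matrix({"a": a, "b": b})
    assert T[0, 1] == pytest.approx(1.0)  # both increasing on the shared window


def test_kendall_insufficient_overlap():
    a = make_series(np.arange(24.0), start_year=2000, taxon_id="a")
    b = make_series(np.arange(24.0), start_year=2010, taxon_id="b")
    with pytest.raises(ValueError, match="share only"):
        phy.kendall_matrix({"a": a, "b": b})


# ------------------------------------------------------------ mantel
def _toy_distances(n, seed=0):
    tree = simulate_tree(SimConfig(n_taxa=n, seed=seed))
    return phy.patristic_matrix(tree)


def test_mantel_perfect_negative_monotone():
    d = _toy_distances(8)
    tau = np.exp(-d.matrix)
    np.fill_diagonal(tau, 1.0)
    res = phy.mantel_association(d, d.taxa, tau, B=999, seed=0)
    assert res.statistic == pytest.approx(-1.0)
    assert res.p_value == pytest.approx(1 / 1000)


def test_mantel_agrees_with_skbio_statistic():
    from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

    d = _toy_distances(10, seed=3)
    rng = np.random.default_rng(1)
    tau = np.clip(np.exp(-d.matrix) + 0.05 * rng.normal(size=d.matrix.shape), -1, 1)
    tau = (tau + tau.T) / 2
    np.fill_diagonal(tau, 1.0)
    ours = phy.mantel_association(d, d.taxa, tau, B=999, seed=0)
    dm1 = DistanceMatrix(d.matrix, ids=d.taxa)
    diss = 1.0 - tau
    np.fill_diagonal(diss, 0.0)
    dm2 = DistanceMatrix(diss, ids=d.taxa)
    r_skbio, _, _ = skbio_mantel(dm1, dm2, method="spearman", permutations=0)
    # agreement of distance with (1 - tau) flips the sign of the correlation
    assert ours.statistic == pytest.approx(-r_skbio, abs=1e-10)


def test_mantel_p_insensitive_to_which_matrix_is_permuted():
    d = _toy_distances(12, seed=4)
    rng = np.random.default_rng(2)
    tau = np.clip(np.exp(-d.matrix) + 0.3 * rng.normal(size=d.matrix.shape), -1, 1)
    tau = (tau + tau.T) / 2
    np.fill_diagonal(tau, 1.0)
    p_tau_perm = phy.mantel_association(d, d.taxa, tau, B=4999, seed=0).p_value
    # permuting the distance matrix instead: swap the roles of the inputs
    as_dist = phy.PhyloDistances(d.taxa, tau)
    swapped = phy.mantel_association(as_dist, d.taxa, d.matrix, B=4999, seed=1)
    assert abs(p_tau_perm - swapped.p_value) < 0.05


def test_mantel_needs_four_taxa():
    d = _toy_distances(5)
    small = d.subset(d.taxa[:3])
    with pytest.raises(ValueError, match="4 taxa"):
        phy.mantel_association(small, small.taxa, np.eye(3), B=999)


# ------------------------------------------------------------ chi-squared
def test_chi2_hand_value_diagonal_table():
    groups = {f"t{i}": ("g1" if i < 10 else "g2") for i in range(20)}
    clusters = {f"t{i}": (0 if i < 10 else 1) for i in range(20)}
    res = phy.cluster_phylogeny_chisq(groups, clusters, B=999, seed=0)
    assert res.chi2 == pytest.approx(20.0)  # all E = 5, sum (O-E)^2/E = 4*25/5
    assert res.df == 1
    assert res.p_permutation == pytest.approx(1 / 1000)


def test_chi2_matches_scipy_contingency():
    rng = np.random.default_rng(3)
    groups = {f"t{i}": f"g{rng.integers(3)}" for i in range(60)}
    clusters = {f"t{i}": int(rng.integers(4)) for i in range(60)}
    res = phy.cluster_phylogeny_chisq(groups, clusters, B=0, seed=0)
    chi2, p, df, _ = stats.chi2_contingency(res.observed.to_numpy(), correction=False)
    assert res.chi2 == pytest.approx(chi2)
    assert res.df == df
    assert res.p_parametric == pytest.approx(p)


def test_chi2_null_calibration_under_independence():
    rng = np.random.default_rng(4)
    trials, alpha, rejections = 300, 0.05, 0
    for _ in range(trials):
        groups = {f"t{i}": f"g{rng.integers(2)}" for i in range(80)}
        clusters = {f"t{i}": int(rng.integers(2)) for i in range(80)}
        res = phy.cluster_phylogeny_chisq(groups, clusters, B=0, seed=0)
        if res.p_parametric < alpha:
            rejections += 1
    rate = rejections / trials
    ci = 1.96 * np.sqrt(alpha * (1 - alpha) / trials)
    assert abs(rate - alpha) <= ci + 0.01


def test_chi2_requires_two_by_two():
    groups = {f"t{i}": "g1" for i in range(10)}
    clusters = {f"t{i}": i % 3 for i in range(10)}
    with pytest.raises(ValueError, match="at least 2 groups"):
        phy.cluster_phylogeny_chisq(groups, clusters, B=0)


def test_chisq_upper_tail_values():
    assert phy.chisq_upper_tail(0.0, 5) == pytest.approx(1.0)
    assert phy.chisq_upper_tail(137.433, 68) < 1e-4

    # independent numerical-integration oracle for P(X >= 90.77), df = 68
    df = 68
    norm = 2 ** (df / 2) * math.gamma(df / 2)
    pdf = lambda x: x ** (df / 2 - 1) * math.exp(-x / 2) / norm
    oracle, _ = integrate.quad(pdf, 90.77, np.inf)
    assert oracle == pytest.approx(0.033, abs=0.002)
    assert phy.chisq_upper_tail(90.77, 68) == pytest.approx(oracle, rel=1e-8)


def test_chisq_upper_tail_invalid_inputs():
    with pytest.raises(ValueError):
        phy.chisq_upper_tail(-1.0, 5)
    with pytest.raises(ValueError):
        phy.chisq_upper_tail(1.0, 0)


# ------------------------------------------------------------ clades
def test_clades_at_depth_partitions_all_tips():
    tree = simulate_tree(SimConfig(n_taxa=20, seed=5))
    groups = phy.clades_at_depth(tree, depth=0.5)
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    assert set(groups) == labels
    assert len(set(groups.values())) >= 2
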