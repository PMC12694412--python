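"""Phylogenetic signal of viral phenology.

Two complementary tests of the claim that closely related phylotypes have
similar temporal dynamics:

* A Mantel-style permutation test of the (negative) association between
  patristic distance and pairwise Kendall tau-b agreement of abundance
  trajectories.
* A chi-squared contingency test of seasonal-cluster membership against
  phylogenetic grouping (taxonomic labels or tree clades), with both the
  parametric upper tail and a cluster-label permutation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import special, stats

from .clustering import ClusterSolution
from .core_io import RegularSeries

__all__ = [
    "PhyloDistances",
    "MantelResult",
    "ContingencyResult",
    "patristic_matrix",
    "kendall_matrix",
    "mantel_association",
    "cluster_phylogeny_chisq",
    "chisq_upper_tail",
    "clades_at_depth",
]


@dataclass
class PhyloDistances:
    """Symmetric patristic (path-length) distance matrix over tree tips."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match taxa")

    def subset(self, taxa: list[str]) -> "PhyloDistances":
        pos = {t: i for i, t in enumerate(self.taxa)}
        idx = [pos[t] for t in taxa]
        return PhyloDistances(list(taxa), self.matrix[np.ix_(idx, idx)])


@dataclass
class MantelResult:
    statistic: float  # rank correlation of off-diagonal d_ij vs tau_ij
    p_value: float  # one-sided, negative association
    permutations: int
    seed: int
    method: str = "spearman"


@dataclass
class ContingencyResult:
    observed: pd.DataFrame  # groups x clusters
    expected: np.ndarray
    chi2: float
    df: int
    p_parametric: float
    p_permutation: float | None
    permutations: int | None
    seed: int | None


def patristic_matrix(tree: dendropy.Tree) -> PhyloDistances:
    """Sum of branch lengths along the tip-to-tip path, for all tip pairs."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t for t in tree.taxon_namespace if t), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            M[i, j] = M[j, i] = d
    return PhyloDistances(labels, M)


def kendall_matrix(
    series: dict[str, RegularSeries], min_overlap: int = 12
) -> tuple[list[str], np.ndarray]:
    """Pairwise Kendall tau-b of abundance trajectories on shared grid months.

    Each pair is compared on the intersection of its monthly grids; fewer
    than ``min_overlap`` shared months is an error.
    """
    taxa = sorted(series)
    starts = {
        t: series[t].start_year * 12 + series[t].start_month - 1 for t in taxa
    }
    n = len(taxa)
    T = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        a, b = series[taxa[i]], series[taxa[j]]
        sa, sb = starts[taxa[i]], starts[taxa[j]]
        lo = max(sa, sb)
        hi = min(sa + len(a), sb + len(b))
        if hi - lo < min_overlap:
            raise ValueError(
                f"{taxa[i]} and {taxa[j]} share only {max(hi - lo, 0)} months "
                f"(< {min_overlap})"
            )
        xa = a.values[lo - sa : hi - sa]
        xb = b.values[lo - sb : hi - sb]
        tau = stats.kendalltau(xa, xb).statistic
        T[i, j] = T[j, i] = 0.0 if np.isnan(tau) else tau
    return taxa, T


def _offdiag_rank_matrix(M: np.ndarray) -> np.ndarray:
    """Rank-transform the off-diagonal entries in place in matrix form."""
    n = M.shape[0]
    mask = ~np.eye(n, dtype=bool)
    R = np.zeros_like(M, dtype=float)
    R[mask] = stats.rankdata(M[mask])
    return R


def mantel_association(
    d: PhyloDistances,
    taxa: list[str],
    tau: np.ndarray,
    B: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> MantelResult:
    """Mantel permutation test of distance vs temporal agreement.

    The statistic is the Spearman (default) correlation between the
    vectorized upper triangles of the patristic matrix and the tau matrix;
    the null is built by B seeded simultaneous row/column permutations of
    the tau matrix, and the one-sided p targets negative association
    (related taxa agree more): p = (1 + #{r_b <= r_obs}) / (B + 1).
    """
    if B < 999:
        raise ValueError("mantel_association needs B >= 999 permutations")
    n = len(taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa")
    D = d.subset(taxa).matrix
    tau = np.asarray(tau, dtype=float)
    if tau.shape != (n, n):
        raise ValueError("tau matrix shape must match taxa")
    if method == "spearman":
        Dm, Tm = _offdiag_rank_matrix(D), _offdiag_rank_matrix(tau)
    elif method == "pearson":
        Dm, Tm = D, tau
    else:
        raise ValueError(f"unknown method {method!r}")
    iu = np.triu_indices(n, k=1)
    x = Dm[iu]
    r_obs = float(np.corrcoef(x, Tm[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        r_b = np.corrcoef(x, Tm[np.ix_(perm, perm)][iu])[0, 1]
        if r_b <= r_obs:
            count += 1
    return MantelResult(
        statistic=r_obs,
        p_value=(1 + count) / (B + 1),
        permutations=B,
        seed=seed,
        method=method,
    )


def chisq_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for chi-squared via the regularized upper incomplete gamma."""
    if x < 0:
        raise ValueError("statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _chi2_stat(O: np.ndarray) -> tuple[float, np.ndarray]:
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    E = rows @ cols / O.sum()
    return float(np.sum((O - E) ** 2 / E)), E


def cluster_phylogeny_chisq(
    groups: dict[str, str],
    clusters: ClusterSolution | dict[str, int],
    B: int = 999,
    seed: int = 0,
) -> ContingencyResult:
    """Chi-squared test of cluster membership against phylogenetic grouping.

    Builds the groups x clusters contingency table over taxa present in
    both mappings (empty rows/columns dropped), computes the Pearson
    chi-squared statistic with df = (r-1)(c-1), the parametric upper-tail
    p, and a permutation p from B seeded shuffles of the cluster labels.
    """
    assign = clusters.assignments if isinstance(clusters, ClusterSolution) else clusters
    taxa = sorted(set(groups) & set(assign))
    missing = sorted(set(assign) - set(groups))
    if missing:
        raise ValueError(f"clustered taxa without a group: {missing}")
    g = pd.Series({t: groups[t] for t in taxa}, name="group")
    c = pd.Series({t: assign[t] for t in taxa}, name="cluster")
    O_df = pd.crosstab(g, c)
    O_df = O_df.loc[O_df.sum(axis=1) > 0, O_df.sum(axis=0) > 0]
    if O_df.shape[0] < 2 or O_df.shape[1] < 2:
        raise ValueError("need at least 2 groups and 2 clusters after dropping empties")
    O = O_df.to_numpy(dtype=float)
    chi2, E = _chi2_stat(O)
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    p_param = chisq_upper_tail(chi2, df)

    p_perm = None
    if B:
        rng = np.random.default_rng(seed)
        g_codes = pd.Categorical(g).codes
        c_codes = pd.Categorical(c).codes
        r, s = g_codes.max() + 1, c_codes.max() + 1
        count = 0
        for _ in range(B):
            shuffled = rng.permutation(c_codes)
            Ob = np.bincount(g_codes * s + shuffled, minlength=r * s).reshape(r, s)
            # drop empty rows/cols to mirror the observed-table construction
            Ob = Ob[Ob.sum(axis=1) > 0][:, Ob.sum(axis=0) > 0]
            if min(Ob.shape) < 2:
                continue
            stat_b, _ = _chi2_stat(Ob.astype(float))
            if stat_b >= chi2:
                count += 1
        p_perm = (1 + count) / (B + 1)
    return ContingencyResult(
        observed=O_df,
        expected=E,
        chi2=chi2,
        df=df,
        p_parametric=p_param,
        p_permutation=p_perm,
        permutations=B or None,
        seed=seed if B else None,
    )


def clades_at_depth(tree: dendropy.Tree, depth: float) -> dict[str, str]:
    """Group tips by the clade their lineage belongs to at a given depth
    from the root (in branch-length units); a simple way to build the
    grouping for the contingency test when no taxonomy is supplied.
    """
    groups: dict[str, str] = {}
    counter = itertools.count(1)

    def assign(node, dist, label):
        edge = node.edge.length or 0.0
        top = dist + edge
        if label is None and top >= depth:
            label = f"clade_{next(counter)}"
        if node.is_leaf():
            groups[node.taxon.label] = label if label else f"clade_{next(counter)}"
        else:
            for ch in node.child_nodes():
                assign(ch, top, label)

    for ch in tree.seed_node.child_nodes():
        assign(ch, 0.0, None)
    return groups
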