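"""Profile-level analytics: QC, similarity, clustering, networks, overlaps.

A genetic interaction profile — the vector of interaction scores of one
query across all array genes — is a functional fingerprint: queries with
correlated profiles act in related pathways.  This module provides the
downstream machinery over such profiles (or over fitness/survival
profiles): pairwise Pearson similarity on shared non-missing genes,
average-linkage hierarchical clustering on 1 - r, PCA-based replicate
QC, thresholded correlation networks, and a Monte-Carlo multiset
intersection test for asking whether gene sets discovered in different
conditions overlap more than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

__all__ = [
    "profile_correlation",
    "cluster_profiles",
    "replicate_pca",
    "correlation_network",
    "multiset_intersection_test",
    "OverlapTestResult",
]


def profile_correlation(
    profiles: pd.DataFrame, min_overlap: int = 10
) -> pd.DataFrame:
    """Pairwise Pearson correlation between profile rows.

    ``profiles`` has one row per (query, condition, state) combination
    and one column per array gene; missing entries are NaN.  Each pair
    is correlated over its complete-pair overlap, requiring at least
    ``min_overlap`` shared genes (NaN otherwise).
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least two profiles")
    return profiles.T.corr(min_periods=min_overlap)


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_profiles(corr: pd.DataFrame, method: str = "average") -> dict:
    """Agglomerative clustering of profiles with distance 1 - r.

    Profiles whose correlation with any other profile is undefined are
    excluded (with a warning).  Returns the scipy linkage matrix, leaf
    labels in dendrogram order, merge heights, and a Newick string.
    """
    corr = corr.copy()
    dropped = 0
    while corr.isna().any().any():
        # drop the profile responsible for the most undefined pairs first
        worst = corr.isna().sum(axis=1).idxmax()
        corr = corr.drop(index=worst, columns=worst)
        dropped += 1
    if dropped:
        warnings.warn(
            f"excluding {dropped} profile(s) with missing correlations",
            stacklevel=2,
        )
    if corr.shape[0] < 2:
        raise ValueError("fewer than two profiles with complete correlations")
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    labels = list(map(str, corr.index))
    order = hierarchy.leaves_list(Z)
    tree = hierarchy.to_tree(Z)
    return {
        "linkage": Z,
        "labels": labels,
        "leaf_order": [labels[i] for i in order],
        "heights": Z[:, 2].copy(),
        "newick": _to_newick(tree, labels) + ";",
    }


def replicate_pca(
    fitness: pd.DataFrame,
    libraries: pd.Series,
    n_components: int = 2,
    mahalanobis_threshold: float = 3.0,
) -> dict:
    """Principal-component QC of per-replicate fitness profiles.

    ``fitness`` has one row per replicate (columns: strains); each
    replicate's PC coordinates are scored by a leave-one-out Mahalanobis
    distance to its library centroid (centroid and pooled within-library
    covariance computed without the replicate itself, so an aberrant
    replicate cannot mask itself by inflating the covariance), and
    replicates beyond ``mahalanobis_threshold`` are flagged as poorly
    correlated replicates for exclusion.
    """
    if fitness.shape[0] < 3:
        raise ValueError("need at least three replicates")
    n_components = min(n_components, fitness.shape[0] - 1, fitness.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(fitness.to_numpy(dtype=float))
    scores = pd.DataFrame(
        scores, index=fitness.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    libraries = libraries.reindex(fitness.index)
    d = np.full(len(scores), np.nan)
    X = scores.to_numpy()
    libs = libraries.to_numpy()
    for i in range(len(X)):
        mates = np.flatnonzero((libs == libs[i]) & (np.arange(len(X)) != i))
        if mates.size == 0:
            continue
        centroid = X[mates].mean(axis=0)
        rest = np.arange(len(X)) != i
        devs = []
        for lib in np.unique(libs):
            members = np.flatnonzero((libs == lib) & rest)
            if members.size >= 2:
                devs.append(X[members] - X[members].mean(axis=0))
        if not devs:
            continue
        dev = np.vstack(devs)
        dof = max(dev.shape[0] - len(np.unique(libs)), 1)
        cov = dev.T @ dev / dof
        delta = X[i] - centroid
        d[i] = float(np.sqrt(delta @ np.linalg.pinv(cov) @ delta))
    dist = pd.Series(d, index=fitness.index, name="mahalanobis")
    return {
        "scores": scores,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "mahalanobis": dist,
        "outliers": dist.index[dist > mahalanobis_threshold].tolist(),
    }


def correlation_network(
    corr: pd.DataFrame, threshold: float = 0.5
) -> nx.Graph:
    """Graph with an edge wherever |r| >= threshold.

    Nodes are the profile labels; edges carry ``weight`` = |r| and
    ``sign`` in {positive, negative}.
    """
    G = nx.Graph()
    G.add_nodes_from(map(str, corr.index))
    cols = list(corr.columns)
    for i, a in enumerate(corr.index):
        for b in cols[i + 1:]:
            r = corr.at[a, b]
            if pd.notna(r) and abs(r) >= threshold:
                G.add_edge(
                    str(a), str(b),
                    weight=float(abs(r)),
                    r=float(r),
                    sign="positive" if r >= 0 else "negative",
                )
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    rows = [
        {"source": u, "target": v, "sign": d["sign"], "weight": d["weight"]}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "weight"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class OverlapTestResult:
    observed: int
    expected: float
    p_value: float
    universe_size: int
    draws: int
    alternative: str


def multiset_intersection_test(
    sets: list,
    universe_size: int,
    draws: int = 10_000,
    seed: int = 0,
    alternative: str = "enrichment",
) -> OverlapTestResult:
    """Monte-Carlo test of a k-way set intersection against independence.

    Under the null, each set is a uniformly random subset of its
    observed size drawn from a universe of ``universe_size`` elements;
    the expected intersection is ``N * prod(n_i / N)``.  The p-value
    compares the observed intersection with ``draws`` resampled ones
    (add-one correction), one-sided for enrichment or depletion.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    sets = [set(s) for s in sets]
    sizes = [len(s) for s in sets]
    if any(n > universe_size for n in sizes):
        raise ValueError("a set is larger than the universe")
    if alternative not in ("enrichment", "depletion"):
        raise ValueError("alternative must be 'enrichment' or 'depletion'")
    observed = len(set.intersection(*sets))
    expected = universe_size * float(np.prod([n / universe_size for n in sizes]))

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(2_000, draws))
    done = 0
    while done < draws:
        m = min(chunk, draws - done)
        inter = np.ones((m, universe_size), dtype=bool)
        for n in sizes:
            u = rng.random((m, universe_size))
            kth = np.partition(u, n - 1, axis=1)[:, n - 1]
            inter &= u <= kth[:, None]
        sim = inter.sum(axis=1)
        if alternative == "enrichment":
            exceed += int((sim >= observed).sum())
        else:
            exceed += int((sim <= observed).sum())
        done += m
    p = (1 + exceed) / (draws + 1)
    return OverlapTestResult(
        observed=observed,
        expected=expected,
        p_value=float(p),
        universe_size=universe_size,
        draws=draws,
        alternative=alternative,
    )
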