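"""Downstream analyses: CLR ordination, diet centroids, integration, adequacy.

These operate on fitted model output: projecting ancestral compositions
into the PCA space of present-day microbiota, measuring which diet's
centroid the ancestral composition is closest to, clustering taxa by their
positive evolutionary covariances, benchmarking against the Mantel test,
and posterior-predictive model-adequacy checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .model import CompositionTable, ModelParams
from .phylo import Phylogeny, phylo_covariance
from .simulate import simulate_microbiota

__all__ = [
    "ProjectionResult",
    "CentroidDistances",
    "IntegrationClusters",
    "clr_transform",
    "project_with_ancestor",
    "diet_centroid_distances",
    "integration_clusters",
    "mantel_baseline",
    "adequacy_check",
]

DIET_CATEGORIES = ("plants", "fruits", "invertebrates", "meat")


def clr_transform(table) -> np.ndarray:
    """Centered log-ratio transform: log Z minus the row-mean log.

    Accepts a CompositionTable or an array of strictly positive rows
    (rows need not be renormalized: CLR is scale-invariant). Output rows
    sum to zero.
    """
    Z = table.values if isinstance(table, CompositionTable) else np.asarray(table, float)
    Z = np.atleast_2d(Z)
    if np.any(Z <= 0):
        raise ValueError(
            "CLR requires strictly positive entries; apply the detection "
            "floor (prepare_table) before transforming"
        )
    logZ = np.log(Z)
    return logZ - logZ.mean(axis=1, keepdims=True)


@dataclass(frozen=True, eq=False)
class ProjectionResult:
    """PCA of present-day CLR compositions with passively projected ancestors."""

    loadings: np.ndarray           # (p, k)
    scores: np.ndarray             # (n, k) extant hosts
    ancestor_scores: np.ndarray    # (a, k)
    explained_variance: np.ndarray
    host_ids: list
    taxon_ids: list


def project_with_ancestor(
    table: CompositionTable, ancestors, k: int = 5
) -> ProjectionResult:
    """PCA on CLR-transformed extant compositions; project ancestors passively.

    The axes are fitted on extant hosts only, so ancestral points have no
    influence on the ordination; they are CLR-transformed with the same
    taxon set and mapped through the fitted rotation.
    """
    p = table.n_taxa
    if not (1 <= k <= p):
        raise ValueError(f"k must lie in [1, {p}], got {k}")
    X = clr_transform(table)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    anc = np.atleast_2d(np.asarray(ancestors, dtype=float))
    if anc.shape[1] != p:
        raise ValueError("ancestors must share the table's taxon set")
    anc_scores = pca.transform(clr_transform(anc))
    return ProjectionResult(
        loadings=pca.components_.T,
        scores=scores,
        ancestor_scores=anc_scores,
        explained_variance=pca.explained_variance_ratio_,
        host_ids=list(table.host_ids),
        taxon_ids=list(table.taxon_ids),
    )


@dataclass(frozen=True, eq=False)
class CentroidDistances:
    """Distance from an ancestral composition to each diet-class centroid."""

    centroids: dict                # diet -> (5,) centroid on PC1..5
    distances: dict                # diet -> distance, ascending
    ancestor: np.ndarray

    @property
    def nearest(self) -> str:
        return next(iter(self.distances))


def diet_centroid_distances(
    proj: ProjectionResult, diet_labels, ancestor_score=None
) -> CentroidDistances:
    """Euclidean distances, on the first five PC axes, to diet centroids.

    ``diet_labels`` aligns with the projection's hosts; empty diet classes
    are omitted with a warning. The ancestor defaults to the projection's
    first ancestral point.
    """
    if proj.scores.shape[1] < 5:
        raise ValueError("five or more PC axes are required (fit with k >= 5)")
    labels = np.asarray(list(diet_labels))
    if labels.size != proj.scores.shape[0]:
        raise ValueError("one diet label per extant host is required")
    if ancestor_score is None:
        ancestor_score = proj.ancestor_scores[0]
    anc = np.asarray(ancestor_score, dtype=float)[:5]
    centroids = {}
    for diet in DIET_CATEGORIES:
        mask = labels == diet
        if not mask.any():
            warnings.warn(f"diet class {diet!r} is empty; omitted")
            continue
        centroids[diet] = proj.scores[mask, :5].mean(axis=0)
    extra = sorted(set(labels) - set(DIET_CATEGORIES))
    for diet in extra:
        centroids[diet] = proj.scores[labels == diet, :5].mean(axis=0)
    dists = {d: float(np.linalg.norm(anc - c)) for d, c in centroids.items()}
    order = sorted(dists, key=dists.get)
    return CentroidDistances(
        centroids={d: centroids[d] for d in order},
        distances={d: dists[d] for d in order},
        ancestor=anc,
    )


@dataclass(frozen=True, eq=False)
class IntegrationClusters:
    """Partition of taxa into positively covarying subsets."""

    clusters: list                 # list of frozensets of taxon ids
    modularity: float

    def cluster_of(self, taxon) -> int:
        for i, c in enumerate(self.clusters):
            if taxon in c:
                return i
        raise KeyError(taxon)


def integration_clusters(R: np.ndarray, taxon_ids) -> IntegrationClusters:
    """Greedy modularity clustering of the positive-covariance graph.

    Builds an undirected weighted graph over taxa with edge weights
    max(R_jk, 0) for j != k (negative covariances carry no edge; the
    diagonal is ignored) and maximizes modularity greedily. When no
    positive off-diagonal covariance exists, every taxon is its own
    cluster.
    """
    R = np.asarray(R, dtype=float)
    taxon_ids = list(taxon_ids)
    p = len(taxon_ids)
    if R.shape != (p, p):
        raise ValueError("R must be p x p with one row per taxon")
    G = nx.Graph()
    G.add_nodes_from(taxon_ids)
    for j in range(p):
        for k in range(j + 1, p):
            w = max(0.5 * (R[j, k] + R[k, j]), 0.0)
            if w > 0:
                G.add_edge(taxon_ids[j], taxon_ids[k], weight=w)
    if G.number_of_edges() == 0:
        warnings.warn("no positive covariances; every taxon is its own cluster")
        return IntegrationClusters(
            clusters=[frozenset([t]) for t in taxon_ids], modularity=0.0
        )
    comms = nx.community.greedy_modularity_communities(G, weight="weight")
    comms = [frozenset(c) for c in comms]
    q = nx.community.modularity(G, comms, weight="weight")
    return IntegrationClusters(clusters=comms, modularity=float(q))


def mantel_baseline(
    tree: Phylogeny, data: CompositionTable, n_perm: int = 999, seed=None
):
    """Mantel test of phylosymbiosis (the correlative baseline).

    Pearson correlation between host patristic distances and Bray-Curtis
    dissimilarities of the microbiota, with a one-sided (positive
    association) permutation p-value under the add-one rule.
    """
    from skbio import DistanceMatrix
    from skbio.stats.distance import mantel

    if data.n_hosts < 4:
        raise ValueError("Mantel test needs at least 4 hosts")
    table = data.reorder(tree.tip_labels)
    pc = phylo_covariance(tree)
    C = pc.matrix
    patristic = np.diag(C)[:, None] + np.diag(C)[None, :] - 2.0 * C
    np.fill_diagonal(patristic, 0.0)
    bc = squareform(pdist(table.values, metric="braycurtis"))
    for name, m in (("patristic", patristic), ("Bray-Curtis", bc)):
        if np.std(squareform(m, checks=False)) == 0:
            raise ValueError(f"{name} dissimilarities are constant; "
                             "the Mantel correlation is undefined")
    ids = [str(h) for h in pc.tip_order]
    dm_x = DistanceMatrix(0.5 * (patristic + patristic.T), ids=ids)
    dm_y = DistanceMatrix(0.5 * (bc + bc.T), ids=ids)
    # skbio draws its permutations from the global numpy RNG
    np.random.seed(None if seed is None else int(seed) % (2**31 - 1))
    stat, p, _ = mantel(
        dm_x, dm_y, method="pearson", permutations=n_perm, alternative="greater"
    )
    return float(stat), float(p)


def adequacy_check(
    tree: Phylogeny,
    fitted: ModelParams,
    data: CompositionTable,
    n_sims: int = 20,
    seed=None,
    k: int = 2,
) -> dict:
    """Posterior-predictive adequacy: do simulations resemble the data?

    Simulates ``n_sims`` datasets from the fitted parameters on the host
    tree, projects empirical and simulated compositions into the
    *empirical* CLR-PCA space, and reports, per principal component, the
    fraction of empirical scores falling inside the simulated scores'
    2.5-97.5% envelope.
    """
    k = min(k, data.n_taxa)
    X = clr_transform(data.reorder(tree.tip_labels))
    pca = PCA(n_components=k)
    emp_scores = pca.fit_transform(X)
    ss = np.random.SeedSequence(seed)
    sims = []
    for child in ss.spawn(n_sims):
        sim_table, _ = simulate_microbiota(tree, fitted, seed=child)
        sims.append(pca.transform(clr_transform(sim_table)))
    sim_scores = np.concatenate(sims, axis=0)
    lo = np.quantile(sim_scores, 0.025, axis=0)
    hi = np.quantile(sim_scores, 0.975, axis=0)
    coverage = ((emp_scores >= lo[None, :]) & (emp_scores <= hi[None, :])).mean(axis=0)
    return {
        "n_sims": int(n_sims),
        "coverage": coverage.tolist(),
        "envelope_low": lo.tolist(),
        "envelope_high": hi.tolist(),
        "explained_variance": pca.explained_variance_ratio_.tolist(),
        "degenerate": bool(n_sims < 2),
    }
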