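"""Ancestral microbiota composition at internal nodes by generalized least squares.

Under the Brownian model, internal-node states given the tip states and the
root are multivariate normal; their conditional expectation is a
phylogenetically weighted average of the tips. Because the rate matrix R
enters the joint covariance as a Kronecker factor shared by nodes and tips,
it cancels from the conditional mean and the GLS weights depend on the
(lambda-transformed) tree alone, applied per taxon:

    logX_hat(nodes) = logZ0 + V_nt V_tt^-1 (logX(tips) - logZ0)

Compositions at nodes are the renormalized exponentials of the estimated
log abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CompositionTable, ModelParams, assemble_latent_logX
from .phylo import Phylogeny, lambda_transform, node_covariance

__all__ = ["AncestralStates", "gls_ancestral", "ancestral_from_fit", "shift_report"]


@dataclass(frozen=True, eq=False)
class AncestralStates:
    """GLS estimates of ancestral microbiota at internal nodes (root first).

    ``compositions`` rows live on the simplex; ``log_abundance_states``
    are the underlying GLS estimates of log absolute abundances.
    ``node_ages`` are root-to-tip-normalized ages on the *input* tree
    (tips at 0, root at tree depth); ``parent_index`` gives, for every
    internal node, the position of its parent within ``node_ids`` (-1 for
    the root), which is what edge-wise shift reports traverse.
    """

    node_ids: list
    compositions: np.ndarray
    log_abundance_states: np.ndarray
    node_ages: np.ndarray
    parent_index: np.ndarray
    taxon_ids: list | None = None


def _internal_nodes(tree: Phylogeny):
    return [v for v in range(tree.n_nodes) if tree.children(v)]


def node_labels(tree: Phylogeny):
    """Stable internal-node identifiers (existing labels or node{index})."""
    return [tree.labels[v] or f"node{v}" for v in _internal_nodes(tree)]


def gls_ancestral(
    tree: Phylogeny,
    lam: float,
    tip_logX: np.ndarray,
    logZ0: np.ndarray,
    jitter: float | None = None,
) -> AncestralStates:
    """GLS ancestral log-abundance estimates on the lambda-transformed tree.

    ``tip_logX`` rows must follow the tree's (post-order) tip sequence.
    With ``lam = 0`` there is no shared history and every internal estimate
    collapses to the root state. A singular tip covariance (e.g. duplicated
    zero-length tips) raises; pass ``jitter`` (typically 1e-10) to
    regularize the diagonal explicitly.
    """
    ttree = lambda_transform(tree, lam)
    tip_idx = ttree.tip_indices
    internal = _internal_nodes(ttree)
    n = tip_idx.size
    tip_logX = np.asarray(tip_logX, dtype=float)
    logZ0 = np.asarray(logZ0, dtype=float)
    if tip_logX.shape[0] != n:
        raise ValueError("tip_logX rows must match the number of tips")
    V = node_covariance(ttree)
    Vtt = V[np.ix_(tip_idx, tip_idx)]
    Vnt = V[np.ix_(internal, tip_idx)]
    if jitter is not None:
        Vtt = Vtt + jitter * np.eye(n)
    D = tip_logX - logZ0[None, :]
    try:
        Wmat = np.linalg.solve(Vtt, D)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "tip covariance is singular; re-run with jitter=1e-10 if the "
            "tree contains (near-)duplicate tips"
        ) from e
    est = logZ0[None, :] + Vnt @ Wmat
    comp = np.exp(est - est.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)

    depths = tree.node_depths
    ages = tree.depth - depths[internal]
    pos = {v: i for i, v in enumerate(internal)}
    parent_index = np.array(
        [-1 if tree.parent[v] < 0 else pos[int(tree.parent[v])] for v in internal]
    )
    return AncestralStates(
        node_ids=[tree.labels[v] or f"node{v}" for v in internal],
        compositions=comp,
        log_abundance_states=est,
        node_ages=ages,
        parent_index=parent_index,
    )


def ancestral_from_fit(
    tree: Phylogeny, data: CompositionTable, params: ModelParams, **kw
) -> AncestralStates:
    """Ancestral states conditional on fitted point estimates.

    Assembles tip log abundances from the observed compositions and the
    point-estimate logYtilde, then applies GLS with the point-estimate
    lambda and root composition.
    """
    if params.logYtilde is None:
        raise ValueError("params must carry logYtilde (e.g. from mean_estimates)")
    table = data.reorder(tree.tip_labels)
    idx = [data.host_ids.index(h) for h in tree.tip_labels]
    tip_logX = assemble_latent_logX(table, params.logYtilde[np.asarray(idx)])
    anc = gls_ancestral(tree, params.lam, tip_logX, np.log(params.Z0), **kw)
    return AncestralStates(
        node_ids=anc.node_ids,
        compositions=anc.compositions,
        log_abundance_states=anc.log_abundance_states,
        node_ages=anc.node_ages,
        parent_index=anc.parent_index,
        taxon_ids=list(data.taxon_ids),
    )


def gls_posterior(
    tree: Phylogeny,
    data: CompositionTable,
    post,
    n_draws: int = 100,
    seed=None,
) -> dict:
    """Propagate posterior uncertainty through the GLS reconstruction.

    Repeats the GLS over ``n_draws`` posterior draws of (lambda, Z0,
    logYtilde) and returns node-wise summaries of the reconstructed
    compositions: ``mean``, ``q2.5`` and ``q97.5`` arrays of shape
    (n_internal, p), plus ``node_ids``. ``post`` is a PosteriorSummary.
    """
    rng = np.random.default_rng(seed)
    lam_d = post.flat("lam")
    Z0_d = post.flat("Z0")
    logY_d = post.flat("logY")
    idx = rng.choice(lam_d.shape[0], size=min(n_draws, lam_d.shape[0]),
                     replace=False)
    table = data.reorder(tree.tip_labels)
    host_pos = np.array([post.host_ids.index(h) for h in tree.tip_labels])
    comps = []
    node_ids = None
    for k in idx:
        tip_logX = np.log(table.values) + logY_d[k][host_pos][:, None]
        anc = gls_ancestral(tree, float(lam_d[k]), tip_logX, np.log(Z0_d[k]))
        comps.append(anc.compositions)
        node_ids = anc.node_ids
    comps = np.stack(comps)
    return {
        "node_ids": node_ids,
        "mean": comps.mean(axis=0),
        "q2.5": np.quantile(comps, 0.025, axis=0),
        "q97.5": np.quantile(comps, 0.975, axis=0),
        "n_draws": int(len(idx)),
    }


def annotated_newick(tree: Phylogeny, anc: AncestralStates, path=None) -> str:
    """Newick string with internal-node labels set to the dominant taxon."""
    from dataclasses import replace

    taxa = anc.taxon_ids or [str(j) for j in range(anc.compositions.shape[1])]
    labels = list(tree.labels)
    pos = 0
    for v in range(tree.n_nodes):
        if tree.children(v):
            labels[v] = str(taxa[int(np.argmax(anc.compositions[pos]))])
            pos += 1
    from .phylo import write_newick

    return write_newick(replace(tree, labels=tuple(labels)), path)


def shift_report(
    anc: AncestralStates, tree: Phylogeny, threshold: float = 0.10
) -> list:
    """Edges with a large reconstructed change in any taxon's share.

    Scans every internal-parent -> internal-child edge and reports
    ``(edge, taxon, delta)`` tuples where the relative abundance of a taxon
    changes by more than ``threshold`` in absolute value, sorted by |delta|
    descending. Taxon entries are labels when available, else indices.
    """
    out = []
    taxa = anc.taxon_ids or list(range(anc.compositions.shape[1]))
    for child in range(len(anc.node_ids)):
        par = anc.parent_index[child]
        if par < 0:
            continue
        delta = anc.compositions[child] - anc.compositions[par]
        for j in np.flatnonzero(np.abs(delta) > threshold):
            out.append(
                ((anc.node_ids[par], anc.node_ids[child]), taxa[j], float(delta[j]))
            )
    return sorted(out, key=lambda rec: abs(rec[2]), reverse=True)
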