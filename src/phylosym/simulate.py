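"""Forward simulation of microbiota evolution and the simulation-study grid.

Log absolute abundances start at log Z0 at the root and accumulate
MVN(0, t*R) increments along every branch of the lambda-transformed host
tree; tip compositions are the renormalized exponentials. The simulator
records the latent truth (lambda, Z0, R, logYtilde, internal-node states)
so that inference and ancestral-reconstruction accuracy can be measured.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import ortho_group

from .model import CompositionTable, ModelParams
from .phylo import Phylogeny, lambda_transform, simulate_pure_birth, write_newick

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "random_spd",
    "sample_root",
    "simulate_microbiota",
    "simulate_dataset",
    "run_grid",
]

#: the simulation-study defaults: host tree sizes, taxon counts,
#: phylosymbiosis levels, rate-matrix eigenvalue, root log-abundance range
GRID_N = (20, 50, 100, 250)
GRID_P = (3, 5, 10, 15)
GRID_LAMBDA = (1.0, 0.75, 0.5, 0.25, 0.0)
DEFAULT_EIGENVALUE = 0.25
ROOT_LOG_RANGE = (-4.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid."""

    n: int
    p: int
    lam: float
    root_log_range: tuple = ROOT_LOG_RANGE
    R_eigenvalue: float = DEFAULT_EIGENVALUE
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.p < 1 or self.n_reps < 1:
            raise ValueError("need n >= 2, p >= 1, n_reps >= 1")
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")


@dataclass(frozen=True, eq=False)
class SimulationTruth:
    """Latent ground truth attached to a simulated composition table."""

    lam: float
    Z0: np.ndarray
    R: np.ndarray
    logYtilde: np.ndarray          # per tip, in the table's host order
    node_logX: np.ndarray          # states at internal nodes (root first)
    node_ids: list
    host_ids: list

    def to_json(self) -> dict:
        return {
            "lam": float(self.lam),
            "Z0": np.asarray(self.Z0).tolist(),
            "R": np.asarray(self.R).tolist(),
            "logYtilde": np.asarray(self.logYtilde).tolist(),
            "node_logX": np.asarray(self.node_logX).tolist(),
            "node_ids": list(self.node_ids),
            "host_ids": list(self.host_ids),
        }

    @classmethod
    def from_json(cls, d: dict) -> "SimulationTruth":
        return cls(
            lam=d["lam"],
            Z0=np.array(d["Z0"]),
            R=np.array(d["R"]),
            logYtilde=np.array(d["logYtilde"]),
            node_logX=np.array(d["node_logX"]),
            node_ids=list(d["node_ids"]),
            host_ids=list(d["host_ids"]),
        )


def random_spd(
    p: int,
    eigenvalue: float = DEFAULT_EIGENVALUE,
    seed=None,
    spectrum: str = "equal",
) -> np.ndarray:
    """Random symmetric positive-definite rate matrix with a set spectrum.

    ``spectrum="equal"`` (default) conjugates diag(eigenvalue, ...) by a
    Haar-random orthogonal matrix, which reduces exactly to
    ``eigenvalue * I`` — a matrix with the requested eigenvalues but no
    evolutionary covariances. ``spectrum="random"`` instead draws
    eigenvalues from a Gamma(2, 1) and rescales them to have mean
    ``eigenvalue``, producing non-trivial off-diagonal structure while
    keeping the overall rate comparable; use it when covariance recovery
    is the point of the experiment.
    """
    if p < 1 or eigenvalue <= 0:
        raise ValueError("need p >= 1 and eigenvalue > 0")
    rng = np.random.default_rng(seed)
    if spectrum == "equal":
        eig = np.full(p, eigenvalue)
    elif spectrum == "random":
        eig = rng.gamma(shape=2.0, scale=1.0, size=p)
        eig = eig * (eigenvalue / eig.mean())
    else:
        raise ValueError(f"unknown spectrum {spectrum!r}")
    if p == 1:
        return eig.reshape(1, 1)
    Q = ortho_group.rvs(dim=p, random_state=rng)
    signs = rng.choice([-1.0, 1.0], size=p)
    Q = Q * signs[None, :]
    R = (Q * eig[None, :]) @ Q.T
    return 0.5 * (R + R.T)


def sample_root(p: int, seed=None, log_range: tuple = ROOT_LOG_RANGE) -> np.ndarray:
    """Ancestral composition: log abundances uniform on ``log_range``, normalized."""
    if p < 1:
        raise ValueError("need p >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(log_range[0], log_range[1], size=p)
    w = np.exp(u)
    return w / w.sum()


def _psd_sqrt(R: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (allows the degenerate R = 0 case)."""
    w, V = np.linalg.eigh(np.asarray(R, dtype=float))
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)[None, :]


def simulate_microbiota(tree: Phylogeny, params: ModelParams, seed=None, floor=None):
    """Simulate tip compositions under the Brownian model on a host tree.

    Branch-wise simulation on the lambda-transformed tree: the root state
    is log Z0 and each child state adds an MVN(0, t*R) increment. Returns
    ``(CompositionTable, SimulationTruth)``; with ``floor`` set, tip
    relative abundances are additionally censored from below at that value
    (then renormalized) to mimic a detection limit.
    """
    rng = np.random.default_rng(seed)
    ttree = lambda_transform(tree, params.lam)
    p = params.p
    S = _psd_sqrt(params.R)
    m = ttree.n_nodes
    x = np.zeros((m, p))
    x[0] = np.log(params.Z0)
    eps = rng.standard_normal(size=(m, p))
    for v in range(1, m):
        x[v] = x[ttree.parent[v]] + np.sqrt(ttree.blen[v]) * (S @ eps[v])
    tip_idx = ttree.tip_indices
    tip_logX = x[tip_idx]
    logY = logsumexp(tip_logX, axis=1)
    Z = np.exp(tip_logX - logY[:, None])
    Z /= Z.sum(axis=1, keepdims=True)
    if floor is not None:
        Z = np.clip(Z, floor, None)
        Z /= Z.sum(axis=1, keepdims=True)
    host_ids = [ttree.labels[v] for v in tip_idx]
    taxon_ids = [f"taxon{j+1}" for j in range(p)]
    internal = [v for v in range(m) if ttree.children(v)]
    node_ids = [ttree.labels[v] or f"node{v}" for v in internal]
    table = CompositionTable(values=Z, host_ids=host_ids, taxon_ids=taxon_ids)
    truth = SimulationTruth(
        lam=params.lam,
        Z0=params.Z0,
        R=params.R,
        logYtilde=logY,
        node_logX=x[internal],
        node_ids=node_ids,
        host_ids=host_ids,
    )
    return table, truth


def simulate_dataset(config: SimulationConfig, rep: int = 0, spectrum: str = "equal"):
    """Simulate one replicate of a grid cell: tree, table and truth."""
    root = np.random.SeedSequence(
        [int(config.seed), int(config.n), int(config.p),
         int(round(config.lam * 100)), int(rep)]
    )
    s_tree, s_R, s_z0, s_bm = root.spawn(4)
    tree = simulate_pure_birth(config.n, seed=s_tree)
    R = random_spd(config.p, config.R_eigenvalue, seed=s_R, spectrum=spectrum)
    Z0 = sample_root(config.p, seed=s_z0, log_range=config.root_log_range)
    params = ModelParams(lam=config.lam, Z0=Z0, R=R)
    table, truth = simulate_microbiota(tree, params, seed=s_bm)
    return tree, table, truth


def run_grid(
    out_dir,
    ns=GRID_N,
    ps=GRID_P,
    lams=GRID_LAMBDA,
    n_reps: int = 100,
    seed: int = 0,
    spectrum: str = "equal",
) -> dict:
    """Write the full simulation grid to disk and return its manifest.

    The default grid covers every (n, p, lambda) combination with 100
    replicates each (8,000 datasets); pass a smaller ``n_reps`` for a
    scaled-down grid. Each replicate folder holds ``tree.nwk``, ``z.tsv``
    and ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = []
    for n, p, lam in itertools.product(ns, ps, lams):
        cfg = SimulationConfig(n=n, p=p, lam=lam, n_reps=n_reps, seed=seed)
        cell_dir = out / f"n{n}_p{p}_lam{lam:g}"
        reps = []
        for rep in range(n_reps):
            tree, table, truth = simulate_dataset(cfg, rep=rep, spectrum=spectrum)
            rep_dir = cell_dir / f"rep{rep}"
            rep_dir.mkdir(parents=True, exist_ok=True)
            write_newick(tree, rep_dir / "tree.nwk")
            table.write_tsv(rep_dir / "z.tsv")
            (rep_dir / "truth.json").write_text(json.dumps(truth.to_json()))
            reps.append(str(rep_dir.relative_to(out)))
        cells.append({"n": n, "p": p, "lam": lam, "replicates": reps})
    manifest = {
        "seed": seed,
        "n_reps": n_reps,
        "spectrum": spectrum,
        "n_datasets": sum(len(c["replicates"]) for c in cells),
        "cells": cells,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
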