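"""The probabilistic model of microbiota evolution.

Log absolute abundances logX (n hosts x p microbial taxa) follow a
multivariate Brownian motion along the host phylogeny after a Pagel's
lambda transformation: row i of logX is the state at tip i, the root state
is logZ0, and increments over a branch of length t are MVN(0, t*R). Only
relative abundances Z are observed; the latent per-host log total
abundances logYtilde link the two through logX_ij = logZ_ij + logYtilde_i.
The root total is fixed at 1 (Ytilde_0 = 1), which pins the root state to
the simplex vector Z0 and makes the latent scale identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import Phylogeny, lambda_transform, phylo_covariance

__all__ = [
    "CompositionTable",
    "ModelParams",
    "assemble_latent_logX",
    "log_likelihood",
    "matrix_normal_logpdf",
    "DEFAULT_FLOOR",
]

#: default detection floor for relative abundances (0.001%)
DEFAULT_FLOOR = 1e-5

_ROW_SUM_TOL = 1e-8


@dataclass(frozen=True, eq=False)
class CompositionTable:
    """Host-species x microbial-taxon relative abundances on the simplex.

    Every row sums to 1 and every entry is strictly positive (zeros must be
    replaced by a detection floor upstream; see ``io_cli.prepare_table``).
    """

    values: np.ndarray
    host_ids: list
    taxon_ids: list

    def __post_init__(self):
        Z = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", Z)
        object.__setattr__(self, "host_ids", list(self.host_ids))
        object.__setattr__(self, "taxon_ids", list(self.taxon_ids))
        n, p = Z.shape
        if n != len(self.host_ids) or p != len(self.taxon_ids):
            raise ValueError("values shape does not match host/taxon labels")
        if len(set(self.host_ids)) != n:
            raise ValueError("duplicate host ids")
        if np.any(Z <= 0):
            bad = np.argwhere(Z <= 0)[0]
            raise ValueError(
                f"non-positive relative abundance at host {self.host_ids[bad[0]]}, "
                f"taxon {self.taxon_ids[bad[1]]}; apply a detection floor first"
            )
        if np.any(np.abs(Z.sum(axis=1) - 1.0) > _ROW_SUM_TOL):
            raise ValueError("every row must sum to 1 (within 1e-8)")

    @property
    def n_hosts(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.host_ids, columns=self.taxon_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionTable":
        return cls(
            values=df.to_numpy(dtype=float),
            host_ids=[str(i) for i in df.index],
            taxon_ids=[str(c) for c in df.columns],
        )

    @classmethod
    def read_tsv(cls, path, sep: str = "\t") -> "CompositionTable":
        return cls.from_frame(pd.read_csv(path, sep=sep, index_col=0))

    def write_tsv(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="host")

    def reorder(self, host_ids) -> "CompositionTable":
        idx = [self.host_ids.index(h) for h in host_ids]
        return CompositionTable(self.values[idx], list(host_ids), self.taxon_ids)


@dataclass(frozen=True, eq=False)
class ModelParams:
    """Parameters (and latent states) of the Brownian microbiota model.

    lam : Pagel's lambda in [0, 1] (phylosymbiosis).
    Z0 : ancestral relative abundances at the root (simplex p-vector).
    R : p x p symmetric positive-definite per-unit-time rate matrix.
    logYtilde : n-vector of latent log total abundances relative to the root.
    """

    lam: float
    Z0: np.ndarray
    R: np.ndarray
    logYtilde: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "Z0", np.asarray(self.Z0, dtype=float))
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        if self.logYtilde is not None:
            object.__setattr__(
                self, "logYtilde", np.asarray(self.logYtilde, dtype=float)
            )
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {self.lam}")
        if np.any(self.Z0 <= 0) or abs(self.Z0.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError("Z0 must be strictly positive and sum to 1")
        if self.R.shape != (self.Z0.size, self.Z0.size):
            raise ValueError("R must be p x p")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")

    @property
    def p(self) -> int:
        return self.Z0.size


def assemble_latent_logX(data: CompositionTable, logYtilde: np.ndarray) -> np.ndarray:
    """Latent log absolute abundances: logX_ij = log Z_ij + logYtilde_i."""
    y = np.asarray(logYtilde, dtype=float)
    if y.shape != (data.n_hosts,):
        raise ValueError(f"logYtilde must have shape ({data.n_hosts},)")
    return np.log(data.values) + y[:, None]


def matrix_normal_logpdf(
    X: np.ndarray, M: np.ndarray, C: np.ndarray, R: np.ndarray
) -> float:
    """Log-density of a matrix normal with row covariance C, column covariance R.

    Evaluated through separate Cholesky factors of C (n x n) and R (p x p),
    equivalent to an MVN over vec(X) with covariance C (x) R (Kronecker).
    """
    n, p = X.shape
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "phylogenetic covariance C is not positive definite"
        ) from e
    try:
        Lr = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("rate matrix R is not positive definite") from e
    D = X - M
    # solve Lc A = D and Lr B' = A' so that ||B||^2 = tr(C^-1 D R^-1 D')
    A = np.linalg.solve(Lc, D)
    B = np.linalg.solve(Lr, A.T)
    quad = float(np.sum(B * B))
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(Lc))))
    logdet_R = 2.0 * float(np.sum(np.log(np.diag(Lr))))
    return -0.5 * (n * p * np.log(2.0 * np.pi) + p * logdet_C + n * logdet_R + quad)


def log_likelihood(
    params: ModelParams, data: CompositionTable, tree: Phylogeny
) -> float:
    """Joint log-density of the tip states implied by the data and latents.

    With C the Brownian covariance of the lambda-transformed tree, the
    matrix logX (rows ordered like the tree's tips) is matrix normal with
    mean 1 * logZ0' , row covariance C and column covariance R. The
    latent logYtilde in ``params`` is required to assemble logX.
    """
    if params.logYtilde is None:
        raise ValueError("params.logYtilde is required to assemble logX")
    tip_labels = tree.tip_labels
    if set(data.host_ids) != set(tip_labels):
        missing = set(tip_labels) ^ set(data.host_ids)
        raise ValueError(f"host ids and tree tips do not match: {sorted(missing)}")
    idx = [data.host_ids.index(h) for h in tip_labels]
    table = data.reorder(tip_labels)
    logX = assemble_latent_logX(table, params.logYtilde[idx])
    C = phylo_covariance(lambda_transform(tree, params.lam)).matrix
    M = np.ones((table.n_hosts, 1)) * np.log(params.Z0)[None, :]
    return matrix_normal_logpdf(logX, M, C, params.R)
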