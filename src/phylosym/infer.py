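"""Bayesian inference of the Brownian microbiota model.

The joint posterior P(lambda, Z0, R, logYtilde | Z, C) is sampled in two
stages. First, the latent log total abundances logYtilde are marginalized
analytically: given (lambda, Z0, R) the model is linear-Gaussian in
logYtilde, so the observed log relative abundances have the marginal
distribution

    vec(logZ) ~ MVN( 1 (x) logZ0 ,  C_lambda (x) R + tau^2 I_n (x) J_p )

with J_p the all-ones matrix and tau the prior scale of logYtilde. Because
an ultrametric tree satisfies C_lambda = lambda*C + (1-lambda)*T*I, a single
eigendecomposition of C block-diagonalizes this covariance for *every*
lambda, making the marginal likelihood O(n p^3) per evaluation and cheap to
vectorize. The reduced posterior over (lambda, Z0, R) -- some tens of
dimensions -- is explored with an ensemble MCMC sampler (emcee, mixing
differential-evolution moves), initialized from a Laplace approximation
around the posterior mode; logYtilde draws are then recovered exactly from
their Gaussian conditional for each retained draw. Convergence is assessed
with rank-normalized split-R-hat and effective sample sizes (arviz),
treating walkers as chains.

Priors (the model itself does not dictate them): lambda ~ Uniform(0, 1);
the root composition is parameterized by an additive-log-ratio vector with
a flat prior; R = diag(sigma) Omega diag(sigma) with sigma half-normal
(scale 2.5 on the depth-1 tree) and Omega ~ LKJ(1) (uniform over
correlation matrices); logYtilde_i ~ Normal(0, 5) i.i.d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp as _scipy_logsumexp

from .model import CompositionTable, ModelParams
from .phylo import Phylogeny, phylo_covariance, rescale_depth

__all__ = [
    "SamplerConfig",
    "PosteriorSummary",
    "PermutationResult",
    "MarginalModel",
    "fit",
    "fit_map",
    "mean_estimates",
    "covariance_significance",
    "lambda_permutation_test",
]

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------
# unconstrained parameterization
# ---------------------------------------------------------------------

class ParamTransform:
    """Bijection between an unconstrained vector and (lambda, Z0, R).

    Layout: [logit(lambda), alr(Z0) (p-1), log(sigma) (p),
    atanh-canonical partial correlations of Omega (p(p-1)/2)].
    ``log_prior`` returns prior density plus all change-of-variable
    Jacobians on the unconstrained scale.
    """

    def __init__(self, p: int, sigma_scale: float = 2.5):
        if p < 2:
            raise ValueError("inference requires at least 2 taxa")
        self.p = p
        self.sigma_scale = sigma_scale
        self.n_corr = p * (p - 1) // 2
        self.dim = 1 + (p - 1) + p + self.n_corr

    def split(self, theta: np.ndarray):
        p = self.p
        t = theta[..., 0]
        alpha = theta[..., 1:p]
        log_sigma = theta[..., p : 2 * p]
        w = theta[..., 2 * p :]
        return t, alpha, log_sigma, w

    def constrain(self, theta: np.ndarray):
        """Map (W, dim) unconstrained draws to constrained parameters.

        Returns ``(lam, logZ0, R, log_prior)`` with leading walker axis.
        """
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        p = self.p
        t, alpha, log_sigma, w = self.split(theta)

        with np.errstate(over="ignore"):
            lam = 1.0 / (1.0 + np.exp(-t))
        # uniform prior on lambda + logit jacobian
        lp = np.where(
            (lam > 0.0) & (lam < 1.0),
            np.log(np.clip(lam, 1e-300, None))
            + np.log(np.clip(1.0 - lam, 1e-300, None)),
            -np.inf,
        )

        full = np.concatenate([alpha, np.zeros((W, 1))], axis=-1)
        logZ0 = full - _scipy_logsumexp(full, axis=-1, keepdims=True)

        sigma = np.exp(log_sigma)
        # half-normal prior on sigma, plus d sigma / d log sigma = sigma
        lp = lp - 0.5 * np.sum(sigma**2, axis=-1) / self.sigma_scale**2
        lp = lp + np.sum(log_sigma, axis=-1)

        L, lp_corr = self._corr_cholesky(w)
        lp = lp + lp_corr

        Ls = sigma[..., :, None] * L  # Cholesky factor of R
        R = Ls @ np.swapaxes(Ls, -1, -2)
        return lam, logZ0, R, lp

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Prior + transform Jacobians only (vectorized, cheap: no data)."""
        return self.constrain(theta)[3]

    def _corr_cholesky(self, w: np.ndarray):
        """Unconstrained -> Cholesky factor of a correlation matrix.

        Canonical-partial-correlation construction; the returned log term
        combines the LKJ(1) density (uniform over correlation matrices)
        with the full transform Jacobian.
        """
        W = w.shape[0]
        p = self.p
        z = np.tanh(w)
        L = np.zeros((W, p, p))
        L[:, 0, 0] = 1.0
        lp = np.sum(np.log1p(-np.clip(z, -1 + 1e-15, 1 - 1e-15) ** 2), axis=-1)
        k = 0
        for i in range(1, p):
            s = np.zeros(W)
            for j in range(i):
                rem = np.clip(1.0 - s, 1e-300, None)
                L[:, i, j] = z[:, k] * np.sqrt(rem)
                lp = lp + 0.5 * np.log(rem)
                s = s + L[:, i, j] ** 2
                k += 1
            L[:, i, i] = np.sqrt(np.clip(1.0 - s, 1e-300, None))
            # LKJ(eta=1) Cholesky density: (p - i - 1) * log L_ii (0-indexed)
            if p - i - 1 > 0:
                lp = lp + (p - i - 1) * np.log(L[:, i, i])
        return L, lp

    def initial(self, data_logZ: np.ndarray) -> np.ndarray:
        """A data-informed starting point on the unconstrained scale."""
        mean_log = data_logZ.mean(axis=0)
        logZ0 = mean_log - _scipy_logsumexp(mean_log)
        alpha = logZ0[:-1] - logZ0[-1]
        sigma = np.clip(data_logZ.std(axis=0), 0.05, None)
        return np.concatenate([[0.0], alpha, np.log(sigma), np.zeros(self.n_corr)])


# ---------------------------------------------------------------------
# marginal model
# ---------------------------------------------------------------------

class MarginalModel:
    """Posterior of (lambda, Z0, R) with logYtilde integrated out.

    The tree is rescaled to unit depth internally (``scale_factor`` maps a
    unit-depth rate matrix back to the original time units: R_orig =
    R_unit / scale_factor).
    """

    def __init__(
        self,
        tree: Phylogeny,
        data: CompositionTable,
        logy_prior_sd: float = 5.0,
        sigma_prior_scale: float = 2.5,
    ):
        tip_labels = tree.tip_labels
        if set(data.host_ids) != set(tip_labels):
            diff = sorted(set(data.host_ids) ^ set(tip_labels))
            raise ValueError(
                f"table hosts and tree tips differ (align first): {diff[:5]}"
            )
        data = data.reorder(tip_labels)
        self.data = data
        self.host_ids = tip_labels
        self.taxon_ids = data.taxon_ids
        self.n, self.p = data.n_hosts, data.n_taxa
        unit_tree, self.scale_factor = rescale_depth(tree, 1.0)
        self.tree = tree
        C = phylo_covariance(unit_tree).matrix
        d, U = np.linalg.eigh(C)
        self.eigvals = np.clip(d, 0.0, None)
        self.U = U
        self.logZ = np.log(data.values)
        self.G = U.T @ self.logZ
        self.u1 = U.T @ np.ones(self.n)
        self.tau2 = float(logy_prior_sd) ** 2
        self.transform = ParamTransform(self.p, sigma_scale=sigma_prior_scale)

    # -- likelihood ----------------------------------------------------
    def loglik(self, lam, logZ0, R) -> np.ndarray:
        """Marginal log-likelihood, vectorized over a walker axis."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        logZ0 = np.atleast_2d(logZ0)
        R = np.asarray(R, dtype=float)
        if R.ndim == 2:
            R = R[None]
        W = lam.shape[0]
        n, p = self.n, self.p
        dl = lam[:, None] * self.eigvals[None, :] + (1.0 - lam[:, None])  # (W, n)
        S = dl[:, :, None, None] * R[:, None, :, :] + self.tau2  # + tau^2 * J
        r = self.G[None, :, :] - self.u1[None, :, None] * logZ0[:, None, :]
        try:
            Lch = np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            # per-walker fallback: mark failures as -inf
            out = np.full(W, -np.inf)
            for wdx in range(W):
                try:
                    Lw = np.linalg.cholesky(S[wdx])
                except np.linalg.LinAlgError:
                    continue
                y = np.linalg.solve(Lw, r[wdx][..., None])[..., 0]
                out[wdx] = -0.5 * (
                    n * p * _LOG2PI
                    + 2.0 * np.sum(np.log(np.diagonal(Lw, axis1=-2, axis2=-1)))
                    + np.sum(y**2)
                )
            return out
        y = np.linalg.solve(Lch, r[..., None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(Lch, axis1=-2, axis2=-1)), axis=(-2, -1))
        quad = np.sum(y**2, axis=(-2, -1))
        return -0.5 * (n * p * _LOG2PI + logdet + quad)

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior on the unconstrained scale (vectorized)."""
        theta = np.atleast_2d(theta)
        lam, logZ0, R, lp = self.transform.constrain(theta)
        ok = np.isfinite(lp)
        out = np.full(theta.shape[0], -np.inf)
        if np.any(ok):
            ll = self.loglik(lam[ok], logZ0[ok], R[ok])
            out[ok] = lp[ok] + ll
        out[~np.isfinite(out)] = -np.inf
        return out

    def _loglik_param_grads(self, lam: float, logZ0, R):
        """Log-likelihood and its gradients w.r.t. (lambda, logZ0, R).

        Closed-form derivatives of the block-diagonalized Gaussian: with
        S_i = d_i(lambda) R + tau^2 J and a_i = S_i^-1 r_i,
        d l/d R = -1/2 sum_i d_i (S_i^-1 - a_i a_i'), etc.
        """
        n, p = self.n, self.p
        dl = lam * self.eigvals + (1.0 - lam)
        S = dl[:, None, None] * R[None] + self.tau2
        r = self.G - self.u1[:, None] * logZ0[None, :]
        Lch = np.linalg.cholesky(S)
        a = np.linalg.solve(S, r[..., None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(Lch, axis1=-2, axis2=-1)))
        quad = float(np.sum(r * a))
        ll = -0.5 * (n * p * _LOG2PI + logdet + quad)
        Sinv = np.linalg.solve(S, np.broadcast_to(np.eye(p), (n, p, p)).copy())
        B = Sinv - a[:, :, None] * a[:, None, :]
        gR = -0.5 * np.einsum("i,ijk->jk", dl, B)
        glam = -0.5 * float(np.sum((self.eigvals - 1.0)[:, None, None] * B * R[None]))
        gz0 = (self.u1[:, None] * a).sum(axis=0)
        return ll, glam, gR, gz0

    def log_posterior_with_grad(self, theta: np.ndarray):
        """Log posterior and its gradient at one unconstrained point.

        The likelihood part is differentiated analytically and chained
        through the constraining transforms; the prior/Jacobian part is
        differentiated by central differences (it involves no data and is
        O(p^2) per evaluation).
        """
        theta = np.asarray(theta, dtype=float)
        tr = self.transform
        p = tr.p
        lam, logZ0, R, lp = tr.constrain(theta[None])
        if not np.isfinite(lp[0]):
            return -np.inf, np.zeros_like(theta)
        lam = float(lam[0])
        logZ0 = logZ0[0]
        try:
            ll, glam, gR, gz0 = self._loglik_param_grads(lam, logZ0, R[0])
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros_like(theta)

        _, _, log_sigma, w = tr.split(theta)
        sigma = np.exp(log_sigma)
        z = np.tanh(w)
        L, _ = tr._corr_cholesky(w[None])
        L = L[0]
        Ls = sigma[:, None] * L

        # lambda <- logit
        gt = glam * lam * (1.0 - lam)
        # logZ0 <- alr (softmax with fixed last coordinate)
        s = np.exp(logZ0)
        gfull = gz0 - s * gz0.sum()
        galpha = gfull[: p - 1]
        # R = Ls Ls' <- (sigma, L); gR is symmetric by construction
        gLs = 2.0 * gR @ Ls
        glog_sigma = (gLs * L).sum(axis=1) * sigma
        gL = sigma[:, None] * gLs
        # L <- canonical partial correlations (row-wise reverse pass)
        gz = np.zeros_like(w)
        k0 = 0
        for i in range(1, p):
            rem = np.empty(i + 1)
            ssum = 0.0
            for j in range(i):
                rem[j] = max(1.0 - ssum, 1e-300)
                ssum += L[i, j] ** 2
            rem[i] = max(1.0 - ssum, 1e-300)
            gs = gL[i, i] * (-0.5 / max(L[i, i], 1e-150))
            for j in range(i - 1, -1, -1):
                Lbar = gL[i, j] + gs * 2.0 * L[i, j]
                sq = np.sqrt(rem[j])
                gz[k0 + j] = Lbar * sq
                gs = gs + Lbar * (-z[k0 + j] / (2.0 * sq))
            k0 += i
        gw = gz * (1.0 - z**2)

        grad = np.concatenate([[gt], galpha, glog_sigma, gw])
        grad = grad + _fd_grad(tr.log_prior, theta)
        return ll + float(lp[0]), grad

    # -- latent totals -------------------------------------------------
    def conditional_logY(self, lam, logZ0, R, rng=None):
        """Gaussian conditional of logYtilde given data and one parameter draw.

        Returns the conditional mean, or an exact draw when ``rng`` is given.
        """
        dl = lam * self.eigvals + (1.0 - lam)
        Rinv1 = np.linalg.solve(R, np.ones(self.p))
        c = float(np.sum(Rinv1))
        e = self.u1[:, None] * logZ0[None, :] - self.G
        with np.errstate(divide="ignore"):
            inv_dl = np.where(dl > 1e-12, 1.0 / np.clip(dl, 1e-12, None), 0.0)
        b = inv_dl * (e @ Rinv1)
        q = c * inv_dl + 1.0 / self.tau2
        mean = self.U @ (b / q)
        if rng is None:
            return mean
        return mean + self.U @ (rng.standard_normal(self.n) / np.sqrt(q))


# ---------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------

@dataclass(eq=False)
class PosteriorSummary:
    """Posterior draws and per-parameter summaries for one model fit.

    ``draws`` maps parameter names to arrays with leading (chain, draw)
    axes: ``lam`` (C, D), ``Z0``/``sigma`` (C, D, p), ``R`` (C, D, p, p),
    ``logY`` (C, D, n). R is reported in the time units of the input tree.
    """

    draws: dict
    host_ids: list
    taxon_ids: list
    scale_factor: float
    config: "SamplerConfig"
    warnings: list = field(default_factory=list)
    _table: pd.DataFrame | None = field(default=None, repr=False)

    def flat(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def summary(self) -> pd.DataFrame:
        if self._table is None:
            self._table = _summary_table(self)
        return self._table

    def row(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def _scalar_views(post: PosteriorSummary):
    """Yield (name, (chain, draw) array) for every scalar parameter."""
    p = len(post.taxon_ids)
    yield "lam", post.draws["lam"]
    for j, tx in enumerate(post.taxon_ids):
        yield f"Z0[{tx}]", post.draws["Z0"][..., j]
    for j, tx in enumerate(post.taxon_ids):
        yield f"sigma[{tx}]", post.draws["sigma"][..., j]
    for j in range(p):
        for k in range(j, p):
            yield f"R[{post.taxon_ids[j]},{post.taxon_ids[k]}]", post.draws["R"][..., j, k]
    for i, h in enumerate(post.host_ids):
        yield f"logY[{h}]", post.draws["logY"][..., i]


def _summary_table(post: PosteriorSummary) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name, a in _scalar_views(post):
        flat = a.reshape(-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(a)) if a.shape[0] > 1 else np.nan
            ess = float(az.ess(a))
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": rhat,
                "ess": ess,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-MCMC settings.

    ``iterations`` counts ensemble steps (default 4,000 with a 2,000-step
    warmup, a conservative choice for posteriors of this size); ``chains`` sets
    the minimum number of walker groups used for convergence diagnostics,
    while the actual number of walkers is at least twice the number of
    free parameters. ``max_kept`` caps the total retained draws by
    thinning, which bounds memory and the cost of the exact logYtilde
    conditional draws.
    """

    iterations: int = 4000
    warmup: int = 2000
    chains: int = 4
    walkers: int | None = None
    seed: int | None = None
    max_kept: int = 8000
    logy_prior_sd: float = 5.0
    sigma_prior_scale: float = 2.5
    rhat_warn: float = 1.01
    ess_warn: float = 200.0
    progress: bool = False


def _fd_grad(f, theta, h=1e-5):
    """Batched central-difference gradient of a vectorized scalar field."""
    d = theta.size
    hs = h * (1.0 + np.abs(theta))
    pts = np.concatenate(
        [theta[None] + np.diag(hs), theta[None] - np.diag(hs)], axis=0
    )
    vals = f(pts)
    return (vals[:d] - vals[d:]) / (2.0 * hs)


def _fd_hessian(f, theta, h=1e-4, chunk=1024):
    d = theta.size
    hs = h * (1.0 + np.abs(theta))
    pts = [theta]
    idx = []
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = hs[i]
            ej[j] = hs[j]
            pts.extend([theta + ei + ej, theta + ei - ej, theta - ei + ej, theta - ei - ej])
            idx.append((i, j))
    pts = np.array(pts)
    vals = np.concatenate([f(pts[k : k + chunk]) for k in range(0, len(pts), chunk)])
    H = np.zeros((d, d))
    for k, (i, j) in enumerate(idx):
        vpp, vpm, vmp, vmm = vals[1 + 4 * k : 5 + 4 * k]
        H[i, j] = H[j, i] = (vpp - vpm - vmp + vmm) / (4.0 * hs[i] * hs[j])
    return H


def _find_map(
    mm: MarginalModel,
    maxiter: int = 300,
    extra_starts=(0.3, 0.8),
    x0=None,
    ftol: float = 1e-9,
):
    """Posterior mode on the unconstrained scale (multi-start L-BFGS).

    ``x0`` adds an explicit warm start (e.g. the mode of an unshuffled
    dataset when fitting its permutations).
    """
    base = mm.transform.initial(mm.logZ)

    def negboth(theta_flat):
        v, g = mm.log_posterior_with_grad(theta_flat)
        if not np.isfinite(v):
            return 1e18, np.zeros_like(theta_flat)
        return -v, -g

    starts = [] if x0 is None else [np.asarray(x0, dtype=float)]
    for lam0 in extra_starts:
        s = base.copy()
        s[0] = np.log(lam0 / (1.0 - lam0))
        starts.append(s)
    best = None
    for s in starts:
        res = minimize(
            negboth, s, jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": ftol},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, -best.fun


def fit_map(
    tree: Phylogeny,
    data: CompositionTable,
    logy_prior_sd: float = 5.0,
    sigma_prior_scale: float = 2.5,
    maxiter: int = 300,
) -> ModelParams:
    """Posterior-mode point estimate (fast; used for permutation nulls)."""
    mm = MarginalModel(tree, data, logy_prior_sd, sigma_prior_scale)
    theta, _ = _find_map(mm, maxiter=maxiter)
    lam, logZ0, R, _ = mm.transform.constrain(theta[None])
    logY = mm.conditional_logY(lam[0], logZ0[0], R[0])
    return ModelParams(
        lam=float(lam[0]),
        Z0=np.exp(logZ0[0]),
        R=R[0] / mm.scale_factor,
        logYtilde=logY,
    )


def fit(
    tree: Phylogeny,
    data: CompositionTable,
    config: SamplerConfig | None = None,
) -> PosteriorSummary:
    """Sample the joint posterior of (lambda, Z0, R, logYtilde).

    The reduced posterior over (lambda, Z0, R) is sampled with an ensemble
    of walkers (differential-evolution moves) started from a Laplace
    approximation at the posterior mode; logYtilde is drawn exactly from
    its Gaussian conditional for every retained draw. Deterministic given
    ``config.seed``.
    """
    import emcee

    cfg = config or SamplerConfig()
    if data.n_taxa < 2 or data.n_hosts < 2:
        raise ValueError("fit requires at least 2 hosts and 2 taxa")
    mm = MarginalModel(tree, data, cfg.logy_prior_sd, cfg.sigma_prior_scale)
    d = mm.transform.dim
    nwalk = cfg.walkers or max(2 * d + 2, 4 * cfg.chains, 32)
    nwalk += nwalk % 2
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed) if cfg.seed is not None else None
    )

    theta_map, _ = _find_map(mm)
    # Laplace scatter for the initial ensemble
    H = _fd_hessian(mm.log_posterior, theta_map)
    try:
        cov = np.linalg.inv(-H)
        scat = np.linalg.cholesky(0.25 * (cov + cov.T) / 2.0)
    except np.linalg.LinAlgError:
        scat = 0.05 * np.eye(d)
    p0 = theta_map[None, :] + rng.standard_normal((nwalk, d)) @ scat.T
    bad = ~np.isfinite(mm.log_posterior(p0))
    p0[bad] = theta_map[None, :] + 0.01 * rng.standard_normal((int(bad.sum()), d))

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        nwalk, d, mm.log_posterior, vectorize=True, moves=moves
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(2**31 - 1)
    ).get_state()
    sampler.run_mcmc(p0, cfg.iterations, progress=cfg.progress)

    kept = sampler.get_chain(discard=cfg.warmup)  # (steps, walkers, d)
    thin = max(1, int(np.ceil(kept.shape[0] * nwalk / cfg.max_kept)))
    kept = kept[::thin]
    steps = kept.shape[0]
    theta = kept.reshape(-1, d)

    lam, logZ0, R, _ = mm.transform.constrain(theta)
    sigma = np.sqrt(np.diagonal(R, axis1=-2, axis2=-1))
    logY = np.empty((theta.shape[0], mm.n))
    for k in range(theta.shape[0]):
        logY[k] = mm.conditional_logY(lam[k], logZ0[k], R[k], rng=rng)

    def chainshape(a):
        return np.swapaxes(a.reshape(steps, nwalk, *a.shape[1:]), 0, 1)

    draws = {
        "lam": chainshape(lam),
        "Z0": chainshape(np.exp(logZ0)),
        "sigma": chainshape(sigma / np.sqrt(mm.scale_factor)),
        "R": chainshape(R / mm.scale_factor),
        "logY": chainshape(logY),
    }
    post = PosteriorSummary(
        draws=draws,
        host_ids=mm.host_ids,
        taxon_ids=mm.taxon_ids,
        scale_factor=mm.scale_factor,
        config=cfg,
    )
    _collect_warnings(post, sampler)
    return post


def _collect_warnings(post: PosteriorSummary, sampler) -> None:
    accept = float(np.mean(sampler.acceptance_fraction))
    if accept < 0.1:
        post.warnings.append(
            f"low ensemble acceptance fraction ({accept:.2f}); "
            "draws may be strongly autocorrelated"
        )
    tab = post.summary
    bad_rhat = tab.index[tab["rhat"] > post.config.rhat_warn].tolist()
    if bad_rhat:
        post.warnings.append(
            f"R-hat > {post.config.rhat_warn} for {len(bad_rhat)} parameter(s), "
            f"e.g. {bad_rhat[:3]}; consider more iterations"
        )
    bad_ess = tab.index[tab["ess"] < post.config.ess_warn].tolist()
    if bad_ess:
        post.warnings.append(
            f"ESS < {post.config.ess_warn:g} for {len(bad_ess)} parameter(s), "
            f"e.g. {bad_ess[:3]}"
        )
    for w in post.warnings:
        warnings.warn(w, stacklevel=3)


def mean_estimates(post: PosteriorSummary) -> ModelParams:
    """Posterior-mean point estimates as a valid ModelParams.

    Z0 is renormalized to the simplex; if the mean of R is not positive
    definite it is projected to the nearest SPD matrix (eigenvalue clip).
    """
    Z0 = post.flat("Z0").mean(axis=0)
    Z0 = Z0 / Z0.sum()
    R = post.flat("R").mean(axis=0)
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w.min() <= 0:
        warnings.warn("posterior-mean R indefinite; projecting to nearest SPD")
        w = np.clip(w, 1e-10 * max(w.max(), 1.0), None)
        R = (V * w[None, :]) @ V.T
    return ModelParams(
        lam=float(post.flat("lam").mean()),
        Z0=Z0,
        R=R,
        logYtilde=post.flat("logY").mean(axis=0),
    )


def covariance_significance(post: PosteriorSummary, level: float = 0.95) -> np.ndarray:
    """Sign matrix of credible covariances.

    +1 where the central credible interval of R_jk lies entirely above 0,
    -1 entirely below, 0 otherwise; variances (diagonal) are +1 by
    construction.
    """
    Rd = post.flat("R")
    lo = np.quantile(Rd, (1.0 - level) / 2.0, axis=0)
    hi = np.quantile(Rd, 1.0 - (1.0 - level) / 2.0, axis=0)
    sig = np.zeros(lo.shape, dtype=int)
    sig[lo > 0] = 1
    sig[hi < 0] = -1
    np.fill_diagonal(sig, 1)
    return sig


# ---------------------------------------------------------------------
# permutation test for phylosymbiosis
# ---------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class PermutationResult:
    """Observed vs permuted phylosymbiosis estimates.

    ``p_value`` uses the add-one rule (1 + #{null >= observed}) /
    (1 + #null); significance at 5% corresponds to the observed lambda
    exceeding at least 95% of the permuted values.
    """

    observed_lambda: float
    null_lambdas: np.ndarray
    p_value: float
    constraint: str | None = None

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _grouped_permutation(rng, groups: np.ndarray) -> np.ndarray:
    """A permutation that only exchanges indices sharing a group label."""
    perm = np.arange(groups.size)
    n_exchangeable = 0
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            n_exchangeable += idx.size
            perm[idx] = rng.permutation(idx)
    if n_exchangeable == 0:
        raise ValueError("no permutation possible: every group is a singleton")
    return perm


def lambda_permutation_test(
    tree: Phylogeny,
    data: CompositionTable,
    n_perm: int = 100,
    groups=None,
    seed=None,
    estimator: str = "map",
    config: SamplerConfig | None = None,
) -> PermutationResult:
    """Permutation test for the significance of phylosymbiosis.

    Host species are shuffled at random (optionally only within identical
    trait groups) to break the phylogenetic structure, the model is
    refitted to every shuffled dataset, and the observed lambda is
    compared against the permutation null. ``estimator`` selects how
    lambda is estimated for the observed and every permuted dataset:
    ``"map"`` (posterior mode, fast; the default) or ``"mcmc"``
    (posterior mean from a full ensemble run; slower but exactly the
    estimator reported by ``fit``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = data.reorder(tree.tip_labels)
    if groups is not None:
        if hasattr(groups, "get"):
            garr = np.array([str(groups.get(h)) for h in data.host_ids])
        else:
            garr = np.asarray(groups).astype(str)
            if garr.size != data.n_hosts:
                raise ValueError("groups must map every host to a label")
    else:
        garr = np.zeros(data.n_hosts)

    if estimator not in ("map", "mcmc"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_perm + 2)
    rng_perm = np.random.default_rng(child[0])
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in child[1:]]

    theta_obs = None
    if estimator == "map":
        mm = MarginalModel(tree, data)
        theta_obs, _ = _find_map(mm)
        observed = float(mm.transform.constrain(theta_obs[None])[0][0])
    else:
        cfg = config or SamplerConfig()
        cfg = SamplerConfig(**{**cfg.__dict__, "seed": seeds[0]})
        observed = float(fit(tree, data, cfg).flat("lam").mean())

    nulls = np.empty(n_perm)
    for k in range(n_perm):
        perm = _grouped_permutation(rng_perm, garr)
        shuffled = CompositionTable(
            data.values[perm], data.host_ids, data.taxon_ids
        )
        if estimator == "map":
            # warm-start each null fit from the observed-data mode
            mm_k = MarginalModel(tree, shuffled)
            th, _ = _find_map(
                mm_k, x0=theta_obs, extra_starts=(0.5,), maxiter=150, ftol=1e-7
            )
            nulls[k] = float(mm_k.transform.constrain(th[None])[0][0])
        else:
            cfg_k = SamplerConfig(**{**(config or SamplerConfig()).__dict__,
                                     "seed": seeds[k + 1]})
            nulls[k] = float(fit(tree, shuffled, cfg_k).flat("lam").mean())
    p = (1.0 + float(np.sum(nulls >= observed))) / (1.0 + n_perm)
    label = None
    if groups is not None:
        sizes = pd.Series(garr).value_counts()
        label = f"{sizes.size} group(s), sizes {sorted(sizes.tolist(), reverse=True)}"
    return PermutationResult(
        observed_lambda=float(observed),
        null_lambdas=nulls,
        p_value=p,
        constraint=label,
    )
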