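"""Marginalized posterior, MAP/MCMC fitting, permutation machinery."""

import numpy as np
import pytest
from scipy.stats import kstest, multivariate_normal

import phylosym as ps
from phylosym.infer import (
    MarginalModel,
    ParamTransform,
    _fd_grad,
    _grouped_permutation,
)
from phylosym.phylo import lambda_transform, phylo_covariance, rescale_depth
from phylosym.simulate import SimulationConfig, simulate_dataset

FAST = ps.SamplerConfig(iterations=600, warmup=200, seed=7)


@pytest.fixture(scope="module")
def medium_fit(medium_dataset):
    import warnings

    tree, table, _ = medium_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ps.fit(tree, table, ps.SamplerConfig(iterations=800, warmup=300, seed=1))


class TestMarginalLikelihood:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_construction(self, seed):
        """Eigen-trick marginal equals the dense n*p Gaussian marginal."""
        rng = np.random.default_rng(seed)
        cfg = SimulationConfig(n=int(rng.integers(3, 7)), p=int(rng.integers(2, 4)),
                               lam=0.7, seed=seed)
        tree, table, _ = simulate_dataset(cfg, spectrum="random")
        mm = MarginalModel(tree, table)
        lam = float(rng.uniform())
        R = ps.random_spd(table.n_taxa, 0.4, seed=seed, spectrum="random")
        Z0 = ps.sample_root(table.n_taxa, seed=seed)
        ll = mm.loglik(np.array([lam]), np.log(Z0)[None], R[None])[0]
        ut, _ = rescale_depth(tree, 1.0)
        C = phylo_covariance(lambda_transform(ut, lam)).matrix
        n, p = table.n_hosts, table.n_taxa
        Sig = np.kron(C, R) + mm.tau2 * np.kron(np.eye(n), np.ones((p, p)))
        l = np.log(table.reorder(tree.tip_labels).values).reshape(-1)
        oracle = multivariate_normal.logpdf(l, mean=np.tile(np.log(Z0), n), cov=Sig)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_conditional_logy_matches_dense(self, cherry_dataset):
        tree, table, _ = cherry_dataset
        mm = MarginalModel(tree, table)
        p = table.n_taxa
        R = ps.random_spd(p, 0.3, seed=1, spectrum="random")
        Z0 = ps.sample_root(p, seed=2)
        lam = 0.4
        m = mm.conditional_logY(lam, np.log(Z0), R)
        ut, _ = rescale_depth(tree, 1.0)
        C = phylo_covariance(lambda_transform(ut, lam)).matrix
        n = table.n_hosts
        Sig = np.kron(C, R)
        A = np.kron(np.eye(n), np.ones((p, 1)))
        l = np.log(table.reorder(tree.tip_labels).values).reshape(-1)
        mu = np.tile(np.log(Z0), n)
        Si = np.linalg.inv(Sig)
        P = A.T @ Si @ A + np.eye(n) / mm.tau2
        oracle = np.linalg.solve(P, A.T @ Si @ (mu - l))
        assert np.abs(m - oracle).max() < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_analytic_gradient_matches_fd(self, seed):
        cfg = SimulationConfig(n=8, p=4, lam=0.6, seed=seed)
        tree, table, _ = simulate_dataset(cfg, spectrum="random")
        mm = MarginalModel(tree, table)
        rng = np.random.default_rng(seed)
        th = mm.transform.initial(mm.logZ) + 0.3 * rng.standard_normal(mm.transform.dim)
        _, g = mm.log_posterior_with_grad(th)
        gfd = _fd_grad(mm.log_posterior, th)
        assert np.max(np.abs(g - gfd) / (1.0 + np.abs(gfd))) < 1e-5


class TestPriorTransform:
    def test_prior_samples_match_target(self):
        """Prior-only MCMC: lambda uniform, p=2 correlation uniform on (-1, 1)."""
        import emcee

        tr = ParamTransform(2)
        rng = np.random.default_rng(0)
        sampler = emcee.EnsembleSampler(
            24, tr.dim, lambda th: tr.log_prior(th), vectorize=True
        )
        sampler.random_state = np.random.RandomState(0).get_state()
        sampler.run_mcmc(0.5 * rng.standard_normal((24, tr.dim)), 3000)
        theta = sampler.get_chain(discard=1000).reshape(-1, tr.dim)
        lam, _, R, _ = tr.constrain(theta)
        rho = R[:, 0, 1] / np.sqrt(R[:, 0, 0] * R[:, 1, 1])
        sub = slice(None, None, 40)  # thin for approximate independence
        assert kstest(lam[sub], "uniform").pvalue > 1e-3
        assert kstest((rho[sub] + 1) / 2, "uniform").pvalue > 1e-3

    def test_constrain_shapes_and_validity(self):
        tr = ParamTransform(4)
        rng = np.random.default_rng(1)
        theta = rng.standard_normal((50, tr.dim))
        lam, logZ0, R, lp = tr.constrain(theta)
        assert ((lam > 0) & (lam < 1)).all()
        assert np.allclose(np.exp(logZ0).sum(axis=1), 1.0)
        assert np.all(np.linalg.eigvalsh(R) > 0)
        assert np.isfinite(lp).all()


class TestFit:
    def test_map_recovers_lambda_extremes(self):
        cfg1 = SimulationConfig(n=50, p=5, lam=1.0, seed=11)
        tree, table, _ = simulate_dataset(cfg1, spectrum="random")
        assert ps.fit_map(tree, table).lam > 0.8
        cfg0 = SimulationConfig(n=50, p=5, lam=0.0, seed=12)
        tree0, table0, _ = simulate_dataset(cfg0, spectrum="random")
        assert ps.fit_map(tree0, table0).lam < 0.3

    def test_seed_determinism(self, star_data):
        tree, table, _ = star_data
        a = ps.fit(tree, table, FAST)
        b = ps.fit(tree, table, FAST)
        for name in ("lam", "Z0", "R", "logY"):
            assert np.array_equal(a.flat(name), b.flat(name))

    def test_summary_interval_contains_mean(self, medium_fit):
        tab = medium_fit.summary
        assert (tab["q2.5"] <= tab["mean"] + 1e-12).all()
        assert (tab["mean"] <= tab["q97.5"] + 1e-12).all()
        assert tab["rhat"].notna().all()
        assert (tab["ess"] > 0).all()

    def test_lambda_posterior_concentrates_high(self, medium_fit):
        assert medium_fit.flat("lam").mean() > 0.8

    def test_mean_estimates_valid(self, medium_fit):
        est = ps.mean_estimates(medium_fit)
        assert est.Z0.sum() == pytest.approx(1.0, abs=1e-8)
        row = medium_fit.row("lam")
        assert row["q2.5"] <= est.lam <= row["q97.5"]
        np.linalg.cholesky(est.R)  # SPD

    def test_r_reported_in_tree_time_units(self, medium_dataset, medium_fit):
        """Posterior R should be on the original (unrescaled) time scale."""
        _, _, truth = medium_dataset
        R_mean = ps.mean_estimates(medium_fit).R
        # same order of magnitude as the generating per-unit-time rates
        assert 0.1 < np.trace(R_mean) / np.trace(truth.R) < 10

    def test_convergence_warnings_reported(self, star_data):
        """A deliberately strict R-hat threshold must produce a warning."""
        tree, table, _ = star_data
        cfg = ps.SamplerConfig(iterations=200, warmup=80, seed=2, rhat_warn=0.5)
        with pytest.warns(UserWarning, match="R-hat"):
            post = ps.fit(tree, table, cfg)
        assert any("R-hat" in w for w in post.warnings)

    def test_rejects_single_taxon(self, three_tip_tree):
        table = ps.CompositionTable(
            np.ones((3, 1)), three_tip_tree.tip_labels, ["only"]
        )
        with pytest.raises(ValueError):
            ps.fit(three_tip_tree, table, FAST)


class TestCovarianceSignificance:
    def test_sign_matrix_symmetric_diag_positive(self, medium_fit):
        sig = ps.covariance_significance(medium_fit)
        assert np.array_equal(sig, sig.T)
        assert (np.diag(sig) == 1).all()
        assert set(np.unique(sig)).issubset({-1, 0, 1})


class TestPermutation:
    def test_grouped_permutation_respects_groups(self):
        rng = np.random.default_rng(0)
        groups = np.array(["a", "a", "b", "b", "b", "c"])
        for _ in range(50):
            perm = _grouped_permutation(rng, groups)
            assert (groups[perm] == groups).all()
            assert perm[5] == 5  # singleton fixed
        assert any(
            not np.array_equal(_grouped_permutation(rng, groups), np.arange(6))
            for _ in range(20)
        )

    def test_all_singletons_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="no permutation possible"):
            _grouped_permutation(rng, np.array(["a", "b", "c"]))

    def test_add_one_rule_and_reproducibility(self, star_data):
        tree, table, _ = star_data
        res = ps.lambda_permutation_test(tree, table, n_perm=5, seed=3)
        count = int(np.sum(res.null_lambdas >= res.observed_lambda))
        assert res.p_value == pytest.approx((1 + count) / 6)
        assert res.p_value > 0
        res2 = ps.lambda_permutation_test(tree, table, n_perm=5, seed=3)
        assert np.array_equal(res.null_lambdas, res2.null_lambdas)
        assert len(res.null_lambdas) == 5

    def test_detects_strong_phylosymbiosis(self, medium_dataset):
        tree, table, _ = medium_dataset
        res = ps.lambda_permutation_test(tree, table, n_perm=20, seed=4)
        assert res.p_value <= 0.05
        assert res.significant

    def test_single_group_equals_unconstrained(self, star_data):
        tree, table, _ = star_data
        groups = {h: "all" for h in table.host_ids}
        a = ps.lambda_permutation_test(tree, table, n_perm=4, seed=5, groups=groups)
        b = ps.lambda_permutation_test(tree, table, n_perm=4, seed=5)
        assert np.array_equal(a.null_lambdas, b.null_lambdas)
        assert a.constraint is not None and b.constraint is None
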