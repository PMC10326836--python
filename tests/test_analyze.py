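"""CLR/PCA projections, diet centroids, integration clustering, Mantel, adequacy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phylosym as ps
from phylosym.analyze import (
    adequacy_check,
    clr_transform,
    diet_centroid_distances,
    integration_clusters,
    mantel_baseline,
    project_with_ancestor,
)
from phylosym.phylo import phylo_covariance

from conftest import random_table


class TestCLR:
    def test_uniform_row_maps_to_zero(self):
        assert np.allclose(clr_transform(np.full((1, 4), 0.25)), 0.0)

    def test_two_part_row(self):
        out = clr_transform(np.array([[0.8, 0.2]]))
        m = 0.5 * (np.log(0.8) + np.log(0.2))
        assert np.allclose(out, [[np.log(0.8) - m, np.log(0.2) - m]])
        assert out.sum() == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        Z = rng.uniform(0.01, 1.0, size=(20, 5))
        scales = rng.uniform(0.5, 10.0, size=(20, 1))
        assert np.abs(clr_transform(Z) - clr_transform(Z * scales)).max() < 1e-10

    def test_rejects_zero_entries(self):
        with pytest.raises(ValueError, match="floor"):
            clr_transform(np.array([[0.0, 1.0]]))

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=8),
        st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_clr_scale_invariance_property(self, row, scale):
        """clr(renormalize(x)) == clr(x): CLR ignores the row's total."""
        x = np.array([row])
        a = clr_transform(x / x.sum())
        b = clr_transform(x * scale)
        assert np.abs(a - b).max() < 1e-9
        assert abs(a.sum()) < 1e-9


class TestProjection:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(1)
        return random_table(rng, 30, 6)

    def test_centroid_ancestor_at_origin(self, table):
        X = clr_transform(table)
        centroid_clr = X.mean(axis=0)
        anc = np.exp(centroid_clr)
        anc /= anc.sum()
        proj = project_with_ancestor(table, anc, k=3)
        assert np.abs(proj.ancestor_scores[0]).max() < 1e-9

    def test_explained_variance_valid(self, table):
        proj = project_with_ancestor(table, ps.sample_root(6, seed=2), k=4)
        ev = proj.explained_variance
        assert (ev >= 0).all() and (ev <= 1).all()
        assert ev.sum() <= 1.0 + 1e-12
        assert (np.diff(ev) <= 1e-12).all()

    def test_passive_projection_reproduces_active(self, table):
        proj = project_with_ancestor(table, ps.sample_root(6, seed=3), k=5)
        row = table.values[7]
        passive = project_with_ancestor(table, row / row.sum(), k=5)
        assert np.abs(passive.ancestor_scores[0] - proj.scores[7]).max() < 1e-9

    def test_k_domain_error(self, table):
        with pytest.raises(ValueError):
            project_with_ancestor(table, ps.sample_root(6, seed=4), k=7)


class TestDietCentroids:
    def _proj(self, scores, anc=(0.0,) * 5):
        from phylosym.analyze import ProjectionResult

        scores = np.asarray(scores, dtype=float)
        return ProjectionResult(
            loadings=np.zeros((3, scores.shape[1])),
            scores=scores,
            ancestor_scores=np.array([anc]),
            explained_variance=np.full(scores.shape[1], 0.1),
            host_ids=[f"h{i}" for i in range(len(scores))],
            taxon_ids=["a", "b", "c"],
        )

    def test_ancestor_on_centroid_gives_zero(self):
        scores = np.vstack([np.eye(5)[:2] + 1.0, -np.ones((2, 5))])
        proj = self._proj(scores)
        labels = ["plants", "plants", "meat", "meat"]
        cd = diet_centroid_distances(proj, labels, ancestor_score=-np.ones(5))
        assert cd.distances["meat"] == pytest.approx(0.0, abs=1e-12)
        assert cd.nearest == "meat"

    def test_mirrored_clouds_equidistant(self):
        cloud = np.array([[1, 0, 0, 0, 0], [1, 1, 0, 0, 0]], dtype=float)
        scores = np.vstack([cloud, -cloud])
        proj = self._proj(scores)
        labels = ["fruits", "fruits", "invertebrates", "invertebrates"]
        cd = diet_centroid_distances(proj, labels, ancestor_score=np.zeros(5))
        assert cd.distances["fruits"] == pytest.approx(cd.distances["invertebrates"])

    def test_distances_sorted_and_warn_on_empty_class(self):
        scores = np.random.default_rng(5).normal(size=(8, 5))
        proj = self._proj(scores)
        labels = ["plants"] * 4 + ["meat"] * 4
        with pytest.warns(UserWarning, match="empty"):
            cd = diet_centroid_distances(proj, labels, ancestor_score=np.zeros(5))
        vals = list(cd.distances.values())
        assert vals == sorted(vals)
        assert set(cd.distances) == {"plants", "meat"}

    def test_requires_five_axes(self):
        proj = self._proj(np.zeros((4, 3)))
        with pytest.raises(ValueError, match="five"):
            diet_centroid_distances(proj, ["plants"] * 4, np.zeros(3))


class TestIntegrationClusters:
    def test_two_block_structure(self):
        R = np.array(
            [
                [1.0, 0.6, -0.2, -0.3],
                [0.6, 1.0, -0.1, -0.2],
                [-0.2, -0.1, 1.0, 0.5],
                [-0.3, -0.2, 0.5, 1.0],
            ]
        )
        res = integration_clusters(R, ["a", "b", "c", "d"])
        assert sorted(sorted(c) for c in res.clusters) == [["a", "b"], ["c", "d"]]
        assert res.modularity > 0

    def test_single_positive_pair(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.4
        res = integration_clusters(R, ["x", "y", "z"])
        assert res.cluster_of("x") == res.cluster_of("y")

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        R = ps.random_spd(6, 0.25, seed=8, spectrum="random")
        ids = [f"t{j}" for j in range(6)]
        res = integration_clusters(R, ids)
        perm = rng.permutation(6)
        res2 = integration_clusters(R[np.ix_(perm, perm)], [ids[i] for i in perm])
        part1 = sorted(sorted(c) for c in res.clusters)
        part2 = sorted(sorted(c) for c in res2.clusters)
        assert part1 == part2

    def test_diagonal_shift_invariance(self):
        R = ps.random_spd(5, 0.25, seed=9, spectrum="random")
        res = integration_clusters(R, list("abcde"))
        res2 = integration_clusters(R + 3.0 * np.eye(5), list("abcde"))
        assert sorted(sorted(c) for c in res.clusters) == sorted(
            sorted(c) for c in res2.clusters
        )

    def test_all_negative_gives_singletons(self):
        R = np.eye(3) - 0.2 * (np.ones((3, 3)) - np.eye(3))
        with pytest.warns(UserWarning, match="no positive"):
            res = integration_clusters(R, ["a", "b", "c"])
        assert len(res.clusters) == 3


class TestMantel:
    def test_perfect_association(self):
        """Compositions built from edge-indicator coordinates give BC ~ patristic."""
        tree = ps.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        # one coordinate per edge; tip vector = lengths of its root path edges
        n_nodes = tree.n_nodes
        tips = tree.tip_indices
        rows = []
        for v in tips:
            vec = np.zeros(n_nodes)
            u = int(v)
            while u > 0:
                vec[u] = tree.blen[u]
                u = int(tree.parent[u])
            rows.append(vec)
        Z = np.array(rows)[:, 1:]  # drop the root's zero column
        Z = np.clip(Z, 1e-9, None)
        Z /= Z.sum(axis=1, keepdims=True)
        table = ps.CompositionTable(Z, [tree.labels[v] for v in tips],
                                    [f"e{j}" for j in range(Z.shape[1])])
        stat, p = mantel_baseline(tree, table, n_perm=99, seed=0)
        assert stat > 0.999
        # (no p-value assertion: a 4-tip tree admits only 24 permutations,
        # a third of which are symmetries that also attain r = 1)

    def test_null_calibration(self):
        """Rejection rate near nominal on independently shuffled data."""
        rng = np.random.default_rng(10)
        tree = ps.simulate_pure_birth(20, seed=42)
        rejections = 0
        n_datasets = 100
        for k in range(n_datasets):
            table = random_table(rng, 20, 4)
            table = ps.CompositionTable(
                table.values, tree.tip_labels, table.taxon_ids
            )
            _, p = mantel_baseline(tree, table, n_perm=99, seed=k)
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_datasets <= 0.12

    def test_too_few_hosts(self, cherry_dataset):
        tree = ps.parse_newick("((A:1,B:1):1,C:2);")
        Z = np.full((3, 2), 0.5)
        table = ps.CompositionTable(Z, ["A", "B", "C"], ["a", "b"])
        with pytest.raises(ValueError):
            mantel_baseline(tree, table)


class TestAdequacy:
    def test_self_consistency(self, medium_dataset):
        tree, table, truth = medium_dataset
        params = ps.ModelParams(
            lam=truth.lam, Z0=truth.Z0, R=truth.R, logYtilde=truth.logYtilde
        )
        report = adequacy_check(tree, params, table, n_sims=20, seed=0)
        assert np.mean(report["coverage"][:2]) >= 0.8
        assert not report["degenerate"]

    def test_single_simulation_flagged_degenerate(self, medium_dataset):
        tree, table, truth = medium_dataset
        params = ps.ModelParams(lam=truth.lam, Z0=truth.Z0, R=truth.R)
        report = adequacy_check(tree, params, table, n_sims=1, seed=1)
        assert report["degenerate"]
        assert len(report["coverage"]) == 2
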