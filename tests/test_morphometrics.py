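"""Procrustes superimposition, shape models and trajectory analysis."""

import itertools

import numpy as np
import pytest

from transloc.morphometrics import (AlignedShapes, LandmarkConfiguration,
                                    allometry_anova, centroid_size,
                                    generalized_procrustes, pairwise_group_tests,
                                    shape_pca, trajectory_analysis)
from transloc.simulate import FISH_TEMPLATE, simulate_morphology

TRI = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 0.8]])


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestGPA:
    def test_identical_shapes_zero_distance(self):
        aligned = generalized_procrustes(np.stack([TRI, TRI]))
        d = np.linalg.norm(aligned.procrustes_coords[0] - aligned.procrustes_coords[1])
        assert d < 1e-12
        assert np.allclose(aligned.consensus, aligned.procrustes_coords[0], atol=1e-12)

    def test_similarity_invariance(self):
        moved = (TRI @ _rot(np.radians(37)).T) * 3.0 + np.array([5.0, -2.0])
        aligned = generalized_procrustes(np.stack([TRI, moved]))
        assert np.allclose(aligned.procrustes_coords[0],
                           aligned.procrustes_coords[1], atol=1e-8)

    def test_unit_size_and_centred(self, rng):
        shapes = FISH_TEMPLATE[None] + 0.01 * rng.standard_normal((6, 14, 2))
        aligned = generalized_procrustes(shapes)
        for x in aligned.procrustes_coords:
            assert np.allclose(x.mean(axis=0), 0, atol=1e-9)
            assert abs(np.sqrt(np.sum(x**2)) - 1) < 1e-9

    def test_invariant_to_random_similarity_transforms(self, rng):
        shapes = FISH_TEMPLATE[None] + 0.02 * rng.standard_normal((5, 14, 2))
        ref = generalized_procrustes(shapes)
        moved = np.stack([
            (s @ _rot(rng.uniform(0, 2 * np.pi)).T) * rng.uniform(0.5, 3.0)
            + rng.uniform(-5, 5, 2)
            for s in shapes
        ])
        other = generalized_procrustes(moved)
        # align the two consensuses before comparing configurations
        for a, b in zip(ref.procrustes_coords, other.procrustes_coords):
            h = b.T @ a
            u, _, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(u @ vt))
            r = u @ np.diag([1.0, d]) @ vt
            assert np.allclose(b @ r, a, atol=1e-8)

    def test_degenerate_configuration_rejected(self):
        flat = np.zeros((3, 2))
        with pytest.raises(ValueError, match="degenerate"):
            generalized_procrustes(np.stack([TRI, flat]))

    def test_residuals_match_grid_search_oracle(self):
        # three fixed 4-landmark shapes; independent coordinate-descent
        # minimization over per-shape rotation angles on a fine grid
        shapes = np.array([
            [[0.0, 0.0], [1.0, 0.1], [0.9, 1.0], [0.1, 0.9]],
            [[0.05, -0.02], [1.1, 0.0], [1.0, 0.9], [0.0, 1.0]],
            [[-0.1, 0.05], [0.95, 0.15], [1.05, 1.1], [0.2, 0.85]],
        ])
        X = shapes - shapes.mean(axis=1, keepdims=True)
        X = X / np.sqrt((X**2).sum(axis=(1, 2)))[:, None, None]

        def total_ss(thetas):
            rot = np.stack([X[i] @ _rot(t).T for i, t in enumerate(thetas)])
            mean = rot.mean(axis=0)
            return np.sum((rot - mean) ** 2)

        thetas = np.zeros(3)
        for step in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5):
            improved = True
            while improved:
                improved = False
                for i in range(3):
                    grid = thetas[i] + np.arange(-20, 21) * step
                    vals = []
                    for t in grid:
                        trial = thetas.copy()
                        trial[i] = t
                        vals.append(total_ss(trial))
                    best = grid[int(np.argmin(vals))]
                    if best != thetas[i]:
                        thetas[i] = best
                        improved = True
        oracle_ss = total_ss(thetas)

        aligned = generalized_procrustes(shapes)
        gpa_ss = np.sum((aligned.procrustes_coords - aligned.consensus) ** 2)
        assert abs(gpa_ss - oracle_ss) < 1e-6


class TestShapePCA:
    def test_rank_one_variation(self, rng):
        direction = rng.standard_normal(28)
        direction /= np.linalg.norm(direction)
        scores = rng.standard_normal(30)
        flat = FISH_TEMPLATE.ravel()[None] + 0.01 * scores[:, None] * direction[None]
        aligned = AlignedShapes(flat.reshape(30, 14, 2), np.ones(30), FISH_TEMPLATE)
        res = shape_pca(aligned)
        assert res.prop_explained[0] > 0.999

    def test_eigenvalues_match_covariance_oracle(self, rng):
        flat = rng.standard_normal((25, 28))
        aligned = AlignedShapes(flat.reshape(25, 14, 2), np.ones(25), FISH_TEMPLATE)
        res = shape_pca(aligned)
        cov = np.cov(flat, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, eig[: len(res.eigenvalues)], atol=1e-9)

    def test_reconstruction(self, rng):
        flat = rng.standard_normal((12, 28))
        aligned = AlignedShapes(flat.reshape(12, 14, 2), np.ones(12), FISH_TEMPLATE)
        res = shape_pca(aligned)
        recon = res.site_scores @ res.loadings.T + flat.mean(axis=0)
        assert np.allclose(recon, flat, atol=1e-9)


class TestAllometryAnova:
    def test_ss_decomposition_adds_up(self, rng):
        n = 40
        Y = rng.standard_normal((n, 6))
        sizes = np.exp(rng.normal(5, 0.3, n))
        groups = np.repeat(["a", "b"], n // 2)
        tab = allometry_anova(Y, sizes, groups, n_perm=99, seed=1)
        ss_terms = tab.loc[tab["term"] != "Total", "SS"].sum()
        ss_total = tab.loc[tab["term"] == "Total", "SS"].iloc[0]
        assert abs(ss_terms - ss_total) < 1e-9

    def test_p_value_range(self, rng):
        Y = rng.standard_normal((30, 4))
        sizes = np.exp(rng.normal(5, 0.3, 30))
        groups = np.repeat(["a", "b", "c"], 10)
        tab = allometry_anova(Y, sizes, groups, n_perm=99, seed=2)
        p = tab["p"].dropna()
        assert ((p >= 1 / 100) & (p <= 1)).all()

    def test_planted_interaction_detected(self, rng):
        # two groups with clearly different allometric directions
        n = 120
        groups = np.repeat(["a", "b"], n // 2)
        log_size = rng.normal(5, 0.4, n)
        dir_a = np.zeros(6); dir_a[0] = 1.0
        dir_b = np.zeros(6); dir_b[1] = 1.0
        slopes = np.where(groups == "a", 1.0, 0.0)[:, None] * dir_a + \
            np.where(groups == "b", 1.0, 0.0)[:, None] * dir_b
        Y = slopes * log_size[:, None] + 0.1 * rng.standard_normal((n, 6))
        tab = allometry_anova(Y, np.exp(log_size), groups, n_perm=199, seed=3)
        p_int = tab.loc[tab["term"] == "log(Size):Group", "p"].iloc[0]
        assert p_int <= 0.01

    def test_exhaustive_enumeration_matches_oracle(self):
        # 6 observations: RRPP over all 720 permutations equals a
        # direct enumeration computed independently here
        rng = np.random.default_rng(4)
        n = 6
        Y = rng.standard_normal((n, 2))
        sizes = np.exp(rng.normal(0, 0.3, n))
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        tab = allometry_anova(Y, sizes, groups, permutations=perms)

        # independent oracle: explicit sequential-SS machinery
        ls = np.log(sizes)
        one = np.ones((n, 1))
        G = (groups == "b").astype(float)[:, None]
        designs = [one, np.hstack([one, ls[:, None]]),
                   np.hstack([one, ls[:, None], G]),
                   np.hstack([one, ls[:, None], G, ls[:, None] * G])]
        hats = [D @ np.linalg.pinv(D) for D in designs]
        ranks = [np.linalg.matrix_rank(D) for D in designs]
        df_res = n - ranks[-1]

        def f_stat(Ym, t):
            ss_t = np.sum((hats[t + 1] @ Ym) ** 2) - np.sum((hats[t] @ Ym) ** 2)
            ss_r = np.sum(Ym**2) - np.sum((hats[-1] @ Ym) ** 2)
            return (ss_t / (ranks[t + 1] - ranks[t])) / (ss_r / df_res)

        for t, term in enumerate(["log(Size)", "Group", "log(Size):Group"]):
            f_obs = f_stat(Y, t)
            fitted = hats[t] @ Y
            resid = Y - fitted
            count = sum(f_stat(fitted + resid[np.array(p)], t) >= f_obs for p in perms)
            p_exact = (count + 1) / (len(perms) + 1)
            assert tab.loc[tab["term"] == term, "p"].iloc[0] == pytest.approx(p_exact)

    def test_constant_sizes_rejected(self, rng):
        Y = rng.standard_normal((12, 4))
        with pytest.raises(ValueError, match="constant"):
            allometry_anova(Y, np.ones(12), np.repeat(["a", "b"], 6), n_perm=99)


class TestPairwise:
    def test_identical_means_zero_distance(self, rng):
        base = rng.standard_normal(6)
        Y = np.tile(base, (12, 1))
        groups = np.repeat(["a", "b", "c"], 4)
        tab = pairwise_group_tests(Y, np.exp(rng.normal(0, 0.2, 12)), groups,
                                   mode="means", n_perm=99, seed=1)
        assert len(tab) == 3
        assert np.allclose(tab["statistic"], 0.0)
        assert (tab["p_adj"] >= tab["p"] - 1e-12).all()

    def test_slopes_mode_runs_and_detects_difference(self, rng):
        n = 60
        groups = np.repeat(["a", "b"], n // 2)
        ls = rng.normal(0, 0.5, n)
        dirs = {"a": np.array([1.0, 0, 0, 0]), "b": np.array([0, 1.0, 0, 0])}
        Y = np.stack([dirs[g] * s for g, s in zip(groups, ls)]) \
            + 0.05 * rng.standard_normal((n, 4))
        tab = pairwise_group_tests(Y, np.exp(ls), groups, mode="slopes",
                                   n_perm=199, seed=2)
        assert tab["p"].iloc[0] <= 0.01
        assert 0 <= tab["statistic"].iloc[0] <= 180


class TestTrajectory:
    @staticmethod
    def _build(vecs, n=40, noise=0.0, seed=0):
        """Two systems; refuge mean displaced by the given vectors."""
        rng = np.random.default_rng(seed)
        p = len(next(iter(vecs.values())))
        Y, syst, typ = [], [], []
        for s, v in vecs.items():
            for t in ("source", "refuge"):
                base = np.zeros(p) if t == "source" else np.asarray(v, float)
                Y.append(base[None] + noise * rng.standard_normal((n, p)))
                syst.extend([s] * n)
                typ.extend([t] * n)
        return np.vstack(Y), np.array(syst), np.array(typ)

    def test_identical_trajectories(self):
        v = np.array([1.0, 0.5, 0.0, 0.0])
        Y, s, t = self._build({"A": v, "B": v})
        res = trajectory_analysis(Y, s, t, n_perm=99, seed=1)
        assert res.delta_l == pytest.approx(0.0, abs=1e-12)
        assert res.theta == pytest.approx(0.0, abs=1e-3)

    def test_orthogonal_equal_length(self):
        Y, s, t = self._build({"A": [1.0, 0, 0, 0], "B": [0, 1.0, 0, 0]},
                              n=100, noise=0.05, seed=2)
        res = trajectory_analysis(Y, s, t, n_perm=99, seed=3)
        assert abs(res.theta - 90.0) < 2.0
        assert res.delta_l < 0.05

    def test_known_angle_and_length_ratio(self):
        a = np.array([2.0, 0.0, 0.0, 0.0])
        b = np.array([np.cos(np.radians(60)), np.sin(np.radians(60)), 0, 0])
        Y, s, t = self._build({"A": a, "B": b}, n=200, noise=0.05, seed=4)
        res = trajectory_analysis(Y, s, t, n_perm=99, seed=5)
        assert abs(res.theta - 60.0) < 3.0
        assert abs(res.delta_l - 1.0) < 0.05

    def test_symmetric_under_system_swap(self):
        Y, s, t = self._build({"A": [1, 0, 0, 0.0], "B": [0, 1.0, 0.5, 0]},
                              n=30, noise=0.1, seed=6)
        r1 = trajectory_analysis(Y, s, t, n_perm=99, seed=7)
        swapped = np.where(s == "A", "B", "A")
        r2 = trajectory_analysis(Y, swapped, t, n_perm=99, seed=7)
        assert r1.theta == pytest.approx(r2.theta)
        assert r1.delta_l == pytest.approx(r2.delta_l)

    def test_missing_level_rejected(self):
        Y, s, t = self._build({"A": [1.0, 0], "B": [0, 1.0]}, n=5)
        t[(s == "A")] = "source"
        with pytest.raises(ValueError, match="missing"):
            trajectory_analysis(Y, s, t, n_perm=99)


def test_gpa_pipeline_on_simulated_fish(rng):
    z = rng.standard_normal(30)
    configs, _ = simulate_morphology(z, rng.standard_normal(30),
                                     (0.5, 0.0, 0.5), seed=1)
    aligned = generalized_procrustes(configs)
    res = shape_pca(aligned)
    # planted single strong direction dominates PC1
    assert res.prop_explained[0] > 0.3


def test_pairwise_slope_p_uniform_under_common_slope():
    """Groups simulated with identical allometric slopes give uniform p."""
    rng = np.random.default_rng(77)
    pvals = []
    for _ in range(200):
        n = 30
        groups = np.repeat(["a", "b"], n // 2)
        ls = rng.normal(0, 0.4, n)
        slope_dir = np.array([1.0, 0.5, 0.0, 0.0])
        Y = ls[:, None] * slope_dir[None, :] + 0.3 * rng.standard_normal((n, 4))
        tab = pairwise_group_tests(Y, np.exp(ls), groups, mode="slopes",
                                   n_perm=99, seed=rng)
        pvals.append(tab["p"].iloc[0])
    from scipy import stats as sps
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
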