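import numpy as np
import pytest

from wingrda.phylo import (CenteredData, LambdaEstimate, center_and_range,
                           gls_root, inverse_sqrt, joint_lambda_ml,
                           lambda_lr_test, lambda_scale, phylo_covariance,
                           pgls_whiten, _profile_loglik)
from wingrda.simulate import simulate_pure_birth_tree, simulate_traits

from .conftest import star_tree, tree_from_newick


def random_spd(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


class TestPhyloCovariance:
    def test_cherry(self):
        cov = phylo_covariance(tree_from_newick("(A:1,B:1);"), taxa=["A", "B"])
        np.testing.assert_allclose(cov.C, np.eye(2))

    def test_three_taxa(self):
        cov = phylo_covariance(tree_from_newick("((A:1,B:1):1,C:2);"),
                               taxa=["A", "B", "C"])
        np.testing.assert_allclose(cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star(self):
        cov = phylo_covariance(star_tree(5, depth=2.5),
                               taxa=[f"t{k + 1}" for k in range(5)])
        np.testing.assert_allclose(cov.C, 2.5 * np.eye(5))

    def test_ultrametric_constant_diagonal(self):
        tree = simulate_pure_birth_tree(16, seed=3)
        cov = phylo_covariance(tree)
        d = np.diag(cov.C)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)

    def test_unrooted_error(self):
        tree = tree_from_newick("(A:1,B:1,C:1);")
        tree.is_rooted = False
        with pytest.raises(ValueError, match="rooted"):
            phylo_covariance(tree)

    def test_missing_taxon_error(self):
        with pytest.raises(ValueError, match="not a tip"):
            phylo_covariance(tree_from_newick("(A:1,B:1);"), taxa=["A", "Z"])

    def test_positive_semidefinite(self):
        tree = simulate_pure_birth_tree(24, seed=9)
        cov = phylo_covariance(tree)
        assert np.linalg.eigvalsh(cov.C)[0] >= -1e-10


class TestLambdaScale:
    def test_lambda_one_identity(self, rng):
        C = random_spd(rng, 5)
        np.testing.assert_allclose(lambda_scale(C, 1.0), C)

    def test_lambda_zero_diagonal(self, rng):
        C = random_spd(rng, 5)
        np.testing.assert_allclose(lambda_scale(C, 0.0), np.diag(np.diag(C)))

    def test_half(self):
        C = np.array([[1.0, 0.8], [0.8, 1.0]])
        out = lambda_scale(C, 0.5)
        assert out[0, 1] == pytest.approx(0.4)
        assert out[0, 0] == 1.0

    @pytest.mark.parametrize("lam", [-0.1, 1.2])
    def test_out_of_range(self, lam):
        with pytest.raises(ValueError, match="lambda"):
            lambda_scale(np.eye(3), lam)


class TestInverseSqrt:
    def test_matches_direct_inverse(self, rng):
        for _ in range(5):
            M = random_spd(rng, 6)
            W = inverse_sqrt(M)
            np.testing.assert_allclose(W @ W, np.linalg.inv(M), atol=1e-8)
            np.testing.assert_allclose(W, W.T, atol=1e-12)

    def test_non_pd_error(self):
        M = np.diag([1.0, -1.0])
        with pytest.raises(ValueError, match="positive definite"):
            inverse_sqrt(M)


@pytest.fixture(scope="module")
def tree64():
    return simulate_pure_birth_tree(64, seed=11)


class TestJointLambdaML:

    def test_brownian_recovery(self, tree64):
        cov = phylo_covariance(tree64)
        lams = []
        for rep in range(5):
            cols = [simulate_traits(tree64, 1.0, 1.0, seed=100 + 3 * rep + j)[1]
                    for j in range(3)]
            lams.append(joint_lambda_ml(np.column_stack(cols), cov).lam)
        assert np.mean(lams) >= 0.8

    def test_white_noise_recovery(self, tree64, rng):
        cov = phylo_covariance(tree64)
        lams = [joint_lambda_ml(rng.standard_normal((64, 3)), cov).lam
                for _ in range(5)]
        assert np.mean(lams) <= 0.15

    def test_loglik_at_optimum_beats_endpoints(self, tree64):
        cov = phylo_covariance(tree64)
        _, x = simulate_traits(tree64, 0.5, 1.0, seed=42)
        est = joint_lambda_ml(x, cov)
        assert 0.0 <= est.lam <= 1.0
        assert est.loglik >= max(est.loglik_0, est.loglik_1) - 1e-6

    def test_optimizer_matches_grid_oracle(self, tree64):
        cov = phylo_covariance(tree64)
        _, x = simulate_traits(tree64, 0.6, 1.0, seed=7)
        data = x[:, None]
        est = joint_lambda_ml(data, cov)
        grid = max(_profile_loglik(data, cov.C, g)[0]
                   for g in np.linspace(0, 1, 101))
        assert est.loglik >= grid - 1e-6

    def test_constant_variable_excluded(self, tree64):
        cov = phylo_covariance(tree64)
        _, x = simulate_traits(tree64, 1.0, 1.0, seed=5)
        data = np.column_stack([x, np.ones(64)])
        with pytest.warns(UserWarning, match="constant"):
            est = joint_lambda_ml(data, cov)
        assert len(est.sigma2) == 1

    def test_too_few_taxa(self):
        cov = phylo_covariance(tree_from_newick("((A:1,B:1):1,C:2);"),
                               taxa=["A", "B", "C"])
        with pytest.raises(ValueError, match="at least 4"):
            joint_lambda_ml(np.ones((3, 1)), cov)


class TestLambdaLrTest:
    def _est(self, lr0, lr1):
        return LambdaEstimate(lam=0.5, loglik=0.0, loglik_0=-lr0 / 2,
                              loglik_1=-lr1 / 2, lr_vs_0=lr0, lr_vs_1=lr1,
                              p_vs_0=np.nan, p_vs_1=np.nan,
                              sigma2=np.ones(1))

    def test_chi2_quantiles(self):
        p0, p1 = lambda_lr_test(self._est(3.841, 0.0))
        assert p0 == pytest.approx(0.05, abs=1e-3)
        assert p1 == 1.0
        p0, _ = lambda_lr_test(self._est(10.83, 0.0))
        assert p0 == pytest.approx(0.001, abs=1e-4)

    def test_negative_lr_error(self):
        with pytest.raises(ValueError, match="optimizer failure"):
            lambda_lr_test(self._est(-1.0, 0.0))


class TestCenterAndRange:
    def test_star_tree_root_is_mean(self):
        C = np.eye(6)
        x = np.array([1.0, 2, 3, 4, 5, 9])
        cd = center_and_range(x, C, [False])
        assert cd.roots[0] == pytest.approx(x.mean())
        assert gls_root(x, C) == pytest.approx(x.mean())

    def test_ranging_divides_by_max_abs(self):
        # centered values (-2, 0, 4) -> (-0.5, 0, 1); C chosen so the GLS
        # root of (-2, 0, 4) is exactly zero and centering is a no-op
        C = np.diag([1.0, 1.0, 2.0])
        x = np.array([-2.0, 0.0, 4.0])
        cd = center_and_range(x, C, [True])
        np.testing.assert_allclose(cd.centered[:, 0], [-0.5, 0.0, 1.0],
                                   atol=1e-12)
        assert cd.scales[0] == pytest.approx(4.0)

    def test_ranged_within_unit_interval(self, rng):
        tree = simulate_pure_birth_tree(20, seed=2)
        cov = phylo_covariance(tree)
        data = rng.standard_normal((20, 3)) * 10
        cd = center_and_range(data, cov.C, [True, True, True])
        assert np.all(np.abs(cd.centered) <= 1.0 + 1e-12)

    def test_zero_range_error(self):
        with pytest.raises(ValueError, match="zero range"):
            center_and_range(np.ones(4), np.eye(4), [True])

    def test_gls_root_weights_by_covariance(self):
        tree = tree_from_newick("((A:1,B:1):3,C:4);")
        cov = phylo_covariance(tree, taxa=["A", "B", "C"])
        x = np.array([1.0, 1.0, 10.0])
        root = gls_root(x, cov.C)
        # A and B are highly correlated; root leans toward C more than OLS
        assert root > x.mean() - 2.0
        assert root != pytest.approx(x.mean())


class TestPglsWhiten:
    def _centered(self, data):
        return CenteredData(taxa=[f"t{i}" for i in range(len(data))],
                            roots=np.zeros(data.shape[1]),
                            scales=np.ones(data.shape[1]),
                            centered=data,
                            ranged=np.zeros(data.shape[1], bool))

    def test_identity_unchanged(self, rng):
        data = rng.standard_normal((5, 2))
        out = pgls_whiten(self._centered(data), np.eye(5))
        np.testing.assert_allclose(out, data)

    def test_scaled_identity_halves(self, rng):
        data = rng.standard_normal((5, 2))
        out = pgls_whiten(self._centered(data), 4.0 * np.eye(5))
        np.testing.assert_allclose(out, data / 2.0)

    def test_whitened_embeds_c_inverse(self, rng):
        C = random_spd(rng, 6)
        data = rng.standard_normal((6, 3))
        out = pgls_whiten(self._centered(data), C)
        np.testing.assert_allclose(out.T @ out,
                                   data.T @ np.linalg.inv(C) @ data, atol=1e-8)

    def test_non_pd_error(self, rng):
        with pytest.raises(ValueError, match="positive definite"):
            pgls_whiten(self._centered(rng.standard_normal((3, 1))),
                        np.diag([1.0, 0.0, 1.0]))

    def test_whitened_residual_covariance_near_identity(self):
        tree = simulate_pure_birth_tree(12, seed=21)
        cov = phylo_covariance(tree)
        lam = 0.7
        C_lam = lambda_scale(cov.C, lam)
        W = inverse_sqrt(C_lam)
        rng = np.random.default_rng(0)
        L = np.linalg.cholesky(C_lam)
        acc = np.zeros((12, 12))
        reps = 400
        for _ in range(reps):
            x = L @ rng.standard_normal(12)
            wx = W @ x
            acc += np.outer(wx, wx)
        acc /= reps
        assert np.linalg.norm(acc - np.eye(12)) / np.linalg.norm(np.eye(12)) < 0.35


class TestLoglikShape:
    def test_continuous_on_unit_interval(self):
        tree = simulate_pure_birth_tree(32, seed=13)
        cov = phylo_covariance(tree)
        _, x = simulate_traits(tree, 0.8, 1.0, seed=14)
        grid = np.linspace(0, 1, 41)
        lls = [_profile_loglik(x[:, None], cov.C, g)[0] for g in grid]
        diffs = np.abs(np.diff(lls))
        assert np.all(np.isfinite(lls))
        assert diffs.max() < 20  # no jumps at this resolution
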