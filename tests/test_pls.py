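"""Behavioral PLS: cross-block matrix, SVD, permutation and bootstrap."""

import numpy as np
import pytest
from scipy import stats

from boldvar.pls import (
    bootstrap_inference,
    cross_block_matrix,
    decompose,
    permutation_test,
    run_behavioral_pls,
)
from boldvar.synthetic import GeneratorConfig, generate_dataset
from boldvar.variability import DataError


@pytest.fixture
def blocks(rng):
    brain = rng.standard_normal((40, 30))
    behavior = rng.standard_normal((40, 5))
    return brain, behavior


class TestCrossBlockMatrix:
    def test_identical_columns_correlate_one(self, rng):
        brain = rng.standard_normal((20, 4))
        behavior = np.column_stack([brain[:, 2], rng.standard_normal(20)])
        R = cross_block_matrix(brain, behavior)
        assert R[0, 2] == pytest.approx(1.0)

    def test_matches_scalar_pearson_probes(self, blocks, rng):
        brain, behavior = blocks
        R = cross_block_matrix(brain, behavior)
        for _ in range(20):
            b = rng.integers(0, 5)
            v = rng.integers(0, 30)
            expected = stats.pearsonr(behavior[:, b], brain[:, v]).statistic
            assert R[b, v] == pytest.approx(expected, abs=1e-12)

    def test_joint_row_permutation_invariance(self, blocks, rng):
        brain, behavior = blocks
        order = rng.permutation(brain.shape[0])
        np.testing.assert_allclose(
            cross_block_matrix(brain[order], behavior[order]),
            cross_block_matrix(brain, behavior),
            atol=1e-12,
        )

    def test_covariance_mode(self, blocks):
        brain, behavior = blocks
        R = cross_block_matrix(brain, behavior, mode="covariance")
        expected = np.cov(behavior[:, 0], brain[:, 0], ddof=1)[0, 1]
        assert R[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_named(self, blocks):
        brain, behavior = blocks
        brain = brain.copy()
        brain[:, 3] = 1.0
        with pytest.raises(DataError, match=r"brain.*\[3\]"):
            cross_block_matrix(brain, behavior)


class TestDecompose:
    def test_single_entry(self):
        dec = decompose(np.array([[0.6]]))
        assert dec.singular_values[0] == pytest.approx(0.6)
        assert dec.covariance_explained[0] == pytest.approx(1.0)

    def test_squared_singular_values_sum_to_frobenius(self, rng):
        R = rng.standard_normal((6, 50))
        dec = decompose(R)
        assert np.sum(dec.singular_values**2) == pytest.approx(
            np.linalg.norm(R) ** 2
        )
        assert dec.covariance_explained.sum() == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_and_orthonormality(self, rng):
        R = rng.standard_normal((10, 200))
        dec = decompose(R)
        recon = dec.behavior_saliences @ np.diag(dec.singular_values) @ dec.voxel_saliences.T
        np.testing.assert_allclose(recon, R, atol=1e-8)
        np.testing.assert_allclose(
            dec.behavior_saliences.T @ dec.behavior_saliences, np.eye(10), atol=1e-8
        )
        np.testing.assert_allclose(
            dec.voxel_saliences.T @ dec.voxel_saliences, np.eye(10), atol=1e-8
        )
        assert np.all(np.diff(dec.singular_values) <= 1e-12)

    def test_matches_eigendecomposition_oracle(self, rng):
        # brute-force oracle on a small instance: eigenpairs of R R^T
        R = rng.standard_normal((4, 10))
        dec = decompose(R)
        evals, evecs = np.linalg.eigh(R @ R.T)
        order = np.argsort(evals)[::-1]
        np.testing.assert_allclose(
            dec.singular_values, np.sqrt(evals[order]), atol=1e-8
        )
        for k in range(4):
            u_oracle = evecs[:, order[k]]
            dot = abs(u_oracle @ dec.behavior_saliences[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_sign_convention_dominant_behavior_salience_positive(self, rng):
        R = rng.standard_normal((5, 40))
        dec = decompose(R)
        for k in range(5):
            col = dec.behavior_saliences[:, k]
            assert col[np.argmax(np.abs(col))] > 0

    def test_brain_scores_projection(self, rng):
        brain = rng.standard_normal((30, 12))
        behavior = rng.standard_normal((30, 4))
        R = cross_block_matrix(brain, behavior)
        dec = decompose(R, brain=brain)
        z = (brain - brain.mean(0)) / brain.std(0, ddof=1)
        np.testing.assert_allclose(dec.brain_scores, z @ dec.voxel_saliences, atol=1e-10)

    def test_nonfinite_rejected(self):
        with pytest.raises(DataError, match="finite"):
            decompose(np.array([[np.nan, 1.0]]))


class TestPermutationTest:
    def test_same_seed_identical(self, blocks):
        brain, behavior = blocks
        a = permutation_test(brain, behavior, n_permutations=50, seed=4)
        b = permutation_test(brain, behavior, n_permutations=50, seed=4)
        np.testing.assert_array_equal(a.p_values, b.p_values)

    def test_joint_permutation_invariance(self, blocks, rng):
        # reordering subjects jointly leaves the observed singular values
        # (and hence the null hypothesis) unchanged exactly; the realized
        # p-values agree up to permutation Monte-Carlo error
        brain, behavior = blocks
        order = rng.permutation(brain.shape[0])
        a = permutation_test(brain, behavior, n_permutations=1000, seed=4)
        b = permutation_test(brain[order], behavior[order], n_permutations=1000, seed=4)
        s_a = np.linalg.svd(cross_block_matrix(brain, behavior), compute_uv=False)
        s_b = np.linalg.svd(
            cross_block_matrix(brain[order], behavior[order]), compute_uv=False
        )
        np.testing.assert_allclose(s_a, s_b, atol=1e-12)
        np.testing.assert_allclose(a.p_values, b.p_values, atol=0.08)

    def test_p_floor_is_one_over_n_plus_one(self):
        cfg = GeneratorConfig(
            n_subjects=100, grid_shape=(5, 5, 5), n_behaviors=6, latent_rank=1,
            effect_size=5.0, seed=21,
        )
        sd, table, _ = generate_dataset(cfg)
        res = permutation_test(
            sd.matrix, table.frame[table.measure_names].to_numpy(),
            n_permutations=99, seed=0,
        )
        assert res.p_values[0] == pytest.approx(1 / 100)
        assert res.p_values.min() >= 1 / 100


class TestBootstrap:
    def test_stable_sentinel_for_deterministic_salience(self, rng):
        # 1 voxel x 1 behavior with exact coupling: every resample yields
        # the same (+/-1) salience, so SE = 0 and the BSR must be flagged
        # infinite rather than overflow
        x = rng.standard_normal(30)
        brain = x[:, None]
        behavior = (2.0 * x + 1.0)[:, None]
        res = bootstrap_inference(brain, behavior, n_bootstrap=50, seed=1)
        assert res.stable_mask[0, 0]
        assert np.isinf(res.bsr[0, 0]) and res.bsr[0, 0] > 0

    def test_ci_ordering_and_sign_contract(self, blocks):
        brain, behavior = blocks
        res = bootstrap_inference(brain, behavior, n_bootstrap=100, seed=2)
        assert np.all(res.correlation_ci_low <= res.correlation_ci_high + 1e-12)
        finite = np.isfinite(res.bsr) & (res.bsr != 0)
        # BSR inherits the sign of the original salience (SE is positive)
        base = decompose(cross_block_matrix(brain, behavior))
        assert np.all(
            np.sign(res.bsr[finite]) == np.sign(base.voxel_saliences[finite])
        )

    def test_noise_voxel_bsr_specificity(self):
        # |BSR| >= 2.5 in pure-noise voxels should be rare
        cfg = GeneratorConfig(
            n_subjects=100, grid_shape=(8, 8, 8), n_behaviors=6, latent_rank=1,
            effect_size=3.0, signal_voxel_fraction=0.2, seed=13,
        )
        sd, table, truth = generate_dataset(cfg)
        res = bootstrap_inference(
            sd.matrix, table.frame[table.measure_names].to_numpy(),
            n_bootstrap=200, seed=5,
        )
        noise_voxels = truth.voxel_saliences_true[:, 0] == 0
        frac = np.mean(np.abs(res.bsr[noise_voxels, 0]) >= 2.5)
        assert frac < 0.08

    def test_null_weight_ci_covers_zero(self):
        # a behavior with planted weight 0 should have its 95% CI cover 0 in
        # most replicates; percentile bootstrap undercovers slightly at
        # n = 100 (~90% measured), so the band guards against gross
        # miscalibration rather than asserting the nominal level exactly
        weights = np.array([1.0, 1.0, -1.0, 1.0, -1.0, 0.0])[:, None]
        covered = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = GeneratorConfig(
                n_subjects=100, grid_shape=(4, 4, 3), n_behaviors=6,
                latent_rank=1, effect_size=2.0, seed=1000 + rep,
            )
            sd, table, _ = generate_dataset(cfg, behavior_weights=weights)
            res = bootstrap_inference(
                sd.matrix, table.frame[table.measure_names].to_numpy(),
                n_bootstrap=300, seed=rep,
            )
            if res.correlation_ci_low[5, 0] <= 0 <= res.correlation_ci_high[5, 0]:
                covered += 1
        assert covered / n_rep >= 0.80


class TestRunBehavioralPLS:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(
            n_subjects=40, grid_shape=(4, 4, 4), n_behaviors=5, latent_rank=1,
            effect_size=2.0, seed=2,
        )
        sd, table, _ = generate_dataset(cfg)
        block = table.frame[table.measure_names].to_numpy()
        a = run_behavioral_pls(sd.matrix, block, 50, 50, seed=9)
        b = run_behavioral_pls(sd.matrix, block, 50, 50, seed=9)
        np.testing.assert_array_equal(a.permutation.p_values, b.permutation.p_values)
        np.testing.assert_array_equal(a.bootstrap.bsr, b.bootstrap.bsr)
        np.testing.assert_array_equal(
            a.bootstrap.correlation_ci_low, b.bootstrap.correlation_ci_low
        )

    def test_planted_sign_pattern_recovered(self):
        # positive-scale measures planted positive, cognitive-like negative;
        # the recovered behavior saliences must reproduce the sign pattern
        weights = np.array([-1.0, -1.0, 1.0, 1.0, 1.0, 1.0, -1.0, -1.0])[:, None]
        cfg = GeneratorConfig(
            n_subjects=120, grid_shape=(6, 6, 6), n_behaviors=8, latent_rank=1,
            effect_size=4.0, seed=17,
        )
        sd, table, truth = generate_dataset(cfg, behavior_weights=weights)
        res = run_behavioral_pls(
            sd.matrix, table.frame[table.measure_names].to_numpy(), 100, 100, seed=3
        )
        u = res.decomposition.behavior_saliences[:, 0]
        # sign convention makes the dominant salience positive; align to truth
        if np.sign(u[2]) != np.sign(truth.behavior_weights_true[2, 0]):
            u = -u
        assert np.array_equal(np.sign(u), np.sign(truth.behavior_weights_true[:, 0]))

    def test_covariance_explained_monotone_in_effect_size(self):
        cov1 = []
        for eff in (0.5, 1.5, 3.0):
            cfg = GeneratorConfig(
                n_subjects=80, grid_shape=(5, 5, 5), n_behaviors=6, latent_rank=1,
                effect_size=eff, seed=31,
            )
            sd, table, _ = generate_dataset(cfg)
            R = cross_block_matrix(sd.matrix, table.frame[table.measure_names].to_numpy())
            cov1.append(decompose(R).covariance_explained[0])
        assert cov1[0] <= cov1[1] <= cov1[2]
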