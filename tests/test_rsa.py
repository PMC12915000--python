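"""Crossnobis RSA: shrinkage covariance limits, the hand-arithmetic toy
oracle, scale and symmetry properties, the same-vs-different-finger contrast,
the task x pair ANOVA against a manual sums-of-squares oracle, and classical
MDS on analytic configurations."""

import numpy as np
import pytest
from dataclasses import replace

from fingermvpa.rsa import (
    CONDITIONS,
    FINGER_PAIRS,
    RDM,
    classical_mds,
    crossnobis_distances,
    crossnobis_rdm,
    diag_offdiag_contrast,
    naive_mahalanobis_rdm,
    shrinkage_covariance,
    within_task_pair_table,
)
from fingermvpa.synth import SynthConfig, generate_subject


class TestShrinkageCovariance:
    def test_full_shrinkage_is_diagonal(self):
        rng = np.random.default_rng(0)
        res = rng.standard_normal((30, 5)) @ rng.standard_normal((5, 5))
        cov = shrinkage_covariance(res, mode=1.0)
        assert np.allclose(cov.sigma, np.diag(np.diag(cov.sigma)))

    def test_zero_shrinkage_returns_sample_covariance(self):
        rng = np.random.default_rng(1)
        res = rng.standard_normal((100, 4))
        cov = shrinkage_covariance(res, mode=0.0)
        assert np.allclose(cov.sigma, np.cov(res, rowvar=False))

    def test_fixed_mode_uses_lambda_0_4(self):
        rng = np.random.default_rng(2)
        res = rng.standard_normal((50, 3))
        cov = shrinkage_covariance(res)
        S = np.cov(res, rowvar=False)
        assert cov.lam == 0.4
        assert np.allclose(cov.sigma, 0.6 * S + 0.4 * np.diag(np.diag(S)))

    def test_optimal_shrinkage_on_white_noise_approaches_identity_whitening(self):
        """With truly white residuals and many observations the optimally
        shrunk covariance whitens like sigma^2 * I: crossnobis distances with
        the two whiteners agree."""
        rng = np.random.default_rng(3)
        res = 2.0 * rng.standard_normal((2000, 20))
        cov = shrinkage_covariance(res, mode="optimal")
        A = rng.standard_normal((4, 20))
        B = rng.standard_normal((4, 20))
        d_opt = crossnobis_distances(A, B, np.linalg.inv(cov.sigma))
        d_id = crossnobis_distances(A, B, np.eye(20) / 4.0)
        assert np.allclose(d_opt, d_id, rtol=0.15, atol=0.05 * np.abs(d_id).max())

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.zeros((1, 3)))


class TestCrossnobisToyOracle:
    def test_two_voxel_two_condition_two_fold_hand_arithmetic(self):
        """d = mean over folds of (a_i - a_j)' (b_i - b_j) / P with identity
        whitening, checked against explicit arithmetic to 1e-12."""
        A1 = np.array([[1.0, 2.0], [3.0, 1.0]])     # fold 1, partition A
        B1 = np.array([[2.0, 2.5], [2.5, 0.5]])     # fold 1, partition B
        A2 = np.array([[0.5, 1.5], [2.0, 2.0]])
        B2 = np.array([[1.0, 1.0], [3.0, 0.0]])
        P = 2
        d1 = crossnobis_distances(A1, B1, n_norm=P)
        d2 = crossnobis_distances(A2, B2, n_norm=P)
        d = 0.5 * (d1 + d2)[0, 1]
        # hand arithmetic: fold 1: a-diff (-2, 1), b-diff (-0.5, 2) -> 3; /2 = 1.5
        #                  fold 2: a-diff (-1.5, -0.5), b-diff (-2, 1) -> 2.5; /2 = 1.25
        assert abs(d - 0.5 * (1.5 + 1.25)) < 1e-12

    def test_identical_conditions_have_zero_distance(self):
        A = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        B = np.array([[4.0, 1.0, 0.0], [4.0, 1.0, 0.0]])
        assert crossnobis_distances(A, B)[0, 1] == 0.0


class TestCrossnobisRdm:
    def test_rdm_shape_symmetry_zero_diagonal(self, default_subject):
        rdm = crossnobis_rdm(default_subject)
        assert rdm.D.shape == (8, 8)
        assert np.allclose(rdm.D, rdm.D.T)
        assert np.allclose(np.diag(rdm.D), 0.0)
        assert rdm.conditions == CONDITIONS

    def test_rdm_constructor_rejects_malformed_matrices(self):
        bad = np.arange(64.0).reshape(8, 8)
        with pytest.raises(ValueError):
            RDM(D=bad)
        sym = 0.5 * (bad + bad.T)
        with pytest.raises(ValueError):
            RDM(D=sym)                          # nonzero diagonal

    def test_scaling_patterns_by_c_scales_distances_by_c_squared(self):
        ds = generate_subject(SynthConfig(seed=9, n_voxels=40))
        c = 3.0
        scaled = replace_betas(ds, ds.betas * c)
        d1 = crossnobis_rdm(ds, noise_cov="identity").D
        d2 = crossnobis_rdm(scaled, noise_cov="identity").D
        assert np.allclose(d2, c**2 * d1, rtol=1e-10)

    def test_naive_mahalanobis_exceeds_crossnobis_under_null(self):
        """Without cross-validation the squared distance is positively
        biased; the cross-validated version is centred near zero."""
        naive_means, cross_means = [], []
        for seed in range(25):
            cfg = SynthConfig(seed=800 + seed, n_voxels=60, exec_amplitude=0.0,
                              imagery_scale=0.0, modality_offset_amplitude=0.0,
                              noise_sd=1.0, noise_sd_imagery=1.0)
            ds = generate_subject(cfg)
            off = ~np.eye(8, dtype=bool)
            naive_means.append(naive_mahalanobis_rdm(ds).D[off].mean())
            cross_means.append(crossnobis_rdm(ds).D[off].mean())
        assert np.mean(naive_means) > np.mean(cross_means)
        assert np.mean(naive_means) > 0
        assert abs(np.mean(cross_means)) < np.mean(naive_means) / 3


def replace_betas(ds, betas):
    from fingermvpa.synth import SubjectDataset

    return SubjectDataset(betas=betas, labels=ds.labels, grid=ds.grid,
                          roi=ds.roi, truth=ds.truth, subject_id=ds.subject_id)


class TestDiagOffdiagContrast:
    def _rdm_with_cross_block(self, diag, off, subject="s"):
        D = np.zeros((8, 8))
        block = np.full((4, 4), off, dtype=float)
        np.fill_diagonal(block, diag)
        D[:4, 4:] = block
        D[4:, :4] = block.T
        return RDM(D=D, subject=subject)

    def test_constant_cross_block_gives_zero_t(self):
        rdms = [self._rdm_with_cross_block(2.0, 2.0, f"s{i}") for i in range(5)]
        res = diag_offdiag_contrast(rdms)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_toy_contrast_is_exactly_minus_one(self):
        rdms = [self._rdm_with_cross_block(1.0, 2.0, f"s{i}") for i in range(4)]
        res = diag_offdiag_contrast(rdms)
        assert np.allclose(res["per_subject_diff"], -1.0)
        assert res["diag_mean"] == 1.0 and res["offdiag_mean"] == 2.0

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            diag_offdiag_contrast([self._rdm_with_cross_block(1, 2)])


class TestWithinTaskPairTable:
    def test_identical_values_give_all_zero_F(self):
        D = np.full((8, 8), 2.0)
        np.fill_diagonal(D, 0.0)
        rdms = [RDM(D=D, subject=f"s{i}") for i in range(4)]
        res = within_task_pair_table(rdms)
        assert np.allclose(res["anova"]["F"], 0.0)

    def test_anova_matches_manual_sums_of_squares(self):
        """Two-way within-subject ANOVA F values against the textbook SS
        decomposition computed by hand."""
        rng = np.random.default_rng(4)
        n_s, n_a, n_b = 6, 2, 6
        y = rng.standard_normal((n_s, n_a, n_b)) + np.arange(n_b) * 0.3
        rdms = []
        for s in range(n_s):
            D = np.zeros((8, 8))
            for a, task in enumerate(("execution", "imagery")):
                base = 0 if task == "execution" else 4
                from fingermvpa.rsa import _pair_cell

                for b, pair in enumerate(FINGER_PAIRS):
                    i, j = _pair_cell(task, pair)
                    D[i, j] = D[j, i] = y[s, a, b]
            rdms.append(RDM(D=D, subject=f"s{s}"))
        res = within_task_pair_table(rdms)

        gm = y.mean()
        ss_s = n_a * n_b * ((y.mean(axis=(1, 2)) - gm) ** 2).sum()
        ss_a = n_s * n_b * ((y.mean(axis=(0, 2)) - gm) ** 2).sum()
        ss_b = n_s * n_a * ((y.mean(axis=(0, 1)) - gm) ** 2).sum()
        cell_ab = y.mean(axis=0)
        ss_ab = n_s * ((cell_ab - y.mean(axis=(0, 2))[:, None]
                        - y.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        cell_as = y.mean(axis=2)
        ss_as = n_b * ((cell_as - y.mean(axis=(1, 2))[:, None]
                        - y.mean(axis=(0, 2))[None, :] + gm) ** 2).sum()
        cell_bs = y.mean(axis=1)
        ss_bs = n_a * ((cell_bs - y.mean(axis=(1, 2))[:, None]
                        - y.mean(axis=(0, 1))[None, :] + gm) ** 2).sum()
        ss_tot = ((y - gm) ** 2).sum()
        ss_abs = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs
        F_a = (ss_a / (n_a - 1)) / (ss_as / ((n_a - 1) * (n_s - 1)))
        F_b = (ss_b / (n_b - 1)) / (ss_bs / ((n_b - 1) * (n_s - 1)))
        F_ab = (ss_ab / ((n_a - 1) * (n_b - 1))) / (
            ss_abs / ((n_a - 1) * (n_b - 1) * (n_s - 1))
        )
        an = res["anova"].set_index("Source")
        assert an.loc["task", "F"] == pytest.approx(F_a, rel=1e-6)
        assert an.loc["pair", "F"] == pytest.approx(F_b, rel=1e-6)
        assert an.loc["task * pair", "F"] == pytest.approx(F_ab, rel=1e-6)

    def test_adjacent_fingers_are_closer_than_distant_in_execution(self):
        """Somatotopic adjacency in the generator shows up as shorter
        within-execution distances for neighbouring finger pairs."""
        adj, dist = [], []
        for seed in range(12):
            ds = generate_subject(SynthConfig(seed=600 + seed))
            rdm = crossnobis_rdm(ds)
            table = within_task_pair_table([rdm, rdm])["table"]
            ex = table[(table.task == "execution")].drop_duplicates(
                subset=["pair"]).set_index("pair")["distance"]
            adj.append(ex[["index-middle", "middle-ring", "ring-little"]].mean())
            dist.append(ex[["index-ring", "middle-little", "index-little"]].mean())
        assert np.mean(adj) < np.mean(dist)

    def test_posthoc_tukey_available(self):
        rng = np.random.default_rng(5)
        rdms = []
        for s in range(5):
            D = rng.standard_normal((8, 8))
            D = 0.5 * (D + D.T)
            np.fill_diagonal(D, 0.0)
            rdms.append(RDM(D=D, subject=f"s{s}"))
        res = within_task_pair_table(rdms, posthoc=True)
        assert set(res["tukey"]) == {"execution", "imagery"}


class TestClassicalMds:
    def test_line_configuration_recovers_spacing(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        D = (x[:, None] - x[None, :]) ** 2
        res = classical_mds(D, dims=3)
        assert res["n_positive"] == 1
        coords = res["coords"][:, 0]
        rec = np.abs(coords[:, None] - coords[None, :])
        assert np.allclose(rec, np.abs(x[:, None] - x[None, :]), atol=1e-8)

    def test_zero_matrix_gives_zero_coordinates(self):
        with pytest.warns(RuntimeWarning):
            res = classical_mds(np.zeros((8, 8)), dims=3)
        assert res["coords"].size == 0 or np.allclose(res["coords"], 0.0)

    def test_modality_offset_dominates_first_axis(self):
        """With the modality offset much larger than the finger signal, the
        first MDS axis separates execution from imagery conditions."""
        rdms = []
        for seed in range(8):
            cfg = SynthConfig(seed=400 + seed, modality_offset_amplitude=60.0)
            rdms.append(crossnobis_rdm(generate_subject(cfg)).D)
        mean_rdm = RDM(D=np.mean(rdms, axis=0), subject="group")
        res = classical_mds(mean_rdm, dims=2)
        ax1 = res["coords"][:, 0]
        gap = abs(ax1[:4].mean() - ax1[4:].mean())
        spread = max(np.ptp(ax1[:4]), np.ptp(ax1[4:]))
        assert gap > spread
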