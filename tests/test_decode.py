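"""Classification machinery: one-vs-one training and voting against a
nearest-centroid oracle, fold-scheme structure and leakage guards, the four
decoding schemes on synthetic subjects, permutation nulls, and the group
t-test against chance."""

import numpy as np
import pytest
from dataclasses import replace

from fingermvpa.decode import (
    EXEC,
    IMAG,
    Fold,
    OvOModel,
    group_vs_chance,
    make_scheme,
    permutation_null,
    predict_vote,
    run_scheme,
    train_ovo,
)
from fingermvpa.synth import SynthConfig, generate_subject
from conftest import make_noise_cfg


def toy_corner_set(n_copies=3):
    """Linearly separable 2-voxel set: four class centroids at unit corners."""
    centroids = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    X = np.repeat(centroids, n_copies, axis=0)
    y = np.repeat([1, 2, 3, 4], n_copies)
    return X, y, centroids


class TestOvO:
    def test_four_classes_give_six_binary_classifiers(self):
        X, y, _ = toy_corner_set()
        model = train_ovo(X, y)
        assert len(model.classifiers) == len(model.pairs) == 6

    def test_two_classes_reduce_to_single_sign_decision(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([1, 1, 2, 2])
        model = train_ovo(X, y)
        assert len(model.classifiers) == 1
        direct = model.classifiers[0].predict([[0.1], [0.9]])
        assert np.array_equal(predict_vote(model, [[0.1], [0.9]]), direct)

    def test_separable_toy_training_accuracy_is_perfect(self):
        X, y, _ = toy_corner_set()
        model = train_ovo(X, y)
        assert np.array_equal(predict_vote(model, X), y)

    def test_predictions_match_nearest_centroid_oracle(self):
        """On noiseless separable data, OvO voting agrees with brute-force
        nearest-centroid classification."""
        X, y, centroids = toy_corner_set()
        model = train_ovo(X, y)
        rng = np.random.default_rng(0)
        probes = rng.uniform(-0.2, 1.2, size=(50, 2))
        oracle = 1 + np.argmin(
            np.linalg.norm(probes[:, None] - centroids[None], axis=2), axis=1
        )
        # drop probes near decision boundaries where the two rules may differ
        d = np.sort(np.linalg.norm(probes[:, None] - centroids[None], axis=2), axis=1)
        clear = d[:, 1] - d[:, 0] > 0.2
        assert np.array_equal(predict_vote(model, probes)[clear], oracle[clear])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_ovo(np.zeros((3, 2)), np.array([1, 1, 1]))

    def test_dimension_mismatch_rejected(self):
        X, y, _ = toy_corner_set()
        model = train_ovo(X, y)
        with pytest.raises(ValueError):
            predict_vote(model, np.zeros((2, 3)))

    def test_tie_breaks_to_lowest_class_index(self):
        """Vote profile (2, 2, 1, 1) must resolve to class 1."""

        class FixedClf:
            def __init__(self, label):
                self.label = label

            def predict(self, X):
                return np.full(len(X), self.label)

        pairs = [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]
        winners = [1, 1, 4, 2, 2, 3]          # votes: 2, 2, 1, 1
        model = OvOModel(
            classes=np.array([1, 2, 3, 4]),
            pairs=pairs,
            classifiers=[FixedClf(w) for w in winners],
            n_features=2,
        )
        assert predict_vote(model, np.zeros((1, 2)))[0] == 1


class TestFoldSchemes:
    def test_within_scheme_structure(self):
        sch = make_scheme("within-exec")
        assert len(sch.folds) == 4 and sch.chance == 25.0
        test_cells = [f.test[0] for f in sch]
        assert sorted(test_cells) == [(EXEC, s) for s in range(4)]
        for f in sch:
            assert not set(f.train) & set(f.test)

    def test_cross_scheme_has_two_directions(self):
        sch = make_scheme("cross")
        assert [f.direction for f in sch] == ["exec->imag", "imag->exec"]
        for f in sch:
            train_mods = {m for m, _ in f.train}
            test_mods = {m for m, _ in f.test}
            assert train_mods != test_mods

    def test_between_modality_scheme_structure(self):
        sch = make_scheme("between-modality")
        assert len(sch.folds) == 8 and sch.chance == 50.0
        for f in sch:
            assert f.label_kind == "modality"
            held = {s for _, s in f.test}
            assert not any(s in held for _, s in f.train)

    def test_overlapping_fold_rejected(self):
        with pytest.raises(ValueError):
            Fold(train=((0, 0), (0, 1)), test=((0, 1),))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("leave-one-finger-out")


class TestRunScheme:
    def test_noiseless_shared_code_gives_perfect_cross_accuracy(self):
        cfg = SynthConfig(seed=1, noise_sd=1e-9, noise_sd_imagery=1e-9,
                          imagery_scale=1.0, modality_offset_amplitude=0.0)
        ds = generate_subject(cfg)
        rec = run_scheme(ds, "cross")
        assert rec.accuracy == 100.0

    def test_accuracy_bounds_and_determinism(self, default_subject):
        a = run_scheme(default_subject, "within-exec")
        b = run_scheme(default_subject, "within-exec")
        assert 0.0 <= a.accuracy <= 100.0
        assert a.accuracy == b.accuracy
        assert a.n_test_blocks == 48

    def test_within_execution_beats_cross_and_imagery_trained_direction_wins(self):
        """At the default shared-code scale, within-execution decoding beats
        cross-modal decoding for most subjects, and training on (noisier)
        imagery then testing on execution outperforms the reverse direction
        on average."""
        n = 100
        win, e2i, i2e = 0, [], []
        for seed in range(n):
            ds = generate_subject(SynthConfig(seed=3000 + seed))
            within = run_scheme(ds, "within-exec").accuracy
            cross = run_scheme(ds, "cross")
            win += within >= cross.accuracy
            e2i.append(cross.direction_accuracy("exec->imag"))
            i2e.append(cross.direction_accuracy("imag->exec"))
        assert win / n >= 0.80
        assert np.mean(i2e) >= np.mean(e2i)


class TestPermutationNull:
    def test_perfect_signal_beats_every_permutation(self):
        cfg = SynthConfig(seed=2, noise_sd=1e-6, noise_sd_imagery=1e-6,
                          n_voxels=50)
        ds = generate_subject(cfg)
        res = permutation_null(ds, "within-exec", n_perm=200, seed=0)
        assert res["observed"] == 100.0
        assert res["p"] <= 2.0 / 200
        assert res["significant"]

    def test_fixed_seed_reproduces_null_distribution(self, default_subject):
        a = permutation_null(default_subject, "cross", n_perm=150, seed=5)
        b = permutation_null(default_subject, "cross", n_perm=150, seed=5)
        assert np.array_equal(a["null"], b["null"])

    def test_small_n_perm_warns(self, default_subject):
        with pytest.warns(RuntimeWarning):
            permutation_null(default_subject, "cross", n_perm=50, seed=1)

    def test_type_one_error_calibration_under_null(self):
        """On data with no finger signal the observed accuracy lies inside
        the central 95% of its own permutation null for ~95% of subjects."""
        inside = 0
        n_subj = 100
        for seed in range(n_subj):
            ds = generate_subject(make_noise_cfg(seed=7000 + seed, n_voxels=60))
            res = permutation_null(ds, "within-exec", n_perm=400, seed=seed)
            lo, hi = np.percentile(res["null"], [2.5, 97.5])
            inside += lo <= res["observed"] <= hi
        assert inside / n_subj >= 0.88


class TestGroupVsChance:
    def test_all_at_chance_gives_t_zero_p_one(self):
        res = group_vs_chance([25.0, 25.0, 25.0], 25.0)
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_matches_hand_computed_t(self):
        accs = np.array([35.0, 30.0, 40.0, 25.0, 20.0, 30.0])
        res = group_vs_chance(accs, 25.0)
        t_oracle = (accs.mean() - 25.0) / (accs.std(ddof=1) / np.sqrt(len(accs)))
        assert res["t"] == pytest.approx(t_oracle, rel=1e-12)
        assert res["dof"] == 5

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_vs_chance([30.0], 25.0)
        with pytest.raises(ValueError):
            group_vs_chance([30.0, 30.0, 30.0], 25.0)
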