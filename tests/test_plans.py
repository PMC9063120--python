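"""Staged MLP architectures, balancing, pseudo-labeling and the PLANS loop."""

import numpy as np
import pytest

from ginplans import chem, evaluation, plans, synthetic
from ginplans.labels import MISSING, MixupConfig
from ginplans.plans import (DatasetBundle, TrainingConfig, balance_training_set,
                            build_mlp_spec, parameter_count, _onehot_targets)


class TestArchitectures:
    def test_small_width_plan_for_2048(self):
        spec = build_mlp_spec("Small", 2048, 32)
        assert spec.hidden_widths == [4096, 8192, 8192, 4096, 2048, 1024, 512]

    def test_medium_inserts_two_3x_layers(self):
        spec = build_mlp_spec("Medium", 2048, 32)
        assert len(spec.hidden_widths) == 9
        assert spec.hidden_widths.count(6144) == 2
        # the insertions sit after Small layers 1 and 3
        assert spec.hidden_widths == [4096, 6144, 8192, 8192, 6144,
                                      4096, 2048, 1024, 512]

    def test_large_includes_two_6x_layers(self):
        spec = build_mlp_spec("Large", 300, 32)
        assert spec.hidden_widths.count(1800) == 2
        assert len(spec.hidden_widths) == 11

    @pytest.mark.parametrize("input_len", [4, 300, 2048])
    def test_parameter_counts_strictly_increase(self, input_len):
        counts = [parameter_count(build_mlp_spec(t, input_len, 32))
                  for t in ("Small", "Medium", "Large")]
        assert counts[0] < counts[1] < counts[2]

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            build_mlp_spec("Huge", 128, 32)

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            build_mlp_spec("Small", 3, 32)

    def test_dropout_rate_recorded(self):
        assert build_mlp_spec("Small", 128, 32).dropout_rate == 0.3


class TestBalancing:
    @staticmethod
    def _rows(classes, n_classes=32, dim=8):
        X = np.arange(len(classes) * dim, dtype=np.float32).reshape(len(classes), dim)
        Y = np.zeros((len(classes), n_classes), dtype=np.float32)
        for i, c in enumerate(classes):
            Y[i, c] = 1.0
        return X, Y

    def test_minority_class_filled_to_cap(self):
        X, Y = self._rows([0] * 100 + [5] * 10)
        Xp, Yp = self._rows([5] * 500)
        Xb, Yb = balance_training_set(X, Y, Xp, Yp)
        counts = np.bincount(Yb.argmax(axis=1), minlength=32)
        assert counts[5] == 100 and counts[0] == 100

    def test_all_negative_pool_rows_never_added(self):
        X, Y = self._rows([0] * 50 + [3] * 5)
        Xp, Yp = self._rows([0] * 200)
        Xb, Yb = balance_training_set(X, Y, Xp, Yp)
        assert len(Xb) == len(X)

    def test_class_at_cap_unchanged(self):
        X, Y = self._rows([0] * 20 + [7] * 20)
        Xp, Yp = self._rows([7] * 50)
        Xb, _ = balance_training_set(X, Y, Xp, Yp)
        assert len(Xb) == len(X)

    def test_empty_pool_returns_labeled_unchanged(self):
        X, Y = self._rows([0, 1, 2])
        Xb, Yb = balance_training_set(X, Y, np.zeros((0, 8)), np.zeros((0, 32)))
        assert np.array_equal(Xb, X) and np.array_equal(Yb, Y)

    def test_original_rows_always_preserved(self):
        X, Y = self._rows([0] * 30 + [2] * 3 + [9] * 1)
        Xp, Yp = self._rows([2] * 100 + [9] * 100)
        Xb, Yb = balance_training_set(X, Y, Xp, Yp)
        assert np.array_equal(Xb[:len(X)], X)
        assert np.array_equal(Yb[:len(Y)], Y)

    def test_invariants_over_random_pools(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lab = rng.integers(0, 8, size=60)
            lab[:20] = 0  # ensure an all-negative majority presence
            pool = rng.integers(0, 8, size=200)
            X, Y = self._rows(lab.tolist(), n_classes=8)
            Xp, Yp = self._rows(pool.tolist(), n_classes=8)
            _, Yb = balance_training_set(X, Y, Xp, Yp)
            counts = np.bincount(Yb.argmax(axis=1), minlength=8)
            before = np.bincount(lab, minlength=8)
            assert counts[0] == before[0]          # no pseudo class-0 added
            for c in range(1, 8):
                # a class never grows past the all-negative cap (classes
                # already above it keep only their original rows)
                assert counts[c] <= max(before[c], before[0])


def _toy_bundle(n=240, seed=0, missing_rate=0.0, unlabeled_fraction=0.0,
                noise=0.0, nbits=128):
    cfg = synthetic.SyntheticConfig(n_molecules=n, missing_rate=missing_rate,
                                    unlabeled_fraction=unlabeled_fraction,
                                    label_noise=noise, seed=seed)
    ds = synthetic.generate_dataset(cfg)
    Xf, _ = chem.ecfp_matrix([s for s, _ in ds.fully_labeled], radius=1,
                             n_bits=nbits)
    yf = np.vstack([l for _, l in ds.fully_labeled])
    if ds.partially_labeled:
        Xp, _ = chem.ecfp_matrix([s for s, _ in ds.partially_labeled],
                                 radius=1, n_bits=nbits)
        yp = np.vstack([l for _, l in ds.partially_labeled])
    else:
        Xp, yp = np.zeros((0, nbits)), np.zeros((0, 5), dtype=np.int64)
    if ds.unlabeled:
        Xu, _ = chem.ecfp_matrix(ds.unlabeled, radius=1, n_bits=nbits)
    else:
        Xu = np.zeros((0, nbits))
    return DatasetBundle(Xf, yf, Xp, yp, Xu)


class TestTeacher:
    def test_capacity_on_linearly_separable_classes(self):
        rng = np.random.default_rng(5)
        n = 200
        y = np.zeros((n, 2), dtype=np.int64)
        y[n // 2:] = 1
        X = rng.standard_normal((n, 16)).astype(np.float32)
        X[n // 2:] += 4.0
        cfg = TrainingConfig(epochs=60, patience=60, seed=0)
        model = plans.train_teacher(X, y, cfg)
        _, _, binary = plans.predict(model, X)
        assert np.mean(np.all(binary == y, axis=1)) >= 0.95

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 8)).astype(np.float32)
        y = (X[:, :3] > 0).astype(np.int64)
        cfg = TrainingConfig(epochs=5, seed=3)
        a = plans.train_teacher(X, y, cfg)
        b = plans.train_teacher(X, y, cfg)
        assert a.history["train_loss"] == b.history["train_loss"]

    def test_single_class_set_warns_but_trains(self, caplog):
        X = np.ones((20, 8), dtype=np.float32)
        y = np.zeros((20, 2), dtype=np.int64)
        with caplog.at_level("WARNING"):
            plans.train_teacher(X, y, TrainingConfig(epochs=2, seed=0))
        assert any("single-class" in r.message for r in caplog.records)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            plans.train_teacher(np.zeros((0, 8)), np.zeros((0, 2)),
                                TrainingConfig(epochs=1))

    def test_noise_asymmetry_flags(self):
        bundle = _toy_bundle(n=60)
        cfg = TrainingConfig(epochs=2, seed=0)
        teacher = plans.train_teacher(bundle.X_full, bundle.y_full, cfg)
        assert teacher.net.dropout_rate == 0.0  # teachers are noise-free
        spec = build_mlp_spec("Small", bundle.input_len, 32)
        student = plans._fit_mlp(spec, bundle.X_full,
                                 _onehot_targets(bundle.y_full), cfg, 0,
                                 noisy=True)
        assert student.net.dropout_rate == pytest.approx(0.3)


@pytest.fixture(scope="module")
def teacher_and_bundle():
    bundle = _toy_bundle(n=200, missing_rate=0.3, unlabeled_fraction=0.2,
                         seed=2)
    cfg = TrainingConfig(epochs=5, seed=0)
    teacher = plans.train_teacher(bundle.X_full, bundle.y_full, cfg)
    return teacher, bundle


@pytest.fixture(scope="module")
def toy_model():
    bundle = _toy_bundle(n=100, seed=7)
    cfg = TrainingConfig(epochs=3, seed=0)
    return plans.train_teacher(bundle.X_full, bundle.y_full, cfg), bundle


class TestPseudoLabeling:
    def test_soft_labels_are_distributions(self, teacher_and_bundle):
        teacher, bundle = teacher_and_bundle
        Yp, Yu = pseudo = plans.pseudo_label(teacher, bundle)
        for block in pseudo:
            if len(block):
                assert np.allclose(block.sum(axis=1), 1.0, atol=1e-6)
                assert (block >= 0).all()
        assert len(Yp) == len(bundle.X_partial)
        assert len(Yu) == len(bundle.X_unlabeled)

    def test_support_restricted_to_candidates(self, teacher_and_bundle):
        teacher, bundle = teacher_and_bundle
        Yp, _ = plans.pseudo_label(teacher, bundle)
        from ginplans.labels import enumerate_candidates
        for i in range(len(Yp)):
            cands = set(enumerate_candidates(bundle.y_partial[i]).tolist())
            assert set(np.flatnonzero(Yp[i] > 0).tolist()) <= cands

    def test_fully_observed_partial_row_is_hard(self, teacher_and_bundle):
        teacher, bundle = teacher_and_bundle
        y = np.array([[0, 1, 0, 0, 0]])
        b2 = DatasetBundle(bundle.X_full, bundle.y_full,
                           bundle.X_partial[:1], y, bundle.X_unlabeled)
        Yp, _ = plans.pseudo_label(teacher, b2)
        assert Yp[0, 8] == 1.0 and Yp[0].sum() == 1.0


class TestPlansLoop:
    def test_degenerate_configuration_runs(self):
        # no partial/unlabeled pools, mixup off: plain staged training
        bundle = _toy_bundle(n=150, seed=3)
        cfg = TrainingConfig(epochs=3, mixup=MixupConfig(enabled=False), seed=0)
        res = plans.run_plans(bundle, cfg)
        tiers = [h["tier"] for h in res.round_history]
        assert tiers == ["Small", "Medium", "Large"]
        assert 0.0 <= res.test_report.micro_f1 <= 1.0

    def test_empty_fully_labeled_rejected(self):
        bundle = DatasetBundle(np.zeros((0, 8)), np.zeros((0, 5), dtype=int),
                               np.zeros((0, 8)), np.zeros((0, 5), dtype=int),
                               np.zeros((0, 8)))
        with pytest.raises(ValueError):
            plans.run_plans(bundle, TrainingConfig(epochs=1))

    def test_test_split_disjoint_from_training(self):
        bundle = _toy_bundle(n=150, seed=4)
        cfg = TrainingConfig(epochs=2, seed=1)
        res = plans.run_plans(bundle, cfg)
        assert set(res.train_idx) & set(res.test_idx) == set()
        assert len(res.train_idx) + len(res.test_idx) == len(bundle.X_full)
        assert len(res.train_idx) == round(0.7 * len(bundle.X_full))

    def test_balancing_keeps_counts_under_cap(self):
        bundle = _toy_bundle(n=250, missing_rate=0.2, unlabeled_fraction=0.3,
                             seed=5)
        cfg = TrainingConfig(epochs=3, balancing=True,
                             mixup=MixupConfig(enabled=False), seed=0)
        res = plans.run_plans(bundle, cfg)
        assert [h["tier"] for h in res.round_history] == ["Small", "Medium",
                                                          "Large"]

    def test_extra_large_rounds_stop_on_stall(self):
        bundle = _toy_bundle(n=120, seed=6)
        cfg = TrainingConfig(epochs=2, max_plans_rounds=5, seed=0)
        res = plans.run_plans(bundle, cfg)
        tiers = [h["tier"] for h in res.round_history]
        assert tiers[:3] == ["Small", "Medium", "Large"]
        assert len(tiers) <= 5


class TestPrediction:
    def test_probabilities_normalised(self, toy_model):
        m, bundle = toy_model
        probs, hard, binary = plans.predict(m, bundle.X_full)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert binary.shape == (len(bundle.X_full), 5)

    def test_argmax_decoding_consistent(self, toy_model):
        from ginplans.labels import decode_class
        m, bundle = toy_model
        probs, hard, binary = plans.predict(m, bundle.X_full)
        for i in range(5):
            assert binary[i].tolist() == decode_class(int(hard[i]), 5).tolist()

    def test_feature_length_mismatch_rejected(self, toy_model):
        m, _ = toy_model
        with pytest.raises(ValueError):
            plans.predict(m, np.zeros((3, 7), dtype=np.float32))

    def test_inference_deterministic(self, toy_model):
        m, bundle = toy_model
        a = m.predict_proba(bundle.X_full)
        b = m.predict_proba(bundle.X_full)
        assert np.array_equal(a, b)

    def test_model_checkpoint_round_trip(self, toy_model, tmp_path):
        m, bundle = toy_model
        plans.save_model(tmp_path / "m.npz", m)
        m2 = plans.load_model(tmp_path / "m.npz")
        assert np.allclose(m.predict_proba(bundle.X_full[:5]),
                           m2.predict_proba(bundle.X_full[:5]))


class TestMultiLabelMode:
    def test_end_to_end_sigmoid_head(self):
        bundle = _toy_bundle(n=120, missing_rate=0.3, unlabeled_fraction=0.2,
                             seed=8)
        cfg = TrainingConfig(epochs=3, label_mode="multilabel",
                             mixup=MixupConfig(enabled=False), seed=0)
        res = plans.run_plans(bundle, cfg)
        probs, hard, binary = plans.predict(res.model, bundle.X_full[:4])
        assert hard is None
        assert ((probs >= 0) & (probs <= 1)).all()
        assert set(np.unique(binary)) <= {0, 1}


def test_parameter_recovery_of_planted_rule():
    """With complete noise-free labels and a motif-rich vocabulary, the Small
    teacher alone recovers the planted substructure rule (micro-F1 >= 0.9 on
    held-out molecules)."""
    vocab = synthetic.vocabulary_with_motif_weight(2.5)
    mols = synthetic.generate_molecules(1200, seed=7, vocabulary=vocab)
    cfg = synthetic.SyntheticConfig(n_molecules=1200, seed=7)
    ds = synthetic.plant_labels(mols, cfg)
    X, _ = chem.ecfp_matrix([s for s, _ in ds.fully_labeled], radius=1,
                            n_bits=512)
    y = np.vstack([l for _, l in ds.fully_labeled])
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(X))
    n_tr, n_va = int(0.63 * len(X)), int(0.07 * len(X))
    tr, va, te = (perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:])
    tcfg = TrainingConfig(epochs=120, patience=10, seed=0)
    model = plans.train_teacher(X[tr], y[tr], tcfg, X_val=X[va],
                                Y_val=_onehot_targets(y[va]))
    _, _, binary = plans.predict(model, X[te])
    report = evaluation.score(binary, y[te])
    assert report.micro_f1 >= 0.9
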