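import itertools
import math

import numpy as np
import pytest
from scipy import stats

from fundusroi.classify import (
    BACKBONE_REGISTRY,
    BranchConfig,
    TinyMLP,
    apply_flip_rotation,
    augment,
    build_backbone,
    partition_labels,
    predict_assemble,
    preprocess,
    select_best_epoch,
    sigmoid_bce_loss,
    softmax_ce_loss,
    split_dataset,
    train_branch,
)
from fundusroi.classify.transforms import draw_augment_params
from fundusroi.synthdata import SyntheticConfig, generate_dataset, load_manifest
from fundusroi.types import DISEASES, LabelVector

from _oracles import binomial_99_interval


class TestPartitionLabels:
    def test_routing_example(self):
        gs, mac, full = partition_labels(LabelVector(1, 0, 1, 0, 1, 0))
        assert gs == 0
        assert mac == (0, 1)
        assert full == (1, 0, 1)

    def test_all_zero_and_all_one(self):
        assert partition_labels(LabelVector(0, 0, 0, 0, 0, 0)) == (0, (0, 0), (0, 0, 0))
        assert partition_labels(LabelVector(1, 1, 1, 1, 1, 1)) == (1, (1, 1), (1, 1, 1))

    def test_round_trip_all_64_vectors(self):
        for bits in itertools.product((0, 1), repeat=6):
            lv = LabelVector.from_sequence(bits)
            gs, (erm, amd), (dr, rb, rvo) = partition_labels(lv)
            assert (dr, rb, rvo, erm, amd, gs) == bits


class TestAugment:
    def test_flip_frequency_binomial(self):
        rng = np.random.default_rng(0)
        n = 10_000
        flips = sum(draw_augment_params(rng)[0] for _ in range(n))
        lo, hi = binomial_99_interval(n, 0.5)
        assert lo <= flips <= hi

    def test_angle_distribution_ks(self):
        rng = np.random.default_rng(1)
        angles = [draw_augment_params(rng)[1] for _ in range(10_000)]
        res = stats.kstest(angles, stats.uniform(loc=-180, scale=360).cdf)
        assert res.pvalue > 0.01

    def test_identity_path(self):
        image = np.random.default_rng(2).random((16, 16))
        out = apply_flip_rotation(image, flip=False, angle=0.0)
        np.testing.assert_array_equal(out, image)

    def test_flip_only_reverses_columns(self):
        image = np.arange(16, dtype=float).reshape(4, 4)
        out = apply_flip_rotation(image, flip=True, angle=0.0)
        np.testing.assert_array_equal(out, image[:, ::-1])

    def test_rotation_180_matches_double_flip(self):
        image = np.random.default_rng(3).random((20, 20))
        out = apply_flip_rotation(image, flip=False, angle=180.0)
        np.testing.assert_allclose(out, image[::-1, ::-1], atol=1e-7)

    def test_augment_deterministic_given_rng(self):
        image = np.random.default_rng(4).random((16, 16))
        a = augment(image, np.random.default_rng(10))
        b = augment(image, np.random.default_rng(10))
        np.testing.assert_array_equal(a, b)


class TestPreprocess:
    def test_identity_normalization(self):
        image = np.random.default_rng(0).random((32, 32))
        out = preprocess(image, 32, norm_mean=0.0, norm_sd=1.0)
        np.testing.assert_allclose(out, image, atol=1e-6)

    def test_constant_image_zeroed(self):
        image = np.full((16, 16), 0.7)
        out = preprocess(image, 16, norm_mean=0.7, norm_sd=1.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_resize_shape(self):
        out = preprocess(np.zeros((64, 64)), 128)
        assert out.shape == (128, 128)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((8, 8)), 8, norm_sd=0.0)


class TestLosses:
    def test_softmax_ce_closed_form(self):
        logits = np.array([[1.0, 3.0], [0.0, 0.0]])
        classes = np.array([1, 0])
        loss, dlogits = softmax_ce_loss(logits, classes)
        expected = (-math.log(math.exp(3) / (math.exp(1) + math.exp(3)))
                    - math.log(0.5)) / 2
        assert loss == pytest.approx(expected, abs=1e-6)
        # gradient: (softmax - onehot) / n
        p1 = math.exp(3) / (math.exp(1) + math.exp(3))
        np.testing.assert_allclose(
            dlogits, [[(1 - p1) / 2, (p1 - 1) / 2], [-0.25, 0.25]], atol=1e-9)

    def test_sigmoid_bce_closed_form(self):
        logits = np.array([[0.0, 2.0]])
        targets = np.array([[1.0, 0.0]])
        loss, dlogits = sigmoid_bce_loss(logits, targets)
        expected = (-math.log(0.5) - math.log(1 - 1 / (1 + math.exp(-2)))) / 2
        assert loss == pytest.approx(expected, abs=1e-6)
        sig2 = 1 / (1 + math.exp(-2))
        np.testing.assert_allclose(dlogits, [[(0.5 - 1) / 2, sig2 / 2]],
                                   atol=1e-9)

    def test_bce_gradient_by_finite_differences(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=(3, 4))
        targets = rng.integers(0, 2, (3, 4)).astype(float)
        _, grad = sigmoid_bce_loss(logits, targets)
        eps = 1e-6
        for i in range(3):
            for j in range(4):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (sigmoid_bce_loss(lp, targets)[0]
                       - sigmoid_bce_loss(lm, targets)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-5)


class TestPredictAssemble:
    def test_symmetric_gs_logits(self):
        out = predict_assemble({
            "od_gs": np.array([[0.0, 0.0]]),
            "mac_erm_amd": np.zeros((1, 2)),
            "full_dr_rb_rvo": np.zeros((1, 3)),
        })
        assert out[0, DISEASES.index("gs")] == pytest.approx(0.5)

    def test_zero_logit_sigmoid(self):
        out = predict_assemble({
            "od_gs": np.array([[0.0, 0.0]]),
            "mac_erm_amd": np.zeros((1, 2)),
            "full_dr_rb_rvo": np.zeros((1, 3)),
        })
        assert out[0, DISEASES.index("dr")] == pytest.approx(0.5)

    def test_gs_softmax_closed_form(self):
        out = predict_assemble({
            "od_gs": np.array([[1.0, 3.0]]),
            "mac_erm_amd": np.zeros((1, 2)),
            "full_dr_rb_rvo": np.zeros((1, 3)),
        })
        expected = math.exp(3) / (math.exp(1) + math.exp(3))
        assert out[0, DISEASES.index("gs")] == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.8808, abs=1e-4)

    def test_missing_branch_raises(self):
        with pytest.raises(KeyError):
            predict_assemble({"od_gs": np.zeros((1, 2))})

    def test_canonical_order(self):
        out = predict_assemble({
            "od_gs": np.array([[0.0, 5.0]]),
            "mac_erm_amd": np.array([[5.0, -5.0]]),
            "full_dr_rb_rvo": np.array([[-5.0, 5.0, 0.0]]),
        })[0]
        assert out[DISEASES.index("gs")] > 0.9
        assert out[DISEASES.index("erm")] > 0.9
        assert out[DISEASES.index("amd")] < 0.1
        assert out[DISEASES.index("dr")] < 0.1
        assert out[DISEASES.index("rb")] > 0.9
        assert out[DISEASES.index("rvo")] == pytest.approx(0.5)


class TestBackbones:
    def test_registry_and_unknown_name(self):
        assert "tiny-mlp" in BACKBONE_REGISTRY
        with pytest.raises(KeyError):
            build_backbone("resnet-9000", 10, 2, np.random.default_rng(0))

    def test_forward_shape(self):
        model = build_backbone("tiny-mlp", 64, 3, np.random.default_rng(0))
        out = model.forward(np.zeros((5, 8, 8)))
        assert out.shape == (5, 3)

    def test_seeded_init_reproducible(self):
        a = TinyMLP(10, (4,), 2, np.random.default_rng(3))
        b = TinyMLP(10, (4,), 2, np.random.default_rng(3))
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])


def _toy_sets(rng, n_train=24, n_val=12, size=12, n_targets=2):
    """Images whose mean intensity encodes the first target."""
    def make(n):
        y = rng.integers(0, 2, (n, n_targets))
        x = []
        for row in y:
            base = 0.25 + 0.5 * row[0]
            x.append(np.clip(rng.normal(base, 0.05, (size, size)), 0, 1))
        return x, y
    x_tr, y_tr = make(n_train)
    x_va, y_va = make(n_val)
    # ensure both classes present per target in val
    for j in range(n_targets):
        y_va[0, j], y_va[1, j] = 0, 1
    return (x_tr, y_tr), (x_va, y_va)


class TestTrainBranch:
    def test_select_best_epoch_injected_history(self):
        history = [{"epoch": e, "mean_val_auc": v}
                   for e, v in enumerate([0.5, 0.6, 0.55, 0.7, 0.65, 0.6,
                                          0.68, 0.9, 0.7, 0.8])]
        assert select_best_epoch(history) == 7

    def test_select_best_epoch_tie_goes_earliest(self):
        history = [{"epoch": 0, "mean_val_auc": 0.8},
                   {"epoch": 1, "mean_val_auc": 0.8}]
        assert select_best_epoch(history) == 0

    def test_overfit_smoke(self):
        rng = np.random.default_rng(0)
        train, val = _toy_sets(rng)
        config = BranchConfig(branch_id="mac_erm_amd", epochs=25,
                              input_size=12, augment=False, lr_init=1e-2,
                              batch_size=24, seed=0)
        trained = train_branch(train, val, config)
        assert trained.history[-1]["train_loss"] < trained.history[0]["train_loss"]

    def test_same_seed_identical_runs(self):
        rng = np.random.default_rng(1)
        train, val = _toy_sets(rng)
        config = BranchConfig(branch_id="mac_erm_amd", epochs=4, input_size=12,
                              seed=7)
        a = train_branch(train, val, config)
        b = train_branch(train, val, config)
        assert a.best_epoch == b.best_epoch
        assert [h["mean_val_auc"] for h in a.history] == \
            [h["mean_val_auc"] for h in b.history]

    def test_degenerate_validation_rejected(self):
        rng = np.random.default_rng(2)
        train, val = _toy_sets(rng)
        x_va, y_va = val
        y_va[:, 0] = 1  # all-positive
        config = BranchConfig(branch_id="mac_erm_amd", epochs=2, input_size=12)
        with pytest.raises(ValueError, match="single-class"):
            train_branch(train, (x_va, y_va), config)

    def test_two_class_branch_trains(self):
        rng = np.random.default_rng(3)
        train, val = _toy_sets(rng, n_targets=1)
        config = BranchConfig(branch_id="od_gs", epochs=8, input_size=12,
                              augment=False, lr_init=1e-2, seed=0)
        trained = train_branch(train, val, config)
        probs = trained.predict_proba(val[0])
        assert probs.shape == (len(val[0]), 1)
        assert np.all((probs >= 0) & (probs <= 1))
        assert trained.history[-1]["mean_val_auc"] > 0.8

    def test_lr_schedule_halves_every_decade(self):
        rng = np.random.default_rng(4)
        train, val = _toy_sets(rng)
        config = BranchConfig(branch_id="mac_erm_amd", epochs=21, input_size=12,
                              lr_init=1e-3, seed=0)
        trained = train_branch(train, val, config)
        lrs = [h["lr"] for h in trained.history]
        assert lrs[0] == pytest.approx(1e-3)
        assert lrs[10] == pytest.approx(5e-4)
        assert lrs[20] == pytest.approx(2.5e-4)

    def test_checkpoint_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        train, val = _toy_sets(rng)
        config = BranchConfig(branch_id="mac_erm_amd", epochs=2, input_size=12,
                              seed=0)
        trained = train_branch(train, val, config)
        path = tmp_path / "branch.npz"
        trained.save(path)
        from fundusroi.classify.training import TrainedBranch
        loaded = TrainedBranch.load(path)
        np.testing.assert_allclose(
            loaded.predict_logits(val[0]), trained.predict_logits(val[0]))
        assert loaded.best_epoch == trained.best_epoch

    def test_branch_default_learning_rates(self):
        assert BranchConfig(branch_id="od_gs").learning_rate == 1e-3
        assert BranchConfig(branch_id="mac_erm_amd").learning_rate == 1e-3
        assert BranchConfig(branch_id="full_dr_rb_rvo").learning_rate == 1e-4

    def test_branch_defaults(self):
        config = BranchConfig(branch_id="od_gs")
        assert config.batch_size == 8
        assert config.epochs == 60
        assert config.lr_decay == 0.5 and config.lr_decay_every == 10


class TestSplitDataset:
    def _manifest(self, tmp_path, n=200, seed=0):
        config = SyntheticConfig(image_size=32, seed=seed,
                                 disc_radius_frac=0.06, lesion_rate=0.0)
        return load_manifest(generate_dataset(config, n, tmp_path / "ds"))

    def test_single_label_exact_split(self):
        import pandas as pd
        rows = []
        for j, d in enumerate(DISEASES):
            for i in range(100):
                row = {"image": f"{d}_{i}.png", **dict.fromkeys(DISEASES, 0)}
                row[d] = 1
                rows.append(row)
        manifest = pd.DataFrame(rows)
        train, val = split_dataset(manifest, 0.9, seed=0)
        for d in DISEASES:
            assert train[d].sum() == 90
            assert val[d].sum() == 10

    def test_disjoint_and_exhaustive(self, tmp_path):
        manifest = self._manifest(tmp_path)
        train, val = split_dataset(manifest, 0.9, seed=1)
        assert len(train) + len(val) == len(manifest)
        assert set(train["image"]).isdisjoint(set(val["image"]))

    def test_val_share_bounded(self, tmp_path):
        manifest = self._manifest(tmp_path)
        train, val = split_dataset(manifest, 0.9, seed=2)
        for d in DISEASES:
            total = manifest[d].sum()
            share = val[d].sum() / total
            assert 0.05 <= share <= 0.15, (d, share)

    def test_bad_ratio(self, tmp_path):
        manifest = self._manifest(tmp_path, n=20)
        with pytest.raises(ValueError):
            split_dataset(manifest, 1.0)

    def test_rare_class_rejected(self):
        import pandas as pd
        rows = [dict(image=f"{i}.png", **dict.fromkeys(DISEASES, 0))
                for i in range(10)]
        rows[0]["gs"] = 1  # single positive
        with pytest.raises(ValueError, match="gs"):
            split_dataset(pd.DataFrame(rows), 0.9)
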