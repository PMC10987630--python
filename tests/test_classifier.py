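"""AI pipeline: preprocessing, backbones, autoencoder, metrics, CV."""

import itertools

import numpy as np
import pytest

from cspws.classifier import (
    Autoencoder,
    ClassificationDataset,
    ClassifierConfig,
    IdentityDownsampleBackbone,
    RandomConvBackbone,
    encode,
    extract_features,
    optimal_cutpoint,
    preprocess_dmap,
    repeated_stratified_cv,
    roc_auc,
    train_autoencoder,
    train_classifier,
)
from cspws.errors import ValidationError
from cspws.models import DMap, NucleusMask
from cspws.synthetic import synthesize_dmap


def make_dmap(values, mask):
    vals = np.asarray(values, dtype=float).copy()
    vals[~mask] = np.nan
    return DMap(values=vals, mask=NucleusMask(mask))


class TestPreprocess:
    def test_constant_map_maps_to_half(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 4:16] = True
        img = preprocess_dmap(make_dmap(np.full((20, 20), 2.5), mask),
                              out_size=(32, 32))
        assert img.shape == (32, 32, 3)
        assert np.isclose(img.max(), 0.5)

    def test_minmax_span_exact(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((30, 30), bool)
        mask[5:25, 8:22] = True
        vals = 2.5 + 0.1 * rng.standard_normal((30, 30))
        img = preprocess_dmap(make_dmap(vals, mask), out_size=(48, 48))
        assert img.min() == 0.0 and img.max() == 1.0

    def test_anisotropic_ellipse_resized_to_square(self):
        dm = synthesize_dmap(2.5, shape=(80, 40), seed=0)
        img = preprocess_dmap(dm, out_size=(64, 64))
        assert img.shape == (64, 64, 3)

    def test_pixels_outside_mask_ignored(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        rng = np.random.default_rng(1)
        base = 2.5 + 0.1 * rng.standard_normal((20, 20))
        a = base.copy()
        b = base.copy()
        b[~mask] += 5.0  # garbage outside the mask
        img_a = preprocess_dmap(make_dmap(a, mask), out_size=(32, 32))
        img_b = preprocess_dmap(make_dmap(b, mask), out_size=(32, 32))
        assert np.array_equal(img_a, img_b)

    def test_degenerate_bbox_rejected(self):
        mask = np.zeros((10, 10), bool)
        mask[4, :] = True  # single-row mask
        with pytest.raises(ValidationError):
            preprocess_dmap(make_dmap(np.full((10, 10), 2.5), mask))


class TestBackbones:
    def test_deterministic(self, small_backbone):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64, 3))
        assert np.array_equal(small_backbone(img), small_backbone(img))

    def test_output_length_2048_on_224(self):
        bb = RandomConvBackbone(out_dim=2048, seed=0)
        vec = extract_features(np.zeros((224, 224, 3)), bb)
        assert vec.shape == (2048,)

    def test_identity_downsample_length(self):
        bb = IdentityDownsampleBackbone(grid=16)
        assert bb(np.random.default_rng(0).random((64, 64, 3))).shape == (256,)

    def test_too_small_image_rejected(self, small_backbone):
        with pytest.raises(ValidationError):
            small_backbone(np.zeros((8, 8, 3)))

    def test_seed_defines_weights(self):
        img = np.random.default_rng(0).random((64, 64, 3))
        a = RandomConvBackbone(out_dim=32, seed=1, channels=(8, 16, 16, 16))
        b = RandomConvBackbone(out_dim=32, seed=1, channels=(8, 16, 16, 16))
        c = RandomConvBackbone(out_dim=32, seed=2, channels=(8, 16, 16, 16))
        assert np.array_equal(a(img), b(img))
        assert not np.array_equal(a(img), c(img))


class TestAutoencoder:
    def test_low_rank_data_reconstructed(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((10, 128))
        X = rng.standard_normal((200, 10)) @ basis
        _, curve = train_autoencoder(X, latent_dim=40, epochs=50, seed=1)
        assert curve[-1] < 0.05
        assert curve[-1] < 0.1 * curve[0]

    def test_training_curve_deterministic_and_sized(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 32))
        _, a = train_autoencoder(X, latent_dim=8, epochs=12, seed=5)
        _, b = train_autoencoder(X, latent_dim=8, epochs=12, seed=5)
        assert a == b
        assert len(a) == 12
        assert a[-1] <= a[0]

    def test_latent_dim_validation(self):
        X = np.random.default_rng(0).standard_normal((50, 20))
        with pytest.raises(ValidationError):
            train_autoencoder(X, latent_dim=20, epochs=1)
        with pytest.raises(ValidationError):
            train_autoencoder(X[:5], latent_dim=10, epochs=1)

    def test_encoder_contract(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 64))
        model, _ = train_autoencoder(X, latent_dim=16, epochs=5, seed=0)
        z = encode(X[0], model)
        assert z.shape == (16,)
        assert np.array_equal(z, encode(X[0], model))
        assert np.all(np.isfinite(encode(np.zeros(64), model)))
        # latent of the train mean lies within the train latents' box
        zs = encode(X, model)
        zm = encode(X.mean(axis=0), model)
        assert np.all(zm >= zs.min(axis=0) - 1e-9)
        assert np.all(zm <= zs.max(axis=0) + 1e-9)
        with pytest.raises(ValidationError):
            encode(np.zeros(17), model)

    def test_five_layer_symmetric_architecture(self):
        model = Autoencoder(input_dim=2048, latent_dim=40, seed=0)
        assert len(model.weights) == 10  # 5 encoder + 5 decoder
        assert model.dims[0] == 2048 and model.dims[-1] == 40
        widths = [w.shape for w in model.weights]
        assert widths[0][0] == 2048 and widths[4][1] == 40
        assert widths[5][0] == 40 and widths[9][1] == 2048


class TestClassifierTraining:
    def test_separable_clusters_perfect_training_auc(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-2, 0.2, (30, 8)), rng.normal(2, 0.2, (30, 8))])
        y = np.repeat([0, 1], 30)
        clf, _ = train_classifier(X, y)
        assert roc_auc(clf.predict_proba(X)[:, 1], y) == 1.0

    def test_single_config_grid_chosen(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5))
        y = np.repeat([0, 1], 20)
        grid = {"n_estimators": [37], "max_depth": [3]}
        _, chosen = train_classifier(X, y, grid=grid)
        assert chosen == {"n_estimators": 37, "max_depth": 3}

    def test_single_class_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValidationError):
            train_classifier(X, np.zeros(10, int))


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_brute_force_pair_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == pytest.approx(0.75)
        # exhaustive pair enumeration on arbitrary ties
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.integers(0, 5, size=10).astype(float)  # many ties
            y = rng.integers(0, 2, size=10)
            if len(set(y)) < 2:
                continue
            pairs = [
                1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
                for i in np.flatnonzero(y == 1)
                for j in np.flatnonzero(y == 0)
            ]
            assert roc_auc(s, y) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_agrees_with_trapezoid_and_sklearn(self):
        from sklearn.metrics import roc_auc_score, roc_curve

        rng = np.random.default_rng(5)
        scores = rng.normal(size=50) + np.repeat([0, 1], 25)
        labels = np.repeat([0, 1], 25)
        ours = roc_auc(scores, labels)
        fpr, tpr, _ = roc_curve(labels, scores)
        assert ours == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestOptimalCutpoint:
    def test_perfect_separation(self):
        thr, se, sp = optimal_cutpoint([1, 2, 8, 9], [0, 0, 1, 1])
        assert se == 1.0 and sp == 1.0
        assert 2 < thr < 8

    def test_tie_broken_toward_sensitivity(self):
        thr, se, sp = optimal_cutpoint([1, 2, 3, 4], [0, 1, 0, 1])
        # accuracy 3/4 at threshold 1.5 (Se 1, Sp .5) or 3.5 (Se .5, Sp 1)
        assert se == 1.0 and sp == 0.5
        assert thr == pytest.approx(1.5)

    def test_brute_force_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            s = rng.normal(size=9)
            y = rng.integers(0, 2, size=9)
            if len(set(y)) < 2:
                continue
            thr, se, sp = optimal_cutpoint(s, y)
            n1, n0 = (y == 1).sum(), (y == 0).sum()
            best = max(
                ((s >= t) & (y == 1)).sum() + ((s < t) & (y == 0)).sum()
                for t in np.concatenate([s - 1e-9, s + 1e-9])
            )
            achieved = ((s >= thr) & (y == 1)).sum() + ((s < thr) & (y == 0)).sum()
            assert achieved == best

    def test_shift_invariance(self):
        s = np.array([0.2, 0.5, 0.4, 0.9, 0.1])
        y = np.array([0, 1, 0, 1, 0])
        thr, se, sp = optimal_cutpoint(s, y)
        thr2, se2, sp2 = optimal_cutpoint(s + 10.0, y)
        assert thr2 == pytest.approx(thr + 10.0)
        assert (se2, sp2) == (se, sp)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            optimal_cutpoint([1.0, 2.0], [0, 0])


class TestRepeatedStratifiedCV:
    def test_twenty_folds_and_stratification(self, strong_signal_report):
        rep = strong_signal_report
        assert len(rep.folds) == 20
        for f in rep.folds:
            # 24 patients, 4 folds -> 6 test patients, 3 per class
            assert len(f["test_patients"]) == 6
            n_case = sum(p.startswith("class1") for p in f["test_patients"])
            assert abs(n_case - 3) <= 1

    def test_no_patient_leakage(self, strong_signal_dataset,
                                strong_signal_report):
        ds = strong_signal_dataset
        for f in strong_signal_report.folds:
            train_p, test_p = set(f["train_patients"]), set(f["test_patients"])
            assert not (train_p & test_p)
            assert train_p | test_p == set(ds.labels)
            # every cell of a patient stays on one side
            train_cells = np.asarray(f["train_cell_indices"])
            test_cells = np.asarray(f["test_cell_indices"])
            assert set(ds.patient_ids[train_cells]) == train_p
            assert set(ds.patient_ids[test_cells]) == test_p
            assert not (set(train_cells) & set(test_cells))
            assert len(train_cells) + len(test_cells) == ds.features.shape[0]

    def test_strong_signal_auc(self, strong_signal_report):
        assert strong_signal_report.auc_mean >= 0.95

    def test_zero_separation_null_auc(self, small_backbone):
        from cspws.synthetic import generate_dmap_dataset

        dmaps, pids, labels = generate_dmap_dataset(
            n_per_class=8, cells_per_patient=6,
            d_by_class=(2.5, 2.5), seed=123,
        )
        ds = ClassificationDataset.from_dmaps(dmaps, pids, labels,
                                              small_backbone, out_size=(64, 64))
        rep = repeated_stratified_cv(
            ds, config=ClassifierConfig(latent_dim=20, epochs=20), seed=1
        )
        assert 0.3 <= rep.auc_mean <= 0.7

    def test_too_few_patients_rejected(self, small_backbone):
        rng = np.random.default_rng(0)
        feats = rng.standard_normal((9, 16))
        pids = np.array(["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        labels = {"a": 0, "b": 1, "c": 1}
        ds = ClassificationDataset(feats, pids, labels)
        with pytest.raises(ValidationError):
            repeated_stratified_cv(ds, k=4, repeats=1)
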