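"""Classifier harness: preprocessing, backends, determinism, gradients."""

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest

from cardioslide.classifier import (
    ClassifierConfig,
    ModelState,
    TrainingError,
    fit,
    predict_proba,
    preprocess_for_model,
)
from cardioslide.dataset import Manifest
from cardioslide.evaluate import roc_auc
from cardioslide.vit import TinyViT, ViTSpec, patchify

SMALL_VIT = dict(input_size=32, embed_patch=8, width=32, depth=2, n_heads=4,
                 epochs=4, batch_size=32, learning_rate=1e-3)


def _manifest(tmp_path, rng, n_per_class=40, mean_shift=0.35, size=32):
    """Write tiny RGB PNGs whose red-channel mean encodes the label."""
    rows = []
    for i in range(2 * n_per_class):
        label = i % 2
        img = rng.normal(90 + label * mean_shift * 255, 12, (size, size, 3))
        img = np.clip(img, 0, 255).astype(np.uint8)
        path = tmp_path / f"item{i:03d}.png"
        iio.imwrite(path, img)
        rows.append((str(path), f"P{i % 8}", label,
                     "train" if i % 8 < 6 else "test", "rot0"))
    frame = pd.DataFrame(rows, columns=["item_path", "patient_id", "label",
                                        "split", "augmentation_tag"])
    return Manifest(frame)


class TestPreprocess:
    def test_square_patch_at_native_size_keeps_geometry(self, rng):
        img = rng.integers(0, 256, (128, 128, 3)).astype(np.uint8)
        out = preprocess_for_model(img, 128)
        assert out.shape == (128, 128, 3)
        assert np.allclose(out, img / 255.0)

    def test_tall_crop_resized_and_padded(self, rng):
        img = rng.integers(50, 256, (30, 10)).astype(np.uint8)
        out = preprocess_for_model(img, 64)
        assert out.shape == (64, 64, 3)
        # 30x10 -> longer side 64, shorter round(10*64/30) = 21
        assert out[:, :21].any()
        assert not out[:, 21:].any()

    def test_constant_image_constant_up_to_padding(self):
        img = np.full((16, 16), 100, dtype=np.uint8)
        out = preprocess_for_model(img, 32)
        assert np.allclose(out, 100 / 255.0, atol=1e-6)

    def test_grayscale_replicated_to_three_channels(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        out = preprocess_for_model(img, 32)
        assert np.array_equal(out[..., 0], out[..., 2])

    def test_values_scaled_to_unit_interval(self, rng):
        img = rng.integers(0, 65536, (20, 20)).astype(np.uint16)
        out = preprocess_for_model(img, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestIntensityBaseline:
    def test_recovers_mean_intensity_rule(self, tmp_path, rng):
        m = _manifest(tmp_path, rng)
        cfg = ClassifierConfig(backend_name="intensity_baseline", input_size=32)
        state = fit(cfg, m.subset("train"))
        scores = predict_proba(state, m.subset("test"))
        acc = ((scores.score > 0.5).astype(int) == scores.true_label).mean()
        assert acc >= 0.95

    def test_scores_live_in_unit_interval(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=10)
        cfg = ClassifierConfig(backend_name="intensity_baseline", input_size=32)
        state = fit(cfg, m.subset("train"))
        scores = predict_proba(state, m.subset("test"))
        assert scores.score.between(0, 1).all()
        assert len(scores) == len(m.subset("test"))

    def test_empty_manifest_scores_empty(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=10)
        cfg = ClassifierConfig(backend_name="intensity_baseline", input_size=32)
        state = fit(cfg, m.subset("train"))
        empty = Manifest(m.frame.iloc[0:0].copy())
        assert len(predict_proba(state, empty)) == 0

    def test_label_inversion_flips_auc(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, mean_shift=0.15)
        cfg = ClassifierConfig(backend_name="intensity_baseline", input_size=32)
        state = fit(cfg, m.subset("train"))
        test = m.subset("test")
        auc = roc_auc(predict_proba(state, test)).area

        flipped_frame = m.frame.assign(label=1 - m.frame.label)
        flipped = Manifest(flipped_frame)
        state_f = fit(cfg, flipped.subset("train"))
        scores_f = predict_proba(state_f, flipped.subset("test"))
        auc_f = roc_auc(scores_f).area
        # the flipped model ranks the original positives low: on the
        # original labels its scores give 1 - AUC
        scores_orig_labels = scores_f.assign(true_label=1 - scores_f.true_label)
        assert roc_auc(scores_orig_labels).area == pytest.approx(1 - auc_f, abs=1e-12)
        assert auc_f == pytest.approx(auc, abs=0.05)


class TestTransformerBackend:
    def test_same_seed_gives_identical_scores(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=12)
        cfg = ClassifierConfig(backend_name="transformer_small", epochs=1,
                               **{k: v for k, v in SMALL_VIT.items()
                                  if k != "epochs"})
        test = m.subset("test")
        a = predict_proba(fit(cfg, m.subset("train")), test)
        b = predict_proba(fit(cfg, m.subset("train")), test)
        assert np.array_equal(a.score.to_numpy(), b.score.to_numpy())

    def test_different_seed_changes_model(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=12)
        base = {k: v for k, v in SMALL_VIT.items() if k != "epochs"}
        a = fit(ClassifierConfig(epochs=1, seed=0, **base), m.subset("train"))
        b = fit(ClassifierConfig(epochs=1, seed=1, **base), m.subset("train"))
        assert not np.array_equal(a.arrays["embed_W"], b.arrays["embed_W"])

    def test_learns_strong_intensity_effect(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=40)
        cfg = ClassifierConfig(backend_name="transformer_small", **SMALL_VIT)
        state = fit(cfg, m.subset("train"))
        scores = predict_proba(state, m.subset("test"))
        acc = ((scores.score > 0.5).astype(int) == scores.true_label).mean()
        assert acc >= 0.9

    def test_single_class_manifest_rejected(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=6)
        single = Manifest(m.frame[m.frame.label == 1].copy())
        with pytest.raises(TrainingError):
            fit(ClassifierConfig(**SMALL_VIT), single)

    def test_missing_file_named_in_error(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=6)
        cfg = ClassifierConfig(backend_name="intensity_baseline", input_size=32)
        state = fit(cfg, m.subset("train"))
        broken = Manifest(m.subset("test").frame.assign(item_path="gone.png")
                          .drop_duplicates("item_path"))
        with pytest.raises(FileNotFoundError, match="gone.png"):
            predict_proba(state, broken)


class TestModelState:
    def test_save_load_roundtrip_bit_identical(self, tmp_path, rng):
        m = _manifest(tmp_path, rng, n_per_class=8)
        cfg = ClassifierConfig(epochs=1, **{k: v for k, v in SMALL_VIT.items()
                                            if k != "epochs"})
        state = fit(cfg, m.subset("train"))
        path = tmp_path / "model.npz"
        state.save(path)
        back = ModelState.load(path)
        assert back.config == state.config
        assert back.manifest_digest == state.manifest_digest
        assert set(back.arrays) == set(state.arrays)
        for k in state.arrays:
            assert np.array_equal(back.arrays[k], state.arrays[k])
        scores_a = predict_proba(state, m.subset("test"))
        scores_b = predict_proba(back, m.subset("test"))
        assert np.array_equal(scores_a.score.to_numpy(),
                              scores_b.score.to_numpy())


class TestViTInternals:
    def test_gradients_match_finite_differences(self):
        spec = ViTSpec(image_size=8, patch_size=4, width=8, depth=1,
                       n_heads=2, mlp_ratio=2)
        model = TinyViT(spec, seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, spec.n_tokens, spec.token_dim))
        y = np.array([0, 1, 1])
        _, grads = model.loss_and_grads(x, y)
        eps = 1e-6
        for key in ("embed_W", "pos", "b0_qkv_W", "b0_proj_W", "b0_fc1_W",
                    "b0_fc2_W", "b0_ln1_g", "b0_ln2_b", "lnf_g", "head_W"):
            p = model.params[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = model.loss_and_grads(x, y)
            p[idx] = orig - eps
            lm, _ = model.loss_and_grads(x, y)
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(numeric, rel=1e-3, abs=1e-7)

    def test_patchify_geometry_roundtrip(self, rng):
        imgs = rng.normal(size=(2, 16, 16, 3))
        tokens = patchify(imgs, 8)
        assert tokens.shape == (2, 4, 192)
        # first token is the top-left 8x8 block, channel-last flattened
        assert np.array_equal(tokens[0, 0], imgs[0, :8, :8, :].ravel())

    def test_probabilities_sum_to_one(self, rng):
        spec = ViTSpec(image_size=16, patch_size=8, width=16, depth=1, n_heads=2)
        model = TinyViT(spec, seed=3)
        toks = rng.normal(size=(5, spec.n_tokens, spec.token_dim))
        probs = model.predict_proba(toks)
        assert probs.shape == (5, 2)
        assert np.allclose(probs.sum(axis=1), 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(backend_name="resnet50_imagenet")
    with pytest.raises(ValueError):
        ClassifierConfig(input_size=8)
    with pytest.raises(ValueError):
        ClassifierConfig(epochs=0)
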