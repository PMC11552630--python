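"""Pluggable patch-classifier harness.

All backends satisfy the same contract — ``fit(config, manifest) ->
ModelState`` and ``predict_proba(state, manifest) -> ScoreTable`` — so
patient-level aggregation and evaluation run unchanged over any of
them.  Two backends ship:

``transformer_small``
    A compact Vision Transformer (NumPy, CPU, trained from scratch;
    see :mod:`cardioslide.vit`).  The reference configuration uses an
    8x8 patch embedding, 4 layers, 4 heads and width 128.
``intensity_baseline``
    A logistic model on per-channel mean/variance features — a fast,
    nearly closed-form sanity backend.

Scores are positive-class probabilities in [0, 1].  With a fixed seed,
fixed manifest and fixed config, repeated fits yield identical scores
(pure-NumPy training; the logistic solver is deterministic).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.linear_model import LogisticRegression

from .dataset import Manifest, apply_rotation
from .vit import TinyViT, ViTSpec, patchify, train_vit

BACKENDS = ("transformer_small", "intensity_baseline")

SCORE_COLUMNS = ["item_path", "patient_id", "true_label", "score"]


class TrainingError(ValueError):
    """Training preconditions violated (e.g. single-class manifest)."""


@dataclass(frozen=True)
class ClassifierConfig:
    backend_name: str = "transformer_small"
    input_size: int = 128
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    pretrained: bool = False          # reserved: load externally trained weights
    seed: int = 0
    # transformer architecture knobs (ignored by non-neural backends)
    embed_patch: int = 8
    width: int = 128
    depth: int = 4
    n_heads: int = 4

    def __post_init__(self) -> None:
        if self.backend_name not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend_name!r}; "
                             f"choose from {BACKENDS}")
        if self.input_size < 16:
            raise ValueError("input_size must be >= 16")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ClassifierConfig":
        return cls(**json.loads(s))


@dataclass
class ModelState:
    """Trained parameters + the config and data digest that produced them.

    ``arrays`` is a flat name->ndarray dict for every backend, so the
    state round-trips bit-identically through :meth:`save`/:meth:`load`.
    """

    config: ClassifierConfig
    arrays: dict[str, np.ndarray]
    manifest_digest: str

    def save(self, path: str | Path) -> None:
        header = {
            "config": dataclasses.asdict(self.config),
            "manifest_digest": self.manifest_digest,
        }
        with open(path, "wb") as fh:
            np.savez(fh, __header__=np.frombuffer(
                json.dumps(header, sort_keys=True).encode(), dtype=np.uint8),
                **self.arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(path) as z:
            header = json.loads(bytes(z["__header__"]).decode())
            arrays = {k: z[k] for k in z.files if k != "__header__"}
        return cls(
            config=ClassifierConfig(**header["config"]),
            arrays=arrays,
            manifest_digest=header["manifest_digest"],
        )


# ---------------------------------------------------------------------------
# item loading & preprocessing
# ---------------------------------------------------------------------------

def preprocess_for_model(image: np.ndarray, input_size: int) -> np.ndarray:
    """Resize to a model-ready (input_size, input_size, 3) float array.

    The longer side is resized to ``input_size`` preserving aspect
    ratio (bicubic), the result is zero-padded bottom/right to a
    square, intensities are scaled to [0, 1], and single-channel input
    is replicated to 3 channels.
    """
    raw = np.asarray(image)
    scale_in = 65535.0 if raw.dtype == np.uint16 or raw.max() > 255 else 255.0
    arr = raw.astype(np.float64)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    h, w = arr.shape[:2]
    if (h, w) != (input_size, input_size):
        if h >= w:
            nh, nw = input_size, max(1, round(w * input_size / h))
        else:
            nh, nw = max(1, round(h * input_size / w)), input_size
        arr = _sk_resize(arr, (nh, nw), order=3, preserve_range=True,
                         anti_aliasing=(nh < h or nw < w))
        out = np.zeros((input_size, input_size, 3), dtype=np.float64)
        out[:nh, :nw, :] = arr
        arr = out
    return np.clip(arr / scale_in, 0.0, 1.0)


def _load_items(manifest: Manifest, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Read, rotate and preprocess every manifest row.

    Returns (X, y) with X of shape (N, input_size, input_size, 3).
    Each underlying file is read once even when several augmentation
    tags reference it.
    """
    cache: dict[str, np.ndarray] = {}
    xs, ys = [], []
    for row in manifest.frame.itertuples(index=False):
        if row.item_path not in cache:
            cache[row.item_path] = iio.imread(row.item_path)
        img = apply_rotation(cache[row.item_path], row.augmentation_tag or "rot0")
        xs.append(preprocess_for_model(img, input_size))
        ys.append(int(row.label))
    if not xs:
        return (np.zeros((0, input_size, input_size, 3)), np.zeros(0, dtype=int))
    return np.stack(xs), np.asarray(ys, dtype=int)


def _manifest_digest(manifest: Manifest) -> str:
    buf = io.StringIO()
    manifest.frame.to_csv(buf, index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:16]


def _intensity_features(x: np.ndarray) -> np.ndarray:
    """Per-channel mean and standard deviation: (N, 6)."""
    mean = x.mean(axis=(1, 2))
    std = x.std(axis=(1, 2))
    return np.concatenate([mean, std], axis=1)


# ---------------------------------------------------------------------------
# fit / predict
# ---------------------------------------------------------------------------

def fit(config: ClassifierConfig, train_manifest: Manifest) -> ModelState:
    """Train the configured backend on the manifest's items."""
    labels = train_manifest.frame["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise TrainingError("training manifest must contain both classes")
    x, y = _load_items(train_manifest, config.input_size)
    digest = _manifest_digest(train_manifest)

    if config.backend_name == "intensity_baseline":
        feats = _intensity_features(x)
        mu, sd = feats.mean(axis=0), feats.std(axis=0) + 1e-12
        clf = LogisticRegression(C=1e3, max_iter=2000, random_state=config.seed)
        clf.fit((feats - mu) / sd, y)
        arrays = {
            "coef": clf.coef_[0], "intercept": clf.intercept_,
            "feat_mu": mu, "feat_sd": sd,
        }
        return ModelState(config, arrays, digest)

    spec = ViTSpec(
        image_size=config.input_size, patch_size=config.embed_patch,
        width=config.width, depth=config.depth, n_heads=config.n_heads,
    )
    tokens = patchify(x, spec.patch_size)
    model = train_vit(
        spec, tokens, y,
        epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate, seed=config.seed,
    )
    return ModelState(config, dict(model.params), digest)


def _scores_transformer(state: ModelState, x: np.ndarray) -> np.ndarray:
    cfg = state.config
    spec = ViTSpec(
        image_size=cfg.input_size, patch_size=cfg.embed_patch,
        width=cfg.width, depth=cfg.depth, n_heads=cfg.n_heads,
    )
    model = TinyViT(spec, seed=cfg.seed)
    model.params = {k: np.asarray(v) for k, v in state.arrays.items()}
    return model.predict_proba(patchify(x, spec.patch_size))[:, 1]


def _scores_baseline(state: ModelState, x: np.ndarray) -> np.ndarray:
    a = state.arrays
    feats = (_intensity_features(x) - a["feat_mu"]) / a["feat_sd"]
    z = feats @ a["coef"] + a["intercept"]
    return 1.0 / (1.0 + np.exp(-z))


def predict_proba(state: ModelState, items: Manifest) -> pd.DataFrame:
    """Score every manifest item; returns the ScoreTable
    (item_path, patient_id, true_label, score) with scores in [0, 1]."""
    df = items.frame
    if df.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    for p in df["item_path"]:
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest item does not exist: {p}")
    x, y = _load_items(items, state.config.input_size)
    if state.config.backend_name == "intensity_baseline":
        scores = _scores_baseline(state, x)
    else:
        scores = _scores_transformer(state, x)
    return pd.DataFrame({
        "item_path": df["item_path"].to_numpy(),
        "patient_id": df["patient_id"].to_numpy(),
        "true_label": y,
        "score": np.clip(scores, 0.0, 1.0),
    })
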