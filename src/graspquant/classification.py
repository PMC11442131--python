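"""Per-finger grasp classifiers over scalogram images.

One classifier is trained per finger, over exactly that finger's
taxonomy subset (13 grasps for the index, 12 middle, 8 ring, 8
little).  The training protocol is fixed: 30% of the images held out
for validation with per-class stratification, SGD with momentum at a
base learning rate of 0.001, mini-batch size 32, 100 epochs.

The model is a frozen image-feature extractor with a trained
neural-network head, sized so the whole pipeline trains in seconds per
finger on one CPU:

* ``pooled_mlp`` (default): 16x16 block-average pooling of the
  224x224x3 raster (588 features) feeding a one-hidden-layer
  perceptron head;
* ``random_conv``: a fixed, seeded random convolutional filter bank
  with ReLU and the same pooling, feeding the identical head — the
  frozen-backbone / replaced-head transfer-learning arrangement with a
  random instead of a pretrained feature bank.

Only the head is ever trained; the extractor is a deterministic
constant of the package.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy.signal import fftconvolve
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix, log_loss
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from graspquant.encoding import IMAGE_SIZE, ScalogramImage, encode_posture
from graspquant.segmentation import GraspPosture
from graspquant.taxonomy import check_finger, finger_grasps

BACKBONES = ("pooled_mlp", "random_conv")

_POOL = 16  # block-pool size: 224 / 16 = 14x14 cells
_N_FILTERS = 8
_FILTER_SIZE = 5
_FILTER_BANK_SEED = 12345  # architecture constant, independent of training seed


@dataclass
class TrainingReport:
    """Validation metrics of one training run."""

    final_val_accuracy: float
    final_val_loss: float
    confusion: NDArray[np.int64]
    loss_history: list[float]
    n_train: int
    n_val: int


@dataclass
class FingerClassifier:
    """Image classifier for one finger over its grasp subset."""

    finger: str
    backbone: str = "pooled_mlp"
    class_names: tuple[str, ...] = field(init=False)
    trained: bool = field(init=False, default=False)
    training_meta: dict = field(init=False, default_factory=dict)
    _scaler: StandardScaler | None = field(init=False, default=None, repr=False)
    _head: MLPClassifier | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        check_finger(self.finger)
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; expected {BACKBONES}")
        self.class_names = finger_grasps(self.finger)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    # -- frozen feature extraction ------------------------------------

    def _features(self, image: ScalogramImage) -> NDArray[np.float64]:
        pixels = np.asarray(image.pixels, dtype=np.float64) / 255.0
        if pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}x3")
        if self.backbone == "random_conv":
            maps = _filter_bank_response(pixels)
        else:
            maps = pixels
        c = IMAGE_SIZE // _POOL
        pooled = maps.reshape(c, _POOL, c, _POOL, maps.shape[2]).mean(axis=(1, 3))
        return pooled.ravel()

    def _feature_matrix(self, images: list[ScalogramImage]) -> NDArray[np.float64]:
        return np.stack([self._features(im) for im in images])

    # -- inference ----------------------------------------------------

    def predict_proba(self, image: ScalogramImage) -> NDArray[np.float64]:
        """Class probabilities in ``class_names`` order (uniform if untrained)."""
        if not self.trained:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        x = self._scaler.transform(self._features(image)[None, :])
        raw = self._head.predict_proba(x)[0]
        probs = np.zeros(self.n_classes)
        for p, cls in zip(raw, self._head.classes_):
            probs[self.class_names.index(cls)] = p
        return probs

    def predict(self, image: ScalogramImage) -> tuple[str, NDArray[np.float64]]:
        probs = self.predict_proba(image)
        return self.class_names[int(np.argmax(probs))], probs


def _filter_bank_response(pixels: NDArray[np.float64]) -> NDArray[np.float64]:
    """Fixed random conv filters + ReLU; returns (H, W, n_filters)."""
    rng = np.random.default_rng(_FILTER_BANK_SEED)
    filters = rng.standard_normal((_N_FILTERS, _FILTER_SIZE, _FILTER_SIZE, 3))
    filters -= filters.mean(axis=(1, 2, 3), keepdims=True)
    out = np.empty((pixels.shape[0], pixels.shape[1], _N_FILTERS))
    for k in range(_N_FILTERS):
        acc = np.zeros(pixels.shape[:2])
        for c in range(3):
            acc += fftconvolve(pixels[:, :, c], filters[k, :, :, c], mode="same")
        out[:, :, k] = np.maximum(acc, 0.0)
    return out


def build(finger: str, backbone: str = "pooled_mlp") -> FingerClassifier:
    """A fresh classifier for one finger; output size = its subset size."""
    return FingerClassifier(finger=finger, backbone=backbone)


def train(
    model: FingerClassifier,
    images: list[ScalogramImage],
    labels: list[str],
    val_fraction: float = 0.3,
    lr: float = 0.001,
    batch: int = 32,
    epochs: int = 100,
    seed: int = 0,
) -> TrainingReport:
    """Train the head with the fixed protocol; returns validation metrics.

    The validation split is stratified per class at ``val_fraction`` and
    seeded, so each class contributes the same holdout share and no
    image appears in both splits.  Classes need >= 2 images each.
    """
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")
    for lab in labels:
        if lab not in model.class_names:
            raise ValueError(
                f"label {lab!r} is not in the {model.finger} finger subset"
            )
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(f"classes with < 2 images: {', '.join(thin)}")

    x = model._feature_matrix(images)
    x_tr, x_va, y_tr, y_va = train_test_split(
        x, y, test_size=val_fraction, stratify=y, random_state=seed
    )

    scaler = StandardScaler().fit(x_tr)
    head = MLPClassifier(
        hidden_layer_sizes=(64,),
        activation="relu",
        solver="sgd",
        learning_rate_init=lr,
        momentum=0.9,
        batch_size=min(batch, x_tr.shape[0]),
        max_iter=epochs,
        tol=1e-9,
        n_iter_no_change=epochs,
        random_state=seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        head.fit(scaler.transform(x_tr), y_tr)

    model._scaler = scaler
    model._head = head
    model.trained = True
    model.training_meta = {
        "seed": seed,
        "epochs": epochs,
        "lr": lr,
        "batch": batch,
        "val_fraction": val_fraction,
        "backbone": model.backbone,
    }

    x_va_s = scaler.transform(x_va)
    y_hat = head.predict(x_va_s)
    proba = head.predict_proba(x_va_s)
    present = [c for c in model.class_names if c in set(y_tr)]
    report = TrainingReport(
        final_val_accuracy=float(np.mean(y_hat == y_va)),
        final_val_loss=float(log_loss(y_va, proba, labels=head.classes_)),
        confusion=confusion_matrix(y_va, y_hat, labels=list(present)),
        loss_history=[float(v) for v in head.loss_curve_],
        n_train=int(x_tr.shape[0]),
        n_val=int(x_va.shape[0]),
    )
    return report


def predict(model: FingerClassifier, image: ScalogramImage) -> tuple[str, NDArray[np.float64]]:
    """Label and probability vector for one image (inference is deterministic)."""
    if not model.trained:
        raise ValueError("model is not trained")
    return model.predict(image)


def classify_adl(
    model: FingerClassifier,
    postures: list[GraspPosture],
    encoder=encode_posture,
) -> list[GraspPosture]:
    """Encode and label segmented ADL postures, order preserved."""
    if not model.trained:
        raise ValueError("model is not trained")
    labeled = []
    for posture in postures:
        if posture.finger != model.finger:
            raise ValueError(
                f"posture finger {posture.finger!r} does not match model "
                f"finger {model.finger!r}"
            )
        label, _probs = model.predict(encoder(posture))
        labeled.append(posture.with_label(label))
    return labeled


def save_checkpoint(model: FingerClassifier, path: str | Path) -> None:
    """Persist the trained head and metadata (joblib + JSON sidecar)."""
    import joblib

    path = Path(path)
    joblib.dump({"scaler": model._scaler, "head": model._head}, path)
    meta = {
        "finger": model.finger,
        "backbone": model.backbone,
        "class_names": list(model.class_names),
        "trained": model.trained,
        "training_meta": model.training_meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> FingerClassifier:
    import joblib

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = FingerClassifier(finger=meta["finger"], backbone=meta["backbone"])
    blob = joblib.load(path)
    model._scaler = blob["scaler"]
    model._head = blob["head"]
    model.trained = meta["trained"]
    model.training_meta = meta["training_meta"]
    return model
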