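"""The two classifier families: boosted trees on object counts and a small
convolutional network on raw frames.

Both are ordinal classifiers over the pollution class schemes.  The image
model is a compact convolutional network written on numpy (im2col
convolutions, manual backpropagation, SGD with momentum) and trained with
an ordinal cross-entropy: the usual ``-log p_y`` plus a smooth log-barrier
penalty on every adjacent-class pair that violates unimodality of the
predicted probability profile around the true class.  The object-count
model is a gradient-boosted multiclass classifier (XGBoost) with early
stopping on validation accuracy.

Training-time image handling follows the campaign analysis contracts:
random border crops that always preserve the central 90% image area,
rotations uniform in [-10°, +10°], horizontal flips with probability 0.5,
and per-channel Z-score normalisation using training-set statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes_splits import SplitPlan
from .synthetic_city import RETAINED_CATEGORIES

__all__ = [
    "TrainConfig",
    "augment",
    "Normalizer",
    "ordinal_loss",
    "phi_barrier",
    "TinyConvNet",
    "CNNClassifier",
    "GBMClassifier",
    "train_cnn",
    "train_gbm",
]

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class TrainConfig:
    """Hyperparameters for either model family.

    CNN defaults follow the full-scale training recipe (batch 32, SGD,
    momentum 0.9); the learning rate and epoch count are set for the
    reduced-scale network.  ``barrier_weight`` (λ) and ``barrier_t`` (t)
    control the ordinal log-barrier penalty.
    """

    family: str = "gbm"
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    barrier_weight: float = 0.1
    barrier_t: float = 5.0
    augment: bool = True
    seed: int = 0
    input_size: int = 32  # CNN model input (frames are resized to this)
    conv_channels: tuple[int, int] = (8, 16)
    # GBM settings
    n_estimators: int = 300
    max_depth: int = 5
    gbm_learning_rate: float = 0.1
    early_stopping_patience: int = 5

    def __post_init__(self) -> None:
        if self.family not in ("gbm", "cnn"):
            raise ValueError(f"unknown model family {self.family!r}")
        if self.barrier_weight < 0 or self.barrier_t <= 0:
            raise ValueError("barrier_weight must be >= 0 and barrier_t > 0")


# ---------------------------------------------------------------------------
# Augmentation and normalisation
# ---------------------------------------------------------------------------

_CROP_KEEP_AREA = 0.90  # central area fraction always preserved


def augment(image: np.ndarray, rng: np.random.Generator, enabled: bool = True) -> np.ndarray:
    """Randomly crop / rotate / flip one square RGB image.

    Border crops are uniform but always preserve the central 90% image
    area; rotation angle is uniform in [-10°, +10°]; horizontal flip has
    probability 1/2.  The result is resized back to the input shape.
    """
    if not enabled:
        return image
    h, w = image.shape[:2]
    side_keep = np.sqrt(_CROP_KEEP_AREA)
    margin = int(h * (1.0 - side_keep) / 2.0)
    out = image
    if margin > 0:
        top = int(rng.integers(0, margin + 1))
        bottom = int(rng.integers(0, margin + 1))
        left = int(rng.integers(0, margin + 1))
        right = int(rng.integers(0, margin + 1))
        out = out[top : h - bottom, left : w - right]
    angle = float(rng.uniform(-10.0, 10.0))
    out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if out.shape[:2] != (h, w):
        out = ndimage.zoom(out, (h / out.shape[0], w / out.shape[1], 1), order=1)
    return np.ascontiguousarray(out)


@dataclass
class Normalizer:
    """Per-channel Z-score using training-set statistics (reused at test)."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    std: np.ndarray = field(default_factory=lambda: np.ones(3))

    @classmethod
    def fit(cls, images: np.ndarray, eps: float = 1e-6) -> "Normalizer":
        mean = images.mean(axis=(0, 1, 2))
        std = images.std(axis=(0, 1, 2))
        degenerate = std < eps
        if degenerate.any():
            logger.warning("near-constant channel(s) %s; guarding with epsilon", np.where(degenerate)[0])
            std = np.where(degenerate, 1.0, std)
        return cls(mean=mean, std=std)

    def transform(self, images: np.ndarray) -> np.ndarray:
        return (images - self.mean) / self.std


# ---------------------------------------------------------------------------
# Ordinal cross-entropy with log-barrier unimodality penalty
# ---------------------------------------------------------------------------


def phi_barrier(z: np.ndarray, t: float) -> np.ndarray:
    """Smooth log-barrier extension of the constraint z <= 0.

    ``phi_t(z) = -(1/t) log(-z)`` for ``z <= -1/t²`` and its convex C¹
    linear extension ``t z - (1/t) log(1/t²) + 1/t`` otherwise.  Finite and
    differentiable everywhere, -> 0 for strictly satisfied constraints as
    t grows.
    """
    z = np.asarray(z, dtype=float)
    thresh = -1.0 / t**2
    inner = np.where(z <= thresh, z, thresh)  # avoid log of nonneg in masked branch
    return np.where(
        z <= thresh,
        -np.log(-inner) / t,
        t * z - np.log(1.0 / t**2) / t + 1.0 / t,
    )


def _phi_prime(z: np.ndarray, t: float) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    thresh = -1.0 / t**2
    inner = np.where(z <= thresh, z, thresh)
    return np.where(z <= thresh, -1.0 / (t * inner), t)


def _constraint_gaps(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """z_k for the K-1 adjacent-pair unimodality constraints, batched.

    For k < y the profile must rise (p_k <= p_{k+1}, i.e. z = p_k - p_{k+1});
    for k >= y it must fall (p_k >= p_{k+1}, z = p_{k+1} - p_k).  All
    z_k <= 0 iff the profile is unimodal with peak at y.
    """
    K = p.shape[1]
    ks = np.arange(K - 1)[None, :]
    rising = ks < np.asarray(y)[:, None]
    diff = p[:, :-1] - p[:, 1:]
    return np.where(rising, diff, -diff)


def ordinal_loss(
    probabilities: np.ndarray,
    y: int | np.ndarray,
    barrier_weight: float = 0.1,
    barrier_t: float = 5.0,
) -> float:
    """Ordinal cross-entropy: -log p_y + λ Σ_k φ_t(z_k).

    With λ=0 this is exactly cross-entropy.  The barrier terms penalise
    any departure of the predicted class-probability profile from a
    unimodal shape peaking at the true class, so the loss uses the class
    ordering rather than treating classes as exchangeable.
    """
    p = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y_arr = np.atleast_1d(np.asarray(y, dtype=int))
    if np.any((p < -1e-9) | (p > 1 + 1e-9)) or np.any(np.abs(p.sum(axis=1) - 1) > 1e-6):
        raise ValueError("probabilities must lie on the simplex")
    if np.any((y_arr < 0) | (y_arr >= p.shape[1])):
        raise ValueError("true class out of range")
    py = p[np.arange(len(y_arr)), y_arr]
    if np.any(py <= 0):
        logger.warning("zero probability at true class; clamping")
        py = np.maximum(py, EPS)
    ce = -np.log(py)
    if barrier_weight > 0:
        z = _constraint_gaps(p, y_arr)
        ce = ce + barrier_weight * phi_barrier(z, barrier_t).sum(axis=1)
    return float(ce.mean())


def _loss_grad_logits(
    logits: np.ndarray, y: np.ndarray, barrier_weight: float, barrier_t: float
) -> tuple[float, np.ndarray]:
    """Mean ordinal loss and its gradient w.r.t. logits (softmax input)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, K = p.shape
    idx = np.arange(n)
    py = np.maximum(p[idx, y], EPS)
    loss = -np.log(py)

    g = np.zeros_like(p)  # dL/dp
    g[idx, y] -= 1.0 / py
    if barrier_weight > 0:
        gaps = _constraint_gaps(p, y)
        loss = loss + barrier_weight * phi_barrier(gaps, barrier_t).sum(axis=1)
        dphi = _phi_prime(gaps, barrier_t)
        ks = np.arange(K - 1)[None, :]
        sign = np.where(ks < y[:, None], 1.0, -1.0)  # dz/dp_k
        g[:, :-1] += barrier_weight * dphi * sign
        g[:, 1:] -= barrier_weight * dphi * sign
    # chain through softmax
    dot = (g * p).sum(axis=1, keepdims=True)
    dlogits = p * (g - dot) / n
    return float(loss.mean()), dlogits


# ---------------------------------------------------------------------------
# Tiny convolutional network (numpy, manual backprop)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, oh*ow, C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, oh, ow, k, k)
    n, c, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k), oh, ow


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = cols.reshape(n, oh, ow, c, k, k)
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di : di + oh * stride : stride, dj : dj + ow * stride : stride] += (
                cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            )
    return xp[:, :, pad : pad + h, pad : pad + w]


class TinyConvNet:
    """Two conv blocks (stride-2) + a dense softmax head.

    Input ``(N, H, W, 3)`` with H = W = ``input_size``; He-initialised,
    fully deterministic given the construction RNG.
    """

    def __init__(
        self,
        n_classes: int,
        input_size: int = 32,
        channels: tuple[int, int] = (8, 16),
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        c1, c2 = channels
        self.spec = dict(n_classes=n_classes, input_size=input_size, channels=channels)
        self.k1, self.s1, self.p1 = 5, 2, 2
        self.k2, self.s2, self.p2 = 3, 2, 1
        o1 = input_size // 2
        o2 = o1 // 2
        self.shapes = (o1, o2)
        feat = c2 * o2 * o2
        def he(fan_in, *shape):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W1": he(3 * self.k1**2, c1, 3 * self.k1**2),
            "b1": np.zeros(c1),
            "W2": he(c1 * self.k2**2, c2, c1 * self.k2**2),
            "b2": np.zeros(c2),
            "W3": he(feat, n_classes, feat),
            "b3": np.zeros(n_classes),
        }

    def forward(self, x: np.ndarray, cache: bool = False):
        """x: (N, H, W, 3) normalised images -> logits (N, K)."""
        n = x.shape[0]
        c1 = self.params["W1"].shape[0]
        c2 = self.params["W2"].shape[0]
        o1, o2 = self.shapes
        xc = x.transpose(0, 3, 1, 2)  # NCHW
        cols1, _, _ = _im2col(xc, self.k1, self.s1, self.p1)
        z1 = cols1 @ self.params["W1"].T + self.params["b1"]
        a1 = np.maximum(z1, 0.0)
        a1_img = a1.reshape(n, o1, o1, c1).transpose(0, 3, 1, 2)
        cols2, _, _ = _im2col(a1_img, self.k2, self.s2, self.p2)
        z2 = cols2 @ self.params["W2"].T + self.params["b2"]
        a2 = np.maximum(z2, 0.0)
        h = a2.reshape(n, -1)
        logits = h @ self.params["W3"].T + self.params["b3"]
        if cache:
            self._cache = (xc, cols1, z1, a1_img, cols2, z2, h)
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        xc, cols1, z1, a1_img, cols2, z2, h = self._cache
        n = xc.shape[0]
        c1 = self.params["W1"].shape[0]
        o1, o2 = self.shapes
        grads = {}
        grads["W3"] = dlogits.T @ h
        grads["b3"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["W3"]
        da2 = dh.reshape(z2.shape)
        dz2 = da2 * (z2 > 0)
        grads["W2"] = np.tensordot(dz2, cols2, axes=([0, 1], [0, 1]))
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = dz2 @ self.params["W2"]
        da1 = _col2im(dcols2, a1_img.shape, self.k2, self.s2, self.p2)
        dz1 = da1.transpose(0, 2, 3, 1).reshape(z1.shape) * (z1 > 0)
        grads["W1"] = np.tensordot(dz1, cols1, axes=([0, 1], [0, 1]))
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _resize_images(images: np.ndarray, size: int) -> np.ndarray:
    if images.shape[1] == size:
        return images
    zoom = size / images.shape[1]
    return ndimage.zoom(images, (1, zoom, zoom, 1), order=1)


@dataclass
class CNNClassifier:
    """Trained image classifier: network + frozen normalisation statistics."""

    net: TinyConvNet
    normalizer: Normalizer
    config: TrainConfig
    n_classes: int
    history: list = field(default_factory=list)  # per-epoch (train_loss, val_acc)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        x = _resize_images(np.asarray(images, dtype=float), self.config.input_size)
        x = self.normalizer.transform(x)
        out = []
        for i in range(0, len(x), 256):
            out.append(_softmax(self.net.forward(x[i : i + 256])))
        return np.vstack(out) if out else np.zeros((0, self.n_classes))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images).argmax(axis=1)


def train_cnn(
    images: Mapping[str, np.ndarray] | np.ndarray,
    labels: pd.Series | Mapping[str, int],
    plan: SplitPlan,
    config: TrainConfig,
) -> CNNClassifier:
    """Train the small convolutional ordinal classifier on a split plan.

    ``images`` maps record id -> (H, W, 3) float frame (or is an array
    aligned with ``labels.index``).  Augmentation is applied per batch,
    normalisation uses training-set channel statistics, optimisation is
    SGD with momentum on the ordinal loss, and the returned model is the
    epoch snapshot with the best validation exact accuracy.
    """
    labels = pd.Series(labels)
    if not isinstance(images, Mapping):
        images = {rid: images[i] for i, rid in enumerate(labels.index)}
    n_classes = int(labels.max()) + 1

    def stack(ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([images[r] for r in ids]).astype(float)
        y = labels.loc[list(ids)].to_numpy(int)
        return X, y

    X_train, y_train = stack(plan.train_ids)
    X_val, y_val = stack(plan.val_ids) if plan.val_ids else (X_train[:0], y_train[:0])
    X_train = _resize_images(X_train, config.input_size)
    X_val = _resize_images(X_val, config.input_size)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    normalizer = Normalizer.fit(X_train)
    Xn_val = normalizer.transform(X_val)

    net = TinyConvNet(n_classes, config.input_size, config.conv_channels, rng)
    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    best = (net.copy_params(), -np.inf)
    history = []
    n = len(X_train)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            take = perm[start : start + config.batch_size]
            batch = X_train[take]
            if config.augment:
                batch = np.stack([augment(im, rng) for im in batch])
            batch = normalizer.transform(batch)
            yb = y_train[take]
            logits = net.forward(batch, cache=True)
            loss, dlogits = _loss_grad_logits(
                logits, yb, config.barrier_weight, config.barrier_t
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}: logit range "
                    f"[{logits.min():.3g}, {logits.max():.3g}]"
                )
            grads = net.backward(dlogits)
            for k in net.params:
                velocity[k] = config.momentum * velocity[k] - config.learning_rate * grads[k]
                net.params[k] += velocity[k]
            epoch_loss += loss * len(take)
        epoch_loss /= n
        if len(X_val):
            val_logits = net.forward(Xn_val)
            val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        else:
            val_acc = -epoch_loss
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_accuracy": val_acc})
        if val_acc > best[1]:
            best = (net.copy_params(), val_acc)
    net.params = best[0]
    return CNNClassifier(
        net=net, normalizer=normalizer, config=config, n_classes=n_classes, history=history
    )


# ---------------------------------------------------------------------------
# Gradient-boosted object-count classifier
# ---------------------------------------------------------------------------


@dataclass
class GBMClassifier:
    """Boosted-tree ordinal classifier over object-count feature vectors."""

    booster: object
    feature_names: list[str]
    classes_: np.ndarray  # original class indices present in training
    n_classes: int
    config: TrainConfig

    def _matrix(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            return features[self.feature_names].to_numpy(float)
        return np.asarray(features, float)

    def predict_proba(self, features) -> np.ndarray:
        raw = self.booster.predict_proba(self._matrix(features))
        if raw.ndim == 1:
            raw = np.stack([1 - raw, raw], axis=1)
        out = np.zeros((len(raw), self.n_classes))
        out[:, self.classes_] = raw
        return out

    def predict(self, features) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=1)


def train_gbm(
    features: pd.DataFrame,
    labels: pd.Series,
    plan: SplitPlan,
    config: TrainConfig,
    n_classes: int | None = None,
) -> GBMClassifier:
    """Train the boosted-tree classifier on a split plan.

    ``features`` is indexed by record id with one column per retained
    object category; ``labels`` holds the binned class indices.  Boosting
    stops early once ``early_stopping_patience`` rounds bring no
    improvement on the validation set.  Deterministic given the seed
    (single-threaded).
    """
    from xgboost import XGBClassifier

    feature_names = [c for c in RETAINED_CATEGORIES if c in features.columns] or list(
        features.columns
    )
    X_train = features.loc[plan.train_ids, feature_names].to_numpy(float)
    y_train_orig = labels.loc[plan.train_ids].to_numpy(int)
    classes = np.unique(y_train_orig)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class; nothing to learn")
    remap = {c: i for i, c in enumerate(classes)}
    y_train = np.array([remap[c] for c in y_train_orig])

    k = n_classes if n_classes is not None else int(labels.max()) + 1
    model = XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.gbm_learning_rate,
        objective="multi:softprob",
        eval_metric="merror",
        early_stopping_rounds=config.early_stopping_patience if plan.val_ids else None,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    if plan.val_ids:
        X_val = features.loc[plan.val_ids, feature_names].to_numpy(float)
        y_val = np.array(
            [remap.get(c, -1) for c in labels.loc[plan.val_ids].to_numpy(int)]
        )
        keep = y_val >= 0  # validation rows in unseen classes can't score
        model.fit(X_train, y_train, eval_set=[(X_val[keep], y_val[keep])], verbose=False)
    else:
        model.fit(X_train, y_train)
    return GBMClassifier(
        booster=model, feature_names=feature_names, classes_=classes,
        n_classes=k, config=config,
    )
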