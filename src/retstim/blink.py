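"""Eyes-open / eyes-closed image classification and blink events.

A small convolutional network (NumPy implementation, no deep-learning
framework required): three 3x3 conv layers with 16, 32 and 64 filters,
each followed by batch normalization and ReLU, 2x2 max-pooling after
the first two layers (36 -> 18 -> 9), then a fully connected 2-way
softmax.  Trained with plain stochastic gradient descent (batch 128)
on 36x36 grayscale eye images with rotation (-45..45 deg), +-1 px
translation and horizontal-mirror augmentation.

Frame labels are converted to blink events by finding maximal runs of
closed frames; blink duration is run length x frame duration and blink
frequency is counted in 15-s windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "BlinkClassifierSpec",
    "BlinkEvent",
    "BlinkCNN",
    "train_blink_classifier",
    "classify_eye_frames",
    "blinks_from_labels",
    "save_model",
    "load_model",
]

IMG = 36  # network input side length


@dataclass(frozen=True)
class BlinkClassifierSpec:
    """Architecture + training recipe.

    ``epochs`` defaults to a desk-scale 50; the full-scale recipe used
    500 (set it via config if you have the time).  Learning rate 0.01
    with no schedule.
    """

    conv_filters: tuple = (16, 32, 64)
    kernel: int = 3
    batch_size: int = 128
    epochs: int = 50
    learning_rate: float = 0.01
    momentum: float = 0.9
    augment_rotation_deg: tuple = (-45.0, 45.0)
    augment_translate_px: int = 1
    augment_mirror: bool = True


@dataclass
class BlinkEvent:
    start_s: float
    duration_s: float
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("blink duration must be positive")


# ---------------------------------------------------------------------------
# Minimal CNN layers (NCHW, float64 inputs downcast to float32)


def _conv_forward(x, w, b):
    # x: (n, c, h, w); w: (f, c, k, k) with same padding
    k = w.shape[-1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    h, wd = x.shape[2], x.shape[3]
    patches = np.stack(
        [xp[:, :, i : i + h, j : j + wd] for i in range(k) for j in range(k)], axis=2
    )  # (n, c, k*k, h, w)
    y = np.einsum("nckhw,fck->nfhw", patches, w.reshape(w.shape[0], w.shape[1], k * k))
    return y + b[None, :, None, None], patches


def _conv_backward(dy, patches, w):
    f, c, k, _ = w.shape
    dw = np.einsum("nfhw,nckhw->fck", dy, patches).reshape(f, c, k, k)
    db = dy.sum(axis=(0, 2, 3))
    dcols = np.einsum("nfhw,fck->nckhw", dy, w.reshape(f, c, k * k))
    n, _, _, h, wd = dcols.shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=dy.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, idx]
            idx += 1
    return dxp[:, :, p : p + h, p : p + wd], dw, db


def _bn_forward(x, gamma, beta, running, momentum=0.1, train=True, eps=1e-5):
    axes = (0, 2, 3)
    if train:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    std = np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
    y = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return y, (xhat, std)


def _bn_backward(dy, cache, gamma):
    xhat, std = cache
    axes = (0, 2, 3)
    m = dy.shape[0] * dy.shape[2] * dy.shape[3]
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    dxhat = dy * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=axes)[None, :, None, None]
        - xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None] / m
    ) / std[None, :, None, None]
    return dx, dgamma, dbeta


def _pool_forward(x):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return y, arg


def _pool_backward(dy, arg, shape):
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(n, c, h, w)


class BlinkCNN:
    """Three-conv-layer open/closed classifier with softmax output."""

    def __init__(self, spec: BlinkClassifierSpec | None = None, seed: int = 0):
        self.spec = spec or BlinkClassifierSpec()
        rng = np.random.default_rng(seed)
        f1, f2, f3 = self.spec.conv_filters
        k = self.spec.kernel
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, dict] = {}

        def conv_init(name, fo, fi):
            scale = np.sqrt(2.0 / (fi * k * k))
            self.params[f"w{name}"] = rng.normal(0, scale, (fo, fi, k, k)).astype(np.float32)
            self.params[f"b{name}"] = np.zeros(fo, np.float32)
            self.params[f"g{name}"] = np.ones(fo, np.float32)
            self.params[f"be{name}"] = np.zeros(fo, np.float32)
            self.running[name] = {"mean": np.zeros(fo, np.float32), "var": np.ones(fo, np.float32)}

        conv_init("1", f1, 1)
        conv_init("2", f2, f1)
        conv_init("3", f3, f2)
        flat = f3 * (IMG // 4) * (IMG // 4)
        self.params["wfc"] = rng.normal(0, np.sqrt(2.0 / flat), (flat, 2)).astype(np.float32)
        self.params["bfc"] = np.zeros(2, np.float32)
        self._velocity = {k_: np.zeros_like(v) for k_, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False, bn_momentum: float = 0.1):
        p = self.params
        cache: dict = {}
        h = x[:, None, :, :].astype(np.float32) / np.float32(255.0)
        for layer, pool in (("1", True), ("2", True), ("3", False)):
            z, patches = _conv_forward(h, p[f"w{layer}"], p[f"b{layer}"])
            zn, bn_cache = _bn_forward(
                z, p[f"g{layer}"], p[f"be{layer}"], self.running[layer],
                momentum=bn_momentum, train=train,
            )
            a = np.maximum(zn, 0.0)
            cache[layer] = {"patches": patches, "bn": bn_cache, "pre": zn, "in_shape": z.shape}
            if pool:
                a, arg = _pool_forward(a)
                cache[layer]["pool_arg"] = arg
                cache[layer]["pool_shape"] = cache[layer]["in_shape"]
            h = a
        cache["flat_shape"] = h.shape
        flat = h.reshape(h.shape[0], -1)
        logits = flat @ p["wfc"] + p["bfc"]
        cache["flat"] = flat
        logits -= logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(x, train=False)
        return probs

    def calibrate_bn(self, x: np.ndarray) -> None:
        """Set batch-norm running statistics from one pass over ``x``
        (needed because few SGD steps leave the exponential running
        averages far from the dataset statistics)."""
        self.forward(x, train=True, bn_momentum=1.0)

    def _backward(self, probs, labels, cache):
        p = self.params
        grads: dict[str, np.ndarray] = {}
        n = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads["wfc"] = cache["flat"].T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        dh = (dlogits @ p["wfc"].T).reshape(cache["flat_shape"])
        for layer, pool in (("3", False), ("2", True), ("1", True)):
            c = cache[layer]
            if pool:
                dh = _pool_backward(dh, c["pool_arg"], c["pool_shape"])
            dh = dh * (c["pre"] > 0)
            dh, grads[f"g{layer}"], grads[f"be{layer}"] = _bn_backward(
                dh, c["bn"], p[f"g{layer}"]
            )
            dh, grads[f"w{layer}"], grads[f"b{layer}"] = _conv_backward(
                dh, c["patches"], p[f"w{layer}"]
            )
        return grads

    def train_step(self, x, labels) -> float:
        probs, cache = self.forward(x, train=True)
        n = len(labels)
        loss = float(-np.log(probs[np.arange(n), labels] + 1e-12).mean())
        grads = self._backward(probs, labels, cache)
        lr, mom = self.spec.learning_rate, self.spec.momentum
        for name, g in grads.items():
            v = self._velocity[name]
            v *= mom
            v -= lr * g
            self.params[name] += v
        return loss

    def state_dict(self) -> dict:
        state = {f"param_{k}": v for k, v in self.params.items()}
        for layer, run in self.running.items():
            state[f"run_{layer}_mean"] = run["mean"]
            state[f"run_{layer}_var"] = run["var"]
        return state

    def load_state_dict(self, state: dict) -> None:
        for key, val in state.items():
            if key.startswith("param_"):
                self.params[key[6:]] = np.array(val)
            elif key.startswith("run_"):
                _, layer, which = key.split("_")
                self.running[layer][which] = np.array(val)


def _resize_to_input(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != (IMG, IMG):
        zoom = (1, IMG / images.shape[1], IMG / images.shape[2])
        images = ndimage.zoom(images.astype(float), zoom, order=1)
    return images.astype(np.float64)


def _augment_batch(batch: np.ndarray, spec: BlinkClassifierSpec, rng) -> np.ndarray:
    lo, hi = spec.augment_rotation_deg
    out = np.empty_like(batch)
    for i, img in enumerate(batch):
        a = img
        if spec.augment_mirror and rng.random() < 0.5:
            a = a[:, ::-1]
        angle = rng.uniform(lo, hi)
        a = ndimage.rotate(a, angle, reshape=False, order=1, mode="nearest")
        tp = spec.augment_translate_px
        dy, dx = rng.integers(-tp, tp + 1, size=2)
        a = np.roll(np.roll(a, dy, axis=0), dx, axis=1)
        out[i] = a
    return out


def train_blink_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    spec: BlinkClassifierSpec | None = None,
    seed: int = 0,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> tuple[BlinkCNN, dict]:
    """Train the open/closed classifier; returns the best-validation
    epoch's parameters plus a per-epoch training report.

    Labels: 0 = open, 1 = closed.  Raises on a single-class training set.
    """
    spec = spec or BlinkClassifierSpec()
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both classes")
    x = _resize_to_input(images)
    if val_images is not None:
        xv = _resize_to_input(val_images)
        yv = np.asarray(val_labels, dtype=int)
    else:
        xv, yv = x, labels

    rng = np.random.default_rng(seed)
    model = BlinkCNN(spec, seed=seed)
    report = {"epochs": [], "spec": asdict(spec)}
    best_acc, best_state = -1.0, None
    n = len(x)
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            sel = order[start : start + spec.batch_size]
            batch = _augment_batch(x[sel], spec, rng)
            losses.append(model.train_step(batch, labels[sel]))
        model.calibrate_bn(x[: min(n, 512)])
        preds = classify_eye_frames(model, xv)[0]
        acc = float((preds == yv).mean())
        report["epochs"].append({"epoch": epoch, "loss": float(np.mean(losses)), "val_acc": acc})
        if acc > best_acc:
            best_acc = acc
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    report["best_val_acc"] = best_acc
    return model, report


def classify_eye_frames(
    model: BlinkCNN, eye_frames: np.ndarray, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame labels (0 open / 1 closed) and class probabilities.

    Frames of a different size are resized (bilinear) to 36x36.
    Inference is deterministic.
    """
    x = _resize_to_input(eye_frames)
    probs = np.vstack(
        [model.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )
    return probs.argmax(axis=1), probs


def blinks_from_labels(
    labels: np.ndarray,
    rate_hz: float = 50.0,
    t0: float = 0.0,
    window_s: float = 15.0,
) -> tuple[list[BlinkEvent], dict]:
    """Blink events and rate series from a closed/open label stream.

    A blink is a maximal run of closed (1) labels; duration is the run
    length times the frame period (20 ms at 50 Hz).  The rate series
    counts blinks per ``window_s`` window; a per-minute conversion is
    included (ambiguous unit in some reports — both are emitted).
    """
    labels = np.asarray(labels, dtype=int)
    dt = 1.0 / rate_hz
    events: list[BlinkEvent] = []
    padded = np.concatenate([[0], labels, [0]])
    starts = np.nonzero(np.diff(padded) == 1)[0]
    ends = np.nonzero(np.diff(padded) == -1)[0]
    for s, e in zip(starts, ends):
        events.append(
            BlinkEvent(
                start_s=t0 + s * dt,
                duration_s=(e - s) * dt,
                frame_indices=np.arange(s, e),
            )
        )
    total_s = labels.size * dt
    edges = np.arange(0.0, total_s + window_s, window_s)
    onsets = np.array([ev.start_s - t0 for ev in events])
    counts = np.histogram(onsets, bins=edges)[0] if events else np.zeros(edges.size - 1, int)
    rate = {
        "window_start_s": edges[:-1] + t0,
        "count_per_window": counts,
        "per_minute": counts * (60.0 / window_s),
        "window_s": window_s,
    }
    return events, rate


def save_model(model: BlinkCNN, path: str) -> None:
    """Serialize parameters + running stats to one portable .npz file."""
    np.savez(path, **model.state_dict())


def load_model(path: str, spec: BlinkClassifierSpec | None = None) -> BlinkCNN:
    model = BlinkCNN(spec)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
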