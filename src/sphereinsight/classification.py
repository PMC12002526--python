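"""Cross-validated CNN classification of rendered image stacks.

The default classifier is a compact convolutional network written directly on
numpy — two 3x3 conv blocks with ReLU and max pooling, global average pooling,
and a linear head — trained with AdamW on binary cross-entropy. At desk-scale
grids (32x32, hundreds of samples) this trains in seconds per fold on one CPU.
A `resnet50` architecture name is reserved for the 224x224 full-scale mode and
requires a deep-learning framework; requesting it raises.

Hyperparameter search follows the log-uniform contract: learning rate sampled
on [1e-6, 1e-2] and weight decay on (1e-6, 1e-2), uniform in log10, so every
order of magnitude is sampled evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

from .exceptions import ValidationError
from .insight_imaging import (
    feature_layout,
    min_area_rectangle,
    normalize_values,
    pixel_assignment,
    render_images,
)
from .tabular_io import LabelVector

LR_RANGE = (1e-6, 1e-2)
WD_RANGE = (1e-6, 1e-2)


@dataclass
class TrainConfig:
    architecture: str = "small_cnn"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("small_cnn", "resnet50"):
            raise ValidationError(f"unknown architecture {self.architecture!r}")
        if not LR_RANGE[0] <= self.learning_rate <= LR_RANGE[1]:
            raise ValidationError(f"learning_rate outside {LR_RANGE}")
        if not WD_RANGE[0] < self.weight_decay < WD_RANGE[1]:
            raise ValidationError(f"weight_decay outside open interval {WD_RANGE}")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")


@dataclass
class ImagingConfig:
    """How tangent-space features become images inside each CV fold."""

    method: str = "pca"
    grid_h: int = 32
    grid_w: int = 32
    epsilon: float = 1 / 255
    segment: bool = True
    normalization: str = "independent"   # or topology_preserving / select_by_validation
    aggregate: str = "mean"
    layout_seed: int = 0


@dataclass
class CVReport:
    fold_aucs: list[float]
    mean_auc: float
    configs_evaluated: int
    best_config: TrainConfig
    scheme_per_fold: list[str] = field(default_factory=list)
    seed: int = 0


def stratified_folds(
    labels: LabelVector | np.ndarray, k: int, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint stratified test-fold index sets; deterministic per seed."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    if k < 2:
        raise ValidationError("need at least 2 folds")
    minority = min(int((y == 0).sum()), int((y == 1).sum()))
    if k > minority:
        raise ValidationError(
            f"k={k} exceeds minority class count {minority}"
        )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(random positive outranks random negative), ties 1/2.

    Implemented via midranks, which is algebraically the pair-counting sum
    with tied pairs contributing one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# numpy CNN
# ---------------------------------------------------------------------------


def _conv2d(x, W, cache_windows=False):
    """Same-size 3x3 convolution, stride 1, zero padding 1.

    x: (N, C, H, W); W: (F, C, 3, 3) -> (N, F, H, W).
    """
    n, c, h, w = x.shape
    f = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))       # N,C,H,W,3,3
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * 9)
    out = cols @ W.reshape(f, c * 9).T                        # N,H,W,F
    out = out.transpose(0, 3, 1, 2)
    return (out, cols) if cache_windows else (out, None)


def _conv2d_backward(dout, cols, x_shape, W):
    n, c, h, w = x_shape
    f = W.shape[0]
    dcols = dout.transpose(0, 2, 3, 1).reshape(n, h, w, f)
    dW = np.tensordot(dcols, cols, axes=([0, 1, 2], [0, 1, 2]))  # F, C*9
    dW = dW.reshape(f, c, 3, 3)
    db = dout.sum(axis=(0, 2, 3))
    # gradient wrt input = full correlation with the flipped, transposed kernel
    Wflip = W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)            # C, F, 3, 3
    dx, _ = _conv2d(dout, Wflip)
    return dx, dW, db


def _maxpool2(x):
    n, c, h, w = x.shape
    xr = x[:, :, : h - h % 2, : w - w % 2].reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    return out, xr


def _maxpool2_backward(dout, xr, x_shape):
    n, c, h, w = x_shape
    mask = xr == xr.max(axis=(3, 5), keepdims=True)
    counts = mask.sum(axis=(3, 5), keepdims=True)
    dxr = mask * dout[:, :, :, None, :, None] / counts
    dx = np.zeros(x_shape)
    dx[:, :, : h - h % 2, : w - w % 2] = dxr.reshape(n, c, h - h % 2, w - w % 2)
    return dx


class SmallCNN:
    """Two conv blocks + global average pooling + linear head, BCE loss."""

    def __init__(self, c1: int = 8, c2: int = 16, seed: int = 0):
        rng = np.random.default_rng(seed)
        he = lambda fan_in, shape: rng.normal(0, np.sqrt(2.0 / fan_in), shape)
        self.params = {
            "W1": he(9, (c1, 1, 3, 3)),
            "b1": np.zeros(c1),
            "W2": he(9 * c1, (c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "Wf": he(c2, (c2,)),
            "bf": np.zeros(1),
        }

    def forward(self, x, train=False):
        p = self.params
        z1, cols1 = _conv2d(x, p["W1"], cache_windows=train)
        z1 += p["b1"][None, :, None, None]
        a1 = np.maximum(z1, 0)
        p1, xr1 = _maxpool2(a1)
        z2, cols2 = _conv2d(p1, p["W2"], cache_windows=train)
        z2 += p["b2"][None, :, None, None]
        a2 = np.maximum(z2, 0)
        g = a2.mean(axis=(2, 3))
        logits = g @ p["Wf"] + p["bf"][0]
        if train:
            self._cache = (x, cols1, z1, a1, p1, xr1, cols2, z2, a2, g)
        return logits

    def backward(self, dlogits):
        p = self.params
        x, cols1, z1, a1, p1, xr1, cols2, z2, a2, g = self._cache
        n, c2, hh, ww = a2.shape
        grads = {}
        grads["Wf"] = dlogits @ g
        grads["bf"] = np.array([dlogits.sum()])
        dg = np.outer(dlogits, p["Wf"])
        da2 = np.broadcast_to(dg[:, :, None, None], a2.shape) / (hh * ww)
        dz2 = da2 * (z2 > 0)
        dp1, grads["W2"], grads["b2"] = _conv2d_backward(dz2, cols2, p1.shape, p["W2"])
        da1 = _maxpool2_backward(dp1, xr1, a1.shape)
        dz1 = da1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = _conv2d_backward(dz1, cols1, x.shape, p["W1"])
        return grads


class AdamW:
    def __init__(self, params, lr, weight_decay, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * params[k])


def train_small_cnn(
    images: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> SmallCNN:
    """Fit the numpy CNN with AdamW on BCE-with-logits; deterministic per seed."""
    if config.architecture == "resnet50":
        raise NotImplementedError(
            "resnet50 at 224x224 requires a deep-learning framework; "
            "use architecture='small_cnn'"
        )
    y = np.asarray(labels, dtype=float)
    x = np.asarray(images, dtype=float)[:, None, :, :]
    model = SmallCNN(seed=config.seed)
    opt = AdamW(model.params, config.learning_rate, config.weight_decay)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(x[idx], train=True)
            prob = 1.0 / (1.0 + np.exp(-logits))
            dlogits = (prob - y[idx]) / idx.size
            grads = model.backward(dlogits)
            opt.step(model.params, grads)
    return model


def predict_scores(model: SmallCNN, images: np.ndarray) -> np.ndarray:
    logits = model.forward(np.asarray(images, dtype=float)[:, None, :, :])
    return 1.0 / (1.0 + np.exp(-logits))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _render_fold(features, train_idx, imaging: ImagingConfig, scheme: str):
    """Layout + normalization fitted on the training rows only."""
    layout = feature_layout(
        features[train_idx],
        method=imaging.method,
        seed=imaging.layout_seed,
        fitted_on="train_fold",
    )
    angle, _ = min_area_rectangle(layout.coords2d)
    pmap = pixel_assignment(layout, angle, imaging.grid_h, imaging.grid_w)
    norm = normalize_values(features, scheme, train_index=train_idx)
    stack = render_images(
        norm, pmap, epsilon=imaging.epsilon, segment=imaging.segment,
        aggregate=imaging.aggregate,
    )
    stack.normalization_scheme = scheme
    return stack


def _select_scheme(features, train_idx, y, imaging, train_config, seed):
    """Pick the normalization scheme with the lowest inner-validation error."""
    from sklearn.model_selection import train_test_split

    inner_tr, inner_val = train_test_split(
        np.arange(train_idx.size), test_size=0.25, random_state=seed,
        stratify=y[train_idx],
    )
    best = None
    quick = replace(train_config, epochs=max(1, train_config.epochs // 3))
    for scheme in ("independent", "topology_preserving"):
        stack = _render_fold(features, train_idx[inner_tr], imaging, scheme)
        model = train_small_cnn(
            stack.images[train_idx[inner_tr]], y[train_idx[inner_tr]], quick
        )
        scores = predict_scores(model, stack.images[train_idx[inner_val]])
        err = float(np.mean((scores > 0.5).astype(int) != y[train_idx[inner_val]]))
        if best is None or err < best[0]:
            best = (err, scheme)
    return best[1]


def cross_validate(
    features: np.ndarray,
    labels: LabelVector | np.ndarray,
    imaging: ImagingConfig,
    train_config: TrainConfig,
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold CV; layout and normalization refit per training fold.

    Test images are rendered with the training fold's layout and statistics,
    so nothing about held-out samples leaks into the fitted transforms.
    """
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    folds = stratified_folds(y, k, seed=seed)
    all_idx = np.arange(y.size)
    fold_aucs: list[float] = []
    schemes: list[str] = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        if len(np.unique(y[train_idx])) < 2:
            raise ValidationError(f"fold {fold_no} has a single-class training set")
        scheme = imaging.normalization
        if scheme == "select_by_validation":
            scheme = _select_scheme(
                features, train_idx, y, imaging, train_config, seed + fold_no
            )
        stack = _render_fold(features, train_idx, imaging, scheme)
        fold_cfg = replace(train_config, seed=train_config.seed + fold_no)
        model = train_small_cnn(stack.images[train_idx], y[train_idx], fold_cfg)
        scores = predict_scores(model, stack.images[test_idx])
        fold_aucs.append(compute_auc(scores, y[test_idx]))
        schemes.append(scheme)
    return CVReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        configs_evaluated=1,
        best_config=train_config,
        scheme_per_fold=schemes,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


def sample_log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(np.log10(lo), np.log10(hi)))


def random_search(
    objective: Callable[[TrainConfig], float],
    lr_range: tuple[float, float] = LR_RANGE,
    wd_range: tuple[float, float] = WD_RANGE,
    n_trials: int = 20,
    seed: int = 0,
    base_config: Optional[TrainConfig] = None,
) -> tuple[TrainConfig, list[dict]]:
    """Log-uniform random search over learning rate and weight decay.

    Each trial draws both hyperparameters uniformly in log10, evaluates the
    objective (higher is better; non-finite marks the trial failed), and the
    argmax config is returned together with the full trial log. Deterministic
    per seed.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if lr_range[0] <= 0 or wd_range[0] <= 0:
        raise ValidationError("ranges must be positive")
    rng = np.random.default_rng(seed)
    base = base_config or TrainConfig()
    trials: list[dict] = []
    best: Optional[tuple[float, TrainConfig]] = None
    for t in range(n_trials):
        cfg = replace(
            base,
            learning_rate=sample_log_uniform(rng, *lr_range),
            weight_decay=sample_log_uniform(rng, *wd_range),
        )
        try:
            value = float(objective(cfg))
        except Exception as exc:  # objective crash = failed trial
            trials.append({"trial": t, "config": cfg, "value": None,
                           "failed": True, "error": str(exc)})
            continue
        failed = not np.isfinite(value)
        trials.append({"trial": t, "config": cfg,
                       "value": None if failed else value, "failed": failed})
        if not failed and (best is None or value > best[0]):
            best = (value, cfg)
    if best is None:
        raise ValidationError("all trials failed")
    return best[1], trials


def linear_probe_auc(
    features: np.ndarray,
    labels: LabelVector | np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean CV AUC of an l2-regularized logistic probe on raw features.

    Used to certify that a synthetic dataset's class signal is linearly
    recoverable from tangent coordinates before blaming the imaging pipeline.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    folds = stratified_folds(y, k, seed=seed)
    all_idx = np.arange(y.size)
    aucs = []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        scaler = StandardScaler().fit(features[train_idx])
        clf = LogisticRegression(max_iter=2000, C=1.0).fit(
            scaler.transform(features[train_idx]), y[train_idx]
        )
        scores = clf.predict_proba(scaler.transform(features[test_idx]))[:, 1]
        aucs.append(compute_auc(scores, y[test_idx]))
    return float(np.mean(aucs))
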