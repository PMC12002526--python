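"""DeepInsight-style feature layout and image rendering with a zero offset.

Features (taxa, in tangent coordinates) are embedded in 2D by dimensionality
reduction of the transposed data matrix, cropped to the minimum-area bounding
rectangle of their convex hull, snapped to a pixel grid, and each sample is
rendered as a grayscale image whose pixel intensities are its normalized
feature values.

The modification for zero-inflated data: after normalization, every foreground
pixel (a pixel owning at least one feature) is clamped up to a small epsilon,
so a "true zero" (a feature whose value is zero) stays distinguishable from a
"fake zero" (background pixel owning no feature). This makes every sample
image share one support — the foreground mask — which is the segmentation the
CNN would otherwise have to infer per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from sklearn.decomposition import PCA, KernelPCA
from sklearn.manifold import TSNE

from .exceptions import DomainError, ValidationError

_METHODS = ("pca", "kpca", "tsne")


@dataclass
class FeatureLayout:
    feature_ids: list[str]
    coords2d: np.ndarray       # n_features x 2
    method: str
    seed: int
    fitted_on: str = "all"

    def __post_init__(self):
        self.coords2d = np.asarray(self.coords2d, dtype=float)
        if not np.all(np.isfinite(self.coords2d)):
            raise ValidationError("layout produced non-finite coordinates")


@dataclass
class PixelMap:
    grid_h: int
    grid_w: int
    rotation_angle: float
    pixel_of_feature: np.ndarray      # n_features x 2 ints, (row, col)
    foreground_mask: np.ndarray       # grid_h x grid_w bool
    collision_groups: dict = field(default_factory=dict)  # (row,col) -> [feature idx]


@dataclass
class ImageStack:
    images: np.ndarray                # n x H x W in [0,1]
    foreground_mask: np.ndarray
    epsilon: float
    normalization_scheme: str


def feature_layout(
    training_matrix: np.ndarray,
    method: str = "pca",
    seed: int = 0,
    feature_ids: Optional[list[str]] = None,
    fitted_on: str = "all",
    **params,
) -> FeatureLayout:
    """Embed features in 2D by reducing the transposed samples x features matrix.

    Deterministic for fixed (method, seed, params, input). t-SNE perplexity
    defaults to min(30, (n_features - 1)/3) so small desk-scale feature sets
    stay valid.
    """
    X = np.asarray(training_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 3:
        raise ValidationError("need at least 3 features to build a layout")
    if method not in _METHODS:
        raise ValidationError(f"unknown layout method {method!r}; use one of {_METHODS}")
    G = X.T  # features become the rows: DeepInsight embeds features, not samples
    n_features = G.shape[0]
    if method == "pca":
        coords = PCA(n_components=2, svd_solver="full").fit_transform(G)
    elif method == "kpca":
        kernel = params.pop("kernel", "rbf")
        coords = KernelPCA(
            n_components=2, kernel=kernel, random_state=seed, **params
        ).fit_transform(G)
    else:
        perplexity = params.pop("perplexity", min(30.0, (n_features - 1) / 3.0))
        coords = TSNE(
            n_components=2,
            random_state=seed,
            perplexity=perplexity,
            init="pca",
            **params,
        ).fit_transform(G)
    ids = feature_ids if feature_ids is not None else [f"f{i}" for i in range(n_features)]
    return FeatureLayout(
        feature_ids=list(ids), coords2d=coords, method=method, seed=seed,
        fitted_on=fitted_on,
    )


def min_area_rectangle(coords2d: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-area bounding rectangle via convex hull + rotating calipers.

    The optimum rectangle has a side collinear with a hull edge, so scanning
    hull-edge angles is exact. Returns (angle, corners): rotating the points by
    -angle makes the rectangle axis-aligned. Collinear inputs fall back to the
    segment direction with a zero-height rectangle.
    """
    pts = np.asarray(coords2d, dtype=float)
    if pts.shape[0] < 3:
        raise ValidationError("need at least 3 points")
    try:
        hull = ConvexHull(pts)
        hull_pts = pts[hull.vertices]
    except QhullError:
        # collinear: use the principal direction of the segment
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        angle = float(np.arctan2(vt[0, 1], vt[0, 0]))
        proj = centered @ vt[0]
        lo, hi = proj.min(), proj.max()
        direction = vt[0]
        c = pts.mean(axis=0)
        corners = np.array([c + lo * direction, c + hi * direction,
                            c + hi * direction, c + lo * direction])
        return angle, corners

    edges = np.diff(np.vstack([hull_pts, hull_pts[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0])
    best = None
    for ang in angles:
        ca, sa = np.cos(-ang), np.sin(-ang)
        rot = hull_pts @ np.array([[ca, -sa], [sa, ca]]).T
        lo = rot.min(axis=0)
        hi = rot.max(axis=0)
        area = float(np.prod(hi - lo))
        if best is None or area < best[0]:
            best = (area, ang, lo, hi)
    _, ang, lo, hi = best
    ca, sa = np.cos(ang), np.sin(ang)
    back = np.array([[ca, -sa], [sa, ca]])
    box = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    corners = box @ back.T
    return float(ang), corners


def _round_half_away(v: np.ndarray) -> np.ndarray:
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def pixel_assignment(
    layout: FeatureLayout, angle: float, grid_h: int, grid_w: int
) -> PixelMap:
    """Snap rotated, rescaled feature coordinates to integer pixels.

    Coordinates are rotated by -angle (axis-aligning the bounding rectangle),
    affinely mapped onto [0, grid_h-1] x [0, grid_w-1], rounded half-away-from-
    zero and clamped. Row 0 is the top of the image (large rotated y).
    """
    if grid_h < 2 or grid_w < 2:
        raise ValidationError("grid dimensions must be at least 2")
    pts = layout.coords2d
    ca, sa = np.cos(-angle), np.sin(-angle)
    rot = pts @ np.array([[ca, -sa], [sa, ca]]).T
    x, y = rot[:, 0], rot[:, 1]

    def _scale(vals, n_cells, flip=False):
        lo, hi = vals.min(), vals.max()
        if hi - lo < 1e-300:
            return np.full(vals.shape, (n_cells - 1) / 2.0)
        u = (vals - lo) / (hi - lo)
        if flip:
            u = 1.0 - u
        return u * (n_cells - 1)

    rows = np.clip(_round_half_away(_scale(y, grid_h, flip=True)), 0, grid_h - 1).astype(int)
    cols = np.clip(_round_half_away(_scale(x, grid_w)), 0, grid_w - 1).astype(int)

    pixel_of_feature = np.stack([rows, cols], axis=1)
    mask = np.zeros((grid_h, grid_w), dtype=bool)
    groups: dict[tuple[int, int], list[int]] = {}
    for idx, (r, c) in enumerate(zip(rows, cols)):
        mask[r, c] = True
        groups.setdefault((int(r), int(c)), []).append(idx)
    return PixelMap(
        grid_h=grid_h,
        grid_w=grid_w,
        rotation_angle=float(angle),
        pixel_of_feature=pixel_of_feature,
        foreground_mask=mask,
        collision_groups=groups,
    )


def normalize_values(
    matrix: np.ndarray,
    scheme: str = "independent",
    train_index: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Map values into [0,1] using statistics from the training subset only.

    independent: per-feature (v - min)/(max - min); constant features map to 0.
    topology_preserving: one global training min and range for every cell, so
    cross-feature ordering of values is preserved in the image intensities.
    Out-of-range (test) values are clipped to [0,1].
    """
    X = np.asarray(matrix, dtype=float)
    idx = np.arange(X.shape[0]) if train_index is None else np.asarray(train_index)
    if idx.size == 0:
        raise ValidationError("empty training subset")
    train = X[idx]
    if scheme == "independent":
        lo = train.min(axis=0)
        rng = train.max(axis=0) - lo
        out = np.where(rng > 0, (X - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    elif scheme == "topology_preserving":
        lo = train.min()
        rng = train.max() - lo
        out = (X - lo) / rng if rng > 0 else np.zeros_like(X)
    else:
        raise ValidationError(f"unknown normalization scheme {scheme!r}")
    return np.clip(out, 0.0, 1.0)


def render_images(
    normalized: np.ndarray,
    pmap: PixelMap,
    epsilon: float = 1 / 255,
    segment: bool = True,
    aggregate: str = "mean",
) -> ImageStack:
    """Render each sample as a grayscale image over the pixel map.

    Each foreground pixel takes the mean (or max, behind the flag) of its
    collision group's normalized values; background pixels are exactly 0. With
    segment=True every foreground value is clamped up to epsilon, giving all
    images one common support equal to the foreground mask. With segment=False
    a sample whose features are zero at a pixel leaves that pixel at 0 —
    indistinguishable from background, the original DeepInsight pathology on
    zero-inflated data.
    """
    if not 0.0 <= epsilon < 1.0:
        raise ValidationError("epsilon must be in [0, 1)")
    X = np.asarray(normalized, dtype=float)
    if X.min() < -1e-12 or X.max() > 1.0 + 1e-12:
        raise ValidationError("normalized values must lie in [0, 1]")
    if aggregate not in ("mean", "max"):
        raise ValidationError("aggregate must be 'mean' or 'max'")
    n = X.shape[0]
    images = np.zeros((n, pmap.grid_h, pmap.grid_w), dtype=float)
    for (r, c), feats in pmap.collision_groups.items():
        vals = X[:, feats]
        images[:, r, c] = vals.mean(axis=1) if aggregate == "mean" else vals.max(axis=1)
    if segment and epsilon > 0:
        fg = pmap.foreground_mask
        images[:, fg] = np.maximum(images[:, fg], epsilon)
    return ImageStack(
        images=images,
        foreground_mask=pmap.foreground_mask.copy(),
        epsilon=epsilon if segment else 0.0,
        normalization_scheme="unspecified",
    )


def support_mask(stack: ImageStack, sample_index: int) -> np.ndarray:
    """Strictly-positive pixel set of one sample's image."""
    n = stack.images.shape[0]
    if not 0 <= sample_index < n:
        raise DomainError(f"sample index {sample_index} out of range [0, {n})")
    return stack.images[sample_index] > 0


def distinct_supports(stack: ImageStack) -> int:
    """Number of distinct per-sample supports (1 when segmentation is on)."""
    seen = {(stack.images[i] > 0).tobytes() for i in range(stack.images.shape[0])}
    return len(seen)
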