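"""Riemannian machinery on the unit hypersphere.

Square-root-transformed compositions live on the nonnegative orthant of the
unit sphere C^{d-1}. Distances along the sphere are great-circle arcs; the
intrinsic (Fréchet) mean minimizes summed squared geodesic distance; a rotation
carries the mean to the pole (0,...,0,1), where the Logarithmic map has the
simple closed form

    Log_p(x) = (theta / sin theta) * (x_1, ..., x_{d-1}),  theta = arccos(x_d),

flattening the data into the tangent space where ordinary PCA applies
(principal geodesic analysis, tangent formulation).

Because orthant data sit inside one open hemisphere, the Fréchet-mean fixed
point iteration converges and antipodal degeneracies cannot occur with valid
inputs; antipodes are therefore treated as caller errors, never silently fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from sklearn.decomposition import PCA

from .compositional import SpherePoints
from .exceptions import ConvergenceError, DomainError, ValidationError

# below this angle, theta/sin(theta) and sin(r)/r switch to their series limits
_SMALL_ANGLE = 1e-6
_UNIT_ATOL = 1e-8


@dataclass
class TangentCoordinates:
    """Tangent-space coordinates at the pole, plus the maps that produced them.

    `values` rows are the Log-mapped samples (length d-1); the Euclidean norm
    of row i equals the geodesic distance theta_i from sample i to the Fréchet
    mean. `rotation` is the d x d special-orthogonal matrix sending
    `frechet_mean` to the pole.
    """

    sample_ids: list[str]
    values: np.ndarray
    frechet_mean: np.ndarray
    rotation: np.ndarray
    theta_per_sample: np.ndarray


@dataclass
class PGAResult:
    scores: np.ndarray          # samples x k
    loadings: np.ndarray        # k x (d-1), orthonormal rows
    variances: np.ndarray       # nonincreasing, length k
    k: int


def _check_unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if abs(np.linalg.norm(v) - 1.0) > _UNIT_ATOL:
        raise ValidationError(f"{name} is not unit norm (|v|={np.linalg.norm(v)})")
    return v


def geodesic_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Great-circle distance arccos(<u,v>) in radians, in [0, pi]."""
    u = _check_unit(u, "u")
    v = _check_unit(v, "v")
    return float(np.arccos(np.clip(u @ v, -1.0, 1.0)))


def _log_map_at(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    """General-point Log map: tangent vectors at p, shape like x (d components).

    Log_p(x) = (theta/sin theta) (x - cos(theta) p). Vectorized over rows of x.
    """
    x = np.atleast_2d(x)
    c = np.clip(x @ p, -1.0, 1.0)
    theta = np.arccos(c)
    factor = np.where(theta < _SMALL_ANGLE, 1.0 + theta**2 / 6.0, theta / np.sin(np.maximum(theta, _SMALL_ANGLE)))
    return factor[:, None] * (x - c[:, None] * p)


def _exp_map_at(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    """General-point Exp map for a single tangent vector v at p."""
    r = np.linalg.norm(v)
    if r < _SMALL_ANGLE:
        out = p + v  # first-order; renormalize below
    else:
        out = np.cos(r) * p + (np.sin(r) / r) * v
    return out / np.linalg.norm(out)


def frechet_mean(
    points: SpherePoints, tol: float = 1e-10, max_iter: int = 200
) -> np.ndarray:
    """Intrinsic mean on the sphere via the fixed-point (Karcher) iteration.

    Initialized at the normalized extrinsic mean; each step averages the
    Log-mapped points at the current estimate and Exp-maps back. Converges for
    data confined to an open hemisphere, which holds for orthant data.
    """
    x = np.asarray(points.values, dtype=float)
    if x.shape[0] == 0:
        raise ValidationError("need at least one point")
    mu = x.mean(axis=0)
    norm = np.linalg.norm(mu)
    if norm < 1e-12:
        raise ValidationError("degenerate configuration: extrinsic mean is zero")
    mu = mu / norm
    step_norm = np.inf
    for _ in range(max_iter):
        v = _log_map_at(mu, x).mean(axis=0)
        step_norm = float(np.linalg.norm(v))
        if step_norm < tol:
            return mu
        mu = _exp_map_at(mu, v)
    raise ConvergenceError(
        f"Fréchet mean did not converge in {max_iter} iterations "
        f"(last step norm {step_norm:.3e})",
        last_iterate=mu,
        step_norm=step_norm,
    )


def rotation_to_pole(mu: np.ndarray) -> np.ndarray:
    """Special-orthogonal matrix R with R @ mu = pole = (0,...,0,1).

    R rotates in span{mu, pole} and is the identity on the orthogonal
    complement, so it moves the data as little as possible.
    """
    mu = _check_unit(mu, "mu")
    d = mu.shape[0]
    pole = np.zeros(d)
    pole[-1] = 1.0
    c = float(np.clip(mu @ pole, -1.0, 1.0))
    if c > 1.0 - 1e-14:
        return np.eye(d)
    if c < -1.0 + 1e-10:
        raise DomainError("mu is antipodal to the pole; rotation plane undefined")
    w = mu - c * pole
    w = w / np.linalg.norm(w)
    s = np.sqrt(1.0 - c * c)
    R = (
        np.eye(d)
        + (c - 1.0) * (np.outer(w, w) + np.outer(pole, pole))
        + s * (np.outer(pole, w) - np.outer(w, pole))
    )
    return R


def log_map_pole(x: np.ndarray) -> np.ndarray:
    """Log map at the pole: (theta/sin theta)*(x_1..x_{d-1}), theta=arccos(x_d).

    Accepts a single unit vector or a stack of rows. The output Euclidean norm
    equals the geodesic distance theta from the pole; the theta -> 0 limit uses
    the series 1 + theta^2/6.
    """
    single = np.asarray(x).ndim == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    norms = np.linalg.norm(x, axis=1)
    if np.any(np.abs(norms - 1.0) > _UNIT_ATOL):
        raise ValidationError("input rows must be unit vectors")
    xd = np.clip(x[:, -1], -1.0, 1.0)
    if np.any(xd < -1.0 + 1e-10):
        raise DomainError("antipode of the pole has no Log image")
    theta = np.arccos(xd)
    factor = np.where(
        theta < _SMALL_ANGLE,
        1.0 + theta**2 / 6.0,
        theta / np.sin(np.maximum(theta, _SMALL_ANGLE)),
    )
    v = factor[:, None] * x[:, :-1]
    return v[0] if single else v


def exp_map_pole(v: np.ndarray) -> np.ndarray:
    """Exp map at the pole: v in R^{d-1} with |v| < pi maps to the sphere."""
    v = np.asarray(v, dtype=float)
    r = float(np.linalg.norm(v))
    if r >= np.pi:
        raise DomainError(f"tangent vector norm {r} is outside the domain [0, pi)")
    if r < _SMALL_ANGLE:
        sinc = 1.0 - r**2 / 6.0
    else:
        sinc = np.sin(r) / r
    out = np.concatenate([sinc * v, [np.cos(r)]])
    return out / np.linalg.norm(out)


def tangent_projection(
    points: SpherePoints, tol: float = 1e-10, max_iter: int = 200
) -> TangentCoordinates:
    """Fréchet mean -> rotation to pole -> row-wise Log map at the pole.

    This is the tangent-space flattening step: after it, samples live in the
    flat (d-1)-dimensional tangent space at the mean, ready for PCA and image
    rendering.
    """
    mu = frechet_mean(points, tol=tol, max_iter=max_iter)
    R = rotation_to_pole(mu)
    rotated = points.values @ R.T
    # rotation preserves norms up to float error; re-clip for arccos stability
    rotated = rotated / np.linalg.norm(rotated, axis=1)[:, None]
    theta = np.arccos(np.clip(rotated[:, -1], -1.0, 1.0))
    tangent = log_map_pole(rotated)
    return TangentCoordinates(
        sample_ids=list(points.sample_ids),
        values=tangent,
        frechet_mean=mu,
        rotation=R,
        theta_per_sample=theta,
    )


def pga(tan: TangentCoordinates, k: Union[int, str] = "all") -> PGAResult:
    """PCA of the tangent coordinates (tangent formulation of PGA).

    k="all" keeps min(n-1, d-1) components, i.e. no truncation: the tangent
    projection itself is the dimensionality step the downstream imaging uses.
    """
    x = np.asarray(tan.values, dtype=float)
    n, dm1 = x.shape
    if n < 2:
        raise ValidationError("PGA needs at least two samples")
    k_max = min(n - 1, dm1)
    if k == "all":
        k_use = k_max
    else:
        k_use = int(k)
        if not 1 <= k_use <= k_max:
            raise ValidationError(f"k must be in [1, {k_max}]")
    model = PCA(n_components=k_use, svd_solver="full")
    scores = model.fit_transform(x)
    return PGAResult(
        scores=scores,
        loadings=model.components_,
        variances=model.explained_variance_,
        k=k_use,
    )
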