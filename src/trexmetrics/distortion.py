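"""Expansion-distortion analysis from matched pre/post landmarks.

Ideal isotropic expansion maps pre-expansion coordinates onto
post-expansion coordinates by a similarity transform (uniform scale s,
rotation, translation).  Real gels additionally deform elastically.  This
module decomposes a landmark correspondence into

* the best-fit similarity transform (closed-form least squares, no
  reflection) — its scale is the macroscopic expansion factor of the
  registered region; and
* a residual elastic field, modeled as a 2D thin-plate spline over the
  pre-expansion coordinates, with residuals expressed in pre-expansion
  (biological) units: ``r_i = (post_i - S(pre_i)) / s``.

The measurement error a user would incur measuring the distance between
two points p, q is then ``‖r(p) - r(q)‖``; binned against the
pre-expansion distance ``‖p - q‖`` this yields the error-versus-length
curve and its overall error fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .exceptions import DegenerateInputError, DomainError

__all__ = [
    "LandmarkPairSet",
    "SimilarityTransform2D",
    "ResidualField",
    "FieldSample",
    "ErrorCurve",
    "fit_similarity",
    "residual_field",
    "sample_field",
    "measurement_error_curve",
    "expansion_from_similarity",
]


@dataclass(frozen=True)
class LandmarkPairSet:
    """Index-matched pre/post-expansion landmark coordinates in µm."""

    pre_points: np.ndarray
    post_points: np.ndarray

    def __post_init__(self) -> None:
        pre = np.atleast_2d(np.asarray(self.pre_points, dtype=float))
        post = np.atleast_2d(np.asarray(self.post_points, dtype=float))
        if pre.shape != post.shape or pre.ndim != 2 or pre.shape[1] != 2:
            raise DomainError("pre and post must be matching (n, 2) arrays")
        if pre.shape[0] < 2:
            raise DomainError("need at least 2 landmark pairs (>= 4 recommended)")
        if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
            raise DomainError("landmark coordinates must be finite")
        object.__setattr__(self, "pre_points", pre)
        object.__setattr__(self, "post_points", post)

    def __len__(self) -> int:
        return self.pre_points.shape[0]


@dataclass(frozen=True)
class SimilarityTransform2D:
    """Uniform scale + rotation + translation (reflection excluded)."""

    scale: float
    rotation_rad: float
    translation_um: np.ndarray
    rms_residual_um: float = 0.0

    @property
    def matrix(self) -> np.ndarray:
        """2x2 linear part (scale * rotation)."""
        c, s = math.cos(self.rotation_rad), math.sin(self.rotation_rad)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation_um, dtype=float)


def fit_similarity(landmarks: LandmarkPairSet) -> SimilarityTransform2D:
    """Closed-form least-squares similarity fit (Umeyama/Procrustes).

    Minimizes ``sum_i ‖post_i - (s R pre_i + t)‖^2`` over scale s > 0,
    rotation R (det +1; mounted-gel flips must be corrected upstream) and
    translation t.
    """
    pre, post = landmarks.pre_points, landmarks.post_points
    mu_pre = pre.mean(axis=0)
    mu_post = post.mean(axis=0)
    p = pre - mu_pre
    q = post - mu_post
    var_pre = float(np.sum(p * p)) / len(pre)
    if var_pre == 0.0:
        raise DegenerateInputError("all pre-expansion landmarks coincide")
    cov = (q.T @ p) / len(pre)
    U, D, Vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, sign])
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S)) / var_pre
    rotation = float(math.atan2(R[1, 0], R[0, 0]))
    translation = mu_post - scale * (R @ mu_pre)
    resid = post - (pre @ (scale * R).T + translation)
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return SimilarityTransform2D(scale=scale, rotation_rad=rotation,
                                 translation_um=translation, rms_residual_um=rms)


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """Thin-plate kernel U(r) = r^2 log(r^2), with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass(frozen=True)
class ResidualField:
    """Thin-plate-spline residual elastic displacement field.

    Control points and residual vectors are in pre-expansion µm.  At
    ``regularization = 0`` the spline interpolates the residuals exactly
    at the control points; positive values trade interpolation accuracy
    for smoothness.
    """

    control_points: np.ndarray
    residuals_um: np.ndarray
    kernel_weights: np.ndarray = field(repr=False)
    affine_weights: np.ndarray = field(repr=False)
    regularization: float = 0.0

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Residual displacement (µm, pre-expansion units) at ``points``."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        K = _tps_kernel(cdist(pts, self.control_points, "sqeuclidean"))
        P = np.column_stack([np.ones(len(pts)), pts])
        return K @ self.kernel_weights + P @ self.affine_weights

    def rms_misfit_um(self) -> float:
        """RMS misfit between the spline and the residuals at the control
        points (0 at regularization 0)."""
        err = self.evaluate(self.control_points) - self.residuals_um
        return float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))


def residual_field(landmarks: LandmarkPairSet,
                   transform: SimilarityTransform2D,
                   regularization: float = 0.0) -> ResidualField:
    """Fit the residual elastic part of the pre->post mapping.

    The per-landmark residual is the post-expansion misfit of the
    similarity transform, divided by its scale so the field lives in
    pre-expansion biological units.  A standard 2D thin-plate spline
    (kernel ``r^2 log r^2`` plus an affine term) is fitted to these
    residuals over the pre-expansion coordinates.
    """
    if regularization < 0:
        raise DomainError("regularization must be nonnegative")
    pre, post = landmarks.pre_points, landmarks.post_points
    if len(pre) >= 2 and pdist(pre).min() == 0.0:
        raise DegenerateInputError("duplicate pre-expansion points make the "
                                   "thin-plate kernel singular")
    residuals = (post - transform.apply(pre)) / transform.scale

    n = len(pre)
    K = _tps_kernel(cdist(pre, pre, "sqeuclidean"))
    if regularization > 0:
        K = K + regularization * np.eye(n)
    P = np.column_stack([np.ones(n), pre])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.zeros((n + 3, 2))
    b[:n] = residuals
    sol = np.linalg.solve(A, b)
    return ResidualField(control_points=pre, residuals_um=residuals,
                         kernel_weights=sol[:n], affine_weights=sol[n:],
                         regularization=regularization)


@dataclass(frozen=True)
class FieldSample:
    """Residual vectors evaluated on a regular grid of sample points."""

    points: np.ndarray
    vectors: np.ndarray


def sample_field(fld: ResidualField, grid_spacing_um: float) -> FieldSample:
    """Evaluate the residual field on a regular grid over the landmark
    bounding box, inclusive of both edges."""
    if grid_spacing_um <= 0:
        raise DomainError("grid spacing must be positive")
    lo = fld.control_points.min(axis=0)
    hi = fld.control_points.max(axis=0)
    extent = hi - lo
    if grid_spacing_um > max(extent):
        raise DomainError("grid spacing exceeds the landmark bounding box")
    axes = []
    for lo_i, ext in zip(lo, extent):
        n = int(math.floor(ext / grid_spacing_um + 1e-9)) + 1
        axes.append(lo_i + grid_spacing_um * np.arange(n))
    gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return FieldSample(points=pts, vectors=fld.evaluate(pts))


@dataclass(frozen=True)
class ErrorCurve:
    """Pairwise measurement error binned by pre-expansion distance."""

    bin_edges_um: np.ndarray
    mean_error_um: np.ndarray
    sd_error_um: np.ndarray
    mean_fraction: np.ndarray
    n_pairs: np.ndarray
    overall_fraction_mean: float
    overall_fraction_sd: float

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def measurement_error_curve(samples: FieldSample,
                            bin_width_um: float = 5.0,
                            max_pairs: int = 1_000_000,
                            seed: int = 0) -> ErrorCurve:
    """Measurement-error-vs-length statistics over all point pairs.

    For each pair (p, q) of sampled points the error is
    ``‖r(p) - r(q)‖`` and the measurement length is ``‖p - q‖`` (both in
    pre-expansion µm).  Errors are binned by length with the given bin
    width; per-bin mean and sample SD are reported along with the mean
    fractional error (error / length) per bin and overall.  When the
    number of pairs exceeds ``max_pairs`` a seeded subsample without
    replacement is used.
    """
    if bin_width_um <= 0:
        raise DomainError("bin width must be positive")
    pts = samples.points
    vecs = samples.vectors
    if len(pts) < 2:
        raise DomainError("need at least 2 sampled points")

    lengths = pdist(pts)
    errors = pdist(vecs)
    n_total = lengths.size
    if n_total > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n_total, size=max_pairs, replace=False)
        lengths = lengths[keep]
        errors = errors[keep]

    # grid points can coincide only pathologically; drop zero-length pairs
    nz = lengths > 0
    lengths, errors = lengths[nz], errors[nz]
    fractions = errors / lengths

    n_bins = int(math.ceil(lengths.max() / bin_width_um))
    edges = bin_width_um * np.arange(n_bins + 1)
    idx = np.minimum((lengths // bin_width_um).astype(int), n_bins - 1)

    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    mean_frac = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k in range(n_bins):
        sel = idx == k
        counts[k] = int(sel.sum())
        if counts[k]:
            e = errors[sel]
            mean[k] = e.mean()
            sd[k] = e.std(ddof=1) if counts[k] > 1 else 0.0
            mean_frac[k] = fractions[sel].mean()

    return ErrorCurve(
        bin_edges_um=edges,
        mean_error_um=mean,
        sd_error_um=sd,
        mean_fraction=mean_frac,
        n_pairs=counts,
        overall_fraction_mean=float(fractions.mean()),
        overall_fraction_sd=float(fractions.std(ddof=1)) if fractions.size > 1 else 0.0,
    )


def expansion_from_similarity(transform: SimilarityTransform2D) -> float:
    """Macroscopic expansion factor: the scale of the similarity part."""
    return transform.scale
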