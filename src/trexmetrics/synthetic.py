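"""Seeded synthetic-data generators with recorded ground truth.

Each generator emulates one class of input the measurement pipeline
consumes — sagged gel edges, matched pre/post-expansion landmark fields,
ring images, 1D line profiles, disk-packed images (microvilli
cross-sections) and paired two-channel 3D blob volumes (synapses) — and
returns the data together with a :class:`SyntheticTruth` record holding
the exact generating parameters, so recovery tests never have to infer
truth from the data itself.

All randomness flows through ``numpy.random.default_rng(seed)``:
identical (generator, seed, parameters) reproduce bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distortion import LandmarkPairSet, SimilarityTransform2D
from .exceptions import DomainError, PlacementError
from .gel import GelEdgePointSet
from .profiles import GAUSSIAN_FWHM_FACTOR, LineProfile

__all__ = [
    "SyntheticTruth",
    "gen_gel_edge",
    "gen_landmark_field",
    "gen_ring_image",
    "gen_profile",
    "gen_disk_image",
    "gen_synapse_volume",
    "sinusoidal_field",
    "PLACEMENT_RETRY_CAP",
]

#: Rejection-sampling retry cap for object placement.
PLACEMENT_RETRY_CAP = 1000


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth record emitted alongside every synthetic dataset."""

    generator_name: str
    seed: int
    params: dict = field(default_factory=dict)
    truth_records: pd.DataFrame = field(default_factory=pd.DataFrame)


def gen_gel_edge(gel_radius_mm: float, sag_fraction: float, n_points: int = 7,
                 noise_sd_mm: float = 0.0, seed: int = 0,
                 ) -> tuple[GelEdgePointSet, SyntheticTruth]:
    """Digitized top edge of an upright semicircular gel punch.

    The edge is a circular arc whose two endpoints (the gel corners, at
    x = +/- gel radius) lie exactly ``sag_fraction * gel_radius_mm``
    below the arc apex; ``sag_fraction = 0`` produces a straight edge.
    Gaussian digitization noise of SD ``noise_sd_mm`` is added to the
    vertical coordinate only, so the x ordering of the digitized points
    is preserved.
    """
    if not 0.0 <= sag_fraction < 1.0:
        raise DomainError("sag_fraction must be in [0, 1)")
    if n_points < 3:
        raise DomainError("need at least 3 edge points")
    rng = np.random.default_rng(seed)
    R = float(gel_radius_mm)
    if sag_fraction == 0.0:
        x = np.linspace(-R, R, n_points)
        y = np.zeros(n_points)
    else:
        s = float(sag_fraction)
        rho = R * (1.0 + s * s) / (2.0 * s)     # arc radius; apex at (0, 0)
        phi_max = math.asin(R / rho)
        phi = np.linspace(-phi_max, phi_max, n_points)
        x = rho * np.sin(phi)
        y = rho * np.cos(phi) - rho
    y = y + rng.normal(0.0, noise_sd_mm, size=n_points) if noise_sd_mm > 0 else y
    edge = GelEdgePointSet(points=np.column_stack([x, y]), gel_radius_mm=R)
    truth = SyntheticTruth(
        generator_name="gen_gel_edge", seed=seed,
        params={"gel_radius_mm": R, "sag_fraction": float(sag_fraction),
                "n_points": n_points, "noise_sd_mm": float(noise_sd_mm)},
        truth_records=pd.DataFrame([{"sag_fraction": float(sag_fraction),
                                     "corner_drop_mm": float(sag_fraction) * R}]),
    )
    return edge, truth


def sinusoidal_field(points: np.ndarray, amplitude_um: float,
                     wavelength_um: float) -> np.ndarray:
    """Analytic elastic displacement used by :func:`gen_landmark_field`.

    Separable sinusoid, in pre-expansion µm:
    ``(A sin(2 pi x / L), A sin(2 pi y / L))``.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    w = 2.0 * np.pi / wavelength_um
    return amplitude_um * np.column_stack([np.sin(w * pts[:, 0]),
                                           np.sin(w * pts[:, 1])])


def gen_landmark_field(n_points: int,
                       domain_um: tuple[float, float, float, float] = (0., 0., 100., 100.),
                       scale: float = 10.0, rotation_deg: float = 0.0,
                       translation_um: tuple[float, float] = (0.0, 0.0),
                       elastic_amplitude_um: float = 0.0,
                       elastic_wavelength_um: float = 20.0,
                       noise_sd_um: float = 0.0, seed: int = 0,
                       ) -> tuple[LandmarkPairSet, SyntheticTruth]:
    """Matched pre/post-expansion landmarks with a known decomposition.

    Pre-expansion landmarks are uniform over ``domain_um``
    (xmin, ymin, xmax, ymax).  Post-expansion landmarks are the known
    similarity transform of the pre landmarks plus ``scale`` times a
    smooth sinusoidal elastic displacement (defined in pre-expansion
    units by :func:`sinusoidal_field`) plus Gaussian noise in post
    coordinates.
    """
    if n_points < 4:
        raise DomainError("need at least 4 landmarks (similarity fit "
                          "underdetermined downstream)")
    if elastic_wavelength_um <= 0:
        raise DomainError("elastic wavelength must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = domain_um
    pre = np.column_stack([rng.uniform(xmin, xmax, n_points),
                           rng.uniform(ymin, ymax, n_points)])
    transform = SimilarityTransform2D(scale=float(scale),
                                      rotation_rad=math.radians(rotation_deg),
                                      translation_um=np.asarray(translation_um, float))
    post = transform.apply(pre)
    if elastic_amplitude_um:
        post = post + scale * sinusoidal_field(pre, elastic_amplitude_um,
                                               elastic_wavelength_um)
    if noise_sd_um > 0:
        post = post + rng.normal(0.0, noise_sd_um, size=post.shape)
    landmarks = LandmarkPairSet(pre_points=pre, post_points=post)
    truth = SyntheticTruth(
        generator_name="gen_landmark_field", seed=seed,
        params={"n_points": n_points, "scale": float(scale),
                "rotation_deg": float(rotation_deg),
                "translation_x_um": float(translation_um[0]),
                "translation_y_um": float(translation_um[1]),
                "elastic_amplitude_um": float(elastic_amplitude_um),
                "elastic_wavelength_um": float(elastic_wavelength_um),
                "noise_sd_um": float(noise_sd_um)},
        truth_records=pd.DataFrame({
            "pre_x_um": pre[:, 0], "pre_y_um": pre[:, 1],
            "post_x_um": post[:, 0], "post_y_um": post[:, 1]}),
    )
    return landmarks, truth


def gen_ring_image(shape_px: tuple[int, int] = (128, 128),
                   pixel_size_nm: float = 10.0,
                   centers_px: list[tuple[float, float]] = ((64.0, 64.0),),
                   ring_radius_px: float = 50.0, shell_sigma_px: float = 3.0,
                   amplitude: float = 1000.0, background: float = 100.0,
                   noise_sd: float = 0.0, seed: int = 0,
                   ) -> tuple[np.ndarray, SyntheticTruth]:
    """Image of Gaussian radial shells (rings) of known radius.

    Around each center the intensity is
    ``background + amplitude * exp(-(r - R)^2 / (2 sigma^2))`` (ring
    contributions summed) plus additive Gaussian noise.  The default
    radius emulates an expanded nuclear-pore ring.  Centers closer than
    ``2 (R + 3 sigma)`` trigger a warning (overlapping shells bias the
    radial profile) but are not an error.
    """
    if ring_radius_px <= shell_sigma_px:
        raise DomainError("ring radius must exceed shell sigma")
    ny, nx = shape_px
    ctrs = np.atleast_2d(np.asarray(centers_px, dtype=float))
    if np.any(ctrs[:, 0] < 0) or np.any(ctrs[:, 0] > nx - 1) \
            or np.any(ctrs[:, 1] < 0) or np.any(ctrs[:, 1] > ny - 1):
        raise DomainError("ring centers must lie inside the image")
    if len(ctrs) > 1:
        from scipy.spatial.distance import pdist
        if pdist(ctrs).min() < 2.0 * (ring_radius_px + 3.0 * shell_sigma_px):
            warnings.warn("ring centers closer than 2*(R + 3*sigma): shells "
                          "overlap and radial profiles may be biased",
                          stacklevel=2)
    rng = np.random.default_rng(seed)
    yy, xx = np.indices((ny, nx), dtype=float)
    img = np.full((ny, nx), float(background))
    for cx, cy in ctrs:
        r = np.hypot(xx - cx, yy - cy)
        img += amplitude * np.exp(-0.5 * ((r - ring_radius_px) / shell_sigma_px) ** 2)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    truth = SyntheticTruth(
        generator_name="gen_ring_image", seed=seed,
        params={"pixel_size_nm": float(pixel_size_nm),
                "ring_radius_px": float(ring_radius_px),
                "shell_sigma_px": float(shell_sigma_px),
                "amplitude": float(amplitude), "background": float(background),
                "noise_sd": float(noise_sd)},
        truth_records=pd.DataFrame({
            "center_x_px": ctrs[:, 0], "center_y_px": ctrs[:, 1],
            "radius_px": np.full(len(ctrs), float(ring_radius_px)),
            "diameter_nm": np.full(len(ctrs),
                                   2.0 * ring_radius_px * pixel_size_nm)}),
    )
    return img, truth


def gen_profile(kind: str, params: dict | None = None, n_samples: int = 201,
                spacing_nm: float = 10.0, noise_sd: float = 0.0, seed: int = 0,
                ) -> tuple[LineProfile, SyntheticTruth]:
    """Synthetic 1D line profiles with known width/separation truth.

    ``kind`` selects the shape:

    * ``gaussian`` — params ``sigma_nm`` (required), ``amplitude``,
      ``background``; truth FWHM = 2 sqrt(2 ln 2) sigma.
    * ``two_peak`` — two Gaussians separated by ``separation_nm``
      (required) with per-peak ``sigma_nm``; emulates the central-null
      profile of a clathrin-coated pit.
    * ``plateau`` — boxcar of ``width_nm`` (required); truth FWHM equals
      the width.
    """
    if n_samples < 5:
        raise DomainError("need at least 5 samples")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    x = spacing_nm * np.arange(n_samples)
    center = params.get("center_nm", x[-1] / 2.0)
    amplitude = params.get("amplitude", 1.0)
    background = params.get("background", 0.0)

    if kind == "gaussian":
        sigma = params["sigma_nm"]
        y = background + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)
        truth_row = {"sigma_nm": sigma, "fwhm_nm": GAUSSIAN_FWHM_FACTOR * sigma}
    elif kind == "two_peak":
        sep = params["separation_nm"]
        sigma = params.get("sigma_nm", sep / 8.0)
        y = background
        for c in (center - sep / 2.0, center + sep / 2.0):
            y = y + amplitude * np.exp(-0.5 * ((x - c) / sigma) ** 2)
        truth_row = {"separation_nm": sep, "sigma_nm": sigma}
    elif kind == "plateau":
        width = params["width_nm"]
        y = background + amplitude * ((x >= center - width / 2.0)
                                      & (x < center + width / 2.0)).astype(float)
        truth_row = {"width_nm": width, "fwhm_nm": width}
    else:
        raise DomainError(f"unknown profile kind: {kind!r}")

    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_samples)
    profile = LineProfile(positions=x, intensities=np.asarray(y, dtype=float))
    truth = SyntheticTruth(
        generator_name="gen_profile", seed=seed,
        params={"kind": kind, "n_samples": n_samples,
                "spacing_nm": float(spacing_nm), "noise_sd": float(noise_sd),
                **{k: float(v) for k, v in params.items()}},
        truth_records=pd.DataFrame([truth_row]),
    )
    return profile, truth


def gen_disk_image(shape_px: tuple[int, int] = (512, 512),
                   diameters_px: np.ndarray | list[float] = (10.8,),
                   n_disks: int = 1, min_gap_px: float = 2.0,
                   noise_sd: float = 0.0, seed: int = 0,
                   ) -> tuple[np.ndarray, SyntheticTruth]:
    """Image densely packed with non-overlapping disks of known diameter.

    Emulates cross-sectioned microvilli.  If ``diameters_px`` has exactly
    ``n_disks`` entries they are used in order; otherwise diameters are
    drawn from the list with replacement.  Disk centers are
    rejection-sampled so every pair keeps at least ``min_gap_px`` edge
    clearance; failure after 1000 attempts per disk raises
    :class:`PlacementError` naming the cap.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape_px
    diams = np.asarray(diameters_px, dtype=float)
    if np.any(diams <= 0):
        raise DomainError("diameters must be positive")
    if diams.size == n_disks:
        chosen = diams.copy()
    else:
        chosen = rng.choice(diams, size=n_disks, replace=True)

    centers = np.empty((0, 2))
    radii: list[float] = []
    for d in chosen:
        r = d / 2.0
        placed = False
        for _ in range(PLACEMENT_RETRY_CAP):
            cx = rng.uniform(r + 1, nx - 2 - r)
            cy = rng.uniform(r + 1, ny - 2 - r)
            if len(radii):
                dist = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy)
                if np.any(dist < np.asarray(radii) + r + min_gap_px):
                    continue
            centers = np.vstack([centers, [cx, cy]])
            radii.append(r)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place disk of diameter {d:g} px after "
                f"{PLACEMENT_RETRY_CAP} attempts")

    yy, xx = np.indices((ny, nx), dtype=float)
    img = np.zeros((ny, nx))
    truth_rows = []
    for (cx, cy), r in zip(centers, radii):
        inside = np.hypot(xx - cx, yy - cy) <= r
        img[inside] = 1.0
        truth_rows.append({"center_x_px": cx, "center_y_px": cy,
                           "diameter_px": 2.0 * r,
                           "area_px_rasterized": int(inside.sum())})
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = SyntheticTruth(
        generator_name="gen_disk_image", seed=seed,
        params={"n_disks": n_disks, "min_gap_px": float(min_gap_px),
                "noise_sd": float(noise_sd)},
        truth_records=pd.DataFrame(truth_rows),
    )
    return img, truth


def gen_synapse_volume(shape_vox: tuple[int, int, int] = (32, 96, 96),
                       voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
                       n_synapses: int = 10, separation_um: float = 1.17,
                       blob_sigma_um: float = 0.2, amplitude: float = 1000.0,
                       noise_sd: float = 0.0, seed: int = 0,
                       ) -> tuple[np.ndarray, np.ndarray, SyntheticTruth]:
    """Two-channel 3D volume of paired Gaussian blobs at known separation.

    Each synapse contributes one blob per channel, displaced from a
    common midpoint by ``separation_um / 2`` along a random unit vector
    (uniform on the sphere).  The default separation matches the expanded
    pre/postsynaptic marker distance this pipeline was built to measure.
    Pair midpoints are rejection-sampled so neighboring synapses stay at
    least ``separation + 6 sigma`` apart; failure after 1000 attempts
    raises :class:`PlacementError`.
    """
    vs = np.asarray(voxel_size_um, dtype=float)
    shape = tuple(int(s) for s in shape_vox)
    diag = float(np.linalg.norm(vs))
    if separation_um < 0:
        raise DomainError("separation must be nonnegative")
    if separation_um > 0 and separation_um < diag:
        raise DomainError("separation below one voxel diagonal is unresolvable")
    extent = (np.asarray(shape) - 1) * vs
    margin = separation_um / 2.0 + 4.0 * blob_sigma_um
    if np.any(extent <= 2 * margin):
        raise DomainError("blobs do not fit inside the volume")
    rng = np.random.default_rng(seed)

    min_dist = separation_um + 6.0 * blob_sigma_um
    mids = np.empty((0, 3))
    for _ in range(n_synapses):
        for attempt in range(PLACEMENT_RETRY_CAP):
            c = np.array([rng.uniform(margin, e - margin) for e in extent])
            if len(mids) == 0 or np.linalg.norm(mids - c, axis=1).min() >= min_dist:
                mids = np.vstack([mids, c])
                break
        else:
            raise PlacementError(
                f"could not place synapse pair after {PLACEMENT_RETRY_CAP} attempts")

    # isotropic random unit vectors
    u = rng.normal(size=(n_synapses, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    coords = [vs[i] * np.arange(shape[i]) for i in range(3)]
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]
    chan_a = np.zeros(shape)
    chan_b = np.zeros(shape)
    truth_rows = []
    for mid, vec in zip(mids, u):
        ca = mid - vec * separation_um / 2.0
        cb = mid + vec * separation_um / 2.0
        for chan, c in ((chan_a, ca), (chan_b, cb)):
            chan += amplitude * np.exp(
                -((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
                / (2.0 * blob_sigma_um ** 2))
        truth_rows.append({
            "a_z_um": ca[0], "a_y_um": ca[1], "a_x_um": ca[2],
            "b_z_um": cb[0], "b_y_um": cb[1], "b_x_um": cb[2],
            "separation_um": float(separation_um),
            "orient_z": vec[0], "orient_y": vec[1], "orient_x": vec[2]})
    if noise_sd > 0:
        chan_a = chan_a + rng.normal(0.0, noise_sd, size=shape)
        chan_b = chan_b + rng.normal(0.0, noise_sd, size=shape)
    truth = SyntheticTruth(
        generator_name="gen_synapse_volume", seed=seed,
        params={"n_synapses": n_synapses, "separation_um": float(separation_um),
                "blob_sigma_um": float(blob_sigma_um),
                "voxel_z_um": vs[0], "voxel_y_um": vs[1], "voxel_x_um": vs[2],
                "amplitude": float(amplitude), "noise_sd": float(noise_sd)},
        truth_records=pd.DataFrame(truth_rows),
    )
    return chan_a, chan_b, truth
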