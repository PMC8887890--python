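"""Intensity-profile size estimators for expanded nanostructures.

Two families of measurement live here:

* **Radial ring fitting** — the nuclear pore complex scaffold (NUP96)
  forms a ring of known 107 nm diameter and serves as a local expansion
  ruler.  The annulus-averaged radial intensity profile around each ring
  center is fitted with a Gaussian-plus-constant; the Gaussian center is
  the ring radius.

* **1D line-profile metrics** — full width at half maximum (tubule
  diameters), peak-to-peak distance of two-peaked profiles
  (clathrin-coated pits, antibody-stained microtubule sidewalls), and
  peak normalization.

Expansion-correction arithmetic (dividing by the macroscopic expansion
factor, local expansion factor relative to a known reference size) is
included because every reported size passes through it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .exceptions import (
    DomainError,
    NoPairError,
    NoRingError,
    UndefinedWidthError,
)

__all__ = [
    "RadialProfile",
    "RingFit",
    "LineProfile",
    "ProfileMetrics",
    "ExpansionContext",
    "radial_profile",
    "fit_ring_radius",
    "ring_diameters",
    "fwhm",
    "peak_to_peak",
    "peak_normalize",
    "correct_for_expansion",
    "local_expansion_factor",
    "GAUSSIAN_FWHM_FACTOR",
]

#: FWHM of a Gaussian = 2 sqrt(2 ln 2) * sigma.
GAUSSIAN_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class RadialProfile:
    """Annulus-averaged intensity versus integer radius.

    Annulus k collects pixels whose center distance from ``center_px``
    falls in [k - 0.5, k + 0.5); empty annuli hold NaN.
    """

    radii_px: np.ndarray
    mean_intensity: np.ndarray
    counts: np.ndarray
    center_px: tuple[float, float]
    pixel_size_nm: float = 1.0


@dataclass(frozen=True)
class RingFit:
    """Gaussian ring fit to a radial profile.

    ``radius_px`` is the fitted Gaussian center; ``diameter_nm`` is
    ``2 * radius_px * pixel_size_nm``.
    """

    radius_px: float
    amplitude: float
    sigma_px: float
    offset: float
    diameter_nm: float
    converged: bool
    window: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class LineProfile:
    """Uniformly sampled 1D intensity profile (positions in nm or µm)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or pos.shape != inten.shape or pos.size < 2:
            raise DomainError("positions and intensities must be matching 1D arrays")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise DomainError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9 * abs(steps[0])):
            raise DomainError("positions must be uniformly spaced")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def __len__(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class ProfileMetrics:
    fwhm: float | None
    peak_to_peak: float | None
    baseline: float
    n_peaks: int


@dataclass(frozen=True)
class ExpansionContext:
    """Macroscopic expansion factor plus a known reference size.

    Reference sizes used as expansion rulers: the 107 nm NUP96 ring and
    the ~100 nm electron-microscopy microvillus diameter.
    """

    expansion_factor: float
    reference_size_nm: float = 107.0

    def __post_init__(self) -> None:
        if self.expansion_factor <= 0 or self.reference_size_nm <= 0:
            raise DomainError("expansion factor and reference size must be positive")


def radial_profile(image: np.ndarray, center_px: tuple[float, float],
                   r_max_px: int, pixel_size_nm: float = 1.0) -> RadialProfile:
    """Annulus-averaged radial intensity distribution around a center.

    ``center_px`` is (x, y) in pixel coordinates with pixel centers at
    integer positions.  Annulus k (k = 0..r_max) aggregates pixels whose
    center distance lies in [k - 0.5, k + 0.5); the value is the mean
    intensity, NaN where the annulus is empty.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DomainError("radial_profile expects a 2D image")
    cx, cy = float(center_px[0]), float(center_px[1])
    ny, nx = img.shape
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise DomainError("center lies outside the image")
    r_max = int(r_max_px)
    if r_max < 3:
        raise DomainError("r_max_px must be at least 3")

    yy, xx = np.indices(img.shape)
    r = np.hypot(xx - cx, yy - cy)
    k = np.rint(r).astype(int)          # [k-0.5, k+0.5) binning
    sel = k <= r_max
    sums = np.bincount(k[sel], weights=img[sel], minlength=r_max + 1)
    counts = np.bincount(k[sel], minlength=r_max + 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(radii_px=np.arange(r_max + 1), mean_intensity=means,
                         counts=counts, center_px=(cx, cy),
                         pixel_size_nm=pixel_size_nm)


def _ring_window(intensity: np.ndarray, min_radius_px: int) -> tuple[int, int, int]:
    """Locate the off-center maximum and its half-maximum window.

    Returns (peak index, window start, window stop-inclusive).  Raises
    NoRingError for profiles with no interior maximum above the floor.
    """
    n = intensity.size
    finite = np.isfinite(intensity)
    if finite.sum() < 5:
        raise NoRingError("too few populated annuli for a ring fit")
    floor = np.nanmin(intensity)
    search = intensity.copy()
    search[: min_radius_px + 1] = -np.inf
    search[~finite] = -np.inf
    peak = int(np.nanargmax(search))
    peak_val = intensity[peak]
    if not np.isfinite(peak_val) or peak_val - floor <= 0:
        raise NoRingError("profile has no intensity maximum above its floor")
    if peak >= n - 1:
        raise NoRingError("profile is monotone to its outer edge (no interior ring)")
    half = floor + 0.5 * (peak_val - floor)
    lo = peak
    while lo > 0 and finite[lo - 1] and intensity[lo - 1] >= half:
        lo -= 1
    hi = peak
    while hi < n - 1 and finite[hi + 1] and intensity[hi + 1] >= half:
        hi += 1
    # pad symmetrically to at least 7 samples so the fit is determined
    while hi - lo + 1 < 7:
        if lo > 0:
            lo -= 1
        if hi < n - 1:
            hi += 1
        if lo == 0 and hi == n - 1:
            break
    return peak, lo, hi


def fit_ring_radius(profile: RadialProfile, min_radius_px: int = 2) -> RingFit:
    """Fit a Gaussian-plus-constant to the ring peak of a radial profile.

    The fit window is the contiguous run of annuli around the global
    off-center maximum whose intensity stays above half maximum (relative
    to the profile floor), padded to at least 7 samples.  The fitted
    Gaussian center is the ring radius.  ``converged`` is False when the
    optimizer fails, the center leaves the window, or sigma exceeds the
    window width.
    """
    inten = np.asarray(profile.mean_intensity, dtype=float)
    peak, lo, hi = _ring_window(inten, min_radius_px)
    r = profile.radii_px[lo:hi + 1].astype(float)
    y = inten[lo:hi + 1]
    ok = np.isfinite(y)
    r, y = r[ok], y[ok]

    floor = float(np.nanmin(inten))
    p0 = (float(inten[peak] - floor), float(peak),
          max(1.0, (hi - lo) / GAUSSIAN_FWHM_FACTOR), floor)

    def model(x, amp, mu, sigma, off):
        return off + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)

    converged = True
    try:
        popt, _ = curve_fit(model, r, y, p0=p0, maxfev=10_000)
        amp, mu, sigma, off = popt
        sigma = abs(float(sigma))
        if not (r[0] - 0.5 <= mu <= r[-1] + 0.5) or sigma > (r[-1] - r[0] + 1):
            converged = False
    except RuntimeError:
        amp, mu, sigma, off = p0
        converged = False

    return RingFit(radius_px=float(mu), amplitude=float(amp), sigma_px=float(sigma),
                   offset=float(off),
                   diameter_nm=2.0 * float(mu) * profile.pixel_size_nm,
                   converged=converged, window=(int(lo), int(hi)))


def ring_diameters(image: np.ndarray, centers: np.ndarray,
                   pixel_size_nm: float, r_max_px: int | None = None,
                   min_radius_px: int = 2) -> tuple[pd.DataFrame, dict]:
    """Per-center ring fits plus a mean +/- SD diameter summary.

    ``centers`` is an (n, 2) array of (x, y) pixel coordinates, typically
    a manually picked ROI list.  ``r_max_px`` defaults to the largest
    radius that keeps every annulus inside the image and, with multiple
    centers, below half the minimum center spacing.  Fits that fail to
    converge (or find no ring) are counted and excluded from the summary.
    """
    ctrs = np.atleast_2d(np.asarray(centers, dtype=float))
    if ctrs.size == 0:
        raise DomainError("need at least one ring center")
    ny, nx = image.shape
    if r_max_px is None:
        border = min(ctrs[:, 0].min(), ctrs[:, 1].min(),
                     nx - 1 - ctrs[:, 0].max(), ny - 1 - ctrs[:, 1].max())
        r_max_px = int(border)
        if len(ctrs) > 1:
            from scipy.spatial.distance import pdist
            r_max_px = min(r_max_px, int(pdist(ctrs).min() / 2))
        r_max_px = max(r_max_px, 3)

    rows = []
    n_failed = 0
    for i, (cx, cy) in enumerate(ctrs):
        try:
            prof = radial_profile(image, (cx, cy), r_max_px, pixel_size_nm)
            fit = fit_ring_radius(prof, min_radius_px=min_radius_px)
        except (NoRingError, DomainError):
            n_failed += 1
            rows.append({"center_x_px": cx, "center_y_px": cy,
                         "radius_px": np.nan, "sigma_px": np.nan,
                         "diameter_nm": np.nan, "converged": False})
            continue
        if not fit.converged:
            n_failed += 1
        rows.append({"center_x_px": cx, "center_y_px": cy,
                     "radius_px": fit.radius_px, "sigma_px": fit.sigma_px,
                     "diameter_nm": fit.diameter_nm, "converged": fit.converged})
    table = pd.DataFrame(rows)
    good = table[table["converged"]]
    summary = {
        "n_total": int(len(table)),
        "n_converged": int(len(good)),
        "n_failed": int(n_failed),
        "mean_diameter_nm": float(good["diameter_nm"].mean()) if len(good) else float("nan"),
        "sd_diameter_nm": float(good["diameter_nm"].std(ddof=1)) if len(good) > 1 else 0.0,
    }
    return table, summary


def _half_crossing(x: np.ndarray, y: np.ndarray, peak: int, level: float,
                   direction: int) -> float:
    """Linearly interpolated crossing of ``level`` nearest the peak,
    walking outward in ``direction`` (-1 left, +1 right)."""
    i = peak
    while 0 <= i + direction < len(y):
        j = i + direction
        if y[i] >= level and y[j] < level:
            frac = (y[i] - level) / (y[i] - y[j])
            return float(x[i] + frac * (x[j] - x[i]))
        i = j
    raise UndefinedWidthError("profile never crosses its half-maximum level")


def fwhm(profile: LineProfile) -> ProfileMetrics:
    """Full width at half maximum of a single-peaked line profile.

    The baseline is the mean of the outer 10% of samples on each side
    (at least one sample per side); the half level sits midway between
    baseline and peak.  Crossings are located by linear interpolation at
    the crossing nearest the peak on each side.
    """
    if len(profile) < 5:
        raise DomainError("FWHM needs at least 5 samples")
    y = profile.intensities
    x = profile.positions
    n_edge = max(1, int(round(0.1 * len(y))))
    baseline = float(np.mean(np.concatenate([y[:n_edge], y[-n_edge:]])))
    peak = int(np.argmax(y))
    if peak == 0 or peak == len(y) - 1:
        raise UndefinedWidthError("profile peaks at its boundary")
    if y[peak] <= baseline:
        raise DomainError("peak is not above the baseline")
    level = baseline + 0.5 * (y[peak] - baseline)
    left = _half_crossing(x, y, peak, level, -1)
    right = _half_crossing(x, y, peak, level, +1)
    return ProfileMetrics(fwhm=right - left, peak_to_peak=None,
                          baseline=baseline, n_peaks=1)


def peak_to_peak(profile: LineProfile, min_prominence_frac: float = 0.1,
                 smooth_window: int = 3) -> ProfileMetrics:
    """Distance between the two most prominent peaks of a line profile.

    The profile is smoothed with a centered moving average before peak
    finding; peaks must exceed ``min_prominence_frac`` of the profile's
    intensity range.  Fewer than two qualifying peaks raises
    :class:`NoPairError` (the structure is unresolved).
    """
    y = profile.intensities.astype(float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        y = np.convolve(y, kernel, mode="same")
    rng_span = float(y.max() - y.min())
    if rng_span <= 0:
        raise NoPairError("flat profile has no peaks")
    peaks, props = find_peaks(y, prominence=min_prominence_frac * rng_span)
    if len(peaks) < 2:
        raise NoPairError(f"found {len(peaks)} peak(s); need 2 "
                          "(unresolved two-peak structure)")
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    x = profile.positions
    dist = float(abs(x[top2[0]] - x[top2[1]]))
    return ProfileMetrics(fwhm=None, peak_to_peak=dist,
                          baseline=float(y.min()), n_peaks=int(len(peaks)))


def peak_normalize(profile: LineProfile) -> LineProfile:
    """Divide intensities by their maximum so the peak equals 1."""
    m = float(np.max(profile.intensities))
    if m <= 0:
        raise DomainError("profile maximum must be positive to normalize")
    return LineProfile(positions=profile.positions.copy(),
                       intensities=profile.intensities / m)


def correct_for_expansion(measured: float, ctx: ExpansionContext) -> float:
    """Convert an expanded-scale measurement to pre-expansion dimensions."""
    if measured <= 0:
        raise DomainError("measured length must be positive")
    return measured / ctx.expansion_factor


def local_expansion_factor(measured_expanded_nm: float,
                           ctx: ExpansionContext) -> tuple[float, float]:
    """Local expansion factor of a structure with a known reference size.

    Returns ``(factor, percent_of_expected)`` where factor is the
    measured expanded size divided by the reference size, and
    percent_of_expected compares it to the macroscopic expansion factor.
    Values are full precision; round only at presentation.
    """
    if measured_expanded_nm <= 0:
        raise DomainError("measured size must be positive")
    factor = measured_expanded_nm / ctx.reference_size_nm
    percent = 100.0 * measured_expanded_nm / (ctx.reference_size_nm * ctx.expansion_factor)
    return factor, percent
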