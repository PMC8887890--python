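"""Gel mechanical characterization for expansion microscopy recipes.

Expansion gels trade expansion factor against mechanical integrity: the
softer the gel, the further a semicircular punch stood upright on its
curved edge sags under gravity.  The *deformation index* quantifies this
as the vertical deflection of each gel corner divided by the gel radius
(0 for a rigid gel, approaching 1 for a gel that collapses freely).  The
top edge of each photographed punch is digitized as a handful of points,
a circle is fitted to them, and the corner drop is read off relative to
the topmost point of the fitted circle.

The *expansion factor* is the diameter of a fully expanded gel specimen
divided by the diameter of the punch used to cast it (6 mm by default).
Recipe families (fixed monomer/initiator composition, crosslinker varied)
are summarized as per-concentration mean +/- SD curves of both quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "GelEdgePointSet",
    "CircleFit",
    "DeformationResult",
    "ExpansionMeasurement",
    "fit_circle",
    "deformation_index",
    "classify_handling",
    "expansion_factor",
    "recipe_curves",
    "HANDLING_EXCELLENT_MAX",
    "HANDLING_ACCEPTABLE_MAX",
]

#: Deformation-index thresholds separating handling classes.  Gels below
#: 0.125 handle excellently, up to 0.25 acceptably, above that they are
#: too soft to handle without breaking.
HANDLING_EXCELLENT_MAX = 0.125
HANDLING_ACCEPTABLE_MAX = 0.25

#: Fitted curvature (1/mm) below which an edge is treated as straight.
_DEGENERATE_CURVATURE = 1e-6


@dataclass(frozen=True)
class GelEdgePointSet:
    """Digitized points along the top edge of an upright gel punch.

    Parameters
    ----------
    points
        ``(n, 2)`` array of (x, y) coordinates in mm, ordered along the
        edge.  The y axis is the vertical (gravity) axis, pointing up.
    gel_radius_mm
        Radius of the semicircular punch at the photographed scale.
    """

    points: np.ndarray
    gel_radius_mm: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise DomainError("edge needs at least 3 (x, y) points")
        if not np.all(np.isfinite(pts)):
            raise DomainError("edge points must be finite")
        if self.gel_radius_mm <= 0:
            raise DomainError("gel_radius_mm must be positive")
        order = np.argsort(pts[:, 0], kind="stable")
        pts = pts[order]
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise DomainError("x coordinates must be strictly monotone after sorting")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class CircleFit:
    """Least-squares circle through edge points (algebraic Kasa fit)."""

    center: tuple[float, float]
    radius_mm: float
    rms_residual_mm: float
    is_degenerate: bool = False


@dataclass(frozen=True)
class DeformationResult:
    """Deformation index of one gel punch.

    ``index_left``/``index_right`` are the per-corner vertical drops below
    the fitted-circle apex, divided by the gel radius and clamped at 0;
    ``index_mean`` is their mean, which is the per-gel statistic used for
    handling classification.
    """

    index_left: float
    index_right: float
    index_mean: float
    circle: CircleFit
    handling_class: str


@dataclass(frozen=True)
class ExpansionMeasurement:
    expanded_diameter_mm: float
    initial_diameter_mm: float = 6.0
    expansion_factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.expanded_diameter_mm <= 0 or self.initial_diameter_mm <= 0:
            raise DomainError("diameters must be positive")
        object.__setattr__(
            self,
            "expansion_factor",
            self.expanded_diameter_mm / self.initial_diameter_mm,
        )


def _collinearity(points: np.ndarray) -> float:
    """Max perpendicular distance to the chord, normalized by chord length."""
    a, b = points[0], points[-1]
    chord = b - a
    span = np.hypot(*chord)
    if span == 0:
        return 0.0
    # 2D cross-product magnitude / chord length = perpendicular distance
    rel = points - a
    d = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / span
    return float(d.max() / span)


def fit_circle(edge: GelEdgePointSet | np.ndarray) -> CircleFit:
    """Fit a circle to edge points by linearized (Kasa) least squares.

    The algebraic formulation ``x^2 + y^2 = 2 a x + 2 b y + c`` is linear
    in (a, b, c) and solved in closed form; center = (a, b) and radius =
    sqrt(c + a^2 + b^2).  Near-straight edges (fitted curvature below
    1e-6 per mm, or points collinear to within 1e-9 of the chord length)
    are flagged degenerate rather than failing.
    """
    pts = edge.points if isinstance(edge, GelEdgePointSet) else np.asarray(edge, float)
    if pts.shape[0] < 3:
        raise DomainError("circle fit needs at least 3 points")
    x, y = pts[:, 0], pts[:, 1]

    if _collinearity(pts) < 1e-9:
        return CircleFit(center=(np.nan, np.nan), radius_mm=np.inf,
                         rms_residual_mm=0.0, is_degenerate=True)

    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x * x + y * y
    (a, b, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    r2 = c + a * a + b * b
    if r2 <= 0 or not np.isfinite(r2):
        return CircleFit(center=(float(a), float(b)), radius_mm=np.inf,
                         rms_residual_mm=np.nan, is_degenerate=True)
    radius = float(np.sqrt(r2))
    if 1.0 / radius < _DEGENERATE_CURVATURE:
        return CircleFit(center=(float(a), float(b)), radius_mm=radius,
                         rms_residual_mm=np.nan, is_degenerate=True)
    dist = np.hypot(x - a, y - b)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return CircleFit(center=(float(a), float(b)), radius_mm=radius,
                     rms_residual_mm=rms, is_degenerate=False)


def deformation_index(edge: GelEdgePointSet) -> DeformationResult:
    """Deformation index of a digitized gel top edge.

    The corners are the first and last digitized points by x.  The apex is
    the topmost point of the circle fitted through all points
    (center_y + radius).  Each corner index is the apex-to-corner vertical
    drop divided by the gel radius, clamped at zero; a degenerate
    (straight) fit yields index 0 for both corners.
    """
    circle = fit_circle(edge)
    if circle.is_degenerate:
        left = right = 0.0
    else:
        apex_y = circle.center[1] + circle.radius_mm
        y_left = edge.points[0, 1]
        y_right = edge.points[-1, 1]
        left = max(0.0, (apex_y - y_left) / edge.gel_radius_mm)
        right = max(0.0, (apex_y - y_right) / edge.gel_radius_mm)
    mean = 0.5 * (left + right)
    return DeformationResult(
        index_left=float(left),
        index_right=float(right),
        index_mean=float(mean),
        circle=circle,
        handling_class=classify_handling(mean),
    )


def classify_handling(index: float) -> str:
    """Map a deformation index onto a handling class.

    [0, 0.125) -> ``excellent``; [0.125, 0.25] -> ``acceptable``;
    above 0.25 -> ``unacceptable``.
    """
    if index < 0:
        raise DomainError("deformation index cannot be negative")
    if index < HANDLING_EXCELLENT_MAX:
        return "excellent"
    if index <= HANDLING_ACCEPTABLE_MAX:
        return "acceptable"
    return "unacceptable"


def expansion_factor(expanded_diameter_mm: float,
                     initial_diameter_mm: float = 6.0) -> ExpansionMeasurement:
    """Expansion factor of a gel specimen: expanded / initial diameter."""
    return ExpansionMeasurement(expanded_diameter_mm, initial_diameter_mm)


def recipe_curves(measurements: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-gel measurements into recipe-family summary curves.

    Parameters
    ----------
    measurements
        Table with columns ``family_id``, ``crosslinker_ug_per_ml``,
        ``expansion_factor`` and ``deformation_index``; one row per gel
        replicate.

    Returns
    -------
    One row per (family, crosslinker concentration) group with mean and
    sample SD of both quantities, replicate count ``n``, and a
    ``single_replicate`` flag (SD reported as 0 when n = 1).  Groups are
    ordered by crosslinker concentration within family.
    """
    required = {"family_id", "crosslinker_ug_per_ml",
                "expansion_factor", "deformation_index"}
    if measurements is None or len(measurements) == 0:
        raise DomainError("measurement table is empty")
    missing = required - set(measurements.columns)
    if missing:
        raise DomainError(f"measurement table missing columns: {sorted(missing)}")

    grouped = measurements.groupby(["family_id", "crosslinker_ug_per_ml"], sort=True)
    rows = []
    for (family, conc), g in grouped:
        n = len(g)
        rows.append({
            "family_id": family,
            "crosslinker_ug_per_ml": conc,
            "expansion_mean": g["expansion_factor"].mean(),
            "expansion_sd": g["expansion_factor"].std(ddof=1) if n > 1 else 0.0,
            "deformation_mean": g["deformation_index"].mean(),
            "deformation_sd": g["deformation_index"].std(ddof=1) if n > 1 else 0.0,
            "n": n,
            "single_replicate": n == 1,
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["family_id", "crosslinker_ug_per_ml"]).reset_index(drop=True)
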