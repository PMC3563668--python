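"""Tissue surface tension from parallel-plate compression data.

An aggregate squeezed between two plates relaxes, over minutes, to the shape
and force of a liquid drop: the equilibrium plate force obeys the Laplace
relation

    F = sigma * pi * R3^2 * (1/R2 + 1/R3)

with R3 the equatorial radius and R2 the radius of curvature of the side
profile at the equator (both curvature centres inside the drop, so a convex
compressed drop has R2 > 0 and sigma > 0).  The pipeline is

    image -> contour -> (R2, R3) -> plateau force -> sigma

with :func:`sigma_single` for one compression and :func:`sigma_slope`
pooling several compressions of one aggregate as the regression slope of F
against pi*R3^2*(1/R2 + 1/R3).  The estimate is valid up to ~50%
compression and independent of aggregate size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import units

__all__ = [
    "AggregateProfile",
    "CompressionRecord",
    "PlateauResult",
    "extract_contour",
    "fit_profile_radii",
    "detect_plateau",
    "sigma_single",
    "sigma_slope",
]


@dataclass
class AggregateProfile:
    """Side-view contour (µm) with fitted principal radii R2, R3 (µm)."""

    contour: np.ndarray
    R2: float
    R3: float

    def __post_init__(self) -> None:
        if self.R2 <= 0 or self.R3 <= 0:
            raise ValueError("principal radii must be positive")


@dataclass
class CompressionRecord:
    """One compression: fitted profile, force trace and its plateau."""

    profile: AggregateProfile
    force_trace: np.ndarray
    plateau_force: float
    compression_fraction: float = 0.0
    warnings: list[str] = field(default_factory=list)


@dataclass
class PlateauResult:
    force: float           # µN
    slope: float           # µN/s on the tail segment
    converged: bool        # |slope| < slope_tol

    def __float__(self) -> float:
        return self.force


def extract_contour(
    image: np.ndarray,
    pixel_size_um: float = 1.0,
    *,
    invert: bool = False,
    level: float | None = None,
) -> np.ndarray:
    """Sub-pixel closed contour (µm) of a single bright-on-dark object.

    Thresholds with Otsu (or a supplied ``level``), requires exactly one
    connected object, and traces its boundary with marching squares.
    Returns an (N, 2) array of (x, y) in µm, counter-clockwise.
    """
    from skimage import measure
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if invert:
        img = img.max() - img
    if img.max() == img.min():
        raise ValueError("blank image: no object to segment")
    thr = level if level is not None else threshold_otsu(img)
    mask = img > thr
    labels, n_obj = measure.label(mask, return_num=True)
    if n_obj == 0:
        raise ValueError("no object found in image")
    if n_obj > 1:
        # tolerate speck noise: demand one dominant object
        sizes = np.bincount(labels.ravel())[1:]
        if np.sort(sizes)[-2] > 0.01 * sizes.max():
            raise ValueError(f"{n_obj} objects found; expected one")
        mask = labels == (np.argmax(sizes) + 1)
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)  # outer boundary
    # rows are y, columns are x; convert to (x, y) µm
    xy = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size_um
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if _signed_area(xy) < 0:
        xy = xy[::-1]
    return xy


def _signed_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def fit_profile_radii(
    contour: np.ndarray,
    plate_gap: float,
    poly_order: int = 4,
    window: float | None = None,
) -> AggregateProfile:
    """Principal radii of a compressed-drop side profile.

    R3 is the maximal half-width of the contour about its symmetry axis;
    R2 comes from a local polynomial fit of the side walls around the
    equator: both walls are folded onto |x|(z) (doubling the usable points)
    and fitted over a window of arc length ``window`` (default one third of
    the side-wall arc, ~ pi*gap/6 on the barrel); the curvature at the
    equator gives R2 = -1/|x|''(0) for the convex wall.  The default
    quartic order cancels the leading truncation bias a quadratic fit
    suffers on a circular arc, and the wide window keeps the curvature
    stable under contour noise.

    The contour must span the plate gap; a non-convex equator (x'' >= 0)
    raises.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or len(pts) < 10:
        raise ValueError("contour must be an (N>=10, 2) array")
    x0 = pts[:, 0].mean()
    z0 = pts[:, 1].mean()
    x = pts[:, 0] - x0
    z = pts[:, 1] - z0
    span = z.max() - z.min()
    if span < 0.9 * plate_gap:
        raise ValueError("contour does not span the plate gap")
    r3 = float(x.max())
    if r3 <= 0:
        raise ValueError("degenerate contour: no width")
    if window is None:
        window = math.pi * plate_gap / 6.0
    # both side walls near the equator (z ~ 0), folded onto |x|: fit |x|(z)
    half_w = max(window / 2.0, plate_gap * 0.05)
    ax = np.abs(x)
    sel = (ax > 0.5 * r3) & (np.abs(z) <= half_w)
    if sel.sum() < max(poly_order + 2, 5):
        sel = (ax > 0.5 * r3) & (np.abs(z) <= plate_gap / 4.0)
    if sel.sum() < poly_order + 2:
        raise ValueError("too few side-wall points in the fitting window")
    coeffs = np.polynomial.polynomial.polyfit(z[sel], ax[sel], poly_order)
    # curvature of the graph x(z) at z = 0
    d1 = coeffs[1] if poly_order >= 1 else 0.0
    d2 = 2.0 * coeffs[2] if poly_order >= 2 else 0.0
    kappa = d2 / (1.0 + d1 ** 2) ** 1.5
    if kappa >= 0:
        raise ValueError("non-convex side profile at the equator")
    r2 = -1.0 / kappa
    return AggregateProfile(contour=pts, R2=float(r2), R3=r3)


def detect_plateau(
    force_trace: np.ndarray,
    tail_fraction: float = 0.2,
    slope_tol: float = 1e-3,
) -> PlateauResult:
    """Equilibrium force as the mean of the terminal trace segment.

    The last ``tail_fraction`` of samples is accepted as a plateau when the
    magnitude of its fitted linear slope is below ``slope_tol`` (µN/s).
    When the slope never settles — e.g. a drug-stiffened aggregate whose
    force keeps creeping — a warning is emitted and the tail mean is still
    returned, flagged ``converged=False``.
    """
    trace = np.asarray(force_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2 or len(trace) < 20:
        raise ValueError("force trace must be an (N>=20, 2) array of (t, F)")
    t, f = trace[:, 0], trace[:, 1]
    n_tail = max(int(len(t) * tail_fraction), 10)
    tt, ff = t[-n_tail:], f[-n_tail:]
    slope = float(np.polyfit(tt, ff, 1)[0]) if np.ptp(tt) > 0 else 0.0
    converged = abs(slope) < slope_tol
    if not converged:
        warnings.warn(
            f"force trace has no plateau (tail slope {slope:.3g} µN/s); "
            "returning tail mean anyway",
            stacklevel=2,
        )
    return PlateauResult(force=float(ff.mean()), slope=slope, converged=converged)


def _laplace_abscissa_uN_per_mN_m(profile: AggregateProfile) -> float:
    """pi*R3^2*(1/R2 + 1/R3) expressed so that F[µN] = sigma[mN/m] * x."""
    return units.laplace_force_uN(1.0, profile.R2, profile.R3)


def sigma_single(F: float, profile: AggregateProfile) -> float:
    """Surface tension (mN/m) from one plateau force (µN) and profile."""
    if F < 0:
        raise ValueError("plateau force must be non-negative")
    return units.sigma_from_laplace_uN(F, profile.R2, profile.R3)


def sigma_slope(
    records: list[CompressionRecord],
    *,
    through_origin: bool = False,
) -> tuple[float, float]:
    """Surface tension from several compressions of one aggregate.

    Ordinary least-squares slope of plateau force against
    pi*R3^2*(1/R2 + 1/R3) across records; returns ``(sigma, ci95)`` in
    mN/m, the half-width being the 95% confidence interval of the slope
    (t-distribution).  With fewer than 3 records the CI is reported as 0
    (slope exact through 2 points).  ``through_origin`` constrains the
    intercept to zero.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 compression records")
    x = np.array([_laplace_abscissa_uN_per_mN_m(r.profile) for r in records])
    y = np.array([r.plateau_force for r in records])
    if np.ptp(x) == 0 and not through_origin:
        raise ValueError("identical abscissae: slope fit is degenerate")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        resid = y - slope * x
        dof = len(x) - 1
        if dof > 0 and np.any(resid != 0):
            se = math.sqrt(float(np.sum(resid ** 2)) / dof / float(np.sum(x * x)))
            ci95 = float(stats.t.ppf(0.975, dof)) * se
        else:
            ci95 = 0.0
        return slope, ci95
    if len(records) == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        return slope, 0.0
    res = stats.linregress(x, y)
    dof = len(x) - 2
    ci95 = float(stats.t.ppf(0.975, dof)) * res.stderr if dof > 0 else 0.0
    return float(res.slope), ci95
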