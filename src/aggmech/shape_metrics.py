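"""Contact angles and contour rugosity of aggregate cross-sections.

Two geometric readouts complement tensiometry and fusion:

* the contact angle theta at a cell/cell/medium triple junction — the angle
  between the two cell–medium tangents at the junction — which feeds the
  Young balance gamma_cc = 2*gamma_cm*cos(theta/2);
* the rugosity of a whole-aggregate outline: the area enclosed between the
  contour and a smooth trend fitted to it, per unit contour length (µm).
  Smooth, liquid-like tissues (angles near 180°) are expected to be less
  rugose than tissues whose cells bulge individually.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RugosityResult",
    "measure_angle",
    "rugosity",
    "angle_rugosity_consistency",
]


@dataclass
class RugosityResult:
    """Mean |contour - smooth fit| area per unit arc length, in µm."""

    roughness: float
    n_regions: int
    region_sizes: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _arc_lengths(contour: np.ndarray) -> np.ndarray:
    d = np.diff(contour, axis=0, append=contour[:1])
    return np.hypot(d[:, 0], d[:, 1])


def measure_angle(
    contour: np.ndarray,
    vertex_hint: np.ndarray | tuple[float, float],
    tangent_window: float = 10.0,
    method: str = "circle",
) -> float:
    """Contact angle (degrees) at a triple junction on a closed contour.

    The contour point nearest ``vertex_hint`` is taken as the vertex; the
    two branches leaving it are followed for ``tangent_window`` µm of arc
    length each, a tangent is estimated per branch, and the angle between
    the two away-from-vertex tangent directions is returned.

    ``method`` selects the tangent estimator per branch:

    * ``"circle"`` (default): algebraic circle fit (Pratt); exact for
      circular-arc branches of any curvature, so the window size does not
      bias the angle.
    * ``"line"``: total-least-squares line; simple but biased by ~w/(2*rho)
      on a branch of radius rho.

    Raises when either branch resolves fewer than 5 points.
    """
    pts = np.asarray(contour, dtype=float)
    hint = np.asarray(vertex_hint, dtype=float)
    n = len(pts)
    if n < 12:
        raise ValueError("contour too short to resolve two branches")
    iv = int(np.argmin(np.sum((pts - hint) ** 2, axis=1)))
    vertex = pts[iv]

    def branch(direction: int) -> np.ndarray:
        # walk until the Euclidean distance from the vertex exceeds the
        # window; robust to noise-inflated polygon arc length
        out, i = [], iv
        for _ in range(n // 2 - 1):
            i = (i + direction) % n
            if np.linalg.norm(pts[i] - vertex) > tangent_window:
                break
            out.append(pts[i])
        return np.asarray(out)

    fwd, bwd = branch(+1), branch(-1)
    if len(fwd) < 5 or len(bwd) < 5:
        raise ValueError("fewer than 5 points per branch in the tangent window")
    d1 = _branch_tangent(fwd, vertex, method)
    d2 = _branch_tangent(bwd, vertex, method)
    cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def _branch_tangent(branch: np.ndarray, vertex: np.ndarray, method: str) -> np.ndarray:
    """Unit tangent at the vertex, oriented away from it along the branch."""
    pts = np.vstack([vertex, branch])
    away = branch.mean(axis=0) - vertex
    if method == "line":
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        d = vt[0]
    elif method == "circle":
        d = _circle_tangent(pts, vertex)
    else:
        raise ValueError(f"unknown tangent method {method!r}")
    if np.dot(d, away) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _circle_tangent(pts: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Tangent at ``at`` of the geometric least-squares circle through pts.

    A linear (Kåsa) solve seeds a geometric refinement minimising the
    orthogonal residuals |p - centre| - radius; the algebraic solve alone
    is biased toward small circles on noisy short arcs.  Falls back to the
    principal direction when the points are essentially collinear.
    """
    from scipy.optimize import least_squares

    x, y = pts[:, 0] - at[0], pts[:, 1] - at[1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    (cx, cy, t), *_ = np.linalg.lstsq(A, b, rcond=None)
    rho2 = t + cx ** 2 + cy ** 2
    span = max(np.ptp(x), np.ptp(y))
    if rho2 <= 0 or math.sqrt(rho2) > 1e4 * span:
        # effectively straight: principal direction of the branch
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        return vt[0]

    def resid(p):
        return np.hypot(x - p[0], y - p[1]) - p[2]

    sol = least_squares(resid, [cx, cy, math.sqrt(rho2)], method="lm")
    cx, cy = sol.x[0], sol.x[1]
    radial = -np.array([cx, cy])  # from centre to the vertex (origin here)
    nrm = np.linalg.norm(radial)
    if nrm == 0:
        raise ValueError("vertex coincides with fitted circle centre")
    radial /= nrm
    return np.array([-radial[1], radial[0]])


# --------------------------------------------------------------------------
# rugosity
# --------------------------------------------------------------------------

def _exp_basis(u: np.ndarray) -> np.ndarray:
    """Low-order exponential trend basis {1, exp(u), exp(-u)} on u ~ [-1, 1]."""
    return np.column_stack([np.ones_like(u), np.exp(u), np.exp(-u)])


def rugosity(
    contour: np.ndarray,
    fit_model: str = "exp",
    region_lengths: list[tuple[int, int]] | None = None,
    exclude: list[tuple[int, int]] | None = None,
) -> RugosityResult:
    """Contour roughness as area deviation from a smooth fit per unit length.

    The contour is expressed as radius vs angle about its centroid and cut
    into regions (index ranges; default: one region spanning the whole
    contour).  Per region a smooth trend is fitted — ``"exp"`` uses the
    exponential basis {1, e^u, e^-u} on the normalised angular coordinate,
    absorbing slow drifts of the radius but not cell-scale texture — and
    the area between contour and fit, sum |r - fit| * ds, is divided by the
    region arc length.  The result averages regions weighted by length.

    ``exclude`` lists index ranges to mask out (e.g. debris or dead cells
    on the outline).  Regions whose fit is degenerate are skipped with a
    warning.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or len(pts) < 20:
        raise ValueError("contour must be an (N>=20, 2) array")
    centre = pts.mean(axis=0)
    rel = pts - centre
    r = np.hypot(rel[:, 0], rel[:, 1])
    phi = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    ds = _arc_lengths(pts)

    n = len(pts)
    regions = region_lengths if region_lengths else [(0, n)]
    excluded = np.zeros(n, dtype=bool)
    for a, b in exclude or []:
        excluded[a:b] = True

    areas, lengths, sizes, warns = [], [], [], []
    for a, b in regions:
        sel = np.arange(a, min(b, n))
        sel = sel[~excluded[sel]]
        if len(sel) < 20:
            warns.append(f"region ({a},{b}) has <20 usable points; skipped")
            continue
        u = phi[sel]
        span = u.max() - u.min()
        if span == 0:
            warns.append(f"region ({a},{b}) degenerate angular span; skipped")
            continue
        u = 2.0 * (u - u.min()) / span - 1.0
        if fit_model == "exp":
            B = _exp_basis(u)
        elif fit_model == "poly":
            B = np.column_stack([np.ones_like(u), u, u ** 2])
        else:
            raise ValueError(f"unknown fit model {fit_model!r}")
        coef, *_ = np.linalg.lstsq(B, r[sel], rcond=None)
        fit = B @ coef
        if not np.all(np.isfinite(fit)):
            warns.append(f"region ({a},{b}) fit degenerate; skipped")
            continue
        dev = np.abs(r[sel] - fit)
        length = float(ds[sel].sum())
        areas.append(float(np.sum(dev * ds[sel])))
        lengths.append(length)
        sizes.append(length)
    for w in warns:
        warnings.warn(w, stacklevel=2)
    if not areas:
        raise ValueError("no usable region for the rugosity fit")
    roughness = float(sum(areas) / sum(lengths))
    return RugosityResult(
        roughness=roughness, n_regions=len(areas), region_sizes=sizes,
        warnings=warns,
    )


def angle_rugosity_consistency(
    cond_a: tuple[float, float], cond_b: tuple[float, float]
) -> tuple[bool, str]:
    """Check that the higher-angle condition is the smoother one.

    Each condition is (theta degrees, roughness µm).  Liquid-like tissues
    with near-180° contact angles should present the lower rugosity; equal
    angles are vacuously consistent.  Returns (consistent, report).
    """
    (ta, ra), (tb, rb) = cond_a, cond_b
    if ta == tb:
        return True, "equal angles: vacuously consistent"
    hi_angle, lo_angle = (cond_a, cond_b) if ta > tb else (cond_b, cond_a)
    ok = hi_angle[1] <= lo_angle[1]
    report = (
        f"theta={hi_angle[0]:.1f}° roughness={hi_angle[1]:.3g} µm vs "
        f"theta={lo_angle[0]:.1f}° roughness={lo_angle[1]:.3g} µm: "
        + ("consistent" if ok else "inconsistent")
    )
    return ok, report
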