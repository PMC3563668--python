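"""Tissue viscosity and fluidity from aggregate-fusion kinetics.

When two aggregates of radius R0 touch, surface tension drives coalescence
against viscous dissipation.  In the initial regime the neck radius r obeys
the corrected viscous-sintering (Frenkel) law, with no numerical prefactor:

    r(t)^2 = (sigma/eta) * R0 * t,      valid for r/R0 <~ 0.5

so the slope of r^2 against R0*t is the visco-capillary velocity v =
sigma/eta.  Combined with an independently measured surface tension this
yields the tissue viscosity eta = sigma/v and fluidity 1/eta.

:func:`measure_neck` extracts r per frame from binary time-lapse images;
:func:`fit_frenkel` fits the law; :func:`temperature_trend` quantifies how v
changes with temperature (active, contractility-driven tissues speed up with
T; contractility-dead ones do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import units

__all__ = [
    "FusionSeries",
    "ViscoCapillaryResult",
    "measure_neck",
    "fit_frenkel",
    "viscosity_from",
    "fluidity_from",
    "temperature_trend",
]


@dataclass
class FusionSeries:
    """Timestamped neck radii of one fusing pair.

    times in min (strictly increasing), neck radii r in µm, R0 the initial
    aggregate radius in µm (mean of the two lobes for slightly unequal
    pairs).  ``flags`` marks frames whose neck could not be measured
    (disconnected lobes -> r = 0 recorded).
    """

    times: np.ndarray
    radii: np.ndarray
    R0: float
    temperature: float | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.radii < 0):
            raise ValueError("neck radii must be non-negative")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


@dataclass
class ViscoCapillaryResult:
    """Fitted visco-capillary velocity and derived material parameters."""

    v: float                 # µm/min
    ci95: float              # µm/min
    intercept: float         # µm², reported but not constrained
    window_used: tuple[int, int]
    n_used: int
    eta: float | None = None        # Pa·s, when sigma supplied
    fluidity: float | None = None   # (Pa·s)^-1


def measure_neck(
    frames: list[np.ndarray],
    pixel_size_um: float = 1.0,
    times: np.ndarray | None = None,
) -> FusionSeries:
    """Neck radii from binary frames of a two-lobed fusing object.

    Per frame the object's pixels are projected onto their principal axis;
    the width profile across that axis has a maximum in each lobe and the
    neck is half the minimal width between the two lobe maxima.  A frame
    whose lobes are disconnected records r = 0 with a flag; an empty frame
    raises.  R0 comes from the first frame's area (two discs: A = 2*pi*R0^2).
    """
    from skimage import measure as skmeasure

    radii, flags = [], []
    R0 = None
    for i, frame in enumerate(frames):
        mask = np.asarray(frame) > 0
        if not mask.any():
            raise ValueError(f"frame {i} is empty")
        labels, n_obj = skmeasure.label(mask, return_num=True)
        if i == 0:
            area_um2 = mask.sum() * pixel_size_um ** 2
            R0 = math.sqrt(area_um2 / (2.0 * math.pi))
        if n_obj > 1:
            radii.append(0.0)
            flags.append(True)
            continue
        radii.append(_neck_half_width(mask) * pixel_size_um)
        flags.append(False)
    t = np.asarray(times, dtype=float) if times is not None else np.arange(len(frames), dtype=float)
    return FusionSeries(
        times=t, radii=np.array(radii), R0=float(R0), flags=np.array(flags)
    )


def _neck_half_width(mask: np.ndarray) -> float:
    """Half the minimal width across the lobe–lobe axis, in pixels.

    The pixel-column width profile is coarse where the union of two discs
    necks down steeply, so after locating the minimum column the squared
    width — which grows linearly in |axial distance| around the neck of two
    overlapping discs — is refined by intersecting line fits to its two
    branches, giving a sub-pixel neck estimate.
    """
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    pts -= pts.mean(axis=0)
    # principal axis via PCA of pixel coordinates
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    u = pts @ vt[0]   # along the lobe axis
    # 1-px bins along the axis; counts = column height for a convex union
    bins = np.floor(u - u.min()).astype(int)
    # a column spanning height h contains ~h+1 pixel centres
    widths = np.clip(np.bincount(bins).astype(float) - 1.0, 0.0, None)
    n_bins = len(widths)
    # lobe centres: width maxima in each half
    mid = n_bins // 2
    left_peak = int(np.argmax(widths[:mid]))
    right_peak = mid + int(np.argmax(widths[mid:]))
    if right_peak - left_peak < 2:
        return float(np.min(widths) / 2.0)
    interior = slice(left_peak, right_peak + 1)
    i0 = left_peak + int(np.argmin(widths[interior]))
    # refine: fit w^2 = a + b*x on each side of the minimum and intersect
    k = max(3, (right_peak - left_peak) // 10)
    li, ri = max(i0 - k, left_peak), min(i0 + k, right_peak)
    xl, xr = np.arange(li, i0), np.arange(i0 + 1, ri + 1)
    if len(xl) >= 2 and len(xr) >= 2:
        bl, al = np.polyfit(xl, widths[xl] ** 2, 1)
        br, ar = np.polyfit(xr, widths[xr] ** 2, 1)
        if br > bl:  # branches must open away from the minimum
            x_star = (al - ar) / (br - bl)
            w2 = al + bl * x_star
            if li <= x_star <= ri and w2 >= 0:
                return float(math.sqrt(w2) / 2.0)
    return float(widths[i0] / 2.0)


def fit_frenkel(
    series: FusionSeries, r_over_R_max: float = 0.5
) -> ViscoCapillaryResult:
    """Fit r^2 = v * R0 * t over the initial regime.

    Frames with r/R0 <= ``r_over_R_max`` (and not flagged) enter an
    unweighted linear fit of r^2 against R0*t with a free intercept; the
    slope is the visco-capillary velocity v (µm/min) with a 95% confidence
    interval from the regression.  Fewer than 4 admitted frames raise.
    """
    r = series.radii
    ok = r <= r_over_R_max * series.R0 * (1.0 + 1e-12)
    if series.flags is not None:
        ok &= ~series.flags
    idx = np.nonzero(ok)[0]
    if len(idx) < 4:
        raise ValueError(
            f"only {len(idx)} frames with r/R0 <= {r_over_R_max}; need >= 4"
        )
    x = series.R0 * series.times[idx]
    y = r[idx] ** 2
    res = stats.linregress(x, y)
    dof = len(idx) - 2
    ci95 = float(stats.t.ppf(0.975, dof)) * res.stderr if dof > 0 else 0.0
    return ViscoCapillaryResult(
        v=float(res.slope),
        ci95=ci95,
        intercept=float(res.intercept),
        window_used=(int(idx[0]), int(idx[-1])),
        n_used=int(len(idx)),
    )


def viscosity_from(sigma: float, v: float) -> float:
    """eta = sigma/v in Pa·s, sigma in mN/m and v in µm/min.

    sigma = 0 gives eta = 0; v <= 0 raises.
    """
    if v <= 0:
        raise ValueError("visco-capillary velocity must be positive")
    if sigma == 0:
        return 0.0
    return units.viscosity_Pa_s(sigma, v)


def fluidity_from(sigma: float, v: float) -> float:
    """Fluidity v/sigma = 1/eta in (Pa·s)^-1; v = 0 returns 0 (degenerate)."""
    if v == 0:
        return 0.0
    if sigma <= 0:
        raise ValueError("sigma must be positive for a finite fluidity")
    return 1.0 / units.viscosity_Pa_s(sigma, v)


def temperature_trend(
    results: list[tuple[float, float]]
) -> tuple[float, float]:
    """Percent change of v per degree, from a linear fit of v against T.

    ``results`` is a list of (temperature °C, v µm/min) with at least 3
    distinct temperatures.  Returns ``(slope_percent_per_degree, ci95)``
    where the slope is normalised by the fitted v at the mid-range
    temperature.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 temperature points")
    T = np.array([p[0] for p in results], dtype=float)
    v = np.array([p[1] for p in results], dtype=float)
    if np.ptp(T) == 0:
        raise ValueError("temperatures are all identical")
    res = stats.linregress(T, v)
    t_mid = 0.5 * (T.min() + T.max())
    v_mid = res.intercept + res.slope * t_mid
    if v_mid == 0:
        raise ValueError("fitted v vanishes at mid-range temperature")
    dof = len(T) - 2
    ci95 = float(stats.t.ppf(0.975, dof)) * res.stderr if dof > 0 else 0.0
    return 100.0 * res.slope / v_mid, 100.0 * ci95 / abs(v_mid)
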