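"""Synthetic aggregate-mechanics data with known ground truth.

Every downstream stage of the pipeline (tensiometry, fusion kinetics, shape
metrics, condition reports) is exercised on data produced here, so each
generator embeds the physical law its analysis counterpart inverts:

* :func:`gen_compressed_aggregate` — a liquid drop of tension sigma squeezed
  between parallel plates.  The side wall is the circular-arc ("barrel")
  approximation of the Young–Laplace profile, tangent to both plates, with
  the equatorial radius R3 fixed by volume conservation; the plate force
  relaxes exponentially to the Laplace plateau sigma*pi*R3^2*(1/R2+1/R3).
* :func:`gen_fusion_sequence` — two coalescing spheres whose neck follows the
  prefactor-free viscous-sintering law r^2 = (sigma/eta)*R0*t in the initial
  regime (r/R0 <= 0.5).
* :func:`gen_doublet` — a two-cell cross-section whose triple-junction angle
  obeys the Young balance theta = 2*arccos(gamma_cc / (2*gamma_cm)).
* :func:`gen_rough_contour` — a closed contour with controlled radial
  roughness, r(phi) = R + sum_k a_k cos(k*phi + phi_k).
* :func:`gen_force_relaxation` — a bare exponential force trace for plateau
  detection.

Measurement noise is additive Gaussian on contour coordinates and scalar
readouts.  All randomness flows through ``numpy.random.default_rng(seed)``:
identical seed and parameters reproduce outputs bit-exactly.  Contours are
(N, 2) arrays in µm, ordered counter-clockwise, implicitly closed (the first
point is not repeated).  Force traces are (N, 2) arrays of (t in s, F in µN).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import units

__all__ = [
    "GroundTruth",
    "SyntheticCompression",
    "SyntheticFusion",
    "SyntheticDoublet",
    "gen_compressed_aggregate",
    "gen_compression_series",
    "gen_fusion_sequence",
    "render_fusion_frame",
    "gen_doublet",
    "gen_rough_contour",
    "harmonic_contour",
    "gen_force_relaxation",
    "barrel_geometry",
    "sphere_radius_from_volume",
    "write_contour_csv",
    "read_contour_csv",
    "write_force_csv",
    "read_force_csv",
    "write_truth_json",
]


# --------------------------------------------------------------------------
# ground truth & containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Generator-side parameters of one synthetic condition.

    Tensions in mN/m, viscosity in Pa·s, angle in degrees, roughness in µm
    (area deviation per unit contour length).  Fields that a particular
    generator does not use stay ``None``.
    """

    sigma: float | None = None
    eta: float | None = None
    gamma_cm: float | None = None
    gamma_cc: float | None = None
    theta: float | None = None
    roughness: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.eta is not None and self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.theta is not None and not 0 <= self.theta <= 180:
            raise ValueError("theta must lie in [0, 180] degrees")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("sigma", "eta", "gamma_cm", "gamma_cc", "theta",
                      "roughness", "seed")
            if getattr(self, k) is not None or k == "seed"
        }


@dataclass
class SyntheticCompression:
    """One parallel-plate compression of a synthetic aggregate.

    ``contour`` is the side-view cross-section through the symmetry axis
    (x = radial, y = axial, µm); ``force_trace`` is (t s, F µN).  ``r2_um``
    (side-arc radius), ``r3_um`` (equatorial radius) and ``plateau_uN`` are
    the noise-free shape parameters and Laplace plateau of the generated
    barrel, kept for round-trip checks.
    """

    contour: np.ndarray
    force_trace: np.ndarray
    plate_gap: float
    volume: float
    truth: GroundTruth
    r2_um: float = 0.0
    r3_um: float = 0.0
    plateau_uN: float = 0.0
    compression_fraction: float = 0.0


@dataclass
class SyntheticFusion:
    """A fusion time-lapse: neck radii (µm) at given times (min).

    ``images`` is an optional list of rendered binary frames (uint8 arrays)
    with pixel size ``pixel_size_um``.
    """

    times: np.ndarray
    radii: np.ndarray
    R0: float
    truth: GroundTruth
    images: list[np.ndarray] = field(default_factory=list)
    pixel_size_um: float | None = None


@dataclass
class SyntheticDoublet:
    """Cross-section outline of two adhering cells.

    ``contour`` traces the outer (cell–medium) outline of both cells;
    ``vertices`` are the two triple-junction points (top, bottom) and
    ``theta`` the Young contact angle (degrees) of the noise-free geometry.
    """

    contour: np.ndarray
    theta: float
    vertices: np.ndarray
    truth: GroundTruth


# --------------------------------------------------------------------------
# compressed drop (parallel-plate tensiometry)
# --------------------------------------------------------------------------

def sphere_radius_from_volume(volume_um3: float) -> float:
    """Radius (µm) of a sphere of the given volume (µm³)."""
    return (3.0 * volume_um3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def barrel_geometry(volume_um3: float, plate_gap_um: float) -> tuple[float, float]:
    """Principal radii (R2, R3) of the circular-arc barrel, in µm.

    The side wall is an arc of radius R2 = gap/2 tangent to both plates
    (non-wetting contact), bulging to the equatorial radius R3.  R3 follows
    from volume conservation: with a = R3 - R2 the contact radius,

        V = pi * (2*a^2*R2 + pi*a*R2^2 + 4/3*R2^3).

    Raises ``ValueError`` when the gap exceeds the free-sphere diameter.
    """
    r_sphere = sphere_radius_from_volume(volume_um3)
    if plate_gap_um > 2.0 * r_sphere * (1.0 + 1e-9):
        raise ValueError(
            f"plate gap {plate_gap_um} µm exceeds free diameter "
            f"{2 * r_sphere:.3f} µm: no contact"
        )
    r2 = plate_gap_um / 2.0
    # quadratic in a: 2*R2*a^2 + pi*R2^2*a + (4/3*R2^3 - V/pi) = 0
    c2 = 2.0 * r2
    c1 = math.pi * r2 ** 2
    c0 = (4.0 / 3.0) * r2 ** 3 - volume_um3 / math.pi
    disc = c1 ** 2 - 4.0 * c2 * c0
    a = (-c1 + math.sqrt(disc)) / (2.0 * c2)
    a = max(a, 0.0)
    return r2, a + r2


def _barrel_contour(r2: float, r3: float, gap: float, n_points: int) -> np.ndarray:
    """Closed CCW cross-section of the barrel: two arcs + two plate segments."""
    a = r3 - r2
    n_arc = max(n_points // 3, 16)
    n_seg = max((n_points - 2 * n_arc) // 2, 4)
    psi = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    right = np.column_stack([a + r2 * np.cos(psi), r2 * np.sin(psi)])
    top = np.column_stack([
        np.linspace(a, -a, n_seg + 2)[1:-1],
        np.full(n_seg, gap / 2.0),
    ])
    # left arc from top vertex down to bottom vertex (CCW overall)
    left = np.column_stack([-(a + r2 * np.cos(psi[::-1])), r2 * np.sin(psi[::-1])])
    bottom = np.column_stack([
        np.linspace(-a, a, n_seg + 2)[1:-1],
        np.full(n_seg, -gap / 2.0),
    ])
    if a == 0:  # uncompressed sphere: arcs already meet at the poles
        return np.vstack([right[:-1], left[:-1]])
    return np.vstack([right, top, left, bottom])


def gen_compressed_aggregate(
    sigma: float,
    volume: float,
    plate_gap: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    n_points: int = 1200,
    tau_s: float = 60.0,
    duration_s: float = 600.0,
    dt_s: float = 1.0,
    f0_factor: float = 2.0,
    force_noise_sd: float = 0.0,
) -> SyntheticCompression:
    """Generate one plate compression of a liquid-drop aggregate.

    Parameters
    ----------
    sigma : float
        Tissue surface tension, mN/m (> 0).
    volume : float
        Aggregate volume, µm³, conserved exactly across compressions.
    plate_gap : float
        Plate separation, µm; must not exceed the free-sphere diameter.
    noise_sd : float
        Gaussian noise sd added to contour coordinates, µm.
    force_noise_sd : float
        Optional Gaussian noise sd on the force trace, µN (default 0: noise
        is added to contour points only).

    The force trace relaxes exponentially (time constant ``tau_s``) from
    ``f0_factor`` times the plateau to the Laplace plateau
    sigma*pi*R3^2*(1/R2 + 1/R3); an uncompressed drop (gap equal to the free
    diameter) exerts no plate force.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    r2, r3 = barrel_geometry(volume, plate_gap)
    r_free = sphere_radius_from_volume(volume)
    compressed = plate_gap < 2.0 * r_free
    plateau = units.laplace_force_uN(sigma, r2, r3) if compressed else 0.0

    contour = _barrel_contour(r2, r3, plate_gap, n_points)
    if noise_sd > 0:
        contour = contour + rng.normal(0.0, noise_sd, size=contour.shape)

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    f = plateau + (f0_factor * plateau - plateau) * np.exp(-t / tau_s)
    if force_noise_sd > 0:
        f = f + rng.normal(0.0, force_noise_sd, size=f.shape)
    trace = np.column_stack([t, f])

    truth = GroundTruth(sigma=sigma, seed=seed)
    return SyntheticCompression(
        contour=contour,
        force_trace=trace,
        plate_gap=plate_gap,
        volume=volume,
        truth=truth,
        r2_um=r2,
        r3_um=r3,
        plateau_uN=plateau,
        compression_fraction=1.0 - plate_gap / (2.0 * r_free),
    )


def gen_compression_series(
    sigma: float,
    volume: float,
    compression_fractions: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> list[SyntheticCompression]:
    """Successive compressions of one aggregate (volume conserved).

    ``compression_fractions`` are 1 - gap/(free diameter), e.g. [0.25, 0.4]
    for a 25% then a 40% compression.
    """
    r_free = sphere_radius_from_volume(volume)
    out = []
    for i, frac in enumerate(compression_fractions):
        if not 0.0 <= frac < 1.0:
            raise ValueError("compression fraction must lie in [0, 1)")
        gap = 2.0 * r_free * (1.0 - frac)
        out.append(
            gen_compressed_aggregate(
                sigma, volume, gap, noise_sd=noise_sd, seed=seed + i, **kwargs
            )
        )
    return out


# --------------------------------------------------------------------------
# fusion of two aggregates
# --------------------------------------------------------------------------

def gen_fusion_sequence(
    sigma: float,
    eta: float,
    R0: float,
    dt: float,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    render: bool = False,
    pixel_size_um: float = 2.0,
) -> SyntheticFusion:
    """Generate neck radii of two fusing aggregates.

    The noise-free neck obeys r(t)^2 = v * R0 * t with visco-capillary
    velocity v = sigma/eta (unit-converted to µm/min), truncated where the
    initial-regime law stops holding (r/R0 = 0.5).  Gaussian noise of sd
    ``noise_sd`` (µm) is added to r.  With ``render=True`` each frame is
    also rasterised as two overlapping binary discs whose lens half-width
    equals the noise-free neck radius.
    """
    if sigma < 0 or eta <= 0 or R0 <= 0:
        raise ValueError("sigma must be >= 0, eta and R0 > 0")
    if n_frames < 5:
        raise ValueError("need at least 5 frames")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    v = units.visco_capillary_velocity(sigma, eta)  # µm/min
    times = np.arange(n_frames) * dt
    r = np.sqrt(v * R0 * times)
    # the initial-regime law holds only up to r/R0 = 0.5: truncate the series
    keep = r <= 0.5 * R0
    if keep.sum() < 5:
        raise ValueError(
            "fewer than 5 frames before r/R0 = 0.5; use a smaller dt"
        )
    times, r = times[keep], r[keep]
    r_clean = r.copy()
    if noise_sd > 0:
        r = np.clip(r + rng.normal(0.0, noise_sd, size=r.shape), 0.0, None)
    truth = GroundTruth(sigma=sigma, eta=eta, seed=seed)
    fusion = SyntheticFusion(times=times, radii=r, R0=R0, truth=truth)
    if render:
        fusion.images = [
            render_fusion_frame(R0, rc, pixel_size_um) for rc in r_clean
        ]
        fusion.pixel_size_um = pixel_size_um
    return fusion


def render_fusion_frame(
    R0: float, neck_radius: float, pixel_size_um: float = 2.0
) -> np.ndarray:
    """Binary image (uint8) of two R0-discs whose lens half-width is the neck.

    Two discs of radius R0 with centre distance d = 2*sqrt(R0^2 - r^2)
    intersect in a lens of half-width r; d = 2*R0 (tangent discs) at r = 0.
    """
    from skimage.draw import disk

    neck_radius = min(neck_radius, R0)
    d = 2.0 * math.sqrt(max(R0 ** 2 - neck_radius ** 2, 0.0))
    margin = 4 * pixel_size_um
    width = d + 2 * R0 + 2 * margin
    height = 2 * R0 + 2 * margin
    shape = (int(np.ceil(height / pixel_size_um)), int(np.ceil(width / pixel_size_um)))
    img = np.zeros(shape, dtype=np.uint8)
    cy = shape[0] / 2.0
    r_px = R0 / pixel_size_um
    for sign in (-1.0, 1.0):
        cx = shape[1] / 2.0 + sign * (d / 2.0) / pixel_size_um
        rr, cc = disk((cy, cx), r_px, shape=shape)
        img[rr, cc] = 1
    return img


# --------------------------------------------------------------------------
# cell doublet (Young angle)
# --------------------------------------------------------------------------

def gen_doublet(
    gamma_cm: float,
    gamma_cc: float,
    cell_radius: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    n_points: int = 1600,
) -> SyntheticDoublet:
    """Cross-section of two equal cells adhering along a straight interface.

    The two cell–medium outlines are circular arcs meeting the (vertical)
    cell–cell interface at the Young angle theta = 2*arccos(gamma_cc /
    (2*gamma_cm)); each cell's area equals that of a disc of radius
    ``cell_radius``.  gamma_cc = 0 gives a single circular outline
    (theta = 180°); gamma_cc = 2*gamma_cm gives two tangent discs
    (theta = 0°); gamma_cc > 2*gamma_cm has no equilibrium and raises.
    """
    if gamma_cm <= 0:
        raise ValueError("gamma_cm must be positive")
    if gamma_cc < 0:
        raise ValueError("gamma_cc must be non-negative")
    if gamma_cc > 2.0 * gamma_cm:
        raise ValueError("gamma_cc > 2*gamma_cm: no mechanical equilibrium")
    rng = np.random.default_rng(seed)
    theta = 2.0 * math.acos(gamma_cc / (2.0 * gamma_cm))  # radians
    # arc radius rho set by equal cell area = pi * cell_radius^2
    seg = 0.5 * (theta - math.sin(theta))  # chord-cut segment area / rho^2
    rho = cell_radius * math.sqrt(math.pi / (math.pi - seg))
    xc = rho * math.cos(theta / 2.0)  # arc centre offset from interface
    h = rho * math.sin(theta / 2.0)   # triple junction height

    half = n_points // 2
    phi_r = np.linspace(-(math.pi - theta / 2.0), math.pi - theta / 2.0, half)
    right = np.column_stack([xc + rho * np.cos(phi_r), rho * np.sin(phi_r)])
    phi_l = np.linspace(theta / 2.0, 2.0 * math.pi - theta / 2.0, half)
    left = np.column_stack([-xc + rho * np.cos(phi_l), rho * np.sin(phi_l)])
    if theta >= math.pi - 1e-12:  # single circle: arcs join smoothly
        contour = np.vstack([right[:-1], left[1:-1]])
    else:
        contour = np.vstack([right[:-1], left[:-1]])
    if noise_sd > 0:
        contour = contour + rng.normal(0.0, noise_sd, size=contour.shape)
    truth = GroundTruth(
        gamma_cm=gamma_cm, gamma_cc=gamma_cc, theta=math.degrees(theta), seed=seed
    )
    return SyntheticDoublet(
        contour=contour,
        theta=math.degrees(theta),
        vertices=np.array([[0.0, h], [0.0, -h]]),
        truth=truth,
    )


# --------------------------------------------------------------------------
# rough contours (rugosity)
# --------------------------------------------------------------------------

def harmonic_contour(
    mean_radius: float, amplitude: float, mode: int, phase: float = 0.0,
    n_points: int = 2000,
) -> np.ndarray:
    """Closed CCW contour r(phi) = R + a*cos(mode*phi + phase)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = mean_radius + amplitude * np.cos(mode * phi + phase)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def gen_rough_contour(
    mean_radius: float,
    amplitude: float,
    n_modes: int = 8,
    seed: int = 0,
    *,
    n_points: int = 2000,
    min_mode: int = 3,
) -> np.ndarray:
    """Closed contour with random multi-mode radial roughness.

    r(phi) = R + sum_k a_k cos(k*phi + phi_k) over ``n_modes`` consecutive
    modes starting at ``min_mode`` (low modes are excluded so roughness is
    texture, not overall shape).  Random amplitudes and phases; the a_k are
    rescaled so the RMS radial perturbation equals ``amplitude`` exactly.
    """
    if amplitude >= mean_radius:
        raise ValueError("amplitude must be smaller than the mean radius")
    rng = np.random.default_rng(seed)
    phi = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = np.full(n_points, float(mean_radius))
    if amplitude > 0 and n_modes > 0:
        modes = np.arange(min_mode, min_mode + n_modes)
        amps = np.abs(rng.normal(1.0, 0.3, size=n_modes))
        amps *= amplitude / math.sqrt(0.5 * np.sum(amps ** 2))  # RMS = amplitude
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        for k, a, p in zip(modes, amps, phases):
            r = r + a * np.cos(k * phi + p)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


# --------------------------------------------------------------------------
# force relaxation traces
# --------------------------------------------------------------------------

def gen_force_relaxation(
    F0: float,
    F_plateau: float,
    tau: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
) -> np.ndarray:
    """Exponential force relaxation F(t) = F_p + (F0 - F_p)*exp(-t/tau).

    Times in s, forces in µN; returns an (N, 2) array.  ``duration`` of at
    least 5*tau is recommended for a clean plateau.
    """
    if F_plateau < 0 or F0 < F_plateau:
        raise ValueError("need F0 >= F_plateau >= 0")
    if tau <= 0 or duration <= 0:
        raise ValueError("tau and duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    f = F_plateau + (F0 - F_plateau) * np.exp(-t / tau)
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=f.shape)
    return np.column_stack([t, f])


# --------------------------------------------------------------------------
# plain-text exchange formats
# --------------------------------------------------------------------------

def write_contour_csv(path: str | Path, contour: np.ndarray) -> None:
    """One row per point: x_um,y_um."""
    np.savetxt(path, contour, delimiter=",", header="x_um,y_um", comments="")


def read_contour_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)


def write_force_csv(path: str | Path, trace: np.ndarray) -> None:
    """One row per sample: t_s,F_uN."""
    np.savetxt(path, trace, delimiter=",", header="t_s,F_uN", comments="")


def read_force_csv(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", skiprows=1)


def write_truth_json(path: str | Path, truth: GroundTruth, **extra) -> None:
    """JSON sidecar recording the ground truth (including the seed)."""
    payload = truth.to_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
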