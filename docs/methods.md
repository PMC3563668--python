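# Methods

This note records the models behind each stage of the pipeline, the
numerical choices and their defaults, what the synthetic-data generators do
and do not emulate, and the known limitations. Units throughout: lengths
µm, tensions mN/m, forces µN, viscosity Pa·s, fusion time min, force-trace
time s; every conversion factor lives in `aggmech.units`.

## Tension algebra (`dith_core`)

The differential interfacial tension hypothesis treats the tissue as a
liquid whose surface tension is set by per-cell interfacial tensions:
γ_cm = Γ_cm for the cell–medium interface and γ_cc = 2Γ_cc − J for the
cell–cell interface, which carries two contractile cortices and gains the
adhesion energy J. The Γ values are *effective* cortical tensions: any
line-tension or cortex-elasticity contribution is absorbed into them and
not separately resolved. The measurable quantities are

* σ = Γ_cm − Γ_cc + J/2 (tissue surface tension), and
* θ = 2·arccos(γ_cc / 2γ_cm) (triple-junction contact angle).

The inverse solver takes σ of the tissue of interest, σ of a
uniform-cortex reference (Γ_cm = Γ_cc ⇒ σ = J/2), and θ, and returns
(Γ_cm, Γ_cc, J) in closed form; it round-trips through the forward maps to
machine precision. Angles are degrees at the API and radians internally.
Parameter sets outside the equilibrium cone (γ_cc < 0 or γ_cc > 2γ_cm) are
*flagged*, not rejected: fitted condition means can legitimately wander
there, and a total solver keeps report assembly robust. θ = 0 makes Γ_cm
diverge and is rejected.

## Parallel-plate tensiometry (`tensiometry`)

At force plateau the compressed aggregate is treated as a liquid drop
obeying the Laplace relation F = σ·πR₃²·(1/R₂ + 1/R₃), with R₃ the
equatorial radius and R₂ the side-profile radius of curvature at the
equator, both curvature centres inside the drop (so a convex compressed
drop gives σ > 0). The relation is inverted per compression
(`sigma_single`) or fitted as the slope of F against πR₃²(1/R₂+1/R₃)
across several compressions of one aggregate (`sigma_slope`; ordinary
least squares, intercept free by default with a `through_origin` option,
95% CI from the t-distribution of the slope). The estimate is treated as
valid up to 50% compression.

Numerical choices:

* **Contour extraction** — Otsu threshold (manual override), single
  dominant object required, marching-squares boundary at sub-pixel
  precision, scaled by the pixel calibration, returned counter-clockwise.
* **Profile radii** — R₃ is the maximal half-width about the symmetry
  axis. R₂ comes from a local polynomial fit of the side wall: both walls
  are folded onto |x|(z) and fitted over a window of one third of the
  side-wall arc (≈ π·gap/6). The default order is **quartic**: on a
  circular arc a quadratic fit carries a truncation bias of ≈ 0.2·(w/R₂)²
  on the curvature (≈ 1.5% at this window), which the even quartic term
  cancels; the wide window keeps the curvature stable under contour noise
  (≈ 3% sd on R₂ at 0.5 µm noise). Both order and window are exposed.
* **Plateau detection** — mean of the terminal 20% of the trace, accepted
  when the fitted tail slope is below 1e-3 µN/s (both configurable). A
  trace that never settles — the behaviour of contractility-hyperactivated
  aggregates whose force creeps for hours — yields a warning and the tail
  mean, flagged unconverged, rather than an error.

A free sphere (gap equal to the free diameter) exerts no plate force, but
the Laplace expression above does not vanish there: it omits the direct
tension pull of the meridional surface on the equatorial cross-section,
which is negligible at real working compressions (25–50%) and is the
expression the slope estimator is built on. The generator therefore emits
a zero plateau in the degenerate uncompressed case and the Laplace plateau
for any true compression; analyses are only asserted at ≥ 20% compression.

## Fusion kinetics (`fusion_kinetics`)

Coalescence of two aggregates of radius R₀ is driven by σ and resisted by
η. In the initial regime the neck obeys the corrected viscous-sintering
law with **no numerical prefactor**, r² = (σ/η)·R₀·t, valid for
r/R₀ ≤ 0.5. `fit_frenkel` fits r² against R₀·t — unweighted, intercept
free (and reported) — over the frames inside that window and returns the
slope v = σ/η with its 95% CI. Irregular frame cadence is accepted. From
an independently measured σ: η = σ/v, fluidity = v/σ = 1/η.

Neck tracking in binary frames projects the object's pixels onto their
principal axis, takes per-column pixel counts as the width profile,
locates the minimum between the two lobe maxima, and refines it by
intersecting line fits to the two branches of width² (which grows linearly
in |axial distance| for overlapping discs) — sub-pixel accuracy where the
profile is steep. Frames with disconnected lobes record r = 0 with a
flag; empty frames are errors. R₀ comes from the first frame's area
(A = 2πR₀²), which for slightly unequal pairs is the mean-area radius.

`temperature_trend` fits v against temperature linearly and reports the
slope as percent of the fitted mid-range v per degree, the natural scale
for "x% increase per degree" statements.

## Shape metrics (`shape_metrics`)

**Contact angle.** The two branches leaving the triple junction are
collected by walking the contour until the *Euclidean* distance from the
vertex exceeds the tangent window (10 µm default) — walking polygon arc
length instead would let coordinate noise inflate the walked length and
silently shrink the window. Per branch the tangent at the vertex is taken
from a geometric least-squares circle fit (Kåsa init, orthogonal-residual
refinement). A straight-line tangent fit is available but is biased by
≈ w/(2ρ) on a branch of curvature radius ρ — several degrees at
cell-scale radii — whereas the circle fit is exact for arcs of any radius,
so it is the default. The angle is the angle between the two
away-from-vertex tangents, in degrees; it is rotation/translation
invariant by construction.

**Rugosity.** The contour is expressed as radius vs angle about its
centroid and cut into regions (whole contour by default; an exclusion
mask drops stretches such as debris or dead cells). Per region a smooth
trend is fitted on the exponential basis {1, e^u, e^−u} of the normalised
angular coordinate — a low-order exponential trend absorbs slow drifts of
the radius but cannot follow cell-scale texture — and the roughness is the
area between contour and trend per unit arc length, Σ|r − fit|·ds / Σds,
averaged over regions weighted by length. For a single radial mode of
amplitude a this converges to the analytic mean deviation 2a/π. The
metric is intensive (per unit length), so regions of different sizes are
comparable; it is insensitive to 2× resampling and linear in perturbation
amplitude at fixed mode content.

## Statistics and reports (`stats_report`)

Condition summaries are mean ± half-width of the 95% t-interval of the
mean with n; a single observation is legal (flagged, CI reported as 0).
Two-condition comparisons use Student's t-test, **Welch by default** with
the pooled-variance variant behind `equal_var=True`; no multiple-testing
correction is applied by default, matching per-comparison α = 0.05
practice. The liquid analogy predicts that of two tissues in contact the
higher-σ one ends up internal; when the supplied CIs overlap the tensions
cannot be ranked and "no sorting" is predicted with an ambiguity flag.
`build_report` assembles the per-condition table, derives η and fluidity
from the condition means, and — given a designated uniform-cortex
condition — runs the tension solve and σ decomposition.

## Synthetic data (`synthetic_data`)

The generators embed exactly the laws the analyses invert, with additive
Gaussian noise on contour coordinates and scalar readouts, and all
randomness through `numpy.random.default_rng(seed)` (bit-identical
reruns). Defaults mirror the study conditions the pipeline targets:
tensions of order 1.5–4.5 mN/m, viscosities of order 6×10⁵ Pa·s
(visco-capillary velocities 0.16–0.46 µm/min), aggregate radii 90–270 µm,
fusion sampled every 4–10 min for ~20 frames, compressions of 20–50%,
contour noise ~0.5 µm and neck noise ~2 µm.

* **Compressed drop** — circular-arc ("barrel") side wall tangent to both
  plates: R₂ = gap/2, R₃ from exact volume conservation (quadratic in the
  contact radius), force trace relaxing exponentially (τ = 60 s default)
  to the Laplace plateau. This is the same approximation the analysis
  formula is built on, so generator and analysis are self-consistent by
  construction; real aggregates deviate from it at high compression, which
  is why validity is asserted only up to 50%.
* **Fusion** — r(t) = √(v·R₀·t) with R₀ held fixed; frames past
  r/R₀ = 0.5 are dropped (the initial-regime law is the model, and a
  clipped plateau would be an artefact the fit window could straddle under
  noise). Optional rasterisation as two overlapping binary discs whose
  lens half-width equals the neck radius.
* **Doublet** — two circular arcs of equal cell area meeting a straight
  interface at the Young angle; γ_cc = 0 degenerates to one circle,
  γ_cc = 2γ_cm to two tangent discs.
* **Rough contour** — r(φ) = R + Σ aₖcos(kφ+φₖ) over modes ≥ 3 (texture,
  not overall shape), amplitudes rescaled so the RMS perturbation is
  exact.

What the generators do **not** emulate: cell-resolved granularity
(vertex/Potts-scale structure), optical blur and uneven illumination,
plate adhesion and gravity flattening, volume loss or growth during long
assays, late-stage coalescence. Passing recovery tests therefore
demonstrate correctness of the inference given the liquid-drop laws and
the stated noise model — not robustness to every artefact of real
microscopy.

## Problem sizes used in the test suite

Recovery suites use 30–100 seeded replicates per condition (100 for the
single-parameter tensiometry/fusion recoveries, 30 for the full
2-line × 2-drug study with temperature sweep), contours of 1200–2000
points, force traces of 600 samples, and 20-frame fusion series — sizes at
which the Monte Carlo means are stable to well under the asserted
tolerances while the whole suite runs in seconds.

## Known limitations

* The Laplace estimator omits the meridional-tension term, so σ from
  compressions below ~15% is biased; use several compressions ≥ 20%.
* Neck tracking assumes a convex two-lobed union; strongly asymmetric
  pairs or lobes connected by debris will bias the width profile.
* The rugosity trend basis is a global low-order fit per region; contours
  whose genuine shape (not texture) has high harmonic content need
  explicit region splitting.
* The inverse tension solve propagates no uncertainty; report CIs cover
  the measured σ and v only.
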