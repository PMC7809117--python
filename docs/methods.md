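# Methods

## The analysis model

A lateral VFSS recording yields, per frame i, pixel positions of the hyoid
body H_i, and of the anteroinferior vertices of C2 and C4. The analysis
assumes (a) the C2–C4 segment is rigid over a swallow, so the frame
(origin C4, ŷ toward C2, x̂ the anterior perpendicular) removes neck motion;
(b) magnification is constant within a recording, so one coin measurement
(23.5 mm diameter by default) fixes the scale; (c) the pixel y axis
convention is declared per file (`image-down` by default) and normalized to
superior-positive. The transform is rebuilt from each frame's own C2/C4
("per-frame" mode), because adjusting for neck movement is the point;
a fixed-reference-frame variant is available (`mode="fixed"`) for
recordings where vertebral landmarks are unreliable in some frames. The
anterior sign is resolved from the hyoid itself, which is always anterior
to the vertebral column in a lateral view.

Swallows are compared on normalized time: the detected (or manually
annotated) window [start, end] is mapped linearly onto a grid of 101
points, 0–100. The start is the hyoid's lowest/quiescent position just
before motion (implemented as the earlier of two candidates: the last
pre-peak frame within 0.3 mm of the minimum height, and a motion-onset
frame found by thresholding a jitter-robust speed estimate at 5 mm/s and
walking back to the quiescent floor); the end is the first post-peak
stretch of 3 intervals below the speed threshold. Manual windows always
win, and a detection failure is an explicit error asking for annotation.

On the grid, velocity is the symmetric difference quotient
v(t) = [d(t+1) − d(t−1)]/2 (one-sided at the endpoints), in mm/percentile.
The direction angle is atan2(v_y, v_x) in degrees on [0, 360), undefined
(NaN) where ‖v‖ < 1e−6 mm/percentile — a zero velocity has no direction.
The early-phase angle is the arithmetic mean over grid points 5–20;
early-phase motion is confined to the 90–180° quadrant where arithmetic
and circular means agree. Discrete summaries (Table-style) are signed
extrema of d and v with earliest-tie-break times, computed on the *raw*
gridded profiles, not the smoothed curves.

## Functional representation and regression

Each signal (disp_x, disp_y, vel_x, vel_y, angle) is represented as
X̂(t) = Σ ĉ_k φ_k(t) in an order-4 (cubic) open-uniform B-spline basis on
[0, 100], fit by penalized least squares with the integrated squared second
derivative as roughness penalty; the penalty matrix is computed exactly by
per-span Gauss–Legendre quadrature. λ = 0 with a saturated basis
interpolates (solved by direct least squares on the design matrix, since
normal equations lose the interpolation limit numerically); λ → ∞ yields
the least-squares straight line. One (K, λ) pair per signal is selected
cohort-wide by minimizing the mean GCV n·RSS/(n − df)², df = tr(hat);
grids default to K ∈ {8, 12, 16, 20} and λ ∈ 10^{−4..6} (11 log-spaced
points). GCV ties within a numerical whisker are resolved toward the
smoother fit (larger λ, then smaller K), which matters for data a basis
reproduces exactly. Angles are unwrapped into a continuous curve before
smoothing (NaN gaps linearly interpolated) so the 0/360 seam cannot
masquerade as signal.

The group comparison is the function-on-scalar model
y_i(t) = Z_i1 β_ref(t) + Z_i2 β_diff(t) + ε_i(t), Z reference-coded with
good prognosis as reference, fitted by OLS at each grid point on the
smoothed curves. Because the design is a one-way layout, β_diff(t) equals
the pointwise difference of group mean curves; the machinery's value is the
pointwise band β̂_diff ± 1.96·SE(t) with SE from σ̂²(t)(ZᵀZ)⁻¹,
σ̂²(t) = RSS(t)/(n − p). A Student-t critical value is available
(`crit="t"`). Maximal runs of grid points whose band excludes zero are the
significant percentile intervals; no multiplicity correction is applied
across grid points (the rule is pointwise, not family-wise, and is
documented as such), and single-point runs are reported. β is estimated
pointwise without a second-stage penalty: the subject curves already carry
the roughness penalty, and a second smoothing layer would need its own
parameterization with no clear selection target.

Discrete comparisons: pooled-variance t test or Mann–Whitney U
(normal approximation with tie correction, no continuity correction —
identical samples must give p = 1), auto-selected by Shapiro–Wilk at
α = 0.05 per group; Pearson chi-square without continuity correction or
Fisher's exact test, auto-switching to Fisher when any expected count
is < 5. All tests are two-sided.

## The synthetic cohort generator

No raw patient trajectories are publicly available, so validation runs on
synthetic cohorts whose displacement template is the minimal smooth family
reproducing the swallow loop:

    x(t) = −B·g(t; 20, 8) + F·g(t; 49, 12.5)
    y(t) =  U·g(t; 34, 15)

with g a Gaussian bump, chord-corrected to vanish at t = 0 and 100 and
renormalized to 1 at its center. Per subject, amplitudes (B, F, U),
duration and bump timings are drawn from group-specific normals (truncated
at zero; timing SDs 3/5/6 percentiles, clipped to anatomically ordered
ranges). Group parameters default to the published post-stroke cohort
moments: F ~ 12.43 ± 4.81 mm (good) vs 9.22 ± 3.95 mm (poor),
U ~ 15.37 ± 7.14 vs 16.81 ± 7.10 mm, motion span 1.76 ± 0.45 vs
1.89 ± 0.47 s at 30 frames/s, B ~ 3.5 ± 2.6 mm with the poor group's
backward amplitude scaled by 0.08 — the mechanism that renders the poor
group's initial pull more vertical.

Rendering places C4 at the origin, C2 38 mm above, the hyoid at rest
30 mm anterior / 12 mm superior to C4, adds a 0.3 s quiescent lead-in and
tail, applies a slow rigid neck drift (rotation random walk, SD 0.002
rad/frame; translation random walk, SD 0.5 px/frame) jointly to all
landmarks, converts to image-down pixels at 0.5 mm/px, and adds iid
Gaussian pixel noise (SD 0.15 px, emulating sub-pixel template-matching
tracking). Everything is deterministic under a seed.

Free shape/noise parameters (bump centers/widths, timing SDs, pixel noise,
the poor-group backward scale) were calibrated once, before the test suite
was frozen, so that the *pipeline-recovered* Monte-Carlo group means
reproduce the published calibration targets: early-phase angle
≈ 119°/96° (gap ≈ 23°) and good-group maximal forward displacement within
0.5 mm of 12.43 mm. Amplitude truncation at zero inflates recovered means
slightly (≈ +0.07 mm for F); the residual +0.2–0.3 mm in recovered forward
displacement comes from taking a maximum over a noisy curve and from
rebase-point placement.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: tracking outliers and frame dropouts; bolus-dependent
kinematics; non-rigid cervical motion; inter-rater annotation variability;
asymmetric return dynamics. Two known template artifacts: (1) the terminal
return velocity decays smoothly to zero, so detection reads the last ~15%
of the rendered motion span as quiescent — detected durations average
≈ 1.52 s where 1.76 s was drawn, and detected times-to-maximum sit ~10
percentiles later than the template centers (group ordering preserved);
(2) the symmetric forward bump makes the fastest backward x-velocity occur
during the late return rather than the early pull, unlike the published
cohort's timing of that extremum. Matching the poor group's early-angle
target through backward-amplitude scaling also sacrifices that group's
backward-displacement moment (≈ −0.3 mm recovered vs −3.01 mm published);
the angle gap was preferred because it is the stated calibration target.

## Numerical choices and degenerate inputs

- Grid: 101 points, 0..100 inclusive; endpoint velocities one-sided.
- Angle floor 1e−6 mm/percentile; undefined angles are excluded from the
  early-phase mean and interpolated only for smoothing.
- Detection: threshold 5 mm/s on a 3-frame-smoothed, 2-interval-baseline
  speed; dwell 3 intervals; minimum window of 4 frames enforced for
  marginal swallows; constant trajectories raise a detection error.
- Ties: earliest grid time for extrema; larger λ then smaller K for GCV.
- Degenerate geometry (C2 = C4, hint on the axis, non-positive coin) raises
  typed errors naming the offending frame.
- Cohort helpers accept per-subject fallback windows so that a subject
  whose swallow defeats automatic detection can fall back to a manual
  (in simulations: ground-truth) annotation instead of aborting the cohort.

## Problem sizes

The test suite validates statistical behaviour at the study's own scale
(18 + 18 subjects): pointwise null false-positive fraction over 500
simulated cohorts, forward-difference localization over 200 cohorts, and
the acceptance script averages recovered moments over 150 cohorts (300 for
the null fraction). These sizes give Monte-Carlo standard errors well below
the tolerances they are compared against.

## Limitations

- Pointwise (not simultaneous) confidence bands; interval endpoints are
  optimistic under multiplicity.
- The homoscedastic OLS standard error ignores possible variance
  differences between groups and correlation induced by smoothing.
- One cohort-wide (K, λ) per signal; subjects with atypical smoothness are
  slightly over- or under-smoothed.
- The early-phase angle uses the arithmetic mean by default; the
  `circular=True` option of `mean_early_phase_angle` is there for data that
  straddle the 0/360 seam, which early-phase swallowing motion normally
  does not.
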