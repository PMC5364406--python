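# Methods

This note records the models implemented in `cytodyn`, the assumptions
behind them, the defaults and the design choices made where the design was
genuinely open. Units are µm, s and µm²/s throughout.

## Two-state diffusion model and MSD estimation

Passive probe motion is modelled as 2D Brownian motion whose diffusion
coefficient switches between a fast state (`d_fast`, default 10.1 µm²/s,
free cytosolic diffusion) and a slow state (`d_slow`, default 0.06 µm²/s,
motion inside the cortical actin meshwork) as a two-state Markov chain with
rates `k_fs`, `k_sf`. Switching is simulated with exact exponential waiting
times and the per-frame step variance is `2·dt·∫D`, the time integral of D
across the frame, so the generator remains valid when `rate·dt` is not
small. Independent Gaussian localization error (`sigma_loc`, default
17.5 nm per coordinate, i.e. a 35 nm average precision) is added to every
observed position. Optional blinking drops frames in alternating
exponential on/off stretches; frame indices and time stamps are retained so
that all delay computations use true time gaps, and pairs spanning gaps are
included in the time-averaged MSD (this maximizes pair counts and matches
the standard time-averaged MSD definition).

The MSD estimator averages squared displacements over all same-track pairs
at each delay. Ensemble curves are averaged per delay with pair-count
weights. The diffusion coefficient is the slope/4 of an unweighted ordinary
least-squares affine fit over the first 25% of delays (`fit_fraction`
configurable); the intercept `dx²` estimates `4·sigma_loc²` and can be
forced to zero. The reported standard error comes from the dispersion of
per-track fits, not from the OLS residuals of the averaged curve: the
residuals of an averaged time-averaged MSD are strongly correlated across
delays and make the naive OLS error far too optimistic, whereas for
equal-length tracks the ensemble fit is algebraically the mean of the
per-track fits, making the between-track dispersion the exact standard
error. Simulation checks in the test suite verify mean bias below 2% and
2σ coverage above 90% at the default conditions.

Fast/slow classification thresholds the per-track mean squared one-frame
displacement (`msd1`). The automatic threshold is placed at the dip between
the two modes of a Gaussian kernel-density estimate of `log10(msd1)`; a dip
qualifies only if its density is below 80% of the lower mode, otherwise the
distribution is declared unimodal and an explicit threshold is required.
This mirrors the visual dashed-line procedure used on bimodal experimental
one-frame-MSD histograms; the exact experimental threshold is not published.

Derived estimates: the Stokes–Einstein reference uses water at 25 °C
(T = 298 K, η = 0.89 mPa·s) by default. The pore-size inversion uses the
Renkin cylindrical-pore hindrance factor
`D/D0 = (1−λ)²(1 − 2.104λ + 2.09λ³ − 0.95λ⁵)` with `λ = probe/pore`,
solved for the pore diameter by bracketed root finding; the original
hindered-diffusion reference does not print its formula, so the model name
is recorded in the output and alternatives can be added. The mesh trapping
timescale is reported in two labelled variants, `(d_mesh−d_probe)²/(6D)`
and `(d_mesh−d_probe)²/D`, because published worked examples have used the
bare numeric D in the denominator; neither is asserted as canonical.

## Spot detection and linking

Detection thresholds local maxima at `median + threshold_sd·1.4826·MAD`
per frame and refines each candidate by least squares against an
*integrated* elliptical Gaussian (expected photon count per pixel, via
error functions) in a square ROI (half-width 4 px default). The integrated
model matches the physics of pixelated detection; on noiseless rendered
spots positions are exact to well below 10⁻³ px. Coordinates follow one
fixed convention package-wide: origin at the image corner, x along columns,
pixel (i, j) centered at `((j+0.5)·px, (i+0.5)·px)` µm. Manual track
curation used in interactive workflows is replaced by quality filters
(fit convergence, residual bound). ROI size and convergence criteria are
this package's defaults; they are not tied to any specific plugin.

Linking is greedy mutual-nearest-neighbour frame to frame: pairs that are
each other's nearest remaining neighbour within `max_disp` are accepted in
order of distance (ties broken by spot index), tracks may bridge up to
`max_gap` missing frames, and unmatched detections seed new tracks. A
global Hungarian assignment is available behind `method="hungarian"`.
Overlapping emitters within one ROI are not deconvolved; that regime is out
of scope.

## Directional runs and B-spline backbones

Motor-driven runs are detected with a sliding window over `window` (10)
consecutive displacements that must satisfy two criteria: mean cosine
between consecutive displacement directions ≥ `min_cos` (0.6) and
net-displacement/path-length ≥ `min_straightness` (0.8). Directions are
median-filtered (3 samples) before the cosine test so that single abrupt
sideways jumps of the underlying filament do not break a run. Overlapping
directional windows merge; merged stretches shorter than `min_run_frames`
(20) are discarded. These thresholds are validated against generator
ground truth in the test suite (frame-level accuracy ≥ 90% at the default
motor kinetics; false-run frames < 5% on pure Brownian tracks).

Each run's backbone is a clamped (non-periodic) cubic B-spline fit by least
squares with `max(4, round(L/spacing)+3)` control points for path length L,
giving the nominal `control_spacing` (default 1 µm) between control points
— the scale at which the filament is considered straight. Parameterization
is chord length, iterated once with arc-length reparameterization on the
fitted curve; interior knots sit at parameter quantiles to keep the system
well posed, and the control-point count is reduced automatically if the
least-squares system is still deficient. Paths shorter than twice the
spacing, runs with fewer than 8 points, or rank-deficient systems fall back
to a principal-axis straight line (flagged `degenerate`). One static spline
per run is used: motors traverse a curve in ~1–3 s, faster than the shape
remodelling time of the filaments, so refitting per time window is not
warranted.

Decomposition projects each position onto the spline (global search over a
2048-point arc-length table, then bounded local refinement; equidistant
feet resolve to the smaller arc length). The longitudinal coordinate is the
arc length of the foot point; the transverse offset is signed positive to
the left of the direction of travel. Component MSDs treat `s(t)` and
`d(t)` as 1D tracks and reuse the 2D machinery. Run statistics are
`run_length = s_end − s_start`, `duration = (n−1)·dt`,
`speed = run_length/duration`.

## Curvature and persistence

Curvature `κ = |x′y″ − y′x″|/(x′²+y′²)^{3/2}` is evaluated from analytic
spline derivatives; clamped ends use the one-sided limit. Distributions are
weighted by arc length (`ds` = 0.05 µm sampling, 0.1 µm⁻¹ bins — the
summary statistic of interest is the fraction of arc length below a
curvature level), and an exponential model is fit to log-counts of
non-empty bins for the characteristic decay constant. Directional
persistence averages the cosine between displacement vectors k steps apart
and maps lag to displacement via an assumed constant speed; the correlation
length comes from fitting `cos(Δ) = exp(−Δ/ℓ)`, reported as infinite for
non-decaying (ballistic) signals. A power-law alternative is not
implemented.

## Filament undulations and kymograph iMSD

Filament shapes are polylines of ≥ 4 control vertices whose lateral offsets
(perpendicular to the local axis) follow independent Ornstein–Uhlenbeck
processes with stationary s.d. `undulation_sd` and relaxation time
`undulation_tau` — a minimal model of slow undulation that preserves mean
shape. In the kymograph generator each filament is a Gaussian ridge whose
position performs confined diffusion: an OU process with short-time
diffusion coefficient D and stationary variance `L²/12`, so its 1D MSD
plateaus at `L²/6`.

Kymographs are sampled by bilinear interpolation along a user-supplied
polyline at pixel-size steps, averaged across `width` perpendicular pixels.
The iMSD stage subtracts the *global* mean intensity and computes, per
delay τ, the time-averaged spatial cross-correlation of the profiles at t
and t+τ; a Gaussian with free baseline is fit within ±8 px of the central
peak. The fitted peak variance is `σ²(τ) = 2σ_psf² + MSD_ridge(τ)` up to
baseline terms absorbed by the fit. Subtracting each position's own
temporal mean instead (as in homogeneous-sample image-correlation work)
would remove the static ridge profile itself; with a small number of
discrete ridges the correlation peak then degenerates into a difference of
near-equal Gaussians and the confinement plateau becomes unidentifiable —
hence the global-mean choice, which keeps the estimator invariant to
additive offsets.

The confined model `σ²(τ) = σ₀² + (L²/6)(1 − exp(−12Dτ/L²))` is fit by
value-weighted least squares (relative weighting keeps the early rise that
carries D from being swamped by the many plateau points). The plateau
factor 6 is a module constant so the `L²/3` convention can be selected.
When the exponential has not decayed within the measured delays the fit is
flagged and `l_conf` is only a lower bound. Condition groups are compared
with the two-tailed Mann–Whitney U test: exact distribution for groups of
≤ 20 without ties, explicit permutation enumeration for small tied samples
(≤ 14 combined), tie-corrected normal approximation otherwise.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume —
two-state Brownian mixtures with localization noise and blinking,
processive runs with Normal-clipped-at-zero speed fluctuation along curved
undulating backbones interleaved with unbound diffusion, integrated-PSF
photon-limited imaging, and confined ridge fluctuations. They do not
emulate: heterogeneous per-cell parameter variation, anomalous diffusion or
viscoelastic memory, motor pausing states, QD photophysics beyond two-state
blinking, 3D motion or focal-plane loss, or spatially varying background.
Passing tests therefore demonstrate estimator correctness and calibration
under the assumed models, not robustness to every property of real
recordings.

## Problem sizes and numerical choices

Default study conditions: 300 tracks × 66 frames at dt = 2.4 ms for
diffusion recovery; 100 motor trajectories × 80 frames at dt = 50 ms for
run statistics; kymographs of 4–6 ridges × 400 frames at 1 s for iMSD.
These sizes give a few-percent statistical error on the recovered
parameters. All generators draw from a single `numpy.random.Generator` per
call and are bitwise reproducible per seed. Root finding uses bracketed
Brent iteration (`xtol` 10⁻¹²); spline projection refines to `xatol`
10⁻¹²; curve fits bound parameters to their physical ranges.
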