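# cytodyn

Trajectory and image analysis of passive and active intracellular particle
dynamics, built for single-particle-tracking experiments in which small
probes (such as quantum dots, QDs) report on the cytoplasm: freely diffusing
probes reveal the viscosity and meshwork structure of the cytosol, while
probes coupled to kinesin motor proteins report on the geometry and
fluctuations of the microtubules they travel along.

The package implements four analysis branches plus the synthetic generators
needed to exercise them end to end:

- **diffusion** — time-averaged mean-squared displacement (MSD) per track,
  pair-count-weighted ensemble averaging, and the 2D estimator
  `MSD(τ) = 4Dτ + dx²` fitted over the first 25% of delays (the intercept
  `dx²` absorbs the squared localization precision). Tracks are classified
  fast/slow from the bimodal distribution of the one-frame MSD, and derived
  physical estimates (Stokes–Einstein reference, cytoplasm/water viscosity
  ratio, hindered-diffusion pore size, mesh trapping timescale) are provided.
- **tracking** — sub-pixel spot detection by least-squares fitting of an
  integrated elliptical Gaussian, greedy mutual-nearest-neighbour linking
  with gap bridging, and minimum-track-length filtering.
- **runs** — extraction of transient directional (motor-driven) episodes with
  a two-criterion sliding-window filter; clamped cubic B-spline backbone
  fitting at fixed control-point spacing (1 µm by default — the length scale
  at which a microtubule is treated as straight); decomposition of motion
  into a longitudinal arc-length coordinate `s(t)` and a signed transverse
  offset `d(t)`; per-run speed, run length and duration.
- **geometry / imsd** — arc-length-weighted curvature distributions and
  directional-persistence correlation lengths of runs; kymograph
  construction and image-MSD (iMSD) analysis of lateral filament
  fluctuations with a confined-diffusion fit
  `σ²(τ) = σ₀² + (L²/6)(1 − e^{−12Dτ/L²})` and Mann–Whitney condition
  comparisons.

## Worked example

Simulate the two-population diffusion experiment (fast cytosolic fraction at
10.1 µm²/s, slow meshwork-trapped fraction at 0.06 µm²/s, 2.4 ms frames,
17.5 nm localization noise) and recover both coefficients:

```python
from cytodyn.diffusion import classify_mobility, ensemble_diffusion, msd_track
from cytodyn.synthetic import TwoStateDiffusionParams, simulate_two_state

params = TwoStateDiffusionParams()          # the defaults above, p_fast0=0.5
tracks = simulate_two_state(params, n_tracks=300, n_frames=66, seed=1)
labels, threshold = classify_mobility(tracks, "auto")
for cls in ("fast", "slow"):
    group = [t for t, lab in zip(tracks, labels) if lab.label == cls]
    est = ensemble_diffusion([msd_track(t) for t in group], fit_fraction=0.25)
    print(f"{cls}: D = {est.d:.3g} um2/s, offset = {est.offset_dx2*1e6:.0f} nm2")
```

```
fast: D = 9.82 um2/s, offset = 4109 nm2
slow: D = 0.0575 um2/s, offset = 1191 nm2
```

The slow-fraction intercept ≈ 1225 nm² = (35 nm)², four times the squared
per-coordinate localization precision (17.5 nm); for the fast fraction the
intercept is a tiny fraction of the signal and correspondingly noisy. The
`classify_mobility` threshold is placed at the dip of the bimodal
log-scale one-frame-MSD distribution.

The same pipelines are scriptable from the shell:

```sh
cytodyn simulate --stage diffusion --seed 1 --out out/
cytodyn diffusion --tracks out/tracks.csv --min-length 12
cytodyn runs --tracks motor_tracks.csv --spacing 1.0
```

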