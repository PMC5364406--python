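"""Synthetic data generators for every analysis stage.

The generators emulate the statistical structure of intracellular
quantum-dot experiments:

* two-state Brownian diffusion (a fast cytosolic population around
  10 µm²/s and a slow, meshwork-trapped population around 0.06 µm²/s,
  imaged at millisecond frame intervals with nanometre localization
  noise and optional blinking),
* processive motor-driven runs at 1–2.5 µm/s along curved, slowly
  undulating filament backbones, interspersed with diffusive episodes,
* fluorescence movies of point emitters (integrated-Gaussian PSF with
  Poisson photon statistics),
* kymographs of laterally fluctuating filaments whose positions perform
  confined (Ornstein–Uhlenbeck) diffusion.

Every generator draws all randomness from one ``numpy.random.Generator``
seeded per call, so outputs are exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import erf

from .containers import ImageStack, Kymograph
from .trajectory import Trajectory

__all__ = [
    "TwoStateDiffusionParams",
    "MotorParams",
    "FilamentShape",
    "ImageStack",
    "simulate_two_state",
    "simulate_run_trajectory",
    "render_spots",
    "simulate_filament_kymograph",
    "ornstein_uhlenbeck",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class TwoStateDiffusionParams:
    """Two-state Brownian motion with localization noise and blinking.

    Defaults are the conditions of rapid intracellular QD imaging:
    D_fast = 10.1 µm²/s, D_slow = 0.06 µm²/s, 2.4 ms frame interval and
    17.5 nm per-coordinate localization error (a 35 nm average precision).
    """

    d_fast: float = 10.1  # µm²/s
    d_slow: float = 0.06  # µm²/s
    k_fs: float = 0.0  # fast->slow switching rate, 1/s
    k_sf: float = 0.0  # slow->fast switching rate, 1/s
    sigma_loc: float = 0.0175  # µm per coordinate
    dt: float = 0.0024  # s
    p_fast0: float = 0.5
    blink_on_mean: float = 0.0  # s; 0 disables blinking
    blink_off_mean: float = 0.0  # s

    def __post_init__(self) -> None:
        vals = [self.d_fast, self.d_slow, self.k_fs, self.k_sf,
                self.sigma_loc, self.dt, self.p_fast0,
                self.blink_on_mean, self.blink_off_mean]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite parameter")
        if not self.d_fast > self.d_slow >= 0:
            raise ValueError("need d_fast > d_slow >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if min(self.k_fs, self.k_sf, self.sigma_loc) < 0:
            raise ValueError("rates and sigma_loc must be >= 0")
        if not 0 <= self.p_fast0 <= 1:
            raise ValueError("p_fast0 must be in [0, 1]")


@dataclass
class MotorParams:
    """Kinesin-like stepping kinetics of a QD-motor complex."""

    speed_mean: float = 1.0  # µm/s (kinesin-1-like; 2.5 emulates kinesin-2)
    speed_sd: float = 0.05  # µm/s, within-run fluctuation
    run_duration_mean: float = 2.0  # s
    off_duration_mean: float = 1.0  # s
    d_unbound: float = 0.5  # µm²/s cytosolic diffusion between runs
    sigma_loc: float = 0.005  # µm (3–5 nm precision regime)
    dt: float = 0.05  # s

    def __post_init__(self) -> None:
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be > 0")
        if self.run_duration_mean <= 0 or self.off_duration_mean <= 0:
            raise ValueError("durations must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class FilamentShape:
    """Polyline control vertices of a filament plus its undulation law.

    Lateral vertex offsets relax as independent Ornstein–Uhlenbeck
    processes with stationary s.d. ``undulation_sd`` and correlation time
    ``undulation_tau``, perpendicular to the local filament axis.
    """

    vertices: np.ndarray  # (n, 2) µm
    undulation_sd: float = 0.05  # µm
    undulation_tau: float = 10.0  # s

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 4:
            raise ValueError("need >= 4 control vertices")
        if self.undulation_sd < 0:
            raise ValueError("undulation_sd must be >= 0")

    def normals(self) -> np.ndarray:
        """Unit normals (left of travel) at each vertex, from the base polyline."""
        tang = np.gradient(self.vertices, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        return np.column_stack([-tang[:, 1], tang[:, 0]])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def ornstein_uhlenbeck(
    n: int, sd: float, tau: float, dt: float, rng: np.random.Generator,
    x0: float | None = None,
) -> np.ndarray:
    """Exact discretization of a stationary OU process.

    Returns ``n`` samples spaced ``dt`` apart with stationary standard
    deviation ``sd`` and autocorrelation ``exp(-Δt/tau)``.  ``x0`` draws
    from the stationary law when None.
    """
    if sd == 0 or n == 0:
        return np.zeros(n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd) if x0 is None else x0
    if n > 1:
        a = np.exp(-dt / tau)
        innov_sd = sd * np.sqrt(1.0 - a * a)
        noise = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(1, n):
            out[i] = a * out[i - 1] + noise[i - 1]
    return out


class _FilamentCurve:
    """Arc-length parameterized curve through displaced filament vertices."""

    def __init__(self, points: np.ndarray, n_dense: int = 1024):
        points = np.asarray(points, dtype=float)
        chord = np.concatenate([[0.0], np.cumsum(
            np.hypot(*np.diff(points, axis=0).T))])
        if chord[-1] <= 0:
            raise ValueError("degenerate filament (zero length)")
        cs = CubicSpline(chord, points, axis=0)
        u = np.linspace(0.0, chord[-1], n_dense)
        self._xy = cs(u)
        seg = np.hypot(*np.diff(self._xy, axis=0).T)
        self._s = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(self._s[-1])

    def point(self, s: float | np.ndarray) -> np.ndarray:
        s = np.clip(s, 0.0, self.length)
        x = np.interp(s, self._s, self._xy[:, 0])
        y = np.interp(s, self._s, self._xy[:, 1])
        return np.stack([x, y], axis=-1)

    def project(self, p: np.ndarray) -> float:
        """Arc length of the dense sample nearest to point ``p``."""
        d2 = np.sum((self._xy - p) ** 2, axis=1)
        return float(self._s[int(np.argmin(d2))])


# ---------------------------------------------------------------------------
# two-state diffusion
# ---------------------------------------------------------------------------


def _state_occupancy(
    params: TwoStateDiffusionParams, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of each frame interval spent in the fast state, plus the
    instantaneous state at each frame time (1 = fast).

    State switching uses exact exponential waiting times, so the result
    stays valid when rate x dt is not small.
    """
    dt = params.dt
    total = (n_frames - 1) * dt
    frac_fast = np.zeros(n_frames - 1)
    state_at = np.zeros(n_frames, dtype=bool)

    state = rng.random() < params.p_fast0
    state_at[0] = state
    t = 0.0
    while t < total:
        rate = params.k_fs if state else params.k_sf
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        t_next = min(t + wait, total)
        # accumulate occupancy of [t, t_next) into overlapping frame bins
        if state:
            i0 = int(t / dt)
            i1 = min(int(np.ceil(t_next / dt)), n_frames - 1)
            for i in range(i0, i1):
                lo, hi = i * dt, (i + 1) * dt
                frac_fast[i] += (min(hi, t_next) - max(lo, t)) / dt
        j0 = int(np.ceil(t / dt)) if t > 0 else 1
        j1 = int(t_next / dt)
        state_at[j0:j1 + 1] = state
        t = t_next
        if wait < np.inf and t < total:
            state = not state
    return np.clip(frac_fast, 0.0, 1.0), state_at


def _blink_mask(
    params: TwoStateDiffusionParams, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    if params.blink_on_mean <= 0 or params.blink_off_mean <= 0:
        return np.ones(n_frames, dtype=bool)
    mask = np.zeros(n_frames, dtype=bool)
    t, on = 0.0, True
    total = n_frames * params.dt
    while t < total:
        mean = params.blink_on_mean if on else params.blink_off_mean
        dur = rng.exponential(mean)
        if on:
            i0, i1 = int(t / params.dt), min(int((t + dur) / params.dt) + 1, n_frames)
            mask[i0:i1] = True
        t += dur
        on = not on
    mask[0] = True  # a track exists only if first seen
    return mask


def simulate_two_state(
    params: TwoStateDiffusionParams,
    n_tracks: int,
    n_frames: int,
    seed: int,
) -> list[Trajectory]:
    """Simulate 2D random walks switching between fast and slow diffusion.

    Per-coordinate step variance over a frame is ``2·dt·(f·D_fast +
    (1-f)·D_slow)`` where ``f`` is the exact fraction of the interval spent
    in the fast state of the two-state Markov chain.  Independent Gaussian
    localization error is added per observed coordinate; blinking (if
    enabled) drops frames but preserves true frame indices and time stamps.
    Each trajectory carries per-frame ``state`` labels (``"fast"``/``"slow"``).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    tracks: list[Trajectory] = []
    for tid in range(n_tracks):
        frac_fast, state_at = _state_occupancy(params, n_frames, rng)
        var = 2.0 * params.dt * (
            frac_fast * params.d_fast + (1.0 - frac_fast) * params.d_slow
        )
        steps = rng.normal(size=(n_frames - 1, 2)) * np.sqrt(var)[:, None]
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        pos = pos + rng.normal(0.0, params.sigma_loc, size=pos.shape)
        keep = _blink_mask(params, n_frames, rng)
        frames = np.nonzero(keep)[0]
        tracks.append(Trajectory(
            track_id=tid,
            frames=frames,
            t=frames * params.dt,
            x=pos[keep, 0],
            y=pos[keep, 1],
            state=np.where(state_at[keep], "fast", "slow"),
        ))
    return tracks


# ---------------------------------------------------------------------------
# motor runs on undulating filaments
# ---------------------------------------------------------------------------


def simulate_run_trajectory(
    shape: FilamentShape,
    motor: MotorParams,
    n_frames: int,
    seed: int,
    track_id: int = 0,
    start_bound: bool = True,
) -> Trajectory:
    """Simulate a QD-motor complex alternating bound runs and free diffusion.

    While bound, the arc-length coordinate advances each frame by
    ``v·dt`` with ``v ~ Normal(speed_mean, speed_sd)`` clipped at 0, and
    the position is the corresponding point of the (time-varying) filament
    curve.  While unbound, the particle diffuses with ``d_unbound``.
    Bound/unbound episode durations are exponential; reaching the filament
    end terminates the bound episode.  The filament's control vertices
    undulate by exact OU updates between frames.  Ground-truth per-frame
    labels are returned in ``Trajectory.state`` (``"bound"``/``"unbound"``).
    """
    rng = np.random.default_rng(seed)
    dt = motor.dt
    base = shape.vertices
    normals = shape.normals()
    n_v = len(base)

    curve0 = _FilamentCurve(base)
    if curve0.length <= motor.speed_mean * motor.run_duration_mean:
        raise ValueError("filament arc length must exceed the expected run length")

    offsets = (rng.normal(0.0, shape.undulation_sd, size=n_v)
               if shape.undulation_sd > 0 else np.zeros(n_v))
    if shape.undulation_sd > 0:
        a = np.exp(-dt / shape.undulation_tau)
        innov_sd = shape.undulation_sd * np.sqrt(1.0 - a * a)
    else:
        a, innov_sd = 1.0, 0.0

    bound = start_bound
    episode_left = rng.exponential(
        motor.run_duration_mean if bound else motor.off_duration_mean)
    s = 0.05 * curve0.length
    xy = np.empty((n_frames, 2))
    labels = np.empty(n_frames, dtype=object)
    curve = _FilamentCurve(base + offsets[:, None] * normals)
    pos = curve.point(s)

    for i in range(n_frames):
        xy[i] = pos
        labels[i] = "bound" if bound else "unbound"
        # advance one frame
        if innov_sd > 0:
            offsets = a * offsets + rng.normal(0.0, innov_sd, size=n_v)
            curve = _FilamentCurve(base + offsets[:, None] * normals)
        if bound:
            v = max(0.0, rng.normal(motor.speed_mean, motor.speed_sd))
            s = s + v * dt
            if s >= curve.length:  # fell off the end
                s = curve.length
                bound = False
                episode_left = rng.exponential(motor.off_duration_mean)
            pos = curve.point(s)
        else:
            pos = pos + rng.normal(0.0, np.sqrt(2.0 * motor.d_unbound * dt), size=2)
        episode_left -= dt
        if episode_left <= 0:
            bound = not bound
            if bound:
                s = min(curve.project(pos), 0.98 * curve.length)
                pos = curve.point(s)
            episode_left = rng.exponential(
                motor.run_duration_mean if bound else motor.off_duration_mean)

    xy += rng.normal(0.0, motor.sigma_loc, size=xy.shape)
    frames = np.arange(n_frames)
    return Trajectory(track_id=track_id, frames=frames, t=frames * dt,
                      x=xy[:, 0], y=xy[:, 1], state=labels.astype(str))


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _integrated_gaussian(shape_hw, centers_px, sigma_px, photons):
    """Sum of integrated 2D Gaussians on a pixel grid (counts per pixel)."""
    h, w = shape_hw
    img = np.zeros((h, w))
    root2 = np.sqrt(2.0)
    for cx, cy in centers_px:
        # pixel i covers [i, i+1); center of pixel i at i + 0.5
        x_edges = np.arange(w + 1)
        y_edges = np.arange(h + 1)
        fx = 0.5 * (erf((x_edges[1:] - cx) / (root2 * sigma_px))
                    - erf((x_edges[:-1] - cx) / (root2 * sigma_px)))
        fy = 0.5 * (erf((y_edges[1:] - cy) / (root2 * sigma_px))
                    - erf((y_edges[:-1] - cy) / (root2 * sigma_px)))
        img += photons * np.outer(fy, fx)
    return img


def render_spots(
    trajectories: list[Trajectory],
    psf_sigma: float,
    photons: float,
    background: float,
    pixel_size: float,
    noise_seed: int | None = None,
    shape: tuple[int, int] | None = None,
    dt: float | None = None,
) -> ImageStack:
    """Render trajectories as diffraction-limited spots in a noisy movie.

    Each particle visible in a frame becomes an integrated 2D Gaussian of
    width ``psf_sigma`` (µm) carrying ``photons`` expected counts; Poisson
    noise is applied to signal + background when ``noise_seed`` is given.
    Image origin is the array corner; the center of pixel (row i, col j)
    sits at ((j+0.5)·pixel_size, (i+0.5)·pixel_size) in µm, x along columns.
    """
    if psf_sigma < 0.25 * pixel_size:
        warnings.warn("psf_sigma < 0.25 pixel: spots undersampled", stacklevel=2)
    if dt is None:
        dt = trajectories[0].dt if trajectories and len(trajectories[0]) > 1 else 1.0
    all_frames = np.concatenate([tr.frames for tr in trajectories]) if trajectories \
        else np.array([0])
    n_frames = int(all_frames.max()) + 1
    if shape is None:
        margin = 5.0 * psf_sigma
        xs = np.concatenate([tr.x for tr in trajectories])
        ys = np.concatenate([tr.y for tr in trajectories])
        if xs.min() < 0 or ys.min() < 0:
            raise ValueError("positions must be non-negative to infer field of view")
        shape = (int(np.ceil((ys.max() + margin) / pixel_size)),
                 int(np.ceil((xs.max() + margin) / pixel_size)))
    h, w = shape
    for tr in trajectories:
        if (np.any(tr.x < 0) or np.any(tr.y < 0)
                or np.any(tr.x > w * pixel_size) or np.any(tr.y > h * pixel_size)):
            raise ValueError(f"track {tr.track_id} leaves the field of view")

    sigma_px = psf_sigma / pixel_size
    stack = np.full((n_frames, h, w), float(background))
    for tr in trajectories:
        for frame, x, y in zip(tr.frames, tr.x, tr.y):
            stack[frame] += _integrated_gaussian(
                (h, w), [(x / pixel_size, y / pixel_size)], sigma_px, photons)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        stack = rng.poisson(stack).astype(float)
    return ImageStack(stack, pixel_size=pixel_size, dt=dt)


# ---------------------------------------------------------------------------
# filament kymographs
# ---------------------------------------------------------------------------


def simulate_filament_kymograph(
    n_filaments: int,
    d_fluct: float,
    l_conf: float,
    psf_sigma: float,
    pixel_size: float,
    dt: float,
    n_frames: int,
    seed: int,
    n_pixels: int | None = None,
    amplitude: float = 100.0,
    background: float = 10.0,
) -> tuple[Kymograph, np.ndarray]:
    """Simulate a kymograph of laterally fluctuating filament ridges.

    Each filament appears as a Gaussian-profile ridge whose position along
    the kymograph line performs confined diffusion: an OU process with
    short-time diffusion coefficient ``d_fluct`` and stationary variance
    ``l_conf²/12``, so the one-dimensional MSD plateaus at ``l_conf²/6`` —
    the confinement convention used by the iMSD fitting stage.

    Returns the kymograph and the (n_filaments, n_frames) matrix of true
    ridge positions in µm.
    """
    if l_conf <= 0 and d_fluct != 0:
        raise ValueError("need l_conf > 0 unless d_fluct == 0")
    rng = np.random.default_rng(seed)
    sd = l_conf / np.sqrt(12.0)
    tau = sd * sd / d_fluct if (d_fluct > 0 and sd > 0) else np.inf

    spacing = 12.0 * psf_sigma + 2.0 * l_conf
    if n_pixels is None:
        n_pixels = int(np.ceil((n_filaments + 0.5) * spacing / pixel_size))
    base = (np.arange(n_filaments) + 0.75) * spacing
    centers = np.empty((n_filaments, n_frames))
    for j in range(n_filaments):
        if np.isfinite(tau):
            centers[j] = base[j] + ornstein_uhlenbeck(n_frames, sd, tau, dt, rng)
        else:
            centers[j] = base[j] + (rng.normal(0.0, sd) if sd > 0 else 0.0)

    xpix = (np.arange(n_pixels) + 0.5) * pixel_size
    inten = np.full((n_pixels, n_frames), float(background))
    for j in range(n_filaments):
        inten += amplitude * np.exp(
            -((xpix[:, None] - centers[j][None, :]) ** 2) / (2.0 * psf_sigma ** 2))
    kymo = Kymograph(inten, pixel_size=pixel_size, dt=dt)
    return kymo, centers
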