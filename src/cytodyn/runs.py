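"""Directional-run extraction and B-spline backbone decomposition.

Motor-driven particles alternate processive, directional runs along
microtubules with episodes of free diffusion.  This module (1) segments
trajectories into directional runs with a two-criterion sliding-window
filter robust to abrupt displacements of the underlying filament,
(2) fits a continuous non-periodic (clamped) cubic B-spline backbone to
each run at a fixed control-point spacing — the length scale at which the
filament is considered straight — and (3) projects the positions onto the
backbone to obtain the longitudinal arc-length coordinate ``s(t)`` and the
signed transverse offset ``d(t)``, from which component MSDs and run
statistics (speed, run length, duration) follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline
from scipy.ndimage import median_filter
from scipy.optimize import minimize_scalar

from .diffusion import MSDCurve, ensemble_msd, msd_track
from .trajectory import Trajectory

__all__ = [
    "RunSegment",
    "SplineFit",
    "ComponentTraces",
    "RunStats",
    "detect_runs",
    "fit_backbone",
    "decompose",
    "component_msd",
    "run_statistics",
]

# default directional-filter thresholds (also in AnalysisConfig)
DEFAULT_WINDOW = 10
DEFAULT_MIN_COS = 0.6
DEFAULT_MIN_STRAIGHTNESS = 0.8
DEFAULT_MIN_RUN_FRAMES = 20


@dataclass
class RunSegment:
    """A contiguous directional sub-trajectory."""

    track_id: int
    frames: np.ndarray  # contiguous frame indices, inclusive range
    t: np.ndarray  # s
    positions: np.ndarray  # (n, 2) µm
    dt: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("run frames must be contiguous")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return float((len(self) - 1) * self.dt)

    def path_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.positions, axis=0).T)))

    @classmethod
    def from_trajectory(cls, traj: Trajectory, i0: int, i1: int) -> "RunSegment":
        """Run over positional index range [i0, i1] inclusive."""
        return cls(traj.track_id, traj.frames[i0:i1 + 1], traj.t[i0:i1 + 1],
                   traj.positions[i0:i1 + 1], traj.dt)


@dataclass
class SplineFit:
    """Clamped cubic B-spline backbone with an arc-length lookup table."""

    spline_x: BSpline
    spline_y: BSpline
    control_spacing: float  # µm, nominal arc-length distance of control points
    degenerate: bool = field(default=False)  # straight-line fallback used
    _u: np.ndarray = field(init=False, repr=False)
    _s: np.ndarray = field(init=False, repr=False)
    _xy: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.spline_x.t
        u = np.linspace(t[3], t[-4], 2048)
        xy = np.column_stack([self.spline_x(u), self.spline_y(u)])
        seg = np.hypot(*np.diff(xy, axis=0).T)
        self._u, self._xy = u, xy
        self._s = np.concatenate([[0.0], np.cumsum(seg)])
        if np.any(np.diff(self._s) < 0):
            raise ValueError("arc-length table must be non-decreasing")

    @property
    def degree(self) -> int:
        return 3

    @property
    def knots(self) -> np.ndarray:
        return self.spline_x.t

    @property
    def control_points(self) -> np.ndarray:
        n = len(self.spline_x.t) - 4
        return np.column_stack([self.spline_x.c[:n], self.spline_y.c[:n]])

    @property
    def arc_length(self) -> float:
        return float(self._s[-1])

    @property
    def domain(self) -> tuple[float, float]:
        return float(self._u[0]), float(self._u[-1])

    def point(self, u):
        return np.stack([self.spline_x(u), self.spline_y(u)], axis=-1)

    def derivative(self, u, order: int = 1):
        return np.stack([self.spline_x.derivative(order)(u),
                         self.spline_y.derivative(order)(u)], axis=-1)

    def tangent(self, u):
        d = np.atleast_2d(self.derivative(u, 1))
        t = d / np.linalg.norm(d, axis=-1, keepdims=True)
        return t[0] if np.isscalar(u) else t

    def s_of_u(self, u):
        return np.interp(u, self._u, self._s)

    def u_of_s(self, s):
        return np.interp(s, self._s, self._u)

    def point_at_arclength(self, s):
        return self.point(self.u_of_s(s))

    def curvature(self, u):
        """|x'y'' - y'x''| / (x'^2 + y'^2)^{3/2} — parameterization invariant."""
        d1 = np.atleast_2d(self.derivative(u, 1))
        d2 = np.atleast_2d(self.derivative(u, 2))
        num = np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
        den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = np.where(den > 0, num / den, 0.0)
        return float(kappa[0]) if np.isscalar(u) else kappa

    def project(self, p: np.ndarray) -> tuple[float, float]:
        """Nearest point on the curve: returns (u*, signed offset d).

        Global search over the dense arc-length table, then bounded local
        refinement; equidistant feet resolve to the smaller arc length
        (the first global minimum in table order).
        """
        p = np.asarray(p, dtype=float)
        d2 = np.sum((self._xy - p) ** 2, axis=1)
        i = int(np.argmin(d2))
        lo = self._u[max(i - 1, 0)]
        hi = self._u[min(i + 1, len(self._u) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda u: float(np.sum((self.point(u) - p) ** 2)),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12})
            u_star = float(res.x)
            if res.fun > d2[i]:
                u_star = float(self._u[i])
        else:
            u_star = float(self._u[i])
        foot = self.point(u_star)
        tang = self.tangent(u_star)
        left = np.array([-tang[1], tang[0]])
        d_signed = float(np.dot(p - foot, left))
        return u_star, d_signed


@dataclass
class ComponentTraces:
    """Longitudinal s(t) and signed transverse d(t) of a run vs its backbone."""

    track_id: int
    frames: np.ndarray
    t: np.ndarray
    s: np.ndarray  # µm, arc length of foot point
    d: np.ndarray  # µm, signed perpendicular offset (positive = left of travel)
    dt: float


@dataclass
class RunStats:
    """Per-run summary: speed = run_length / duration."""

    track_id: int
    speed: float  # µm/s
    run_length: float  # µm
    duration: float  # s


# ---------------------------------------------------------------------------
# run detection
# ---------------------------------------------------------------------------


def detect_runs(
    traj: Trajectory,
    window: int = DEFAULT_WINDOW,
    min_cos: float = DEFAULT_MIN_COS,
    min_straightness: float = DEFAULT_MIN_STRAIGHTNESS,
    min_run_frames: int = DEFAULT_MIN_RUN_FRAMES,
) -> list[RunSegment]:
    """Mark directional stretches with a two-criterion sliding window.

    A window of ``window`` consecutive displacements is directional when
    (a) the mean cosine between consecutive displacement directions is at
    least ``min_cos`` and (b) the ratio of net displacement to path length
    is at least ``min_straightness``.  Directions are median-filtered
    (3-sample) before the cosine test so that single abrupt sideways jumps
    of the underlying filament do not break a run.  Overlapping directional
    windows merge; merged stretches shorter than ``min_run_frames`` frames
    are discarded.
    """
    if len(traj) >= 2 and np.any(np.diff(traj.frames) != 1):
        raise ValueError("detect_runs requires a gap-free track (uniform dt)")
    n_disp = len(traj) - 1
    if n_disp < window:
        return []
    disp = traj.displacements()
    # median-filter displacement components to stabilize directions
    fdisp = np.column_stack([
        median_filter(disp[:, 0], size=3, mode="nearest"),
        median_filter(disp[:, 1], size=3, mode="nearest"),
    ])
    norm = np.linalg.norm(fdisp, axis=1)
    unit = np.divide(fdisp, norm[:, None], out=np.zeros_like(fdisp),
                     where=norm[:, None] > 0)
    cosines = np.einsum("ij,ij->i", unit[:-1], unit[1:])  # length n_disp-1

    pos = traj.positions
    step_len = np.linalg.norm(disp, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(step_len)])

    marked = np.zeros(len(traj), dtype=bool)
    for i in range(n_disp - window + 1):
        mean_cos = float(np.mean(cosines[i:i + window - 1]))
        path = cum[i + window] - cum[i]
        net = float(np.linalg.norm(pos[i + window] - pos[i]))
        straight = net / path if path > 0 else 0.0
        if mean_cos >= min_cos and straight >= min_straightness:
            marked[i:i + window + 1] = True

    runs: list[RunSegment] = []
    i = 0
    while i < len(marked):
        if marked[i]:
            j = i
            while j + 1 < len(marked) and marked[j + 1]:
                j += 1
            if j - i + 1 >= min_run_frames:
                runs.append(RunSegment.from_trajectory(traj, i, j))
            i = j + 1
        else:
            i += 1
    return runs


# ---------------------------------------------------------------------------
# backbone fitting
# ---------------------------------------------------------------------------


def _straight_line_fit(points: np.ndarray, control_spacing: float) -> SplineFit:
    """Principal-axis straight line expressed as a clamped cubic spline."""
    center = points.mean(axis=0)
    centered = points - center
    if np.allclose(centered, 0):
        axis = np.array([1.0, 0.0])
        proj = np.zeros(len(points))
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        proj = centered @ axis
    lo, hi = float(proj.min()), float(proj.max())
    if hi - lo < 1e-12:
        hi = lo + 1e-9
    p0 = center + lo * axis
    p1 = center + hi * axis
    length = hi - lo
    knots = np.concatenate([[0.0] * 4, [length] * 4])
    ctrl = np.linspace(0, 1, 4)[:, None] * (p1 - p0)[None, :] + p0[None, :]
    sx = BSpline(knots, ctrl[:, 0], 3)
    sy = BSpline(knots, ctrl[:, 1], 3)
    return SplineFit(sx, sy, control_spacing, degenerate=True)


def _lsq_spline_2d(u: np.ndarray, points: np.ndarray, n_ctrl: int):
    """Least-squares clamped cubic fit; interior knots at parameter quantiles."""
    u0, u1 = float(u[0]), float(u[-1])
    n_interior = n_ctrl - 4
    if n_interior > 0:
        q = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(u, q)
    else:
        interior = np.array([])
    t = np.concatenate([[u0] * 4, interior, [u1] * 4])
    sx = make_lsq_spline(u, points[:, 0], t, k=3)
    sy = make_lsq_spline(u, points[:, 1], t, k=3)
    return sx, sy


def fit_backbone(run: RunSegment, control_spacing: float = 1.0) -> SplineFit:
    """Fit a clamped cubic B-spline backbone to a run's positions.

    The number of control points is ``max(4, round(L/spacing) + 3)`` for
    path length L, so the nominal control-point distance equals
    ``control_spacing`` (1 µm by default: the scale at which microtubules
    are treated as straight).  The fit uses chord-length parameterization
    and is iterated once with arc-length reparameterization on the fitted
    curve.  Degenerate inputs (path shorter than twice the spacing, too
    few points, or a rank-deficient system) fall back to a straight-line
    fit along the principal axis, flagged via ``SplineFit.degenerate``.
    """
    points = np.asarray(run.positions, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(
        np.hypot(*np.diff(points, axis=0).T))])
    length = float(chord[-1])
    if length < 2.0 * control_spacing or len(points) < 8:
        return _straight_line_fit(points, control_spacing)

    n_ctrl = max(4, int(round(length / control_spacing)) + 3)
    # never more unknowns than (distinct-parameter) observations
    n_ctrl = min(n_ctrl, max(4, len(points) - 2))

    u = chord.copy()
    # strictly increasing parameters required: nudge coincident points
    dup = np.diff(u) <= 0
    while np.any(dup):
        u[1:][dup] = u[:-1][dup] + 1e-9
        dup = np.diff(u) <= 0

    fit = None
    for nc in range(n_ctrl, 3, -1):
        try:
            sx, sy = _lsq_spline_2d(u, points, nc)
            fit = SplineFit(sx, sy, control_spacing)
            break
        except Exception:
            continue
    if fit is None:
        return _straight_line_fit(points, control_spacing)

    # one arc-length reparameterization pass on the fitted curve
    try:
        s_at = fit.s_of_u(u)
        s_at = np.maximum.accumulate(s_at)
        dup = np.diff(s_at) <= 0
        while np.any(dup):
            s_at[1:][dup] = s_at[:-1][dup] + 1e-9
            dup = np.diff(s_at) <= 0
        sx, sy = _lsq_spline_2d(s_at, points, len(fit.control_points))
        fit = SplineFit(sx, sy, control_spacing)
    except Exception:
        pass  # keep the chord-length fit
    return fit


# ---------------------------------------------------------------------------
# decomposition and statistics
# ---------------------------------------------------------------------------


def decompose(run: RunSegment, spline: SplineFit) -> ComponentTraces:
    """Project run positions onto the backbone.

    ``s`` is the arc length of the nearest point on the spline, ``d`` the
    signed perpendicular offset (positive to the left of the direction of
    travel).
    """
    s = np.empty(len(run))
    d = np.empty(len(run))
    for i, p in enumerate(run.positions):
        u_star, d_signed = spline.project(p)
        s[i] = spline.s_of_u(u_star)
        d[i] = d_signed
    return ComponentTraces(run.track_id, run.frames, run.t, s, d, run.dt)


def component_msd(
    traces: list[ComponentTraces],
) -> tuple[MSDCurve, MSDCurve]:
    """Ensemble 1D MSDs of the longitudinal and transverse components.

    Each component is treated as a 1D track; per-run time-averaged MSDs
    are pair-count weighted exactly as in the 2D ensemble average.
    """
    if not traces:
        raise ValueError("need >= 1 trace")

    def curves(component: str) -> list[MSDCurve]:
        out = []
        for tr in traces:
            vals = tr.s if component == "s" else tr.d
            t1d = Trajectory(tr.track_id, tr.frames, tr.t,
                             x=vals, y=np.zeros_like(vals))
            out.append(msd_track(t1d))
        return out

    return ensemble_msd(curves("s")), ensemble_msd(curves("d"))


def run_statistics(run: RunSegment, spline: SplineFit) -> RunStats:
    """Speed, run length and duration of one run along its backbone."""
    traces = decompose(run, spline)
    run_length = float(traces.s[-1] - traces.s[0])
    duration = run.duration
    speed = run_length / duration if duration > 0 else np.nan
    return RunStats(run.track_id, speed, run_length, duration)
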