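"""Spot detection and nearest-neighbour track linking.

Detection finds local maxima above a robust noise threshold and refines
each to sub-pixel precision by least-squares fitting of an integrated
elliptical Gaussian (the expected photon count of a Gaussian PSF summed
over each pixel).  Linking joins detections frame-to-frame by greedy
mutual-nearest-neighbour matching with a maximum displacement and
optional gap bridging; a global (Hungarian) assignment is available
behind a flag.

Coordinate convention (fixed across the package): origin at the image
corner, x along columns, y along rows, the center of pixel (row i,
col j) at ((j+0.5)·pixel_size, (i+0.5)·pixel_size) µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

from .containers import ImageStack
from .trajectory import Trajectory

__all__ = ["SpotDetection", "detect_spots", "link_nearest_neighbour", "filter_tracks"]

logger = logging.getLogger(__name__)


@dataclass
class SpotDetection:
    frame: int
    x: float  # µm
    y: float  # µm
    sigma_x: float  # µm
    sigma_y: float  # µm
    amplitude: float  # total fitted photon count
    background: float  # counts / pixel
    residual: float  # rms residual / peak signal

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigmas must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _integrated_gauss_model(params, jj, ii):
    """Expected counts per pixel of an integrated elliptical Gaussian."""
    x0, y0, sx, sy, amp, bg = params
    root2 = np.sqrt(2.0)
    fx = 0.5 * (erf((jj + 1 - x0) / (root2 * sx)) - erf((jj - x0) / (root2 * sx)))
    fy = 0.5 * (erf((ii + 1 - y0) / (root2 * sy)) - erf((ii - y0) / (root2 * sy)))
    return amp * fx * fy + bg


def _fit_spot(roi: np.ndarray, j0: int, i0: int):
    """Fit one ROI; coordinates in pixel units relative to the full frame."""
    ii, jj = np.mgrid[0:roi.shape[0], 0:roi.shape[1]]
    bg0 = float(np.percentile(roi, 20))
    sig = np.clip(roi - bg0, 0, None)
    tot = sig.sum()
    if tot <= 0:
        return None
    cy = float((ii * sig).sum() / tot)
    cx = float((jj * sig).sum() / tot)
    p0 = [cx, cy, 1.2, 1.2, tot, bg0]
    lo = [-1, -1, 0.3, 0.3, 0.0, -np.inf]
    hi = [roi.shape[1], roi.shape[0], roi.shape[1], roi.shape[0], np.inf, np.inf]

    def resid(p):
        return (_integrated_gauss_model(p, jj, ii) - roi).ravel()

    try:
        res = least_squares(resid, p0, bounds=(lo, hi), max_nfev=400)
    except Exception:
        return None
    if not res.success:
        return None
    x0, y0, sx, sy, amp, bg = res.x
    peak = amp / (2 * np.pi * sx * sy)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    # x0 is in pixel-edge units (pixel j spans [j, j+1)), matching x_um/px
    return (j0 + x0, i0 + y0, sx, sy, amp, bg,
            rms / peak if peak > 0 else np.inf)


def detect_spots(
    stack: ImageStack,
    threshold_sd: float = 5.0,
    roi_halfwidth: int = 4,
    max_residual: float = np.inf,
) -> list[SpotDetection]:
    """Detect and sub-pixel-localize fluorescent spots in every frame.

    Candidate maxima must exceed the frame background (median) by
    ``threshold_sd`` robust noise standard deviations (1.4826·MAD); each
    is refined by an integrated elliptical Gaussian least-squares fit in a
    square ROI of half-width ``roi_halfwidth`` pixels.  Non-converged fits
    are dropped and counted in the module log.
    """
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    px = stack.pixel_size
    detections: list[SpotDetection] = []
    n_failed = 0
    for f in range(stack.n_frames):
        img = stack.intensity[f]
        bg = float(np.median(img))
        mad = float(np.median(np.abs(img - bg)))
        noise = 1.4826 * mad
        thr = bg + threshold_sd * max(noise, 1e-12)
        peaks = peak_local_max(img, min_distance=max(roi_halfwidth, 1),
                               threshold_abs=thr, exclude_border=False)
        for (pi, pj) in peaks:
            i0 = max(pi - roi_halfwidth, 0)
            i1 = min(pi + roi_halfwidth + 1, img.shape[0])
            j0 = max(pj - roi_halfwidth, 0)
            j1 = min(pj + roi_halfwidth + 1, img.shape[1])
            out = _fit_spot(img[i0:i1, j0:j1], j0, i0)
            if out is None:
                n_failed += 1
                continue
            x_px, y_px, sx, sy, amp, b, resid = out
            if resid > max_residual:
                n_failed += 1
                continue
            detections.append(SpotDetection(
                frame=f, x=x_px * px, y=y_px * px,
                sigma_x=sx * px, sigma_y=sy * px,
                amplitude=float(amp), background=float(b),
                residual=float(resid)))
    if n_failed:
        logger.info("detect_spots: %d fits dropped (non-converged or poor)",
                    n_failed)
    return detections


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------


class _ActiveTrack:
    __slots__ = ("detections", "last_frame", "last_pos")

    def __init__(self, det: SpotDetection):
        self.detections = [det]
        self.last_frame = det.frame
        self.last_pos = np.array([det.x, det.y])

    def add(self, det: SpotDetection) -> None:
        self.detections.append(det)
        self.last_frame = det.frame
        self.last_pos = np.array([det.x, det.y])


def _match_greedy_mutual(cost: np.ndarray, max_disp: float):
    """Iterative mutual-nearest-neighbour matching.

    Repeatedly accepts pairs that are each other's nearest remaining
    neighbour within ``max_disp``; deterministic tie-break by smaller
    distance, then lower column (spot) index.
    """
    cost = cost.copy()
    matches = []
    while True:
        if not np.any(cost <= max_disp):
            break
        row_min = np.argmin(cost, axis=1)
        col_min = np.argmin(cost, axis=0)
        mutual = [(cost[r, row_min[r]], row_min[r], r)
                  for r in range(cost.shape[0])
                  if cost[r, row_min[r]] <= max_disp
                  and col_min[row_min[r]] == r]
        if not mutual:
            break
        mutual.sort()  # by distance, then spot index
        taken_r, taken_c = set(), set()
        for dist, c, r in mutual:
            if r in taken_r or c in taken_c:
                continue
            matches.append((r, c))
            taken_r.add(r)
            taken_c.add(c)
            cost[r, :] = np.inf
            cost[:, c] = np.inf
    return matches


def _match_hungarian(cost: np.ndarray, max_disp: float):
    from scipy.optimize import linear_sum_assignment

    big = cost.copy()
    big[big > max_disp] = 1e9
    rows, cols = linear_sum_assignment(big)
    return [(r, c) for r, c in zip(rows, cols) if cost[r, c] <= max_disp]


def link_nearest_neighbour(
    detections: list[SpotDetection],
    max_disp: float,
    max_gap: int = 0,
    dt: float = 1.0,
    method: str = "greedy",
) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Frame-to-frame matching is greedy mutual nearest neighbour (default)
    or global Hungarian assignment (``method="hungarian"``); matches
    beyond ``max_disp`` (µm) are forbidden, tracks may bridge up to
    ``max_gap`` missing frames, and unmatched detections start new tracks.
    """
    if method not in ("greedy", "hungarian"):
        raise ValueError("method must be 'greedy' or 'hungarian'")
    by_frame: dict[int, list[SpotDetection]] = {}
    for det in detections:
        by_frame.setdefault(det.frame, []).append(det)

    active: list[_ActiveTrack] = []
    done: list[_ActiveTrack] = []
    for f in sorted(by_frame):
        dets = by_frame[f]
        # retire tracks whose gap is exceeded
        still = []
        for tr in active:
            (still if f - tr.last_frame <= max_gap + 1 else done).append(tr)
        active = still
        if active and dets:
            heads = np.array([tr.last_pos for tr in active])
            pts = np.array([[d.x, d.y] for d in dets])
            cost = np.linalg.norm(heads[:, None, :] - pts[None, :, :], axis=2)
            matcher = (_match_greedy_mutual if method == "greedy"
                       else _match_hungarian)
            matches = matcher(cost, max_disp)
        else:
            matches = []
        matched_dets = {c for _, c in matches}
        for r, c in matches:
            active[r].add(dets[c])
        for c, det in enumerate(dets):
            if c not in matched_dets:
                active.append(_ActiveTrack(det))
        # unmatched tracks stay active until their gap allowance runs out
    done.extend(active)

    tracks = []
    for tid, tr in enumerate(done):
        frames = np.array([d.frame for d in tr.detections])
        order = np.argsort(frames)
        frames = frames[order]
        tracks.append(Trajectory(
            track_id=tid,
            frames=frames,
            t=frames * dt,
            x=np.array([tr.detections[i].x for i in order]),
            y=np.array([tr.detections[i].y for i in order]),
        ))
    return tracks


def filter_tracks(tracks: list[Trajectory], min_length: int) -> list[Trajectory]:
    """Keep only tracks strictly longer than ``min_length`` frames.

    The standard cuts are 12 frames for diffusion analysis and 50 frames
    for motor-run analysis.  Order is preserved; kept/dropped counts are
    logged.
    """
    kept = [tr for tr in tracks if len(tr) > min_length]
    logger.info("filter_tracks: kept %d, dropped %d (min_length=%d)",
                len(kept), len(tracks) - len(kept), min_length)
    return kept
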