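"""Kymograph-based image MSD (iMSD) of lateral filament fluctuations.

Instead of tracking individual filaments, the spatial cross-correlation
of intensity fluctuations along a kymograph line is computed at
increasing time delay; the variance of its central Gaussian peak,
``sigma2(τ)``, grows like the one-dimensional MSD of the underlying
ridge positions on top of a static PSF-set offset.  Confined (corralled)
lateral motion is captured by

    sigma2(τ) = sigma0² + (L²/6)·(1 − exp(−12·D·τ/L²)),

whose early slope gives the fluctuation diffusion coefficient D and
whose plateau gives the confinement size L.  Condition groups of fitted
parameters are compared with the two-tailed Mann–Whitney U test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu, rankdata

from .containers import ImageStack, Kymograph

__all__ = [
    "Kymograph",
    "IMSDCurve",
    "ConfinedFit",
    "build_kymograph",
    "imsd_from_kymograph",
    "fit_confined",
    "confined_model",
    "compare_conditions",
    "mann_whitney_p",
]

logger = logging.getLogger(__name__)

MIN_SPATIAL = 16
MIN_TEMPORAL = 16
PEAK_FIT_HALFWIDTH = 8  # pixels around the correlation maximum
PLATEAU_FACTOR = 6.0  # sigma2 plateau = L² / PLATEAU_FACTOR (L²/3 selectable)


@dataclass
class IMSDCurve:
    """Correlation-peak variance vs time delay."""

    delays: np.ndarray  # s
    sigma2: np.ndarray  # µm²
    fit_quality: np.ndarray  # R² of the per-delay Gaussian peak fit

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.fit_quality = np.asarray(self.fit_quality, dtype=float)
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be >= 0")


@dataclass
class ConfinedFit:
    """Confined-diffusion parameters of one iMSD curve."""

    d: float  # µm²/s
    l_conf: float  # µm
    sigma0_2: float  # µm², static offset
    covariance: np.ndarray
    plateau_resolved: bool = field(default=True)  # False: l_conf is a lower bound


# ---------------------------------------------------------------------------
# kymograph construction
# ---------------------------------------------------------------------------


def build_kymograph(
    stack: ImageStack, line: np.ndarray, width: int = 1
) -> Kymograph:
    """Sample a movie along a polyline to produce a space x time matrix.

    Intensity is bilinearly interpolated at ``pixel_size`` steps along the
    polyline and averaged over ``width`` pixels perpendicular to it, per
    frame.  ``line`` is an (n, 2) polyline of (x, y) in µm, image
    coordinates.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[0] < 2:
        raise ValueError("line must be an (n, 2) polyline")
    px = stack.pixel_size
    seg = np.diff(line, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    n_samples = int(np.floor(total / px)) + 1
    if n_samples < MIN_SPATIAL:
        raise ValueError(f"line shorter than {MIN_SPATIAL} pixels")

    s_nodes = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(n_samples) * px
    x = np.interp(s, s_nodes, line[:, 0])
    y = np.interp(s, s_nodes, line[:, 1])
    # local perpendicular direction
    tx = np.gradient(x)
    ty = np.gradient(y)
    tn = np.hypot(tx, ty)
    tx, ty = tx / tn, ty / tn
    nx, ny = -ty, tx

    offsets = (np.arange(width) - (width - 1) / 2.0) * px
    h, w = stack.shape
    out = np.empty((n_samples, stack.n_frames))
    for f in range(stack.n_frames):
        vals = np.zeros(n_samples)
        for off in offsets:
            xs = x + off * nx
            ys = y + off * ny
            cols = xs / px - 0.5  # pixel centers at (j+0.5)*px
            rows = ys / px - 0.5
            vals += map_coordinates(stack.intensity[f], [rows, cols],
                                    order=1, mode="nearest")
        out[:, f] = vals / width
    return Kymograph(out, pixel_size=px, dt=stack.dt, line=line)


# ---------------------------------------------------------------------------
# iMSD extraction
# ---------------------------------------------------------------------------


def _gaussian_peak(xi, amp, sigma, offset):
    return amp * np.exp(-(xi**2) / (2.0 * sigma**2)) + offset


def _fit_correlation_peak(corr: np.ndarray, px: float):
    """Gaussian fit around the maximum of a spatial correlation profile.

    Returns (sigma2 in µm², R²) or None when the fit does not converge.
    """
    n = len(corr)
    center = int(np.argmax(corr))
    lo = max(center - PEAK_FIT_HALFWIDTH, 0)
    hi = min(center + PEAK_FIT_HALFWIDTH + 1, n)
    xi = (np.arange(lo, hi) - center) * px
    y = corr[lo:hi]
    amp0 = float(y.max() - y.min())
    if amp0 <= 0:
        return None
    try:
        popt, _ = curve_fit(
            _gaussian_peak, xi, y, p0=[amp0, 2.0 * px, float(y.min())],
            bounds=([0, 0.1 * px, -np.inf], [np.inf, n * px, np.inf]),
            maxfev=5000)
    except Exception:
        return None
    pred = _gaussian_peak(xi, *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(popt[1] ** 2), r2


def imsd_from_kymograph(kymo: Kymograph, max_delay: float) -> IMSDCurve:
    """Correlation-peak variance of intensity fluctuations vs delay.

    The global mean intensity is subtracted (making the result invariant
    to additive offsets while keeping the static ridge profile that
    carries the correlation peak); for each delay τ the spatial
    cross-correlation of the profiles at times t and t+τ is averaged over
    t and its central peak fit by a Gaussian with a free baseline.  The
    raw fitted variance is returned — the static PSF-set offset is
    handled by the confined-model fit, not subtracted here.  Delays whose
    peak fit fails are omitted and logged.

    Subtracting each position's own temporal mean instead would remove
    the ridge profile itself: for a small number of discrete ridges the
    correlation peak then degenerates into a difference of near-equal
    Gaussians and the confinement plateau becomes unidentifiable.
    """
    if kymo.n_space < MIN_SPATIAL or kymo.n_time < MIN_TEMPORAL:
        raise ValueError("kymograph too small for iMSD analysis")
    fluct = kymo.intensity - kymo.intensity.mean()
    if not np.any(fluct):
        raise ValueError("kymograph has no intensity fluctuations")
    k_max = min(int(np.floor(max_delay / kymo.dt)), kymo.n_time - 2)

    delays, sig2, qual = [], [], []
    n_omitted = 0
    for k in range(0, k_max + 1):
        a = fluct[:, : kymo.n_time - k]
        b = fluct[:, k:]
        # average spatial cross-correlation over time via FFT
        nfft = 2 * kymo.n_space
        fa = np.fft.rfft(a, n=nfft, axis=0)
        fb = np.fft.rfft(b, n=nfft, axis=0)
        corr = np.fft.irfft(fa.conj() * fb, n=nfft, axis=0).mean(axis=1)
        corr = np.fft.fftshift(corr)
        out = _fit_correlation_peak(corr, kymo.pixel_size)
        if out is None:
            n_omitted += 1
            continue
        delays.append(k * kymo.dt)
        sig2.append(out[0])
        qual.append(out[1])
    if n_omitted:
        logger.info("imsd_from_kymograph: %d delays omitted (peak fit failed)",
                    n_omitted)
    return IMSDCurve(np.array(delays), np.array(sig2), np.array(qual))


# ---------------------------------------------------------------------------
# confined-diffusion fit
# ---------------------------------------------------------------------------


def confined_model(tau, d, l_conf, sigma0_2, plateau_factor=PLATEAU_FACTOR):
    """sigma2(τ) of confined 1D lateral diffusion under a Gaussian PSF."""
    plateau = l_conf**2 / plateau_factor
    rate = 2.0 * plateau_factor * d / l_conf**2
    return sigma0_2 + plateau * (1.0 - np.exp(-rate * tau))


def fit_confined(imsd: IMSDCurve) -> ConfinedFit:
    """Fit the confined-diffusion model to an iMSD curve.

    Initial guesses come from the early slope (D) and the late plateau
    (L); when the curve shows no saturation within the measured delays the
    returned ``l_conf`` is only a lower bound (``plateau_resolved=False``).
    """
    if len(imsd.delays) < 6:
        raise ValueError("need >= 6 delays to fit the confined model")
    tau = imsd.delays
    y = imsd.sigma2
    sigma0_0 = float(y[0])
    plateau0 = max(float(y[-1] - y[0]), 1e-12)
    l0 = float(np.sqrt(PLATEAU_FACTOR * plateau0))
    pos = tau > 0
    early = np.argmax(pos)  # first nonzero delay
    d0 = max((y[early] - y[0]) / (2.0 * tau[early]), 1e-12) if np.any(pos) else 1e-12

    # relative (value-proportional) weighting: the early rise that carries D
    # would otherwise be swamped by the many plateau points
    popt, pcov = curve_fit(
        confined_model, tau, y, p0=[d0, l0, sigma0_0],
        sigma=np.maximum(y, 1e-12), absolute_sigma=False,
        bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000)
    d, l_conf, sigma0_2 = (float(v) for v in popt)
    # plateau resolved only if the exponential has decayed within the record
    rate = 2.0 * PLATEAU_FACTOR * d / l_conf**2 if l_conf > 0 else np.inf
    resolved = bool(rate * tau[-1] >= 1.0)
    return ConfinedFit(d, l_conf, sigma0_2, pcov, plateau_resolved=resolved)


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 20  # per group, tie-free recursive exact distribution
_ENUM_MAX_TOTAL = 14  # combined, explicit enumeration when ties present


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)


def _enumerate_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed permutation p-value of the Mann–Whitney U statistic."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _u_statistic(x, y)
    idx = range(len(pooled))
    us = []
    for comb in itertools.combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        us.append(_u_statistic(pooled[mask], pooled[~mask]))
    us = np.asarray(us)
    p_lo = np.mean(us <= u_obs)
    p_hi = np.mean(us >= u_obs)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def mann_whitney_p(x, y) -> float:
    """Two-tailed Mann–Whitney p-value.

    Exact distribution for groups of at most 20 without ties; explicit
    permutation enumeration for small tied samples; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N:
        return float(mannwhitneyu(x, y, alternative="two-sided",
                                  method="exact").pvalue)
    if has_ties and len(pooled) <= _ENUM_MAX_TOTAL:
        return _enumerate_p(x, y)
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic",
                              use_continuity=False).pvalue)


def compare_conditions(groups: dict[str, list[float]]) -> dict[tuple[str, str], float]:
    """Pairwise two-tailed Mann–Whitney p-values between condition groups."""
    names = list(groups)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            out[(a, b)] = mann_whitney_p(groups[a], groups[b])
    return out
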