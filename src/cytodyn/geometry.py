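"""Curvature and directional-persistence statistics of directed runs.

Two complementary measures of trajectory geometry: the distribution of
local backbone curvature (weighted by arc length, with an exponential
decay constant summarizing the tail) and the directional persistence of
raw displacements — the mean cosine between consecutive displacement
directions as a function of cumulative displacement, summarized by the
correlation length of its exponential decay.  Together they separate
smoothly curved trajectories from trajectories distorted by stochastic
filament motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .runs import RunSegment, SplineFit

__all__ = [
    "CurvatureDistribution",
    "PersistenceCurve",
    "local_curvature",
    "curvature_distribution",
    "directional_persistence",
]


@dataclass
class CurvatureDistribution:
    """Arc-length-weighted histogram of local curvature."""

    bin_edges: np.ndarray  # µm⁻¹
    weights: np.ndarray  # µm of arc length per bin
    cumulative_fraction: np.ndarray  # ends at 1
    decay_constant: float  # µm⁻¹, exponential fit; nan if skipped
    decay_stderr: float

    def fraction_below(self, kappa: float) -> float:
        """Fraction of total arc length with curvature below ``kappa``."""
        total = self.weights.sum()
        frac = 0.0
        for lo, hi, w in zip(self.bin_edges[:-1], self.bin_edges[1:], self.weights):
            if hi <= kappa:
                frac += w
            elif lo < kappa:
                frac += w * (kappa - lo) / (hi - lo)
        return float(frac / total) if total > 0 else np.nan


@dataclass
class PersistenceCurve:
    """Mean cosine between consecutive displacements vs cumulative displacement."""

    displacement: np.ndarray  # µm bin centers (lag · speed · dt)
    mean_cos: np.ndarray
    sem: np.ndarray
    correlation_length: float  # µm; inf when no decay observed
    correlation_length_stderr: float


def local_curvature(spline: SplineFit, s: float | np.ndarray) -> float | np.ndarray:
    """Curvature κ(s) = |x'y'' − y'x''| / (x'²+y'²)^{3/2} at arc length s.

    Evaluated from analytic spline derivatives; clamped ends use the
    one-sided limit (evaluation just inside the domain).
    """
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < -1e-9) or np.any(s_arr > spline.arc_length + 1e-9):
        raise ValueError("arc length outside the spline domain")
    u = spline.u_of_s(np.clip(s_arr, 0.0, spline.arc_length))
    lo, hi = spline.domain
    eps = 1e-9 * max(hi - lo, 1.0)
    u = np.clip(u, lo + eps, hi - eps)
    kappa = spline.curvature(u)
    return float(kappa[0]) if np.isscalar(s) else kappa


def curvature_distribution(
    splines: list[SplineFit],
    ds: float = 0.05,
    kappa_max: float = 5.0,
    bin_width: float = 0.1,
) -> CurvatureDistribution:
    """Arc-length-weighted curvature histogram over a set of backbones.

    Curvature is sampled every ``ds`` µm of arc length on every spline and
    histogrammed with weight ``ds`` per sample, so bin weights are µm of
    arc length and sum to the total sampled length.  An exponential
    probability model is fit to the weighted histogram by least squares on
    log-counts (empty bins excluded), giving the characteristic decay
    constant of the curvature distribution.
    """
    if ds <= 0:
        raise ValueError("ds must be > 0")
    samples, weights = [], []
    for sp in splines:
        n = max(int(np.floor(sp.arc_length / ds)), 1)
        s_vals = (np.arange(n) + 0.5) * (sp.arc_length / n)
        kappa = np.atleast_1d(local_curvature(sp, s_vals))
        samples.append(np.clip(kappa, 0.0, kappa_max))
        weights.append(np.full(len(s_vals), sp.arc_length / n))
    kappa = np.concatenate(samples)
    w = np.concatenate(weights)

    edges = np.arange(0.0, kappa_max + bin_width, bin_width)
    hist, _ = np.histogram(kappa, bins=edges, weights=w)
    cum = np.cumsum(hist) / hist.sum()

    centers = 0.5 * (edges[:-1] + edges[1:])
    pos = hist > 0
    if pos.sum() >= 2 and np.any(kappa > bin_width):
        logc = np.log(hist[pos])
        slope, intercept = np.polyfit(centers[pos], logc, 1)
        # slope = -1/decay; stderr via residual variance of the linear fit
        resid = logc - (slope * centers[pos] + intercept)
        dof = max(pos.sum() - 2, 1)
        var_slope = (np.sum(resid**2) / dof
                     / np.sum((centers[pos] - centers[pos].mean()) ** 2))
        if slope < 0:
            decay = -1.0 / slope
            stderr = np.sqrt(var_slope) / slope**2
        else:
            decay, stderr = np.nan, np.nan
    else:
        decay, stderr = np.nan, np.nan
    return CurvatureDistribution(edges, hist, cum, float(decay), float(stderr))


def directional_persistence(
    runs: list[RunSegment],
    speed_assumption: float,
    max_lag: int | None = None,
) -> PersistenceCurve:
    """Mean cosine between displacements vs cumulative displacement.

    For each lag k, the cosine of the angle between displacement vectors
    ``k`` steps apart is averaged over all runs; the lag axis is converted
    to µm of displacement assuming constant speed ``speed_assumption``.
    The correlation length ℓ comes from a least-squares fit of
    ``mean_cos(Δ) = exp(−Δ/ℓ)``; a non-decaying (ballistic) signal reports
    ``ℓ = inf``.
    """
    if not runs or any(len(r) < 3 for r in runs):
        raise ValueError("runs must each have >= 3 points")
    dt = runs[0].dt
    n_max = max(len(r) - 2 for r in runs)
    if max_lag is None:
        max_lag = n_max
    max_lag = min(max_lag, n_max)
    if max_lag < 2:
        raise ValueError("insufficient lags for a persistence curve")

    sums = np.zeros(max_lag)
    sqs = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for r in runs:
        disp = np.diff(r.positions, axis=0)
        norm = np.linalg.norm(disp, axis=1)
        unit = np.divide(disp, norm[:, None], out=np.zeros_like(disp),
                         where=norm[:, None] > 0)
        for k in range(1, max_lag + 1):
            if len(unit) <= k:
                break
            c = np.einsum("ij,ij->i", unit[:-k], unit[k:])
            sums[k - 1] += c.sum()
            sqs[k - 1] += (c**2).sum()
            counts[k - 1] += len(c)

    good = counts > 0
    mean_cos = sums[good] / counts[good]
    var = sqs[good] / counts[good] - mean_cos**2
    sem = np.sqrt(np.maximum(var, 0.0) / counts[good])
    lags = np.arange(1, max_lag + 1)[good]
    displacement = lags * speed_assumption * dt

    if np.all(mean_cos > 0.99):
        ell, ell_err = np.inf, np.nan
    else:
        try:
            p0 = [max(displacement[-1] / 3.0, displacement[0])]
            popt, pcov = curve_fit(
                lambda x, ell: np.exp(-x / ell), displacement, mean_cos,
                p0=p0, maxfev=10000)
            ell = float(popt[0])
            ell_err = float(np.sqrt(pcov[0, 0]))
        except Exception:
            ell, ell_err = np.nan, np.nan
    return PersistenceCurve(displacement, mean_cos, sem, ell, ell_err)
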