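"""Signed RBC velocity from kymographs.

The primary estimator is windowed cross-correlation PIV: within each
short time window, every kymograph line is correlated against the line
``line_lag`` samples later, the normalized correlograms are averaged,
and the sub-pixel peak offset gives the displacement per line.  Windows
advance by a stride much shorter than the window, so successive
estimates overlap (a 2-ms window with 0.2-ms stride yields 5 estimates
per millisecond).

A Radon-transform estimator (streak angle of maximal sinogram variance)
is provided as an independent secondary method; it degrades near the
measurement bound where streaks become nearly horizontal.

The bound itself: a cell must be sampled at least twice while crossing
the focal array, so the displacement between consecutive samples can be
at most half the array length h, giving ``v_max = f·h/2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import radon

from .containers import GainProfile, Kymograph, VelocityTrace

__all__ = [
    "PIVConfig",
    "max_measurable_speed",
    "piv_velocity",
    "radon_velocity",
]


def max_measurable_speed(sampling_rate: float, array_length: float) -> float:
    """Maximum measurable flow speed ``v = f·h/2`` in mm/s.

    Parameters
    ----------
    sampling_rate : float
        Line or frame rate f in Hz.
    array_length : float
        Length h of the focal array (µm).
    """
    if sampling_rate < 0 or array_length < 0:
        raise ValueError("rate and length must be nonnegative")
    return sampling_rate * array_length / 2.0 * 1e-3  # µm/s → mm/s


@dataclass
class PIVConfig:
    """Windowing and peak-refinement parameters for kymograph PIV."""

    window_ms: float = 2.0
    stride_ms: float = 0.2
    line_lag: int = 1
    subpixel: str = "parabolic"  # or "centroid"
    min_quality: float = 0.1

    def __post_init__(self) -> None:
        if self.stride_ms > self.window_ms:
            raise ValueError("stride must not exceed the window length")
        if self.line_lag < 1:
            raise ValueError("line_lag must be >= 1")
        if self.subpixel not in ("parabolic", "centroid"):
            raise ValueError("subpixel must be 'parabolic' or 'centroid'")


def _subpixel_offset(corr: np.ndarray, peak: int, method: str) -> float:
    """Refine an integer correlation peak to sub-pixel precision."""
    if peak <= 0 or peak >= corr.size - 1:
        return 0.0
    c0, c1, c2 = corr[peak - 1], corr[peak], corr[peak + 1]
    if method == "parabolic":
        denom = c0 - 2 * c1 + c2
        if denom >= 0:
            return 0.0
        return 0.5 * (c0 - c2) / denom
    # centroid over the 3-point neighborhood, shifted to be nonnegative
    w = np.array([c0, c1, c2]) - min(c0, c1, c2)
    if w.sum() <= 0:
        return 0.0
    return float((w @ np.array([-1.0, 0.0, 1.0])) / w.sum())


def piv_velocity(k: Kymograph, cfg: PIVConfig | None = None,
                 gain: GainProfile | None = None) -> VelocityTrace:
    """Windowed cross-correlation PIV on a kymograph.

    For each window, every line is correlated against the line
    ``line_lag`` later (both mean-removed and variance-normalized), the
    correlograms are averaged, and the peak offset — refined to sub-pixel
    precision — gives the displacement in px/line.  The signed velocity is
    ``displacement · pixel_size · line_rate / line_lag`` converted to mm/s;
    positive means motion toward increasing column index.

    Windows whose peak correlation falls below ``cfg.min_quality``, blank
    windows, and peaks at the edge of the search range (|d| = X/2,
    out-of-range flow) are reported as NaN.  Columns excluded by
    normalization (``gain.excluded_mask``) are masked out of the
    correlation.
    """
    cfg = cfg or PIVConfig()
    data = np.asarray(k.data, dtype=float)
    n_lines, n_px = data.shape
    win = max(int(round(cfg.window_ms * 1e-3 * k.line_rate)), cfg.line_lag + 1)
    stride = max(int(round(cfg.stride_ms * 1e-3 * k.line_rate)), 1)
    if win > n_lines:
        raise ValueError("window longer than the kymograph")
    max_d = n_px // 2

    if gain is not None and gain.excluded_mask.any():
        data = data.copy()
        # excluded columns carry raw gain-shaded values; replace them with
        # the per-line mean of included columns so they are correlation-neutral
        inc = ~gain.excluded_mask
        data[:, ~inc] = data[:, inc].mean(axis=1, keepdims=True)

    starts = np.arange(0, n_lines - win + 1, stride)
    times = (starts + (win - 1) / 2.0) / k.line_rate
    vel = np.full(starts.size, np.nan)
    quality = np.full(starts.size, np.nan)

    # normalized cross-correlation on the overlap region, per lag, via FFT:
    # means and energies over the overlap come from correlations with a
    # box kernel, so short overlaps are not biased toward zero lag
    nfft = 2 * n_px
    lags = np.concatenate([np.arange(0, n_px), np.arange(-n_px, 0)])  # FFT order
    keep = np.abs(lags) <= max_d
    lag_vals = lags[keep]
    order = np.argsort(lag_vals)
    lag_vals = lag_vals[order]
    n_overlap = n_px - np.abs(lag_vals)
    ones = np.ones(n_px)
    f_ones = np.fft.rfft(ones, nfft)

    for i, w0 in enumerate(starts):
        seg = data[w0 : w0 + win]
        a = seg[: -cfg.line_lag]
        b = seg[cfg.line_lag :]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            continue  # featureless window
        fa = np.fft.rfft(a, nfft, axis=1)
        fb = np.fft.rfft(b, nfft, axis=1)
        faa = np.fft.rfft(a**2, nfft, axis=1)
        fbb = np.fft.rfft(b**2, nfft, axis=1)
        cross = np.fft.irfft(np.conj(fa) * fb, nfft, axis=1)[:, keep][:, order]
        sa = np.fft.irfft(np.conj(fa) * f_ones, nfft, axis=1)[:, keep][:, order]
        sb = np.fft.irfft(np.conj(f_ones) * fb, nfft, axis=1)[:, keep][:, order]
        saa = np.fft.irfft(np.conj(faa) * f_ones, nfft, axis=1)[:, keep][:, order]
        sbb = np.fft.irfft(np.conj(f_ones) * fbb, nfft, axis=1)[:, keep][:, order]
        var_a = np.clip(saa - sa**2 / n_overlap, 0, None)
        var_b = np.clip(sbb - sb**2 / n_overlap, 0, None)
        denom = np.sqrt(var_a * var_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > 1e-12 * np.max(denom, initial=0),
                           (cross - sa * sb / n_overlap) / denom, -np.inf)
        pair_ok = np.isfinite(ncc).any(axis=1)
        if not pair_ok.any():
            continue
        corr = np.where(np.isfinite(ncc), ncc, 0.0)[pair_ok].mean(axis=0)
        p = int(np.argmax(corr))
        peak_val = corr[p]
        quality[i] = peak_val
        if peak_val < cfg.min_quality:
            continue
        if abs(lag_vals[p]) >= max_d:
            continue  # displacement at the search boundary: out of range
        d = lag_vals[p] + _subpixel_offset(corr, p, cfg.subpixel)
        vel[i] = d * k.pixel_size * k.line_rate / cfg.line_lag * 1e-3

    return VelocityTrace(times, vel, window_length=win / k.line_rate * 1e3,
                         stride=stride / k.line_rate * 1e3, quality=quality)


def radon_velocity(k: Kymograph, min_anisotropy: float = 2.5) -> float:
    """Streak-angle velocity estimate of a kymograph window via the Radon
    transform.

    The projection angle maximizing the variance of the sinogram column is
    the direction along the streaks; the corresponding slope in px/line
    converts to mm/s exactly as in PIV.  Returns NaN when no dominant
    angle exists (peak variance below ``min_anisotropy`` × median).
    """
    data = np.asarray(k.data, dtype=float)
    if data.shape[0] < 16 or data.shape[1] < 16:
        raise ValueError("radon window must be at least 16×16 px")
    img = data - data.mean()
    if np.allclose(img, 0):
        return float("nan")
    # restrict to the inscribed circle so all projections see the same mass
    theta = np.arange(0.5, 180.0, 0.5)
    sino = radon(img, theta=theta, circle=True)
    var = sino.var(axis=0)
    med = np.median(var)
    if med <= 0 or var.max() / med < min_anisotropy:
        return float("nan")
    ang = theta[int(np.argmax(var))]
    # data axes: axis 0 = time (rows), axis 1 = space (columns).  A streak
    # advancing m px per line produces a projection-variance peak at the
    # angle with tan(theta) = m in skimage's convention (calibrated on
    # synthetic streaks of known slope; theta = 90° is a vertical streak
    # i.e. infinite speed, theta > 90° negative flow).
    slope = np.tan(np.deg2rad(ang))
    return float(slope * k.pixel_size * k.line_rate * 1e-3)
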