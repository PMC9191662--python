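"""Spectral structure and pulsatility of velocity traces.

Arteriolar velocity traces oscillate at the cardiac fundamental (5–15 Hz
in mouse) with a comb of harmonics; venular traces are much flatter.
The amplitude spectrum locates the fundamental and its harmonics; the
pulsatility index

    PI = (V_peak_systolic − V_min_diastolic) / V_mean

is computed per cardiac cycle (segmented peak-to-peak on the
fundamental-band-passed trace) and averaged.  For a pure modulation
``v0 (1 + m sin 2π f0 t)`` the PI is exactly 2m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import VelocityTrace

__all__ = [
    "SpectrumResult",
    "PulsatilityResult",
    "velocity_spectrum",
    "pulsatility_index",
    "correlation_matrix",
]


@dataclass
class SpectrumResult:
    frequency: np.ndarray        # Hz
    amplitude: np.ndarray        # same units as velocity; Σa² = variance
    f0: float | None             # detected fundamental, Hz
    harmonics: list              # detected harmonic orders (1 = fundamental)
    band_widths: dict            # order -> width at half prominence, Hz
    interpolated_fraction: float


@dataclass
class PulsatilityResult:
    pi: float
    per_cycle: np.ndarray        # (n_cycles, 3): V_peak, V_min, V_mean
    cycle_bounds: np.ndarray     # s

    def __post_init__(self) -> None:
        if self.pi < 0:
            raise ValueError("PI must be nonnegative")


def _fill_gaps(trace: VelocityTrace):
    v = trace.velocity.copy()
    bad = ~np.isfinite(v)
    frac = bad.mean() if v.size else 0.0
    if bad.any():
        if bad.all():
            raise ValueError("trace has no finite samples")
        v[bad] = np.interp(trace.time[bad], trace.time[~bad], v[~bad])
    return v, float(frac)


def velocity_spectrum(trace: VelocityTrace, detrend: bool = True,
                      window: str = "hann",
                      search_band: tuple = (5.0, 15.0),
                      harmonic_threshold: float = 3.0,
                      max_order: int = 12) -> SpectrumResult:
    """Amplitude spectrum of a velocity trace with harmonic detection.

    The trace must be uniformly sampled (NaN gaps are interpolated and
    their fraction reported) and at least 5 expected cardiac cycles long.
    Normalization: the amplitudes satisfy Parseval's identity — the sum of
    squared amplitudes equals the variance of the (window-compensated)
    trace; with the default Hann window the identity refers to the
    windowed trace.

    The fundamental is the largest peak inside ``search_band``; harmonic
    order k is detected when the local amplitude at k·f0 exceeds
    ``harmonic_threshold`` × the median spectral floor in its
    neighborhood.
    """
    v, frac = _fill_gaps(trace)
    n = v.size
    dt = trace.sampling_interval
    duration = n * dt
    if duration < 5.0 / search_band[0]:
        raise ValueError("record shorter than 5 expected cardiac cycles")

    x = v - v.mean()
    if detrend:
        x = signal.detrend(x)
    if window in (None, "boxcar", "rect"):
        w = np.ones(n)
    else:
        w = signal.get_window(window, n)
    xw = x * w / np.sqrt(np.mean(w**2))

    X = np.fft.rfft(xw)
    freq = np.fft.rfftfreq(n, dt)
    scale = np.full(freq.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    amp = np.sqrt(scale) * np.abs(X) / n

    df = freq[1] - freq[0]
    in_band = (freq >= search_band[0]) & (freq <= search_band[1])
    if not in_band.any():
        raise ValueError("search band outside the resolvable frequencies")
    f0 = None
    harmonics: list[int] = []
    widths: dict[int, float] = {}
    band_amp = np.where(in_band, amp, 0.0)
    i0 = int(np.argmax(band_amp))
    # significance gate: the band argmax is large by construction, so it
    # must clear a broadband floor before it counts as a cardiac peak
    # (a white-noise trace otherwise always "finds" a fundamental)
    floor_sel = (freq > 0) & (np.abs(freq - freq[i0]) > 3 * df)
    broad_floor = np.median(amp[floor_sel]) if floor_sel.any() else 0.0
    if band_amp[i0] > 0 and band_amp[i0] > 4.0 * broad_floor:
        f0 = float(freq[i0])
        half_bw = max(2 * df, 0.15 * f0 / 2)
        nyq = freq[-1]
        for k in range(1, max_order + 1):
            fk = k * f0
            if fk > nyq - half_bw:
                break
            sel = np.abs(freq - fk) <= half_bw
            neigh = (np.abs(freq - fk) <= 10 * half_bw) & ~sel & (freq > 0)
            floor = np.median(amp[neigh]) if neigh.any() else 0.0
            peak = amp[sel].max() if sel.any() else 0.0
            if floor > 0 and peak > harmonic_threshold * floor:
                harmonics.append(k)
                j = int(np.flatnonzero(sel)[np.argmax(amp[sel])])
                try:
                    w_, *_ = signal.peak_widths(amp, [j], rel_height=0.5)
                    widths[k] = float(w_[0] * df)
                except ValueError:
                    widths[k] = df
        if not harmonics:
            f0 = None  # no significant periodicity: report no structure
    return SpectrumResult(frequency=freq, amplitude=amp, f0=f0,
                          harmonics=harmonics, band_widths=widths,
                          interpolated_fraction=frac)


def pulsatility_index(trace: VelocityTrace, f0: float,
                      band: tuple = (0.5, 1.5)) -> PulsatilityResult:
    """Per-cycle pulsatility index, averaged over cardiac cycles.

    Cycles are segmented at successive peaks of the trace band-passed
    around ``f0`` (passband ``band[0]·f0 – band[1]·f0``, zero-phase);
    within each peak-to-peak window on the raw trace,
    ``(V_peak − V_min)/V_mean`` is computed and the PI is the mean over
    cycles.  A trace with no detectable oscillation returns PI = 0.
    Fewer than 3 complete cycles (with oscillation present) raises.
    """
    if not (f0 > 0):
        raise ValueError("f0 must be positive")
    v, _ = _fill_gaps(trace)
    dt = trace.sampling_interval
    fs = 1.0 / dt
    nyq = fs / 2.0
    lo, hi = band[0] * f0, min(band[1] * f0, 0.95 * nyq)
    if lo >= hi:
        raise ValueError("band-pass limits collapse at this sampling rate")
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    filt = signal.sosfiltfilt(sos, v - v.mean())

    vscale = max(abs(v.mean()), np.abs(v).max(), 1e-300)
    if np.ptp(filt) < 1e-10 * vscale:
        # steady flow: no cardiac oscillation, PI is zero by definition
        return PulsatilityResult(pi=0.0, per_cycle=np.empty((0, 3)),
                                 cycle_bounds=np.array([]))

    peaks, _ = signal.find_peaks(filt, distance=max(1, int(0.6 * fs / f0)))
    if peaks.size < 4:  # need >= 3 complete peak-to-peak cycles
        raise ValueError("fewer than 3 complete cardiac cycles")
    if peaks.size >= 6:
        # zero-phase filtering distorts the record edges; the outermost
        # peaks can be off by a sample, so drop the boundary cycles
        peaks = peaks[1:-1]
    rows = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        seg = v[a:b]
        vmean = seg.mean()
        if vmean == 0:
            continue
        rows.append((seg.max(), seg.min(), vmean))
    per_cycle = np.asarray(rows)
    pi_vals = (per_cycle[:, 0] - per_cycle[:, 1]) / per_cycle[:, 2]
    return PulsatilityResult(pi=float(pi_vals.mean()), per_cycle=per_cycle,
                             cycle_bounds=trace.time[peaks])


def correlation_matrix(traces) -> np.ndarray:
    """Pairwise Pearson correlation of velocity fluctuations.

    Traces must already share a common time grid (equal length); means
    are removed by the correlation itself.  Zero-variance traces get NaN
    off-diagonal entries and a unit diagonal.
    """
    arrs = [t.velocity if isinstance(t, VelocityTrace) else np.asarray(t, float)
            for t in traces]
    n = len(arrs)
    if n < 2:
        raise ValueError("need at least two traces")
    length = arrs[0].size
    if any(a.size != length for a in arrs):
        raise ValueError("traces must be resampled to a common grid first")
    X = np.vstack(arrs)
    std = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C[std == 0, :] = np.nan
    C[:, std == 0] = np.nan
    np.fill_diagonal(C, 1.0)
    return C
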