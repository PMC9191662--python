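"""Illumination normalization, temporal binning and rigid motion correction.

The FACED focal array illuminates the scan line non-uniformly, so raw
frames and kymographs carry a fixed multiplicative gain along the line
(column) direction.  Normalization estimates this gain from the data
itself — from the time-summed trace of a kymograph, or from the
brightest rows of the time-averaged frame for 2D stacks — and divides it
out.  Positions whose correction would boost the signal more than
``boost_cap``-fold (dim edges of the field of view) are excluded and
keep their original values.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .containers import FrameStack, GainProfile, Kymograph

__all__ = [
    "normalize_kymograph",
    "normalize_stack",
    "bin_time",
    "register_rigid",
]


def _gain_from_trace(trace: np.ndarray, boost_cap: float):
    """Turn a summed-intensity trace into a unit-mean gain estimate and an
    exclusion mask (boost factor > cap, or zero signal)."""
    trace = np.asarray(trace, dtype=float)
    excluded = trace <= 0
    for _ in range(8):
        included = ~excluded
        if not included.any():
            raise ValueError("all positions excluded during normalization")
        gain = trace / trace[included].mean()
        with np.errstate(divide="ignore"):
            boost = np.where(gain > 0, 1.0 / gain, np.inf)
        new_excluded = (boost > boost_cap) | (trace <= 0)
        if np.array_equal(new_excluded, excluded):
            break
        excluded = new_excluded
    gain = trace / trace[~excluded].mean()
    return gain, excluded


def normalize_kymograph(k: Kymograph, boost_cap: float = 5.0):
    """Divide each kymograph column by the unit-mean gain estimated from
    the time-summed trace.  Returns ``(Kymograph, GainProfile)``."""
    if np.any(k.data < 0):
        raise ValueError("normalization expects nonnegative intensities")
    trace = k.data.sum(axis=0)
    gain, excluded = _gain_from_trace(trace, boost_cap)
    out = k.data.astype(float).copy()
    inc = ~excluded
    out[:, inc] = out[:, inc] / gain[inc]
    return Kymograph(out, k.line_rate, k.pixel_size), GainProfile(gain, excluded)


def normalize_stack(s: FrameStack, n_lines: int = 10, boost_cap: float = 5.0):
    """Normalize the along-line (column) FACED gain of a frame stack.

    The time-averaged frame's rows are ranked by their summed signal; the
    ``n_lines`` brightest rows are summed along the slow (row) axis to give a
    per-column trace, which after rescaling to unit mean divides every row
    of every frame.  Returns ``(FrameStack, GainProfile)``.
    """
    if s.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate the gain")
    mean_img = s.data.mean(axis=0)
    H = mean_img.shape[0]
    if H < n_lines:
        warnings.warn(f"only {H} rows available; using all of them")
        n_lines = H
    row_sums = mean_img.sum(axis=1)
    top = np.argsort(row_sums)[-n_lines:]
    trace = mean_img[top].sum(axis=0)
    gain, excluded = _gain_from_trace(trace, boost_cap)
    out = s.data.astype(float).copy()
    inc = ~excluded
    out[:, :, inc] = out[:, :, inc] / gain[inc]
    return FrameStack(out, s.frame_rate, s.pixel_size, s.origin), GainProfile(gain, excluded)


def bin_time(x, factor: int):
    """Non-overlapping temporal mean binning; the trailing remainder is
    dropped and the rate divided by ``factor``."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if isinstance(x, Kymograph):
        n = x.n_lines
        if factor > n:
            raise ValueError("factor exceeds number of lines")
        m = n // factor
        data = x.data[: m * factor].reshape(m, factor, -1).mean(axis=1)
        return Kymograph(data, x.line_rate / factor, x.pixel_size)
    if isinstance(x, FrameStack):
        n = x.n_frames
        if factor > n:
            raise ValueError("factor exceeds number of frames")
        m = n // factor
        shape = (m, factor) + x.data.shape[1:]
        data = x.data[: m * factor].reshape(shape).mean(axis=1)
        return FrameStack(data, x.frame_rate / factor, x.pixel_size, x.origin)
    raise TypeError("bin_time expects a FrameStack or Kymograph")


def register_rigid(s: FrameStack, reference: str | int = "mean",
                   upsample_factor: int = 10, min_peak: float = 0.05):
    """Correct whole-frame rigid translation by phase correlation.

    Each frame is aligned to the reference (the temporal mean, or a chosen
    frame index) with sub-pixel precision via upsampled cross-correlation,
    then shifted by spline interpolation with replicate padding.  Returns
    ``(FrameStack, displacements)`` where ``displacements[k] = (dx, dy)`` is
    the estimated motion of frame k (the applied correction is its
    negative).  Featureless frames (normalized correlation peak below
    ``min_peak``) are left unshifted with a warning.
    """
    if s.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if reference == "mean":
        ref = s.data.mean(axis=0)
    else:
        ref = s.data[int(reference)]

    out = np.empty_like(s.data, dtype=float)
    disp = np.zeros((s.n_frames, 2))
    ref_var = ref.std()
    for k in range(s.n_frames):
        frame = s.data[k].astype(float)
        if ref_var == 0 or frame.std() == 0:
            warnings.warn(f"frame {k}: featureless; zero shift assumed")
            out[k] = frame
            continue
        (dy, dx), error, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        peak = 1.0 - error  # error = sqrt(1 - cc^2) proxy from skimage
        if not np.isfinite(peak) or peak < min_peak:
            warnings.warn(f"frame {k}: correlation peak below threshold; zero shift")
            out[k] = frame
            continue
        # phase correlation returns the shift that maps frame onto ref
        out[k] = ndimage.shift(frame, (dy, dx), order=1, mode="nearest")
        disp[k] = (-dx, -dy)
    return FrameStack(out, s.frame_rate, s.pixel_size, s.origin), disp
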