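"""Kymograph and cross-section extraction along polyline ROIs.

A line-shaped ROI drawn along a vessel axis turns a frame stack into a
kymograph (one row per frame, sampled at uniform arc-length spacing by
bilinear interpolation).  A short line drawn perpendicular to a
capillary yields a cross-section image whose dark blobs are individual
RBC transits, consumed by the bifurcation flux counter.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .containers import CrossSectionImage, FrameStack, Kymograph, PolylineROI

__all__ = ["extract_kymograph", "extract_cross_section", "offset_polyline"]


def _sample_points(s: FrameStack, roi: PolylineROI, band_width: int = 1) -> np.ndarray:
    """Sample the stack at the resampled ROI points (optionally averaging
    across a perpendicular band of ``band_width`` parallel samples);
    returns (T, N)."""
    pts = roi.resample()
    if pts.shape[0] < 3:
        raise ValueError("ROI shorter than 3 samples at the requested spacing")
    H, W = s.data.shape[1:]
    if (pts[:, 0].min() < -0.5 or pts[:, 0].max() > W - 0.5
            or pts[:, 1].min() < -0.5 or pts[:, 1].max() > H - 0.5):
        raise ValueError("ROI extends outside the image bounds")

    offsets = [0.0]
    if band_width > 1:
        offsets = np.arange(band_width) - (band_width - 1) / 2.0
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    acc = np.zeros((s.n_frames, pts.shape[0]))
    for off in np.atleast_1d(offsets):
        p = pts + off * normal
        coords = np.vstack([p[:, 1], p[:, 0]])  # (row, col) order
        for k in range(s.n_frames):
            acc[k] += ndimage.map_coordinates(
                s.data[k].astype(float), coords, order=1, mode="nearest"
            )
    return acc / max(1, len(np.atleast_1d(offsets)))


def extract_kymograph(s: FrameStack, roi: PolylineROI, band_width: int = 1) -> Kymograph:
    """Extract a kymograph along a vessel-axis polyline.

    The polyline is resampled at uniform arc-length spacing
    (``roi.spacing`` px, default 1); each frame contributes one row.  The
    kymograph inherits the stack frame rate as its line rate and
    ``spacing · pixel_size`` as its spatial sampling.  Reversing the ROI
    flips the sign of downstream velocities.
    """
    data = _sample_points(s, roi, band_width)
    return Kymograph(data, line_rate=s.frame_rate,
                     pixel_size=roi.spacing * s.pixel_size)


def extract_cross_section(s: FrameStack, line: PolylineROI,
                          band_width: int = 1) -> CrossSectionImage:
    """Extract a T×X image along a line perpendicular to a capillary axis;
    RBC transits appear as dark blobs."""
    data = _sample_points(s, line, band_width)
    return CrossSectionImage(data, frame_rate=s.frame_rate,
                             pixel_size=line.spacing * s.pixel_size, line=line)


def offset_polyline(roi: PolylineROI, offset_px: float) -> PolylineROI:
    """Shift a polyline laterally along its local normal by ``offset_px``
    pixels (positive = normal side of the tangent, i.e. tangent rotated
    +90° in image coordinates).  Used to build radial profiles."""
    v = roi.vertices
    tang = np.gradient(v, axis=0)
    tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    return PolylineROI(v + offset_px * normal, roi.spacing)
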