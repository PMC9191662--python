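"""Core calibrated-image containers shared across the pipeline.

Conventions used throughout the package:

* ``FrameStack.data`` is ``(T, H, W)`` — time, rows, columns.
* ``Kymograph.data`` is ``(T, X)`` — rows are time (successive line samples),
  columns are space along the scan line.
* Pixel coordinates are 0-based, ``(x, y)`` with origin at the top-left
  corner; ``x`` indexes columns, ``y`` indexes rows.
* Velocities are signed: positive means motion toward increasing column
  index / increasing ROI arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FrameStack:
    """Calibrated T×H×W image time series.

    Parameters
    ----------
    data : ndarray, shape (T, H, W)
        Intensity frames (photon-count scale for simulated data).
    frame_rate : float
        Frames per second (Hz).
    pixel_size : float
        Lateral sampling, µm per pixel (isotropic).
    origin : str
        Free-form acquisition label.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("FrameStack.data must be a (T, H, W) array with T >= 1")
        if not (self.frame_rate > 0):
            raise ValueError("frame_rate must be positive")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def times(self) -> np.ndarray:
        """Frame time stamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class Kymograph:
    """2D space–time image; rows are time, columns are space."""

    data: np.ndarray
    line_rate: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Kymograph.data must be 2D (time × space)")
        if not (self.line_rate > 0):
            raise ValueError("line_rate must be positive")
        if not (self.pixel_size > 0):
            raise ValueError("pixel_size must be positive")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_lines / self.line_rate


@dataclass
class GainProfile:
    """Per-position multiplicative illumination factors.

    ``factors[i]`` is the estimated relative gain at spatial position ``i``
    (unit mean over included positions).  ``excluded_mask[i]`` is True where
    the correction would exceed the boost cap and the data were left
    untouched.
    """

    factors: np.ndarray
    excluded_mask: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
        if self.factors.shape != self.excluded_mask.shape:
            raise ValueError("factors and excluded_mask must have identical shape")
        included = self.factors[~self.excluded_mask]
        if included.size and not np.all(included > 0):
            raise ValueError("gain factors must be positive where not excluded")


@dataclass
class PolylineROI:
    """Ordered polyline in pixel coordinates.

    Vertices are ``(x, y)`` pairs, 0-based, origin top-left.  ``spacing`` is
    the arc-length resampling step (pixels) used when the ROI is sampled.
    """

    vertices: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.vertices.shape[0] < 2 or self.vertices.shape[1] != 2:
            raise ValueError("PolylineROI needs >= 2 (x, y) vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("ROI vertices must be finite")
        if not (self.spacing > 0):
            raise ValueError("spacing must be positive")

    def arc_length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))

    def resample(self) -> np.ndarray:
        """Resample at uniform arc-length spacing; returns (N, 2) (x, y)."""
        v = self.vertices
        seg = np.diff(v, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        if total <= 0:
            raise ValueError("degenerate ROI (zero length)")
        n = int(np.floor(total / self.spacing)) + 1
        s = np.arange(n) * self.spacing
        x = np.interp(s, cum, v[:, 0])
        y = np.interp(s, cum, v[:, 1])
        return np.column_stack([x, y])

    def reversed(self) -> "PolylineROI":
        return PolylineROI(self.vertices[::-1].copy(), self.spacing)


@dataclass
class CrossSectionImage:
    """T×X image sampled along a line crossing a vessel perpendicular
    to its axis; consumed by flux counting at bifurcations."""

    data: np.ndarray
    frame_rate: float
    pixel_size: float
    line: PolylineROI | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[1] < 3:
            raise ValueError("CrossSectionImage must be T×X with X >= 3")
        if not (self.frame_rate > 0):
            raise ValueError("frame_rate must be positive")


@dataclass
class VelocityTrace:
    """Signed RBC velocity vs time from windowed velocimetry.

    ``quality`` is the per-window peak correlation score; windows flagged
    unusable carry NaN velocity.
    """

    time: np.ndarray
    velocity: np.ndarray
    window_length: float  # ms
    stride: float  # ms
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.time.shape != self.velocity.shape:
            raise ValueError("time and velocity must have identical shape")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=float)

    @property
    def sampling_interval(self) -> float:
        """Median spacing between estimates, in seconds."""
        if self.time.size < 2:
            raise ValueError("need >= 2 samples")
        return float(np.median(np.diff(self.time)))


@dataclass
class FlowField:
    """Per-pixel 2D displacement field between two frames.

    ``u`` is the horizontal (column) component, ``v`` vertical (row), both in
    native pixels per frame.  ``mask`` marks pixels considered valid for
    reporting; masked-out pixels are zero.
    """

    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray | None = None
    pixel_size: float = 1.0
    frame_rate: float = 1.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have identical shape")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def speed_px(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def speed_mm_s(self) -> np.ndarray:
        """Flow speed map in mm/s (pixel_size µm/px × frame_rate 1/s)."""
        return self.speed_px() * self.pixel_size * self.frame_rate * 1e-3


def save_roi_csv(roi: PolylineROI, path) -> None:
    """Write a polyline ROI as CSV with header ``x_px,y_px``."""
    import pandas as pd

    pd.DataFrame(roi.vertices, columns=["x_px", "y_px"]).to_csv(path, index=False)


def load_roi_csv(path, spacing: float = 1.0) -> PolylineROI:
    import pandas as pd

    df = pd.read_csv(path)
    return PolylineROI(df[["x_px", "y_px"]].to_numpy(float), spacing=spacing)
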