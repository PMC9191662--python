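"""Synthetic blood-flow data with exact ground truth.

Emulates the raw data of kilohertz two-photon hemodynamic imaging:
dark unlabeled red blood cells (RBCs) moving through bright
dextran-labeled plasma, observed either as slanted streaks in a
space–time kymograph, as moving blobs in a full-frame video of a vessel
with a blunted laminar velocity profile, or as transitory fluorescence
dips when cells cross the focal plane of a penetrating vessel.

Every generator is deterministic given its spec and seed and returns the
exact ground truth (trajectories, velocities, event times, gain and
motion traces) alongside the rendered data, so each downstream analysis
stage can be validated without real recordings.

Cells are rendered as smooth dark blobs with error-function edges so
that sub-pixel displacement is physically meaningful; Poisson shot noise
is applied on the photon-count scale, with optional additive Gaussian
read noise after.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .containers import FrameStack, Kymograph, PolylineROI

SPEED_OF_LIGHT = 2.998e8  # m/s

__all__ = [
    "NoiseModel",
    "SimKymographSpec",
    "SimVesselSpec",
    "SimPenetratingSpec",
    "GroundTruth",
    "simulate_kymograph",
    "simulate_vessel_video",
    "simulate_penetrating_trace",
    "faced_geometry",
    "blunted_profile",
]


# ---------------------------------------------------------------------------
# noise

@dataclass
class NoiseModel:
    """Photon-detection noise: ``kind`` in {"none", "poisson",
    "poisson+gaussian"}; ``read_sigma`` is the additive Gaussian read-noise
    standard deviation (counts), used only by the third kind."""

    kind: str = "none"
    read_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise kind: {self.kind!r}")
        if self.kind == "poisson+gaussian" and not (self.read_sigma > 0):
            raise ValueError("poisson+gaussian requires read_sigma > 0")

    @classmethod
    def coerce(cls, value) -> "NoiseModel":
        if isinstance(value, cls):
            return value
        if value is None:
            return cls("none")
        if isinstance(value, str):
            return cls(value)
        raise TypeError("noise model must be a NoiseModel or a string")

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return clean
        noisy = rng.poisson(np.clip(clean, 0, None)).astype(float)
        if self.kind == "poisson+gaussian":
            noisy = noisy + rng.normal(0.0, self.read_sigma, clean.shape)
        return noisy


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Exact simulation truth.

    Only the fields relevant to the generator that produced it are set.
    Positions are in µm along the scan line / vessel axis; velocities in
    mm/s; times in seconds.
    """

    times: np.ndarray | None = None
    velocity: np.ndarray | None = None            # true advection speed per line/frame
    trajectories: np.ndarray | None = None        # (n_times, n_cells) positions, µm
    radial_offsets: np.ndarray | None = None      # per-cell r, µm
    event_times: np.ndarray | None = None
    diameter: float | None = None                 # µm
    gain_profile: np.ndarray | None = None
    motion_trace: np.ndarray | None = None        # (T, 2) (dx, dy) px
    occlusion_fraction: np.ndarray | None = None  # per line/frame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.event_times is not None:
            self.event_times = np.asarray(self.event_times, dtype=float)
            if self.event_times.size > 1 and not np.all(np.diff(self.event_times) > 0):
                raise ValueError("event times must be strictly increasing")


# ---------------------------------------------------------------------------
# specs

@dataclass
class SimKymographSpec:
    """Line-scan kymograph of single-file flow.

    ``velocity_fn`` maps time (s) to signed velocity (mm/s); positive flow
    moves cells toward increasing space coordinate.
    """

    line_rate: float = 1000.0        # Hz
    pixel_size: float = 0.5          # µm/px
    line_length: float = 50.0        # µm
    duration: float = 1.0            # s
    velocity_fn: Callable[[np.ndarray], np.ndarray] = lambda t: np.full_like(t, 2.0)
    rbc_linear_density: float = 100.0  # cells/mm
    rbc_length: float = 6.0          # µm
    contrast: float = 0.8
    background_level: float = 200.0  # photon counts
    edge_softness: float = 0.5       # µm, erf edge scale
    noise_model: NoiseModel | str = "none"
    seed: int = 0
    max_lines: int = 5_000_000       # memory cap

    def validate(self) -> None:
        if not (self.line_rate > 0 and self.pixel_size > 0):
            raise ValueError("line_rate and pixel_size must be positive")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")
        if self.duration * self.line_rate > self.max_lines:
            raise ValueError("duration·line_rate exceeds the memory cap")


@dataclass
class SimVesselSpec:
    """Full-frame video of a vessel with a blunted laminar profile.

    The radial velocity profile is
    ``V(r) = Vmax [1 − (1 − β)|(r − r0)/R|^B]``, modulated in time by a
    cardiac fundamental ``f0`` plus harmonics with the given per-harmonic
    modulation depths.  ``faced_gain_profile`` (length W) is the relative
    pulse intensity along the focal array, applied to every row.
    """

    frame_rate: float = 1000.0       # Hz
    pixel_size: float = 0.5          # µm/px
    fov: tuple = (40, 96)            # (H, W) px
    vessel_axis: np.ndarray | None = None  # polyline (x, y) px; default horizontal
    lumen_radius: float = 8.0        # µm
    vmax: float = 5.0                # mm/s
    bluntness_B: float = 2.0
    beta: float = 0.0
    r0: float = 0.0                  # µm
    f0: float = 10.0                 # Hz cardiac fundamental
    modulation_depths: Sequence[float] = ()   # per harmonic, fraction of mean
    n_rbc: int = 60
    rbc_radius: float = 3.0          # µm
    contrast: float = 0.85
    background_level: float = 200.0  # plasma counts
    outside_level: float = 10.0      # parenchyma counts
    outside_texture: float = 0.0     # static parenchyma speckle amplitude
    edge_softness: float = 0.5       # µm
    motion_trace: np.ndarray | None = None    # (T, 2) px
    faced_gain_profile: np.ndarray | None = None  # length W
    noise_model: NoiseModel | str = "none"
    duration: float = 0.2            # s
    seed: int = 0

    def validate(self) -> None:
        if not (self.bluntness_B > 0):
            raise ValueError("bluntness index B must be positive")
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must lie in [0, 1]")
        if not (abs(self.r0) < self.lumen_radius):
            raise ValueError("r0 must lie strictly inside the lumen")
        if self.faced_gain_profile is not None and np.any(
            np.asarray(self.faced_gain_profile) <= 0
        ):
            raise ValueError("gain profile must be strictly positive")


@dataclass
class SimPenetratingSpec:
    """Fluorescence trace of a penetrating vessel cross-section.

    RBC transits arrive as a Poisson process at ``mean_flux`` and each
    produces a Gaussian dip (both edges of width ``transit_sigma``) of
    fractional depth ``dip_depth`` below ``baseline``.
    """

    frame_rate: float = 1000.0   # Hz
    mean_flux: float = 50.0      # cells/s
    transit_sigma: float = 2e-3  # s
    dip_depth: float = 0.6       # fraction of baseline
    baseline: float = 200.0      # counts
    duration: float = 10.0       # s
    noise_model: NoiseModel | str = "none"
    seed: int = 0

    def validate(self) -> None:
        if self.mean_flux < 0:
            raise ValueError("mean_flux must be >= 0")
        if not (self.transit_sigma > 0):
            raise ValueError("transit_sigma must be positive")
        if not (0 < self.dip_depth <= 1):
            raise ValueError("dip_depth must be in (0, 1]")


# ---------------------------------------------------------------------------
# profile model (shared with the fitting module)

def blunted_profile(r, vmax: float, R: float, B: float, beta: float, r0: float = 0.0):
    """Blunted-parabola radial velocity profile
    ``V(r) = Vmax [1 − (1 − β)|(r − r0)/R|^B]``."""
    r = np.asarray(r, dtype=float)
    return vmax * (1.0 - (1.0 - beta) * np.abs((r - r0) / R) ** B)


def _cell_occupancy_1d(x_px: np.ndarray, centers: np.ndarray, length: float,
                       softness: float) -> np.ndarray:
    """Summed occupancy of 1D cells with erf edges, clipped to [0, 1].

    ``x_px``: pixel-center coordinates (µm); ``centers``: (n_lines, n_cells).
    """
    half = length / 2.0
    s = softness * np.sqrt(2.0)
    # broadcast: (n_lines, n_cells, n_px)
    d = x_px[None, None, :] - centers[:, :, None]
    occ = 0.5 * (erf((d + half) / s) - erf((d - half) / s))
    return np.clip(occ.sum(axis=1), 0.0, 1.0)


# ---------------------------------------------------------------------------
# kymograph generator

def simulate_kymograph(spec: SimKymographSpec):
    """Render a single-file flow kymograph with exact truth.

    Returns ``(Kymograph, GroundTruth)``.  Streak slope in px/line equals
    ``v·1000 / (pixel_size · line_rate)`` for velocity v in mm/s.
    """
    spec.validate()
    noise = NoiseModel.coerce(spec.noise_model)
    rng = np.random.default_rng(spec.seed)

    n_lines = int(round(spec.duration * spec.line_rate))
    n_px = int(round(spec.line_length / spec.pixel_size))
    t = np.arange(n_lines) / spec.line_rate
    v = np.asarray(spec.velocity_fn(t), dtype=float)
    if v.shape != t.shape:
        v = np.broadcast_to(v, t.shape).astype(float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity_fn returned non-finite values")

    # cumulative displacement in µm (velocity mm/s = µm/ms)
    disp = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) / 2.0) / spec.line_rate]) * 1e3

    L = spec.line_length
    n_cells = max(1, int(round(spec.rbc_linear_density * L / 1000.0)))
    x0 = rng.uniform(0.0, L, n_cells)
    pos = np.mod(x0[None, :] + disp[:, None], L)

    x_px = (np.arange(n_px) + 0.5) * spec.pixel_size
    # replicate cells at ±L so wrap-around streaks stay continuous
    centers = np.concatenate([pos, pos - L, pos + L], axis=1)
    occ = _cell_occupancy_1d(x_px, centers, spec.rbc_length, spec.edge_softness)

    clean = spec.background_level * (1.0 - spec.contrast * occ)
    data = noise.apply(clean, rng)

    truth = GroundTruth(
        times=t,
        velocity=v,
        trajectories=pos,
        occlusion_fraction=occ.mean(axis=1),
        params={
            "line_rate": spec.line_rate,
            "pixel_size": spec.pixel_size,
            "background_level": spec.background_level,
            "contrast": spec.contrast,
            "initial_positions": x0,
            "cumulative_displacement_um": disp,
        },
    )
    return Kymograph(data, spec.line_rate, spec.pixel_size), truth


# ---------------------------------------------------------------------------
# vessel video generator

def _default_axis(fov, pixel_size):
    H, W = fov
    y = (H - 1) / 2.0
    return np.array([[0.0, y], [W - 1.0, y]])


def simulate_vessel_video(spec: SimVesselSpec):
    """Render a full-frame vessel video with exact truth.

    RBCs are seeded uniformly over the lumen cross-section and advected at
    the blunted-profile velocity of their radial offset, modulated by the
    cardiac waveform.  Whole-frame rigid motion, per-column FACED gain and
    photon noise are applied in that order.  Cells leaving the segment
    re-enter upstream (periodic boundary) so density stays stationary.
    """
    spec.validate()
    noise = NoiseModel.coerce(spec.noise_model)
    rng = np.random.default_rng(spec.seed)

    H, W = spec.fov
    n_frames = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n_frames) / spec.frame_rate
    px = spec.pixel_size
    R = spec.lumen_radius

    axis = spec.vessel_axis
    if axis is None:
        axis = _default_axis(spec.fov, px)
    axis_roi = PolylineROI(np.asarray(axis, dtype=float), spacing=0.25)
    pts = axis_roi.resample()                      # (N, 2) px, 0.25 px steps
    seg = np.diff(pts, axis=0)
    seg_len_um = np.hypot(seg[:, 0], seg[:, 1]) * px
    arc = np.concatenate([[0.0], np.cumsum(seg_len_um)])  # µm along axis
    L_axis = arc[-1]
    if L_axis <= 0:
        raise ValueError("vessel axis is degenerate")
    # unit tangent / normal per sample (normal = tangent rotated +90°)
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.hypot(tang[:, 0], tang[:, 1]), 1e-12)[:, None]
    norm = np.column_stack([-tang[:, 1], tang[:, 0]])

    single_file = 2.0 * spec.rbc_radius >= 2.0 * R
    s0 = rng.uniform(0.0, L_axis, spec.n_rbc)
    if single_file:
        r_off = np.zeros(spec.n_rbc)
    else:
        # chord-projected uniform seeding over the circular cross-section:
        # p(r) ∝ sqrt(R² − r²)
        r_off = np.empty(spec.n_rbc)
        filled = 0
        while filled < spec.n_rbc:
            cand = rng.uniform(-R, R, 2 * spec.n_rbc)
            acc = rng.uniform(0, 1, cand.size) < np.sqrt(1 - (cand / R) ** 2)
            take = cand[acc][: spec.n_rbc - filled]
            r_off[filled : filled + take.size] = take
            filled += take.size

    v_r = blunted_profile(r_off, spec.vmax, R, spec.bluntness_B, spec.beta, spec.r0)

    depths = np.asarray(spec.modulation_depths, dtype=float)
    mod = np.ones_like(t)
    for k, m in enumerate(depths, start=1):
        mod = mod + m * np.sin(2 * np.pi * k * spec.f0 * t)
    if np.any(mod < 0):
        warnings.warn("cardiac modulation drives velocity negative")

    # cumulative modulation integral (unit mean ⇒ µm displacement = v_r·I(t))
    mod_int = np.concatenate([[0.0], np.cumsum((mod[1:] + mod[:-1]) / 2.0)]) / spec.frame_rate
    s_t = np.mod(s0[None, :] + v_r[None, :] * 1e3 * mod_int[:, None], L_axis)  # (T, n)

    motion = spec.motion_trace
    if motion is None:
        motion = np.zeros((n_frames, 2))
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_frames, 2):
        raise ValueError("motion_trace must have shape (T, 2)")

    gain = spec.faced_gain_profile
    if gain is None:
        gain = np.ones(W)
    gain = np.asarray(gain, dtype=float)
    if gain.shape != (W,):
        raise ValueError("faced_gain_profile must have length W")

    # static soft lumen mask from distance-to-axis, precomputed with padding
    pad = int(np.ceil(np.abs(motion).max())) + 2 if n_frames else 2
    yy, xx = np.mgrid[-pad : H + pad, -pad : W + pad]
    d2 = np.full(yy.shape, np.inf)
    for i in range(0, pts.shape[0], 4):  # 1-px axis sampling is enough
        d2 = np.minimum(d2, (xx - pts[i, 0]) ** 2 + (yy - pts[i, 1]) ** 2)
    d2 = np.minimum(d2, (xx - pts[-1, 0]) ** 2 + (yy - pts[-1, 1]) ** 2)
    dist_um = np.sqrt(d2) * px
    soft = spec.edge_softness * np.sqrt(2.0)
    lumen_pad = 0.5 * (1.0 - erf((dist_um - R) / soft))
    # static parenchyma speckle (fixed pattern, moves rigidly with the
    # brain) — the texture image registration locks onto in vivo
    tex_pad = np.ones_like(lumen_pad)
    if spec.outside_texture > 0:
        speckle = ndimage.gaussian_filter(
            rng.standard_normal(lumen_pad.shape), 1.0)
        speckle /= max(speckle.std(), 1e-12)
        tex_pad = np.clip(1.0 + spec.outside_texture * speckle, 0.05, None)

    frames = np.empty((n_frames, H, W))
    traj = np.empty((n_frames, spec.n_rbc))
    rr = spec.rbc_radius
    cell_pad_px = int(np.ceil((rr + 4 * spec.edge_softness) / px)) + 1

    ygrid = np.arange(H)
    xgrid = np.arange(W)
    for k in range(n_frames):
        dx, dy = motion[k]
        # sample the padded static lumen field at shifted coordinates
        ys = ygrid[:, None] - dy + pad
        xs = xgrid[None, :] - dx + pad
        iy = np.clip(ys, 0, lumen_pad.shape[0] - 1)
        ix = np.clip(xs, 0, lumen_pad.shape[1] - 1)
        coords = np.broadcast_arrays(iy, ix)
        lum = ndimage.map_coordinates(lumen_pad, coords, order=1, mode="nearest")
        tex = ndimage.map_coordinates(tex_pad, coords, order=1, mode="nearest")
        frame = spec.outside_level * tex * (1.0 - lum) + spec.background_level * lum

        # cells: interpolate axis position + normal offset, then rigid shift;
        # each cell is also rendered at s ± L so streaks wrap continuously
        # across the periodic boundary (ends extrapolated along the tangent)
        s_all = np.concatenate([s_t[k], s_t[k] - L_axis, s_t[k] + L_axis])
        r_all = np.tile(r_off, 3)
        cxy = np.empty((s_all.size, 2))
        nvec = np.empty((s_all.size, 2))
        inside = (s_all >= 0) & (s_all <= L_axis)
        idx = np.interp(s_all[inside], arc, np.arange(pts.shape[0]))
        i0 = np.clip(idx.astype(int), 0, pts.shape[0] - 1)
        frac = idx - i0
        i1 = np.clip(i0 + 1, 0, pts.shape[0] - 1)
        cxy[inside] = pts[i0] * (1 - frac[:, None]) + pts[i1] * frac[:, None]
        nvec[inside] = norm[i0]
        below = s_all < 0
        cxy[below] = pts[0] + tang[0] * (s_all[below, None] / px)
        nvec[below] = norm[0]
        above = s_all > L_axis
        cxy[above] = pts[-1] + tang[-1] * ((s_all[above, None] - L_axis) / px)
        nvec[above] = norm[-1]
        centers = cxy + nvec * (r_all[:, None] / px) + np.array([dx, dy])
        traj[k] = s_t[k]

        occ = np.zeros((H, W))
        for c in range(centers.shape[0]):
            cx, cy = centers[c]
            x_lo = max(0, int(np.floor(cx)) - cell_pad_px)
            x_hi = min(W, int(np.ceil(cx)) + cell_pad_px + 1)
            y_lo = max(0, int(np.floor(cy)) - cell_pad_px)
            y_hi = min(H, int(np.ceil(cy)) + cell_pad_px + 1)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            dloc = np.hypot(
                (np.arange(x_lo, x_hi)[None, :] - cx) * px,
                (np.arange(y_lo, y_hi)[:, None] - cy) * px,
            )
            occ[y_lo:y_hi, x_lo:x_hi] += 0.5 * (1.0 - erf((dloc - rr) / soft))
        occ = np.clip(occ, 0.0, 1.0)

        frame = frame * (1.0 - spec.contrast * occ * lum)
        frames[k] = frame * gain[None, :]

    data = noise.apply(frames, rng)

    truth = GroundTruth(
        times=t,
        velocity=spec.vmax * mod,          # centerline velocity per frame, mm/s
        trajectories=traj,
        radial_offsets=r_off,
        diameter=2.0 * R,
        gain_profile=gain,
        motion_trace=motion,
        params={
            "vmax": spec.vmax,
            "R": R,
            "B": spec.bluntness_B,
            "beta": spec.beta,
            "r0": spec.r0,
            "f0": spec.f0,
            "modulation_depths": depths,
            "per_cell_velocity": v_r,
            "modulation": mod,
            "axis_points": pts,
            "axis_arc_um": arc,
        },
    )
    return FrameStack(data, spec.frame_rate, spec.pixel_size, origin="synthetic"), truth


# ---------------------------------------------------------------------------
# penetrating-vessel trace generator

def simulate_penetrating_trace(spec: SimPenetratingSpec):
    """Render the mean-fluorescence trace of a penetrating vessel.

    Returns ``(trace, GroundTruth)`` where ``trace`` is a 1D array sampled
    at ``frame_rate``; truth lists the exact transit times.
    """
    spec.validate()
    noise = NoiseModel.coerce(spec.noise_model)
    rng = np.random.default_rng(spec.seed)

    n = int(round(spec.duration * spec.frame_rate))
    t = np.arange(n) / spec.frame_rate

    if spec.mean_flux > 0:
        gaps = rng.exponential(1.0 / spec.mean_flux, size=max(16, int(spec.mean_flux * spec.duration * 2) + 16))
        while gaps.sum() < spec.duration:
            gaps = np.concatenate([gaps, rng.exponential(1.0 / spec.mean_flux, gaps.size)])
        events = np.cumsum(gaps)
        events = events[events < spec.duration]
        if events.size and 1.0 / spec.mean_flux < 4.0 * spec.transit_sigma:
            warnings.warn("expected inter-event gap < 4·transit_sigma; merged dips likely")
    else:
        events = np.array([])

    clean = np.full(n, float(spec.baseline))
    depth = spec.dip_depth * spec.baseline
    for te in events:
        clean -= depth * np.exp(-((t - te) ** 2) / (2.0 * spec.transit_sigma**2))
    clean = np.clip(clean, 0.0, None)

    trace = noise.apply(clean, rng)
    truth = GroundTruth(
        times=t,
        event_times=events,
        params={
            "baseline": spec.baseline,
            "dip_depth": spec.dip_depth,
            "transit_sigma": spec.transit_sigma,
            "frame_rate": spec.frame_rate,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# bifurcation cross-sections and multifile line scans

def simulate_bifurcation_images(mean_flux: float = 100.0,
                                fractions: Sequence[float] = (0.6, 0.4),
                                duration: float = 5.0,
                                frame_rate: float = 1000.0,
                                transit_sigma: float = 2e-3,
                                n_space: int = 9,
                                baseline: float = 100.0,
                                dip_depth: float = 0.7,
                                pixel_size: float = 0.5,
                                noise_model: NoiseModel | str = "none",
                                seed: int = 0):
    """Cross-section images of a capillary bifurcation.

    Parent transits arrive as a Poisson process at ``mean_flux`` and each
    cell is routed to one daughter with the given ``fractions`` (a
    fraction of 0 makes that daughter a plasma channel).  Each branch is
    rendered as a T×X image of bright plasma with a dark Gaussian blob
    per transit.  Returns ``(parent, daughters, GroundTruth)`` where the
    truth lists parent event times and each daughter's event times in
    ``params['daughter_events']``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or not np.isclose(fractions.sum(), 1.0):
        raise ValueError("fractions must be nonnegative and sum to 1")
    noise = NoiseModel.coerce(noise_model)
    rng = np.random.default_rng(seed)

    n_ev = rng.poisson(mean_flux * duration)
    events = np.sort(rng.uniform(0.0, duration, n_ev))
    branch_of = rng.choice(fractions.size, size=n_ev, p=fractions)

    t = np.arange(int(round(duration * frame_rate))) / frame_rate
    x = np.arange(n_space)
    spatial = np.exp(-((x - (n_space - 1) / 2.0) ** 2) / (2 * (n_space / 4.0) ** 2))

    def render(ev):
        occ = np.zeros((t.size,))
        for te in ev:
            occ += np.exp(-((t - te) ** 2) / (2 * transit_sigma**2))
        img = baseline * (1.0 - dip_depth * np.clip(occ, 0, 1))[:, None] * spatial[None, :]
        return noise.apply(img, rng)

    from .containers import CrossSectionImage

    parent = CrossSectionImage(render(events), frame_rate, pixel_size)
    daughters = []
    daughter_events = []
    for b in range(fractions.size):
        ev = events[branch_of == b]
        daughters.append(CrossSectionImage(render(ev), frame_rate, pixel_size))
        daughter_events.append(ev)
    truth = GroundTruth(times=t, event_times=events,
                        params={"fractions": fractions,
                                "daughter_events": daughter_events,
                                "transit_sigma": transit_sigma})
    return parent, daughters, truth


def simulate_multifile_linescan(n_transits: int = 500,
                                duration: float = 0.5,
                                line_rate: float = 1e6,
                                line_length: float = 40.0,
                                pixel_size: float = 0.5,
                                transit_sigma: float = 0.25e-3,
                                rbc_sigma: float = 2.0,
                                baseline: float = 200.0,
                                contrast: float = 0.8,
                                noise_model: NoiseModel | str = "none",
                                seed: int = 0):
    """Megahertz line scan across a large vessel with multifile flow.

    Each of ``n_transits`` cells crosses the focal line at a random time
    and lateral position, rendered as a separable Gaussian dark blob
    (temporal width ``transit_sigma`` s, lateral width ``rbc_sigma`` µm).
    Returns ``(Kymograph, GroundTruth)``; truth lists transit times.
    """
    noise = NoiseModel.coerce(noise_model)
    rng = np.random.default_rng(seed)
    n_lines = int(round(duration * line_rate))
    n_px = int(round(line_length / pixel_size))
    times = np.sort(rng.uniform(0.0, duration, n_transits))
    xpos = rng.uniform(0.1 * line_length, 0.9 * line_length, n_transits)

    t = np.arange(n_lines) / line_rate
    x = (np.arange(n_px) + 0.5) * pixel_size
    occ = np.zeros((n_lines, n_px))
    half_t = 4 * transit_sigma
    for te, xe in zip(times, xpos):
        i0 = max(0, int((te - half_t) * line_rate))
        i1 = min(n_lines, int((te + half_t) * line_rate) + 1)
        tt = t[i0:i1]
        occ[i0:i1] += np.outer(
            np.exp(-((tt - te) ** 2) / (2 * transit_sigma**2)),
            np.exp(-((x - xe) ** 2) / (2 * rbc_sigma**2)),
        )
    clean = baseline * (1.0 - contrast * np.clip(occ, 0, 1))
    data = noise.apply(clean, rng)
    truth = GroundTruth(times=None, event_times=times,
                        params={"x_positions": xpos, "transit_sigma": transit_sigma,
                                "rbc_sigma": rbc_sigma})
    return Kymograph(data, line_rate, pixel_size), truth


# ---------------------------------------------------------------------------
# virtual-source arithmetic

def faced_geometry(delta_theta: float, alpha: float, S: float):
    """Focus count and interpulse delay of a FACED mirror pair.

    A beam with convergence angle ``delta_theta`` (degrees) entering a
    mirror pair with misalignment ``alpha`` (degrees) and separation ``S``
    (mm) splits into ``N = Δθ/α`` subpulses delayed by ``2S/c``.

    Returns ``(n_foci, delay_ns)`` with the focus count rounded down to an
    integer and the delay rounded to 3 significant figures.
    """
    if not (alpha > 0 and S > 0):
        raise ValueError("alpha and S must be positive")
    if alpha >= delta_theta:
        raise ValueError("alpha must be smaller than delta_theta")
    ratio = delta_theta / alpha
    n_foci = int(np.floor(ratio + 1e-9))  # guard against float round-off
    delay_s = 2.0 * (S * 1e-3) / SPEED_OF_LIGHT
    delay_ns = delay_s * 1e9
    magnitude = np.floor(np.log10(abs(delay_ns)))
    delay_ns = round(delay_ns, int(2 - magnitude))
    return n_foci, delay_ns
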