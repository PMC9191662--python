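"""TIFF / CSV round-tripping for calibrated stacks and kymographs.

Stacks are written as multi-page TIFF with ImageJ-style metadata
(``finterval`` in seconds, x/y resolution in pixels per µm).  A sidecar
YAML file (``<name>.yaml`` next to the TIFF) overrides embedded metadata
when present, with keys ``frame_rate``, ``pixel_size`` (and ``line_rate``
for kymographs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import FrameStack, Kymograph


def _sidecar(path: Path) -> dict:
    p = Path(path).with_suffix(".yaml")
    if p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh) or {}
    return {}


def write_stack(stack: FrameStack, path) -> None:
    """Write a FrameStack to multi-page TIFF with ImageJ metadata."""
    path = Path(path)
    data = stack.data
    if data.dtype.kind == "f" and data.dtype.itemsize > 4:
        data = data.astype(np.float32)
    res = 1.0 / stack.pixel_size  # px per µm
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"finterval": 1.0 / stack.frame_rate, "unit": "um", "axes": "TYX"},
    )


def read_stack(path, frame_rate: float | None = None,
               pixel_size: float | None = None) -> FrameStack:
    """Read a multi-page TIFF into a FrameStack.

    Metadata resolution order: explicit arguments > sidecar YAML > embedded
    ImageJ tags.  Missing frame rate or pixel size raises.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.imagej_metadata or {}
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
    if data.ndim == 2:
        data = data[None]
    side = _sidecar(path)

    if frame_rate is None:
        frame_rate = side.get("frame_rate")
    if frame_rate is None and meta.get("finterval"):
        frame_rate = 1.0 / meta["finterval"]
    if pixel_size is None:
        pixel_size = side.get("pixel_size")
    if pixel_size is None and xres is not None:
        num, den = xres.value
        if num:
            pixel_size = den / num
    if frame_rate is None or pixel_size is None:
        raise ValueError(
            f"{path}: frame rate / pixel size not found in metadata; "
            "supply them explicitly or via a sidecar YAML"
        )
    return FrameStack(data, float(frame_rate), float(pixel_size), origin=str(path))


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write a kymograph to single-page TIFF (or CSV if the suffix is .csv).

    Rows are time, columns are space in both formats.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(kymo.data).to_csv(path, index=False, header=False)
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(
                {"line_rate": kymo.line_rate, "pixel_size": kymo.pixel_size}, fh
            )
        return
    data = kymo.data
    if data.dtype.kind == "f" and data.dtype.itemsize > 4:
        data = data.astype(np.float32)
    res = 1.0 / kymo.pixel_size
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(res, res),
        metadata={"finterval": 1.0 / kymo.line_rate, "unit": "um"},
    )


def read_kymograph(path, line_rate: float | None = None,
                   pixel_size: float | None = None) -> Kymograph:
    path = Path(path)
    side = _sidecar(path)
    if path.suffix.lower() == ".csv":
        data = pd.read_csv(path, header=None).to_numpy(float)
        meta = {}
    else:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            meta = tif.imagej_metadata or {}
            xres = tif.pages[0].tags.get("XResolution")
        if pixel_size is None and side.get("pixel_size") is None and xres is not None:
            num, den = xres.value
            if num:
                side["pixel_size"] = den / num
        if meta.get("finterval"):
            side.setdefault("line_rate", 1.0 / meta["finterval"])
    if line_rate is None:
        line_rate = side.get("line_rate")
    if pixel_size is None:
        pixel_size = side.get("pixel_size")
    if line_rate is None or pixel_size is None:
        raise ValueError(f"{path}: line rate / pixel size missing")
    return Kymograph(np.asarray(data, float), float(line_rate), float(pixel_size))


def write_ground_truth(truth, out_dir, stem: str = "truth") -> None:
    """Serialize a GroundTruth: scalar/params to JSON, arrays to CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {"diameter_um": truth.diameter}
    if truth.event_times is not None:
        payload["event_times_s"] = truth.event_times.tolist()
    payload["params"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.params.items()
        if np.isscalar(v) or isinstance(v, (list, np.ndarray))
    }
    with open(out / f"{stem}.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    if truth.trajectories is not None and truth.times is not None:
        df = pd.DataFrame(
            np.asarray(truth.trajectories),
            index=pd.Index(truth.times, name="time_s"),
        )
        df.to_csv(out / f"{stem}_trajectories.csv")
    if truth.motion_trace is not None:
        pd.DataFrame(truth.motion_trace, columns=["dx_px", "dy_px"]).to_csv(
            out / f"{stem}_motion.csv", index_label="frame"
        )
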