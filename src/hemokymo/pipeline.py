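"""End-to-end pipeline runs from a single YAML config.

A config names an ordered list of stages, each with a parameter block;
the runner executes them in order inside a run directory, hashes every
file written into ``manifest.json``, and — because every random stage
takes an explicit seed — reruns with the same config and seed reproduce
the manifest hashes bit for bit for deterministic stages.

Stage vocabulary (parameters in parentheses are the accepted keys):

* ``simulate_kymograph`` — SimKymographSpec fields; writes ``kymograph.tif``
  and ground truth.
* ``simulate_vessel`` — SimVesselSpec fields; writes ``stack.tif`` + truth.
* ``simulate_penetrating`` — SimPenetratingSpec fields; writes ``trace.csv``
  + truth.
* ``normalize_kymograph`` (boost_cap) — normalizes the kymograph in the run.
* ``bin_time`` (factor) — temporal binning of the kymograph.
* ``piv`` (PIVConfig fields) — writes ``velocity.csv``.
* ``spectrum`` (detrend, search_band, ...) — writes ``spectrum.csv``.
* ``pulsatility`` (band) — writes ``pulsatility.csv``.
* ``count_events`` (smooth_width, min_prominence, min_separation) — writes
  ``events.csv`` from the penetrating trace.

Unknown stage names or parameter keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import flux as flux_mod
from . import io as io_mod
from . import prep, pulsatility, synthetic, velocimetry
from .containers import Kymograph

log = logging.getLogger("hemokymo")

_TOP_KEYS = {"seed", "log_level", "stages"}


def _fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}

_STAGE_PARAMS = {
    "simulate_kymograph": _fields(synthetic.SimKymographSpec) | {"velocity_mm_s",
                                                                 "pulse_freq_hz",
                                                                 "pulse_depth"},
    "simulate_vessel": _fields(synthetic.SimVesselSpec),
    "simulate_penetrating": _fields(synthetic.SimPenetratingSpec),
    "normalize_kymograph": {"boost_cap"},
    "bin_time": {"factor"},
    "piv": _fields(velocimetry.PIVConfig),
    "spectrum": {"detrend", "window", "search_band", "harmonic_threshold"},
    "pulsatility": {"band", "f0"},
    "count_events": {"smooth_width", "min_prominence", "min_separation",
                     "with_half_times"},
}
# specs carry their own seed; the pipeline seed is injected instead
for _k in ("simulate_kymograph", "simulate_vessel", "simulate_penetrating"):
    _STAGE_PARAMS[_k] = _STAGE_PARAMS[_k] - {"seed", "velocity_fn", "motion_trace",
                                             "vessel_axis", "faced_gain_profile"}


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "stages" not in cfg or not isinstance(cfg["stages"], list):
        raise ValueError("config must define a 'stages' list")
    for stage in cfg["stages"]:
        if not isinstance(stage, dict) or "name" not in stage:
            raise ValueError("each stage needs a 'name'")
        name = stage["name"]
        if name not in _STAGE_PARAMS:
            raise ValueError(f"unknown stage name: {name!r}")
        params = set(stage) - {"name"}
        bad = params - _STAGE_PARAMS[name]
        if bad:
            raise ValueError(f"stage {name!r}: unknown parameter key(s): {sorted(bad)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config, out_dir) -> dict:
    """Execute a pipeline config; returns the manifest dict.

    ``config`` is a YAML path or an already-parsed dict.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    seed = int(config.get("seed", 0))
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO"))))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    for stage in config["stages"]:
        name = stage["name"]
        params = {k: v for k, v in stage.items() if k != "name"}
        log.info("stage %s", name)
        try:
            _run_stage(name, params, seed, state, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    files = sorted(p for p in out.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _run_stage(name, params, seed, state, out: Path) -> None:
    if name == "simulate_kymograph":
        v0 = float(params.pop("velocity_mm_s", 2.0))
        fp = float(params.pop("pulse_freq_hz", 10.0))
        md = float(params.pop("pulse_depth", 0.0))
        spec = synthetic.SimKymographSpec(
            velocity_fn=lambda t: v0 * (1.0 + md * np.sin(2 * np.pi * fp * t)),
            seed=seed, **params)
        kymo, truth = synthetic.simulate_kymograph(spec)
        io_mod.write_kymograph(kymo, out / "kymograph.tif")
        io_mod.write_ground_truth(truth, out, stem="kymograph_truth")
        state["kymograph"] = kymo
    elif name == "simulate_vessel":
        spec = synthetic.SimVesselSpec(seed=seed, **params)
        stack, truth = synthetic.simulate_vessel_video(spec)
        io_mod.write_stack(stack, out / "stack.tif")
        io_mod.write_ground_truth(truth, out, stem="vessel_truth")
        state["stack"] = stack
    elif name == "simulate_penetrating":
        spec = synthetic.SimPenetratingSpec(seed=seed, **params)
        trace, truth = synthetic.simulate_penetrating_trace(spec)
        pd.DataFrame({"time_s": truth.times, "intensity": trace}).to_csv(
            out / "trace.csv", index=False)
        io_mod.write_ground_truth(truth, out, stem="penetrating_truth")
        state["trace"] = (trace, spec.frame_rate)
    elif name == "normalize_kymograph":
        kymo, gain = prep.normalize_kymograph(state["kymograph"], **params)
        state["kymograph"] = kymo
        pd.DataFrame({"gain": gain.factors,
                      "excluded": gain.excluded_mask}).to_csv(
            out / "gain.csv", index_label="column")
    elif name == "bin_time":
        state["kymograph"] = prep.bin_time(state["kymograph"], **params)
    elif name == "piv":
        cfg = velocimetry.PIVConfig(**params)
        tr = velocimetry.piv_velocity(state["kymograph"], cfg)
        pd.DataFrame({"time_s": tr.time, "velocity_mm_s": tr.velocity,
                      "quality": tr.quality}).to_csv(out / "velocity.csv",
                                                     index=False)
        state["trace_vel"] = tr
    elif name == "spectrum":
        if "search_band" in params:
            params["search_band"] = tuple(params["search_band"])
        spec = pulsatility.velocity_spectrum(state["trace_vel"], **params)
        pd.DataFrame({"frequency_hz": spec.frequency,
                      "amplitude": spec.amplitude}).to_csv(
            out / "spectrum.csv", index=False)
        state["f0"] = spec.f0
    elif name == "pulsatility":
        f0 = params.pop("f0", None) or state.get("f0")
        if f0 is None:
            raise ValueError("no fundamental available; run 'spectrum' first")
        if "band" in params:
            params["band"] = tuple(params["band"])
        res = pulsatility.pulsatility_index(state["trace_vel"], f0, **params)
        pd.DataFrame(res.per_cycle,
                     columns=["v_peak", "v_min", "v_mean"]).to_csv(
            out / "pulsatility.csv", index_label="cycle")
        state["pi"] = res.pi
    elif name == "count_events":
        trace, rate = state["trace"]
        res = flux_mod.count_rbc_events(trace, rate, **params)
        pd.DataFrame({"event_time_s": res.event_times}).to_csv(
            out / "events.csv", index=False)
        state["flux"] = res
    else:  # pragma: no cover - validate_config rejects these
        raise ValueError(f"unknown stage {name!r}")
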