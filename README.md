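# hemokymo

Analysis toolkit for **kilohertz two-photon imaging of cortical blood
flow**: from raw frame stacks and megahertz line-scan kymographs to red
blood cell (RBC) velocities, dense 2D velocity maps, radial flow
profiles, RBC fluxes and pulsatility metrics — together with a synthetic
blood-flow simulator that provides exact ground truth for every stage of
the pipeline.

## Who this is for

Ultrafast two-photon microscopes built around a passive pulse-multiplexing
mirror pair (FACED: an input beam with convergence angle Δθ entering a
mirror pair with misalignment α and separation S splits into N = Δθ/α
sub-pulses delayed by 2S/c) scan a line of foci at the laser repetition
rate, yielding full 2D frames at ~1 kHz or 1D line scans at ~1 MHz. In
these recordings, unlabeled RBCs appear as dark objects moving through
bright dextran-labeled plasma. This package implements the downstream
quantification for such data — and, because raw in vivo recordings are
large and scarce, ships a simulator that renders kymographs, vessel
videos and penetrating-vessel traces with known velocities, fluxes, gain
profiles and motion, so every estimator can be validated against truth.

## The methods at the core

* **Measurable-speed bound.** A cell must be sampled at least twice
  while inside the focal array of length *h* at sampling rate *f*, so
  the bound is *v* = *f·h*/2 (25 mm/s for a 50-µm array at 1 kHz;
  25 m/s at 1 MHz).
* **Kymograph PIV.** Within a short window (default 2 ms, advanced by
  0.2 ms → 5 estimates/ms), each kymograph line is cross-correlated with
  the next; the normalized correlograms are averaged and the sub-pixel
  peak offset gives the signed velocity. A Radon streak-angle estimator
  is included as an independent cross-check.
* **Dense 2D velocity maps.** Per-pixel SIFT descriptors are matched
  between consecutive frames by minimizing a discrete energy
  E(w) = Σ min(‖s₁(p) − s₂(p+w)‖₁, t) + Σ η(|u|+|v|) +
  Σ<sub>(p,q)</sub> [min(α|u(p)−u(q)|, d) + min(α|v(p)−v(q)|, d)]
  with loopy belief propagation (η = 0.01, α = 50, d = 10020); frames
  are up-sampled 2× first so integer flow carries half-pixel precision.
* **Blunted-parabola profiles.** Radial velocity profiles are fitted with
  V(r) = V<sub>max</sub>[1 − (1−β)|(r−r₀)/R|<sup>B</sup>], and flow
  bluntness is summarized by V<sub>max</sub>/V<sub>avg</sub> = (B+2)/(B+2β).
* **RBC flux and transit half-times.** Transit dips in penetrating-vessel
  traces are counted by smoothed inverted peak detection; each dip edge
  is fitted with a negative Gaussian and the 10–90% half-time (1.687 σ)
  converts to speed via an effective RBC length (6 µm).
* **Pulsatility.** Velocity spectra locate the cardiac fundamental and
  harmonics; the pulsatility index is
  (V<sub>peak</sub> − V<sub>min</sub>)/V<sub>mean</sub> per cardiac cycle.

## Worked example

Simulate a pulsatile capillary kymograph (10-kHz line rate, 0.5 µm/px,
velocity 2 mm/s modulated 30% at a 10-Hz heart rate, photon noise), then
estimate velocity, spectrum and pulsatility:

```python
import numpy as np
from hemokymo import (SimKymographSpec, simulate_kymograph,
                      PIVConfig, piv_velocity, max_measurable_speed)
from hemokymo.pulsatility import velocity_spectrum, pulsatility_index

spec = SimKymographSpec(
    line_rate=10_000.0, pixel_size=0.5, line_length=50.0, duration=2.0,
    velocity_fn=lambda t: 2.0 * (1 + 0.3 * np.sin(2 * np.pi * 10 * t)),
    noise_model="poisson", seed=1,
)
kymo, truth = simulate_kymograph(spec)
trace = piv_velocity(kymo, PIVConfig(window_ms=2.0, stride_ms=0.2))
spectrum = velocity_spectrum(trace)
pi = pulsatility_index(trace, f0=spectrum.f0)
```

Output of this exact script:

```
kymograph: 20000 lines x 100 px, bound 250 mm/s
PIV: 9991 estimates, mean velocity 1.96 mm/s
cardiac fundamental 10.0 Hz, harmonics [1, 2]
pulsatility index 0.721 over 17 cycles
```

Reading the numbers: the mean velocity (1.96 mm/s) matches the simulated
2 mm/s within 2%; the spectrum finds the injected 10-Hz drive (the weak
second harmonic is distortion from half-pixel displacement quantization
at this short window); the pulsatility index for a 30% sinusoidal
modulation is ideally 2m = 0.6 — photon noise inflates the per-cycle
extrema, giving 0.72 at this noise level. Longer windows reduce both
effects at the cost of temporal resolution.

A multi-stage run (simulate → normalize → PIV → spectrum → PI) with a
hashed output manifest:

```bash
hemokymo run --config pipeline.yaml --out run/
```

## Layout

| module | contents |
| --- | --- |
| `hemokymo.synthetic` | simulators (kymograph, vessel video, penetrating trace, bifurcation, multifile line scan) + FACED geometry |
| `hemokymo.io` / `hemokymo.prep` | TIFF/CSV I/O, FACED gain normalization, temporal binning, rigid registration |
| `hemokymo.kymo` | kymograph / cross-section extraction along polyline ROIs |
| `hemokymo.velocimetry` | windowed cross-correlation PIV, Radon estimator, speed bound |
| `hemokymo.siftflow` | dense SIFT-flow velocity mapping (BP optimizer + exact DP oracle) |
| `hemokymo.profiles` | vessel diameter, radial profiles, blunted-parabola fits |
| `hemokymo.flux` | transit counting, half-times, bifurcation partition, multifile flux |
| `hemokymo.pulsatility` | spectra, harmonics, pulsatility index, correlations |
| `hemokymo.pipeline` / `hemokymo.cli` | YAML-configured runs with hashed manifests; `hemokymo` CLI |

See `docs/methods.md` for the models, defaults and numerical choices.
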