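# qmwi — quantitative microwave imaging via sampling-method segmentation

`qmwi` is a research library for 2-D quantitative microwave imaging. It
targets the transverse-magnetic inverse scattering problem — recovering the
complex permittivity map ε(r) − jσ(r)/(ωε0) of targets inside a domain Ω from
multi-static, multi-frequency scattered-field measurements on a surrounding
antenna circle Γ — which is non-linear and ill-posed, the central obstacle to
deploying microwave imaging for medical diagnostics (brain-stroke detection
and classification being the motivating application).

Rather than iterative inversion, the pipeline is two direct steps:

1. **Orthogonality sampling method (OSM).** For each pixel p and transmitter
   t, project the scattered field onto the background Green's function:
   `Ered(p,t) = Σ_m Es(m,t)·conj(G(m,p))·Δs`, and form the indicator
   `I(p) = Σ_t |Ered(p,t)|²·Δt` per frequency. The per-frequency indicator
   images localize targets and implicitly encode their contrast
   τ = εeq/εb − 1.
2. **Segmentation as inversion.** Restrict τ to Nc classes and train a
   convolutional encoder–decoder (U-Net style) to map the Nf-channel stack of
   [0,1]-normalized indicators to a per-pixel class map — a quantized
   quantitative reconstruction, produced in real time once trained.

The package contains everything needed to study this pipeline end to end:
a method-of-moments CG-FFT forward solver with an analytic cylinder-series
oracle, the OSM with analytic and numerical (inhomogeneous-background)
Green's tables and differential-data support, synthetic scene generators
(random two-cylinder scenes; a procedural head phantom with Cole-Cole tissue
dispersion and one inserted stroke), a numpy implementation of the
segmentation network with seeded training and 10-fold cross-validation,
Dice/Matthews evaluation, a Fresnel-database-style ASCII reader/writer, and a
thin CLI (`qmwi simulate|osm|train|predict|evaluate|run`).

## Worked example

`examples/01_forward_scattering.py` simulates the multi-static field
scattered by a dielectric cylinder (ε=2, radius 2 cm) at 3 GHz on a 64×64
grid and checks it against the exact eigenfunction series:

```
scattered field shape (receivers x transmitters): (241, 8)
peak |Es| at the receivers: 1.743e-03
relative RMS error vs analytic cylinder series: 0.62%
```

The 0.62 % is the discretization error of the pulse-basis grid; it drops to
0.17 % at 128×128. `examples/02_osm_imaging.py` then images two cylinders
(radii 2.5 and 1.8 cm) from their scattered data; the indicator argmax at
every frequency falls inside one of the true discs:

```
indicator stack shape (pixels x frequencies): (4096, 3)
  4 GHz: peak at (+5.7, -2.5) cm (targets at (-5,+3) and (+5,-4) cm)
  6 GHz: peak at (+5.3, -5.7) cm (targets at (-5,+3) and (+5,-4) cm)
  8 GHz: peak at (-4.9, +1.0) cm (targets at (-5,+3) and (+5,-4) cm)
```

`examples/03_train_segmentation.py` trains the reduced network on a small
corpus and prints a per-class Dice/Matthews table; `04_brain_stroke.py` runs
the differential stroke pipeline on the head phantom (the indicator peak
lands within ~2 cm of the true stroke); `05_fresnel_io.py` round-trips an
experiment through the ASCII measurement format.

A full experiment from one config file:

```bash
qmwi run -c config.yaml --seed 1 -o runs/demo
```

writes the dataset, per-fold models, training curves and a per-class metrics
report (`report.txt`) into the output directory.

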