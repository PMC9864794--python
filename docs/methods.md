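# Methods

## Problem setting

The package addresses the 2-D transverse-magnetic inverse scattering problem:
recover the spatial map of complex relative permittivity inside a square
imaging domain Ω from multi-static, multi-frequency measurements of the
scattered electric field on a surrounding circle Γ. The unknown is the
contrast τ(r) = εeq(r)/εb − 1, with εeq = ε − jσ/(ωε0) under the e^{+jωt}
time convention (lossy media have Im εeq ≤ 0) and εb the host permittivity.
The problem is non-linear (the internal total field depends on τ) and
ill-posed (the data operator has a smoothing kernel).

Instead of an iterative inversion, the pipeline solves the problem in two
direct steps:

1. **Sampling-method pre-processing.** The orthogonality sampling method
   (OSM) projects the scattered data onto background Green's functions
   anchored at each pixel — the *reduced field*
   Ered(p, t) = Σ_m Es(m, t)·conj(G(m, p))·Δs — and forms the indicator
   I(p) = Σ_t |Ered(p, t)|²·Δt per frequency. The indicator is a shape image
   whose spatial structure across frequencies also encodes the contrast
   amplitude, though not in any closed form.

2. **Segmentation as inversion.** The admissible contrast range is split into
   a finite set of classes, and a convolutional encoder–decoder network maps
   the Nf-channel stack of [0,1]-normalized indicators to a per-pixel class
   map, i.e. a quantized quantitative reconstruction. Training pairs come
   from a synthetic scene generator plus the bundled forward solver.

## Forward solver

The state (domain) equation E = Einc + k_b²·Gd[τE] is discretized with pulse
(pixel) basis functions and point matching. Each square cell is replaced by
the equal-area disc, for which the integrated Green's function has Richmond's
closed forms; the self-term keeps the singularity integrable and the operator
a block-Toeplitz convolution plus a diagonal. Gd is applied with 2-D FFTs on
a zero-padded grid; the linear system is solved per transmitter and frequency
with BiCGSTAB (default relative tolerance 1e-6, max 1000 iterations, GMRES
retry on stagnation, hard error with the final residual otherwise). Receivers
are evaluated through the discretized data equation with the same
cell-integrated kernel. A dense assembly of the identical discretization
provides an algebraic cross-check on small grids (agreement ~1e-12 measured,
asserted at 1e-8).

Accuracy against the analytic line-source/cylinder eigenfunction series is
governed by pixels-per-interior-wavelength: measured 0.15–1 % relative RMS at
≥ 15 px/λ on a 64×64 grid over the 25 cm domain, degrading to tens of percent
below ~5 px/λ (9 GHz in ε=3.5). This is the expected behaviour of any
pixel-basis method-of-moments scheme; tests therefore assert the ≤2 % bound
in resolved regimes and monotone improvement under grid refinement, not a
blanket bound over the full frequency×permittivity rectangle. For comparisons
against continuous-geometry references, discs are rasterized with an
area-fraction (anti-aliased) option; training scenes use plain pixel-centre
membership so that scene and label are consistent pixelwise.

The incident field is a unit-amplitude line source, Einc = −(j/4)H0^(2)(k_b·
|r−rt|). No absolute amplitude calibration is attempted: the indicator
normalization cancels global scale, and externally calibrated data can be
rescaled at ingest.

## OSM details

The scalar product on Γ is conjugate-linear in the Green's argument with
constant arc-length weights (uniform angular sampling); the weights only
rescale the indicator and are kept explicit for clarity. Each frequency slice
is min-max normalized to [0,1] independently; an all-constant slice maps to
zeros (it carries no spatial information, and this avoids 0/0). Sampling grid
= scene grid, which keeps training pairs aligned pixel-for-pixel.

For a known inhomogeneous background (the healthy head in its matching
medium) the analytic Green's function is replaced by a numerical table:
column m is the total field of a unit line source at receiver m propagated
through the background scene (one forward solve per receiver and frequency,
cached per dataset). For a homogeneous background the table reduces to the
analytic kernel within discretization error (≤2 % measured).

**Green's-function energy normalization.** In a lossy background the plain
indicator is dominated by the pixels nearest the receivers, because |G|
decays exponentially with depth and the projection weight scales with it
(measured stroke-localization errors of 4–15 cm). The brain pipeline
therefore projects onto unit-energy test functions — dividing each pixel's
reduced field by ‖G(·,p)‖²_Γ — a standard sampling-method variant. With it,
the differential-indicator argmax lands 0.2–2 cm from the true stroke centre
across seeds, kinds and frequencies. The free-space pipeline keeps the plain
projection (there ‖G‖ is nearly constant over Ω and the option is a global
rescale); the flag is explicit in `reduced_field`/`compute_indicator_stack`.

Stroke imaging operates on differential data: the scattered field of the
stroke-bearing head minus that of the same (per-sample perturbed) head
without the stroke, isolating the perturbation while the known nominal
healthy head supplies the Green's table.

## Scene generators

**Two-cylinder family (free space).** Two possibly overlapping lossless
cylinders drawn uniformly: radius 1.2–5 cm, relative permittivity 1.3–3.5,
full containment in the 25×25 cm domain enforced by rejection; the
second-drawn cylinder overwrites the first (producing nested targets).
Measurement geometry: 8 transmitters every 45°, 241 receivers every 1.5°,
both on a 167 cm ring; 8 frequencies, 2–9 GHz in 1 GHz steps. Ground truth is
the pixelwise contrast thresholded into 7 classes — background 0 plus six
half-open intervals (0,0.6], (0.6,1.0], (1.0,1.4], (1.4,1.8], (1.8,2.2],
(2.2,2.5] with inclusive upper edges. Data are simulated noiselessly (the
sampling step is strongly noise-filtering; a noise option exists but is off
by default).

**Head-phantom family (matching medium).** A procedural stand-in for a
segmented anatomical brain slice: nested ellipses for skin (4 mm), cortical
bone (7 mm), CSF (3 mm) and brain (grey matter with a white-matter core at
60 % of the brain axes), global size jitter ±5 %, immersed in a matching
medium with ε=23, σ=0.19 S/m. It reproduces the layered electromagnetic
structure (high-contrast skull/CSF interfaces, lossy interior), not anatomy;
conclusions about anatomical realism cannot be drawn from it. Tissue
dispersion follows four-pole Cole-Cole models with the standard literature
constants (verified at 1 GHz: blood ε'=61.1, σ=1.58 S/m; grey matter 52.3,
0.99; white 38.6, 0.62; CSF 68.4, 2.46; skin 40.9, 0.90; cortical bone 12.4,
0.16). Each sample scales every tissue's dispersive amplitudes by an
independent factor uniform in [0.9, 1.1] (inter-subject variability). One
circular stroke per sample, radius 1–2.6 cm, placed uniformly with its disc
inside the brain ellipse; hemorrhagic strokes are blood, ischemic strokes use
a synthetic surrogate — grey matter with all amplitudes scaled by 0.81, a
constant fixed analytically so the surrogate's contrast amplitude against the
matching medium is ≈0.96 at 1 GHz (measured ischemic-tissue Cole-Cole
constants are not tabulated in the bundled literature set). Under the same
definition |τ| = |εeq/εb − 1|, blood evaluates to ≈1.96 at 1 GHz with these
constants. Antennas: 16 Tx/Rx on a 25 cm ring (outside the 24 cm domain's
corner radius), 4 frequencies evenly spaced over 0.5–1.25 GHz. Ground truth
has 3 classes: non-stroke tissue/background, ischemic, hemorrhagic; each
sample contains exactly one stroke, so at most two classes appear.

All randomness flows from one dataset seed through counter-based per-sample
derivation (`SeedSequence([seed, index])`), so datasets are bit-reproducible
and single samples can be re-derived in isolation.

## Segmentation network and training

The network is a classic U-shaped encoder–decoder: per level two 3×3
convolutions with ReLU, 2× max-pooling on the way down, nearest-neighbour
upsampling + 3×3 reduction and channel-concatenation skips on the way up, and
a final 1×1 projection to class logits; softmax is applied by the loss. Two
presets: `paper` (4 levels, base 64 channels, for 64×64 inputs) and `reduced`
(2 levels, small width, for CPU-scale experiments). The stack is implemented
directly on numpy arrays with explicit im2col convolutions and
backpropagation; the backward pass is validated against a finite-difference
directional derivative to ~1e-8 relative in float64.

Training minimizes mean pixelwise categorical cross-entropy (averaged rather
than summed — the sum differs by a constant factor; averaging makes learning
rates portable across image sizes) with Adam. The default configuration
mirrors the published recipe (learning rate 1e-4, batch 16, 200 epochs);
desk-scale experiments pass explicit smaller configurations. The background
class participates in the loss and is scored like any other class. Class
weighting is available but off by default. Data order is reshuffled each
epoch with a seeded generator; 10 % of the training split is held out for the
validation curve by default. Cross-validation follows the seeded
near-equal-fold partition of `make_folds`; every sample is predicted exactly
once by the model whose training fold excluded it.

Determinism caveat: given fixed seeds, runs are reproducible on a fixed
BLAS/CPU; floating-point reduction order may differ across BLAS builds.

## Evaluation

Per class, one-vs-rest pixel confusion counts feed the Dice similarity
coefficient 2TP/(2TP+FP+FN) and the Matthews correlation coefficient
(TP·TN−FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Degenerate conventions: a
class absent from both maps scores DSC 1 (flagged), a zero MCC denominator
factor scores 0. The averaging order — per-sample metrics, averaged within a
fold, then across folds — is fixed and documented; a pooled-counts-per-fold
mode is available behind a flag since the alternative is equally defensible.

## Desk-scale study conditions and what they show

Full-scale training (7000 samples, 64×64, 4-level network) is a GPU-scale
computation. The bundled desk-scale experiment uses: 32×32 grid on the 25 cm
domain, 8 transmitters / 64 receivers on the 167 cm ring, 4 frequencies
2–5 GHz, 300 samples of two *non-overlapping* cylinders (≥2 cm boundary gap)
with ε drawn from {1.5, 2.2, 3.0} — one value per class of a 3-target-class
binning (0,0.85], (0.85,1.6], (1.6,2.5] — and the reduced network (2 levels,
base 16) trained 50 epochs at 1e-3 plus 30 at 2e-4 on a 90/10 split. These
sizes were chosen once as the largest configuration that runs in minutes on
one CPU.

Measured at these conditions: held-out mean target-class Dice ≈ 0.80,
background Dice ≈ 0.99, and both cylinders' classes retrieved correctly on
≈ 73 % of held-out samples. The residual errors are adjacent-class
confusions (mostly between the two highest-contrast classes): with only four
narrow-band frequencies the indicator stacks of neighbouring contrast values
are genuinely similar, so perfect class retrieval on every sample — which the
full-scale configuration attains with twenty-one times the training data,
twice the bandwidth and 241 receivers — is not reached at desk scale. The
desk-scale result demonstrates that the pipeline learns contrast classes from
sampling-method images; it does not bound full-scale accuracy from below.

## Numerical choices and degenerate inputs

- Solver tolerances: 1e-6 default; 1e-5 for corpus generation (receiver
  fields converge much faster than the interior residual); 1e-8–1e-12 in
  oracle comparisons.
- Series truncation grows adaptively until the last order's relative weight
  is < 1e-10 (doubling check asserts < 1e-9 drift).
- Zero contrast short-circuits both the state solve (E = Einc exactly) and
  the data equation (Es = 0 exactly).
- Constant indicator slices normalize to zeros; zero data produce zero
  indicators and a background-only prediction downstream.
- Class binning validates its input range and names the offending value;
  upper edges are inclusive, τ=0 is its own class.
- Aspect-limited external data are represented with zeros at unavailable
  receivers, which drop out of the OSM sums; predictions on such data run
  but their quality is not asserted.

## Known limitations

- The head phantom is procedural; no claim of anatomical fidelity.
- The ischemic surrogate reproduces a target contrast amplitude, not a
  measured dispersion curve.
- Pixel-basis MoM accuracy degrades below ~10 px/λ; the 64×64 default grid
  under-resolves the highest frequency×permittivity corner of the cylinder
  family (consistently for data and labels, but absolute field accuracy is
  reduced there).
- The Fresnel-style parser reads the documented dialect only; real database
  files may need header adaptation, and multi-frequency channel matching to
  a trained model is the caller's responsibility.
- Training is CPU-bound numpy; the `paper` preset is defined and functional
  but not practical without hours of compute.
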