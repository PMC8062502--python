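# Methods

`lcosyforge` is an end-to-end simulation study of accelerated and
quantified two-dimensional localized correlated spectroscopy (L-COSY).
This note records the models, the numerical choices, and what the
package's synthetic experiments do and do not demonstrate.

## Spin simulation

Metabolite signals are simulated by density-matrix evolution of coupled
proton networks under the L-COSY sequence 90°–TE/2–180°–TE/2–t1–90°–t2
with ideal, instantaneous, non-selective pulses.  The rotating-frame
Hamiltonian is

    H = Σ_k 2π ν_k Iz_k + Σ_{k<l} 2π J_kl (I_k · I_l),
    ν_k = (δ_k − δ_carrier) · f_larmor,

with chemical shifts δ in ppm and scalar couplings J in Hz taken from the
standard brain-metabolite compilation bundled as per-metabolite YAML
files.  Defaults: TE = 30 ms, 2048 × 100 (t2 × t1) points, spectral
bandwidths 2000/1250 Hz, f_larmor = 123.25 MHz (nominal 3 T proton
frequency; it makes the 512-point direct-dimension crop span almost
exactly 4 ppm), carrier at the water position 4.7 ppm.

Implementation notes:

- All delays are applied as elementwise phase factors in the eigenbasis of
  H; each t1 increment then costs two small matrix products and one
  transition-amplitude × Fourier-kernel product, which makes the full
  17-metabolite basis simulate in seconds.
- Detection reads the ⟨I−⟩ coherence, and **N-type (echo) pathway
  selection** is applied during t1 (only coherence order +1 is retained).
  The real sequence enforces this selection with crusher gradients;
  without it every peak would alias a mirror image reflected about the
  carrier in F1.  With the convention ppm = carrier − f/f_larmor used on
  both axes, a spin at δ produces its diagonal peak at (δ, δ).
- t1 = 0 for the first increment; amplitudes are normalized so one proton
  contributes unit initial transverse amplitude; equivalent protons are
  listed explicitly up to the 8-spin (256 × 256) cap.  Networks larger
  than 8 protons are split into published sub-systems whose weighted FIDs
  are summed (glucose anomers at 0.36/0.64; trimethyl groups carry a
  proton-count weight).
- Relaxation, radiation damping, B0/B1 inhomogeneity, slice selection and
  gradient physics are not simulated; linewidths enter only through the
  synthesis broadening below.

## Spectrum synthesis

A composite spectrum is built from the unit-concentration basis set B_m:

    B_lb,m = B_m · exp(−π·lb2_m·t2) · exp(−π·lb1_m·t1) · exp(−i·φ_m)
    s_init = Σ_m c_m · B_lb,m

with independent uniform draws per metabolite: lb2 ∈ [5, 25] Hz,
lb1 ∈ [0, 15] Hz (the added Lorentzian FWHM per axis — the only reading
consistent with Hz-valued broadening), φ ∈ [0, 2π), c ∈ [0, 10]
mmol-equivalents.  Complex white Gaussian noise is added in the (F2,F1)
domain with per-component standard deviation equal to a noise fraction
(uniform in [0, 0.25] unless fixed) times the maximum magnitude of the
clean cropped spectrum; adding noise in the frequency domain makes
"percent of the maximum signal" exact and the sweep levels well defined.
Water contamination, used only in the evaluation sweep, adds a water FID
broadened by 8–20 Hz on both axes and scaled so its full-grid spectral
peak is `water_amp` times the tallest metabolite peak.

Transforms use one fixed convention: forward FFT per time axis with
orthonormal scaling and fftshift centering (so Parseval holds exactly).
The analysis window is a fixed contiguous 512 × 32 crop whose ppm extents
best match F2 0.5–4.5 ppm and F1 1.2–4.3 ppm.  Spectra are encoded as
(real, imaginary, magnitude) channel stacks normalized by the magnitude
maximum to 0–1 (reconstruction) or 0–100 (quantitation); each stack is
normalized by its own maximum, and the recorded `scale_max` inverts the
normalization.  Quantitation targets are the 17 per-metabolite clean
magnitude windows divided by the same input `scale_max` (×100), so channel
intensities stay proportional to concentration.

## Non-uniform sampling and compressed sensing

Masks select t1 increments without replacement with weight
exp(−decay·i/n), decay = 2 (the weight at the last index is e⁻² of the
first; the rate is otherwise a free parameter), and the last increment is
always forced on.  Shipped reference masks keep 75/50/25 of 100 points
(1.3x/2x/4x) with fixed seeds 1/2/3.

The l1 reconstruction solves

    min ‖u‖₁  s.t.  ‖M F u − f‖₂² ≤ σ²

on the full 2048 × 100 plane with the spectrum itself as the sparse
domain.  A monotone FISTA (unit step — both partial Fourier maps are
orthonormal, so the forward operator is a sub-isometry) minimizes the
Lagrangian on a descending log grid of 8 relative regularization values
(10^−0.5 … 10^−3 of max|Aᴴf|, warm-started), stopping at the largest λ
whose residual meets the noise budget; a final λ = 0 stage guarantees
exact data consistency when σ² = 0, which also makes the full-mask
zero-noise case reproduce the plain FFT spectrum.  Stage caps: 50
iterations per λ, 500 total, relative-change tolerance 1e−6.  σ² is
estimated from the signal-free F2 9–12 ppm band as per-point complex
variance scaled to the number of measured points (with orthonormal
transforms this equals region variance × full grid size, independent of
the mask).  Note the signal-free band sees no ridging because F2 is fully
sampled; only noise enters the estimate.

## Dense U-Net models

Both tasks share one encoder–decoder over the 512 × 32 window (3×3
kernels, stride 1, ReLU, same padding).  Encoder level l applies a dense
block (each convolution sees the block input concatenated with all
previous block outputs; two convolutions per block, growth
base_filters + growth·l) followed by 2×2 max pooling; the decoder mirrors
with 1×1 compression, 2× nearest upsampling, skip concatenation and a
one-convolution dense block.  The output head is a small two-layer 1×1
projection (hidden width 24, ReLU) over the concatenation of the raw
input, the first-level features and the decoder output, yielding 3
(reconstruction) or 17 (quantitation) channels.  Three further numerical
choices proved important for trainability and are declared here (the
source architecture leaves them open):

- fixed coordinate maps (linear ramps along both axes) are concatenated
  to the input inside the network, because absolute ppm position decides
  metabolite identity but is otherwise invisible to a
  translation-equivariant CNN away from the padded boundaries;
- non-negative output channels (magnitude, quantitation) use |x| rather
  than a ReLU: it enforces non-negativity with no zero-gradient region,
  so no output channel can die during training (with a ReLU head several
  metabolite channels collapsed to exact zero and never recovered);
- the head weights start at a tenth of the He scale, and 0–100-scaled
  quantitation data are divided by an internal gain of 100 at the input
  and re-multiplied at the output, so both tasks train at the same unit
  working scale (real/imaginary channels stay linear throughout).

Depth matters more than width here: a fully convolutional network is
translation-equivariant, so absolute ppm position — which decides
*which metabolite* owns a peak — is only available through boundary
(padding) effects within the receptive field.  At depth 5 (the 32-bin F1
axis collapses to 1) the receptive field spans essentially the whole
window and every output pixel can see a boundary, which proved necessary
for the quantitation task to learn channel assignment at all; with a
shallow network, visually identical singlets at different ppm cannot be
told apart in the window interior.

Training uses Adam (lr 1e−3), batch 10, mean-squared-error loss over the
512 × 32 grid averaged over channels and batch, a 10% validation split,
and best-validation checkpointing.  The network engine is a compact
reverse-mode numpy implementation (convolutions as nine shifted
full-grid BLAS products in channels-last layout); training is
bit-reproducible on a fixed seed.

Two profiles are declared once:

- **full** — the published scale (depth 4–5, base 32 filters, 40,000 /
  21,000 training spectra, 100 epochs); supported by configuration but
  not exercised by the test suite.
- **desk** — the package's single-CPU reference profile used by the tests
  and the acceptance experiments: depth 5, base_filters 4, growth 4
  (≈90k parameters), 600 training spectra, 10 (reconstruction) or 16
  (quantitation) epochs.  Problem sizes were chosen so the full
  acceptance pipeline completes on one CPU core in well under half an
  hour.

## Evaluation

- MSE: mean squared difference over the 512 × 32 grid, averaged over
  channels; NMSE% = 100 × MSE / max|actual|² (= 100 × MSE on unit-max
  spectra).  Quantitation channel errors are expressed on the unit-max
  scale — normalized by the clean spectrum's peak rather than the noisy
  0–100 working scale, whose maximum grows with noise and would otherwise
  deflate the metric as noise increases.
- Concentration readout: the maximum intensity of a predicted metabolite
  channel, un-normalized by the input's `scale_max`, divided by the
  maximum of that metabolite's unit-concentration window at the fixed
  reference broadening lb2 = 15 Hz, lb1 = 7.5 Hz (the range midpoints).
  The readout is proportional; residual slope bias is absorbed by the
  ordinary-least-squares linearity fit, reported per metabolite as slope,
  coefficient of determination and the standard error of the slope.
- Noise sweep: level k ↦ noise fraction 0.025·k (k = 1…10; level 2 = 5%,
  level 8 = 20%), re-noising the same spectra with fixed per-level seeds.
- Water sweep: amplitudes {0, 0.5, 1, 2, 4, 8} × the tallest metabolite
  peak; the metric is the mean slope standard error across metabolites of
  a model trained without water.

## What the synthetic experiments show — and what they do not

The generator reproduces the study's stated conditions: randomized
Lorentzian broadening, random phases, uniform concentrations, white
noise, exponential t1 undersampling.  It does not model macromolecule or
lipid baselines, Gaussian/Voigt lineshapes, frequency drifts, water
suppression residuals other than the additive water signal, or
scanner-specific artifacts.  Passing tests therefore demonstrate the
internal consistency and the relative behavior of the reconstruction and
quantitation methods under these idealized conditions, not in vivo
performance.

A scale observation that matters when comparing to published numbers: in
our simulations the clean 512 × 32 windows concentrate their energy in a
few pixels (mean pixel energy ≈ 0.4% of the squared maximum), so
*per-spectrum* normalized MSE values are intrinsically below ~1% for any
reasonable reconstruction, and the headline per-spectrum percentages
produced here are correspondingly small.  Error totals accumulated over a
100-spectrum test set are 100× larger and match the magnitude of
published error tables; `scripts/acceptance.py` reports the per-spectrum
mean, as defined above.

## Known limitations

- The desk profile's quantitation linearity is limited by single-CPU
  training time, and the limitation is structural, not incidental: at a
  few hundred Adam updates the model fits only the dominant
  choline-region channels, and even the fully position-aware per-pixel
  linear upper bound (closed-form ridge per pixel) reaches r2 <= ~0.34,
  because unmixing randomly phased, randomly broadened overlapping
  metabolites is locally unidentifiable — the information sits in joint
  multiplet and cross-peak patterns that require published-scale training
  (tens of thousands of spectra) to exploit.  Desk-scale concentration
  linearity is therefore reported as measured and falls far short of
  full-scale results; treat the desk quantitation model as a pipeline
  exerciser, not a validated quantifier.
- The exact dense-block layout of the original architecture is not public;
  the block design above is declared, not inferred.
- GAMMA's absolute signal normalization is unknown; all downstream scales
  are self-normalized, so only relative amplitudes matter.
- The shipped reference masks are statistically equivalent to, not
  bit-identical with, any particular published mask realization.
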