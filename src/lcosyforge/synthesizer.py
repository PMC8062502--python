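"""Parametric synthesis of composite L-COSY spectra from the basis set.

A synthetic spectrum is built by per-metabolite Lorentzian line broadening
and phasing of the unit-concentration basis FIDs,

    B_lb,m = B_m * exp(-pi*lb2_m*t2) * exp(-pi*lb1_m*t1) * exp(-i*phi_m),

linear mixing with random concentrations (0-10 mmol equivalents),

    s_init = sum_m c_m * B_lb,m,

followed by additive complex white Gaussian noise (0-25% of the maximum
metabolite magnitude) and optional water contamination.  Spectra are
Fourier transformed with a fixed convention (forward FFT per axis,
orthonormal scaling, fftshift centering), cropped to the 512 x 32 analysis
window (F2 0.5-4.5 ppm, F1 1.2-4.3 ppm) and encoded as normalized
(real, imaginary, magnitude) channel stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spin_simulator import BasisFID, BasisSet, SequenceParams

__all__ = [
    "SynthesisRanges",
    "SynthesisParams",
    "LCOSYSpectrum",
    "ChannelStack",
    "WINDOW_SHAPE",
    "F2_WINDOW_PPM",
    "F1_WINDOW_PPM",
    "REFERENCE_LB2",
    "REFERENCE_LB1",
    "draw_synthesis_params",
    "apply_line_broadening",
    "mix_metabolites",
    "add_noise",
    "add_water",
    "fid_to_spectrum",
    "spectrum_to_fid",
    "crop_to_window",
    "to_channels",
    "channels_to_complex",
    "SpectrumDataset",
    "generate_dataset",
]

WINDOW_SHAPE = (512, 32)
F2_WINDOW_PPM = (0.5, 4.5)
F1_WINDOW_PPM = (1.2, 4.3)

#: Range midpoints; used as the fixed broadening of the unit-concentration
#: reference windows in the concentration readout.
REFERENCE_LB2 = 15.0
REFERENCE_LB1 = 7.5


# ---------------------------------------------------------------------------
# axes and domains
# ---------------------------------------------------------------------------

def time_axes(params: SequenceParams):
    t2 = np.arange(params.n_t2) * params.dwell2
    t1 = np.arange(params.n_t1) * params.dwell1
    return t2, t1


def ppm_axes(params: SequenceParams):
    """fftshift-centered ppm axes; ppm = carrier_ppm - f / larmor_mhz."""
    f2 = np.fft.fftshift(np.fft.fftfreq(params.n_t2, params.dwell2))
    f1 = np.fft.fftshift(np.fft.fftfreq(params.n_t1, params.dwell1))
    return (params.carrier_ppm - f2 / params.larmor_mhz,
            params.carrier_ppm - f1 / params.larmor_mhz)


@dataclass
class LCOSYSpectrum:
    """Complex 2D L-COSY data with axis metadata.

    ``data`` is indexed [direct, indirect]; ``domain`` is one of
    ``"t2,t1"``, ``"F2,t1"``, ``"F2,F1"``; axes hold seconds (time) or ppm
    (frequency) coordinates matching the domain tag.
    """

    data: np.ndarray
    domain: str
    params: SequenceParams
    axis2: np.ndarray
    axis1: np.ndarray
    provenance: object = None

    _DOMAINS = ("t2,t1", "F2,t1", "F2,F1")

    def __post_init__(self):
        if self.domain not in self._DOMAINS:
            raise ValueError(f"unknown domain tag {self.domain!r}")
        if self.data.shape != (len(self.axis2), len(self.axis1)):
            raise ValueError("data shape inconsistent with axes")

    def copy(self) -> "LCOSYSpectrum":
        return replace(self, data=self.data.copy())


def from_fid(fid_data: np.ndarray, params: SequenceParams,
             provenance=None) -> LCOSYSpectrum:
    t2, t1 = time_axes(params)
    return LCOSYSpectrum(fid_data, "t2,t1", params, t2, t1, provenance)


def fid_to_spectrum(spec: LCOSYSpectrum) -> LCOSYSpectrum:
    """Transform to the (F2,F1) domain with the package's fixed convention:
    forward FFT per remaining time axis, orthonormal scaling, fftshift."""
    ppm2, ppm1 = ppm_axes(spec.params)
    if spec.domain == "t2,t1":
        s = np.fft.fftshift(np.fft.fft2(spec.data, norm="ortho"))
        return LCOSYSpectrum(s, "F2,F1", spec.params, ppm2, ppm1,
                             spec.provenance)
    if spec.domain == "F2,t1":
        s = np.fft.fftshift(np.fft.fft(spec.data, axis=1, norm="ortho"),
                            axes=1)
        return LCOSYSpectrum(s, "F2,F1", spec.params, spec.axis2, ppm1,
                             spec.provenance)
    raise ValueError(f"cannot transform from domain {spec.domain!r}")


def spectrum_to_fid(spec: LCOSYSpectrum) -> LCOSYSpectrum:
    """Inverse of :func:`fid_to_spectrum` (full-grid spectra only)."""
    if spec.domain != "F2,F1":
        raise ValueError(f"cannot invert from domain {spec.domain!r}")
    if spec.data.shape != (spec.params.n_t2, spec.params.n_t1):
        raise ValueError("cropped spectra cannot be transformed back")
    data = np.fft.ifft2(np.fft.ifftshift(spec.data), norm="ortho")
    t2, t1 = time_axes(spec.params)
    return LCOSYSpectrum(data, "t2,t1", spec.params, t2, t1, spec.provenance)


def _best_slice(axis_ppm: np.ndarray, lo: float, hi: float, n: int) -> slice:
    """Contiguous n-bin slice of a descending ppm axis best matching
    [lo, hi] (least-squares match of both edges)."""
    if len(axis_ppm) < n:
        raise ValueError("axis shorter than requested window")
    starts = np.arange(len(axis_ppm) - n + 1)
    cost = (axis_ppm[starts] - hi) ** 2 + (axis_ppm[starts + n - 1] - lo) ** 2
    i0 = int(starts[np.argmin(cost)])
    return slice(i0, i0 + n)


def window_slices(params: SequenceParams):
    ppm2, ppm1 = ppm_axes(params)
    s2 = _best_slice(ppm2, *F2_WINDOW_PPM, WINDOW_SHAPE[0])
    s1 = _best_slice(ppm1, *F1_WINDOW_PPM, WINDOW_SHAPE[1])
    return s2, s1


def crop_to_window(spec: LCOSYSpectrum) -> LCOSYSpectrum:
    """Crop an (F2,F1) spectrum to the fixed 512 x 32 analysis window."""
    if spec.domain != "F2,F1":
        raise ValueError("crop_to_window requires an (F2,F1) spectrum")
    s2 = _best_slice(spec.axis2, *F2_WINDOW_PPM, WINDOW_SHAPE[0])
    s1 = _best_slice(spec.axis1, *F1_WINDOW_PPM, WINDOW_SHAPE[1])
    return LCOSYSpectrum(spec.data[s2, s1], "F2,F1", spec.params,
                         spec.axis2[s2], spec.axis1[s1], spec.provenance)


# ---------------------------------------------------------------------------
# synthesis parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthesisRanges:
    """Uniform-draw ranges for the synthesis distributions."""

    lb2_hz: tuple = (5.0, 25.0)
    lb1_hz: tuple = (0.0, 15.0)
    phase_rad: tuple = (0.0, 2.0 * np.pi)
    concentration: tuple = (0.0, 10.0)
    noise_frac: tuple = (0.0, 0.25)
    water_amp: tuple = (0.0, 0.0)
    water_lb_hz: tuple = (8.0, 20.0)

    def __post_init__(self):
        for name in ("lb2_hz", "lb1_hz", "phase_rad", "concentration",
                     "noise_frac", "water_amp", "water_lb_hz"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"degenerate range for {name}: {lo} > {hi}")


@dataclass
class SynthesisParams:
    """One concrete draw of per-metabolite and global synthesis factors."""

    metabolites: tuple
    lb2: np.ndarray          # Hz, per metabolite (t2 broadening)
    lb1: np.ndarray          # Hz, per metabolite (t1 broadening)
    phase: np.ndarray        # rad, per metabolite
    concentration: np.ndarray  # mmol equivalents, per metabolite
    noise_frac: float = 0.0
    water_amp: float = 0.0
    water_lb: float = 14.0

    def __post_init__(self):
        n = len(self.metabolites)
        for name in ("lb2", "lb1", "phase", "concentration"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per metabolite")
            setattr(self, name, arr)


def draw_synthesis_params(rng: np.random.Generator,
                          metabolites,
                          ranges: SynthesisRanges | None = None
                          ) -> SynthesisParams:
    """Independent uniform draws of all synthesis factors."""
    ranges = ranges or SynthesisRanges()
    n = len(metabolites)
    u = lambda r, size=None: rng.uniform(*r, size)
    return SynthesisParams(
        metabolites=tuple(metabolites),
        lb2=u(ranges.lb2_hz, n),
        lb1=u(ranges.lb1_hz, n),
        phase=u(ranges.phase_rad, n),
        concentration=u(ranges.concentration, n),
        noise_frac=float(u(ranges.noise_frac)),
        water_amp=float(u(ranges.water_amp)),
        water_lb=float(u(ranges.water_lb_hz)),
    )


# ---------------------------------------------------------------------------
# synthesis operations
# ---------------------------------------------------------------------------

def _broadening_grids(params: SequenceParams, lb2: float, lb1: float):
    t2, t1 = time_axes(params)
    return np.exp(-np.pi * lb2 * t2), np.exp(-np.pi * lb1 * t1)


def apply_line_broadening(fid: BasisFID, lb2: float, lb1: float,
                          phase: float = 0.0) -> BasisFID:
    """Lorentzian broadening (added FWHM lb2/lb1 in Hz per axis) and
    constant phase roll of a basis FID."""
    if lb2 < 0 or lb1 < 0:
        raise ValueError("line broadenings must be >= 0")
    w2, w1 = _broadening_grids(fid.params, lb2, lb1)
    data = fid.data * np.exp(-1j * phase) * np.outer(w2, w1)
    return BasisFID(fid.metabolite, data, fid.params)


def mix_metabolites(basis: BasisSet, sp: SynthesisParams) -> LCOSYSpectrum:
    """s_init = sum_m c_m * B_lb,m in the (t2,t1) domain."""
    if tuple(sp.metabolites) != basis.names:
        raise KeyError(
            f"params metabolites {sp.metabolites} != basis {basis.names}")
    params = basis.params
    t2, t1 = time_axes(params)
    acc = np.zeros((params.n_t2, params.n_t1), dtype=complex)
    for i, name in enumerate(basis.names):
        c = sp.concentration[i]
        if c == 0:
            continue
        w2 = np.exp(-np.pi * sp.lb2[i] * t2) * (c * np.exp(-1j * sp.phase[i]))
        w1 = np.exp(-np.pi * sp.lb1[i] * t1)
        acc += basis[name].data * np.outer(w2, w1)
    return from_fid(acc, params, provenance=sp)


def add_noise(spec: LCOSYSpectrum, noise_frac: float,
              rng: np.random.Generator) -> LCOSYSpectrum:
    """Add i.i.d. complex Gaussian noise in the (F2,F1) domain with
    per-component standard deviation noise_frac * max |cropped spectrum|."""
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    if spec.domain != "F2,F1":
        raise ValueError("add_noise expects an (F2,F1) spectrum")
    if noise_frac == 0:
        return spec.copy()
    scale = np.abs(crop_to_window(spec).data).max() if \
        spec.data.shape != WINDOW_SHAPE else np.abs(spec.data).max()
    sigma = noise_frac * scale
    noise = rng.standard_normal(spec.data.shape) + \
        1j * rng.standard_normal(spec.data.shape)
    return replace(spec, data=spec.data + sigma * noise)


def add_water(spec_fid: LCOSYSpectrum, water_amp: float, water_lb: float,
              water_basis: BasisFID) -> LCOSYSpectrum:
    """Add a line-broadened water signal scaled so that its full-grid
    spectral peak is water_amp times the tallest metabolite peak."""
    if water_amp < 0:
        raise ValueError("water_amp must be >= 0")
    if spec_fid.domain != "t2,t1":
        raise ValueError("add_water expects a (t2,t1) FID")
    if water_amp == 0:
        return spec_fid.copy()
    water = apply_line_broadening(water_basis, water_lb, water_lb).data
    met_peak = np.abs(np.fft.fft2(spec_fid.data, norm="ortho")).max()
    water_peak = np.abs(np.fft.fft2(water, norm="ortho")).max()
    scale = water_amp * met_peak / water_peak
    return replace(spec_fid, data=spec_fid.data + scale * water)


# ---------------------------------------------------------------------------
# channel encoding
# ---------------------------------------------------------------------------

@dataclass
class ChannelStack:
    """Real 3D (channels, 512, 32) encoding of a cropped spectrum.

    For spectra the channels are (real, imaginary, magnitude); quantitation
    targets hold one magnitude window per metabolite.  ``scale_max`` is the
    magnitude maximum divided out before scaling to ``target_scale``.
    """

    data: np.ndarray
    scale_max: float
    target_scale: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("channel stack must be (channels, H, W)")


def to_channels(spec: LCOSYSpectrum, target_scale: float = 1.0) -> ChannelStack:
    """Normalize by the magnitude maximum and emit (real, imag, magnitude)."""
    if target_scale not in (1, 1.0, 100, 100.0):
        raise ValueError("target_scale must be 1 or 100")
    mag = np.abs(spec.data)
    scale_max = float(mag.max())
    if scale_max == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    k = target_scale / scale_max
    data = np.stack([spec.data.real * k, spec.data.imag * k, mag * k])
    return ChannelStack(data, scale_max, float(target_scale))


def channels_to_complex(stack: ChannelStack) -> np.ndarray:
    """Invert :func:`to_channels` back to un-normalized complex data."""
    k = stack.scale_max / stack.target_scale
    return (stack.data[0].astype(float) + 1j * stack.data[1].astype(float)) * k


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class SpectrumDataset:
    """In-memory training/test container with full regeneration metadata."""

    task: str                       # "recon" | "quant"
    inputs: np.ndarray              # (n, 3, 512, 32) float32
    targets: np.ndarray             # (n, 3 or 17, 512, 32) float32
    input_scales: np.ndarray        # per-sample scale_max of the input stack
    target_scales: np.ndarray
    params_list: list = field(default_factory=list)
    seed: int = 0
    mask: object = None
    metabolites: tuple = ()

    def __len__(self) -> int:
        return len(self.inputs)


def _windowed(spec_data_fid: np.ndarray, params: SequenceParams,
              s2: slice, s1: slice) -> np.ndarray:
    """Cropped (F2,F1) window of a (t2,t1) array, transforming only the
    needed rows along the indirect axis."""
    x = np.fft.fftshift(np.fft.fft(spec_data_fid, axis=0, norm="ortho"),
                        axes=0)[s2]
    x = np.fft.fftshift(np.fft.fft(x, axis=1, norm="ortho"), axes=1)[:, s1]
    return x


def generate_dataset(n: int, task: str, basis: BasisSet, mask=None,
                     seed: int = 0, ranges: SynthesisRanges | None = None,
                     noise_frac=None, water_basis: BasisFID | None = None
                     ) -> SpectrumDataset:
    """Generate n synthetic samples for the reconstruction or quantitation
    task.

    recon: (noisy NUS 3-channel input, noise-free fully sampled 3-channel
    target), both at scale 0-1.  quant: (noisy fully sampled 3-channel input
    at scale 0-100, 17 clean per-metabolite magnitude channels on the same
    global scale).  ``noise_frac`` overrides the drawn noise fraction with a
    fixed level (used by the evaluation sweeps).  Bit-identical under a
    fixed seed.
    """
    from .nus import undersample  # local import to avoid cycle

    if task not in ("recon", "quant"):
        raise ValueError(f"unknown task {task!r}")
    if task == "recon" and mask is None:
        raise ValueError("task='recon' requires a sampling mask")
    params = basis.params
    s2, s1 = window_slices(params)
    ranges = ranges or SynthesisRanges()
    n_ch = 3 if task == "recon" else len(basis)
    inputs = np.empty((n, 3, *WINDOW_SHAPE), dtype=np.float32)
    targets = np.empty((n, n_ch, *WINDOW_SHAPE), dtype=np.float32)
    in_scales = np.empty(n)
    tg_scales = np.empty(n)
    params_list = []
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]

    for k in range(n):
        rng = rngs[k]
        sp = draw_synthesis_params(rng, basis.names, ranges)
        if noise_frac is not None:
            sp.noise_frac = float(noise_frac)
        fid = mix_metabolites(basis, sp)
        if sp.water_amp > 0:
            if water_basis is None:
                raise ValueError("water_amp > 0 requires a water basis FID")
            fid = add_water(fid, sp.water_amp, sp.water_lb, water_basis)
        clean = crop_to_window(fid_to_spectrum(mix_metabolites(basis, sp))) \
            if sp.water_amp > 0 else None

        if task == "recon":
            spec = fid_to_spectrum(fid)
            noisy = add_noise(spec, sp.noise_frac, rng)
            nus = undersample(spectrum_to_fid(noisy), mask)
            inp = to_channels(crop_to_window(nus), 1.0)
            tgt = to_channels(clean or crop_to_window(spec), 1.0)
        else:
            spec = crop_to_window(fid_to_spectrum(fid))
            sigma = sp.noise_frac * (np.abs(clean.data).max() if clean
                                     else np.abs(spec.data).max())
            noisy = replace(spec, data=spec.data + sigma * (
                rng.standard_normal(spec.data.shape)
                + 1j * rng.standard_normal(spec.data.shape)))
            inp = to_channels(noisy, 100.0)
            t2g, t1g = time_axes(params)
            tgt_data = np.empty((n_ch, *WINDOW_SHAPE), dtype=np.float32)
            for i, name in enumerate(basis.names):
                c = sp.concentration[i]
                if c == 0:
                    tgt_data[i] = 0.0
                    continue
                w = np.outer(np.exp(-np.pi * sp.lb2[i] * t2g) * c,
                             np.exp(-np.pi * sp.lb1[i] * t1g))
                tgt_data[i] = np.abs(
                    _windowed(basis[name].data * w, params, s2, s1))
            tgt_data *= 100.0 / inp.scale_max
            tgt = ChannelStack(tgt_data, inp.scale_max, 100.0)

        inputs[k] = inp.data
        targets[k] = tgt.data
        in_scales[k] = inp.scale_max
        tg_scales[k] = tgt.scale_max
        params_list.append(sp)

    return SpectrumDataset(task, inputs, targets, in_scales, tg_scales,
                           params_list, seed, mask, basis.names)
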