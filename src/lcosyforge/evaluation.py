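"""Metrics and experiment harnesses: MSE/NMSE, concentration readout,
linearity statistics, noise-level and water-amplitude sweeps.

The error metric is the per-spectrum mean squared difference over the
512 x 32 window, averaged over channels; on spectra normalized to unit
maximum magnitude the normalized MSE percentage is simply 100 x MSE.
Concentrations are read out from a quantitation model's per-metabolite
magnitude windows as the channel maximum, un-normalized by the input's
recorded scale and divided by the unit-concentration reference window
maximum at the fixed reference broadening; residual proportionality bias is
absorbed by the ordinary-least-squares linearity fit (slope, coefficient of
determination, standard error of the slope).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as _stats

from .dunet_models import TrainedModel, quantify_spectrum
from .spin_simulator import BasisSet
from .synthesizer import (
    REFERENCE_LB1,
    REFERENCE_LB2,
    ChannelStack,
    SpectrumDataset,
    SynthesisParams,
    add_water,
    crop_to_window,
    fid_to_spectrum,
    mix_metabolites,
    time_axes,
    to_channels,
    window_slices,
    _windowed,
)

__all__ = [
    "RegressionStats",
    "SweepResult",
    "mse",
    "nmse_percent",
    "reference_window_maxima",
    "extract_concentration",
    "extract_concentrations",
    "fit_linearity",
    "linearity_table",
    "noise_sweep",
    "water_sweep",
    "NOISE_LEVELS",
]

#: Noise level k corresponds to a fraction 0.025 * k of the maximum signal
#: (level 2 = 5%, level 8 = 20%).
NOISE_LEVELS = tuple(0.025 * k for k in range(1, 11))


@dataclass(frozen=True)
class RegressionStats:
    """Slope, coefficient of determination and slope standard error of the
    predicted-vs-actual concentration fit (ideal: 1, 1, 0)."""

    slope: float
    r2: float
    std_error: float

    def __post_init__(self):
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


@dataclass
class SweepResult:
    """Per-level mean metric (with dispersion) along a sweep axis."""

    axis: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    metric: str
    manifest: dict

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("sweep axis must be strictly increasing")
        if len(self.axis) != len(self.mean):
            raise ValueError("one metric entry per axis value required")


# ---------------------------------------------------------------------------
# error metrics
# ---------------------------------------------------------------------------

def _stack_data(x) -> np.ndarray:
    return x.data if isinstance(x, ChannelStack) else np.asarray(x)


def mse(recon, actual) -> float:
    """Mean squared difference over the 512 x 32 grid, averaged over
    channels."""
    r, a = _stack_data(recon), _stack_data(actual)
    if r.shape != a.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {a.shape}")
    return float(np.mean((r.astype(np.float64) - a.astype(np.float64)) ** 2))


def nmse_percent(recon, actual) -> float:
    """100 x MSE / max(|actual|)^2; equals 100 x MSE on unit-max spectra."""
    a = _stack_data(actual)
    peak = float(np.abs(a).max())
    if peak == 0:
        raise ValueError("actual spectrum is identically zero")
    return 100.0 * mse(recon, actual) / peak ** 2


# ---------------------------------------------------------------------------
# concentration readout
# ---------------------------------------------------------------------------

def reference_window_maxima(basis: BasisSet,
                            lb2: float = REFERENCE_LB2,
                            lb1: float = REFERENCE_LB1) -> np.ndarray:
    """Maximum of each metabolite's unit-concentration cropped magnitude
    window at the fixed reference broadening."""
    params = basis.params
    s2, s1 = window_slices(params)
    t2, t1 = time_axes(params)
    w = np.outer(np.exp(-np.pi * lb2 * t2), np.exp(-np.pi * lb1 * t1))
    return np.array([
        np.abs(_windowed(basis[name].data * w, params, s2, s1)).max()
        for name in basis.names])


def extract_concentration(pred: ChannelStack, metabolite: str,
                          basis: BasisSet, scale_max: float | None = None,
                          ref_maxima: np.ndarray | None = None) -> float:
    """Maximum-intensity concentration estimate for one metabolite channel."""
    if metabolite not in basis.names:
        raise KeyError(f"unknown metabolite {metabolite!r}")
    i = basis.names.index(metabolite)
    ref = ref_maxima if ref_maxima is not None \
        else reference_window_maxima(basis)
    scale_max = scale_max if scale_max is not None else pred.scale_max
    peak = float(pred.data[i].max())
    return peak * (scale_max / pred.target_scale) / ref[i]


def extract_concentrations(pred: ChannelStack, basis: BasisSet,
                           scale_max: float | None = None,
                           ref_maxima: np.ndarray | None = None) -> np.ndarray:
    """Vectorized per-metabolite maximum-intensity readout."""
    ref = ref_maxima if ref_maxima is not None \
        else reference_window_maxima(basis)
    scale_max = scale_max if scale_max is not None else pred.scale_max
    peaks = pred.data.reshape(len(ref), -1).max(axis=1)
    return peaks * (scale_max / pred.target_scale) / ref


def fit_linearity(actual, predicted) -> RegressionStats:
    """OLS of predicted on actual (with intercept)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.var(actual) == 0:
        raise ValueError("zero variance in actual concentrations")
    res = _stats.linregress(actual, predicted)
    return RegressionStats(float(res.slope), float(res.rvalue) ** 2,
                           float(res.stderr))


def linearity_table(actual: np.ndarray, predicted: np.ndarray,
                    names) -> dict:
    """Per-metabolite RegressionStats from (n_spectra, n_met) arrays."""
    return {name: fit_linearity(actual[:, i], predicted[:, i])
            for i, name in enumerate(names)}


# ---------------------------------------------------------------------------
# quantitation sweeps
# ---------------------------------------------------------------------------

def _renoise_and_quantify(trained: TrainedModel, base: SpectrumDataset,
                          basis: BasisSet, noise_frac: float, seed: int,
                          water_amp: float = 0.0,
                          water_basis=None):
    """Re-noise the clean cropped spectra of a quant dataset at a fixed
    level (optionally after water injection), run the model, and return
    (per-spectrum channel MSEs, actual conc matrix, predicted conc matrix).

    The clean complex windows are rebuilt from the stored SynthesisParams,
    so the identical underlying spectra are reused across levels.  Channel
    MSEs are expressed on the unit-max scale (normalized by the clean
    spectrum's peak): the working 0-100 scale is set by the *noisy*
    magnitude maximum, which grows with the noise level and would
    otherwise deflate the error metric as noise increases."""
    rng_stream = np.random.SeedSequence(seed).spawn(len(base))
    ref = reference_window_maxima(basis)
    errors = np.empty(len(base))
    actual = np.empty((len(base), len(basis)))
    predicted = np.empty((len(base), len(basis)))
    for k, sp in enumerate(base.params_list):
        rng = np.random.default_rng(rng_stream[k])
        fid = mix_metabolites(basis, sp)
        if water_amp > 0:
            fid = add_water(fid, water_amp, sp.water_lb, water_basis)
        clean = crop_to_window(fid_to_spectrum(fid))
        clean_peak = np.abs(clean.data).max() if water_amp == 0 else \
            np.abs(crop_to_window(
                fid_to_spectrum(mix_metabolites(basis, sp))).data).max()
        sigma = noise_frac * clean_peak
        noisy = replace(clean, data=clean.data + sigma * (
            rng.standard_normal(clean.data.shape)
            + 1j * rng.standard_normal(clean.data.shape)))
        inp = to_channels(noisy, 100.0)
        pred = quantify_spectrum(trained, inp)
        # clean 17-channel target on the same global scale as the input
        tgt = _quant_target(basis, sp, inp.scale_max)
        errors[k] = mse(pred.data, tgt) * \
            (inp.scale_max / (100.0 * clean_peak)) ** 2
        actual[k] = sp.concentration
        predicted[k] = extract_concentrations(pred, basis, inp.scale_max, ref)
    return errors, actual, predicted


def _quant_target(basis: BasisSet, sp: SynthesisParams,
                  scale_max: float) -> np.ndarray:
    params = basis.params
    s2, s1 = window_slices(params)
    t2, t1 = time_axes(params)
    out = np.empty((len(basis), s2.stop - s2.start, s1.stop - s1.start),
                   dtype=np.float32)
    for i, name in enumerate(basis.names):
        c = sp.concentration[i]
        if c == 0:
            out[i] = 0
            continue
        w = np.outer(np.exp(-np.pi * sp.lb2[i] * t2) * c,
                     np.exp(-np.pi * sp.lb1[i] * t1))
        out[i] = np.abs(_windowed(basis[name].data * w, params, s2, s1))
    return out * (100.0 / scale_max)


def noise_sweep(trained: TrainedModel, base: SpectrumDataset,
                basis: BasisSet, levels=NOISE_LEVELS,
                seed: int = 0) -> SweepResult:
    """Mean 17-channel unit-max MSE of the quantitation model on the same
    spectra re-noised at each level (fixed per-level seeds)."""
    if trained.task != "quant":
        raise ValueError("noise_sweep requires a trained quantitation model")
    levels = tuple(levels)
    means, stds = [], []
    for j, frac in enumerate(levels):
        errs, _, _ = _renoise_and_quantify(trained, base, basis, frac,
                                           seed=seed * 1000 + j)
        means.append(errs.mean())
        stds.append(errs.std())
    return SweepResult(np.asarray(levels), np.asarray(means),
                       np.asarray(stds), "mse",
                       {"n_spectra": len(base), "seed": seed})


WATER_AMPLITUDES = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)


def water_sweep(trained: TrainedModel, base: SpectrumDataset,
                basis: BasisSet, water_basis, amplitudes=WATER_AMPLITUDES,
                noise_frac: float = 0.05, seed: int = 0) -> SweepResult:
    """Mean slope standard error across metabolites as a function of the
    injected water amplitude (model trained without water)."""
    if trained.task != "quant":
        raise ValueError("water_sweep requires a trained quantitation model")
    amplitudes = tuple(amplitudes)
    means, stds = [], []
    for j, amp in enumerate(amplitudes):
        _, actual, predicted = _renoise_and_quantify(
            trained, base, basis, noise_frac, seed=seed * 1000 + j,
            water_amp=amp, water_basis=water_basis)
        table = linearity_table(actual, predicted, basis.names)
        se = np.array([st.std_error for st in table.values()])
        means.append(se.mean())
        stds.append(se.std())
    return SweepResult(np.asarray(amplitudes), np.asarray(means),
                       np.asarray(stds), "std_error",
                       {"n_spectra": len(base), "seed": seed,
                        "noise_frac": noise_frac})
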