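"""Spectrum synthesis: parameter draws, broadening, mixing, noise, water,
FFT conventions, cropping, channel encoding and dataset generation."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from lcosyforge.spin_simulator import SpinSystem, simulate_lcosy_fid
from lcosyforge.synthesizer import (ChannelStack, SynthesisRanges,
                                    add_noise, add_water,
                                    apply_line_broadening,
                                    channels_to_complex, crop_to_window,
                                    draw_synthesis_params, fid_to_spectrum,
                                    from_fid, generate_dataset,
                                    mix_metabolites, spectrum_to_fid,
                                    to_channels)


# ---------------------------------------------------------------------------
# parameter draws
# ---------------------------------------------------------------------------

def test_draws_reproducible_and_within_ranges():
    names = tuple("m%d" % i for i in range(17))
    a = draw_synthesis_params(np.random.default_rng(7), names)
    b = draw_synthesis_params(np.random.default_rng(7), names)
    assert np.array_equal(a.lb2, b.lb2) and a.noise_frac == b.noise_frac

    rng = np.random.default_rng(1)
    lb2 = np.concatenate([draw_synthesis_params(rng, names).lb2
                          for _ in range(600)])
    assert lb2.min() >= 5.0 and lb2.max() <= 25.0
    assert lb2.min() < 6.0 and lb2.max() > 24.0    # spans the stated range


def test_collapsed_ranges_are_deterministic():
    ranges = SynthesisRanges(lb2_hz=(10, 10), lb1_hz=(5, 5),
                             phase_rad=(0, 0), concentration=(2, 2),
                             noise_frac=(0.1, 0.1))
    sp = draw_synthesis_params(np.random.default_rng(0), ("a", "b"), ranges)
    assert np.all(sp.lb2 == 10) and np.all(sp.concentration == 2)
    assert sp.noise_frac == 0.1


def test_degenerate_range_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        SynthesisRanges(lb2_hz=(25, 5))


# ---------------------------------------------------------------------------
# line broadening
# ---------------------------------------------------------------------------

def test_broadening_identity_and_phase(small_params):
    fid = simulate_lcosy_fid(SpinSystem("x", (2.0,), np.zeros((1, 1))),
                             small_params)
    same = apply_line_broadening(fid, 0.0, 0.0, 0.0)
    assert np.allclose(same.data, fid.data)
    neg = apply_line_broadening(fid, 0.0, 0.0, np.pi)
    assert np.allclose(neg.data, -fid.data, atol=1e-12)
    with pytest.raises(ValueError):
        apply_line_broadening(fid, -1.0, 0.0)


def test_broadening_sets_lorentzian_width(params):
    """lb2 controls the added F2 Lorentzian FWHM (fit on |S|^2)."""
    fid = simulate_lcosy_fid(SpinSystem("x", (3.0,), np.zeros((1, 1))),
                             params)
    for lb2 in (8.0, 15.0):
        spec = fid_to_spectrum(from_fid(
            apply_line_broadening(fid, lb2, 6.0).data, params))
        mag = np.abs(spec.data)
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        f_hz = (params.carrier_ppm - spec.axis2) * params.larmor_mhz
        prof = mag[:, j] ** 2

        def lorentz2(f, a, f0, w):
            return a / ((np.pi * w) ** 2 + (2 * np.pi * (f - f0)) ** 2)

        sl = slice(i - 60, i + 60)
        popt, _ = curve_fit(lorentz2, f_hz[sl], prof[sl],
                            p0=[prof[i] * (np.pi * lb2) ** 2, f_hz[i], lb2])
        assert abs(popt[2]) == pytest.approx(lb2, rel=0.05)


def test_broadening_never_increases_peak_height(basis):
    b = basis["NAA"]
    plain = np.abs(fid_to_spectrum(from_fid(b.data, b.params)).data).max()
    broad = np.abs(fid_to_spectrum(from_fid(
        apply_line_broadening(b, 12.0, 6.0).data, b.params)).data).max()
    assert broad <= plain


# ---------------------------------------------------------------------------
# mixing
# ---------------------------------------------------------------------------

def test_mixing_linearity(basis):
    rng = np.random.default_rng(3)
    sp = draw_synthesis_params(rng, basis.names)

    zero = sp
    zero.concentration = np.zeros(17)
    assert not mix_metabolites(basis, zero).data.any()

    only_naa = draw_synthesis_params(np.random.default_rng(4), basis.names)
    only_naa.concentration = np.zeros(17)
    i = basis.names.index("NAA")
    only_naa.concentration[i] = 1.0
    mixed = mix_metabolites(basis, only_naa)
    manual = apply_line_broadening(basis["NAA"], only_naa.lb2[i],
                                   only_naa.lb1[i], only_naa.phase[i])
    assert np.allclose(mixed.data, manual.data, atol=1e-10)

    sp2 = draw_synthesis_params(np.random.default_rng(5), basis.names)
    one = mix_metabolites(basis, sp2)
    sp2.concentration = 2 * sp2.concentration
    two = mix_metabolites(basis, sp2)
    assert np.allclose(two.data, 2 * one.data, rtol=1e-12)


def test_mixing_requires_matching_metabolites(basis):
    sp = draw_synthesis_params(np.random.default_rng(0), ("NAA", "Lac"))
    with pytest.raises(KeyError):
        mix_metabolites(basis, sp)


# ---------------------------------------------------------------------------
# noise and water
# ---------------------------------------------------------------------------

def test_noise_statistics(basis):
    sp = draw_synthesis_params(np.random.default_rng(6), basis.names)
    spec = fid_to_spectrum(mix_metabolites(basis, sp))
    assert np.array_equal(add_noise(spec, 0.0,
                                    np.random.default_rng(0)).data,
                          spec.data)
    peak = np.abs(crop_to_window(spec).data).max()
    noisy = add_noise(spec, 0.25, np.random.default_rng(1))
    resid = (noisy.data - spec.data).real.ravel() / peak
    assert np.std(resid) == pytest.approx(0.25, rel=0.03)
    noisy2 = add_noise(spec, 0.25, np.random.default_rng(2))
    assert not np.array_equal(noisy.data, noisy2.data)


def test_water_scaling_and_energy(basis, water_fid):
    sp = draw_synthesis_params(np.random.default_rng(8), basis.names)
    fid = mix_metabolites(basis, sp)
    assert np.array_equal(add_water(fid, 0.0, 12.0, water_fid).data,
                          fid.data)
    met_peak = np.abs(fid_to_spectrum(fid).data).max()
    energies = []
    for amp in (0.5, 2.0, 4.0):
        wet = add_water(fid, amp, 12.0, water_fid)
        spec = fid_to_spectrum(wet)
        energies.append(np.sum(np.abs(spec.data) ** 2))
        if amp == 2.0:
            assert np.abs(spec.data).max() == pytest.approx(2 * met_peak,
                                                            rel=0.15)
    assert energies == sorted(energies)            # monotone in amplitude


# ---------------------------------------------------------------------------
# FFT convention and cropping
# ---------------------------------------------------------------------------

def test_fft_roundtrip_parseval_and_single_bin(params):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((params.n_t2, params.n_t1)) + \
        1j * rng.standard_normal((params.n_t2, params.n_t1))
    fid = from_fid(data, params)
    spec = fid_to_spectrum(fid)
    back = spectrum_to_fid(spec)
    assert np.abs(back.data - data).max() / np.abs(data).max() < 1e-10
    assert np.sum(np.abs(spec.data) ** 2) == pytest.approx(
        np.sum(np.abs(data) ** 2), rel=1e-12)       # Parseval (ortho norm)

    # a pure complex exponential concentrates in a single bin per axis
    t2 = np.arange(params.n_t2) * params.dwell2
    t1 = np.arange(params.n_t1) * params.dwell1
    nu2, nu1 = 250.0, -125.0
    pure = np.exp(-1j * 2 * np.pi * (nu2 * t2[:, None] + nu1 * t1[None, :]))
    s = fid_to_spectrum(from_fid(pure, params))
    mag = np.abs(s.data)
    assert mag.max() ** 2 == pytest.approx(np.sum(mag ** 2), rel=1e-12)


def test_domain_tag_enforced(params):
    spec = fid_to_spectrum(from_fid(np.ones((params.n_t2, params.n_t1),
                                            complex), params))
    with pytest.raises(ValueError):
        fid_to_spectrum(spec)                      # already (F2,F1)
    with pytest.raises(ValueError):
        spectrum_to_fid(crop_to_window(spec))      # cropped: not invertible


def test_crop_window_shape_extent_idempotence(basis):
    sp = draw_synthesis_params(np.random.default_rng(9), basis.names)
    spec = fid_to_spectrum(mix_metabolites(basis, sp))
    w = crop_to_window(spec)
    assert w.data.shape == (512, 32)
    assert w.axis2[0] - w.axis2[-1] == pytest.approx(4.0, abs=0.15)
    assert w.axis1[0] - w.axis1[-1] == pytest.approx(3.1, abs=0.25)
    again = crop_to_window(w)
    assert np.array_equal(again.data, w.data)      # idempotent


# ---------------------------------------------------------------------------
# channel encoding
# ---------------------------------------------------------------------------

def test_channels_normalization_and_roundtrip(basis):
    sp = draw_synthesis_params(np.random.default_rng(10), basis.names)
    w = crop_to_window(fid_to_spectrum(mix_metabolites(basis, sp)))
    for scale in (1.0, 100.0):
        stack = to_channels(w, scale)
        assert stack.data[2].max() == pytest.approx(scale, rel=1e-6)
        assert np.allclose(stack.data[2],
                           np.hypot(stack.data[0], stack.data[1]),
                           atol=1e-4 * scale)
        rt = channels_to_complex(stack)
        assert np.allclose(rt, w.data, rtol=1e-5,
                           atol=1e-6 * np.abs(w.data).max())

    zero = w.copy()
    zero.data = np.zeros_like(zero.data)
    with pytest.raises(ValueError):
        to_channels(zero)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def test_dataset_determinism_and_contracts(basis, mask4):
    a = generate_dataset(4, "recon", basis, mask=mask4, seed=77)
    b = generate_dataset(4, "recon", basis, mask=mask4, seed=77)
    assert np.array_equal(a.inputs, b.inputs)
    assert np.array_equal(a.targets, b.targets)    # bit-identical

    # recon targets are the clean fully sampled windows (no noise):
    # rebuild from the stored synthesis parameters
    sp = a.params_list[0]
    clean = to_channels(crop_to_window(
        fid_to_spectrum(mix_metabolites(basis, sp))), 1.0)
    assert np.allclose(a.targets[0], clean.data, atol=1e-6)

    q = generate_dataset(3, "quant", basis, seed=78)
    assert q.targets.shape == (3, 17, 512, 32)
    assert q.inputs.shape == (3, 3, 512, 32)
    assert q.inputs[0, 2].max() == pytest.approx(100.0, rel=1e-5)
    assert (q.targets >= 0).all()                  # magnitude targets

    with pytest.raises(ValueError):
        generate_dataset(2, "recon", basis, mask=None, seed=0)
    with pytest.raises(ValueError):
        generate_dataset(2, "nope", basis, seed=0)


def test_quant_targets_are_scaled_singleton_windows(basis):
    """Each quant channel is the metabolite's own broadened magnitude
    window on the input's global 0-100 scale."""
    ds = generate_dataset(2, "quant", basis, seed=90)
    sp = ds.params_list[0]
    i = basis.names.index("NAA")
    manual = apply_line_broadening(basis["NAA"], sp.lb2[i], sp.lb1[i],
                                   sp.phase[i])
    win = np.abs(crop_to_window(fid_to_spectrum(from_fid(
        manual.data * sp.concentration[i], basis.params))).data)
    expected = win * 100.0 / ds.input_scales[0]
    assert np.allclose(ds.targets[0, i], expected, rtol=1e-4, atol=1e-4)
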