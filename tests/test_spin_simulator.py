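"""Density-matrix simulator: operator algebra, peak positions, multiplets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcosyforge.spin_simulator import (CANONICAL_METABOLITES, SequenceParams,
                                       SpinSystem, available_systems,
                                       build_basis_set,
                                       free_evolution_operator,
                                       load_spin_system, pulse_operator,
                                       simulate_lcosy_fid)
from lcosyforge.synthesizer import (apply_line_broadening, fid_to_spectrum,
                                    from_fid, ppm_axes)


def _random_system(rng, n_spins):
    shifts = tuple(rng.uniform(1.0, 4.5, n_spins))
    j = np.zeros((n_spins, n_spins))
    for a in range(n_spins):
        for b in range(a + 1, n_spins):
            j[a, b] = j[b, a] = rng.uniform(-15, 15)
    return SpinSystem("rand", shifts, j)


def _spectrum(system, params, lb2=10.0, lb1=5.0):
    fid = simulate_lcosy_fid(system, params)
    fid = apply_line_broadening(fid, lb2, lb1)
    return fid_to_spectrum(from_fid(fid.data, params))


def _peak_ppm(spec):
    i, j = np.unravel_index(np.argmax(np.abs(spec.data)), spec.data.shape)
    return spec.axis2[i], spec.axis1[j]


# ---------------------------------------------------------------------------
# operator properties
# ---------------------------------------------------------------------------

@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_operators_are_unitary(seed, n_spins):
    """Evolution and pulse operators satisfy U U+ = I to 1e-10."""
    rng = np.random.default_rng(seed)
    sys_ = _random_system(rng, n_spins)
    p = SequenceParams()
    eye = np.eye(2 ** n_spins)
    for u in (free_evolution_operator(sys_, rng.uniform(0, 0.05), p),
              pulse_operator(sys_, rng.uniform(0, 360),
                             rng.uniform(0, 360))):
        assert np.abs(u @ u.conj().T - eye).max() < 1e-10


def test_density_matrix_trace_conserved(ax_system):
    """The full 90-180-t1-90 unitary chain preserves the trace."""
    p = SequenceParams()
    dim = 4
    rho = np.diag(np.array([1.0, 0.5, -0.5, -1.0]))
    trace0 = np.trace(rho)
    for u in (pulse_operator(ax_system, 90),
              free_evolution_operator(ax_system, p.te / 2, p),
              pulse_operator(ax_system, 180),
              free_evolution_operator(ax_system, p.te / 2, p),
              free_evolution_operator(ax_system, 3 * p.dwell1, p),
              pulse_operator(ax_system, 90)):
        rho = u @ rho @ u.conj().T
    assert abs(np.trace(rho) - trace0) < 1e-10
    assert rho.shape == (dim, dim)


def test_zero_duration_and_zero_flip_are_identity(single_spin_system):
    p = SequenceParams()
    assert np.allclose(free_evolution_operator(single_spin_system, 0.0, p),
                       np.eye(2), atol=1e-12)
    assert np.allclose(pulse_operator(single_spin_system, 0.0), np.eye(2),
                       atol=1e-12)


def test_double_180_is_identity_up_to_global_phase(ax_system):
    u = pulse_operator(ax_system, 180.0, 0.0)
    uu = u @ u
    phase = uu[0, 0] / abs(uu[0, 0])
    assert np.abs(uu / phase - np.eye(4)).max() < 1e-10


def test_90_pulse_creates_maximal_transverse_magnetization(
        single_spin_system):
    iz = np.diag([0.5, -0.5])
    iminus = np.array([[0, 0], [1, 0]], dtype=complex)
    coherences = {}
    for flip in (30.0, 60.0, 90.0, 120.0):
        u = pulse_operator(single_spin_system, flip)
        rho = u @ iz @ u.conj().T
        coherences[flip] = abs(np.trace(rho @ iminus))
    assert max(coherences, key=coherences.get) == 90.0
    assert coherences[90.0] == pytest.approx(0.5, abs=1e-10)


def test_single_spin_free_evolution_phase(single_spin_system):
    """Off-resonance precession rotates the I+ coherence by exp(-i 2 pi nu t)."""
    p = SequenceParams()
    nu = (single_spin_system.shifts[0] - p.carrier_ppm) * p.larmor_mhz
    tau = 3.1e-3
    u = free_evolution_operator(single_spin_system, tau, p)
    iplus = np.array([[0, 1], [0, 0]], dtype=complex)
    rotated = u @ iplus @ u.conj().T
    assert np.allclose(rotated, np.exp(-1j * 2 * np.pi * nu * tau) * iplus,
                       atol=1e-10)


# ---------------------------------------------------------------------------
# sequence-level spectra
# ---------------------------------------------------------------------------

def _local_maxima(mag):
    """Boolean map of strict 4-neighborhood local maxima."""
    m = np.zeros_like(mag, dtype=bool)
    c = mag[1:-1, 1:-1]
    m[1:-1, 1:-1] = ((c > mag[:-2, 1:-1]) & (c > mag[2:, 1:-1])
                     & (c > mag[1:-1, :-2]) & (c > mag[1:-1, 2:]))
    return m


def test_single_spin_yields_single_diagonal_peak(single_spin_system, params):
    spec = _spectrum(single_spin_system, params)
    p2, p1 = _peak_ppm(spec)
    assert abs(p2 - 3.0) < 0.02 and abs(p1 - 3.0) < 0.07
    # the only local maxima above 1% of the peak are the peak itself and
    # its own truncation/tail structure in the peak's rows and columns
    mag = np.abs(spec.data)
    i, j = np.unravel_index(np.argmax(mag), mag.shape)
    peaks = _local_maxima(mag) & (mag > 0.01 * mag.max())
    peaks[max(0, i - 30):i + 31, :] = False
    peaks[:, max(0, j - 4):j + 5] = False
    assert not peaks.any()


def test_frequency_axis_consistent_with_analytic_fid(params):
    """Peak bin of the simulated spin matches a directly constructed
    single-exponential FID transformed with the same convention."""
    delta = 3.2
    sys_ = SpinSystem("x", (delta,), np.zeros((1, 1)))
    spec = _spectrum(sys_, params)
    i_sim, j_sim = np.unravel_index(np.argmax(np.abs(spec.data)),
                                    spec.data.shape)
    nu = (delta - params.carrier_ppm) * params.larmor_mhz
    t2 = np.arange(params.n_t2) * params.dwell2
    t1 = np.arange(params.n_t1) * params.dwell1
    analytic = np.exp(-1j * 2 * np.pi * nu * (t2[:, None] + t1[None, :]))
    analytic *= np.exp(-np.pi * 10 * t2[:, None] - np.pi * 5 * t1[None, :])
    ref = fid_to_spectrum(from_fid(analytic, params))
    i_ref, j_ref = np.unravel_index(np.argmax(np.abs(ref.data)),
                                    ref.data.shape)
    assert (i_sim, j_sim) == (i_ref, j_ref)


def test_ax_system_shows_cross_peaks(ax_system, small_params):
    """A J-coupled AX pair produces cross-peaks at (dA, dX) and (dX, dA)."""
    spec = _spectrum(ax_system, small_params)
    mag = np.abs(spec.data)
    ppm2, ppm1 = spec.axis2, spec.axis1

    bin2 = small_params.sbw2 / small_params.n_t2 / small_params.larmor_mhz
    bin1 = small_params.sbw1 / small_params.n_t1 / small_params.larmor_mhz
    # F1 bins are coarse (0.32 ppm) on the reduced grid
    half2, half1 = 0.15, 1.2 * bin1
    j_ppm = 7.0 / small_params.larmor_mhz
    for pa, pb in [(3.0, 2.0), (2.0, 3.0), (3.0, 3.0), (2.0, 2.0)]:
        m2 = (ppm2 > pa - half2) & (ppm2 < pa + half2)
        m1 = (ppm1 > pb - half1) & (ppm1 < pb + half1)
        block = mag[np.ix_(m2, m1)]
        assert block.max() > 0.2 * mag.max()
        i, j = np.unravel_index(np.argmax(block), block.shape)
        # peak coordinate within one spectral bin (plus J-multiplet width)
        assert abs(ppm2[m2][i] - pa) <= bin2 + j_ppm
        assert abs(ppm1[m1][j] - pb) <= bin1 + j_ppm


def test_lactate_cross_peak_and_creatine_singlet(params):
    lac = _spectrum(load_spin_system("Lac"), params)
    mag = np.abs(lac.data)
    m2 = (lac.axis2 > 3.9) & (lac.axis2 < 4.3)
    m1 = (lac.axis1 > 1.0) & (lac.axis1 < 1.6)
    assert mag[np.ix_(m2, m1)].max() > 0.1 * mag.max()

    cr = _spectrum(load_spin_system("Cr3.0"), params)
    cmag = np.abs(cr.data)
    i, j = np.unravel_index(np.argmax(cmag), cmag.shape)
    peaks = _local_maxima(cmag) & (cmag > 0.01 * cmag.max())
    peaks[max(0, i - 30):i + 31, :] = False
    peaks[:, max(0, j - 4):j + 5] = False
    assert not peaks.any()                        # no cross-peaks


def test_two_equivalent_protons_double_the_fid(small_params):
    one = simulate_lcosy_fid(SpinSystem("a", (2.5,), np.zeros((1, 1))),
                             small_params)
    two = simulate_lcosy_fid(
        SpinSystem("b", (2.5, 2.5), np.zeros((2, 2))), small_params)
    assert np.allclose(two.data, 2 * one.data, atol=1e-9)


def test_fid_amplitude_bounded_by_proton_count(small_params):
    lac = simulate_lcosy_fid(load_spin_system("Lac"), small_params)
    assert np.abs(lac.data).max() <= 4.0 + 1e-9


def test_direct_window_spans_about_four_ppm(params):
    assert 512 / 2048 * params.sbw2 / params.larmor_mhz == pytest.approx(
        4.0, abs=0.15)


# ---------------------------------------------------------------------------
# spin-system table and basis construction
# ---------------------------------------------------------------------------

def test_load_spin_system_contents():
    lac = load_spin_system("Lac")
    assert len(lac) == 1 and lac[0].n_spins == 4
    assert sum(abs(s - 1.31) < 0.02 for s in lac[0].shifts) == 3
    assert lac[0].j_matrix[0, 1] == pytest.approx(6.9, abs=0.2)

    water = load_spin_system("Water")
    assert water[0].n_spins == 2
    assert water[0].shifts == (4.7, 4.7)
    assert not water[0].j_matrix.any()

    cr = load_spin_system("Cr3.0")
    assert not cr[0].j_matrix.any()               # uncoupled singlet group


def test_load_spin_system_unknown_name_lists_available():
    with pytest.raises(KeyError, match="Asp"):
        load_spin_system("NotAMetabolite")


def test_spin_system_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SpinSystem("bad", (1.0, 2.0), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        SpinSystem("bad", (1.0,), np.array([[1.0]]))
    with pytest.raises(ValueError, match="shape"):
        SpinSystem("bad", (1.0, 2.0), np.zeros((3, 3)))


def test_all_bundled_systems_fit_capacity():
    for name in available_systems():
        for sub in load_spin_system(name):
            assert 1 <= sub.n_spins <= 8


def test_basis_set_order_and_cache(tmp_path, small_params):
    names = ("Lac", "Asp", "Cr3.0")
    bs = build_basis_set(names, small_params, cache_dir=tmp_path)
    assert bs.names == ("Asp", "Cr3.0", "Lac")    # canonical ordering
    again = build_basis_set(names, small_params, cache_dir=tmp_path)
    for n in bs.names:
        assert np.array_equal(bs[n].data, again[n].data)  # bit-identical

    solo = build_basis_set(["Lac"], small_params)
    assert solo.names == ("Lac",)


def test_default_basis_has_17_entries(basis):
    assert len(basis) == 17
    assert basis.names == CANONICAL_METABOLITES
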