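"""Density-matrix simulation of the L-COSY experiment.

Simulates noise-free 2D time-domain signals (FIDs) for networks of J-coupled
protons evolving under the localized correlated spectroscopy sequence

    90x -- TE/2 -- 180x -- TE/2 -- t1 -- 90x -- acquire(t2)

with ideal, instantaneous, non-selective pulses.  Spin systems are described
by chemical shifts (ppm) and scalar couplings (Hz); the isotropic Hamiltonian
in the rotating frame of the transmitter is

    H = sum_k 2*pi*nu_k Iz_k + sum_{k<l} 2*pi*J_kl (I_k . I_l),

with nu_k = (delta_k - carrier_ppm) * larmor_mhz in Hz.  Detection is the
<I-> coherence so that, with the package's forward-FFT convention, a spin at
delta ppm appears at ppm = carrier_ppm - f/larmor_mhz on both axes.

Metabolites whose coupled network exceeds eight protons are bundled as
independent sub-systems (e.g. the two glucose anomers) whose weighted FIDs
are summed; equivalent uncoupled groups carry a proton-count weight.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import yaml

__all__ = [
    "SpinSystem",
    "SequenceParams",
    "BasisFID",
    "BasisSet",
    "CANONICAL_METABOLITES",
    "available_systems",
    "load_spin_system",
    "free_evolution_operator",
    "pulse_operator",
    "simulate_lcosy_fid",
    "build_basis_set",
]

#: Canonical metabolite ordering; defines the 17 quantitation output channels.
CANONICAL_METABOLITES = (
    "Asp", "Ch", "Cr3.0", "Cr3.9", "GABA", "Glc", "Gln", "Glu", "GSH",
    "Lac", "mI", "NAA", "NAAG", "PCh", "PE", "Tau", "Thr",
)

MAX_SPINS = 8


@dataclass(frozen=True)
class SpinSystem:
    """One coupled proton network.

    Parameters
    ----------
    name : str
        Metabolite identifier (sub-systems share their parent's name).
    shifts : tuple of float
        Chemical shift in ppm for every proton; equivalent protons are
        listed individually.
    j_matrix : ndarray
        Symmetric scalar-coupling matrix in Hz with zero diagonal.
    weight : float
        Amplitude multiplier (proton-count weight for condensed equivalent
        groups, anomeric fraction for glucose).
    """

    name: str
    shifts: tuple
    j_matrix: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        j = np.asarray(self.j_matrix, dtype=float)
        n = len(self.shifts)
        if j.shape != (n, n):
            raise ValueError(f"{self.name}: j_matrix shape {j.shape} != ({n},{n})")
        if not np.allclose(j, j.T):
            raise ValueError(f"{self.name}: j_matrix must be symmetric")
        if np.any(np.diag(j) != 0):
            raise ValueError(f"{self.name}: j_matrix diagonal must be zero")
        if not 1 <= n <= MAX_SPINS:
            raise ValueError(
                f"{self.name}: {n} spins outside supported range 1..{MAX_SPINS}"
            )
        object.__setattr__(self, "shifts", tuple(float(s) for s in self.shifts))
        object.__setattr__(self, "j_matrix", j)

    @property
    def n_spins(self) -> int:
        return len(self.shifts)


@dataclass(frozen=True)
class SequenceParams:
    """L-COSY acquisition parameters.

    te is the echo time in seconds; n_t2/n_t1 the direct/indirect grid;
    sbw2/sbw1 the spectral bandwidths in Hz; larmor_mhz the proton frequency
    (Siemens 3T nominal by default) and carrier_ppm the transmitter position
    (water).
    """

    te: float = 0.030
    n_t2: int = 2048
    n_t1: int = 100
    sbw2: float = 2000.0
    sbw1: float = 1250.0
    larmor_mhz: float = 123.25
    carrier_ppm: float = 4.7

    def __post_init__(self):
        for name in ("te", "sbw2", "sbw1", "larmor_mhz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_t2 < 1 or self.n_t1 < 1:
            raise ValueError("n_t2 and n_t1 must be >= 1")

    @property
    def dwell2(self) -> float:
        return 1.0 / self.sbw2

    @property
    def dwell1(self) -> float:
        return 1.0 / self.sbw1

    def cache_key(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in
             ("te", "n_t2", "n_t1", "sbw2", "sbw1", "larmor_mhz", "carrier_ppm")},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class BasisFID:
    """Noise-free complex 2D FID for one metabolite at unit concentration."""

    metabolite: str
    data: np.ndarray  # complex, indexed [t2, t1]
    params: SequenceParams

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != (self.params.n_t2, self.params.n_t1):
            raise ValueError(
                f"{self.metabolite}: data shape {self.data.shape} != "
                f"({self.params.n_t2}, {self.params.n_t1})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.metabolite}: non-finite FID entries")

    def copy(self) -> "BasisFID":
        return BasisFID(self.metabolite, self.data.copy(), self.params)


@dataclass
class BasisSet:
    """Ordered metabolite -> BasisFID map sharing one set of SequenceParams."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        params = {fid.params.cache_key() for fid in self.entries.values()}
        if len(params) > 1:
            raise ValueError("all basis entries must share SequenceParams")

    @property
    def names(self) -> tuple:
        return tuple(self.entries)

    @property
    def params(self) -> SequenceParams:
        return next(iter(self.entries.values())).params

    def __getitem__(self, name: str) -> BasisFID:
        return self.entries[name]

    def __len__(self) -> int:
        return len(self.entries)

    def stack(self) -> np.ndarray:
        """(n_metabolites, n_t2, n_t1) complex array in canonical order."""
        return np.stack([fid.data for fid in self.entries.values()])


# ---------------------------------------------------------------------------
# bundled spin-parameter table
# ---------------------------------------------------------------------------

def _data_file(name: str):
    fn = name.replace(".", "_").lower() + ".yaml"
    return resources.files("lcosyforge.spin_systems").joinpath(fn)


def available_systems() -> tuple:
    return CANONICAL_METABOLITES + ("Water",)


def load_spin_system(name: str):
    """Load the bundled spin system(s) for one metabolite.

    Returns a tuple of :class:`SpinSystem` sub-systems whose weighted FIDs
    sum to the metabolite signal (a single-element tuple for most
    metabolites).
    """
    if name not in available_systems():
        raise KeyError(
            f"unknown spin system {name!r}; available: "
            + ", ".join(available_systems()))
    doc = yaml.safe_load(_data_file(name).read_text())
    systems = []
    for grp in doc["groups"]:
        shifts = grp["shifts_ppm"]
        n = len(shifts)
        j = np.zeros((n, n))
        for a, b, v in grp.get("j_hz", []):
            j[a, b] = j[b, a] = v
        systems.append(SpinSystem(doc["name"], tuple(shifts), j,
                                  float(grp.get("weight", 1.0))))
    return tuple(systems)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)


def _single_spin_ops(n: int):
    """Per-spin Ix, Iy, Iz in the 2^n product basis."""
    ops = []
    for k in range(n):
        mats = []
        for s in (_SX, _SY, _SZ):
            m = np.array([[1.0]], dtype=complex)
            for i in range(n):
                m = np.kron(m, s if i == k else np.eye(2))
            mats.append(m)
        ops.append(tuple(mats))
    return ops


def _hamiltonian(system: SpinSystem, params: SequenceParams) -> np.ndarray:
    """Rotating-frame isotropic Hamiltonian in rad/s."""
    ops = _single_spin_ops(system.n_spins)
    dim = 2 ** system.n_spins
    h = np.zeros((dim, dim), dtype=complex)
    for k, (ix, iy, iz) in enumerate(ops):
        nu_k = (system.shifts[k] - params.carrier_ppm) * params.larmor_mhz
        h += 2 * np.pi * nu_k * iz
    for k in range(system.n_spins):
        for l in range(k + 1, system.n_spins):
            jkl = system.j_matrix[k, l]
            if jkl == 0:
                continue
            ixk, iyk, izk = ops[k]
            ixl, iyl, izl = ops[l]
            h += 2 * np.pi * jkl * (ixk @ ixl + iyk @ iyl + izk @ izl)
    return h


def free_evolution_operator(system: SpinSystem, duration: float,
                            params: SequenceParams) -> np.ndarray:
    """exp(-i H duration) for the free-evolution Hamiltonian."""
    if not np.isfinite(duration):
        raise ValueError("duration must be finite")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    evals, vecs = np.linalg.eigh(_hamiltonian(system, params))
    return (vecs * np.exp(-1j * evals * duration)) @ vecs.conj().T


def pulse_operator(system: SpinSystem, flip_deg: float,
                   phase_deg: float = 0.0) -> np.ndarray:
    """Ideal hard pulse exp(-i theta sum_k (Ix_k cos(phi) + Iy_k sin(phi)))."""
    if not (np.isfinite(flip_deg) and np.isfinite(phase_deg)):
        raise ValueError("flip and phase must be finite")
    theta = np.deg2rad(flip_deg)
    phi = np.deg2rad(phase_deg)
    ops = _single_spin_ops(system.n_spins)
    gen = sum(ix * np.cos(phi) + iy * np.sin(phi) for ix, iy, _ in ops)
    evals, vecs = np.linalg.eigh(gen)
    return (vecs * np.exp(-1j * theta * evals)) @ vecs.conj().T


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _simulate_subsystem(system: SpinSystem, params: SequenceParams) -> np.ndarray:
    """FID (n_t2, n_t1) of one coupled network, weighted, via eigenbasis
    propagation: all delays are elementwise phase factors in the eigenbasis
    of H, so each t1 increment costs two small matrix products plus one
    transition-amplitude x Fourier-kernel product along t2."""
    n = system.n_spins
    dim = 2 ** n
    ops = _single_spin_ops(n)
    h = _hamiltonian(system, params)
    evals, vecs = np.linalg.eigh(h)
    vh = vecs.conj().T

    p90 = vh @ pulse_operator(system, 90.0) @ vecs
    p180 = vh @ pulse_operator(system, 180.0) @ vecs

    iz_tot = sum(izk for _, _, izk in ops)
    iminus = sum(ixk - 1j * iyk for ixk, iyk, _ in ops)
    rho = vh @ iz_tot @ vecs          # equilibrium, eigenbasis
    det = vh @ iminus @ vecs

    omega = evals[:, None] - evals[None, :]      # rad/s transition frequencies

    def delay(r, tau):
        return r * np.exp(-1j * omega * tau)

    rho = p90 @ rho @ p90.conj().T
    rho = delay(rho, params.te / 2)
    rho = p180 @ rho @ p180.conj().T
    rho_te = delay(rho, params.te / 2)

    # N-type (echo) coherence-pathway selection during t1, as enforced by
    # the sequence's crusher gradients: keep only coherence order +1 in the
    # convention where the detected <I-> elements carry order +1.  Without
    # this the amplitude-modulated signal would alias every peak to a mirror
    # position reflected about the carrier in F1.
    mz = np.real(np.diag(vh @ iz_tot @ vecs))    # total Iz per eigenstate
    order = mz[:, None] - mz[None, :]
    rho_te = rho_te * (np.abs(order - 1.0) < 1e-6)

    # detection: s(t1_i, t2) = sum_ab det[b,a] * rho_i[a,b] * exp(-i w_ab t2).
    # H commutes with total Iz, so det (a single-quantum operator) is only
    # nonzero between adjacent Zeeman manifolds; threshold the rest away.
    dt = det.T
    keep = np.abs(dt) > 1e-12 * max(np.abs(dt).max(), 1e-300)
    a_idx, b_idx = np.nonzero(keep)
    det_amp = dt[a_idx, b_idx]                   # det[b,a]

    scale = system.weight / (dim / 4.0)          # unit amplitude per proton
    phase1 = np.exp(-1j * omega * params.dwell1)
    amps = np.empty((params.n_t1, a_idx.size), dtype=complex)
    rho_t1 = rho_te
    for i in range(params.n_t1):                 # t1 = i * dwell1, first = 0
        rho_obs = p90 @ rho_t1 @ p90.conj().T
        amps[i] = det_amp * rho_obs[a_idx, b_idx]
        rho_t1 = rho_t1 * phase1

    t2 = np.arange(params.n_t2) * params.dwell2
    kernel = np.exp(-1j * np.outer(omega[a_idx, b_idx], t2))
    return scale * (amps @ kernel).T             # (n_t2, n_t1)


def simulate_lcosy_fid(system, params: SequenceParams | None = None) -> BasisFID:
    """Simulate the L-COSY FID for a spin system or tuple of sub-systems."""
    params = params or SequenceParams()
    systems = (system,) if isinstance(system, SpinSystem) else tuple(system)
    if not systems:
        raise ValueError("no spin systems given")
    for s in systems:
        if s.n_spins > MAX_SPINS:
            raise ValueError(f"{s.name}: too many spins ({s.n_spins} > {MAX_SPINS})")
    data = sum(_simulate_subsystem(s, params) for s in systems)
    return BasisFID(systems[0].name, data, params)


# ---------------------------------------------------------------------------
# basis set construction with on-disk cache
# ---------------------------------------------------------------------------

def _write_basis_cache(path: Path, basis: BasisSet) -> None:
    p = basis.params
    with h5py.File(path, "w") as f:
        f.attrs["version"] = 1
        for k in ("te", "n_t2", "n_t1", "sbw2", "sbw1", "larmor_mhz", "carrier_ppm"):
            f.attrs[k] = getattr(p, k)
        for name, fid in basis.entries.items():
            grp = f.create_group(name)
            grp.create_dataset("real", data=fid.data.real)
            grp.create_dataset("imag", data=fid.data.imag)


def _read_basis_cache(path: Path, names, params: SequenceParams):
    try:
        with h5py.File(path, "r") as f:
            entries = {}
            for name in names:
                if name not in f:
                    return None
                grp = f[name]
                data = grp["real"][()] + 1j * grp["imag"][()]
                entries[name] = BasisFID(name, data, params)
        return BasisSet(entries)
    except OSError:
        return None


def build_basis_set(names=None, params: SequenceParams | None = None,
                    cache_dir=None) -> BasisSet:
    """Simulate (or load from cache) the basis FIDs for the given metabolites.

    The cache is an HDF5 file keyed by the SequenceParams hash; repeated
    calls with identical parameters return bit-identical arrays.
    """
    params = params or SequenceParams()
    names = tuple(names) if names is not None else CANONICAL_METABOLITES
    # canonical ordering for known names, appended order for extras (Water)
    ordered = [m for m in CANONICAL_METABOLITES if m in names]
    ordered += [m for m in names if m not in ordered]

    cache_path = None
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        cache_path = cache_dir / f"basis_{params.cache_key()}.h5"
        cached = _read_basis_cache(cache_path, ordered, params)
        if cached is not None:
            return cached

    entries = {}
    for name in ordered:
        try:
            entries[name] = simulate_lcosy_fid(load_spin_system(name), params)
        except Exception as exc:
            raise RuntimeError(f"simulating {name} failed: {exc}") from exc
    basis = BasisSet(entries)
    if cache_path is not None:
        _write_basis_cache(cache_path, basis)
        basis = _read_basis_cache(cache_path, ordered, params) or basis
    return basis
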