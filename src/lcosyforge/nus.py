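"""Exponential-PDF non-uniform sampling of the indirect (t1) dimension.

Masks select a subset of t1 increments with selection weight proportional
to exp(-decay * i / n_total), emphasizing early increments where the signal
is strongest; the last increment is always sampled.  Applying a mask to a
fully sampled acquisition produces the characteristic F1 ridging artifacts
that both the compressed-sensing and the U-Net reconstructions remove.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthesizer import LCOSYSpectrum, fid_to_spectrum

__all__ = [
    "SamplingMask",
    "make_exponential_mask",
    "acceleration_factor",
    "undersample",
    "reference_mask",
    "REFERENCE_MASK_SEEDS",
]

#: Fixed seeds of the shipped reference masks, keyed by points kept of 100.
REFERENCE_MASK_SEEDS = {75: 1, 50: 2, 25: 3}
DEFAULT_DECAY = 2.0


@dataclass(frozen=True)
class SamplingMask:
    """Binary t1-sampling vector (1 = sampled)."""

    bits: np.ndarray
    decay: float = DEFAULT_DECAY
    seed: int | None = None

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.int8)
        if bits.ndim != 1 or not np.isin(bits, (0, 1)).all():
            raise ValueError("mask bits must be a 1D 0/1 vector")
        if bits[-1] != 1:
            raise ValueError("last t1 point must always be sampled")
        object.__setattr__(self, "bits", bits)

    @property
    def n_total(self) -> int:
        return len(self.bits)

    @property
    def n_sampled(self) -> int:
        return int(self.bits.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def make_exponential_mask(n_total: int, n_sampled: int,
                          decay: float = DEFAULT_DECAY,
                          rng=None) -> SamplingMask:
    """Draw a mask of n_sampled of n_total t1 points without replacement
    with weight exp(-decay * i / n_total); the last point is forced on
    (displacing the lowest-weight selected index if necessary)."""
    if not 1 <= n_sampled <= n_total:
        raise ValueError(f"n_sampled={n_sampled} outside 1..{n_total}")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = np.arange(n_total)
    w = np.exp(-decay * idx / n_total)
    chosen = rng.choice(idx, size=n_sampled, replace=False, p=w / w.sum())
    chosen = set(chosen.tolist())
    if n_total - 1 not in chosen:
        chosen.discard(max(chosen))          # lowest-weight selected index
        chosen.add(n_total - 1)
    bits = np.zeros(n_total, dtype=np.int8)
    bits[sorted(chosen)] = 1
    return SamplingMask(bits, decay=decay, seed=seed)


def reference_mask(n_sampled: int, n_total: int = 100) -> SamplingMask:
    """One of the shipped fixed masks (75/50/25 points kept of 100)."""
    if n_total != 100 or n_sampled not in REFERENCE_MASK_SEEDS:
        raise ValueError("reference masks keep 25, 50 or 75 of 100 points")
    return make_exponential_mask(n_total, n_sampled, DEFAULT_DECAY,
                                 REFERENCE_MASK_SEEDS[n_sampled])


def acceleration_factor(mask: SamplingMask) -> float:
    """Scan acceleration n_total / n_sampled, reported to one decimal."""
    return round(mask.n_total / mask.n_sampled, 1)


def undersample(spec: LCOSYSpectrum, mask: SamplingMask) -> LCOSYSpectrum:
    """Zero unsampled t1 increments of a (t2,t1) FID and transform to
    (F2,F1), producing the artifact-bearing NUS spectrum."""
    if spec.domain != "t2,t1":
        raise ValueError("undersample expects a (t2,t1) FID")
    if mask.n_total != spec.params.n_t1:
        raise ValueError(
            f"mask length {mask.n_total} != n_t1 {spec.params.n_t1}")
    masked = replace(spec, data=spec.data * mask.bits[None, :])
    return fid_to_spectrum(masked)
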