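"""Serialization of spectra, masks and datasets.

Arrays live in HDF5 with complex data stored as paired float64 "real"/
"imag" datasets for portability; masks are plain text (one 0/1 per line
with a comment header); datasets carry a sidecar JSON manifest holding the
per-sample synthesis parameters needed for exact regeneration.  Every file
embeds a format version; mismatches raise instead of silently defaulting.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np

from .nus import SamplingMask
from .spin_simulator import SequenceParams
from .synthesizer import LCOSYSpectrum, SpectrumDataset, SynthesisParams

__all__ = [
    "save_spectrum", "load_spectrum",
    "save_mask", "load_mask",
    "save_dataset", "load_dataset",
]

_VERSION = 1
_PARAM_KEYS = ("te", "n_t2", "n_t1", "sbw2", "sbw1", "larmor_mhz",
               "carrier_ppm")


def _write_params(obj, params: SequenceParams):
    for k in _PARAM_KEYS:
        obj.attrs[k] = getattr(params, k)


def _read_params(obj) -> SequenceParams:
    kw = {k: obj.attrs[k] for k in _PARAM_KEYS}
    kw["n_t2"] = int(kw["n_t2"])
    kw["n_t1"] = int(kw["n_t1"])
    return SequenceParams(**kw)


def save_spectrum(spec: LCOSYSpectrum, path) -> None:
    """Lossless write of complex data, domain tag, axes and parameters."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _VERSION
        f.attrs["domain"] = spec.domain
        _write_params(f, spec.params)
        f.create_dataset("real", data=np.asarray(spec.data.real, float))
        f.create_dataset("imag", data=np.asarray(spec.data.imag, float))
        f.create_dataset("axis2", data=np.asarray(spec.axis2, float))
        f.create_dataset("axis1", data=np.asarray(spec.axis1, float))


def load_spectrum(path) -> LCOSYSpectrum:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("version")
        if version != _VERSION:
            raise ValueError(
                f"unsupported spectrum file version {version!r}; "
                f"expected {_VERSION}")
        if "domain" not in f.attrs:
            raise ValueError("spectrum file is missing its domain tag")
        data = f["real"][()] + 1j * f["imag"][()]
        return LCOSYSpectrum(data, str(f.attrs["domain"]), _read_params(f),
                             f["axis2"][()], f["axis1"][()])


def save_mask(mask: SamplingMask, path) -> None:
    path = Path(path)
    header = (f"# lcosyforge sampling mask v{_VERSION}: "
              f"n_total={mask.n_total} n_sampled={mask.n_sampled} "
              f"decay={mask.decay} seed={mask.seed}\n")
    path.write_text(header + "".join(f"{int(b)}\n" for b in mask.bits))


def load_mask(path) -> SamplingMask:
    lines = Path(path).read_text().splitlines()
    meta = {}
    bits = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
        else:
            bits.append(int(line))
    decay = float(meta.get("decay", 0.0))
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return SamplingMask(np.array(bits, dtype=np.int8), decay=decay, seed=seed)


def save_dataset(ds: SpectrumDataset, path) -> None:
    """HDF5 container (groups inputs/targets/meta) plus a JSON manifest of
    per-sample synthesis parameters next to it."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _VERSION
        f.attrs["task"] = ds.task
        f.attrs["seed"] = ds.seed
        f.attrs["metabolites"] = list(ds.metabolites)
        if ds.mask is not None:
            f.attrs["mask_bits"] = np.asarray(ds.mask.bits)
            f.attrs["mask_decay"] = ds.mask.decay
        f.create_dataset("inputs", data=ds.inputs)
        f.create_dataset("targets", data=ds.targets)
        meta = f.create_group("meta")
        meta.create_dataset("input_scales", data=ds.input_scales)
        meta.create_dataset("target_scales", data=ds.target_scales)
    manifest = [
        {k: (v.tolist() if isinstance(v, np.ndarray) else
             list(v) if isinstance(v, tuple) else v)
         for k, v in asdict(sp).items()}
        for sp in ds.params_list]
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"version": _VERSION, "task": ds.task, "seed": ds.seed,
                    "samples": manifest}, indent=1))


def load_dataset(path) -> SpectrumDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("version") != _VERSION:
            raise ValueError("unsupported dataset file version")
        mask = None
        if "mask_bits" in f.attrs:
            mask = SamplingMask(np.asarray(f.attrs["mask_bits"], np.int8),
                                decay=float(f.attrs["mask_decay"]))
        ds = SpectrumDataset(
            task=str(f.attrs["task"]),
            inputs=f["inputs"][()],
            targets=f["targets"][()],
            input_scales=f["meta/input_scales"][()],
            target_scales=f["meta/target_scales"][()],
            seed=int(f.attrs["seed"]),
            mask=mask,
            metabolites=tuple(str(m) for m in f.attrs["metabolites"]),
        )
    manifest_path = path.with_suffix(path.suffix + ".json")
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        ds.params_list = [
            SynthesisParams(
                metabolites=tuple(s["metabolites"]),
                lb2=np.array(s["lb2"]), lb1=np.array(s["lb1"]),
                phase=np.array(s["phase"]),
                concentration=np.array(s["concentration"]),
                noise_frac=s["noise_frac"], water_amp=s["water_amp"],
                water_lb=s["water_lb"])
            for s in manifest["samples"]]
    return ds
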