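"""Serialization of models and multimodal data (HDF5 primary, NPZ fallback).

File format is chosen by extension: ``.h5``/``.hdf5`` use h5py, anything
else ``numpy.savez``.  Small fixtures can also be exported to CSV (one row
per bin, missing continuous cells empty).
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np

from .params import MultiscaleParams, validate_params
from .simulate import MultimodalData

__all__ = [
    "save_model",
    "load_model",
    "save_data",
    "load_data",
    "export_data_csv",
    "import_data_csv",
]

_MODEL_ARRAYS = ("A", "C_y", "C_z", "Q", "R_y", "d_z")


def _is_hdf5(path) -> bool:
    return Path(path).suffix.lower() in (".h5", ".hdf5")


def save_model(path, p: MultiscaleParams, M: int = 1, horizons: tuple[int, int] = (10, 10)) -> None:
    meta = {
        "n_x": p.n_x,
        "n_y": p.n_y,
        "n_z": p.n_z,
        "bin_width_s": p.bin_width_s,
        "M": M,
        "h_z": horizons[0],
        "h_y": horizons[1],
    }
    arrays = {k: getattr(p, k) for k in _MODEL_ARRAYS}
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            for k, v in arrays.items():
                f.create_dataset(k, data=v)
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        np.savez(path, **arrays, **{f"meta_{k}": v for k, v in meta.items()})


def load_model(path) -> tuple[MultiscaleParams, dict]:
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            arrays = {k: f[k][()] for k in _MODEL_ARRAYS}
            meta = dict(f.attrs)
    else:
        with np.load(path) as f:
            arrays = {k: f[k] for k in _MODEL_ARRAYS}
            meta = {k[5:]: f[k][()] for k in f.files if k.startswith("meta_")}
    p = MultiscaleParams(**arrays, bin_width_s=float(meta.get("bin_width_s", 0.010)))
    report = validate_params(p)
    if not report:
        raise ValueError("loaded model fails validation: " + "; ".join(report.messages))
    return p, meta


def save_data(path, data: MultimodalData, seed: int | None = None) -> None:
    arrays = {"N": data.N, "y": data.y, "mask": data.mask}
    meta = {"M": data.M, "bin_width_s": data.bin_width_s}
    if seed is not None:
        meta["seed"] = seed
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            for k, v in arrays.items():
                f.create_dataset(k, data=v)
            for k, v in meta.items():
                f.attrs[k] = v
    else:
        np.savez(path, **arrays, **{f"meta_{k}": v for k, v in meta.items()})


def load_data(path) -> MultimodalData:
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            arrays = {k: f[k][()] for k in ("N", "y", "mask")}
            meta = dict(f.attrs)
    else:
        with np.load(path) as f:
            arrays = {k: f[k] for k in ("N", "y", "mask")}
            meta = {k[5:]: f[k][()] for k in f.files if k.startswith("meta_")}
    return MultimodalData(
        N=arrays["N"].astype(np.int64),
        y=arrays["y"].astype(float),
        mask=arrays["mask"].astype(bool),
        M=int(meta.get("M", 1)),
        bin_width_s=float(meta.get("bin_width_s", 0.010)),
    )


def export_data_csv(path, data: MultimodalData) -> None:
    """One row per bin: counts then continuous channels (empty if missing)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [f"N{i}" for i in range(data.n_z)] + [f"y{i}" for i in range(data.n_y)]
        )
        for t in range(data.T):
            row = [int(v) for v in data.N[t]]
            if data.mask[t]:
                row += [repr(float(v)) for v in data.y[t]]
            else:
                row += [""] * data.n_y
            w.writerow(row)


def import_data_csv(path, M: int = 1, bin_width_s: float = 0.010) -> MultimodalData:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        n_z = sum(1 for h in header if h.startswith("N"))
        n_y = len(header) - n_z
        Ns, ys, mask = [], [], []
        for row in reader:
            Ns.append([int(v) for v in row[:n_z]])
            obs = all(v != "" for v in row[n_z:]) and n_y > 0
            mask.append(obs or n_y == 0)
            ys.append([float(v) if v != "" else np.nan for v in row[n_z:]])
    return MultimodalData(
        N=np.array(Ns, dtype=np.int64).reshape(len(Ns), n_z),
        y=np.array(ys, dtype=float).reshape(len(ys), n_y),
        mask=np.array(mask, dtype=bool),
        M=M,
        bin_width_s=bin_width_s,
    )
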