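"""Output writers: MRC, TIFF, HDF5, CSV and JSON run summaries.

The MRC writer is deliberately minimal (mode-2 float32, 1024-byte header per
the MRC2014 standard) so the package has no dependency beyond numpy for it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__

MRC_HEADER_SIZE = 1024


def write_mrc(path: str | Path, data: np.ndarray,
              voxel_size_nm: float | tuple[float, float, float] = 1.0) -> None:
    """Write a 2-D image or 3-D volume as a mode-2 (float32) MRC file."""
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("MRC data must be 2-D or 3-D")
    nz, ny, nx = arr.shape
    if np.isscalar(voxel_size_nm):
        vs = (voxel_size_nm,) * 3
    else:
        vs = tuple(voxel_size_nm)
    header = np.zeros(256, dtype=np.int32)
    fheader = header.view(np.float32)
    header[0:3] = (nx, ny, nz)
    header[3] = 2                      # mode 2: float32
    header[7:10] = (nx, ny, nz)        # mx, my, mz
    fheader[10:13] = [n * v * 10.0 for n, v in zip((nx, ny, nz), vs)]  # cell, A
    fheader[13:16] = 90.0
    header[16:19] = (1, 2, 3)
    fheader[19] = float(arr.min())
    fheader[20] = float(arr.max())
    fheader[21] = float(arr.mean())
    header[52] = 542130509             # 'MAP ' little-endian
    header[53] = 17476                 # machine stamp 0x44 0x44
    fheader[54] = float(arr.std())
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(arr.tobytes())


def read_mrc(path: str | Path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = np.frombuffer(fh.read(MRC_HEADER_SIZE), dtype=np.int32)
        nx, ny, nz, mode = header[0], header[1], header[2], header[3]
        if mode != 2:
            raise ValueError(f"only mode-2 MRC supported, got mode {mode}")
        data = np.frombuffer(fh.read(), dtype=np.float32,
                             count=nx * ny * nz)
    return data.reshape(nz, ny, nx).squeeze()


def write_tiff(path: str | Path, data: np.ndarray) -> None:
    """16-bit TIFF preview, linearly scaled to the data range."""
    import tifffile
    arr = np.asarray(data, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    tifffile.imwrite(str(path), (scaled * 65535).astype(np.uint16))


def write_wave(path: str | Path, wave, beam=None, delta_t: float | None = None,
               ) -> None:
    """Exit wave as HDF5 (real + imag datasets with sampling metadata)."""
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("real", data=np.real(wave.array))
        fh.create_dataset("imag", data=np.imag(wave.array))
        fh.attrs["L_nm"] = wave.L
        fh.attrs["N"] = wave.N
        if beam is not None:
            fh.attrs["energy_keV"] = beam.energy_keV
        if delta_t is not None:
            fh.attrs["delta_t_nm"] = delta_t


def read_wave(path: str | Path):
    import h5py

    from .multislice import WaveField
    with h5py.File(path, "r") as fh:
        arr = fh["real"][...] + 1j * fh["imag"][...]
        return WaveField(arr, float(fh.attrs["L_nm"]))


def write_4d_record(path: str | Path, record) -> None:
    """HDF5 layout: /data (scan_y, scan_x, ring, segment) + geometry attrs."""
    import h5py
    with h5py.File(path, "w") as fh:
        d = fh.create_dataset("data", data=record.data)
        d.attrs["dims"] = "scan_y, scan_x, ring, segment"
        fh.create_dataset("beyond", data=record.beyond)
        fh.create_dataset("absorbed", data=record.absorbed)
        fh.create_dataset("ring_edges_mrad",
                          data=np.asarray(record.detector.ring_edges_mrad))
        fh.create_dataset("segments_per_ring",
                          data=np.asarray(record.detector.segments_per_ring))
        fh.attrs["scan_step_nm"] = record.scan_step
        fh.attrs["scan_origin_nm"] = record.scan_origin
        for k, v in record.meta.items():
            fh.attrs[k] = v


def write_mc_result(path: str | Path, result) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=result.counts)
        fh.create_dataset("out_of_range", data=result.out_of_range)
        if result.unscattered is not None:
            fh.create_dataset("unscattered", data=result.unscattered)
        fh.attrs["bin_labels"] = result.bin_labels
        fh.attrs["electrons_per_pixel"] = result.config.electrons_per_pixel
        fh.attrs["scan_step_nm"] = result.config.scan_step
        fh.attrs["energy_keV"] = result.config.energy_keV
        fh.attrs["seed"] = result.config.seed


def write_csv(path: str | Path, columns: dict[str, np.ndarray]) -> None:
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n]) for n in names])
    np.savetxt(path, data, delimiter=",", header=",".join(names), comments="")


def config_digest(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_summary(path: str | Path, config: dict, results: dict) -> None:
    """JSON run log with provenance (config digest, package version)."""
    payload = {
        "package": "cryocontrast",
        "version": __version__,
        "config_digest": config_digest(config),
        "config": config,
        "results": results,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
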