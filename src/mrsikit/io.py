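"""HDF5 container for raw complex k-space echo arrays.

Layout
------
``/kspace``
    complex128 dataset, axes (channel, slice, ky, kx, time), little-endian.
``/meta``
    group with scalar attributes: ``spectral_width`` (Hz), ``dt`` (s),
    ``te`` (ms), ``tr`` (ms), ``slice_thickness`` (mm), ``slice_spacing``
    (mm), ``n_channels``.

This is the only entry point for real data; the synthetic generator
writes the same layout.
"""

from __future__ import annotations

import h5py
import numpy as np

from .exceptions import DataError
from .recon_combine import KSpaceVolume

__all__ = ["save_kspace", "load_kspace"]


def save_kspace(path: str, kvol: KSpaceVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.ascontiguousarray(kvol.data, dtype=np.complex128))
        meta = f.create_group("meta")
        meta.attrs["spectral_width"] = kvol.spectral_width
        meta.attrs["dt"] = kvol.dt
        meta.attrs["n_channels"] = kvol.n_channels
        for key, val in (
            ("te", kvol.te), ("tr", kvol.tr),
            ("slice_thickness", kvol.slice_thickness),
            ("slice_spacing", kvol.slice_spacing),
        ):
            if val is not None:
                meta.attrs[key] = val
        for key, val in kvol.meta.items():
            try:
                meta.attrs[f"x_{key}"] = val
            except TypeError:
                pass  # non-scalar ad hoc metadata is not persisted


def load_kspace(path: str) -> KSpaceVolume:
    with h5py.File(path, "r") as f:
        if "kspace" not in f or "meta" not in f:
            raise DataError(f"{path} is not a k-space container (missing groups)")
        data = f["kspace"][()]
        attrs = dict(f["meta"].attrs)
    if data.ndim != 5:
        raise DataError(f"/kspace must be 5-D, got shape {data.shape}")
    extra = {k[2:]: v for k, v in attrs.items() if k.startswith("x_")}
    return KSpaceVolume(
        data,
        spectral_width=float(attrs["spectral_width"]),
        te=float(attrs["te"]) if "te" in attrs else None,
        tr=float(attrs["tr"]) if "tr" in attrs else None,
        slice_thickness=float(attrs.get("slice_thickness")) if "slice_thickness" in attrs else None,
        slice_spacing=float(attrs.get("slice_spacing")) if "slice_spacing" in attrs else None,
        meta=extra,
    )
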