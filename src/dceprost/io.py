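"""NIfTI and sidecar I/O.

Images move through the pipeline as NIfTI volumes on a common co-registered
grid: 4D (x, y, z, t) for the dynamic series, 3D for parameter maps and
integer masks.  Affines and headers are preserved from input to output, and
every parameter-map directory gets a plain-text sidecar recording the
configuration that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .conversion import AcquisitionParams

__all__ = ["DceSeries", "load_dce", "save_volume", "load_volume", "write_sidecar"]


@dataclass
class DceSeries:
    """A 4D dynamic series with its time vector and acquisition metadata."""

    signal: np.ndarray  # (x, y, z, t)
    times: np.ndarray  # seconds
    acq: AcquisitionParams
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, t)")
        if self.signal.shape[3] != self.times.size:
            raise ValueError("time axis length must match the time vector")


def load_dce(path, acq: AcquisitionParams, dt_tolerance: float = 0.01) -> DceSeries:
    """Load a 4D NIfTI dynamic series, checking it against the acquisition.

    The frame count must match ``acq.n_timepoints``; a mismatch is a hard
    error before any computation, as is a non-uniform time axis implied by a
    NIfTI header whose temporal zoom disagrees with ``acq.dt`` by more than
    ``dt_tolerance`` (relative).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D series, got shape {data.shape}")
    if data.shape[3] != acq.n_timepoints:
        raise ValueError(
            f"{path}: {data.shape[3]} frames but acquisition declares {acq.n_timepoints}"
        )
    zooms = img.header.get_zooms()
    if len(zooms) >= 4 and zooms[3] > 0:
        if abs(zooms[3] - acq.dt) / acq.dt > dt_tolerance:
            raise ValueError(
                f"{path}: header temporal spacing {zooms[3]:g}s disagrees with "
                f"acquisition dt {acq.dt:g}s"
            )
    return DceSeries(signal=data, times=acq.times, acq=acq, affine=img.affine)


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None, dt: float | None = None) -> None:
    """Write a 3D map or 4D series as NIfTI, preserving the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    if dt is not None and data.ndim == 4:
        zooms = list(img.header.get_zooms())
        zooms[3] = dt
        img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON sidecar describing how an output was produced."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
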