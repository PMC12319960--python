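"""Volume I/O, acquisition metadata, masks and label volumes.

All volumes are NIfTI-1 on disk (via :mod:`nibabel`); acquisition metadata
travels in a JSON sidecar. Susceptibility is handled in ppm internally and
converted to ppb only at reporting boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "GYROMAGNETIC_RATIO",
    "DEFAULT_B0",
    "AcquisitionParams",
    "ComplexEchoSeries",
    "BrainMask",
    "LabelVolume",
    "wrap_phase",
    "read_volume",
    "write_volume",
    "read_label_names",
    "write_label_names",
    "to_ppb",
    "to_ppm",
]

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GYROMAGNETIC_RATIO = 2.6752e8

#: Default main field strength (tesla).
DEFAULT_B0 = 11.7


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase values into the interval ``(-pi, pi]``."""
    wrapped = np.mod(np.asarray(phi, dtype=float), 2.0 * np.pi)
    wrapped = np.where(wrapped > np.pi, wrapped - 2.0 * np.pi, wrapped)
    return wrapped


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition constants consumed by every processing stage.

    Parameters
    ----------
    B0
        Main magnetic field strength in tesla.
    gamma
        Gyromagnetic ratio in rad s^-1 T^-1.
    echo_times
        Strictly increasing echo times in seconds.
    voxel_size
        Voxel edge lengths in millimetres.
    b0_dir
        Unit vector of the main field direction in the image frame.
    """

    B0: float = DEFAULT_B0
    gamma: float = GYROMAGNETIC_RATIO
    echo_times: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    voxel_size: tuple[float, float, float] = (0.07, 0.07, 0.07)
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.echo_times is None:
            object.__setattr__(self, "echo_times", _default_echo_times())
        object.__setattr__(self, "echo_times", tuple(float(t) for t in self.echo_times))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        tes = np.asarray(self.echo_times)
        if tes.size == 0 or np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo_times must be strictly increasing and positive")
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        b = np.asarray(self.b0_dir, dtype=float)
        norm = float(np.linalg.norm(b))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("b0_dir must be a nonzero vector")
            b = b / norm
        object.__setattr__(self, "b0_dir", tuple(float(x) for x in b))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def echo_times_array(self) -> np.ndarray:
        return np.asarray(self.echo_times, dtype=float)

    @classmethod
    def default(
        cls,
        n_echoes: int = 8,
        te1: float = 4.0e-3,
        delta_te: float = 3.8e-3,
        **kwargs,
    ) -> "AcquisitionParams":
        """Multi-echo protocol: 8 echoes, TE1 = 4 ms, spacing 3.8 ms, 11.7 T."""
        tes = tuple(te1 + i * delta_te for i in range(n_echoes))
        return cls(echo_times=tes, **kwargs)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "B0_T": self.B0,
            "gamma_rad_per_s_per_T": self.gamma,
            "echo_times_s": list(self.echo_times),
            "b0_dir": list(self.b0_dir),
            "voxel_size_mm": list(self.voxel_size),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            B0=payload["B0_T"],
            gamma=payload["gamma_rad_per_s_per_T"],
            echo_times=tuple(payload["echo_times_s"]),
            b0_dir=tuple(payload.get("b0_dir", (0.0, 0.0, 1.0))),
            voxel_size=tuple(payload.get("voxel_size_mm", (0.07, 0.07, 0.07))),
        )


def _default_echo_times() -> tuple[float, ...]:
    return tuple(4.0e-3 + i * 3.8e-3 for i in range(8))


@dataclass
class ComplexEchoSeries:
    """Multi-echo complex image held as magnitude + wrapped phase.

    The echo axis is always last; phase is normalized to ``(-pi, pi]``
    on construction.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    params: AcquisitionParams

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must share a shape")
        if self.magnitude.ndim != 4:
            raise ValueError("expected a 4D (x, y, z, echo) array")
        if self.magnitude.shape[-1] != self.params.n_echoes:
            raise ValueError(
                f"echo axis has length {self.magnitude.shape[-1]}, "
                f"params declare {self.params.n_echoes} echoes"
            )
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")
        self.phase = wrap_phase(self.phase)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.magnitude.shape

    def complex(self) -> np.ndarray:
        """Complex-valued signal ``M * exp(i*phase)``."""
        return self.magnitude * np.exp(1j * self.phase)

    @classmethod
    def from_complex(cls, signal: np.ndarray, params: AcquisitionParams) -> "ComplexEchoSeries":
        signal = np.asarray(signal)
        return cls(magnitude=np.abs(signal), phase=np.angle(signal), params=params)


@dataclass
class BrainMask:
    """Boolean foreground mask on the same grid as the image volumes."""

    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (0.07, 0.07, 0.07)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabelVolume:
    """Integer ROI labels (0 = background) plus a label -> name table."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"labels missing from name table: {sorted(missing)}")

    def present_labels(self) -> list[int]:
        return sorted(set(int(v) for v in np.unique(self.labels)) - {0})


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a 3D/4D NIfTI-1 volume.

    Returns
    -------
    data, voxel_size
        The array (echo axis last for 4D) and voxel edge lengths in mm.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the payload is not NIfTI-1 or contains non-finite voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several exception types
        raise ValueError(f"not a readable NIfTI-1 file: {path}") from exc
    data = np.asarray(img.dataobj)
    n_bad = int(np.size(data) - np.isfinite(data).sum())
    if n_bad:
        plural = "voxel" if n_bad == 1 else "voxels"
        raise ValueError(f"{path}: {n_bad} non-finite {plural}")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms)


def write_volume(
    array: np.ndarray,
    voxel_size: Sequence[float],
    path: str | Path,
    description: str = "",
) -> Path:
    """Write an array as NIfTI-1, recording voxel size and an optional unit tag."""
    array = np.asarray(array)
    if not np.all(np.isfinite(array)):
        raise ValueError("refusing to write non-finite data")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(array, affine)
    zooms = list(voxel_size) + [1.0] * (array.ndim - 3)
    img.header.set_zooms(tuple(zooms[: array.ndim]))
    if description:
        img.header["descrip"] = description.encode()[:79]
    path = Path(path)
    nib.save(img, str(path))
    return path


def write_label_names(names: Mapping[int, str], path: str | Path) -> Path:
    df = pd.DataFrame(sorted(names.items()), columns=["label", "name"])
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_label_names(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return {int(row.label): str(row.name) for row in df.itertuples(index=False)}


def to_ppb(chi_ppm: np.ndarray | float) -> np.ndarray | float:
    """Convert susceptibility from ppm to ppb (reporting unit)."""
    return np.asarray(chi_ppm, dtype=float) * 1000.0 if np.ndim(chi_ppm) else float(chi_ppm) * 1000.0


def to_ppm(chi_ppb: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`to_ppb`."""
    return np.asarray(chi_ppb, dtype=float) / 1000.0 if np.ndim(chi_ppb) else float(chi_ppb) / 1000.0
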