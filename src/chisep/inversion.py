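"""Dipole inversion: local field maps -> susceptibility maps.

The forward relation in k-space is ``field_ppm = D(k) * chi_ppm`` with the
unit dipole kernel ``D(k) = 1/3 - (k . b0)^2 / |k|^2``. Inversion uses
thresholded k-space division (TKD): the kernel is clamped at ``delta``
where it is near its zero cone. Maps are referenced to the in-mask mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.fft import fftn, ifftn, fftfreq

from .acquisition import AcquisitionParams

__all__ = [
    "DipoleKernel",
    "dipole_kernel",
    "forward_dipole",
    "invert_dipole",
    "reference_to_mask_mean",
    "per_echo_qsm",
    "combined_qsm",
]


@dataclass
class DipoleKernel:
    values: np.ndarray
    b0_dir: tuple[float, float, float]
    voxel_size: tuple[float, float, float]


def dipole_kernel(
    shape: Sequence[int],
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    b0_dir: Sequence[float] = (0.0, 0.0, 1.0),
) -> DipoleKernel:
    """Unit dipole kernel on the FFT grid; ``D(0) = 0`` by convention."""
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel_size must be positive")
    b = np.asarray(b0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    ks = [fftfreq(n, d=dv) for n, dv in zip(shape, voxel_size)]
    kx = ks[0][:, None, None]
    ky = ks[1][None, :, None]
    kz = ks[2][None, None, :]
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - np.where(k2 > 0, kb**2 / np.where(k2 > 0, k2, 1.0), 0.0)
    d[0, 0, 0] = 0.0
    return DipoleKernel(values=d, b0_dir=tuple(b), voxel_size=tuple(float(v) for v in voxel_size))


def forward_dipole(chi_ppm: np.ndarray, kernel: DipoleKernel) -> np.ndarray:
    """Field perturbation (ppm) induced by a susceptibility map (ppm)."""
    return np.real(ifftn(kernel.values * fftn(chi_ppm)))


def reference_to_mask_mean(chi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the in-mask mean; zero outside the mask."""
    mask = np.asarray(mask, dtype=bool)
    out = np.where(mask, chi - chi[mask].mean(), 0.0)
    return out


def invert_dipole(
    field_ppm: np.ndarray,
    kernel: DipoleKernel,
    delta: float = 0.2,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Thresholded k-space division.

    ``chi(k) = F(k)/D(k)`` where ``|D| >= delta`` and ``F(k)*sign(D)/delta``
    elsewhere. The result is referenced to the in-mask mean when a mask is
    given.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("delta must lie in (0, 1)")
    d = kernel.values
    fk = fftn(np.asarray(field_ppm, dtype=float))
    sign = np.where(d >= 0, 1.0, -1.0)
    d_safe = np.where(np.abs(d) >= delta, d, sign * delta)
    chi = np.real(ifftn(fk / d_safe))
    if mask is not None:
        chi = reference_to_mask_mean(chi, mask)
    return chi


def per_echo_qsm(
    local_field: np.ndarray,
    params: AcquisitionParams,
    mask: np.ndarray,
    delta: float = 0.2,
) -> np.ndarray:
    """Per-echo susceptibility series (ppm) from a local-field series.

    ``local_field`` holds radians at each TE (echo axis last); each echo is
    scaled by ``1 / (gamma * B0 * TE_i * 1e-6)`` to ppm before inversion and
    each map is referenced to the in-mask mean.
    """
    local_field = np.asarray(local_field, dtype=float)
    if local_field.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, echo) local field")
    tes = params.echo_times_array
    if np.any(tes == 0):
        raise ValueError("echo times must be nonzero")
    kernel = dipole_kernel(local_field.shape[:3], params.voxel_size, params.b0_dir)
    out = np.empty_like(local_field)
    for i, te in enumerate(tes):
        field_ppm = local_field[..., i] / (params.gamma * params.B0 * te * 1e-6)
        out[..., i] = invert_dipole(field_ppm, kernel, delta=delta, mask=mask)
    return out


def combined_qsm(
    normalized_field_ppm: np.ndarray,
    params: AcquisitionParams,
    mask: np.ndarray,
    delta: float = 0.2,
) -> np.ndarray:
    """Susceptibility map (ppm) from the echo-combined normalized field."""
    kernel = dipole_kernel(normalized_field_ppm.shape, params.voxel_size, params.b0_dir)
    return invert_dipole(normalized_field_ppm, kernel, delta=delta, mask=mask)
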