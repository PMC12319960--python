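"""Labelled digital phantoms with known three-pool ground truth.

Two forward modes generate multi-echo complex data from a phantom:

``voxelwise``
    Evaluates the three-pool signal model independently per voxel — phase
    comes directly from each pool's frequency shift. This validates the
    fitter in isolation.
``field``
    Computes the nonlocal dipole field of the bulk susceptibility map, adds
    a smooth harmonic background field, and accrues phase linearly with TE.
    This exercises the unwrap -> background removal -> inversion chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import (
    AcquisitionParams,
    BrainMask,
    ComplexEchoSeries,
    LabelVolume,
    wrap_phase,
)
from .inversion import dipole_kernel, forward_dipole
from .separation import decay_kernel, model_signal

__all__ = [
    "PoolParams",
    "PhantomTruth",
    "make_phantom",
    "forward_signal",
    "forward_field",
    "add_noise",
    "simulate_cohort_table",
    "LAYOUTS",
]

LAYOUTS = ("shells", "layered_slab", "two_group")

#: Harmonic polynomial basis used for the smooth background field. Every
#: element has zero Laplacian, so SMV filtering can remove it exactly.
_BACKGROUND_BASIS = (
    lambda x, y, z: x,
    lambda x, y, z: y,
    lambda x, y, z: z,
    lambda x, y, z: x * y,
    lambda x, y, z: x * z,
    lambda x, y, z: y * z,
    lambda x, y, z: x**2 - y**2,
    lambda x, y, z: 2 * z**2 - x**2 - y**2,
)


@dataclass(frozen=True)
class PoolParams:
    """Region-wise three-pool ground truth."""

    alpha0: float
    alpha_plus: float
    alpha_minus: float
    chi_plus: float  # ppm, >= 0
    chi_minus: float  # ppm, <= 0
    r2star0: float  # s^-1

    def __post_init__(self) -> None:
        if self.chi_plus < 0 or self.chi_minus > 0:
            raise ValueError("chi_plus must be >= 0 and chi_minus <= 0")
        if max(abs(self.chi_plus), abs(self.chi_minus)) >= 0.1:
            raise ValueError("|chi| must stay below 0.1 ppm")
        if min(self.alpha0, self.alpha_plus, self.alpha_minus) < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.alpha0 + self.alpha_plus + self.alpha_minus <= 0:
            raise ValueError("total amplitude must be positive")
        if self.r2star0 <= 0:
            raise ValueError("r2star0 must be positive")

    @property
    def total(self) -> float:
        return self.alpha0 + self.alpha_plus + self.alpha_minus

    @property
    def chi_bulk(self) -> float:
        """Fraction-weighted bulk susceptibility C+*chi+ + C-*chi- (ppm)."""
        return (self.alpha_plus * self.chi_plus + self.alpha_minus * self.chi_minus) / self.total


@dataclass
class PhantomTruth:
    """Label volume plus region-wise parameters and simulation settings."""

    labels: LabelVolume
    mask: np.ndarray
    region_params: dict[int, PoolParams]
    background_coeffs: np.ndarray
    snr: float
    seed: int
    layout: str
    voxel_size: tuple[float, float, float] = (0.07, 0.07, 0.07)
    group: str = "A"

    _FIELDS = ("alpha0", "alpha_plus", "alpha_minus", "chi_plus", "chi_minus", "r2star0")

    def parameter_maps(self) -> dict[str, np.ndarray]:
        """Rasterize region parameters into voxelwise maps."""
        maps = {name: np.zeros(self.labels.labels.shape) for name in self._FIELDS}
        for label, pp in self.region_params.items():
            sel = self.labels.labels == label
            for name in self._FIELDS:
                maps[name][sel] = getattr(pp, name)
        return maps

    def chi_bulk_map(self) -> np.ndarray:
        """Ground-truth bulk susceptibility map (ppm)."""
        out = np.zeros(self.labels.labels.shape)
        for label, pp in self.region_params.items():
            out[self.labels.labels == label] = pp.chi_bulk
        return out

    def pcs_map(self) -> np.ndarray:
        """Ground-truth composite paramagnetic map C+*chi+ (ppm)."""
        out = np.zeros(self.labels.labels.shape)
        for label, pp in self.region_params.items():
            out[self.labels.labels == label] = pp.alpha_plus * pp.chi_plus / pp.total
        return out

    def dcs_map(self) -> np.ndarray:
        """Ground-truth composite diamagnetic map C-*chi- (ppm)."""
        out = np.zeros(self.labels.labels.shape)
        for label, pp in self.region_params.items():
            out[self.labels.labels == label] = pp.alpha_minus * pp.chi_minus / pp.total
        return out

    def background_field(self, params: AcquisitionParams, target_wrap: float = 3 * np.pi) -> np.ndarray:
        """Smooth harmonic background frequency field (rad/s).

        Scaled so the peak in-mask background phase at the final echo is
        ``target_wrap`` radians, forcing both unwrapping and background
        removal to do real work.
        """
        shape = self.mask.shape
        coords = [np.linspace(-1.0, 1.0, n) for n in shape]
        x = coords[0][:, None, None]
        y = coords[1][None, :, None]
        z = coords[2][None, None, :]
        raw = np.zeros(shape)
        for c, basis in zip(self.background_coeffs, _BACKGROUND_BASIS):
            raw = raw + c * basis(x, y, z)
        peak = np.abs(raw[self.mask]).max()
        if peak == 0:
            return raw
        te_last = params.echo_times[-1]
        return raw * (target_wrap / (peak * te_last))

    def brain_mask(self) -> BrainMask:
        return BrainMask(mask=self.mask, voxel_size=self.voxel_size)


_BASE_REGIONS = {
    "neutral": PoolParams(1.0, 0.0, 0.0, 0.0, 0.0, 40.0),
    "para": PoolParams(0.6, 0.4, 0.0, 0.03, 0.0, 50.0),
    "dia": PoolParams(0.6, 0.0, 0.4, 0.0, -0.03, 50.0),
    "mixed": PoolParams(0.4, 0.3, 0.3, 0.02, -0.02, 60.0),
    "lesion": PoolParams(0.5, 0.3, 0.2, 0.02, -0.01, 55.0),
}


def _jitter(pp: PoolParams, rng: np.random.Generator, cv: float) -> PoolParams:
    """Multiplicative inter-subject variability on the region parameters."""

    def scale(v, lo=None, hi=None):
        if v == 0:
            return 0.0
        out = v * (1.0 + cv * rng.standard_normal())
        if lo is not None:
            out = max(out, lo)
        if hi is not None:
            out = min(out, hi)
        return out

    return PoolParams(
        alpha0=scale(pp.alpha0, lo=0.01),
        alpha_plus=scale(pp.alpha_plus, lo=0.0),
        alpha_minus=scale(pp.alpha_minus, lo=0.0),
        chi_plus=scale(pp.chi_plus, lo=0.0, hi=0.099),
        chi_minus=scale(pp.chi_minus, lo=-0.099, hi=0.0),
        r2star0=scale(pp.r2star0, lo=1.0),
    )


def _shell_geometry(grid_shape):
    coords = [np.arange(n) - (n - 1) / 2.0 for n in grid_shape]
    r = np.sqrt(
        (coords[0][:, None, None] / (grid_shape[0] / 2.0)) ** 2
        + (coords[1][None, :, None] / (grid_shape[1] / 2.0)) ** 2
        + (coords[2][None, None, :] / (grid_shape[2] / 2.0)) ** 2
    )
    mask = r <= 0.85
    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[(r <= 0.85)] = 1  # neutral rim
    labels[(r < 0.68)] = 2  # paramagnetic shell
    labels[(r < 0.47)] = 3  # diamagnetic shell
    labels[(r < 0.26)] = 4  # mixed core
    return mask, labels


def make_phantom(
    grid_shape: tuple[int, int, int] | int,
    layout: str = "shells",
    seed: int = 0,
    snr: float = 40.0,
    group: str = "A",
    effect_size: float = 6.0,
    jitter_cv: float = 0.08,
    voxel_size: tuple[float, float, float] = (0.07, 0.07, 0.07),
) -> PhantomTruth:
    """Build a labelled phantom with region-wise three-pool ground truth.

    Layouts
    -------
    ``shells``
        Concentric ellipsoidal shells: neutral rim, paramagnetic-dominant
        shell, diamagnetic-dominant shell, mixed core (hippocampus-like
        laminar contrast).
    ``layered_slab``
        The same four region types stacked as axial laminae inside an
        ellipsoid.
    ``two_group``
        The shells geometry plus an off-centre "lesion" blob whose
        parameters are drawn per subject; ``group="B"`` shifts the lesion
        chi_plus by ``effect_size`` between-subject standard deviations.
        All regions receive inter-subject jitter (``jitter_cv``).
    """
    if isinstance(grid_shape, int):
        grid_shape = (grid_shape,) * 3
    if any(n < 16 for n in grid_shape):
        raise ValueError("each grid dimension must be >= 16")
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    rng = np.random.default_rng(seed)

    if layout in ("shells", "two_group"):
        mask, labels = _shell_geometry(grid_shape)
        names = {1: "neutral_rim", 2: "para_shell", 3: "dia_shell", 4: "mixed_core"}
        region_params = {
            1: _BASE_REGIONS["neutral"],
            2: _BASE_REGIONS["para"],
            3: _BASE_REGIONS["dia"],
            4: _BASE_REGIONS["mixed"],
        }
    else:  # layered_slab
        coords = [np.arange(n) - (n - 1) / 2.0 for n in grid_shape]
        rr = np.sqrt(
            (coords[0][:, None, None] / (grid_shape[0] / 2.0)) ** 2
            + (coords[1][None, :, None] / (grid_shape[1] / 2.0)) ** 2
            + (coords[2][None, None, :] / (grid_shape[2] / 2.0)) ** 2
        )
        mask = rr <= 0.85
        labels = np.zeros(grid_shape, dtype=np.int32)
        thickness = max(2, grid_shape[2] // 12)
        layer = (np.arange(grid_shape[2]) // thickness) % 4 + 1
        labels[mask] = layer[None, None, :].repeat(grid_shape[0], 0).repeat(grid_shape[1], 1)[mask]
        names = {1: "neutral_layers", 2: "para_layers", 3: "dia_layers", 4: "mixed_layers"}
        region_params = {
            1: _BASE_REGIONS["neutral"],
            2: _BASE_REGIONS["para"],
            3: _BASE_REGIONS["dia"],
            4: _BASE_REGIONS["mixed"],
        }

    if layout == "two_group":
        if group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        # off-centre lesion blob
        centre = np.array(grid_shape) * np.array([0.62, 0.5, 0.5])
        coords = np.indices(grid_shape).astype(float)
        d = np.sqrt(sum((coords[i] - centre[i]) ** 2 for i in range(3)))
        lesion = (d <= min(grid_shape) * 0.1) & mask
        labels = labels.copy()
        labels[lesion] = 5
        names[5] = "lesion"
        region_params = {lab: _jitter(pp, rng, jitter_cv) for lab, pp in region_params.items()}
        base = _BASE_REGIONS["lesion"]
        lesion_pp = _jitter(base, rng, jitter_cv)
        if group == "B":
            shift = effect_size * jitter_cv * base.chi_plus
            lesion_pp = PoolParams(
                alpha0=lesion_pp.alpha0,
                alpha_plus=lesion_pp.alpha_plus,
                alpha_minus=lesion_pp.alpha_minus,
                chi_plus=min(lesion_pp.chi_plus + shift, 0.099),
                chi_minus=lesion_pp.chi_minus,
                r2star0=lesion_pp.r2star0,
            )
        region_params[5] = lesion_pp

    background_coeffs = rng.standard_normal(len(_BACKGROUND_BASIS))
    return PhantomTruth(
        labels=LabelVolume(labels=labels, names=names),
        mask=mask,
        region_params=region_params,
        background_coeffs=background_coeffs,
        snr=snr,
        seed=seed,
        layout=layout,
        voxel_size=voxel_size,
        group=group,
    )


def forward_signal(
    truth: PhantomTruth,
    params: AcquisitionParams | None = None,
    a: float | None = None,
) -> ComplexEchoSeries:
    """Noiseless voxelwise three-pool signal (no nonlocal field)."""
    params = params or AcquisitionParams.default(voxel_size=truth.voxel_size)
    if a is None:
        a = decay_kernel(params.B0, params.gamma)
    if a <= 0:
        raise ValueError("decay kernel must be positive")
    t = params.echo_times_array
    shape = truth.mask.shape
    signal = np.zeros(shape + (params.n_echoes,), dtype=complex)
    for label, pp in truth.region_params.items():
        sel = truth.labels.labels == label
        s = model_signal(
            pp.alpha0, pp.alpha_plus, pp.alpha_minus, pp.r2star0, pp.chi_plus, pp.chi_minus,
            t, a, params,
        )
        signal[sel] = s
    return ComplexEchoSeries.from_complex(signal, params)


def forward_field(
    truth: PhantomTruth,
    params: AcquisitionParams | None = None,
    a: float | None = None,
    add_background: bool = True,
) -> ComplexEchoSeries:
    """Noiseless field-mode data: dipole field + background, three-pool decay.

    The bulk susceptibility map is convolved with the unit dipole kernel to
    obtain the local frequency; per-echo phase accrues linearly with TE.
    Magnitude decays with the three-pool magnitude terms.
    """
    params = params or AcquisitionParams.default(voxel_size=truth.voxel_size)
    if a is None:
        a = decay_kernel(params.B0, params.gamma)
    t = params.echo_times_array
    shape = truth.mask.shape

    kernel = dipole_kernel(shape, params.voxel_size, params.b0_dir)
    field_ppm = forward_dipole(truth.chi_bulk_map(), kernel)
    omega = field_ppm * 1e-6 * params.gamma * params.B0  # rad/s
    if add_background:
        omega = omega + truth.background_field(params)

    magnitude = np.zeros(shape + (params.n_echoes,))
    for label, pp in truth.region_params.items():
        sel = truth.labels.labels == label
        mag = (
            pp.alpha0 * np.exp(-pp.r2star0 * t)
            + pp.alpha_plus * np.exp(-(pp.r2star0 + a * pp.chi_plus) * t)
            + pp.alpha_minus * np.exp(-(pp.r2star0 - a * pp.chi_minus) * t)
        )
        magnitude[sel] = mag
    phase = wrap_phase(omega[..., None] * t)
    phase = np.where(truth.mask[..., None], phase, 0.0)
    magnitude = np.where(truth.mask[..., None], magnitude, 0.0)
    return ComplexEchoSeries(magnitude=magnitude, phase=phase, params=params)


def simulate_cohort_table(
    n_per_group: int = 5,
    grid_shape: int | tuple[int, int, int] = 24,
    base_seed: int = 0,
    metrics: tuple[str, ...] = ("PCS",),
    effect_size: float = 8.0,
    jitter_cv: float = 0.08,
):
    """Two-group phantom cohort summarized as a long-format ROI table.

    Each subject gets its own ``two_group`` phantom (independent seed);
    group B subjects carry the lesion effect. ROI means of the ground-truth
    composite maps (ppb) are tabulated per subject for the requested
    metrics, matching the input contract of the group-statistics module.
    ``effect_size=0`` yields a null cohort.
    """
    import pandas as pd

    from .acquisition import to_ppb
    from .stats import roi_means

    rows = []
    for gi, group in enumerate(("A", "B")):
        for s in range(n_per_group):
            seed = base_seed * 10_000 + gi * 1_000 + s
            truth = make_phantom(
                grid_shape, "two_group", seed=seed, group=group,
                effect_size=effect_size, jitter_cv=jitter_cv,
            )
            maps = {
                "PCS": to_ppb(truth.pcs_map()),
                "DCS": to_ppb(truth.dcs_map()),
                "QSM": to_ppb(truth.chi_bulk_map()),
            }
            for metric in metrics:
                summary = roi_means(maps[metric], truth.labels)
                for rec in summary.itertuples(index=False):
                    rows.append(
                        {
                            "subject": f"{group}{s}",
                            "group": group,
                            "roi": rec.roi,
                            "metric": metric,
                            "value": rec.mean,
                        }
                    )
    return pd.DataFrame(rows)


def add_noise(
    series: ComplexEchoSeries,
    snr: float | None,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> ComplexEchoSeries:
    """Add i.i.d. complex Gaussian noise at the requested first-echo SNR.

    Noise s.d. is (mean in-mask first-echo magnitude) / snr on both the
    real and imaginary channels. ``snr=None`` returns the input unchanged.
    """
    if snr is None:
        return series
    if snr <= 0:
        raise ValueError("snr must be positive")
    if mask is None:
        mask = series.magnitude[..., 0] > 0
    sigma = series.magnitude[..., 0][mask].mean() / snr
    rng = np.random.default_rng(seed)
    noise = rng.normal(scale=sigma, size=series.magnitude.shape) + 1j * rng.normal(
        scale=sigma, size=series.magnitude.shape
    )
    return ComplexEchoSeries.from_complex(series.complex() + noise, series.params)
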