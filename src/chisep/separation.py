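"""Three-pool paramagnetic/diamagnetic/neutral signal model and its fitter.

A voxel's multi-echo complex signal is modelled as the sum of three
exponentially decaying pools: a neutral reference pool, a paramagnetic pool
(chi_plus >= 0) and a diamagnetic pool (chi_minus <= 0). Under the static
dephasing regime the magnitude decay rate of each susceptibility pool is
offset from the reference rate by ``a * |chi|``, with ``a`` the spherical
source decay kernel; the phase of each pool evolves with the Lorentz-sphere
corrected frequency shift ``(2/3) * chi * gamma * B0``.

The fitter alternates three bounded sub-problems (non-negative linear solve
for the pool amplitudes, bounded solve for the reference rate, bounded solve
for the pool susceptibilities) for a fixed number of outer iterations,
tracking the complex-residual L2 objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.optimize import least_squares, nnls

from .acquisition import AcquisitionParams, to_ppb

__all__ = [
    "decay_kernel",
    "synthesize_signal",
    "model_signal",
    "FitOptions",
    "ThreePoolFit",
    "fit_three_pool",
    "fit_volume",
    "signal_fractions",
    "composite_maps",
]

#: Conversion between ppm susceptibility and dimensionless susceptibility.
PPM = 1e-6

#: Lorentz sphere factor relating local susceptibility to frequency shift.
LORENTZ = 2.0 / 3.0


def decay_kernel(B0: float, gamma: float) -> float:
    """Static-dephasing magnitude decay kernel for spherical sources.

    ``a = 2*pi*gamma*B0 / (9*sqrt(3))`` scaled per ppm of susceptibility,
    returned in s^-1/ppm (divide by 1e3 for kHz/ppm).
    """
    if B0 <= 0 or gamma <= 0:
        raise ValueError("B0 and gamma must be positive")
    return 2.0 * np.pi * gamma * B0 / (9.0 * np.sqrt(3.0)) * PPM


def phase_rate(chi_ppm: np.ndarray | float, params: AcquisitionParams) -> np.ndarray | float:
    """Angular frequency (rad/s) of a pool with susceptibility ``chi_ppm``."""
    return LORENTZ * np.asarray(chi_ppm, dtype=float) * PPM * params.gamma * params.B0


def synthesize_signal(
    magnitude: np.ndarray,
    chi_series_ppm: np.ndarray,
    params: AcquisitionParams,
) -> np.ndarray:
    """Combine magnitude and per-echo susceptibility into a complex signal.

    ``y(t) = M(t) * exp(i * (2/3) * chi(t) * gamma * B0 * t)`` with chi in ppm.
    Arrays broadcast; the echo axis is last.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    chi = np.asarray(chi_series_ppm, dtype=float)
    if magnitude.shape[-1] != params.n_echoes or chi.shape[-1] != params.n_echoes:
        raise ValueError("echo axis length must match params.n_echoes")
    t = params.echo_times_array
    return magnitude * np.exp(1j * phase_rate(chi, params) * t)


def model_signal(
    alpha0: float,
    alpha_plus: float,
    alpha_minus: float,
    r2star0: float,
    chi_plus: float,
    chi_minus: float,
    t: np.ndarray,
    a: float,
    params: AcquisitionParams,
) -> np.ndarray:
    """Three-pool complex signal at echo times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    w_p = phase_rate(chi_plus, params)
    w_m = phase_rate(chi_minus, params)
    s0 = alpha0 * np.exp(-r2star0 * t)
    sp = alpha_plus * np.exp(-(r2star0 + a * chi_plus) * t) * np.exp(1j * w_p * t)
    sm = alpha_minus * np.exp(-(r2star0 - a * chi_minus) * t) * np.exp(1j * w_m * t)
    return s0 + sp + sm


def _basis(r2star0, chi_plus, chi_minus, t, a, params):
    """Complex design matrix (n_echoes x 3) for the linear amplitudes."""
    w_p = phase_rate(chi_plus, params)
    w_m = phase_rate(chi_minus, params)
    cols = [
        np.exp(-r2star0 * t),
        np.exp(-(r2star0 + a * chi_plus) * t + 1j * w_p * t),
        np.exp(-(r2star0 - a * chi_minus) * t + 1j * w_m * t),
    ]
    return np.stack(cols, axis=1)


@dataclass
class FitOptions:
    """Controls for the alternating minimization."""

    n_alt: int = 10
    chi_bound: float = 0.1  # ppm, open bound on |chi|
    r2_bounds: tuple[float, float] = (1.0, 500.0)
    chi_eps: float = 1e-4  # ppm, susceptibility initialization floor
    step_tol: float = 1e-10  # early stop when objective change falls below
    grid_init: bool = True  # coarse (chi+, chi-, R2*) grid search before alternating
    joint_polish: bool = True  # final bounded joint refinement of all six parameters
    step_residual: str = "complex"  # "complex" or "log" residuals in the nonlinear steps
    magnitude_floor: float = 0.05  # fraction of in-mask median TE1 magnitude

    #: chi grid nodes as fractions of ``chi_bound`` (both signs explored).
    chi_grid_fractions: tuple[float, ...] = (0.03, 0.1, 0.2, 0.35, 0.55)
    #: multiplicative offsets around the log-linear R2* estimate.
    r2_grid_factors: tuple[float, ...] = (0.5, 0.7, 1.0, 1.4, 2.0)


@dataclass
class ThreePoolFit:
    """Voxelwise fit result."""

    alpha0: float
    alpha_plus: float
    alpha_minus: float
    r2star0: float
    chi_plus: float
    chi_minus: float
    converged: bool
    n_iter: int
    objective: float
    objective_trace: list[float] = field(default_factory=list)

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = self.alpha0 + self.alpha_plus + self.alpha_minus
        if total <= 0:
            raise ValueError("non-positive total amplitude")
        return (self.alpha0 / total, self.alpha_plus / total, self.alpha_minus / total)

    @property
    def pcs(self) -> float:
        return self.fractions[1] * self.chi_plus

    @property
    def dcs(self) -> float:
        return self.fractions[2] * self.chi_minus


def _objective(theta, y, t, a, params) -> float:
    s = model_signal(*theta, t=t, a=a, params=params)
    r = s - y
    return float(np.sum(r.real**2 + r.imag**2))


def _solve_amplitudes(y, t, a, params, r2star0, chi_plus, chi_minus):
    """Step 1: non-negative least squares for (alpha0, alpha+, alpha-)."""
    basis = _basis(r2star0, chi_plus, chi_minus, t, a, params)
    design = np.vstack([basis.real, basis.imag])
    target = np.concatenate([y.real, y.imag])
    alphas, _ = nnls(design, target)
    return alphas


def _step_residual(s, y, kind):
    if kind == "complex":
        r = s - y
        return np.concatenate([r.real, r.imag])
    # log reading: match log-magnitude and wrapped phase difference
    eps = 1e-12
    mag = np.log(np.abs(s) + eps) - np.log(np.abs(y) + eps)
    ang = np.angle(s * np.conj(y))
    return np.concatenate([mag, ang])


def _solve_r2star(y, t, a, params, alphas, chi_plus, chi_minus, r2star0, options):
    """Step 2: bounded 1-D solve for the reference decay rate."""
    lo, hi = options.r2_bounds

    def residual(x):
        s = model_signal(alphas[0], alphas[1], alphas[2], x[0], chi_plus, chi_minus, t, a, params)
        return _step_residual(s, y, options.step_residual)

    res = least_squares(
        residual,
        x0=[np.clip(r2star0, lo + 1e-9, hi - 1e-9)],
        bounds=([lo], [hi]),
        method="trf",
    )
    return float(res.x[0])


def _solve_chi(y, t, a, params, alphas, r2star0, starts, bound, options):
    """Step 3: bounded solve for (chi+, chi-) within [0, bound] x [-bound, 0].

    Tries each start point and returns the candidate with the smallest
    complex-residual objective.
    """

    def residual(x):
        s = model_signal(alphas[0], alphas[1], alphas[2], r2star0, x[0], x[1], t, a, params)
        return _step_residual(s, y, options.step_residual)

    best = None
    for chi_p0, chi_m0 in starts:
        x0 = [np.clip(chi_p0, 0.0, bound - 1e-9), np.clip(chi_m0, -bound + 1e-9, 0.0)]
        res = least_squares(residual, x0=x0, bounds=([0.0, -bound], [bound, 0.0]), method="trf")
        cand = (float(res.x[0]), float(res.x[1]))
        obj = _objective((alphas[0], alphas[1], alphas[2], r2star0, *cand), y, t, a, params)
        if best is None or obj < best[0]:
            best = (obj, cand)
    return best[1]


def _initialize(y, t, a, params, options, chi_hint=None):
    """Coarse global search over (chi+, chi-, R2*0) with NNLS amplitudes.

    R2*0 comes from a log-linear magnitude fit (scanned over a few
    multiplicative offsets); the susceptibility plane is scanned on a small
    grid plus an optional hint (e.g. the voxel's per-echo QSM mean or the
    signal's phase slope).
    """
    logm = np.log(np.abs(y) + 1e-300)
    slope, _ = np.polyfit(t, logm, 1)
    r2_est = float(np.clip(-slope, options.r2_bounds[0], options.r2_bounds[1]))

    if chi_hint is None:
        phi = np.unwrap(np.angle(y))
        omega = np.polyfit(t, phi, 1)[0]
        chi_hint = omega / (LORENTZ * PPM * params.gamma * params.B0)
    eps = options.chi_eps
    hi = options.chi_bound - eps
    candidates = [(float(np.clip(max(chi_hint, eps), eps, hi)),
                   float(np.clip(min(-eps, chi_hint), -hi, -eps)))]
    if options.grid_init:
        nodes = [f * options.chi_bound for f in options.chi_grid_fractions]
        candidates += [(gp, -gm) for gp in nodes for gm in nodes]
        r2_grid = np.unique(np.clip(r2_est * np.asarray(options.r2_grid_factors), *options.r2_bounds))
    else:
        r2_grid = np.asarray([r2_est])

    best = None
    for chi_p, chi_m in candidates:
        for r2 in r2_grid:
            alphas = _solve_amplitudes(y, t, a, params, r2, chi_p, chi_m)
            obj = _objective((alphas[0], alphas[1], alphas[2], r2, chi_p, chi_m), y, t, a, params)
            if best is None or obj < best[0]:
                best = (obj, alphas, float(r2), chi_p, chi_m)
    return best[1], best[2], best[3], best[4], best[0]


def _joint_polish(y, t, a, params, alphas, r2, chi_p, chi_m, options):
    """Bounded joint refinement of all six parameters (complex residuals)."""

    def residual(x):
        s = model_signal(x[0], x[1], x[2], x[3], x[4], x[5], t, a, params)
        r = s - y
        return np.concatenate([r.real, r.imag])

    lo = [0.0, 0.0, 0.0, options.r2_bounds[0], 0.0, -options.chi_bound]
    hi = [np.inf, np.inf, np.inf, options.r2_bounds[1], options.chi_bound, 0.0]
    x0 = np.clip([alphas[0], alphas[1], alphas[2], r2, chi_p, chi_m], lo, hi)
    res = least_squares(residual, x0=x0, bounds=(lo, hi), method="trf")
    x = res.x
    return np.asarray(x[:3]), float(x[3]), float(x[4]), float(x[5])


def fit_three_pool(
    y: np.ndarray,
    params: AcquisitionParams,
    a: float | None = None,
    options: FitOptions | None = None,
    chi_hint: float | None = None,
) -> ThreePoolFit:
    """Fit the three-pool model to one voxel's complex echo series.

    Parameters
    ----------
    y
        Complex signal at each echo time.
    params
        Acquisition constants (supplies echo times, gamma, B0).
    a
        Decay kernel in s^-1/ppm; derived from ``params`` when omitted.
    options
        Alternating-minimization controls.
    chi_hint
        Optional per-voxel susceptibility estimate (ppm), e.g. the mean of
        the per-echo QSM series, used to initialize the nonlinear step.

    Notes
    -----
    Each outer iteration runs the amplitude, rate and susceptibility steps
    in sequence; a candidate update is kept only if it does not increase
    the complex-residual L2 objective, which makes the objective trace
    monotone non-increasing by construction. An optional bounded joint
    refinement (``options.joint_polish``) follows the alternations, under
    the same acceptance rule.
    """
    y = np.asarray(y, dtype=complex)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D per-voxel echo series")
    if not np.all(np.isfinite(y)):
        raise ValueError("NaN/inf in input signal")
    if np.all(y == 0):
        raise ValueError("all-zero signal")
    options = options or FitOptions()
    if params.n_echoes < 6:
        raise ValueError("need >= 6 echoes for 6 unknowns")
    t = params.echo_times_array
    if a is None:
        a = decay_kernel(params.B0, params.gamma)

    alphas, r2, chi_p, chi_m, obj = _initialize(y, t, a, params, options, chi_hint)
    trace = [obj]
    converged = False
    n_done = 0
    for it in range(options.n_alt):
        n_done += 1

        alphas_new = _solve_amplitudes(y, t, a, params, r2, chi_p, chi_m)
        cand = _objective((alphas_new[0], alphas_new[1], alphas_new[2], r2, chi_p, chi_m), y, t, a, params)
        if cand <= obj:
            alphas, obj = alphas_new, cand

        r2_new = _solve_r2star(y, t, a, params, alphas, chi_p, chi_m, r2, options)
        cand = _objective((alphas[0], alphas[1], alphas[2], r2_new, chi_p, chi_m), y, t, a, params)
        if cand <= obj:
            r2, obj = r2_new, cand

        starts = [(chi_p, chi_m)]
        if it == 0 and options.grid_init:
            nodes = [f * options.chi_bound for f in options.chi_grid_fractions]
            grid_best = min(
                ((_objective((alphas[0], alphas[1], alphas[2], r2, gp, -gm), y, t, a, params), gp, -gm)
                 for gp in nodes for gm in nodes)
            )
            starts.append((grid_best[1], grid_best[2]))
        chi_p_new, chi_m_new = _solve_chi(y, t, a, params, alphas, r2, starts, options.chi_bound, options)
        cand = _objective((alphas[0], alphas[1], alphas[2], r2, chi_p_new, chi_m_new), y, t, a, params)
        if cand <= obj:
            chi_p, chi_m, obj = chi_p_new, chi_m_new, cand

        trace.append(obj)
        if trace[-2] - trace[-1] < options.step_tol:
            converged = True
            break

    if options.joint_polish:
        alphas_new, r2_new, chi_p_new, chi_m_new = _joint_polish(
            y, t, a, params, alphas, r2, chi_p, chi_m, options
        )
        cand = _objective(
            (alphas_new[0], alphas_new[1], alphas_new[2], r2_new, chi_p_new, chi_m_new), y, t, a, params
        )
        if cand <= obj:
            alphas, r2, chi_p, chi_m, obj = alphas_new, r2_new, chi_p_new, chi_m_new, cand
        trace.append(obj)

    return ThreePoolFit(
        alpha0=float(alphas[0]),
        alpha_plus=float(alphas[1]),
        alpha_minus=float(alphas[2]),
        r2star0=float(r2),
        chi_plus=float(chi_p),
        chi_minus=float(chi_m),
        converged=converged,
        n_iter=n_done,
        objective=obj,
        objective_trace=trace,
    )


def fit_volume(
    y: np.ndarray,
    mask: np.ndarray,
    params: AcquisitionParams,
    a: float | None = None,
    options: FitOptions | None = None,
    chi_hint: np.ndarray | None = None,
    progress: bool = False,
) -> dict[str, np.ndarray]:
    """Fit every eligible in-mask voxel; returns parameter maps.

    Voxels whose first-echo magnitude falls below ``magnitude_floor`` times
    the in-mask median are excluded (returned in ``fitted_mask`` as False).
    Results are independent of voxel processing order.
    """
    y = np.asarray(y, dtype=complex)
    mask = np.asarray(mask, dtype=bool)
    options = options or FitOptions()
    shape = y.shape[:-1]
    te1_mag = np.abs(y[..., 0])
    floor = options.magnitude_floor * np.median(te1_mag[mask])
    eligible = mask & (te1_mag >= floor)

    maps = {
        name: np.zeros(shape)
        for name in ("alpha0", "alpha_plus", "alpha_minus", "r2star0", "chi_plus", "chi_minus")
    }
    maps["fitted_mask"] = eligible
    maps["n_iter"] = np.zeros(shape, dtype=int)

    idx = np.argwhere(eligible)
    iterator = idx
    if progress:
        from tqdm import tqdm

        iterator = tqdm(idx, desc="three-pool fit")
    for ijk in iterator:
        i, j, k = (int(v) for v in ijk)
        hint = None if chi_hint is None else float(chi_hint[i, j, k])
        fit = fit_three_pool(y[i, j, k], params, a=a, options=options, chi_hint=hint)
        maps["alpha0"][i, j, k] = fit.alpha0
        maps["alpha_plus"][i, j, k] = fit.alpha_plus
        maps["alpha_minus"][i, j, k] = fit.alpha_minus
        maps["r2star0"][i, j, k] = fit.r2star0
        maps["chi_plus"][i, j, k] = fit.chi_plus
        maps["chi_minus"][i, j, k] = fit.chi_minus
        maps["n_iter"][i, j, k] = fit.n_iter
    return maps


def signal_fractions(
    alpha0: np.ndarray,
    alpha_plus: np.ndarray,
    alpha_minus: np.ndarray,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Normalize pool amplitudes to fractions summing to one.

    Voxels with zero total amplitude are flagged (``valid`` False) and get
    zero fractions.
    """
    total = np.asarray(alpha0, dtype=float) + alpha_plus + alpha_minus
    valid = total > 0
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    safe = np.where(valid, total, 1.0)
    out = {
        "C0": np.where(valid, alpha0 / safe, 0.0),
        "C_plus": np.where(valid, alpha_plus / safe, 0.0),
        "C_minus": np.where(valid, alpha_minus / safe, 0.0),
        "valid": valid,
    }
    return out


def composite_maps(
    fractions: dict[str, np.ndarray],
    chi_plus: np.ndarray,
    chi_minus: np.ndarray,
    ppb: bool = False,
) -> dict[str, np.ndarray]:
    """Fraction-weighted composite susceptibility maps.

    PCS = C+ * chi+ (>= 0) and DCS = C- * chi- (<= 0), in ppm by default or
    ppb when ``ppb=True``.
    """
    pcs = fractions["C_plus"] * np.asarray(chi_plus, dtype=float)
    dcs = fractions["C_minus"] * np.asarray(chi_minus, dtype=float)
    if ppb:
        pcs, dcs = to_ppb(pcs), to_ppb(dcs)
    return {"PCS": pcs, "DCS": dcs}
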