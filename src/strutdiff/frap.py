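"""FRAP recovery-curve analysis.

Fluorescence recovery after photobleaching (FRAP) bleaches a disk of
radius ``omega`` in a fluorophore-loaded sample and times the diffusive
refill.  For a uniform-disk bleach in a thin film the diffusion
coefficient follows from the recovery half-time as

    D = 0.224 * omega**2 / t_half

(the 0.224 is the half-time coefficient of the uniform-disk recovery
law; see :func:`strutdiff.frap_synth.soumpasis_recovery` for the closed
form it derives from).  A measured diffusivity ratio of a macromolecular
probe is then rescaled to another solute (here: oxygen) with an
obstruction model for diffusion through a random fiber network,

    D / D0 = exp(-phi_v * r_s / r_f)

where ``phi_v`` is the fiber volume fraction, ``r_f`` the fiber radius
and ``r_s`` the solute radius.  One FRAP measurement identifies only the
lump ``kappa = phi_v / r_f``; that lump is what this module exposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DomainError,
    InsufficientRecoveryError,
    InvalidBleachError,
    MalformedInputError,
    UnphysicalRatioError,
)
from .units import um_to_cm

#: Half-time coefficient of the uniform-disk bleach recovery law:
#: the root of f(t) = 1/2 satisfies D * t_half / omega**2 = 0.224.
HALF_TIME_COEF = 0.224


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryCurve:
    """A normalized fractional-fluorescence recovery trace.

    Parameters
    ----------
    times : array of float
        Seconds since the end of the bleach pulse; strictly increasing,
        first sample at or just after the bleach.
    f : array of float
        Fractional fluorescence per time point (0 = fully bleached,
        1 = full recovery).  Values outside [0, 1] are tolerated up to
        [-0.1, 1.2] to accommodate measurement noise.
    omega : float
        Bleach-spot radius in micrometers.
    meta : dict
        Free-form provenance (sample id, normalization intensities, ...).
    """

    times: np.ndarray
    f: np.ndarray
    omega: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "f", f)
        if times.ndim != 1 or f.ndim != 1 or len(times) != len(f):
            raise MalformedInputError("times and f must be 1-D and equal length")
        if len(times) < 3:
            raise MalformedInputError("a recovery curve needs at least 3 samples")
        if not np.all(np.diff(times) > 0):
            raise MalformedInputError("times must be strictly increasing")
        if not (self.omega > 0):
            raise DomainError("bleach-spot radius omega must be positive")
        if f.min() < -0.1 or f.max() > 1.2:
            raise MalformedInputError(
                f"fractional fluorescence out of the tolerated band [-0.1, 1.2]: "
                f"range [{f.min():.3g}, {f.max():.3g}]"
            )

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FrapResult:
    """Outcome of analyzing one recovery curve."""

    t_half: float  # seconds
    D: float  # cm^2/s
    omega: float  # micrometers
    method: str  # {"interpolation", "soumpasis_fit"}
    fit_residual: float = 0.0  # RMS residual of the model fit (0 for interpolation)


@dataclass(frozen=True)
class ObstructionParams:
    """The identifiable lump of the fiber-obstruction model.

    ``kappa = phi_v / r_f`` (1/nm) is a property of the sample; the fiber
    volume fraction and fiber radius are not separately identifiable from
    a single diffusivity ratio.
    """

    kappa: float  # 1/nm
    r_ref: float  # nm, reference-probe radius
    D_ratio_ref: float  # dimensionless measured D/D0 of the reference probe

    def __post_init__(self):
        if not (self.r_ref > 0):
            raise DomainError("reference probe radius must be positive")
        if not (0 < self.D_ratio_ref <= 1):
            raise DomainError("reference D/D0 must lie in (0, 1]")
        if self.kappa < 0:
            raise DomainError("kappa must be non-negative")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def normalize_recovery(
    times: Sequence[float],
    intensities: Sequence[float],
    f_pre: float,
    f_0: Optional[float] = None,
    omega: float = 50.0,
    meta: Optional[dict] = None,
) -> RecoveryCurve:
    """Normalize a raw intensity trace to fractional fluorescence.

    f(t) = (F(t) - F_0) / (F_pre - F_0), with times shifted so the end of
    the bleach (the first post-bleach sample) is t = 0.  ``F_pre`` is the
    mean pre-bleach intensity; ``F_0`` defaults to the first post-bleach
    sample of the trace.

    Under this convention f starts at 0 and approaches 1 at full
    recovery, and the output is invariant to rescaling all raw
    intensities by a positive constant.
    """
    times = np.asarray(times, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.size == 0 or times.shape != intensities.shape:
        raise MalformedInputError("trace must be non-empty with matching shapes")
    if not np.all(np.diff(times) > 0):
        raise MalformedInputError("times must be strictly increasing")
    if f_0 is None:
        f_0 = float(intensities[0])
    if not (f_pre > f_0):
        raise InvalidBleachError(
            f"pre-bleach intensity ({f_pre!r}) must exceed first post-bleach "
            f"intensity ({f_0!r})"
        )
    if f_0 < 0:
        raise DomainError("post-bleach intensity must be non-negative")
    f = (intensities - f_0) / (f_pre - f_0)
    if abs(f[0]) > 0.05:
        raise MalformedInputError(
            f"normalized curve must start near 0 (got f[0] = {f[0]:.3g}); "
            "check F_0 against the first post-bleach sample"
        )
    m = dict(meta or {})
    m.setdefault("F_pre", float(f_pre))
    m.setdefault("F_0", float(f_0))
    return RecoveryCurve(times=times - times[0], f=f, omega=omega, meta=m)


def estimate_half_time(
    curve: RecoveryCurve,
    method: str = "interpolation",
    smooth_window: Optional[int] = None,
    fit_mobile_fraction: bool = False,
) -> float:
    """Half-time of recovery: the time at which f first reaches 0.5.

    ``method="interpolation"`` (default) locates the first upward
    crossing of f = 0.5 by piecewise-linear interpolation, optionally
    after a centered moving-average smoothing of the trace.
    ``method="soumpasis_fit"`` least-squares fits the uniform-disk
    closed-form recovery and returns the fitted model's half-time.
    """
    if method == "interpolation":
        t_half, _ = _half_time_interpolation(curve, smooth_window)
        return t_half
    if method == "soumpasis_fit":
        t_half, _, _ = _half_time_soumpasis_fit(curve, fit_mobile_fraction)
        return t_half
    raise ValueError(f"unknown method {method!r}")


def _smooth(f: np.ndarray, window: Optional[int]) -> np.ndarray:
    if not window or window <= 1:
        return f
    kernel = np.ones(int(window)) / int(window)
    return np.convolve(f, kernel, mode="same")


def _half_time_interpolation(curve, smooth_window):
    f = _smooth(curve.f, smooth_window)
    t = curve.times
    crossings = np.nonzero((f[:-1] < 0.5) & (f[1:] >= 0.5))[0]
    if crossings.size == 0:
        if f.max() < 0.5:
            raise InsufficientRecoveryError(
                f"curve never reaches f = 0.5 (max f = {f.max():.3g})",
                max_f=float(f.max()),
            )
        raise InsufficientRecoveryError(
            "curve shows no upward crossing of 0.5 (starts at or above it); "
            "bleach depth insufficient for half-time",
            max_f=float(f.max()),
        )
    i = int(crossings[0]) + 1
    t_half = t[i - 1] + (0.5 - f[i - 1]) * (t[i] - t[i - 1]) / (f[i] - f[i - 1])
    return float(t_half), f


def _half_time_soumpasis_fit(curve, fit_mobile_fraction):
    from scipy.optimize import curve_fit

    from .frap_synth import soumpasis_half_time, soumpasis_recovery

    t_half0, _ = _half_time_interpolation(curve, None)
    d0 = HALF_TIME_COEF * um_to_cm(curve.omega) ** 2 / t_half0

    if fit_mobile_fraction:
        def model(t, d, a):
            return a * soumpasis_recovery(t, curve.omega, d)
        p0 = [d0, 1.0]
    else:
        def model(t, d):
            return soumpasis_recovery(t, curve.omega, d)
        p0 = [d0]

    popt, _ = curve_fit(model, curve.times, curve.f, p0=p0, maxfev=10000)
    resid = float(np.sqrt(np.mean((model(curve.times, *popt) - curve.f) ** 2)))
    t_half = soumpasis_half_time(curve.omega, popt[0])
    return float(t_half), float(popt[0]), resid


def diffusion_from_half_time(t_half: float, omega: float) -> float:
    """Diffusion coefficient (cm^2/s) from the recovery half-time.

    D = 0.224 * omega**2 / t_half with omega in micrometers, t_half in
    seconds; the micrometer -> centimeter conversion is applied here.
    """
    if not (t_half > 0) or not (omega > 0):
        raise DomainError("t_half and omega must both be positive")
    return HALF_TIME_COEF * um_to_cm(omega) ** 2 / t_half


def analyze_curve(
    curve: RecoveryCurve,
    method: str = "interpolation",
    smooth_window: Optional[int] = None,
    fit_mobile_fraction: bool = False,
) -> FrapResult:
    """Full analysis of one normalized curve: half-time then diffusivity."""
    if method == "interpolation":
        t_half, _ = _half_time_interpolation(curve, smooth_window)
        d = diffusion_from_half_time(t_half, curve.omega)
        return FrapResult(t_half=t_half, D=d, omega=curve.omega, method=method)
    if method == "soumpasis_fit":
        t_half, d_fit, resid = _half_time_soumpasis_fit(curve, fit_mobile_fraction)
        return FrapResult(
            t_half=t_half, D=d_fit, omega=curve.omega, method=method, fit_residual=resid
        )
    raise ValueError(f"unknown method {method!r}")


def obstruction_parameter(d_ratio: float, r_probe: float) -> ObstructionParams:
    """Obstruction lump kappa = -ln(D/D0) / r_probe from one measured ratio.

    ``d_ratio`` is the measured diffusivity of the reference probe in the
    sample relative to free solution; ``r_probe`` its hydrodynamic radius
    in nanometers.
    """
    if d_ratio > 1:
        raise UnphysicalRatioError(
            f"D/D0 = {d_ratio} exceeds 1: obstruction cannot speed diffusion up"
        )
    if not (d_ratio > 0):
        raise DomainError("D/D0 must be positive")
    if not (r_probe > 0):
        raise DomainError("probe radius must be positive")
    kappa = -math.log(d_ratio) / r_probe
    return ObstructionParams(kappa=kappa, r_ref=r_probe, D_ratio_ref=d_ratio)


def rescale_diffusion(params: ObstructionParams, r_new: float, d0_new: float) -> float:
    """Diffusivity of a different solute in the same sample.

    D_new = D0_new * exp(-kappa * r_new); equivalently
    D_new / D0_new = (D_ratio_ref) ** (r_new / r_ref).
    """
    if not (r_new > 0):
        raise DomainError("solute radius must be positive")
    if not (d0_new > 0):
        raise DomainError("free-solution diffusivity must be positive")
    return d0_new * math.exp(-params.kappa * r_new)


def decompose_kappa(params: ObstructionParams, r_fiber_nm: float) -> float:
    """Fiber volume fraction implied by kappa for a GIVEN fiber radius.

    This is a derived, not measured, quantity: kappa = phi_v / r_f only
    fixes the ratio, so phi_v = kappa * r_f inherits all uncertainty in
    the supplied fiber radius.
    """
    if not (r_fiber_nm > 0):
        raise DomainError("fiber radius must be positive")
    return params.kappa * r_fiber_nm


def average_curves(
    curves: Sequence[RecoveryCurve], n_grid: int = 200
) -> tuple[RecoveryCurve, np.ndarray]:
    """Pointwise mean of replicate curves on a common time grid.

    Replicates are linearly interpolated onto a uniform grid spanning the
    overlap of their time ranges; returns the mean curve and the per-point
    standard deviation.  Mirrors the practice of averaging 5-7 replicate
    bleaches per condition.
    """
    if not curves:
        raise MalformedInputError("need at least one curve to average")
    omega = curves[0].omega
    if any(abs(c.omega - omega) > 1e-9 for c in curves):
        raise MalformedInputError("replicate curves must share the bleach-spot radius")
    t_lo = max(c.times[0] for c in curves)
    t_hi = min(c.times[-1] for c in curves)
    if t_hi <= t_lo:
        raise MalformedInputError("curves have no overlapping time range")
    grid = np.linspace(t_lo, t_hi, n_grid)
    stack = np.vstack([np.interp(grid, c.times, c.f) for c in curves])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    meta = {"n_replicates": len(curves)}
    return RecoveryCurve(times=grid, f=np.clip(mean, -0.1, 1.2), omega=omega, meta=meta), sd
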