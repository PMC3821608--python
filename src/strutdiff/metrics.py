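"""Headline metrics of scaffold simulations and parameter sweeps.

The quantities mirror how patterned-scaffold transport studies report
results: the *saturated depth* (how far below the media-exposed surface
the cell density reaches the confluent maximum at steady state), the
*saturation time* ``t_s`` (time for the fully permeable D_s/D_w = 1
model to reach steady state), and timing of the top-surface saturation
and the transient bottom-surface density peak, expressed as fractions
of ``t_s``.  By convention the t_s of the D_s/D_w = 1 run normalizes
the time fractions of ALL runs, not each run's own steady-state time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import NotConvergedSeriesError
from .geometry import ScaffoldSpec, VoxelGrid, build_scaffold, symmetry_reduce
from .solver import KineticParams, SimState, SimulationSeries, run_simulation

SWEEP_COLUMNS = [
    "alpha",
    "arrangement",
    "ds_over_dw",
    "pitch_um",
    "voxel_um",
    "kd_per_hr",
    "saturated_depth_um",
    "t_s_hr",
    "top_sat_frac",
    "bottom_peak_frac",
    "converged",
]


@dataclass(frozen=True)
class SimMetrics:
    """Derived metrics of one run (times in hours, depths in um)."""

    saturated_depth: float
    t_s: Optional[float]
    top_saturation_time: Optional[float]
    top_saturation_frac: Optional[float]
    bottom_peak_time: Optional[float]
    bottom_peak_frac: Optional[float]
    converged: bool


def depth_profile(state: SimState, grid: VoxelGrid) -> np.ndarray:
    """Per-slab mean cell density over culture voxels.

    One value per voxel slab from the top down; slabs containing no
    culture voxels yield NaN (flagged rather than zero-filled).
    """
    culture = grid.culture
    counts = culture.sum(axis=(0, 1)).astype(float)
    sums = np.where(culture, state.rho, 0.0).sum(axis=(0, 1))
    return np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)


def saturated_depth(
    profile: np.ndarray,
    rho_max: float,
    voxel_size: float,
    threshold_frac: float = 0.99,
) -> float:
    """Depth (um) to which the scaffold is saturated with cells.

    The deepest slab lower edge such that every shallower culture slab
    has mean density >= threshold_frac * rho_max; 0 if the top slab is
    unsaturated.  Slabs with no culture voxels (NaN) do not interrupt a
    saturated run.
    """
    profile = np.asarray(profile, dtype=float)
    valid = np.nonzero(~np.isnan(profile))[0]
    if valid.size == 0:
        return 0.0
    depth = 0.0
    for k, val in enumerate(profile):
        if np.isnan(val):  # cell-free slab bridges a saturated run
            depth = (k + 1) * voxel_size
            continue
        if val >= threshold_frac * rho_max:
            depth = (k + 1) * voxel_size
        else:
            break
    # trailing cell-free slabs do not extend the saturated region
    last_valid_edge = (valid[-1] + 1) * voxel_size
    return float(min(depth, last_valid_edge))


def saturation_time(series: SimulationSeries, eps: float = 1e-3) -> float:
    """First checkpoint time (hours) at which the max per-voxel density
    change, per day and relative to rho_max, falls below ``eps``.

    If the series ever shows activity above ``eps``, the criterion is
    assessed only after the LAST such checkpoint, so a quiescent lag
    phase before growth cannot masquerade as steady state; a series
    that never exceeds ``eps`` is steady from its first checkpoint.
    """
    if len(series.checkpoints) < 3:
        raise NotConvergedSeriesError("need at least 3 checkpoints to assess steadiness")
    vals = np.array([cp.max_daily_drho for cp in series.checkpoints])
    times = series.times
    above = np.nonzero(vals >= eps)[0]
    if above.size == 0:
        return float(times[0])
    after = np.nonzero((np.arange(len(vals)) > above[-1]) & (vals < eps))[0]
    if after.size == 0:
        raise NotConvergedSeriesError(
            f"series never met the steady criterion (last daily change "
            f"{vals[-1]:.3g} >= {eps})"
        )
    return float(times[after[0]])


def top_saturation_time(
    series: SimulationSeries, threshold_frac: float = 0.99
) -> Optional[float]:
    """First checkpoint time at which the top-slab culture mean reaches
    threshold_frac * rho_max; None if it never does."""
    rho_max = series.params.rho_max
    for cp in series.checkpoints:
        if cp.rho_top >= threshold_frac * rho_max:
            return cp.t
    return None


def bottom_peak_time(series: SimulationSeries) -> tuple[Optional[float], bool]:
    """Time of the bottom-slab density maximum and whether it is a true
    interior peak.

    Returns ``(t_peak, defined)``; ``defined`` is False when the series
    is monotone or the maximum sits at the final checkpoint (no decline
    observed, e.g. when the decay rate k_d is zero).
    """
    bottom = np.array([cp.rho_bottom for cp in series.checkpoints])
    times = series.times
    i = int(np.nanargmax(bottom))
    defined = 0 < i < len(bottom) - 1 and bottom[i] > bottom[-1]
    if not defined:
        return (float(times[i]), False)
    return (float(times[i]), True)


def compute_metrics(
    series: SimulationSeries,
    t_s_ref: Optional[float] = None,
    threshold_frac: float = 0.99,
    eps: float = 1e-3,
) -> SimMetrics:
    """All headline metrics of one run.

    ``t_s_ref`` is the saturation time of the D_s/D_w = 1 reference run
    used to normalize time fractions; when omitted, the run's own
    steady-state time is used (only appropriate if this IS the
    reference run).
    """
    state = series.final_state
    profile = depth_profile(state, series.grid)
    depth = saturated_depth(
        profile, series.params.rho_max, series.grid.voxel_size, threshold_frac
    )
    try:
        t_s_own = saturation_time(series, eps)
    except NotConvergedSeriesError:
        t_s_own = None
    t_s = t_s_ref if t_s_ref is not None else t_s_own
    t_top = top_saturation_time(series, threshold_frac)
    t_peak, peak_defined = bottom_peak_time(series)
    return SimMetrics(
        saturated_depth=depth,
        t_s=t_s,
        top_saturation_time=t_top,
        top_saturation_frac=(t_top / t_s if (t_top is not None and t_s) else None),
        bottom_peak_time=(t_peak if peak_defined else None),
        bottom_peak_frac=(t_peak / t_s if (peak_defined and t_s) else None),
        converged=series.converged,
    )


def sweep(
    alphas: Sequence[float],
    arrangements: Sequence[str],
    ds_over_dw: Sequence[float],
    base_spec: Optional[ScaffoldSpec] = None,
    base_params: Optional[KineticParams] = None,
    dt_growth: float = 2.0,
    t_end: Optional[float] = 2400.0,
    steady_eps: float = 1e-3,
    threshold_frac: float = 0.99,
    use_symmetry: bool = True,
) -> pd.DataFrame:
    """Run one simulation per (alpha, arrangement, D_s/D_w) combination.

    For each (alpha, arrangement) group the D_s/D_w = 1 run's saturation
    time normalizes the group's time fractions (the reference run is
    added implicitly when missing from ``ds_over_dw``).  Per-run failures
    are recorded in the table and the sweep continues.  Deterministic.
    """
    from dataclasses import replace

    base_params = base_params or KineticParams()
    rows = []
    for alpha, arrangement in itertools.product(alphas, arrangements):
        spec = replace(
            base_spec or ScaffoldSpec(alpha=alpha), alpha=alpha, arrangement=arrangement
        )
        ratios = list(ds_over_dw)
        runs: dict[float, SimulationSeries] = {}
        for ratio in sorted(set(ratios) | {1.0}):
            params = replace(base_params, d_s=ratio * base_params.d_w)
            grid = build_scaffold(spec)
            if use_symmetry:
                try:
                    grid = symmetry_reduce(grid)
                except ValueError:
                    pass
            try:
                runs[ratio] = run_simulation(
                    grid, params, dt_growth=dt_growth, t_end=t_end, steady_eps=steady_eps
                )
            except Exception as exc:  # record and continue
                runs[ratio] = exc  # type: ignore[assignment]
        ref = runs.get(1.0)
        t_s_ref = None
        if isinstance(ref, SimulationSeries):
            try:
                t_s_ref = saturation_time(ref, steady_eps)
            except NotConvergedSeriesError:
                t_s_ref = None
        for ratio in ratios:
            series = runs[ratio]
            row = {
                "alpha": alpha,
                "arrangement": arrangement,
                "ds_over_dw": ratio,
                "pitch_um": spec.pitch,
                "voxel_um": spec.voxel_size,
                "kd_per_hr": base_params.k_d,
            }
            if isinstance(series, SimulationSeries):
                m = compute_metrics(series, t_s_ref=t_s_ref, threshold_frac=threshold_frac,
                                    eps=steady_eps)
                row.update(
                    saturated_depth_um=m.saturated_depth,
                    t_s_hr=t_s_ref,
                    top_sat_frac=m.top_saturation_frac,
                    bottom_peak_frac=m.bottom_peak_frac,
                    converged=m.converged,
                )
            else:
                row.update(
                    saturated_depth_um=np.nan,
                    t_s_hr=t_s_ref,
                    top_sat_frac=np.nan,
                    bottom_peak_frac=np.nan,
                    converged=False,
                )
                row["error"] = repr(series)
            rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS + (["error"] if any("error" in r for r in rows) else []))
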