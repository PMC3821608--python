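"""Coupled oxygen-transport / cell-growth model of a patterned scaffold.

Physics
-------
Oxygen diffuses through a heterogeneous medium: the culture (inter-strut)
domain with diffusivity ``D_t`` and the strut domain with diffusivity
``D_s`` (0 for a non-permeable strut, up to the value in water for a
fully permeable one).  Cells live only in the culture domain and consume
oxygen with Michaelis-Menten kinetics,

    R = rho * V_max * C / (K_m + C),

and proliferate with Monod kinetics expressed as a population doubling
rate,

    r_g = r_gmax * C / (K + C),     r_gmax = 1 / t_d,

so the density evolves as ``rho -> rho * 2**(r_g * dt)`` up to a hard
cap ``rho_max``.  An optional first-order decay ``k_d`` (also in
doublings per hour) makes the net rate ``r_g - k_d``; it is the minimal
loss mechanism that lets deep, oxygen-starved regions decline after
their early peak.

Boundary conditions: the top surface is held at the media oxygen
concentration ``C_0`` (Dirichlet), the bottom is a wall (zero flux), and
the lateral faces are mirror planes (zero flux), representing one period
of an infinite flat scaffold.

Numerics
--------
Cell-centered finite volumes on the voxel grid, 7-point stencil, with
harmonic-mean face diffusivities (exact for piecewise-constant D; a zero
strut diffusivity automatically produces zero-flux strut faces).  Oxygen
equilibrates in seconds while the cell population evolves over days, so
the oxygen field is solved to steady state at each growth step
(quasi-steady operator splitting): Picard iteration on the nonlinear
sink (coefficient frozen at the current concentration), each inner step
a symmetric positive-definite sparse solve by preconditioned conjugate
gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .errors import NonConvergenceError
from .geometry import ScaffoldSpec, VoxelGrid, build_scaffold
from .units import cm2s_to_m2s, um_to_m

D_WATER_O2 = 2.68e-5  # cm^2/s, oxygen in water at 37 C


@dataclass(frozen=True)
class KineticParams:
    """Transport and kinetic constants.

    Defaults are the standard literature values for oxygen-limited
    mammalian cell culture used throughout this package:

    ======== ===================================================== ==============
    field    meaning                                               default
    ======== ===================================================== ==============
    v_max    max cellular O2 consumption rate (mol/cell/s)         3.3e-16
    k_m      half-maximum-rate O2 concentration (mol/m^3)          3.79e-3
    k_monod  Monod saturation constant (mol/m^3; "3 nmol/mL")      3.0e-3
    c0       media / max dissolved O2 concentration (mol/m^3)      0.1
    rho0     seeding cell density (cell/m^3)                       2.1e11
    rho_max  confluent cell density (cell/m^3)                     1.5e14
    t_d      minimum cell division time (h)                        36.5
    d_t      O2 diffusivity in the culture domain (cm^2/s)         2.0e-5
    d_s      O2 diffusivity in the strut domain (cm^2/s)           0.0
    d_w      O2 diffusivity in water at 37 C (cm^2/s)              2.68e-5
    k_d      first-order decay rate (doublings/h); None ->         0.1 / t_d
    ======== ===================================================== ==============
    """

    v_max: float = 3.3e-16
    k_m: float = 3.79e-3
    k_monod: float = 3.0e-3
    c0: float = 0.1
    rho0: float = 2.1e11
    rho_max: float = 1.5e14
    t_d: float = 36.5
    d_t: float = 2.0e-5
    d_s: float = 0.0
    d_w: float = D_WATER_O2
    k_d: Optional[float] = None

    def __post_init__(self):
        for name in ("v_max", "k_m", "k_monod", "c0", "rho0", "rho_max", "t_d", "d_t", "d_s", "d_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.rho0 > self.rho_max:
            raise ValueError("seeding density cannot exceed the confluent density")
        if self.d_s > self.d_w + 1e-30:
            raise ValueError("strut diffusivity cannot exceed the value in water")
        if self.k_d is None:
            object.__setattr__(self, "k_d", 0.1 / self.t_d)
        if self.k_d < 0:
            raise ValueError("k_d must be non-negative")

    @property
    def r_g_max(self) -> float:
        """Maximum doubling rate, 1/t_d (doublings per hour)."""
        return 1.0 / self.t_d


@dataclass
class SimState:
    """Oxygen concentration (mol/m^3) and cell density (cell/m^3) fields."""

    C: np.ndarray
    rho: np.ndarray
    t: float  # hours since seeding

    def validate(self, grid: VoxelGrid, params: KineticParams) -> None:
        eps = 1e-9
        assert self.C.shape == grid.shape and self.rho.shape == grid.shape
        assert self.C.min() >= -eps * params.c0 and self.C.max() <= params.c0 * (1 + eps)
        assert self.rho.min() >= 0 and self.rho.max() <= params.rho_max * (1 + eps)
        assert not np.any(self.rho[grid.strut] != 0)


@dataclass(frozen=True)
class Checkpoint:
    """Laterally reduced snapshot of one growth step."""

    t: float  # hours
    c_profile: np.ndarray  # per-slab mean C over all voxels (mol/m^3)
    rho_profile: np.ndarray  # per-slab mean rho over culture voxels (cell/m^3)
    rho_top: float  # culture mean in the shallowest slab
    rho_bottom: float  # culture mean in the deepest slab
    max_daily_drho: float  # max |delta rho| / rho_max per day over the last step


@dataclass
class SimulationSeries:
    """Full record of one simulation run."""

    checkpoints: list[Checkpoint]
    final_state: SimState
    grid: VoxelGrid
    params: KineticParams
    converged: bool
    steady_eps: float
    dt_growth: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([cp.t for cp in self.checkpoints])


# ---------------------------------------------------------------------------
# face diffusivities and the steady oxygen solve
# ---------------------------------------------------------------------------


def voxel_diffusivity(grid: VoxelGrid, params: KineticParams) -> np.ndarray:
    """Per-voxel diffusivity in m^2/s (D_t in culture, D_s in strut)."""
    return np.where(grid.strut, cm2s_to_m2s(params.d_s), cm2s_to_m2s(params.d_t))


def face_diffusivity(grid: VoxelGrid, params: KineticParams) -> dict:
    """Harmonic-mean diffusivities on interior faces and the top boundary.

    Returns arrays ``x`` (nx-1, ny, nz), ``y`` (nx, ny-1, nz), ``z``
    (nx, ny, nz-1) for interior faces and ``top`` (nx, ny), the adjacent
    voxel's diffusivity used by the Dirichlet ghost at z = 0.  All other
    boundary faces are zero-flux and carry no entry.  A zero strut
    diffusivity gives zero on every culture|strut face (harmonic mean
    with zero), i.e. impermeable strut walls.
    """
    d = voxel_diffusivity(grid, params)

    def hmean(a, b):
        s = a + b
        out = np.zeros_like(a)
        nz = s > 0
        out[nz] = 2 * a[nz] * b[nz] / s[nz]
        return out

    return {
        "x": hmean(d[:-1, :, :], d[1:, :, :]),
        "y": hmean(d[:, :-1, :], d[:, 1:, :]),
        "z": hmean(d[:, :, :-1], d[:, :, 1:]),
        "top": d[:, :, 0].copy(),
    }


class OxygenSolver:
    """Steady-state oxygen solver for a fixed grid and parameter set.

    Caches the sparse finite-volume operator across calls, which matters
    when the solver is called hundreds of times during a growth
    simulation with slowly varying cell-density fields; successive
    solves warm-start from the previous oxygen field.
    """

    def __init__(self, grid: VoxelGrid, params: KineticParams):
        self.grid = grid
        self.params = params
        self.h = um_to_m(grid.voxel_size)
        self.shape = grid.shape
        self.n = int(np.prod(grid.shape))
        self._build_base()

    def _build_base(self):
        nx, ny, nz = self.shape
        h = self.h
        faces = face_diffusivity(self.grid, self.params)
        idx = np.arange(self.n).reshape(self.shape)
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)

        def add_faces(t_face, ia, ib):
            t = (t_face * h).ravel()  # transmissibility D*A/h = D*h  (m^3/s)
            a, b = ia.ravel(), ib.ravel()
            rows.extend([a, b])
            cols.extend([b, a])
            vals.extend([-t, -t])
            np.add.at(diag, a, t)
            np.add.at(diag, b, t)

        add_faces(faces["x"], idx[:-1, :, :], idx[1:, :, :])
        add_faces(faces["y"], idx[:, :-1, :], idx[:, 1:, :])
        add_faces(faces["z"], idx[:, :, :-1], idx[:, :, 1:])

        # Dirichlet top: ghost at distance h/2 -> transmissibility 2*D*h
        t_top = (2 * faces["top"] * h).ravel()
        top_idx = idx[:, :, 0].ravel()
        np.add.at(diag, top_idx, t_top)
        b_top = np.zeros(self.n)
        b_top[top_idx] = t_top * self.params.c0

        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        vals.append(np.zeros(self.n))  # placeholder; diag added below
        a = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsr()
        # nondimensionalize by a characteristic transmissibility so linear-
        # solver tolerances act on O(1) numbers regardless of voxel size
        self._t_scale = max(float(diag.max()), 1e-300)
        a /= self._t_scale
        diag = diag / self._t_scale
        b_top = b_top / self._t_scale
        self._offdiag = a
        self._diag0 = diag
        self._b_top = b_top
        # voxels with no connections and no possible sink (isolated, e.g.
        # strut interiors at D_s = 0): pin to C_0 so the system is regular
        self._isolated = diag == 0

    def _matrix(self, sink_diag: np.ndarray) -> sparse.csr_matrix:
        d = self._diag0 + sink_diag
        d = np.where(self._isolated, 1.0, d)
        return self._offdiag + sparse.diags(d)

    def _rhs(self, c0: float) -> np.ndarray:
        b = self._b_top.copy()
        b[self._isolated] = c0
        return b

    @staticmethod
    def _preconditioner(a: sparse.csr_matrix):
        d = a.diagonal()
        return LinearOperator(a.shape, lambda x: x / d)

    def solve(
        self,
        rho: np.ndarray,
        c_init: Optional[np.ndarray] = None,
        tol: float = 1e-6,
        max_iter: int = 300,
        collect: Optional[dict] = None,
    ) -> np.ndarray:
        """Steady oxygen field for a given cell-density field.

        Picard iteration: the Michaelis-Menten sink ``rho V_max C/(K_m+C)``
        is linearized as ``s(C_old) * C`` with the coefficient frozen at
        the current iterate.  This keeps every linear operator a strictly
        diagonally dominant M-matrix, so iterates stay positive and the
        fixed point is the physical solution even in the stiff zero-order
        ``C >> K_m`` regime (where a Newton linearization with projection
        can lock onto a spurious all-zero state).  Each linear system is
        solved by Jacobi-preconditioned CG warm-started from the previous
        iterate.  Converged when the max concentration update, relative
        to C_0, falls below ``tol``.
        """
        p = self.params
        c = (
            np.full(self.n, p.c0)
            if c_init is None
            else np.asarray(c_init, dtype=float).ravel().copy()
        )
        rho_flat = np.asarray(rho, dtype=float).ravel()
        vol = self.h**3
        history = []
        total_cg = 0
        for it in range(max_iter):
            cbar = np.clip(c, 0.0, p.c0)
            k_sink = rho_flat * p.v_max * vol / self._t_scale
            s = k_sink / (p.k_m + cbar)  # frozen-coefficient linearized sink
            a = self._matrix(s)
            b = self._rhs(p.c0)
            n_it = [0]

            def count(_):
                n_it[0] += 1

            c_new, info = cg(a, b, x0=c, rtol=1e-7, atol=0.0,
                             M=self._preconditioner(a), maxiter=20000, callback=count)
            total_cg += n_it[0]
            if info != 0:
                raise NonConvergenceError(
                    f"inner CG failed (info={info}) at Picard iteration {it}",
                    residuals=history,
                )
            c_new = np.clip(c_new, 0.0, p.c0)  # project onto physical bounds
            resid = float(np.max(np.abs(c_new - c)) / p.c0)
            history.append(resid)
            if len(history) >= 3 and resid > 0.9 * history[-2]:
                c = 0.7 * c_new + 0.3 * c  # damp on stagnation
            else:
                c = c_new
            if resid < tol:
                c = np.clip(c, 0.0, p.c0)
                if collect is not None:
                    collect["picard_iters"] = it + 1
                    collect["cg_iters"] = total_cg
                    collect["residuals"] = history
                return c.reshape(self.shape)
        raise NonConvergenceError(
            f"Picard iteration did not reach tol={tol} in {max_iter} steps",
            residuals=history,
        )


def steady_oxygen(
    grid: VoxelGrid,
    rho: np.ndarray,
    params: KineticParams,
    tol: float = 1e-6,
    c_init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One-shot steady oxygen solve (see :class:`OxygenSolver`)."""
    return OxygenSolver(grid, params).solve(rho, c_init=c_init, tol=tol)


def transient_oxygen(
    grid: VoxelGrid,
    rho: np.ndarray,
    params: KineticParams,
    dt_s: float,
    t_end_s: float,
    c_init: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Implicit-Euler transient oxygen integration at fixed cell density.

    Independent cross-check of :func:`steady_oxygen`: run to equilibrium,
    the two must agree.  The sink coefficient is lagged one time step
    (linearly implicit), unconditionally stable.
    """
    solver = OxygenSolver(grid, params)
    p = params
    vol = solver.h**3
    c = (
        np.full(solver.n, p.c0)
        if c_init is None
        else np.asarray(c_init, dtype=float).ravel().copy()
    )
    rho_flat = np.asarray(rho, dtype=float).ravel()
    mass = vol / dt_s / solver._t_scale
    n_steps = int(round(t_end_s / dt_s))
    from scipy.sparse.linalg import splu

    s0 = rho_flat * p.v_max / (p.k_m + c) * vol / solver._t_scale
    lu = None
    for _ in range(n_steps):
        s = rho_flat * p.v_max / (p.k_m + np.maximum(c, 0.0)) * vol / solver._t_scale
        if lu is None or np.max(np.abs(s - s0)) > 0.05 * np.max(s0 + mass):
            a = solver._matrix(s) + sparse.diags(np.full(solver.n, mass))
            lu = splu(a.tocsc())
            s0 = s
        b = solver._rhs(p.c0) + mass * c
        b[solver._isolated] = (1.0 + mass) * p.c0  # pinned voxels keep C_0
        c = lu.solve(b)
    return np.clip(c, 0.0, p.c0).reshape(grid.shape)


# ---------------------------------------------------------------------------
# growth update and the coupled run
# ---------------------------------------------------------------------------


def update_cells(
    rho: np.ndarray, c: np.ndarray, dt: float, params: KineticParams, grid: VoxelGrid
) -> np.ndarray:
    """Advance the cell-density field by one growth step of ``dt`` hours.

    Net doubling rate per culture voxel: ``r_gmax * C/(K + C) - k_d``
    (doublings per hour); density multiplies by ``2**(r_net * dt)``,
    clipped to [0, rho_max].  Strut voxels stay at zero.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params
    r_net = p.r_g_max * c / (p.k_monod + c) - p.k_d
    rho_new = np.clip(rho * np.exp2(r_net * dt), 0.0, p.rho_max)
    rho_new[grid.strut] = 0.0
    return rho_new


def _checkpoint(grid, c, rho, t, max_daily, params) -> Checkpoint:
    culture = grid.culture
    nz = grid.nz
    c_profile = c.mean(axis=(0, 1))
    counts = culture.sum(axis=(0, 1)).astype(float)
    sums = np.where(culture, rho, 0.0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    top = rho_profile[np.nonzero(counts > 0)[0][0]] if counts.any() else np.nan
    bottom = rho_profile[np.nonzero(counts > 0)[0][-1]] if counts.any() else np.nan
    assert c_profile.shape == (nz,)
    return Checkpoint(
        t=float(t),
        c_profile=c_profile,
        rho_profile=rho_profile,
        rho_top=float(top),
        rho_bottom=float(bottom),
        max_daily_drho=float(max_daily),
    )


def run_simulation(
    spec_or_grid,
    params: KineticParams,
    dt_growth: float = 2.0,
    t_end: Optional[float] = None,
    steady_eps: float = 1e-3,
    min_steps: int = 3,
    oxygen_tol: float = 1e-6,
    checkpoint_every: int = 1,
    progress: Optional[Callable[[float, float], None]] = None,
) -> SimulationSeries:
    """Run the coupled quasi-steady-oxygen / Monod-growth simulation.

    Starts from a uniform seeding density ``rho0`` on culture voxels and
    oxygen at the media concentration ``C_0`` everywhere.  At each step
    of ``dt_growth`` hours the oxygen field is re-solved to steady state
    for the current cell density, then the density is advanced.  The run
    stops when the max per-voxel density change, normalized by
    ``rho_max`` and expressed per day, falls below ``steady_eps``
    (default 1e-3/day) — but only after that daily change has first
    exceeded ``steady_eps``, since at seeding the population is so far
    below ``rho_max`` that the criterion would otherwise fire before any
    growth has happened — or at ``t_end`` hours, whichever comes first;
    ``converged`` records which.  Fully deterministic.
    """
    grid = build_scaffold(spec_or_grid) if isinstance(spec_or_grid, ScaffoldSpec) else spec_or_grid
    p = params
    solver = OxygenSolver(grid, p)
    rho = np.where(grid.culture, p.rho0, 0.0)
    c = np.full(grid.shape, p.c0)
    t = 0.0
    checkpoints = [_checkpoint(grid, c, rho, t, np.inf, p)]
    converged = False
    armed = False  # becomes True once growth activity exceeds steady_eps
    diag = {"picard_iters": [], "cg_iters": []}
    step = 0
    if t_end is not None and t_end <= 0:
        return SimulationSeries(
            checkpoints=checkpoints,
            final_state=SimState(C=c, rho=rho, t=t),
            grid=grid,
            params=p,
            converged=False,
            steady_eps=steady_eps,
            dt_growth=dt_growth,
        )
    while True:
        info: dict = {}
        c = solver.solve(rho, c_init=c, tol=oxygen_tol, collect=info)
        diag["picard_iters"].append(info.get("picard_iters"))
        diag["cg_iters"].append(info.get("cg_iters"))
        rho_new = update_cells(rho, c, dt_growth, p, grid)
        max_daily = float(np.max(np.abs(rho_new - rho)) / p.rho_max * (24.0 / dt_growth))
        rho = rho_new
        t += dt_growth
        step += 1
        if step % checkpoint_every == 0:
            checkpoints.append(_checkpoint(grid, c, rho, t, max_daily, p))
        if progress is not None:
            progress(t, max_daily)
        if max_daily >= steady_eps:
            armed = True
        if armed and step >= min_steps and max_daily < steady_eps:
            converged = True
            break
        if t_end is not None and t >= t_end - 1e-9:
            break
    if checkpoints[-1].t < t:  # always record the final state
        checkpoints.append(_checkpoint(grid, c, rho, t, max_daily, p))
    return SimulationSeries(
        checkpoints=checkpoints,
        final_state=SimState(C=c, rho=rho, t=t),
        grid=grid,
        params=p,
        converged=converged,
        steady_eps=steady_eps,
        dt_growth=dt_growth,
        diagnostics=diag,
    )
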