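"""Quasi-static Darcy–Brinkman flow through the capsule under actuation.

Momentum balance solved in every cell of the three-domain grid::

    (mu / eps) * lap(u)  -  (mu / k) * u  -  grad(p) = 0,    div(u) = 0

with the capsule's permeability and porosity in CAPSULE cells and a large
penalization permeability (porosity 1) in free-fluid cells, which is the
standard single-domain treatment of a porous layer embedded in free fluid.
At the printed scales the Darcy drag term dominates viscosity everywhere, so
the penalized formulation coincides with the Darcy limit in the capsule while
remaining well posed in the open fluid.

Discretization is a MAC staggered grid (pressures at cell centres, velocity
components on faces), which suppresses checkerboard pressure modes.  The
actuation pressure is applied as a Dirichlet ghost pressure on the bottom
boundary under the reservoir footprint; the far outer boundary is an open
outlet at zero pressure; solid walls are no-slip.  Because the system is
linear, the field at any instant of the actuation ramp is the peak-pressure
solution scaled by the instantaneous inlet pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .model_config import ActuationPulse, DomainGeometry, TransportParams

__all__ = [
    "FlowField",
    "FlowSolveError",
    "actuation_pressure_at",
    "solve_flow",
    "peri_membrane_velocity",
]

#: Penalization permeability (m²) representing free-fluid cells.
K_FREE_DEFAULT = 1e-6

#: Relative residual above which the linear solve is rejected.
SOLVER_TOL = 1e-10


class FlowSolveError(RuntimeError):
    """Linear solve failed or did not meet the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class FlowField:
    """Pressure and staggered face velocities on the model grid.

    ``u`` has shape (ny, nx+1) (x-velocity on vertical faces), ``v`` shape
    (ny+1, nx) (y-velocity on horizontal faces), ``pressure`` shape (ny, nx).
    """

    pressure: np.ndarray
    u: np.ndarray
    v: np.ndarray
    h: float
    time: float = 0.0

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components averaged to cell centres."""
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return uc, vc

    def speed(self) -> np.ndarray:
        uc, vc = self.cell_velocity()
        return np.hypot(uc, vc)

    def divergence(self) -> np.ndarray:
        """Discrete per-cell divergence (1/s)."""
        return (np.diff(self.u, axis=1) + np.diff(self.v, axis=0)) / self.h

    def scaled(self, factor: float) -> "FlowField":
        return FlowField(self.pressure * factor, self.u * factor, self.v * factor, self.h, self.time)


def actuation_pressure_at(t: float, pulse: ActuationPulse) -> float:
    """Inlet pressure (Pa) of the triangular pulse train at time ``t`` (s).

    Each cycle ramps linearly up to the amplitude over half the ramp duration
    and back down over the other half; cycles start at multiples of the cycle
    period; the pressure is zero outside pulses.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if pulse.n_cycles == 0 or pulse.amplitude == 0:
        return 0.0
    period = 1.0 / pulse.cycle_frequency
    cycle = int(np.floor(t / period))
    if cycle >= pulse.n_cycles:
        return 0.0
    phase = t - cycle * period
    half = pulse.ramp_duration / 2.0
    if phase < half:
        frac = phase / half
    elif phase < pulse.ramp_duration:
        frac = (pulse.ramp_duration - phase) / half
    else:
        frac = 0.0
    return pulse.amplitude_pa * frac


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return 2.0 * a * b / (a + b)


def solve_flow(
    geometry: DomainGeometry,
    params: TransportParams,
    inlet_pressure: float,
    k_free: float = K_FREE_DEFAULT,
    side_walls: bool = False,
) -> FlowField:
    """Solve the steady penalized Stokes–Brinkman system at a given inlet pressure.

    Parameters
    ----------
    inlet_pressure : float
        Dirichlet pressure (Pa) applied on the bottom boundary under the
        reservoir footprint; the outer boundary is held at zero pressure.
    k_free : float
        Penalization permeability for free-fluid cells (m²).
    side_walls : bool
        Replace the left/right open outlets by no-slip walls (1D column
        verification geometries).

    Returns the velocity/pressure :class:`FlowField`; raises
    :class:`FlowSolveError` when the linear solve misses the residual
    tolerance.
    """
    if inlet_pressure < 0:
        raise ValueError("inlet_pressure must be >= 0")
    if params.k_perm <= 0:
        raise FlowSolveError("impermeable capsule (k_perm <= 0) unsupported")

    ny, nx = geometry.shape
    h = geometry.h
    mu = params.mu_visc

    cap = geometry.capsule_mask
    kcell = np.where(cap, params.k_perm, k_free)
    eps = np.where(cap, params.porosity, 1.0)

    Nu = ny * (nx + 1)
    Nv = (ny + 1) * nx
    Np = ny * nx
    N = Nu + Nv + Np
    IU = np.arange(Nu).reshape(ny, nx + 1)
    IV = (Nu + np.arange(Nv)).reshape(ny + 1, nx)
    IP = (Nu + Nv + np.arange(Np)).reshape(ny, nx)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(N)

    def add(r, c, v):
        r = np.asarray(r).ravel()
        c = np.asarray(c).ravel()
        v = np.asarray(v, dtype=float).ravel()
        if v.size == 1:
            v = np.full(r.size, v[0])
        rows.append(r)
        cols.append(c)
        vals.append(v)

    inlet = np.zeros(nx, dtype=bool)
    inlet[geometry.inlet_columns] = True

    # ---- u momentum: faces (j, i), i = 0..nx ------------------------------
    jj, ii = np.meshgrid(np.arange(ny), np.arange(1, nx), indexing="ij")
    kf = _harmonic(kcell[jj, ii - 1], kcell[jj, ii])
    ef = 0.5 * (eps[jj, ii - 1] + eps[jj, ii])
    visc = mu / ef / h**2
    drag = mu / kf
    me = IU[jj, ii]
    diag = -drag.copy()
    # east / west neighbours always exist as unknowns (incl. boundary faces)
    add(me, IU[jj, ii + 1], visc)
    add(me, IU[jj, ii - 1], visc)
    diag -= 2 * visc
    # north: open top ghost = u (zero contribution); interior neighbour else
    interior_n = jj < ny - 1
    add(me[interior_n], IU[jj[interior_n] + 1, ii[interior_n]], visc[interior_n])
    diag[interior_n] -= visc[interior_n]
    # south: no-slip bottom wall ghost = -u
    interior_s = jj > 0
    add(me[interior_s], IU[jj[interior_s] - 1, ii[interior_s]], visc[interior_s])
    diag[interior_s] -= visc[interior_s]
    diag[~interior_s] -= 2 * visc[~interior_s]
    add(me, me, diag)
    add(me, IP[jj, ii], -1.0 / h)
    add(me, IP[jj, ii - 1], 1.0 / h)

    # boundary u faces (i = 0 and i = nx)
    j = np.arange(ny)
    for side, icol, inb, pcol, psign in (
        ("left", 0, 1, 0, -2.0 / h),
        ("right", nx, nx - 1, nx - 1, 2.0 / h),
    ):
        me = IU[j, icol]
        if side_walls:
            add(me, me, 1.0)
            continue
        kf = kcell[j, pcol]
        ef = eps[j, pcol]
        visc = mu / ef / h**2
        diag = -mu / kf
        add(me, IU[j, inb], visc)
        diag = diag - visc
        interior_n = j < ny - 1
        add(me[interior_n], IU[j[interior_n] + 1, icol], visc[interior_n])
        diag = diag - np.where(interior_n, visc, 0.0)
        interior_s = j > 0
        add(me[interior_s], IU[j[interior_s] - 1, icol], visc[interior_s])
        diag = diag - np.where(interior_s, visc, 2 * visc)
        add(me, me, diag)
        add(me, IP[j, pcol], psign)  # outer pressure 0 -> no rhs term

    # ---- v momentum: faces (j, i), j = 0..ny ------------------------------
    jj, ii = np.meshgrid(np.arange(1, ny), np.arange(nx), indexing="ij")
    kf = _harmonic(kcell[jj - 1, ii], kcell[jj, ii])
    ef = 0.5 * (eps[jj - 1, ii] + eps[jj, ii])
    visc = mu / ef / h**2
    me = IV[jj, ii]
    diag = -(mu / kf)
    add(me, IV[jj + 1, ii], visc)
    add(me, IV[jj - 1, ii], visc)
    diag -= 2 * visc
    interior_e = ii < nx - 1
    add(me[interior_e], IV[jj[interior_e], ii[interior_e] + 1], visc[interior_e])
    diag[interior_e] -= visc[interior_e]
    if side_walls:  # no-slip ghost = -v on closed sides
        diag[~interior_e] -= 2 * visc[~interior_e]
    interior_w = ii > 0
    add(me[interior_w], IV[jj[interior_w], ii[interior_w] - 1], visc[interior_w])
    diag[interior_w] -= visc[interior_w]
    if side_walls:
        diag[~interior_w] -= 2 * visc[~interior_w]
    add(me, me, diag)
    add(me, IP[jj, ii], -1.0 / h)
    add(me, IP[jj - 1, ii], 1.0 / h)

    # bottom boundary v faces: inlet under the reservoir, wall elsewhere
    i = np.arange(nx)
    me = IV[0, i]
    wall = ~inlet
    add(me[wall], me[wall], 1.0)
    if inlet.any():
        ii = i[inlet]
        kf = kcell[0, ii]
        ef = eps[0, ii]
        visc = mu / ef / h**2
        diag = -(mu / kf)
        add(IV[0, ii], IV[1, ii], visc)
        diag = diag - visc  # south ghost: zero-gradient
        e_ok = ii < nx - 1
        add(IV[0, ii[e_ok]], IV[0, ii[e_ok] + 1], visc[e_ok])
        diag = diag - np.where(e_ok, visc, 2 * visc if side_walls else 0.0)
        w_ok = ii > 0
        add(IV[0, ii[w_ok]], IV[0, ii[w_ok] - 1], visc[w_ok])
        diag = diag - np.where(w_ok, visc, 2 * visc if side_walls else 0.0)
        add(IV[0, ii], IV[0, ii], diag)
        add(IV[0, ii], IP[0, ii], -2.0 / h)
        rhs[IV[0, ii]] = -2.0 / h * inlet_pressure

    # top boundary v faces: open outlet at zero pressure
    me = IV[ny, i]
    kf = kcell[ny - 1, i]
    ef = eps[ny - 1, i]
    visc = mu / ef / h**2
    diag = -(mu / kf)
    add(me, IV[ny - 1, i], visc)
    diag = diag - visc
    e_ok = i < nx - 1
    add(me[e_ok], IV[ny, i[e_ok] + 1], visc[e_ok])
    diag = diag - np.where(e_ok, visc, 2 * visc if side_walls else 0.0)
    w_ok = i > 0
    add(me[w_ok], IV[ny, i[w_ok] - 1], visc[w_ok])
    diag = diag - np.where(w_ok, visc, 2 * visc if side_walls else 0.0)
    add(me, me, diag)
    add(me, IP[ny - 1, i], 2.0 / h)  # -(2*p_out - 2*p)/h with p_out = 0

    # ---- continuity per cell ---------------------------------------------
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    me = IP[jj, ii]
    add(me, IU[jj, ii + 1], 1.0 / h)
    add(me, IU[jj, ii], -1.0 / h)
    add(me, IV[jj + 1, ii], 1.0 / h)
    add(me, IV[jj, ii], -1.0 / h)

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(N, N)
    ).tocsr()
    try:
        lu = sp.linalg.splu(A.tocsc())
    except RuntimeError as exc:  # singular factorization
        raise FlowSolveError(f"singular Brinkman system: {exc}") from exc
    x = lu.solve(rhs)
    if not np.all(np.isfinite(x)):
        raise FlowSolveError("singular Brinkman system (non-finite solution)")

    def _resid(x: np.ndarray) -> float:
        # residual relative to the natural magnitude of each equation block,
        # robust to the wide coefficient scale of the drag terms
        denom = np.abs(A) @ np.abs(x) + np.abs(rhs)
        r = np.abs(A @ x - rhs)
        out = 0.0
        for block in (slice(0, Nu), slice(Nu, Nu + Nv), slice(Nu + Nv, N)):
            scale = denom[block].max()
            if scale > 0:
                out = max(out, r[block].max() / scale)
        return out

    resid = _resid(x)
    for _ in range(3):  # iterative refinement against the conditioning of the drag terms
        if resid <= SOLVER_TOL:
            break
        x = x + lu.solve(rhs - A @ x)
        resid = _resid(x)
    if resid > SOLVER_TOL:
        raise FlowSolveError(f"linear solve residual {resid:.3e} above tolerance", residual=resid)

    return FlowField(
        pressure=x[Nu + Nv:].reshape(ny, nx),
        u=x[:Nu].reshape(ny, nx + 1),
        v=x[Nu:Nu + Nv].reshape(ny + 1, nx),
        h=h,
    )


def peri_membrane_velocity(field: FlowField, geometry: DomainGeometry) -> float:
    """Mean speed (m/s) over the first tissue-side cell layer on the capsule.

    Evaluated on OUTER cells 4-adjacent to CAPSULE cells; call with the field
    solved at the instant of peak inlet pressure to obtain the peri-membrane
    velocity immediately following actuation.
    """
    cap = geometry.capsule_mask
    if not cap.any():
        raise ValueError("geometry has no capsule layer")
    from scipy.ndimage import binary_dilation

    ring = binary_dilation(cap) & geometry.outer_mask
    if not ring.any():
        raise ValueError("capsule has no tissue-side neighbours")
    return float(field.speed()[ring].mean())
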