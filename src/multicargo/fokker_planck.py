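"""Fokker-Planck description of the cargo-position density,

    dP/dt = d/dx [ D_eff(x) dP/dx ] - d/dx [ v_eff(x) P ] + k_on(x) - k_off(x) P,

discretized in conservative flux form on a uniform periodic grid (central
differences, method of lines).

Two modes are provided.  ``conservative`` drops the source/sink pair and
propagates a normalized density (mass conserved to round-off by the
telescoping flux sum).  ``source_sink`` adds the sink ``k_off(x) P`` (the
reciprocal mean dwell time) and closes the unspecified attachment term
k_on with a spatially uniform source whose total influx balances the total
sink flux, mirroring the uniform teleportation used in the Langevin layer;
its stationary, normalized density is obtained by implicit-Euler marching
until the relative change per unit time falls below 1e-8.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import lu_factor, lu_solve

from .meanfield import MeanFieldTables

__all__ = ["FPSolution", "solve_fokker_planck"]


@dataclasses.dataclass
class FPSolution:
    grid: np.ndarray
    times: np.ndarray
    P: np.ndarray           # (nt, nx), last row is the final/stationary density
    mode: str

    @property
    def stationary(self) -> np.ndarray:
        return self.P[-1]

    def mass(self, row: int = -1) -> float:
        dx = self.grid[1] - self.grid[0]
        return float(np.sum(self.P[row]) * dx)


def _advection_diffusion_operator(x, v, D):
    """Dense periodic operator A with (A P)_i = -(F_{i+1/2} - F_{i-1/2})/dx,
    F_{i+1/2} = v_{i+1/2} (P_i + P_{i+1})/2 - D_{i+1/2} (P_{i+1} - P_i)/dx."""
    nx = x.size
    dx = x[1] - x[0]
    vf = 0.5 * (v + np.roll(v, -1))       # face i+1/2 between i and i+1
    Df = 0.5 * (D + np.roll(D, -1))
    A = np.zeros((nx, nx))
    for i in range(nx):
        ip = (i + 1) % nx
        # flux at face i+1/2 contributes -F/dx to cell i and +F/dx to cell ip
        c_self = 0.5 * vf[i] + Df[i] / dx
        c_next = 0.5 * vf[i] - Df[i] / dx
        A[i, i] += -c_self / dx
        A[i, ip] += -c_next / dx
        A[ip, i] += c_self / dx
        A[ip, ip] += c_next / dx
    return A


def solve_fokker_planck(
    tables: MeanFieldTables,
    mode: str = "source_sink",
    P0: Optional[np.ndarray] = None,
    times=None,
    rtol: float = 1e-8,
    t_stationary_max: float = 10000.0,
) -> FPSolution:
    """Solve the continuity equation on the table grid.

    conservative: integrate dP/dt = A P over ``times`` (stiff BDF).
    source_sink: march dP/dt = A P - k_off P + (dx/W) 1 (k_off . P) to its
    stationary density (renormalized each step) and report it.
    """
    x = np.asarray(tables.x, dtype=float)
    nx = x.size
    dx = x[1] - x[0]
    if not np.allclose(np.diff(x), dx):
        raise ValueError("Fokker-Planck solver needs a uniform grid")
    W = dx * nx
    v = np.asarray(tables.v_eff, dtype=float)
    D = np.maximum(np.asarray(tables.D_eff, dtype=float), 0.0)
    A = _advection_diffusion_operator(x, v, D)
    if P0 is None:
        P0 = np.full(nx, 1.0 / W)
    else:
        P0 = np.asarray(P0, dtype=float)
        P0 = P0 / (np.sum(P0) * dx)

    if mode == "conservative":
        if times is None:
            times = np.linspace(0.0, 10.0, 11)
        times = np.asarray(times, dtype=float)
        sol = solve_ivp(
            lambda t, p: A @ p,
            (times[0], times[-1]),
            P0,
            t_eval=times,
            method="BDF",
            jac=A,
            rtol=1e-8,
            atol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(f"Fokker-Planck integration failed: {sol.message}")
        return FPSolution(grid=x, times=times, P=sol.y.T, mode=mode)

    if mode == "source_sink":
        koff = np.maximum(np.asarray(tables.k_off, dtype=float), 0.0)
        # uniform re-injection balancing total detachment keeps the mass fixed
        M = A - np.diag(koff) + np.outer(np.full(nx, dx / W), koff)
        dt = 1.0
        lu = lu_factor(np.eye(nx) - dt * M)
        P = P0.copy()
        t = 0.0
        while t < t_stationary_max:
            Pn = lu_solve(lu, P)
            Pn = np.maximum(Pn, 0.0)
            Pn /= np.sum(Pn) * dx
            delta = np.max(np.abs(Pn - P)) / max(np.max(np.abs(Pn)), 1e-300)
            P = Pn
            t += dt
            if delta < rtol * dt:
                break
        else:
            raise RuntimeError("stationary Fokker-Planck iteration did not converge")
        return FPSolution(grid=x, times=np.array([t]), P=P[None, :], mode=mode)

    raise ValueError(f"unknown mode {mode!r}")
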