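"""Exact event-driven (Gillespie) simulation of individual multivalent cargo.

Each trajectory starts from a single bound leg and evolves by three event
types: binding of a free leg at a position drawn from kappa1 weighted by
the shape factor (m = 1), unbinding of a bound leg at its current position
with rate kappa2(x_l) (m = 2), and collective displacement of all bound
legs by ``k3_step`` at rate ``k3_rate`` (m = 3).  After every event the
cargo centre is the arithmetic mean of the bound leg positions; the
trajectory terminates when the last leg unbinds or at ``t_max``.

Positions are kept unwrapped; on periodic domains the rate profiles are
evaluated at wrapped coordinates.  This is the ground truth against which
the mean-field and coarse-grained layers are validated.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .model import CargoModel, Domain

__all__ = [
    "CargoState",
    "Trajectory",
    "Ensemble",
    "propensities",
    "sample_binding_position",
    "simulate_cargo",
    "simulate_ensemble",
]

_RAND_BLOCK = 8192


class _ProfileGrid:
    """Dense-grid cache of a profile: O(1) point values, window integrals
    (via the trapezoid antiderivative) and a global rejection envelope."""

    def __init__(self, profile, domain: Domain, L: float, n: int = 16384):
        self.periodic = domain.periodic
        if self.periodic:
            lo, hi = domain.lo, domain.hi
        else:
            # cover all positions a bound cargo can reach
            lo, hi = domain.lo - 2.0 * L, domain.hi + 2.0 * L
            if profile.support is not None:
                lo = min(lo, profile.support[0] - 2.0 * L)
                hi = max(hi, profile.support[1] + 2.0 * L)
        xs = np.linspace(lo, hi, n + 1)
        vals = np.asarray(profile(xs), dtype=float)
        self.lo = lo
        self.hi = hi
        self.width = hi - lo
        self.inv_dx = n / self.width
        self.vals = vals
        self.F = cumulative_trapezoid(vals, xs, initial=0.0)
        self.total = float(self.F[-1])
        self.vmax = float(vals.max())
        self.n = n

    def value(self, x: float) -> float:
        if self.periodic:
            x = self.lo + (x - self.lo) % self.width
        t = (x - self.lo) * self.inv_dx
        if t <= 0.0:
            return float(self.vals[0]) if self.periodic else 0.0
        if t >= self.n:
            return float(self.vals[-1]) if self.periodic else 0.0
        i = int(t)
        f = t - i
        v = self.vals[i]
        return float(v + (self.vals[i + 1] - v) * f)

    def _antider(self, x: float) -> float:
        if self.periodic:
            k = math.floor((x - self.lo) / self.width)
            x = x - k * self.width
            base = k * self.total
        else:
            base = 0.0
            if x <= self.lo:
                return 0.0
            if x >= self.hi:
                return self.total
        t = (x - self.lo) * self.inv_dx
        i = min(int(t), self.n - 1)
        f = t - i
        F0 = self.F[i]
        return float(base + F0 + (self.F[i + 1] - F0) * f)

    def integral(self, a: float, b: float) -> float:
        return self._antider(b) - self._antider(a)


_GRID_CACHE: dict = {}


def _profile_grid(profile, domain: Domain, L: float) -> _ProfileGrid:
    key = (id(profile), domain, round(L, 12))
    g = _GRID_CACHE.get(key)
    if g is None:
        g = _ProfileGrid(profile, domain, L)
        if len(_GRID_CACHE) > 64:
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = g
    return g


@dataclasses.dataclass
class CargoState:
    """Instantaneous state: bound leg positions, centre, time."""

    bound_positions: np.ndarray
    centre: float
    time: float = 0.0

    @property
    def n(self) -> int:
        return len(self.bound_positions)


def propensities(state: CargoState, model: CargoModel):
    """(total binding rate, per-leg unbinding rates, k3 rate) at a state.

    Binding: (N - n) * Int kappa1(y) S_H(y | x_a) dy over the cargo window.
    Unbinding: each bound leg unbinds at kappa2 evaluated at its position.
    """
    n = state.n
    L = model.L
    g1 = _profile_grid(model.kappa1, model.domain, L)
    B = (model.N - n) * g1.integral(state.centre - L, state.centre + L) / (2.0 * L)
    unbind = np.asarray(model.kappa2_at(state.bound_positions), dtype=float)
    return float(max(B, 0.0)), unbind, model.k3_rate


def sample_binding_position(state: CargoState, model: CargoModel, rng) -> float:
    """Draw a binding position ~ kappa1(y) S_H(y | x_a) by rejection against
    the global profile maximum over the window."""
    L = model.L
    g1 = _profile_grid(model.kappa1, model.domain, L)
    x_a = state.centre
    if g1.integral(x_a - L, x_a + L) <= 0.0:
        raise ValueError("binding window has zero density (cargo off the substrate)")
    env = g1.vmax
    while True:
        y = x_a - L + 2.0 * L * rng.random()
        if rng.random() * env <= g1.value(y):
            return y


@dataclasses.dataclass
class Trajectory:
    """Event-resolved record of a single cargo.

    Arrays are aligned per event: ``times`` strictly increasing, ``m`` the
    event type, ``x_event`` the leg position involved (the step for m = 3),
    ``n_after`` the bound-leg count and ``x_after`` the centre after the
    event.  ``x0`` is the initial binding position (n = 1 at t = 0) and
    ``detached`` records whether the last leg unbound before ``t_max``.
    """

    x0: float
    times: np.ndarray
    m: np.ndarray
    x_event: np.ndarray
    n_after: np.ndarray
    x_after: np.ndarray
    t_max: float
    detached: bool
    seed: Optional[int] = None

    @property
    def dwell_time(self) -> float:
        return float(self.times[-1]) if self.detached else math.inf

    @property
    def end_time(self) -> float:
        return float(self.times[-1]) if self.detached else self.t_max

    def positions_at(self, ts):
        """Centre position at the requested times; NaN after detachment."""
        ts = np.asarray(ts, dtype=float)
        if self.times.size == 0:
            return np.where(ts <= self.end_time, self.x0, np.nan)
        idx = np.searchsorted(self.times, ts, side="right")
        x = np.where(idx == 0, self.x0, self.x_after[np.maximum(idx - 1, 0)])
        x = np.where(ts <= self.end_time, x, np.nan)
        if self.detached:
            x = np.where(ts >= self.times[-1], np.nan, x)
        return x


@dataclasses.dataclass
class Ensemble:
    trajectories: list
    model: CargoModel
    master_seed: int

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def positions_at(self, ts):
        ts = np.asarray(ts, dtype=float)
        out = np.empty((len(self.trajectories), ts.size))
        for i, tr in enumerate(self.trajectories):
            out[i] = tr.positions_at(ts)
        return out

    def dwell_times(self):
        return np.array([tr.dwell_time for tr in self.trajectories])


def _draw_initial_position(model: CargoModel, rng, mode: str):
    dom = model.domain
    if mode == "uniform":
        return dom.lo + dom.width * rng.random()
    if mode == "kappa1":
        g1 = _profile_grid(model.kappa1, dom, model.L)
        while True:
            y = dom.lo + dom.width * rng.random()
            if rng.random() * g1.vmax <= g1.value(y):
                return y
    raise ValueError(f"unknown initial-position mode {mode!r}")


def simulate_cargo(
    model: CargoModel,
    t_max: float,
    rng,
    x0: Optional[float] = None,
    x0_mode: str = "uniform",
    seed_label: Optional[int] = None,
) -> Trajectory:
    """Simulate one cargo from first binding to detachment or ``t_max``."""
    N = model.N
    L = model.L
    dom = model.domain
    g1 = _profile_grid(model.kappa1, dom, L)
    k2_uniform = model.kappa2.is_uniform and model.kappa2.support is None
    k2c = model.kappa2.params.get("rate", 1.0) if k2_uniform else None
    g2 = None if k2_uniform else _profile_grid(model.kappa2, dom, L)
    k1_uniform = model.kappa1.is_uniform and model.kappa1.support is None
    k1c = model.kappa1.params.get("rate", 1.0) if k1_uniform else None
    k3 = model.k3_rate
    dx3 = model.k3_step
    inv2L = 1.0 / (2.0 * L)
    env = g1.vmax

    if x0 is None:
        x0 = _draw_initial_position(model, rng, x0_mode)
    x0 = float(x0)

    buf = rng.random(_RAND_BLOCK)
    bi = 0

    def nx():
        nonlocal buf, bi
        if bi == _RAND_BLOCK:
            buf = rng.random(_RAND_BLOCK)
            bi = 0
        v = buf[bi]
        bi += 1
        return v

    legs = [x0]
    if not k2_uniform:
        legk2 = [g2.value(x0)]
    xa = x0
    t = 0.0
    n = 1
    ts, ms, xes, ns, xas = [], [], [], [], []
    detached = False

    while True:
        if k1_uniform:
            B = (N - n) * k1c
        else:
            B = (N - n) * g1.integral(xa - L, xa + L) * inv2L
            if B < 0.0:
                B = 0.0
        if k2_uniform:
            U = n * k2c
        else:
            U = 0.0
            for v in legk2:
                U += v
        R = B + U + k3
        if R <= 0.0:
            # frozen state (can only happen with vanishing unbinding rates)
            break
        t += -math.log(1.0 - nx()) / R
        if t >= t_max:
            break
        u = nx() * R
        if u < B:
            # binding at a sampled position
            while True:
                y = xa - L + 2.0 * L * nx()
                if k1_uniform or nx() * env <= g1.value(y):
                    break
            legs.append(y)
            if not k2_uniform:
                legk2.append(g2.value(y))
            xa += (y - xa) / (n + 1)
            n += 1
            mtype, xev = 1, y
        elif u < B + U:
            if k2_uniform:
                j = int(nx() * n)
                if j == n:
                    j -= 1
            else:
                r = u - B
                acc = 0.0
                j = n - 1
                for jj, v in enumerate(legk2):
                    acc += v
                    if r < acc:
                        j = jj
                        break
                legk2.pop(j)
            y = legs.pop(j)
            if n == 1:
                n = 0
                detached = True
                ts.append(t); ms.append(2); xes.append(y); ns.append(0); xas.append(xa)
                break
            xa += (xa - y) / (n - 1)
            n -= 1
            mtype, xev = 2, y
        else:
            for j in range(n):
                legs[j] += dx3
            if not k2_uniform:
                for j in range(n):
                    legk2[j] = g2.value(legs[j])
            xa += dx3
            mtype, xev = 3, dx3
        ts.append(t); ms.append(mtype); xes.append(xev); ns.append(n); xas.append(xa)

    return Trajectory(
        x0=x0,
        times=np.asarray(ts),
        m=np.asarray(ms, dtype=np.int8),
        x_event=np.asarray(xes),
        n_after=np.asarray(ns, dtype=np.int16),
        x_after=np.asarray(xas),
        t_max=float(t_max),
        detached=detached,
        seed=seed_label,
    )


def simulate_ensemble(
    model: CargoModel,
    count: int,
    t_max: float,
    master_seed: int,
    x0: Optional[float] = None,
    x0_mode: str = "uniform",
) -> Ensemble:
    """Simulate ``count`` independent cargo with per-trajectory RNG streams
    spawned deterministically from ``master_seed`` (bit-reproducible)."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(count)
    trajectories = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        trajectories.append(
            simulate_cargo(model, t_max, rng, x0=x0, x0_mode=x0_mode, seed_label=i)
        )
    return Ensemble(trajectories=trajectories, model=model, master_seed=master_seed)
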