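"""Ito Langevin dynamics of the cargo centre, parameterized by mean-field
tables:

    dx = S1(x) dt + sqrt(S2(x)) dW,

integrated with the Euler-Maruyama scheme (no Stratonovich correction; the
multiplicative noise is intended in the Ito sense).  Detachment/rebinding
is emulated by teleporting walkers to a uniform position in the periodic
domain with the position-dependent rate k_ran(x) = 1/t_dwell(x).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .meanfield import MeanFieldTables

__all__ = ["LangevinParams", "LangevinResult", "langevin_step", "langevin_simulate"]


@dataclasses.dataclass
class LangevinParams:
    dt: float = 0.02
    t_max: float = 100.0
    rebind_randomization: bool = True
    burn_in: float = 0.0
    store_every: int = 50

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > 0.1:
            raise ValueError("dt must not exceed 0.1 t_c")


def langevin_step(x, tables: MeanFieldTables, dt: float, rng):
    """One Euler-Maruyama step for an array of walkers; periodic wrap."""
    x = np.asarray(x, dtype=float)
    S1 = tables.S1_at(x)
    S2 = tables.S2_at(x)  # clamped at 0
    z = rng.standard_normal(x.shape)
    xn = x + S1 * dt + np.sqrt(S2 * dt) * z
    dom = tables.model.domain
    return dom.wrap(xn) if dom.periodic else xn


@dataclasses.dataclass
class LangevinResult:
    times: np.ndarray        # stored sample times
    positions: np.ndarray    # (count, n_stored)
    hist_edges: Optional[np.ndarray]
    hist: Optional[np.ndarray]  # time-weighted histogram after burn-in

    def stationary_density(self):
        bw = np.diff(self.hist_edges)
        total = np.sum(self.hist * bw)
        return 0.5 * (self.hist_edges[:-1] + self.hist_edges[1:]), self.hist / total


def langevin_simulate(
    tables: MeanFieldTables,
    params: LangevinParams,
    count: int,
    seed: int,
    hist_edges=None,
) -> LangevinResult:
    """Forward-Euler ensemble of ``count`` walkers started uniformly.

    Wiener increments by inverse-transform sampling of uniform variates.
    When ``rebind_randomization`` is on, each walker teleports to a uniform
    position with probability 1 - exp(-k_ran(x) dt) per step (thinning).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    dom = tables.model.domain
    dt = params.dt
    nsteps = int(round(params.t_max / dt))
    x = dom.lo + dom.width * rng.random(count)
    stored_t = []
    stored_x = []
    hist = None
    inv_bw = None
    nb = 0
    if hist_edges is not None:
        hist_edges = np.asarray(hist_edges, dtype=float)
        nb = hist_edges.size - 1
        hist = np.zeros(nb)
        inv_bw = nb / (hist_edges[-1] - hist_edges[0])
    from scipy.special import ndtri  # inverse normal CDF (inverse-transform sampling)

    for step in range(nsteps):
        t = step * dt
        S1 = tables.S1_at(x)
        S2 = tables.S2_at(x)
        z = ndtri(rng.random(count))
        x = x + S1 * dt + np.sqrt(S2 * dt) * z
        if dom.periodic:
            x = dom.wrap(x)
        if params.rebind_randomization:
            kran = tables.k_off_at(x)
            tele = rng.random(count) < -np.expm1(-kran * dt)
            nt = int(tele.sum())
            if nt:
                x[tele] = dom.lo + dom.width * rng.random(nt)
        if hist is not None and t >= params.burn_in:
            idx = np.clip(((x - hist_edges[0]) * inv_bw).astype(np.int64), 0, nb - 1)
            hist += np.bincount(idx, minlength=nb) * dt
        if step % params.store_every == 0:
            stored_t.append(t + dt)
            stored_x.append(x.copy())
    return LangevinResult(
        times=np.asarray(stored_t),
        positions=np.asarray(stored_x).T if stored_x else np.empty((count, 0)),
        hist_edges=hist_edges,
        hist=hist,
    )
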