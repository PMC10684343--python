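"""Two-dimensional cargo: disk-shaped footprint on a planar substrate.

The event logic is identical to the 1D engine: legs bind at positions
drawn from kappa1 weighted by the uniform disk shape factor 1/(pi L^2),
unbind from their bound positions, and the centre is the mean bound-leg
vector.  The binding propensity needs the disk average of kappa1 around
the centre; it is precomputed once per model by circular FFT convolution
of the rate field with the normalized disk kernel on a fine periodic grid,
and interpolated bilinearly during simulation (binding *positions* are
sampled exactly by rejection, so the spatial law of accepted events is
exact; only the event-time intensity carries the grid discretization).

The empirical vector drift field is assembled from per-event centre
displacements binned by pre-event position (first moments, second moments
and the cross moment), corrected by the half-divergence of the noise
tensor, smoothed over each point and its four nearest neighbours, and
decomposed into radial/tangential components about a declared origin.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .model import CargoModel

__all__ = [
    "Trajectory2D",
    "Ensemble2D",
    "VectorField2D",
    "simulate_cargo_2d",
    "simulate_ensemble_2d",
    "velocity_field_2d",
]

_RAND_BLOCK = 8192


def _planar_eval(profile):
    """Evaluate a rate profile on (..., 2) point arrays.

    2D profiles evaluate directly; uniform 1D profiles broadcast; anything
    else has no well-defined planar meaning here.
    """
    if profile.dim == 2:
        return lambda pts: np.asarray(profile(pts), dtype=float)
    if profile.is_uniform and profile.support is None:
        rate = float(profile.params.get("rate", 1.0))
        return lambda pts: np.full(np.shape(pts)[:-1], rate)
    raise NotImplementedError("2D models need a 2D (or uniform) rate profile")


class _DiskAverageGrid:
    """Periodic grid cache of kappa1 and of its disk average (FFT convolution)."""

    def __init__(self, model: CargoModel, n: int = 512):
        dom = model.domain
        self.lo = dom.lo
        self.width = dom.width
        self.n = n
        self.inv_dx = n / self.width
        ax = self.lo + self.width * np.arange(n) / n
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        pts = np.stack([X, Y], axis=-1)
        self.vals = _planar_eval(model.kappa1)(pts)
        self.vmax = float(self.vals.max())
        # disk kernel, normalized to the shape-factor average
        dx = self.width / n
        r = np.minimum(np.abs(np.arange(n) * dx), np.abs(self.width - np.arange(n) * dx))
        RX, RY = np.meshgrid(r, r, indexing="ij")
        kernel = (RX**2 + RY**2 <= model.L**2).astype(float)
        kernel /= kernel.sum()
        self.disk_avg = np.real(
            np.fft.ifft2(np.fft.fft2(self.vals) * np.fft.fft2(kernel))
        )

    def _frac_idx(self, x, y):
        tx = ((x - self.lo) % self.width) * self.inv_dx
        ty = ((y - self.lo) % self.width) * self.inv_dx
        return tx, ty

    def _bilinear(self, arr, x, y):
        tx, ty = self._frac_idx(x, y)
        i, j = int(tx), int(ty)
        fx, fy = tx - i, ty - j
        ip, jp = (i + 1) % self.n, (j + 1) % self.n
        return float(
            arr[i, j] * (1 - fx) * (1 - fy)
            + arr[ip, j] * fx * (1 - fy)
            + arr[i, jp] * (1 - fx) * fy
            + arr[ip, jp] * fx * fy
        )

    def value(self, x, y):
        return self._bilinear(self.vals, x, y)

    def disk_average(self, x, y):
        return max(self._bilinear(self.disk_avg, x, y), 0.0)


_GRID2_CACHE: dict = {}


def _disk_grid(model: CargoModel) -> _DiskAverageGrid:
    key = (id(model.kappa1), model.domain, round(model.L, 12))
    g = _GRID2_CACHE.get(key)
    if g is None:
        g = _DiskAverageGrid(model)
        if len(_GRID2_CACHE) > 16:
            _GRID2_CACHE.clear()
        _GRID2_CACHE[key] = g
    return g


@dataclasses.dataclass
class Trajectory2D:
    x0: np.ndarray           # (2,)
    times: np.ndarray
    m: np.ndarray
    x_event: np.ndarray      # (nev, 2)
    n_after: np.ndarray
    x_after: np.ndarray      # (nev, 2)
    t_max: float
    detached: bool
    seed: Optional[int] = None

    @property
    def end_time(self) -> float:
        return float(self.times[-1]) if self.detached else self.t_max

    def positions_at(self, ts):
        ts = np.asarray(ts, dtype=float)
        if self.times.size == 0:
            out = np.broadcast_to(self.x0, (ts.size, 2)).copy()
            out[ts > self.end_time] = np.nan
            return out
        idx = np.searchsorted(self.times, ts, side="right")
        out = np.where(
            (idx == 0)[:, None], self.x0, self.x_after[np.maximum(idx - 1, 0)]
        ).astype(float)
        out[ts > self.end_time] = np.nan
        if self.detached:
            out[ts >= self.times[-1]] = np.nan
        return out


@dataclasses.dataclass
class Ensemble2D:
    trajectories: list
    model: CargoModel
    master_seed: int

    def __len__(self):
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def positions_at(self, ts):
        ts = np.asarray(ts, dtype=float)
        out = np.empty((len(self.trajectories), ts.size, 2))
        for i, tr in enumerate(self.trajectories):
            out[i] = tr.positions_at(ts)
        return out


def simulate_cargo_2d(
    model: CargoModel,
    t_max: float,
    rng,
    x0=None,
    x0_mode: str = "uniform",
    seed_label: Optional[int] = None,
) -> Trajectory2D:
    """Simulate one disk-shaped cargo in 2D (periodic square domain)."""
    if model.dim != 2:
        raise ValueError("model.dim must be 2")
    N, L = model.N, model.L
    dom = model.domain
    g = _disk_grid(model)
    if not (model.kappa2.is_uniform and model.kappa2.support is None):
        raise NotImplementedError("2D engine supports uniform unbinding rates")
    k2c = model.kappa2.params.get("rate", 1.0)
    k3 = model.k3_rate
    dx3 = model.k3_step

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

    if x0 is None:
        if x0_mode == "uniform":
            x0 = (dom.lo + dom.width * nx(), dom.lo + dom.width * nx())
        elif x0_mode == "kappa1":
            while True:
                cand = (dom.lo + dom.width * nx(), dom.lo + dom.width * nx())
                if nx() * g.vmax <= g.value(*cand):
                    x0 = cand
                    break
        else:
            raise ValueError(f"unknown initial-position mode {x0_mode!r}")
    xax, xay = float(x0[0]), float(x0[1])
    legs_x = [xax]
    legs_y = [xay]
    n = 1
    t = 0.0
    ts, ms, ns = [], [], []
    xev, xaf = [], []
    detached = False
    env = g.vmax
    two_pi = 2.0 * math.pi

    while True:
        B = (N - n) * g.disk_average(xax, xay)
        U = n * k2c
        R = B + U + k3
        if R <= 0.0:
            break
        t += -math.log(1.0 - nx()) / R
        if t >= t_max:
            break
        u = nx() * R
        if u < B:
            while True:
                r = L * math.sqrt(nx())
                th = two_pi * nx()
                yx = xax + r * math.cos(th)
                yy = xay + r * math.sin(th)
                if nx() * env <= g.value(yx, yy):
                    break
            legs_x.append(yx)
            legs_y.append(yy)
            xax += (yx - xax) / (n + 1)
            xay += (yy - xay) / (n + 1)
            n += 1
            mtype, ev = 1, (yx, yy)
        elif u < B + U:
            j = int(nx() * n)
            if j == n:
                j -= 1
            yx = legs_x.pop(j)
            yy = legs_y.pop(j)
            if n == 1:
                detached = True
                ts.append(t); ms.append(2); ns.append(0)
                xev.append((yx, yy)); xaf.append((xax, xay))
                break
            xax += (xax - yx) / (n - 1)
            xay += (xay - yy) / (n - 1)
            n -= 1
            mtype, ev = 2, (yx, yy)
        else:
            for j in range(n):
                legs_x[j] += dx3
            xax += dx3
            mtype, ev = 3, (dx3, 0.0)
        ts.append(t); ms.append(mtype); ns.append(n)
        xev.append(ev); xaf.append((xax, xay))

    return Trajectory2D(
        x0=np.array([float(x0[0]), float(x0[1])]),
        times=np.asarray(ts),
        m=np.asarray(ms, dtype=np.int8),
        x_event=np.asarray(xev).reshape(-1, 2),
        n_after=np.asarray(ns, dtype=np.int16),
        x_after=np.asarray(xaf).reshape(-1, 2),
        t_max=float(t_max),
        detached=detached,
        seed=seed_label,
    )


def simulate_ensemble_2d(
    model: CargoModel,
    count: int,
    t_max: float,
    master_seed: int,
    x0=None,
    x0_mode: str = "uniform",
) -> Ensemble2D:
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(count)
    trajectories = []
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        trajectories.append(
            simulate_cargo_2d(model, t_max, rng, x0=x0, x0_mode=x0_mode, seed_label=i)
        )
    return Ensemble2D(trajectories=trajectories, model=model, master_seed=master_seed)


@dataclasses.dataclass
class VectorField2D:
    """Binned empirical drift/noise fields and their polar decomposition."""

    x: np.ndarray            # bin centers along each axis
    y: np.ndarray
    S1x: np.ndarray          # (nx, ny)
    S1y: np.ndarray
    S2x: np.ndarray
    S2y: np.ndarray
    Sxy: np.ndarray          # cross moment sum(dx dy)/T
    vx: np.ndarray           # v_eff components (with half-divergence correction)
    vy: np.ndarray
    v_radial: np.ndarray
    v_tangential: np.ndarray
    se_x: np.ndarray
    se_y: np.ndarray
    counts: np.ndarray
    occupancy: np.ndarray

    def well_sampled(self, min_events: int = 50):
        return self.counts >= min_events

    def to_frame(self):
        import pandas as pd

        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        rows = []
        for name, arr, err in [
            ("v_radial", self.v_radial, None),
            ("v_tangential", self.v_tangential, None),
            ("vx", self.vx, self.se_x),
            ("vy", self.vy, self.se_y),
        ]:
            rows.append(
                pd.DataFrame(
                    {
                        "x": X.ravel(),
                        "y": Y.ravel(),
                        "component": name,
                        "value": arr.ravel(),
                        "error": (err.ravel() if err is not None else np.nan),
                        "count": self.counts.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _smooth_plus(a):
    """Average each point with its four nearest neighbours (NaN-aware)."""
    out = np.zeros_like(a)
    norm = np.zeros_like(a)
    val = np.nan_to_num(a)
    fin = np.isfinite(a).astype(float)
    for sx, sy in [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]:
        out += np.roll(np.roll(val, sx, axis=0), sy, axis=1)
        norm += np.roll(np.roll(fin, sx, axis=0), sy, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, out / norm, np.nan)


def velocity_field_2d(ensemble: Ensemble2D, edges, smoothing: bool = True,
                      origin=(0.0, 0.0)) -> VectorField2D:
    """Empirical effective-velocity vector field on a square grid.

    Per bin: S1 components are rate-weighted mean displacements (sum of
    per-event centre displacements over occupancy time), S2/cross terms
    the analogous second moments; v_eff subtracts half the divergence of
    the noise tensor (finite differences).  Tangential components vanish
    on radially symmetric models up to estimation error.
    """
    model = ensemble.model
    edges = np.asarray(edges, dtype=float)
    nb = edges.size - 1
    lo = edges[0]
    inv_bw = nb / (edges[-1] - edges[0])
    pw = model.domain.width if model.domain.periodic else None

    occ = np.zeros((nb, nb))
    sdx = np.zeros((nb, nb))
    sdy = np.zeros((nb, nb))
    sdx2 = np.zeros((nb, nb))
    sdy2 = np.zeros((nb, nb))
    sdxdy = np.zeros((nb, nb))
    cnt = np.zeros((nb, nb))

    def bin_idx(p):
        q = p
        if pw is not None:
            q = lo + np.mod(p - lo, pw)
        idx = np.floor((q - lo) * inv_bw).astype(np.int64)
        return np.clip(idx, 0, nb - 1)

    for traj in ensemble:
        ne = traj.times.size
        if ne == 0:
            x_before = traj.x0[None, :]
            durs = np.array([traj.t_max])
            dxy = np.empty((0, 2))
            ev_before = np.empty((0, 2))
        else:
            x_before = np.vstack([traj.x0, traj.x_after[:-1]])
            t_before = np.concatenate(([0.0], traj.times[:-1]))
            durs = traj.times - t_before
            dxy = traj.x_after - x_before
            ev_before = x_before
            if not traj.detached and traj.t_max > traj.times[-1]:
                x_before = np.vstack([x_before, traj.x_after[-1]])
                durs = np.concatenate([durs, [traj.t_max - traj.times[-1]]])
        ix = bin_idx(x_before[:, 0])
        iy = bin_idx(x_before[:, 1])
        np.add.at(occ, (ix, iy), durs)
        if len(ev_before):
            jx = bin_idx(ev_before[:, 0])
            jy = bin_idx(ev_before[:, 1])
            np.add.at(sdx, (jx, jy), dxy[:, 0])
            np.add.at(sdy, (jx, jy), dxy[:, 1])
            np.add.at(sdx2, (jx, jy), dxy[:, 0] ** 2)
            np.add.at(sdy2, (jx, jy), dxy[:, 1] ** 2)
            np.add.at(sdxdy, (jx, jy), dxy[:, 0] * dxy[:, 1])
            np.add.at(cnt, (jx, jy), 1.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        S1x = np.where(occ > 0, sdx / occ, np.nan)
        S1y = np.where(occ > 0, sdy / occ, np.nan)
        S2x = np.where(occ > 0, sdx2 / occ, np.nan)
        S2y = np.where(occ > 0, sdy2 / occ, np.nan)
        Sxy = np.where(occ > 0, sdxdy / occ, np.nan)
        se_x = np.where(occ > 0, np.sqrt(sdx2) / occ, np.nan)
        se_y = np.where(occ > 0, np.sqrt(sdy2) / occ, np.nan)

    if smoothing:
        S1x, S1y = _smooth_plus(S1x), _smooth_plus(S1y)
        S2x, S2y, Sxy = _smooth_plus(S2x), _smooth_plus(S2y), _smooth_plus(Sxy)
        se_x = _smooth_plus(se_x) / math.sqrt(5.0)
        se_y = _smooth_plus(se_y) / math.sqrt(5.0)

    centers = 0.5 * (edges[:-1] + edges[1:])
    dxg = centers[1] - centers[0]
    gx = lambda a: np.gradient(a, dxg, axis=0)
    gy = lambda a: np.gradient(a, dxg, axis=1)
    vx = S1x - 0.5 * (gx(S2x) + gy(Sxy))
    vy = S1y - 0.5 * (gx(Sxy) + gy(S2y))

    X, Y = np.meshgrid(centers - origin[0], centers - origin[1], indexing="ij")
    r = np.hypot(X, Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_rad = np.where(r > 0, (vx * X + vy * Y) / r, np.nan)
        v_tan = np.where(r > 0, (-vx * Y + vy * X) / r, np.nan)

    return VectorField2D(
        x=centers, y=centers,
        S1x=S1x, S1y=S1y, S2x=S2x, S2y=S2y, Sxy=Sxy,
        vx=vx, vy=vy, v_radial=v_rad, v_tangential=v_tan,
        se_x=se_x, se_y=se_y, counts=cnt, occupancy=occ,
    )
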