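"""Turn simulated ensembles into measured quantities: MSD and short/long
time diffusivities, empirical leg-count and bound-leg distributions,
empirical drift/noise fields, and stationary densities.

All histograms are time-weighted: a cargo contributes to a bin in
proportion to the time it spends there, matching how an experimentalist
would average a tracked particle over frames.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .gillespie import Ensemble, Trajectory
from .meanfield import (
    BoundLegDistribution,
    empirical_bound_legs,
    drift_and_noise,
)

__all__ = [
    "Moments",
    "EmpiricalField",
    "msd_and_diffusivities",
    "estimate_bound_leg_distribution",
    "estimate_bound_leg_distributions",
    "fit_bound_leg_distribution",
    "estimate_Pn",
    "empirical_drift_noise",
    "stationary_density",
]


# ---------------------------------------------------------------------------
# MSD and diffusivities
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Moments:
    """Ensemble MSD over survivors and fitted short/long-time diffusivities."""

    lags: np.ndarray
    msd: np.ndarray
    msd_se: np.ndarray
    counts: np.ndarray
    D_short: float
    zeta_short: float
    D_long: float
    zeta_long: float
    crossover_time: Optional[float] = None
    dim: int = 1


def _wls_slope(t, y, w):
    W = np.sum(w)
    Wt = np.sum(w * t)
    Wtt = np.sum(w * t * t)
    Wy = np.sum(w * y)
    Wty = np.sum(w * t * y)
    det = W * Wtt - Wt * Wt
    return (W * Wty - Wt * Wy) / det


def _fit_D(lags, disp2, se, window, dim, n_blocks=20):
    """Weighted LS slope of the ensemble MSD in a lag window; the error is
    a delete-one-block jackknife over trajectories, which accounts for the
    strong correlation of MSD values across lags."""
    lo, hi = window
    msd = np.nanmean(disp2, axis=0)
    mask = (lags >= lo) & (lags <= hi) & np.isfinite(msd) & np.isfinite(se)
    if mask.sum() < 3:
        raise ValueError("too few surviving-lag points in the fit window")
    t = lags[mask]
    sew = se[mask]
    if np.all(sew == 0):  # immobile cargo: zero-variance MSD
        w = np.ones_like(sew)
    else:
        w = 1.0 / np.maximum(sew, sew[sew > 0].min()) ** 2
    slope = _wls_slope(t, msd[mask], w)
    ntraj = disp2.shape[0]
    n_blocks = min(n_blocks, ntraj)
    bounds = np.linspace(0, ntraj, n_blocks + 1).astype(int)
    sums = np.nansum(disp2[:, mask], axis=0)
    cnts = np.sum(np.isfinite(disp2[:, mask]), axis=0)
    jack = []
    for k in range(n_blocks):
        sl = slice(bounds[k], bounds[k + 1])
        bs = np.nansum(disp2[sl, mask], axis=0)
        bc = np.sum(np.isfinite(disp2[sl, mask]), axis=0)
        rc = cnts - bc
        ok = rc > 0
        if ok.sum() < 3:
            continue
        jack.append(_wls_slope(t[ok], (sums - bs)[ok] / rc[ok], w[ok]))
    jack = np.asarray(jack)
    m = len(jack)
    var = (m - 1) / m * np.sum((jack - jack.mean()) ** 2) if m > 1 else np.nan
    D = slope / (2.0 * dim)
    return float(D), float(math.sqrt(var) / (2.0 * dim))


def msd_and_diffusivities(
    ensemble,
    short_window=(0.05, 0.8),
    long_window=(2.0, 6.0),
    lags=None,
    dim: int = 1,
) -> Moments:
    """MSD(t) from first binding, survivors only, with diffusivities fitted
    per window by weighted least squares (D = slope / 2 in 1D, / 4 in 2D)."""
    if lags is None:
        lags = np.unique(
            np.concatenate(
                [
                    np.linspace(short_window[0], short_window[1], 12),
                    np.linspace(long_window[0], long_window[1], 16),
                    np.linspace(short_window[1], long_window[0], 8)[1:-1],
                ]
            )
        )
    lags = np.asarray(lags, dtype=float)
    X = ensemble.positions_at(lags)  # (ntraj, nlags), NaN after detachment
    if dim == 1:
        x0 = np.array([tr.x0 for tr in ensemble])
        disp2 = (X - x0[:, None]) ** 2
    else:
        x0 = np.array([tr.x0 for tr in ensemble])  # (ntraj, 2)
        disp2 = np.sum((X - x0[:, None, :]) ** 2, axis=-1)
    counts = np.sum(np.isfinite(disp2), axis=0)
    with np.errstate(invalid="ignore"):
        msd = np.nanmean(disp2, axis=0)
        sd = np.nanstd(disp2, axis=0)
    se = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    D_s, z_s = _fit_D(lags, disp2, se, short_window, dim)
    D_l, z_l = _fit_D(lags, disp2, se, long_window, dim)
    return Moments(
        lags=lags, msd=msd, msd_se=se, counts=counts,
        D_short=D_s, zeta_short=z_s, D_long=D_l, zeta_long=z_l,
        crossover_time=None, dim=dim,
    )


# ---------------------------------------------------------------------------
# Event replay helpers
# ---------------------------------------------------------------------------

def _replay(traj: Trajectory):
    """Yield (t0, t1, n, xa, legs_list) for each constant-state interval.

    ``legs_list`` is a live list; consumers must not mutate or keep it.
    """
    legs = [traj.x0]
    xa = traj.x0
    t_prev = 0.0
    for t, m, xev, n_after, xa_after in zip(
        traj.times.tolist(), traj.m.tolist(), traj.x_event.tolist(),
        traj.n_after.tolist(), traj.x_after.tolist(),
    ):
        if t > t_prev:
            yield t_prev, t, len(legs), xa, legs
        if m == 1:
            legs.append(xev)
        elif m == 2:
            # unbinding: remove the leg closest to the recorded position
            j = min(range(len(legs)), key=lambda k: abs(legs[k] - xev))
            legs.pop(j)
        else:
            for j in range(len(legs)):
                legs[j] += xev
        xa = xa_after
        t_prev = t
    if not traj.detached and traj.t_max > t_prev and legs:
        yield t_prev, traj.t_max, len(legs), xa, legs


def estimate_bound_leg_distribution(ensemble, n: int, bins: int = 81) -> dict:
    """Time-weighted histogram of bound-leg offsets y - x_a during sojourns
    with exactly ``n`` legs bound.  Returns {"u", "density", "time"}."""
    out = estimate_bound_leg_distributions(ensemble, bins=bins, counts=(n,))
    return out[n]


def estimate_bound_leg_distributions(ensemble, bins: int = 81, counts=None):
    """Per-n empirical bound-leg offset densities for a whole ensemble."""
    L = ensemble.model.L
    N = ensemble.model.N
    wanted = set(counts) if counts is not None else set(range(1, N + 1))
    edges = np.linspace(-L, L, bins + 1)
    inv_bw = bins / (2.0 * L)
    hists = {n: np.zeros(bins) for n in wanted}
    times = {n: 0.0 for n in wanted}
    for traj in ensemble:
        for t0, t1, n, xa, legs in _replay(traj):
            if n not in hists:
                continue
            dt = t1 - t0
            h = hists[n]
            for leg in legs:
                k = int((leg - xa + L) * inv_bw)
                if 0 <= k < bins:
                    h[k] += dt
            times[n] += dt
    out = {}
    centers = 0.5 * (edges[:-1] + edges[1:])
    for n in wanted:
        total = hists[n].sum()
        if total <= 0:
            raise ValueError(f"no sojourns observed with n={n} legs bound")
        out[n] = {
            "u": centers,
            "density": hists[n] / (total * (2.0 * L / bins)),
            "time": times[n],
        }
    return out


def empirical_pb(ensemble, bins: int = 81) -> BoundLegDistribution:
    """Empirical bound-leg distribution object usable by the mean-field layer."""
    N = ensemble.model.N
    raw = estimate_bound_leg_distributions(ensemble, bins=bins,
                                           counts=range(2, N + 1) if N > 1 else (1,))
    if N == 1:
        return empirical_bound_legs(raw[1]["u"], {1: raw[1]["density"]}, ensemble.model.L)
    dens = {n: raw[n]["density"] for n in raw}
    return empirical_bound_legs(raw[2]["u"], dens, ensemble.model.L)


def fit_bound_leg_distribution(u, density, L: float):
    """Least-squares fit of the symmetric two-parameter family

        p(y) ~ (1 - |y/L|**a)**b  on [-L, L],

    renormalized exactly (numerically) at every parameter value.
    Returns (params dict, fitted density on ``u``)."""
    u = np.asarray(u, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.all(density <= 0):
        raise ValueError("degenerate histogram")
    ufine = np.linspace(-L, L, 801)

    def family(logab):
        a, b = np.exp(logab)
        base = np.maximum(1.0 - np.abs(ufine / L) ** a, 0.0) ** b
        Z = np.trapezoid(base, ufine)
        vals = np.maximum(1.0 - np.abs(u / L) ** a, 0.0) ** b / Z
        return vals

    def resid(logab):
        return family(logab) - density

    res = least_squares(resid, x0=np.log([2.0, 2.0]), bounds=(np.log(1e-2), np.log(1e3)))
    a, b = np.exp(res.x)
    fitted = family(res.x)
    return {"a": float(a), "b": float(b), "residual": float(np.sum(res.fun**2))}, fitted


def fitted_pb(ensemble, bins: int = 81) -> BoundLegDistribution:
    """Fit the heuristic family to each empirical per-n histogram."""
    model = ensemble.model
    raw = estimate_bound_leg_distributions(
        ensemble, bins=bins, counts=range(2, model.N + 1)
    )
    dens = {}
    params = {}
    u = None
    for n, h in raw.items():
        u = h["u"]
        p, fitted = fit_bound_leg_distribution(u, h["density"], model.L)
        dens[n] = fitted
        params[n] = p
    pb = empirical_bound_legs(u, dens, model.L, provenance="fitted")
    pb.meta["fit_params"] = params
    return pb


# ---------------------------------------------------------------------------
# Occupancies and fields
# ---------------------------------------------------------------------------

def _interval_arrays(traj: Trajectory):
    """Vectorized (t_start, duration, n_before, x_before) per interval plus
    per-event (x_before, dx) displacement records."""
    nt = traj.times.size
    if nt == 0:
        dur = np.array([traj.t_max])
        return (np.array([traj.x0]), dur, np.array([1]),
                np.empty(0), np.empty(0))
    x_before = np.concatenate(([traj.x0], traj.x_after[:-1]))
    n_before = np.concatenate(([1], traj.n_after[:-1]))
    t_before = np.concatenate(([0.0], traj.times[:-1]))
    dur = traj.times - t_before
    dx = traj.x_after - x_before
    xs, ns, ds = x_before, n_before, dur
    if not traj.detached and traj.t_max > traj.times[-1]:
        xs = np.concatenate((xs, [traj.x_after[-1]]))
        ns = np.concatenate((ns, [traj.n_after[-1]]))
        ds = np.concatenate((ds, [traj.t_max - traj.times[-1]]))
    return xs, ds, ns, x_before, dx


def _bin_index(x, lo, inv_bw, nbins, periodic_width=None):
    if periodic_width is not None:
        x = lo + np.mod(x - lo, periodic_width)
    idx = np.floor((x - lo) * inv_bw).astype(np.int64)
    return np.clip(idx, 0, nbins - 1), (idx >= 0) & (idx < nbins)


def estimate_Pn(ensemble, grid, t_range=None):
    """Time-weighted occupancy of the leg count n binned by centre position.

    ``t_range=(t0, t1)`` restricts the occupancy to a time window (e.g. a
    late window where the leg count has relaxed, for comparison against the
    quasi-stationary law).  Returns (bin centers, P (nx, N) with rows
    normalized, occupancy time)."""
    model = ensemble.model
    edges = np.asarray(grid, dtype=float)
    nb = edges.size - 1
    lo = edges[0]
    inv_bw = nb / (edges[-1] - edges[0])
    pw = model.domain.width if model.domain.periodic else None
    occ = np.zeros((nb, model.N))
    for traj in ensemble:
        xs, ds, ns, _, _ = _interval_arrays(traj)
        if t_range is not None:
            t_end = np.cumsum(ds)
            t_start = t_end - ds
            ds = np.minimum(t_end, t_range[1]) - np.maximum(t_start, t_range[0])
            keep = ds > 0
            xs, ds, ns = xs[keep], ds[keep], ns[keep]
        idx, ok = _bin_index(xs, lo, inv_bw, nb, pw)
        flat = idx[ok] * model.N + (np.minimum(ns[ok], model.N) - 1)
        occ += np.bincount(flat, weights=ds[ok], minlength=nb * model.N).reshape(nb, model.N)
    tot = occ.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(tot > 0, occ / tot, np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, P, occ.sum(axis=1)


@dataclasses.dataclass
class EmpiricalField:
    """Binned drift/noise estimates with standard errors."""

    x: np.ndarray
    S1: np.ndarray
    S1_se: np.ndarray
    S2: np.ndarray
    S2_se: np.ndarray
    counts: np.ndarray
    occupancy: np.ndarray
    smoothing: int = 1

    def well_sampled(self, min_events: int = 100):
        return self.counts >= min_events


def _moving_average(a, w):
    if w <= 1:
        return a
    kernel = np.ones(w) / w
    out = np.convolve(np.nan_to_num(a), kernel, mode="same")
    norm = np.convolve(np.isfinite(a).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, out / norm, np.nan)


def empirical_drift_noise(
    ensemble,
    grid,
    smoothing: int = 5,
    route: str = "events",
    pb: Optional[BoundLegDistribution] = None,
    Pn=None,
) -> EmpiricalField:
    """Empirical drift S1(x) and noise intensity S2(x).

    route "events" (cross-check): bin per-event centre displacements by the
    pre-event position; S1 = sum(dx)/T_bin, S2 = sum(dx^2)/T_bin with T_bin
    the occupancy time.  route "meanfield" (as in the analytic comparison):
    plug the empirical P_n(x) and bound-leg distributions into the
    displacement-moment and rate formulas.
    """
    model = ensemble.model
    edges = np.asarray(grid, dtype=float)
    nb = edges.size - 1
    lo = edges[0]
    inv_bw = nb / (edges[-1] - edges[0])
    pw = model.domain.width if model.domain.periodic else None
    centers = 0.5 * (edges[:-1] + edges[1:])

    occ = np.zeros(nb)
    if route == "events":
        s1 = np.zeros(nb)
        s2 = np.zeros(nb)
        s4 = np.zeros(nb)
        cnt = np.zeros(nb)
        for traj in ensemble:
            xs, ds, ns, x_ev, dx = _interval_arrays(traj)
            idx, ok = _bin_index(xs, lo, inv_bw, nb, pw)
            occ += np.bincount(idx[ok], weights=ds[ok], minlength=nb)
            if x_ev.size:
                ie, oke = _bin_index(x_ev, lo, inv_bw, nb, pw)
                ie = ie[oke]
                dxe = dx[oke]
                s1 += np.bincount(ie, weights=dxe, minlength=nb)
                s2 += np.bincount(ie, weights=dxe**2, minlength=nb)
                s4 += np.bincount(ie, weights=dxe**4, minlength=nb)
                cnt += np.bincount(ie, minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            S1 = np.where(occ > 0, s1 / occ, np.nan)
            S2 = np.where(occ > 0, s2 / occ, np.nan)
            S1_se = np.where(occ > 0, np.sqrt(s2) / occ, np.nan)
            S2_se = np.where(occ > 0, np.sqrt(s4) / occ, np.nan)
        S1 = _moving_average(S1, smoothing)
        S2 = _moving_average(S2, smoothing)
        denom = math.sqrt(max(smoothing, 1))
        S1_se = _moving_average(S1_se, smoothing) / denom
        S2_se = _moving_average(S2_se, smoothing) / denom
        return EmpiricalField(centers, S1, S1_se, S2, S2_se, cnt, occ, smoothing)

    if route == "meanfield":
        if pb is None:
            pb = empirical_pb(ensemble)
        if Pn is None:
            _, Pn, occ = estimate_Pn(ensemble, edges)
        S1 = np.empty(nb)
        S2 = np.empty(nb)
        for j, xj in enumerate(centers):
            row = Pn[j]
            if np.any(~np.isfinite(row)):
                S1[j] = S2[j] = np.nan
                continue
            S1[j], S2[j] = drift_and_noise(xj, model, pb, Pn=row)
        S1 = _moving_average(S1, smoothing)
        S2 = _moving_average(S2, smoothing)
        zeros = np.zeros(nb)
        cnt = np.where(np.isfinite(S1), np.inf, 0.0)
        return EmpiricalField(centers, S1, zeros, S2, zeros, cnt, occ, smoothing)

    raise ValueError(f"unknown route {route!r}")


def stationary_density(ensemble, grid):
    """Time-weighted histogram of (wrapped) centre positions over all
    trajectories and times, normalized to a density, with per-bin SEs."""
    model = ensemble.model
    edges = np.asarray(grid, dtype=float)
    nb = edges.size - 1
    lo = edges[0]
    bw = (edges[-1] - edges[0]) / nb
    inv_bw = 1.0 / bw
    pw = model.domain.width if model.domain.periodic else None
    total = np.zeros(nb)
    total_sq = np.zeros(nb)
    T = 0.0
    ntraj = len(ensemble)
    for traj in ensemble:
        xs, ds, _, _, _ = _interval_arrays(traj)
        idx, ok = _bin_index(xs, lo, inv_bw, nb, pw)
        h = np.bincount(idx[ok], weights=ds[ok], minlength=nb)
        total += h
        total_sq += h * h
        T += ds[ok].sum()
    density = total / (T * bw)
    # between-trajectory scatter of the per-trajectory bin masses
    var = total_sq / ntraj - (total / ntraj) ** 2
    se = np.sqrt(np.maximum(var, 0.0) * ntraj) / (T * bw)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, se
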