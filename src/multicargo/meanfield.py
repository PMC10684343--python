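"""Mean-field layer: displacement moments, leg-count statistics, dwell
times, and the effective drift/noise fields of a bound cargo.

For each event type (m = 1 binding, m = 2 unbinding, m = 3 collective
displacement) the cargo-centre displacement moments and mean event rates
are

    lambda_m^(i)(x, n) = (1/(n + D_m))^i * Int[(D_m (y - x))^i k_m dy] / Int[k_m dy]
    kbar_m(x, n)       = (N d_{m,1} - n D_m) * Int[k_m dy]

with D_1 = +1, D_2 = -1, k_1 = kappa1(y) S(y|x) and k_2 = kappa2(y) P_b(y|x, n).
Event-rate-weighted sums over the leg-count distribution P_n(x) give the
drift S1(x) and noise intensity S2(x) of the coarse-grained dynamics,

    S1 = sum_n P_n sum_m kbar_m lambda_m^(1) + k3 dx,
    S2 = sum_n P_n sum_m kbar_m lambda_m^(2) + k3 dx^2,
    D_eff = S2 / 2,     v_eff = S1 - dD_eff/dx.

Unbinding of the last leg (m = 2 at n = 1) is a terminal detachment event:
it contributes to the death rate d_1 and to the cargo unbinding rate
k_off = 1/t_dwell, but contributes no centre displacement (the 1/(n-1)
prefactor is never evaluated at n = 1).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import CargoModel, Domain

__all__ = [
    "BoundLegDistribution",
    "uniform_bound_legs",
    "empirical_bound_legs",
    "MeanFieldTables",
    "FixedPoint",
    "displacement_moment",
    "mean_event_rate",
    "birth_death_rates",
    "mean_dwell_time",
    "mean_dwell_time_linear_solve",
    "steady_state_Pn",
    "drift_and_noise",
    "effective_tables",
    "small_cargo_drift",
    "edge_drift",
    "find_fixed_points",
]

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


class TerminalEventError(ValueError):
    """Raised when a centre displacement is requested for a terminal event."""


def _window_rate_moments(profile, x_a: float, L: float, domain: Optional[Domain]):
    """(I0, I1, I2): Int kappa(y) (y-x_a)^i S_H(y|x_a) dy for i = 0, 1, 2.

    Gauss-Legendre quadrature over [x_a - L, x_a + L], split at profile
    support edges and breakpoints.  On periodic domains the profile is
    evaluated at wrapped coordinates (smooth profiles assumed there).
    """

    lo, hi = x_a - L, x_a + L
    cuts = [lo, hi]
    if domain is None or not domain.periodic:
        pts = list(profile.breakpoints)
        if profile.support is not None:
            pts.extend(profile.support)
        cuts.extend(p for p in pts if lo < p < hi)
    cuts = np.unique(np.asarray(cuts, dtype=float))
    I = np.zeros(3)
    for a, b in zip(cuts[:-1], cuts[1:]):
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        y = mid + half * _GL_NODES
        yy = domain.wrap(y) if (domain is not None and domain.periodic) else y
        vals = profile(yy) * (half * _GL_WEIGHTS)
        u = y - x_a
        I[0] += vals.sum()
        I[1] += (vals * u).sum()
        I[2] += (vals * u * u).sum()
    return I / (2.0 * L)


class BoundLegDistribution:
    """Mean-field density P_b(u | n) of a bound leg's position relative to
    the cargo centre, per leg count n.

    For n = 1 the single bound leg *is* the centre, so P_b is a point mass
    at u = 0 in every mode.  The ``uniform_surrogate`` mode replaces P_b by
    the shape factor itself (a uniform density on [-L, L]); ``empirical``
    and ``fitted`` carry per-n densities on a grid over [-L, L].

    Because the centre is defined as the mean bound-leg position, the true
    P_b always has zero mean.  Near a substrate edge a naive uniform
    surrogate clipped by the edge would violate this and fabricate an
    outward unbinding drift; passing ``edge=(x_edge, side)`` makes the
    surrogate a symmetric uniform density on [-b, b] with
    b = min(L, |x_edge - x_a|), which respects both the edge support and
    the zero-mean constraint.
    """

    def __init__(self, L: float, provenance: str, u_grid=None, densities=None,
                 meta=None, edge=None):
        if provenance not in ("uniform_surrogate", "empirical", "fitted"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self.L = float(L)
        self.provenance = provenance
        self.u_grid = None if u_grid is None else np.asarray(u_grid, dtype=float)
        self.densities = densities or {}
        self.meta = meta or {}
        if edge is not None and edge[1] not in ("left", "right"):
            raise ValueError("edge side must be 'left' or 'right'")
        self.edge = edge

    def _half_width(self, x_a: float) -> float:
        if self.edge is None:
            return self.L
        x_edge, side = self.edge
        dist = (x_edge - x_a) if side == "right" else (x_a - x_edge)
        return min(self.L, max(dist, 1e-9 * self.L))

    # -- densities ---------------------------------------------------------
    def density(self, u, n: int):
        u = np.asarray(u, dtype=float)
        if n == 1:
            raise ValueError("P_b(u | n=1) is a point mass at u = 0")
        if self.provenance == "uniform_surrogate":
            return np.where(np.abs(u) <= self.L, 1.0 / (2.0 * self.L), 0.0)
        dens = self._density_array(n)
        return np.interp(u, self.u_grid, dens, left=0.0, right=0.0)

    def _density_array(self, n: int):
        if n in self.densities:
            return self.densities[n]
        if not self.densities:
            raise ValueError("no densities stored")
        # fall back to the closest available leg count
        avail = sorted(self.densities)
        key = min(avail, key=lambda k: abs(k - n))
        return self.densities[key]

    # -- integrals against kappa2 ------------------------------------------
    def kappa2_moments(self, model: CargoModel, x_a: float, n: int):
        """(K0, K1, K2): Int kappa2(x_a + u) u^i P_b(u | n) du for i = 0, 1, 2."""
        if n <= 0:
            raise ValueError("need n >= 1")
        if n == 1:
            return np.array([float(model.kappa2_at(x_a)), 0.0, 0.0])
        if self.provenance == "uniform_surrogate":
            return _window_rate_moments(model.kappa2, x_a, self._half_width(x_a), model.domain)
        u = self.u_grid
        dens = self._density_array(n)
        k2 = np.asarray(model.kappa2_at(x_a + u), dtype=float)
        w = k2 * dens
        return np.array(
            [
                np.trapezoid(w, u),
                np.trapezoid(w * u, u),
                np.trapezoid(w * u * u, u),
            ]
        )

    def mean_offset(self, n: int) -> float:
        """I(n) = Int u P_b(u | n) du (0 for symmetric distributions)."""
        if n == 1:
            return 0.0
        if self.provenance == "uniform_surrogate":
            return 0.0
        u = self.u_grid
        return float(np.trapezoid(u * self._density_array(n), u))

    def partial_mean(self, n: int, lo: float, hi: float) -> float:
        """Int_lo^hi u P_b(u | n) du over the relative coordinate."""
        if n == 1:
            return 0.0
        if self.provenance == "uniform_surrogate":
            a, b = max(lo, -self.L), min(hi, self.L)
            if b <= a:
                return 0.0
            return (b * b - a * a) / (4.0 * self.L)
        u = self.u_grid
        mask = (u >= lo) & (u <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(u[mask] * self._density_array(n)[mask], u[mask]))


def uniform_bound_legs(L: float = 1.0, edge=None) -> BoundLegDistribution:
    """P_b = S_H: every bound leg uniformly distributed over the footprint.

    ``edge=(x_edge, "left"|"right")`` enables the edge-aware symmetric
    variant for cargo near the end of a finite substrate.
    """
    return BoundLegDistribution(L, "uniform_surrogate", edge=edge)


def empirical_bound_legs(u_grid, densities: dict, L: float, provenance: str = "empirical") -> BoundLegDistribution:
    """Wrap per-n histogram densities (normalized over [-L, L])."""
    u_grid = np.asarray(u_grid, dtype=float)
    dens = {}
    for n, d in densities.items():
        d = np.asarray(d, dtype=float)
        mass = np.trapezoid(d, u_grid)
        if mass <= 0:
            raise ValueError(f"degenerate density for n={n}")
        dens[int(n)] = d / mass
    return BoundLegDistribution(L, provenance, u_grid=u_grid, densities=dens)


# ---------------------------------------------------------------------------
# Event-level moments and rates
# ---------------------------------------------------------------------------

def displacement_moment(
    m: int, i: int, x_a: float, n: int, model: CargoModel, pb: BoundLegDistribution
) -> float:
    """i-th moment of the cargo-centre displacement for one event of type m."""
    if i not in (1, 2):
        raise ValueError("moment order i must be 1 or 2")
    if m == 3:
        return model.k3_step**i
    if m == 1:
        if n >= model.N:
            raise ValueError("binding displacement undefined at n = N (no free legs)")
        I = _window_rate_moments(model.kappa1, x_a, model.L, model.domain)
        if I[0] <= 0:
            raise ValueError("no binding events possible: zero total binding rate")
        return (1.0 / (n + 1)) ** i * I[i] / I[0]
    if m == 2:
        if n <= 1:
            raise TerminalEventError(
                "unbinding at n = 1 detaches the cargo and displaces nothing"
            )
        K = pb.kappa2_moments(model, x_a, n)
        if K[0] <= 0:
            raise ValueError("no unbinding events possible: zero total unbinding rate")
        return ((-1.0) ** i) * K[i] / ((n - 1) ** i * K[0])
    raise ValueError(f"unknown event type m={m}")


def mean_event_rate(m: int, x_a: float, n: int, model: CargoModel, pb: BoundLegDistribution) -> float:
    """Mean rate of events of type m for a cargo at x_a with n legs bound."""
    if not 0 <= n <= model.N:
        raise ValueError("need 0 <= n <= N")
    if m == 3:
        return model.k3_rate
    if m == 1:
        I0 = _window_rate_moments(model.kappa1, x_a, model.L, model.domain)[0]
        return (model.N - n) * I0
    if m == 2:
        if n == 0:
            return 0.0
        return n * pb.kappa2_moments(model, x_a, n)[0]
    raise ValueError(f"unknown event type m={m}")


def birth_death_rates(x: float, model: CargoModel, pb: BoundLegDistribution):
    """Local birth-death chain in the leg count at fixed centre position.

    Returns ``(b, d)`` with ``b[n]`` the binding rate from n legs
    (n = 0..N-1) and ``d[n-1]`` the unbinding rate from n legs (n = 1..N).
    """
    N = model.N
    I0 = _window_rate_moments(model.kappa1, x, model.L, model.domain)[0]
    b = np.array([(N - n) * I0 for n in range(N)])
    d = np.array([n * pb.kappa2_moments(model, x, n)[0] for n in range(1, N + 1)])
    return b, d


def mean_dwell_time(x: float, model: CargoModel, pb: BoundLegDistribution) -> float:
    """Mean first-passage time of the leg-count chain from n = 1 to n = 0.

    T = sum_{n=1}^{N} (1/d_n) prod_{j=1}^{n-1} (b_j / d_j).
    Returns ``inf`` if any death rate vanishes.
    """
    b, d = birth_death_rates(x, model, pb)
    return dwell_time_from_rates(b, d)


def dwell_time_from_rates(b, d) -> float:
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    N = d.size
    if np.any(d <= 0):
        return math.inf
    T = 0.0
    prod = 1.0
    for n in range(1, N + 1):
        T += prod / d[n - 1]
        if n < N:
            prod *= b[n] / d[n - 1]  # b[n]: binding from n legs; d[n-1]: unbinding from n
    return T


def mean_dwell_time_linear_solve(b, d) -> float:
    """Independent oracle: mean absorption time from state 1 by solving
    the linear system of the absorbing birth-death generator."""
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    N = d.size
    A = np.zeros((N, N))
    for n in range(1, N + 1):
        i = n - 1
        up = b[n] if n < N else 0.0
        A[i, i] = -(up + d[n - 1])
        if n < N:
            A[i, i + 1] = up
        if n > 1:
            A[i, i - 1] = d[n - 1]
    tau = np.linalg.solve(A, -np.ones(N))
    return float(tau[0])


def steady_state_Pn(
    x: float, model: CargoModel, pb: BoundLegDistribution, mode: str = "reflecting"
):
    """Steady-state probability of having n legs bound (n = 1..N) at x.

    ``reflecting``: stationary distribution of the chain restricted to
    {1..N} (detailed balance).  ``quasi_stationary``: normalized leading
    left eigenvector of the generator with absorption at n = 0, i.e. the
    leg-count distribution conditioned on survival.
    """
    b, d = birth_death_rates(x, model, pb)
    return _pn_from_rates(b, d, mode)


def _pn_from_rates(b, d, mode: str):
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    N = d.size
    if N == 1:
        return np.array([1.0])
    if mode == "reflecting":
        w = np.empty(N)
        w[0] = 1.0
        for n in range(2, N + 1):
            if d[n - 1] <= 0:
                raise ValueError("degenerate chain: zero death rate")
            w[n - 1] = w[n - 2] * b[n - 1] / d[n - 1]
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("degenerate chain")
        return w / s
    if mode == "quasi_stationary":
        Q = np.zeros((N, N))
        for n in range(1, N + 1):
            i = n - 1
            up = b[n] if n < N else 0.0
            Q[i, i] = -(up + d[n - 1])
            if n < N:
                Q[i, i + 1] = up
            if n > 1:
                Q[i, i - 1] = d[n - 1]
        vals, vecs = np.linalg.eig(Q.T)
        k = int(np.argmax(vals.real))
        v = vecs[:, k].real
        v = np.abs(v)
        return v / v.sum()
    raise ValueError(f"unknown P_n mode {mode!r}")


# ---------------------------------------------------------------------------
# Drift and noise fields
# ---------------------------------------------------------------------------

def drift_and_noise(
    x: float,
    model: CargoModel,
    pb: BoundLegDistribution,
    Pn=None,
    pn_mode: str = "reflecting",
):
    """(S1, S2): event-rate-weighted first and second displacement moments.

    ``Pn`` may be supplied (e.g. empirically estimated); otherwise the
    steady-state distribution in ``pn_mode`` is used.
    """
    N = model.N
    I = _window_rate_moments(model.kappa1, x, model.L, model.domain)
    if Pn is None:
        d = np.array([n * pb.kappa2_moments(model, x, n)[0] for n in range(1, N + 1)])
        b = np.array([(N - n) * I[0] for n in range(N)])
        Pn = _pn_from_rates(b, d, pn_mode)
    Pn = np.asarray(Pn, dtype=float)
    S1 = 0.0
    S2 = 0.0
    for n in range(1, N + 1):
        p = Pn[n - 1]
        if p == 0.0:
            continue
        # m = 1: kbar_1 lambda_1^(i) = (N-n)/(n+1)^i * I_i
        if n < N:
            S1 += p * (N - n) * I[1] / (n + 1)
            S2 += p * (N - n) * I[2] / (n + 1) ** 2
        # m = 2 (n >= 2): kbar_2 lambda_2^(i) = n (-1)^i K_i / (n-1)^i
        if n >= 2:
            K = pb.kappa2_moments(model, x, n)
            S1 -= p * n * K[1] / (n - 1)
            S2 += p * n * K[2] / (n - 1) ** 2
    S1 += model.k3_rate * model.k3_step
    S2 += model.k3_rate * model.k3_step**2
    return float(S1), float(S2)


@dataclasses.dataclass
class MeanFieldTables:
    """Gridded mean-field quantities for one model."""

    x: np.ndarray
    Pn: np.ndarray          # (nx, N)
    S1: np.ndarray
    S2: np.ndarray
    D_eff: np.ndarray
    v_eff: np.ndarray
    k_off: np.ndarray
    model: CargoModel
    pb: BoundLegDistribution
    pn_mode: str = "reflecting"

    def _interp(self, field, xq):
        dom = self.model.domain
        xq = dom.wrap(xq) if dom.periodic else xq
        return np.interp(xq, self.x, field)

    def S1_at(self, xq):
        return self._interp(self.S1, xq)

    def S2_at(self, xq):
        return np.maximum(self._interp(self.S2, xq), 0.0)

    def v_eff_at(self, xq):
        return self._interp(self.v_eff, xq)

    def D_eff_at(self, xq):
        return np.maximum(self._interp(self.D_eff, xq), 0.0)

    def k_off_at(self, xq):
        return np.maximum(self._interp(self.k_off, xq), 0.0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.x,
                "S1": self.S1,
                "S2": self.S2,
                "v_eff": self.v_eff,
                "D_eff": self.D_eff,
                "k_off": self.k_off,
            }
        )
        for n in range(1, self.Pn.shape[1] + 1):
            df[f"P_n{n}"] = self.Pn[:, n - 1]
        return df

    def to_csv(self, path, header_path=None):
        self.to_frame().to_csv(path, index=False)
        if header_path is not None:
            from .config import model_to_spec

            with open(header_path, "w") as fh:
                json.dump(
                    {"model": model_to_spec(self.model), "pb": self.pb.provenance,
                     "pn_mode": self.pn_mode},
                    fh, indent=2,
                )


def effective_tables(
    grid,
    model: CargoModel,
    pb: BoundLegDistribution,
    pn_mode: str = "reflecting",
    Pn_empirical=None,
) -> MeanFieldTables:
    """Fill the mean-field tables on ``grid``.

    ``Pn_empirical``: optional (nx, N) array of measured leg-count
    probabilities to use in place of the chain steady state.
    """
    x = np.asarray(grid, dtype=float)
    N = model.N
    nx = x.size
    Pn = np.empty((nx, N))
    S1 = np.empty(nx)
    S2 = np.empty(nx)
    k_off = np.empty(nx)
    for j, xj in enumerate(x):
        b, d = birth_death_rates(xj, model, pb)
        if Pn_empirical is not None:
            Pn[j] = Pn_empirical[j]
        else:
            Pn[j] = _pn_from_rates(b, d, pn_mode)
        S1[j], S2[j] = drift_and_noise(xj, model, pb, Pn=Pn[j])
        T = dwell_time_from_rates(b, d)
        k_off[j] = 0.0 if not math.isfinite(T) else 1.0 / T
    D = S2 / 2.0
    dD = np.gradient(D, x)
    v = S1 - dD
    return MeanFieldTables(
        x=x, Pn=Pn, S1=S1, S2=S2, D_eff=D, v_eff=v, k_off=k_off,
        model=model, pb=pb, pn_mode=pn_mode,
    )


def small_cargo_drift(
    x: float,
    model: CargoModel,
    pb: BoundLegDistribution,
    Pn=None,
    pn_mode: str = "reflecting",
) -> float:
    """Leading-order drift for cargo small against the rate variation scale:

    S1(x) ~= sum_n P_n [ (N-n) L^2 kappa1'(x) / (3(n+1))
                         - (n/(n-1)) kappa2(x) I(x, n) ] + k3 dx,

    with I(x, n) the mean bound-leg offset; the terminal n = 1 unbinding
    term is omitted.  Requires an analytic derivative of kappa1.
    """
    if model.kappa1.derivative_fn is None:
        raise ValueError("small-cargo drift needs an analytic kappa1 derivative")
    N, L = model.N, model.L
    if Pn is None:
        Pn = steady_state_Pn(x, model, pb, mode=pn_mode)
    dk1 = float(model.kappa1.derivative(model.domain.wrap(x)))
    k2x = float(model.kappa2_at(x))
    S1 = 0.0
    for n in range(1, N + 1):
        p = Pn[n - 1]
        term = (N - n) * L * L * dk1 / (3.0 * (n + 1))
        if n >= 2:
            term -= (n / (n - 1)) * k2x * pb.mean_offset(n)
        S1 += p * term
    return float(S1 + model.k3_rate * model.k3_step)


def edge_drift(
    x: float,
    model: CargoModel,
    pb: BoundLegDistribution,
    Pn=None,
    x_edge: float = 0.0,
    side: str = "right",
    pn_mode: str = "reflecting",
    return_components: bool = False,
):
    """Drift of a cargo overhanging a substrate edge, for rates uniform
    inside the substrate:

    S1(x) = sum_n P_n [ +/- (N-n) kappa1 ((x_edge - x)^2 - L^2) / (4 L (n+1))
                        - (n kappa2/(n-1)) J_+/- ] + k3 dx.

    ``side``: "right" (+) or "left" (-) edge.  J_+ integrates (y - x) P_b
    from the substrate interior up to the edge; J_- from the edge inward.
    The binding term vanishes when the cargo is fully interior.
    """
    N, L = model.N, model.L
    sign = {"right": 1.0, "left": -1.0}[side]
    # rate values inside the substrate (uniform there by assumption)
    x_in = x_edge - sign * 2.0 * L
    k1 = float(model.kappa1(x_in))
    k2 = float(model.kappa2(x_in))
    if Pn is None:
        Pn = steady_state_Pn(x, model, pb, mode=pn_mode)
    u_edge = x_edge - x
    overlap = u_edge**2 - L * L if abs(u_edge) < L else 0.0
    binding = 0.0
    unbinding = 0.0
    for n in range(1, N + 1):
        p = Pn[n - 1]
        binding += p * sign * (N - n) * k1 * overlap / (4.0 * L * (n + 1))
        if n >= 2:
            if side == "right":
                J = pb.partial_mean(n, -L, u_edge)
            else:
                J = pb.partial_mean(n, u_edge, L)
            unbinding -= p * (n * k2 / (n - 1)) * J
    total = float(binding + unbinding + model.k3_rate * model.k3_step)
    if return_components:
        return {"binding": float(binding), "unbinding": float(unbinding), "total": total}
    return total


@dataclasses.dataclass(frozen=True)
class FixedPoint:
    x: float
    stable: bool


def find_fixed_points(tables: MeanFieldTables, refine: bool = True, atol: Optional[float] = None):
    """Zeros of S1 on the table grid, with linear stability from the slope.

    Drift values below ``atol`` (default: 1e-9 of the field maximum, floored
    at 1e-12) are treated as exactly zero so that quadrature round-off in
    flat regions does not create spurious roots.  Sign changes between
    significant nodes are refined by root-finding on the full drift
    computation; a run of zeros bracketed by opposite signs yields a root
    at its midpoint.
    """
    x, S1 = tables.x, np.asarray(tables.S1, dtype=float)
    if atol is None:
        atol = max(1e-12, 1e-9 * float(np.max(np.abs(S1), initial=0.0)))
    s = np.where(np.abs(S1) < atol, 0.0, S1)
    nz = np.nonzero(s)[0]
    out = []

    def f(xx):
        return drift_and_noise(xx, tables.model, tables.pb, pn_mode=tables.pn_mode)[0]

    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        a, b = s[i], s[j]
        if a * b >= 0.0:
            continue
        if refine and j == i + 1:
            root = brentq(f, x[i], x[j], xtol=1e-12)
        elif j == i + 1:
            root = x[i] - a * (x[j] - x[i]) / (b - a)
        else:
            root = 0.5 * (x[i] + x[j])  # flat-zero run between the brackets
        out.append(FixedPoint(float(root), stable=bool(b < a)))
    return out
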