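"""Microtubule plus-end tracking application.

End-binding proteins (EBs) bind preferentially near the growing tip of a
microtubule, producing a comet-shaped enhancement of the effective leg
binding rate (and a reduction of the unbinding rate) in the tip region.
Working in the co-moving frame of a tip growing at ``v_MT``, positions are
measured relative to the tip: the lattice occupies x <= x_edge = 0 and the
frame motion enters as the collective leg displacement event with
``-k3_rate * k3_step = v_MT`` (legs are swept away from the tip, towards
the lattice, in steps of one tubulin dimer length by default).

A cargo tip-tracks when the effective velocity generated by leg binding
and unbinding can counter-balance the growth velocity, i.e. when the full
drift S1(x) (including the frame term) has a stable zero behind the tip.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .model import CargoModel, Domain
from .profiles import RateProfile
from . import meanfield

__all__ = [
    "comet_profile",
    "load_eb_params",
    "example_params_path",
    "build_eb_rate_profiles",
    "make_tip_model",
    "TipModel",
    "ScanResult",
    "scan_tip_tracking",
    "force_estimate",
]

KB_PN_NM_PER_K = 0.01380649  # Boltzmann constant in pN nm / K
TUBULIN_DIMER_NM = 8.0

_REQUIRED_PARAMS = (
    "kappa1_tip",
    "kappa1_lattice",
    "kappa2_tip",
    "kappa2_lattice",
    "comet_length",
    "x_edge",
    "v_MT",
)


def comet_profile(
    tip_rate: float,
    lattice_rate: float,
    decay_length: float,
    x_edge: float = 0.0,
    lattice_extent: float = 5000.0,
) -> RateProfile:
    """Exponential comet behind the tip plus a lattice baseline:

        kappa(x) = lattice + (tip - lattice) exp((x - x_edge)/decay_length)

    for x <= x_edge, zero beyond the tip.  Rates in 1/s, lengths in nm.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    tip, lat, ell, xe = map(float, (tip_rate, lattice_rate, decay_length, x_edge))

    def value(x):
        x = np.asarray(x, dtype=float)
        return lat + (tip - lat) * np.exp(np.minimum((x - xe) / ell, 0.0))

    def deriv(x):
        x = np.asarray(x, dtype=float)
        return (tip - lat) / ell * np.exp(np.minimum((x - xe) / ell, 0.0))

    return RateProfile(
        kind="comet",
        value_fn=value,
        derivative_fn=deriv,
        support=(xe - lattice_extent, xe),
        params={
            "tip_rate": tip, "lattice_rate": lat, "decay_length": ell,
            "x_edge": xe, "lattice_extent": float(lattice_extent),
        },
        breakpoints=(xe,),
    )


def example_params_path() -> Path:
    """Packaged synthetic example of an EB-microtubule rate parameter file."""
    return Path(__file__).parent / "data" / "eb_tip_params_synthetic.yaml"


def load_eb_params(path) -> dict:
    with open(path) as fh:
        params = yaml.safe_load(fh)
    missing = [k for k in _REQUIRED_PARAMS if k not in params]
    if missing:
        raise KeyError(f"EB parameter file missing required field(s): {missing}")
    return params


def build_eb_rate_profiles(params: dict):
    """(kappa1, kappa2) profiles in the tip frame from an EB parameter set.

    ``kappa1`` is enhanced in the comet region; ``kappa2`` interpolates
    from its (smaller) tip value to the lattice value over the same decay
    length.  Both vanish beyond the tip (x > x_edge).
    """
    missing = [k for k in _REQUIRED_PARAMS if k not in params]
    if missing:
        raise KeyError(f"EB parameter set missing required field(s): {missing}")
    ell = float(params["comet_length"])
    xe = float(params["x_edge"])
    extent = float(params.get("lattice_extent", 5000.0))
    kappa1 = comet_profile(params["kappa1_tip"], params["kappa1_lattice"], ell, xe, extent)
    ell2 = float(params.get("comet_length_unbinding", ell))
    kappa2 = comet_profile(params["kappa2_tip"], params["kappa2_lattice"], ell2, xe, extent)
    return kappa1, kappa2


@dataclasses.dataclass
class TipModel:
    """Cargo model in the tip frame (nm, s) plus the growth velocity."""

    model: CargoModel
    v_MT: float
    x_edge: float


def make_tip_model(params: dict, N: int, L: float, step_nm: float = TUBULIN_DIMER_NM) -> TipModel:
    """Build a cargo model in physical units from an EB parameter set.

    The frame drift is implemented as collective leg displacements of
    ``-step_nm`` (one tubulin dimer towards the lattice) at a rate
    ``v_MT / step_nm`` so that -k3_rate * k3_step = v_MT.
    """
    kappa1, kappa2 = build_eb_rate_profiles(params)
    v_mt = float(params["v_MT"])
    xe = float(params["x_edge"])
    extent = float(params.get("lattice_extent", 5000.0))
    domain = Domain(lo=xe - extent, hi=xe, mode="edged")
    model = CargoModel(
        N=N,
        kappa1=kappa1,
        kappa2=kappa2,
        L=float(L),
        k3_rate=v_mt / step_nm,
        k3_step=-step_nm,
        dim=1,
        domain=domain,
    )
    return TipModel(model=model, v_MT=v_mt, x_edge=xe)


@dataclasses.dataclass
class ScanResult:
    """Tip-tracking scan over leg count N and cargo diameter 2L."""

    Ns: np.ndarray
    diameters: np.ndarray
    max_drive: np.ndarray      # (nN, nL): max over x of the binding/unbinding drift
    min_S1: np.ndarray         # min over x of the same field
    tracking: np.ndarray       # bool: stable fixed point of the full drift exists
    fixed_points: list         # per (N, L): list of meanfield.FixedPoint
    v_MT: float

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, N in enumerate(self.Ns):
            for j, d in enumerate(self.diameters):
                rows.append(
                    {
                        "N": int(N), "diameter": float(d),
                        "max_drive": self.max_drive[i, j],
                        "min_S1": self.min_S1[i, j],
                        "tracking": bool(self.tracking[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _tip_grid(tip: TipModel, L: float, span: float = 6.0, spacing_frac: float = 0.1):
    ell = tip.model.kappa1.params.get("decay_length", 100.0)
    reach = max(span * ell, 4.0 * L)
    return np.arange(tip.x_edge - reach, tip.x_edge + 1e-9, min(L * spacing_frac, ell / 10.0))


def scan_tip_tracking(
    params: dict,
    Ns: Sequence[int],
    diameters: Sequence[float],
    engine: str = "meanfield",
    n_cargo: int = 2000,
    t_max: float = 20.0,
    seed: int = 0,
    pb=None,
) -> ScanResult:
    """Classify tip-tracking over a grid of leg counts and cargo sizes.

    For each (N, 2L) the binding/unbinding drift field S1(x) is computed
    (mean-field with the uniform-surrogate bound-leg distribution, or
    empirically from Gillespie ensembles), the frame term -v_MT is added,
    and the cell is classified as tracking when the full drift has a
    stable zero behind the tip, i.e. when max_x S1_bind(x) >= v_MT.
    """
    Ns = np.asarray(list(Ns), dtype=int)
    diameters = np.asarray(list(diameters), dtype=float)
    max_drive = np.empty((Ns.size, diameters.size))
    min_S1 = np.empty_like(max_drive)
    tracking = np.zeros(max_drive.shape, dtype=bool)
    fps = []
    v_mt = float(params["v_MT"])
    for i, N in enumerate(Ns):
        for j, d in enumerate(diameters):
            L = d / 2.0
            tip = make_tip_model(params, int(N), L)
            grid = _tip_grid(tip, L)
            if engine == "meanfield":
                use_pb = pb if pb is not None else meanfield.uniform_bound_legs(
                    L, edge=(tip.x_edge, "right")
                )
                tables = meanfield.effective_tables(grid, tip.model, use_pb)
                S1_full = tables.S1
            elif engine == "gillespie":
                from .gillespie import simulate_ensemble
                from .analysis import empirical_drift_noise

                ens = simulate_ensemble(
                    tip.model, n_cargo, t_max, master_seed=seed + 1000 * i + j,
                    x0_mode="kappa1",
                )
                edges = np.linspace(grid[0], grid[-1], 81)
                field = empirical_drift_noise(ens, edges, smoothing=5)
                S1_full = field.S1
                grid = field.x
                tables = None
            else:
                raise ValueError(f"unknown engine {engine!r}")
            drive = S1_full + v_mt  # remove the frame term: binding/unbinding only
            max_drive[i, j] = np.nanmax(drive)
            min_S1[i, j] = np.nanmin(S1_full)
            if tables is not None:
                pts = meanfield.find_fixed_points(tables)
            else:
                pts = _fixed_points_from_grid(grid, S1_full)
            fps.append(pts)
            tracking[i, j] = any(p.stable for p in pts) and max_drive[i, j] >= v_mt
    return ScanResult(
        Ns=Ns, diameters=diameters, max_drive=max_drive, min_S1=min_S1,
        tracking=tracking, fixed_points=fps, v_MT=v_mt,
    )


def _fixed_points_from_grid(x, S1):
    out = []
    S1 = np.asarray(S1, dtype=float)
    ok = np.isfinite(S1)
    x, S1 = x[ok], S1[ok]
    for i in range(len(x) - 1):
        if S1[i] * S1[i + 1] < 0:
            root = x[i] - S1[i] * (x[i + 1] - x[i]) / (S1[i + 1] - S1[i])
            out.append(meanfield.FixedPoint(float(root), stable=bool(S1[i + 1] < S1[i])))
    return out


def force_estimate(tables: meanfield.MeanFieldTables, temperature: float = 310.15):
    """Effective force profile F(x) = k_B T v_eff(x) / D_eff(x), in pN.

    ``tables`` must be in physical units (nm, s); bins with vanishing
    diffusivity are masked to NaN.
    """
    kBT = KB_PN_NM_PER_K * float(temperature)
    D = np.asarray(tables.D_eff, dtype=float)
    v = np.asarray(tables.v_eff, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(D > 0, kBT * v / D, np.nan)
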