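"""Canonical desk-scale scenario configurations used by tests and the CLI.

Each fixture mirrors one of the headline model settings: uniform rates,
the central high-binding-rate bump (1D and 2D), a finite-substrate edge,
and the EB tip-tracking setup.  Sizes are deliberately small; scale
``n_cargo``/``t_max`` up for production runs.
"""

from __future__ import annotations

from .config import RunConfig

__all__ = ["make_fixture", "FIXTURE_NAMES"]

_BUMP = {"kind": "logistic_bump", "params": {"amplitude": 4.0, "baseline": 1.0, "width": 2.0, "exponent": 6.0}}
_BUMP_2D = {"kind": "logistic_bump_2d", "params": {"amplitude": 4.0, "baseline": 1.0, "scale": 4.0, "exponent": 3.0}}
_UNIFORM = {"kind": "uniform", "params": {"rate": 1.0}}


def _cfg(name, model, **kw):
    return RunConfig(scenario=name, model=model, **kw)


def make_fixture(name: str) -> RunConfig:
    if name not in _BUILDERS:
        raise ValueError(f"unknown scenario {name!r}; known: {sorted(_BUILDERS)}")
    return _BUILDERS[name]()


def _uniform_model(N, **kw):
    spec = {
        "N": N, "L": 1.0, "kappa1": _UNIFORM, "kappa2": _UNIFORM,
        "domain": {"lo": -10.0, "hi": 10.0, "mode": "periodic"},
    }
    spec.update(kw)
    return spec


def _bump_model(N, **kw):
    spec = {
        "N": N, "L": 1.0, "kappa1": _BUMP, "kappa2": _UNIFORM,
        "domain": {"lo": -10.0, "hi": 10.0, "mode": "periodic"},
    }
    spec.update(kw)
    return spec


_BUILDERS = {
    "uniform_N4": lambda: _cfg(
        "uniform_N4", _uniform_model(4), n_cargo=500, t_max=20.0, seed=1,
        x0_mode="uniform", analyses=("msd",),
    ),
    "uniform_sweep": lambda: _cfg(
        "uniform_sweep", _uniform_model(4), n_cargo=300, t_max=15.0, seed=2,
        analyses=("msd",),
    ),
    "bump_N4": lambda: _cfg(
        "bump_N4", _bump_model(4), n_cargo=500, t_max=30.0, seed=3,
        analyses=("density", "fields"),
    ),
    "bump_N4_drift": lambda: _cfg(
        "bump_N4_drift", _bump_model(4, k3_rate=2.0, k3_step=0.05),
        n_cargo=500, t_max=30.0, seed=4, analyses=("density",),
    ),
    "edge_uniform": lambda: _cfg(
        "edge_uniform",
        {
            "N": 6, "L": 1.0,
            "kappa1": {"kind": "uniform", "params": {"rate": 1.0}, "support": [-20.0, 0.0]},
            "kappa2": _UNIFORM,
            "domain": {"lo": -20.0, "hi": 2.0, "mode": "edged"},
        },
        n_cargo=300, t_max=20.0, seed=5, x0_mode="kappa1", analyses=("fields",),
    ),
    "bump_2d": lambda: _cfg(
        "bump_2d",
        {
            "N": 4, "L": 1.0, "dim": 2, "kappa1": _BUMP_2D, "kappa2": _UNIFORM,
            "domain": {"lo": -6.0, "hi": 6.0, "mode": "periodic"},
        },
        engine="gillespie2d", n_cargo=400, t_max=20.0, seed=6, analyses=("field2d",),
    ),
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))
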