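"""Run configuration: serializable model specs, YAML round-trips, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Optional

import yaml

from .model import CargoModel, Domain
from .profiles import make_rate_profile, profile_to_spec

__all__ = ["RunConfig", "model_from_spec", "model_to_spec", "config_hash"]


def model_from_spec(spec: dict) -> CargoModel:
    """Build a CargoModel from a plain mapping (inverse of model_to_spec)."""
    if not isinstance(spec, dict):
        raise ValueError("model spec must be a mapping")
    for field in ("N", "kappa1", "kappa2"):
        if field not in spec:
            raise ValueError(f"model spec missing required field {field!r}")
    dom = spec.get("domain", {})
    domain = Domain(
        lo=float(dom.get("lo", -10.0)),
        hi=float(dom.get("hi", 10.0)),
        mode=dom.get("mode", "periodic"),
    )
    return CargoModel(
        N=int(spec["N"]),
        kappa1=make_rate_profile(spec["kappa1"]),
        kappa2=make_rate_profile(spec["kappa2"]),
        L=float(spec.get("L", 1.0)),
        k3_rate=float(spec.get("k3_rate", 0.0)),
        k3_step=float(spec.get("k3_step", 0.05)),
        dim=int(spec.get("dim", 1)),
        domain=domain,
    )


def model_to_spec(model: CargoModel) -> dict:
    return {
        "N": model.N,
        "L": model.L,
        "kappa1": profile_to_spec(model.kappa1),
        "kappa2": profile_to_spec(model.kappa2),
        "k3_rate": model.k3_rate,
        "k3_step": model.k3_step,
        "dim": model.dim,
        "domain": {"lo": model.domain.lo, "hi": model.domain.hi, "mode": model.domain.mode},
    }


@dataclasses.dataclass
class RunConfig:
    """One reproducible run: scenario, model, engine, sizes, seed."""

    scenario: str
    model: dict
    engine: str = "gillespie"
    n_cargo: int = 1000
    t_max: float = 20.0
    seed: int = 0
    x0_mode: str = "uniform"
    analyses: tuple = ()
    out_dir: Optional[str] = None

    def build_model(self) -> CargoModel:
        return model_from_spec(self.model)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        if "analyses" in d:
            d["analyses"] = tuple(d["analyses"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
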