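"""Serialization glue: event tables as CSV with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import model_to_spec
from .gillespie import Ensemble, Trajectory
from .model import CargoModel

__all__ = ["ensemble_to_frame", "write_ensemble", "read_ensemble"]


def ensemble_to_frame(ensemble: Ensemble) -> pd.DataFrame:
    """Concatenated event table: traj, t, m, x_event, n, x_a (one row per event)."""
    frames = []
    for i, tr in enumerate(ensemble):
        frames.append(
            pd.DataFrame(
                {
                    "traj": i,
                    "t": tr.times,
                    "m": tr.m,
                    "x_event": tr.x_event,
                    "n": tr.n_after,
                    "x_a": tr.x_after,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["traj", "t", "m", "x_event", "n", "x_a"])
    return pd.concat(frames, ignore_index=True)


def write_ensemble(ensemble: Ensemble, path, manifest_extra=None):
    """Write the event table plus a JSON sidecar with model config and seeds."""
    path = Path(path)
    ensemble_to_frame(ensemble).to_csv(path, index=False, float_format="%.12g")
    sidecar = {
        "model": model_to_spec(ensemble.model),
        "master_seed": ensemble.master_seed,
        "count": len(ensemble),
        "t_max": ensemble.trajectories[0].t_max if len(ensemble) else None,
        "x0": [tr.x0 for tr in ensemble],
        "detached": [bool(tr.detached) for tr in ensemble],
    }
    if manifest_extra:
        sidecar.update(manifest_extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_ensemble(path) -> Ensemble:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    from .config import model_from_spec

    model = model_from_spec(meta["model"])
    t_max = meta["t_max"]
    trajs = []
    grouped = dict(iter(df.groupby("traj"))) if len(df) else {}
    for i in range(meta["count"]):
        g = grouped.get(i)
        if g is None:
            arr = lambda dtype=float: np.empty(0, dtype=dtype)
            trajs.append(
                Trajectory(
                    x0=meta["x0"][i], times=arr(), m=arr(np.int8), x_event=arr(),
                    n_after=arr(np.int16), x_after=arr(), t_max=t_max,
                    detached=meta["detached"][i], seed=i,
                )
            )
            continue
        trajs.append(
            Trajectory(
                x0=meta["x0"][i],
                times=g["t"].to_numpy(),
                m=g["m"].to_numpy(np.int8),
                x_event=g["x_event"].to_numpy(),
                n_after=g["n"].to_numpy(np.int16),
                x_after=g["x_a"].to_numpy(),
                t_max=t_max,
                detached=meta["detached"][i],
                seed=i,
            )
        )
    return Ensemble(trajectories=trajs, model=model, master_seed=meta["master_seed"])
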