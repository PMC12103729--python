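"""File formats: trajectory CSV, parameter YAML, and model containers.

Trajectory files are plain CSV with the header
``time,theta,theta_dot,u_pf,u_df,grf,sigma``; angles and angular velocities
are stored in degrees(/s) and converted to radians on read.  Parameter files
are flat YAML mirroring the dataclass field names.  Trained models are stored
as a single ``.npz`` (named matrices plus a JSON metadata string) with a
plain-text observable-descriptor sidecar so a model file is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .edmd import KoopmanModel
from .lifting import make_dictionary
from .plant import DEG, RAD2DEG, AnklePlantParams, ReferenceTrajectory, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_params",
    "read_params",
    "write_reference",
    "read_reference",
    "save_model",
    "load_model",
]

_TRAJ_COLUMNS = ["time", "theta", "theta_dot", "u_pf", "u_df", "grf", "sigma"]


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame(
        {
            "time": traj.time,
            "theta": traj.theta * RAD2DEG,
            "theta_dot": traj.theta_dot * RAD2DEG,
            "u_pf": traj.u_pf,
            "u_df": traj.u_df,
            "grf": traj.grf,
            "sigma": traj.sigma,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    return Trajectory(
        time=df["time"].to_numpy(float),
        theta=df["theta"].to_numpy(float) * DEG,
        theta_dot=df["theta_dot"].to_numpy(float) * DEG,
        u_pf=df["u_pf"].to_numpy(float),
        u_df=df["u_df"].to_numpy(float),
        grf=df["grf"].to_numpy(float),
        sigma=df["sigma"].to_numpy(int),
    )


def write_reference(ref: ReferenceTrajectory, path) -> None:
    pd.DataFrame(
        {
            "time": ref.time,
            "theta_d": ref.theta_d * RAD2DEG,
            "theta_dot_d": ref.theta_dot_d * RAD2DEG,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def read_reference(path) -> ReferenceTrajectory:
    df = pd.read_csv(path)
    return ReferenceTrajectory(
        df["time"].to_numpy(float),
        df["theta_d"].to_numpy(float) * DEG,
        df["theta_dot_d"].to_numpy(float) * DEG,
    )


def write_params(params: AnklePlantParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=True)


def read_params(path) -> AnklePlantParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnklePlantParams(**data)


def save_model(model: KoopmanModel, path) -> None:
    """Write a model container (.npz) and its descriptor sidecar (.dict.txt)."""
    path = Path(path)
    d = model.dictionary
    meta = {
        "dictionary": d.name,
        "descriptors": list(d.descriptors),
        "embedding_length": d.embedding_length,
        "state_dim": d.state_dim,
        "include_constant": d.include_constant,
        "reference_dim": model.reference_dim,
        "diagnostics": json.loads(json.dumps(model.diagnostics, default=float)),
    }
    arrays = {"C": model.C, "meta": np.array(json.dumps(meta))}
    for ph in ("stance", "swing"):
        arrays[f"K_xx_{ph}"] = model.K_xx[ph]
        arrays[f"K_xu_{ph}"] = model.K_xu[ph]
        arrays[f"A_tilde_{ph}"] = model.A_tilde[ph]
        arrays[f"B_tilde_{ph}"] = model.B_tilde[ph]
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".dict.txt")
    sidecar.write_text(
        "\n".join(list(d.descriptors) + (["const"] if d.include_constant else [])) + "\n"
    )


def load_model(path) -> KoopmanModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        dictionary = make_dictionary(
            meta["dictionary"],
            embedding_length=meta["embedding_length"],
            state_dim=meta["state_dim"],
            include_constant=meta["include_constant"],
        )
        if list(dictionary.descriptors) != meta["descriptors"]:
            raise ValueError("model file descriptors disagree with the named dictionary")
        kw = {"K_xx": {}, "K_xu": {}, "A_tilde": {}, "B_tilde": {}}
        for ph in ("stance", "swing"):
            kw["K_xx"][ph] = data[f"K_xx_{ph}"]
            kw["K_xu"][ph] = data[f"K_xu_{ph}"]
            kw["A_tilde"][ph] = data[f"A_tilde_{ph}"]
            kw["B_tilde"][ph] = data[f"B_tilde_{ph}"]
        return KoopmanModel(
            dictionary=dictionary,
            C=data["C"],
            diagnostics=meta.get("diagnostics", {}),
            reference_dim=meta.get("reference_dim", 2),
            **kw,
        )
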