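"""Plain-text and binary export of trajectories, networks and profiles.

Every artifact that carries simulation provenance is written with a YAML
sidecar (same path + ``.meta.yaml``) recording the parameters that produced
it, so any run can be reconstructed from its outputs.
"""

from __future__ import annotations

import os
from dataclasses import asdict
from typing import Any

import numpy as np
import yaml

from .dynamics import ModelParams, Trajectory
from .errors import ParameterError
from .synthetic import ConnectivityMatrix, ExcitabilityProfile

__all__ = [
    "write_sidecar",
    "read_sidecar",
    "write_trajectory_text",
    "write_trajectory_npz",
    "read_trajectory_npz",
    "write_matrix_text",
    "read_matrix_text",
    "write_edge_list",
    "read_edge_list",
    "write_profile_text",
    "read_profile_text",
]


def write_sidecar(path: str, metadata: dict[str, Any]) -> str:
    side = path + ".meta.yaml"
    with open(side, "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=True)
    return side


def read_sidecar(path: str) -> dict[str, Any]:
    with open(path + ".meta.yaml") as fh:
        return yaml.safe_load(fh)


def _traj_metadata(traj: Trajectory, params: ModelParams | None,
                   extra: dict[str, Any] | None) -> dict[str, Any]:
    meta: dict[str, Any] = {
        "dt": float(traj.dt),
        "n_samples": int(traj.times.size),
        "n_nodes": int(traj.n_nodes),
    }
    if params is not None:
        meta["params"] = asdict(params)
    if extra:
        meta.update(extra)
    return meta


def write_trajectory_text(
    traj: Trajectory, path: str,
    params: ModelParams | None = None,
    metadata: dict[str, Any] | None = None,
) -> None:
    """One row per sample: time, then x1,y1,z,x2,y2,g per node."""
    states = traj.states.reshape(traj.times.size, -1)
    data = np.column_stack([traj.times, states])
    n = traj.n_nodes
    cols = ["time"] + [f"{v}_{i}" for i in range(n)
                       for v in ("x1", "y1", "z", "x2", "y2", "g")]
    np.savetxt(path, data, delimiter="\t", header="\t".join(cols), comments="")
    write_sidecar(path, _traj_metadata(traj, params, metadata))


def write_trajectory_npz(
    traj: Trajectory, path: str,
    params: ModelParams | None = None,
    metadata: dict[str, Any] | None = None,
) -> None:
    """Compact binary container (NumPy .npz) plus the same YAML sidecar."""
    np.savez_compressed(path, times=traj.times, states=traj.states,
                        dt=np.asarray(traj.dt))
    real = path if path.endswith(".npz") else path + ".npz"
    write_sidecar(real, _traj_metadata(traj, params, metadata))


def read_trajectory_npz(path: str) -> Trajectory:
    with np.load(path) as data:
        return Trajectory(times=data["times"], states=data["states"],
                          dt=float(data["dt"]))


def write_matrix_text(mat: ConnectivityMatrix, path: str) -> None:
    np.savetxt(path, mat.weights, delimiter="\t")
    write_sidecar(path, {"n": mat.n,
                         "focal_indices": list(mat.focal_indices),
                         "global_scale": float(mat.global_scale)})


def read_matrix_text(path: str) -> ConnectivityMatrix:
    w = np.loadtxt(path, delimiter="\t")
    meta: dict[str, Any] = {}
    if os.path.exists(path + ".meta.yaml"):
        meta = read_sidecar(path)
    return ConnectivityMatrix(
        weights=w,
        focal_indices=tuple(meta.get("focal_indices", ())),
        global_scale=float(meta.get("global_scale", 1.0)),
    )


def write_edge_list(mat: ConnectivityMatrix, path: str) -> None:
    """Three-column weighted edge list (i, j, w), 0-based, i < j, one line
    per undirected edge."""
    iu, ju = np.triu_indices(mat.n, k=1)
    w = mat.weights[iu, ju]
    keep = w > 0
    with open(path, "w") as fh:
        fh.write("i\tj\tw\n")
        for a, b, ww in zip(iu[keep], ju[keep], w[keep]):
            fh.write(f"{a}\t{b}\t{float(ww)!r}\n")
    write_sidecar(path, {"n": mat.n,
                         "focal_indices": list(mat.focal_indices),
                         "global_scale": float(mat.global_scale)})


def read_edge_list(path: str, n: int | None = None) -> ConnectivityMatrix:
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    meta: dict[str, Any] = {}
    if os.path.exists(path + ".meta.yaml"):
        meta = read_sidecar(path)
    if n is None:
        if "n" in meta:
            n = int(meta["n"])
        elif data.size:
            n = int(data[:, :2].max()) + 1
        else:
            raise ParameterError("cannot infer node count from an empty edge list")
    w = np.zeros((n, n))
    for a, b, ww in data:
        w[int(a), int(b)] = w[int(b), int(a)] = ww
    return ConnectivityMatrix(
        weights=w,
        focal_indices=tuple(meta.get("focal_indices", ())),
        global_scale=float(meta.get("global_scale", 1.0)),
    )


def write_profile_text(profile: ExcitabilityProfile, path: str,
                       seed: int | None = None) -> None:
    """Two-column (node, x0) table; the header comment records the
    generating distribution."""
    with open(path, "w") as fh:
        fh.write(f"# mu={float(profile.mu)!r} sigma={float(profile.sigma)!r} "
                 f"x0_nonfocal={float(profile.x0_nonfocal)!r} seed={seed}\n")
        fh.write(f"# focal_indices={','.join(map(str, profile.focal_indices))}\n")
        fh.write("node\tx0\n")
        for i, v in enumerate(profile.x0_values):
            fh.write(f"{i}\t{float(v)!r}\n")


def read_profile_text(path: str) -> ExcitabilityProfile:
    header: dict[str, str] = {}
    focal: tuple[int, ...] = ()
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("focal_indices="):
                txt = body.split("=", 1)[1]
                focal = tuple(int(x) for x in txt.split(",") if x)
            else:
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
    data = np.loadtxt(path, delimiter="\t", skiprows=3, ndmin=2)
    x0 = np.zeros(int(data[:, 0].max()) + 1)
    x0[data[:, 0].astype(int)] = data[:, 1]
    return ExcitabilityProfile(
        x0_values=x0, focal_indices=focal,
        mu=float(header["mu"]), sigma=float(header["sigma"]),
        x0_nonfocal=float(header["x0_nonfocal"]))
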