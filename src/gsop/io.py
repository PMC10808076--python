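"""Stable on-disk formats: HDF5 trajectory containers and CSV exports."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .encoder import MicroTrajectorySet

FORMAT_VERSION = 1


class FormatError(IOError):
    pass


def store_trajectories(path, data: MicroTrajectorySet,
                       params: dict | None = None,
                       observables: dict | None = None) -> None:
    """Write a trajectory container: /positions [M, Nt+1, D], /times, attrs."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["source"] = data.source
        f.attrs["params"] = json.dumps(params or {})
        f.create_dataset("positions", data=data.states)
        f.create_dataset("times", data=data.times)
        if observables:
            grp = f.create_group("observables")
            for k, v in observables.items():
                grp.create_dataset(k, data=np.asarray(v))


def load_trajectories(path) -> tuple[MicroTrajectorySet, dict]:
    """Read a container back; arrays round-trip bitwise."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != FORMAT_VERSION:
                raise FormatError(
                    f"unsupported container version {f.attrs.get('format_version')!r}")
            if "positions" not in f or "times" not in f:
                raise FormatError("missing /positions or /times dataset")
            data = MicroTrajectorySet(f["times"][()], f["positions"][()],
                                      source=str(f.attrs.get("source", "external")))
            params = json.loads(f.attrs.get("params", "{}"))
    except OSError as e:
        raise FormatError(f"cannot read container {path}: {e}") from e
    return data, params


def export_reduced_csv(path, times: np.ndarray, reduced: np.ndarray) -> None:
    """Reduced trajectories (M, Nt+1, d) as tidy CSV: t, Z1..Zd, traj_id."""
    reduced = np.asarray(reduced)
    M, n_snap, d = reduced.shape
    frames = []
    for j in range(M):
        df = pd.DataFrame(reduced[j], columns=[f"Z{i+1}" for i in range(d)])
        df.insert(0, "t", np.asarray(times))
        df["traj_id"] = j
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_encoder(path, enc) -> None:
    """Encoder checkpoint: PCA statistics, centering means and network weights."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["n_closure"] = enc.n_closure
        f.attrs["rho1"] = enc.rho1
        f.attrs["has_decoder"] = enc.nn_d is not None
        f.create_dataset("pca/eigvals", data=enc.eig_values)
        f.create_dataset("pca/eigvecs", data=enc.eig_vectors)
        f.create_dataset("centering/means", data=enc.snapshot_means)
        f.create_dataset("centering/times", data=enc.times)
        for i, p in enumerate(enc.nn_e.parameters):
            f.create_dataset(f"nn_e/{i}", data=p.data)
        if enc.nn_d is not None:
            for i, p in enumerate(enc.nn_d.parameters):
                f.create_dataset(f"nn_d/{i}", data=p.data)
        f.attrs["nn_e_sizes"] = enc.nn_e.sizes
        if enc.nn_d is not None:
            f.attrs["nn_d_sizes"] = enc.nn_d.sizes


def load_encoder(path):
    from .encoder import EncoderDecoder
    from .nets import MLP
    with h5py.File(path, "r") as f:
        if f.attrs.get("format_version") != FORMAT_VERSION:
            raise FormatError("unsupported encoder checkpoint version")
        nn_e = MLP(list(f.attrs["nn_e_sizes"]), activation="tanh")
        nn_e.load_state([f[f"nn_e/{i}"][()] for i in range(len(nn_e.parameters))])
        nn_d = None
        if f.attrs["has_decoder"]:
            nn_d = MLP(list(f.attrs["nn_d_sizes"]), activation="tanh")
            nn_d.load_state([f[f"nn_d/{i}"][()] for i in range(len(nn_d.parameters))])
        enc = EncoderDecoder(
            f["pca/eigvals"][()], f["pca/eigvecs"][()],
            int(f.attrs["n_closure"]), f["centering/means"][()],
            f["centering/times"][()], nn_e=nn_e, nn_d=nn_d,
            rho1=float(f.attrs["rho1"]), use_decoder=f.attrs["has_decoder"])
    return enc
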