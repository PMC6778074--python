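"""Result and geometry file I/O: HDF5 for arrays, CSV for tables.

Every results file stores the run-configuration digest and seed so a run
is reproducible from its stored config alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import RunConfig
from .decay import EmissionBatch
from .geometry import NPCluster

__all__ = [
    "write_results", "read_results", "write_cluster_csv", "read_cluster_csv",
    "events_to_dataframe", "write_events", "read_events",
]

FORMAT_VERSION = 1


def write_results(arrays: dict[str, np.ndarray], path: str | Path,
                  config: RunConfig | None = None,
                  metadata: dict | None = None) -> None:
    """Write named arrays plus metadata to an HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        if config is not None:
            fh.attrs["config_digest"] = config.digest()
            fh.attrs["config_json"] = json.dumps(config.to_dict(),
                                                 sort_keys=True)
            fh.attrs["seed"] = config.seed
        for key, value in (metadata or {}).items():
            fh.attrs[key] = value
        for name, arr in arrays.items():
            fh.create_dataset(name, data=np.asarray(arr))


def read_results(path: str | Path,
                 keys: list[str] | None = None) -> tuple[dict, dict]:
    """Read (arrays, metadata); missing requested keys raise KeyError."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format_version")
        if version != FORMAT_VERSION:
            import warnings
            warnings.warn(f"results file version {version} != {FORMAT_VERSION}")
        names = keys if keys is not None else list(fh.keys())
        arrays = {}
        for name in names:
            if name not in fh:
                raise KeyError(f"dataset {name!r} not in {path}")
            arrays[name] = fh[name][()]
        meta = dict(fh.attrs)
    return arrays, meta


def write_cluster_csv(cluster: NPCluster, path: str | Path) -> None:
    """Cluster positions as CSV with a JSON sidecar (box, sd_max, seed)."""
    path = Path(path)
    df = pd.DataFrame({
        "id": np.arange(cluster.n),
        "x_nm": cluster.centers_nm[:, 0],
        "y_nm": cluster.centers_nm[:, 1],
        "z_nm": cluster.centers_nm[:, 2],
        "labeled": cluster.labeled.astype(int),
    })
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {"box_nm": cluster.box_nm, "sd_max_nm": cluster.sd_max_nm,
               "seed": cluster.seed, "outer_radius_nm": cluster.outer_radius_nm}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_cluster_csv(path: str | Path) -> NPCluster:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return NPCluster(
        centers_nm=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
        labeled=df["labeled"].to_numpy().astype(bool),
        box_nm=sidecar["box_nm"], sd_max_nm=sidecar["sd_max_nm"],
        seed=sidecar["seed"], outer_radius_nm=sidecar["outer_radius_nm"])


def events_to_dataframe(events: EmissionBatch) -> pd.DataFrame:
    return pd.DataFrame({
        "type": [EmissionBatch.PTYPE_NAMES[t] for t in events.ptype],
        "subtype": [EmissionBatch.SUBTYPE_NAMES[s] for s in events.subtype],
        "energy_keV": events.energy_kev,
        "dir_x": events.direction[:, 0],
        "dir_y": events.direction[:, 1],
        "dir_z": events.direction[:, 2],
        "x_nm": events.origin_nm[:, 0],
        "y_nm": events.origin_nm[:, 1],
        "z_nm": events.origin_nm[:, 2],
        "history": events.history,
        "nuclide": [events.nuclide_names[i] for i in events.nuclide],
    })


def write_events(events: EmissionBatch, path: str | Path) -> None:
    """Emission stream to CSV (.csv) or HDF5 (anything else)."""
    path = Path(path)
    if path.suffix == ".csv":
        events_to_dataframe(events).to_csv(path, index=False,
                                           float_format="%.10g")
        return
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["nuclide_names"] = json.dumps(list(events.nuclide_names))
        for name in ("ptype", "subtype", "energy_kev", "direction",
                     "origin_nm", "history", "nuclide"):
            fh.create_dataset(name, data=getattr(events, name))


def read_events(path: str | Path) -> EmissionBatch:
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        names = list(dict.fromkeys(df["nuclide"]))
        return EmissionBatch(
            ptype=np.array([EmissionBatch.PTYPE_NAMES.index(t)
                            for t in df["type"]], dtype=np.int8),
            subtype=np.array([EmissionBatch.SUBTYPE_NAMES.index(s)
                              for s in df["subtype"]], dtype=np.int8),
            energy_kev=df["energy_keV"].to_numpy(),
            direction=df[["dir_x", "dir_y", "dir_z"]].to_numpy(),
            origin_nm=df[["x_nm", "y_nm", "z_nm"]].to_numpy(),
            history=df["history"].to_numpy().astype(np.int64),
            nuclide=np.array([names.index(n) for n in df["nuclide"]],
                             dtype=np.int16),
            nuclide_names=tuple(names))
    with h5py.File(path, "r") as fh:
        return EmissionBatch(
            ptype=fh["ptype"][()], subtype=fh["subtype"][()],
            energy_kev=fh["energy_kev"][()], direction=fh["direction"][()],
            origin_nm=fh["origin_nm"][()],
            history=fh["history"][()], nuclide=fh["nuclide"][()],
            nuclide_names=tuple(json.loads(fh.attrs["nuclide_names"])))
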