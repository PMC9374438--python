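"""Reading and writing pipeline artifacts.

Plume records go to HDF5 (one chunked dataset plus config/coordinate
attributes); feature tables and datasets to tab-separated text with a JSON
sidecar; fitted kernel models to ``.npz`` with a JSON header. Per-location
series can also be exchanged as two-column (t, c) delimited text.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cone import RegressionDataset
from .regression import KernelModel, Standardizer
from .synthetic import PlumeConfig, PlumeRealization

__all__ = [
    "save_plume",
    "load_plume",
    "save_series_text",
    "load_series_text",
    "save_feature_table",
    "load_feature_table",
    "save_dataset",
    "load_dataset",
    "save_model",
    "load_model",
    "load_config_file",
]


def _config_to_json(config: PlumeConfig) -> str:
    d = dataclasses.asdict(config)
    d["grid_shape"] = list(d["grid_shape"])
    d["whiff_duration_law"] = list(d["whiff_duration_law"])
    d["blank_duration_law"] = list(d["blank_duration_law"])
    return json.dumps(d)


def _config_from_json(text: str) -> PlumeConfig:
    d = json.loads(text)
    for key in ("grid_shape", "whiff_duration_law", "blank_duration_law"):
        d[key] = tuple(d[key])
    return PlumeConfig(**d)


def save_plume(path: str | Path, plume: PlumeRealization) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset(
            "concentration",
            data=plume.concentration,
            chunks=(1, plume.concentration.shape[1], plume.concentration.shape[2]),
            compression="gzip",
        )
        dset.attrs["config"] = _config_to_json(plume.config)
        f.create_dataset("z1", data=plume.z1)
        f.create_dataset("z2", data=plume.z2)


def load_plume(path: str | Path) -> PlumeRealization:
    with h5py.File(path, "r") as f:
        conc = f["concentration"][...]
        config = _config_from_json(f["concentration"].attrs["config"])
        z1 = f["z1"][...]
        z2 = f["z2"][...]
    return PlumeRealization(concentration=conc, z1=z1, z2=z2, config=config)


def save_series_text(path: str | Path, t: np.ndarray, c: np.ndarray) -> None:
    pd.DataFrame({"t": t, "c": c}).to_csv(path, sep="\t", index=False)


def load_series_text(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["t"].to_numpy(), df["c"].to_numpy()


def save_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_dataset(path: str | Path, dataset: RegressionDataset) -> None:
    """Dataset table as TSV plus a JSON metadata sidecar (same stem)."""
    path = Path(path)
    dataset.table.to_csv(path, sep="\t", index=False)
    meta = {
        "output_axis": dataset.output_axis,
        "memory": dataset.memory,
        "dt": dataset.dt,
        "cone_R": dataset.cone_R,
        "seed": dataset.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_dataset(path: str | Path) -> RegressionDataset:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RegressionDataset(table=table, **meta)


def save_model(path: str | Path, model: KernelModel) -> None:
    np.savez(
        path,
        X_train=model.X_train,
        coef=model.coef,
        center=model.standardizer.center,
        scale=model.standardizer.scale,
        hyper=np.array([model.sigma, model.lam]),
    )


def load_model(path: str | Path) -> KernelModel:
    with np.load(path) as f:
        return KernelModel(
            X_train=f["X_train"],
            coef=f["coef"],
            sigma=float(f["hyper"][0]),
            lam=float(f["hyper"][1]),
            standardizer=Standardizer(center=f["center"], scale=f["scale"]),
        )


def load_config_file(path: str | Path) -> dict:
    """Key-value config text (YAML subset) to a plain dict."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
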