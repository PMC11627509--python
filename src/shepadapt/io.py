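"""Serialization: HDF5 array containers, CSV tables, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cohort import PopulationResponse


def save_population_response(path, resp: PopulationResponse) -> None:
    """Write counts + alignment to an HDF5 file with a CSV sidecar for
    the neuron metadata (same stem, ``_neurons.csv``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=resp.counts, compression="gzip")
        f.attrs["bin_width"] = resp.bin_width
        f.attrs["mode"] = resp.mode
        align = resp.alignment
        grp = f.create_group("alignment")
        for col in align.columns:
            vals = align[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)
    resp.neuron_meta.to_csv(path.with_name(path.stem + "_neurons.csv"), index=False)


def load_population_response(path) -> PopulationResponse:
    path = Path(path)
    with h5py.File(path, "r") as f:
        counts = f["counts"][...]
        bin_width = float(f.attrs["bin_width"])
        mode = str(f.attrs["mode"])
        cols = {}
        for col in f["alignment"]:
            vals = f["alignment"][col][...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
        align = pd.DataFrame(cols)
    meta = pd.read_csv(path.with_name(path.stem + "_neurons.csv"))
    return PopulationResponse(counts=counts, bin_width=bin_width, alignment=align,
                              neuron_meta=meta, mode=mode)


def config_to_yaml(cfg, path) -> None:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(conv(cfg), fh)


def config_from_yaml(cls, path):
    """Rebuild a (possibly nested) dataclass config from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _build(cls, data)


def _build(cls, data):
    import typing

    if dataclasses.is_dataclass(cls) and isinstance(data, dict):
        hints = typing.get_type_hints(cls)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            v = data[f.name]
            ftype = hints.get(f.name, f.type)
            if isinstance(ftype, type) and dataclasses.is_dataclass(ftype):
                kwargs[f.name] = _build(ftype, v)
            elif isinstance(v, list):
                kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)
    return data
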