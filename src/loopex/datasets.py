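"""Observed-data containers shared by the simulators and the global fit.

A :class:`Dataset` is one experiment's worth of points (values + per-point
uncertainties) together with its acquisition schedule, condition tags
(complex, RNA state, para/dia, field) and a role->parameter-name map that
tells the global fit which named parameters feed its forward model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exchange import (CESTSchedule, CPMGSchedule, EXSYSchedule, IRSchedule,
                       SpectrumGrid)

__all__ = ["Dataset", "DatasetCollection", "EXPERIMENT_KINDS"]

EXPERIMENT_KINDS = ("CEST", "CPMG", "EXSY", "IR", "SPECTRUM")

_SCHEDULE_TYPES = {
    "CEST": CESTSchedule, "CPMG": CPMGSchedule, "EXSY": EXSYSchedule,
    "IR": IRSchedule, "SPECTRUM": SpectrumGrid,
}


@dataclass
class Dataset:
    name: str
    kind: str
    schedule: object
    y: np.ndarray
    sigma: np.ndarray
    tags: dict = field(default_factory=dict)
    param_map: dict = field(default_factory=dict)   # role -> parameter name

    def __post_init__(self) -> None:
        if self.kind not in EXPERIMENT_KINDS:
            raise ValueError(f"unknown experiment kind {self.kind!r}")
        expected = _SCHEDULE_TYPES[self.kind]
        if not isinstance(self.schedule, expected):
            raise TypeError(f"{self.kind} dataset needs a {expected.__name__}, "
                            f"got {type(self.schedule).__name__}")
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.sigma = np.asarray(self.sigma, dtype=float).ravel()
        if self.y.size != self.sigma.size:
            raise ValueError("y and sigma differ in length")
        if np.any(self.sigma <= 0):
            raise ValueError(f"dataset {self.name}: all sigmas must be > 0")

    @property
    def x(self) -> np.ndarray:
        """The independent variable: offsets, frequencies or delays.

        EXSY datasets store flattened 2x2 intensity matrices per mixing
        time; their x repeats each mixing time four times (GG, EG, GE, EE).
        """
        s = self.schedule
        if self.kind == "CEST":
            return s.offsets
        if self.kind == "CPMG":
            return s.nu_CPMG
        if self.kind == "EXSY":
            return np.repeat(s.mixing_times, 4)
        if self.kind == "IR":
            return s.delays
        return s.offsets

    @property
    def n(self) -> int:
        return self.y.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "value": self.y, "sigma": self.sigma})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class DatasetCollection:
    """Ordered collection of datasets with selection helpers and disk I/O."""

    def __init__(self, datasets: list[Dataset] | None = None,
                 truth: dict | None = None):
        self.datasets: list[Dataset] = list(datasets or [])
        #: generating parameter values when the collection is synthetic
        self.truth: dict = dict(truth or {})

    def add(self, ds: Dataset) -> None:
        self.datasets.append(ds)

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, key):
        if isinstance(key, str):
            for ds in self.datasets:
                if ds.name == key:
                    return ds
            raise KeyError(key)
        return self.datasets[key]

    def select(self, **tags) -> "DatasetCollection":
        keep = [ds for ds in self.datasets
                if all(ds.tags.get(k) == v for k, v in tags.items())]
        return DatasetCollection(keep, truth=self.truth)

    @property
    def n_points(self) -> int:
        return sum(ds.n for ds in self.datasets)

    # -- disk round trip: one TSV per dataset + a JSON manifest -------------

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"truth": self.truth, "datasets": []}
        for ds in self.datasets:
            fname = f"{ds.name}.tsv"
            ds.write_tsv(directory / fname)
            manifest["datasets"].append({
                "name": ds.name, "kind": ds.kind, "file": fname,
                "tags": ds.tags, "param_map": ds.param_map,
                "schedule": ds.schedule.to_dict()
                if hasattr(ds.schedule, "to_dict") else
                {"offsets": ds.schedule.offsets.tolist(),
                 "scale": ds.schedule.scale},
            })
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "DatasetCollection":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        out = cls(truth=manifest.get("truth", {}))
        for entry in manifest["datasets"]:
            sched_cls = _SCHEDULE_TYPES[entry["kind"]]
            sd = dict(entry["schedule"])
            for key in ("offsets", "reference_offsets", "nu_CPMG",
                        "mixing_times", "delays"):
                if key in sd:
                    sd[key] = np.asarray(sd[key], dtype=float)
            schedule = sched_cls(**sd)
            df = pd.read_csv(directory / entry["file"], sep="\t")
            out.add(Dataset(name=entry["name"], kind=entry["kind"],
                            schedule=schedule, y=df["value"].to_numpy(),
                            sigma=df["sigma"].to_numpy(),
                            tags=entry.get("tags", {}),
                            param_map=entry.get("param_map", {})))
        return out
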