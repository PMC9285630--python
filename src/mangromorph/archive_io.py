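"""Persist run archives: gridded annual snapshots as NetCDF (scipy
NetCDF3 backend), the cohort table as CSV and the resume checkpoint as a
YAML + flat-array bundle inside the same dataset."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .orchestrator import RunArchive
from .scenario import ScenarioConfig

__all__ = ["save_archive", "load_archive"]


def _dataset(archive: RunArchive) -> xr.Dataset:
    years = archive.years_array()
    x = archive.x
    data = {
        "bed_elevation": (("time", "cell"), np.asarray(archive.bed)),
        "veg_count": (("time", "cell"), np.asarray(archive.veg_count)),
        "veg_max_diameter": (("time", "cell"),
                             np.asarray(archive.veg_max_diameter)),
        "hydroperiod": (("time", "cell"), np.asarray(archive.hydroperiod)),
        "mean_offset": (("time",), np.asarray(archive.mean_offset)),
    }
    ds = xr.Dataset(data, coords={"time": years, "cell_x": ("cell", x)})
    ds.attrs["config_yaml"] = yaml.safe_dump(archive.config.to_dict())
    ds.attrs["failed"] = int(archive.failed)
    ds.attrs["failure_info"] = archive.failure_info or ""
    ds.attrs["mass_balance_json"] = json.dumps(archive.mass_balance)
    return ds


def save_archive(archive: RunArchive, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _dataset(archive).to_netcdf(d / "snapshots.nc", engine="scipy")
    archive.cohort_table().to_csv(d / "cohorts.csv", index=False)
    if archive.checkpoint is not None:
        ck = dict(archive.checkpoint)
        arrays = {}
        for key in ("eta", "u", "bed", "hc", "prev_tau90", "depth_ref",
                    "last_P"):
            val = ck.pop(key)
            arrays[key] = None if val is None else np.asarray(val).tolist()
        ck["arrays"] = arrays
        (d / "checkpoint.json").write_text(json.dumps(ck))
    return d


def load_archive(directory: str | Path) -> RunArchive:
    d = Path(directory)
    ds = xr.load_dataset(d / "snapshots.nc", engine="scipy")
    cfg = ScenarioConfig.from_dict(yaml.safe_load(ds.attrs["config_yaml"]))
    archive = RunArchive(config=cfg)
    archive.years = [float(t) for t in ds["time"].values]
    archive.bed = [row.copy() for row in ds["bed_elevation"].values]
    archive.veg_count = [row.copy() for row in ds["veg_count"].values]
    archive.veg_max_diameter = [row.copy()
                                for row in ds["veg_max_diameter"].values]
    archive.hydroperiod = [row.copy() for row in ds["hydroperiod"].values]
    archive.mean_offset = [float(v) for v in ds["mean_offset"].values]
    archive.mass_balance = json.loads(ds.attrs["mass_balance_json"])
    archive.failed = bool(ds.attrs["failed"])
    archive.failure_info = ds.attrs["failure_info"] or None
    table = pd.read_csv(d / "cohorts.csv") if (d / "cohorts.csv").exists() \
        else pd.DataFrame()
    archive.cohort_rows = [tuple(r) for r in table.itertuples(index=False)]
    ck_path = d / "checkpoint.json"
    if ck_path.exists():
        ck = json.loads(ck_path.read_text())
        arrays = ck.pop("arrays")
        for key, val in arrays.items():
            ck[key] = None if val is None else np.asarray(val, dtype=float)
        archive.checkpoint = ck
    return archive
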