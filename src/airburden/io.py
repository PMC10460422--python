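"""Reading and writing the standard input/output bundle.

Gridded fields travel as NetCDF (dims member, year, lat, lon; units
attribute "ug m-3"), tables as tidy CSV, region masks as an integer raster
plus a CSV label map, and run metadata as a YAML manifest.  Grid
registration is cell-centre, latitude ascending, longitude in [-180, 180).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml


def _netcdf3_safe(ds: xr.Dataset | xr.DataArray):
    """Downcast 64-bit integers for the NetCDF3 (scipy) writer."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds = ds.copy()
    for name in list(ds.variables):
        if ds[name].dtype == np.int64:
            ds[name] = ds[name].astype(np.int32)
    return ds


def write_netcdf(ds: xr.Dataset | xr.DataArray, path) -> None:
    _netcdf3_safe(ds).to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy").load()


def write_region_mask(mask: xr.DataArray, labels: dict[int, str],
                      mask_path, labels_path) -> None:
    write_netcdf(mask.rename("region_id"), mask_path)
    pd.DataFrame(
        {"region_id": list(labels), "region": list(labels.values())}
    ).to_csv(labels_path, index=False)


def read_region_mask(mask_path, labels_path):
    mask = read_netcdf(mask_path)["region_id"]
    lab = pd.read_csv(labels_path)
    return mask, dict(zip(lab["region_id"], lab["region"]))


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config_dict: dict) -> str:
    """Stable hash of a configuration mapping."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
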