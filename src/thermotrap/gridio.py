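"""Self-describing array export of concentration grids.

States are exchanged as xarray Datasets with named ``x`` (cross-gap, um from
the cold wall) and ``z`` (height, um from the bottom) dimensions, one data
variable per species, so they can be written to NetCDF-style containers or
inspected interactively.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .trap_model import ChamberGeometry
from .transport import TransportState


def state_to_dataset(state: TransportState) -> xr.Dataset:
    geom = state.geometry
    data = {
        name: xr.DataArray(
            grid.T,  # (n_x, n_z) -> dims (x, z)
            dims=("x", "z"),
            coords={"x": geom.x_centers, "z": geom.z_centers},
            attrs={"units": "uM"},
        )
        for name, grid in state.c.items()
    }
    ds = xr.Dataset(
        data,
        attrs={
            "time_s": state.time_s,
            "gap_um": geom.gap_um,
            "height_um": geom.height_um,
            "depth_um": geom.depth_um,
            "orientation": geom.orientation,
        },
    )
    for name, value in state.channel_uM.items():
        ds.attrs[f"channel_{name}_uM"] = value
    return ds


def dataset_to_state(ds: xr.Dataset) -> TransportState:
    geom = ChamberGeometry(
        gap_um=float(ds.attrs["gap_um"]),
        height_um=float(ds.attrs["height_um"]),
        depth_um=float(ds.attrs["depth_um"]),
        n_x=ds.sizes["x"],
        n_z=ds.sizes["z"],
        orientation=ds.attrs.get("orientation", "vertical"),
    )
    c = {name: np.asarray(ds[name].values).T for name in ds.data_vars}
    chan = {
        key[len("channel_") : -len("_uM")]: float(val)
        for key, val in ds.attrs.items()
        if key.startswith("channel_") and key.endswith("_uM")
    }
    return TransportState(geom, float(ds.attrs["time_s"]), c, chan)


def save_state(state: TransportState, path) -> None:
    state_to_dataset(state).to_netcdf(path, engine="scipy")


def load_state(path) -> TransportState:
    with xr.open_dataset(path, engine="scipy") as ds:
        return dataset_to_state(ds.load())
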