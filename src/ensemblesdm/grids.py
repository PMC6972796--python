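"""Gridded environmental data containers.

A regular lon/lat grid (WGS-84 degrees) holds one 2-D array per
environmental variable plus a shared nodata ("land") mask.  Pixel
indexing is row-major and 0-based with the origin at the grid's
north-west corner; a pixel covers the half-open interval
[edge, edge + cell_size) in longitude and, symmetrically, one
cell_size of latitude counted down from the northern edge.  Every
module in the package uses this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr


class ConfigurationError(ValueError):
    """Raised when a grid or stack is internally inconsistent."""


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid definition.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    lon_min, lat_min
        Coordinates of the grid's south-west corner, in degrees.
    cell_size
        Pixel edge length in degrees.  The default of 1/12 degree is
        5 arc-minutes, the native resolution of the Bio-ORACLE layers.
    """

    n_rows: int
    n_cols: int
    lon_min: float = -180.0
    lat_min: float = -90.0
    cell_size: float = 1.0 / 12.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if not (-180.0 <= self.lon_min and self.lon_max <= 180.0 + 1e-9):
            raise ConfigurationError("grid longitudes must lie within [-180, 180]")
        if not (-90.0 <= self.lat_min and self.lat_max <= 90.0 + 1e-9):
            raise ConfigurationError("grid latitudes must lie within [-90, 90]")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.n_cols * self.cell_size

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        # row 0 at the northern edge
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_of(self, row: np.ndarray | int, col: np.ndarray | int):
        """Lon/lat of pixel centers for (row, col) indices."""
        lon = self.lon_min + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.lat_max - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon: np.ndarray, lat: np.ndarray):
        """Map lon/lat points to (row, col); points outside get -1.

        Longitude intervals are half-open [edge, edge + cell);
        latitude rows are counted down from the northern edge with the
        matching half-open convention (the northern edge belongs to
        row 0).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((self.lat_max - lat) / self.cell_size).astype(int)
        # northern edge itself maps into row 0
        row = np.where(np.isclose(lat, self.lat_max), 0, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(inside, row, -1), np.where(inside, col, -1)


@dataclass
class EnvStack:
    """Named multi-layer raster stack on a shared grid.

    ``nodata_mask`` is True on cells without data ("land"); masked
    cells are masked in every layer.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ConfigurationError("nodata_mask shape does not match grid")
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ConfigurationError("layer names must be unique")
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ConfigurationError(f"layer {name!r} shape does not match grid")
            arr = arr.copy()
            arr[self.nodata_mask] = np.nan
            self.layers[name] = arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def values_at(self, rows: np.ndarray, cols: np.ndarray,
                  names: list[str] | None = None) -> np.ndarray:
        """Predictor matrix (points x variables) at pixel centers."""
        names = names if names is not None else self.layer_names
        out = np.empty((len(np.atleast_1d(rows)), len(names)))
        for j, name in enumerate(names):
            out[:, j] = self.layers[name][rows, cols]
        return out

    def copy(self) -> "EnvStack":
        return EnvStack(self.grid, {k: v.copy() for k, v in self.layers.items()},
                        self.nodata_mask.copy())

    # ---------------------------------------------------------------- I/O
    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lat_centers(), "lon": self.grid.lon_centers()}
        data = {name: (("lat", "lon"), arr) for name, arr in self.layers.items()}
        data["nodata_mask"] = (("lat", "lon"), self.nodata_mask.astype("int8"))
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["cell_size"] = self.grid.cell_size
        ds.attrs["lon_min"] = self.grid.lon_min
        ds.attrs["lat_min"] = self.grid.lat_min
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvStack":
        ds = xr.load_dataset(path, engine="scipy")
        n_rows, n_cols = ds["nodata_mask"].shape
        grid = GridSpec(n_rows=n_rows, n_cols=n_cols,
                        lon_min=float(ds.attrs["lon_min"]),
                        lat_min=float(ds.attrs["lat_min"]),
                        cell_size=float(ds.attrs["cell_size"]))
        mask = ds["nodata_mask"].values.astype(bool)
        layers = {str(k): ds[k].values.astype(float)
                  for k in ds.data_vars if k != "nodata_mask"}
        return cls(grid, layers, mask)
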