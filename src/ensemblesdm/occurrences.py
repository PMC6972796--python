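"""Occurrence record cleaning, buffering, thinning and absence sampling.

Occurrence sets are pandas DataFrames with columns
``lon, lat, detected, source, imprecision_m`` (imprecision may be NaN
for survey records, which carry none).  Cleaning applies, in order:

(a) drop records outside the survey buffer (when one is supplied);
(b) drop records whose latitude AND longitude both equal zero
    (missing/incorrect coordinates);
(c) drop records whose reported imprecision exceeds 10,000 m — the
    pixel size of a 5 arc-minute grid — using a strict inequality, so
    a record at exactly 10,000 m is retained.  Records without an
    imprecision field (surveys) are exempt.

Thinning keeps at most one record per grid pixel with presence
priority: a pixel containing any presence becomes a presence pixel,
otherwise an absence pixel.  Absences are then subsampled to a 1:10
presence-absence ratio for modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec

EARTH_RADIUS_KM = 6371.0

OCCURRENCE_COLUMNS = ["lon", "lat", "detected", "source", "imprecision_m"]


class EmptyResultError(RuntimeError):
    """All records were removed by cleaning — not a silent success."""


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km on a sphere of radius 6,371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def mean_pairwise_haversine(lons, lats) -> float:
    """Mean haversine distance (km) over all unordered point pairs."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = len(lons)
    if n < 2:
        raise ValueError("need at least two points for a pairwise distance")
    iu, ju = np.triu_indices(n, k=1)
    return float(np.mean(haversine_km(lons[iu], lats[iu], lons[ju], lats[ju])))


@dataclass
class BufferRegion:
    """Union-of-circles calibration region around anchor points.

    A pixel belongs to the buffer iff its center lies within
    ``radius_km`` great-circle distance of at least one anchor.
    """

    radius_km: float
    anchor_lons: np.ndarray
    anchor_lats: np.ndarray
    member_mask: np.ndarray
    grid: GridSpec

    def contains(self, lon, lat) -> np.ndarray:
        """Point-in-buffer test by direct distance to the anchors."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = np.zeros(len(lon), dtype=bool)
        for i in range(len(lon)):
            d = haversine_km(lon[i], lat[i], self.anchor_lons, self.anchor_lats)
            inside[i] = bool(np.any(d <= self.radius_km))
        return inside


def build_buffer(anchor_lons, anchor_lats, radius_km: float,
                 grid: GridSpec) -> BufferRegion:
    """Rasterize the union of circles of ``radius_km`` around anchors."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    anchor_lons = np.asarray(anchor_lons, dtype=float)
    anchor_lats = np.asarray(anchor_lats, dtype=float)
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    glon, glat = np.meshgrid(lon_c, lat_c)
    flat_lon = glon.ravel()
    flat_lat = glat.ravel()
    min_d = np.full(flat_lon.shape, np.inf)
    # chunk the anchors so the distance matrix stays small
    for start in range(0, len(anchor_lons), 256):
        al = anchor_lons[start:start + 256]
        aa = anchor_lats[start:start + 256]
        d = haversine_km(flat_lon[:, None], flat_lat[:, None], al[None, :], aa[None, :])
        np.minimum(min_d, d.min(axis=1), out=min_d)
    mask = (min_d <= radius_km).reshape(grid.shape)
    return BufferRegion(radius_km=radius_km, anchor_lons=anchor_lons,
                        anchor_lats=anchor_lats, member_mask=mask, grid=grid)


def clean_records(records: pd.DataFrame, max_imprecision_m: float = 10_000.0,
                  buffer: BufferRegion | None = None):
    """Apply the three cleaning rules; return (kept, removal_log).

    The log counts removals per rule under the first rule that fires
    for each record, in the order buffer -> zero-coords -> imprecision.
    """
    if len(records) == 0:
        raise ValueError("records is empty")
    df = records.reset_index(drop=True)
    removed = np.zeros(len(df), dtype=bool)
    log = {"outside_buffer": 0, "zero_coordinates": 0, "imprecision": 0}

    if buffer is not None:
        out = ~buffer.contains(df["lon"].to_numpy(), df["lat"].to_numpy())
        out &= ~removed
        log["outside_buffer"] = int(out.sum())
        removed |= out

    zero = (df["lon"].to_numpy() == 0.0) & (df["lat"].to_numpy() == 0.0)
    zero &= ~removed
    log["zero_coordinates"] = int(zero.sum())
    removed |= zero

    imp = df["imprecision_m"].to_numpy(dtype=float)
    bad = np.isfinite(imp) & (imp > max_imprecision_m)  # strict: == is kept
    bad &= ~removed
    log["imprecision"] = int(bad.sum())
    removed |= bad

    kept = df.loc[~removed].reset_index(drop=True)
    if len(kept) == 0:
        raise EmptyResultError("cleaning removed every record")
    return kept, log


@dataclass
class PixelDataset:
    """Thinned design matrix: one row per grid pixel.

    ``pixel_ids`` are (row, col) tuples in the shared grid indexing;
    ``X`` is pixels x variables with no missing values; ``y`` is the
    binary presence label.
    """

    pixel_ids: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    variable_names: list[str]
    log: dict = field(default_factory=dict)

    @property
    def n_presence(self) -> int:
        return int(self.y.sum())

    @property
    def n_absence(self) -> int:
        return int((self.y == 0).sum())

    def subset_variables(self, names: list[str]) -> "PixelDataset":
        idx = [self.variable_names.index(n) for n in names]
        return PixelDataset(self.pixel_ids, self.X[:, idx].copy(),
                            self.y.copy(), list(names), dict(self.log))

    def to_frame(self) -> pd.DataFrame:
        rows = np.array([p[0] for p in self.pixel_ids])
        cols = np.array([p[1] for p in self.pixel_ids])
        df = pd.DataFrame({"pixel_row": rows, "pixel_col": cols, "y": self.y.astype(int)})
        for j, name in enumerate(self.variable_names):
            df[name] = self.X[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PixelDataset":
        var_names = [c for c in df.columns if c not in ("pixel_row", "pixel_col", "y")]
        ids = list(zip(df["pixel_row"].astype(int), df["pixel_col"].astype(int)))
        return cls(ids, df[var_names].to_numpy(dtype=float),
                   df["y"].to_numpy(dtype=int), var_names)


def thin_to_pixels(records: pd.DataFrame, env: EnvStack) -> PixelDataset:
    """One record per pixel, presence priority; nodata pixels dropped.

    Records falling outside the grid extent or over pixels where any
    predictor is nodata are dropped and counted in the dataset log.
    """
    grid = env.grid
    rows, cols = grid.index_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    inside = rows >= 0
    n_outside = int((~inside).sum())
    rows, cols = rows[inside], cols[inside]
    det = records["detected"].to_numpy(dtype=int)[inside]

    # presence priority: a pixel's label is the max detection in it
    label: dict[tuple[int, int], int] = {}
    for r, c, d in zip(rows, cols, det):
        key = (int(r), int(c))
        if label.get(key, -1) < d:
            label[key] = int(d)

    ids = sorted(label)
    rr = np.array([p[0] for p in ids], dtype=int)
    cc = np.array([p[1] for p in ids], dtype=int)
    X = env.values_at(rr, cc)
    valid = ~np.isnan(X).any(axis=1) & ~env.nodata_mask[rr, cc]
    n_nodata = int((~valid).sum())
    ids = [p for p, v in zip(ids, valid) if v]
    X = X[valid]
    y = np.array([label[p] for p in ids], dtype=int)
    return PixelDataset(ids, X, y, env.layer_names,
                        log={"outside_grid": n_outside, "nodata_pixels": n_nodata,
                             "n_presence_pixels": int(y.sum()),
                             "n_absence_pixels": int((y == 0).sum())})


def sample_absences(data: PixelDataset, ratio: int = 10,
                    seed: int | None = 0) -> PixelDataset:
    """Keep all presences; sample ratio x n_presence absences.

    Sampling is uniform without replacement.  If fewer absences exist
    than requested, all are kept with a warning.
    """
    pres = np.flatnonzero(data.y == 1)
    abs_ = np.flatnonzero(data.y == 0)
    if len(pres) == 0:
        raise ValueError("dataset has no presence pixels")
    n_want = ratio * len(pres)
    rng = np.random.default_rng(seed)
    if len(abs_) <= n_want:
        if len(abs_) < n_want:
            warnings.warn(f"only {len(abs_)} absences available for a "
                          f"1:{ratio} ratio with {len(pres)} presences; keeping all")
        chosen = abs_
    else:
        chosen = rng.choice(abs_, size=n_want, replace=False)
    keep = np.sort(np.concatenate([pres, chosen]))
    return PixelDataset([data.pixel_ids[i] for i in keep], data.X[keep].copy(),
                        data.y[keep].copy(), list(data.variable_names),
                        dict(data.log))
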