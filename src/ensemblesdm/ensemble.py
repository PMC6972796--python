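"""Final ensemble: refit on the full modeling data, project, summarize.

Retained algorithms are refit on the complete modeling dataset
(no held-out test sample) and projected onto environmental raster
stacks — the current conditions and any number of future scenarios.
The ensemble summary is the per-pixel arithmetic mean and sample
variance (denominator n - 1) of the member predictions; variance
highlights where the algorithms disagree.  Cells outside the survey
buffer are flagged rather than deleted, so full-extent rasters remain
writable while summaries are restricted to the calibrated region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from . import algorithms
from .grids import EnvStack
from .occurrences import BufferRegion, PixelDataset


@dataclass
class EnsembleResult:
    scenario: str
    per_algorithm_maps: dict[str, np.ndarray]
    mean_map: np.ndarray
    variance_map: np.ndarray
    buffer_mask: np.ndarray | None = None  # True = inside modeled region

    def inside_values(self, which: str = "mean") -> np.ndarray:
        """Finite map values restricted to the buffered region."""
        arr = self.mean_map if which == "mean" else self.variance_map
        mask = np.isfinite(arr)
        if self.buffer_mask is not None:
            mask &= self.buffer_mask
        return arr[mask]

    def to_netcdf(self, path) -> None:
        data = {f"suitability_{t}": (("row", "col"), m)
                for t, m in self.per_algorithm_maps.items()}
        data["ensemble_mean"] = (("row", "col"), self.mean_map)
        data["ensemble_variance"] = (("row", "col"), self.variance_map)
        if self.buffer_mask is not None:
            data["buffer_mask"] = (("row", "col"), self.buffer_mask.astype("int8"))
        ds = xr.Dataset(data)
        ds.attrs["scenario"] = self.scenario
        ds.to_netcdf(path, engine="scipy")


def refit_full(retained_tags: list[str], data: PixelDataset,
               seed: int = 0) -> list[algorithms.FittedModel]:
    """One final model per retained tag, fitted on all rows."""
    if not retained_tags:
        raise ValueError("retained set is empty; nothing to refit")
    return [algorithms.fit(algorithms.get_spec(tag, seed=seed),
                           data.X, data.y, data.variable_names)
            for tag in retained_tags]


def project(models: list[algorithms.FittedModel], env: EnvStack,
            clamp: bool = True) -> dict[str, np.ndarray]:
    """Per-algorithm suitability rasters over the unmasked cells."""
    if not models:
        raise ValueError("no models to project")
    names = models[0].variable_names
    for m in models:
        missing = [v for v in m.variable_names if v not in env.layers]
        if missing:
            raise KeyError(f"stack is missing layer(s) {missing} "
                           f"required by {m.spec.name}")
    water = ~env.nodata_mask
    rr, cc = np.nonzero(water)
    out: dict[str, np.ndarray] = {}
    for m in models:
        X = env.values_at(rr, cc, m.variable_names)
        valid = ~np.isnan(X).any(axis=1)
        pred = np.full(len(rr), np.nan)
        pred[valid] = m.predict(X[valid])
        if clamp:
            pred = np.clip(pred, 0.0, 1.0)
        grid_map = np.full(env.grid.shape, np.nan)
        grid_map[rr, cc] = pred
        out[m.spec.name] = grid_map
    return out


def ensemble_stats(per_algorithm_maps: dict[str, np.ndarray]):
    """Per-pixel mean and sample (n-1) variance across member maps."""
    stack = np.stack(list(per_algorithm_maps.values()))
    mean = stack.mean(axis=0)
    var = stack.var(axis=0, ddof=1) if stack.shape[0] > 1 \
        else np.zeros_like(mean)
    return mean, var


def build_ensemble(models, env: EnvStack, scenario: str = "current",
                   clamp: bool = True) -> EnsembleResult:
    maps = project(models, env, clamp=clamp)
    mean, var = ensemble_stats(maps)
    return EnsembleResult(scenario=scenario, per_algorithm_maps=maps,
                          mean_map=mean, variance_map=var)


def mask_outside_buffer(result: EnsembleResult,
                        buffer: BufferRegion) -> EnsembleResult:
    """Attach the modeled-region flag; maps themselves are untouched."""
    result.buffer_mask = buffer.member_mask.copy()
    return result
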