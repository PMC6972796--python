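"""Refit the retained ensemble and project current + future scenarios.

Refits every retained algorithm on the complete modeling dataset,
projects onto the current stack and the four future stacks, computes
per-pixel ensemble mean and variance flagged by the survey buffer, and
scores the current mean map with the continuous Boyce index against
the modeled and the external presence sets.  Writes per-scenario
summaries and maps to results/projection/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ensemblesdm import ensemble
from ensemblesdm.evaluation import boyce
from ensemblesdm.grids import EnvStack
from ensemblesdm.occurrences import (PixelDataset, build_buffer,
                                     mean_pairwise_haversine)

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "projection"
SEED = 31
SCENARIOS = ["2040-2050_rcp26", "2040-2050_rcp85",
             "2090-2100_rcp26", "2090-2100_rcp85"]


def main() -> None:
    env = EnvStack.from_netcdf(ROOT / "world" / "env_current.nc")
    with open(ROOT / "evaluation" / "retained.json") as fh:
        info = json.load(fh)
    modeling = PixelDataset.from_frame(
        pd.read_csv(ROOT / "selection" / "pixels_modeling.csv"))
    modeling = modeling.subset_variables(info["modal_subset"])

    records = pd.read_csv(ROOT / "world" / "occurrences.csv")
    surv = records[records["source"] == "survey"]
    pres = surv[surv["detected"] == 1]
    radius = mean_pairwise_haversine(pres["lon"], pres["lat"])
    buffer = build_buffer(surv["lon"].to_numpy(), surv["lat"].to_numpy(),
                          radius, env.grid)

    models = ensemble.refit_full(info["retained"], modeling, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    results = {}
    for label in ["current"] + SCENARIOS:
        stack = env if label == "current" else \
            EnvStack.from_netcdf(ROOT / "world" / f"env_{label}.nc")
        res = ensemble.build_ensemble(models, stack, label)
        ensemble.mask_outside_buffer(res, buffer)
        res.to_netcdf(OUT / f"ensemble_{label}.nc")
        results[label] = res
        rows.append({"scenario": label,
                     "mean_suitability": float(np.mean(res.inside_values("mean"))),
                     "mean_variance": float(np.mean(res.inside_values("variance")))})
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "scenario_summary.csv", index=False)

    cur = results["current"]
    water = ~env.nodata_mask & cur.buffer_mask & np.isfinite(cur.mean_map)
    bg = cur.mean_map[water]
    pres_ids = [p for p, y in zip(modeling.pixel_ids, modeling.y) if y == 1]
    internal = boyce(bg, np.array([cur.mean_map[r, c] for r, c in pres_ids]))
    ext = pd.read_csv(ROOT / "world" / "external_presences.csv")
    er, ec = env.grid.index_of(ext["lon"].to_numpy(), ext["lat"].to_numpy())
    escores = cur.mean_map[er[er >= 0], ec[er >= 0]]
    external = boyce(bg, escores[np.isfinite(escores)])
    with open(OUT / "boyce.json", "w") as fh:
        json.dump({"internal": internal.boyce, "external": external.boyce},
                  fh, indent=2)

    print(summary.to_string(index=False))
    print(f"Boyce: internal {internal.boyce:.3f}, external {external.boyce:.3f}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
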