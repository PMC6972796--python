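"""End-to-end pipeline: world -> cleaning -> selection -> ensemble -> maps.

Stage order follows the standard ensemble-modeling workflow:

1. acquire the world (simulate a virtual species, or load user files);
2. build the survey buffer (radius = mean pairwise great-circle
   distance between presence points; anchors = all surveyed points)
   and clean the records;
3. thin records to the predictor grid with presence priority;
4. stability selection: repeated 1:10 absence resampling, variable
   selection per resample, modal subset + representative seed;
5. fix the modeling sample from the representative seed and the modal
   variable subset; record the selection GLM's AUC and D^2;
6. cross-validate all ensemble algorithms, screen by AUC/TSS/range;
7. refit the retained algorithms on the full modeling sample and
   project onto the current and future stacks (mean + variance maps,
   flagged outside the buffer);
8. score the masked current mean map with the continuous Boyce index
   against the modeled presences and an external presence set.

Every stage logs its seed and record counts into the report, and each
stage failure raises an error naming the stage; artifacts written
before the failure are left in place.
"""

from __future__ import annotations

import json
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import algorithms, ensemble, evaluation, occurrences, selection, synthetic
from .config import PipelineConfig
from .grids import EnvStack, GridSpec
from .occurrences import (PixelDataset, build_buffer, clean_records,
                          mean_pairwise_haversine, sample_absences,
                          thin_to_pixels)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seed(master_seed: int, stage: str) -> int:
    key = zlib.crc32(stage.encode()) % (2 ** 16)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_world(cfg: PipelineConfig, seed: int):
    """Build the synthetic study system from the config."""
    sim = cfg.simulate
    grid = GridSpec(n_rows=sim.n_rows, n_cols=sim.n_cols, lon_min=sim.lon_min,
                    lat_min=sim.lat_min, cell_size=sim.cell_size)
    names = (synthetic.BIO_ORACLE_V2_CODES if sim.n_layers == 24 else None)
    name_list = names or [f"env{i:02d}" for i in range(sim.n_layers)]
    pairs = [(name_list.index(a), name_list.index(b))
             for a, b in sim.collinear_pairs
             if a in name_list and b in name_list]
    env = synthetic.generate_env_layers(
        grid, sim.n_layers, smoothness=sim.smoothness,
        inter_layer_corr=sim.inter_layer_corr, collinear_pairs=pairs,
        layer_names=name_list, land_fraction=sim.land_fraction,
        seed=_stage_seed(seed, "env"))
    truth = synthetic.TrueModel(driver_names=list(sim.betas),
                                beta0=sim.beta0, betas=dict(sim.betas))
    suit = synthetic.make_true_suitability(env, truth)
    records = synthetic.sample_survey(
        suit, grid, env.nodata_mask,
        effort_centers=[tuple(c) for c in sim.effort_centers],
        n_records=sim.n_records, prevalence_target=sim.prevalence_target,
        online_n=sim.online_n,
        imprecision_dist=(sim.imprecision_log_mean, sim.imprecision_log_sd),
        zero_coord_fraction=sim.zero_coord_fraction,
        kernel_sd_deg=sim.kernel_sd_deg, seed=_stage_seed(seed, "survey"))
    external = synthetic.sample_external_presences(
        suit, grid, env.nodata_mask, n=sim.external_n,
        seed=_stage_seed(seed, "external"))
    scenarios = {label: synthetic.perturb_future(
                     env, {k: (v[0], float(v[1])) for k, v in deltas.items()})
                 for label, deltas in sim.scenarios.items()}
    return env, records, external, scenarios, truth, suit


def load_world(cfg: PipelineConfig):
    files = cfg.files
    env = EnvStack.from_netcdf(files.env)
    records = pd.read_csv(files.occurrences)
    external = (pd.read_csv(files.external_presences)
                if files.external_presences else None)
    scenarios = {label: EnvStack.from_netcdf(path)
                 for label, path in files.scenarios.items()}
    return env, records, external, scenarios, None, None


def run_pipeline(cfg: PipelineConfig, out_dir=None, seed: int | None = None) -> dict:
    """Execute the full workflow; return the machine-readable report."""
    seed = cfg.seed if seed is None else seed
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": {}}

    def record(stage: str, **info):
        report["stages"][stage] = info

    # ---------------------------------------------------------- 1. world
    try:
        if cfg.mode == "simulate":
            env, records, external, scenarios, truth, true_suit = \
                simulate_world(cfg, seed)
        else:
            env, records, external, scenarios, truth, true_suit = load_world(cfg)
    except Exception as e:  # noqa: BLE001
        raise StageError("world", e)
    record("world", mode=cfg.mode, n_records=len(records),
           n_layers=len(env.layer_names),
           true_drivers=sorted(truth.driver_names) if truth else None)
    if out is not None:
        env.to_netcdf(out / "env_current.nc")
        records.to_csv(out / "occurrences.csv", index=False)

    # --------------------------------------------- 2. buffer + cleaning
    try:
        surv = records[records["source"] == "survey"]
        pres = surv[surv["detected"] == 1]
        radius = mean_pairwise_haversine(pres["lon"], pres["lat"])
        # anchor on the unique survey pixels (identical membership,
        # far fewer circles than raw records)
        arow, acol = env.grid.index_of(surv["lon"].to_numpy(),
                                       surv["lat"].to_numpy())
        keep = arow >= 0
        upix = np.unique(np.stack([arow[keep], acol[keep]]), axis=1)
        alon, alat = env.grid.center_of(upix[0], upix[1])
        buffer = build_buffer(alon, alat, radius, env.grid)
        cleaned, removal_log = clean_records(
            records, max_imprecision_m=cfg.max_imprecision_m, buffer=buffer)
    except Exception as e:  # noqa: BLE001
        raise StageError("clean", e)
    record("clean", buffer_radius_km=radius, removal_log=removal_log,
           n_records_kept=len(cleaned))

    # ------------------------------------------------------- 3. thinning
    try:
        thinned = thin_to_pixels(cleaned, env)
    except Exception as e:  # noqa: BLE001
        raise StageError("thin", e)
    record("thin", **thinned.log)
    if out is not None:
        thinned.to_frame().to_csv(out / "pixels_thinned.csv", index=False)

    # -------------------------------------------- 4. stability selection
    try:
        sel_seed = _stage_seed(seed, "selection")
        tally = selection.stability_selection(
            thinned, n_repeats=cfg.selection_repeats, ratio=cfg.absence_ratio,
            master_seed=sel_seed, threshold=cfg.correlation_threshold,
            q=cfg.fdr_q)
    except Exception as e:  # noqa: BLE001
        raise StageError("select_vars", e)
    freq = {" + ".join(k) if k else "(empty)": v
            for k, v in sorted(tally.subset_frequencies.items(),
                               key=lambda kv: -kv[1])}
    record("select_vars", seed=sel_seed, n_repeats=tally.n_repeats,
           modal_subset=list(tally.modal_subset),
           modal_count=tally.subset_frequencies[tally.modal_subset],
           n_unique_subsets=len(tally.subset_frequencies),
           representative_seed=tally.representative_seed,
           subset_frequencies=freq)
    if out is not None:
        with open(out / "tally.json", "w") as fh:
            json.dump(report["stages"]["select_vars"], fh, indent=2)
    if not tally.modal_subset:
        raise StageError("select_vars",
                         RuntimeError("modal variable subset is empty"))

    # ------------------------------------------------ 5. modeling sample
    try:
        modeling_full = sample_absences(thinned, ratio=cfg.absence_ratio,
                                        seed=tally.representative_seed)
        sel = selection.select_variables(modeling_full,
                                         threshold=cfg.correlation_threshold,
                                         q=cfg.fdr_q)
        modeling = modeling_full.subset_variables(list(tally.modal_subset))
        glm_auc = evaluation.auc(modeling.y, sel.model.predict(
            modeling_full.X[:, [modeling_full.variable_names.index(n)
                                for n in sel.final_subset]]))
    except Exception as e:  # noqa: BLE001
        raise StageError("modeling_sample", e)
    record("modeling_sample", n_presence=modeling.n_presence,
           n_absence=modeling.n_absence, selection_glm_auc=glm_auc,
           selection_glm_d_squared=sel.d_squared, selection_glm_aic=sel.aic,
           final_subset=list(sel.final_subset))
    if out is not None:
        modeling.to_frame().to_csv(out / "pixels_modeling.csv", index=False)

    # -------------------------------------------------- 6. CV + screening
    try:
        tags = [s.name for s in algorithms.registry()] \
            if cfg.algorithms == ["all"] else list(cfg.algorithms)
        plan = evaluation.CVPlan(n_runs=cfg.cv_runs,
                                 test_fraction=cfg.cv_test_fraction,
                                 seed=_stage_seed(seed, "cv"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = evaluation.evaluate_algorithms(
                tags, modeling, plan, seed=_stage_seed(seed, "fit"))
        retained = evaluation.screen_algorithms(
            metrics, auc_min=cfg.auc_min, tss_min=cfg.tss_min,
            range_tol=cfg.range_tol)
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", e)
    record("evaluate",
           metrics={m.algorithm: {"mean_auc": m.mean_auc,
                                  "mean_tss": m.mean_tss,
                                  "range_violation": m.range_violation_fraction}
                    for m in metrics},
           retained=retained, n_retained=len(retained))
    if out is not None:
        with open(out / "metrics.json", "w") as fh:
            json.dump(report["stages"]["evaluate"], fh, indent=2)

    # --------------------------------------------- 7. refit + projection
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = ensemble.refit_full(retained, modeling,
                                         seed=_stage_seed(seed, "fit"))
            results = {"current": ensemble.build_ensemble(models, env, "current")}
            for label, scen_env in scenarios.items():
                results[label] = ensemble.build_ensemble(models, scen_env, label)
        for res in results.values():
            ensemble.mask_outside_buffer(res, buffer)
    except Exception as e:  # noqa: BLE001
        raise StageError("project", e)
    scen_summary = {label: {
        "mean_suitability_inside": float(np.mean(res.inside_values("mean"))),
        "mean_variance_inside": float(np.mean(res.inside_values("variance"))),
    } for label, res in results.items()}
    record("project", scenarios=scen_summary)
    if out is not None:
        for label, res in results.items():
            res.to_netcdf(out / f"ensemble_{label}.nc")

    # --------------------------------------------------------- 8. Boyce
    try:
        cur = results["current"]
        water = ~env.nodata_mask & cur.buffer_mask & np.isfinite(cur.mean_map)
        background = cur.mean_map[water]
        pres_ids = [p for p, yy in zip(modeling.pixel_ids, modeling.y) if yy == 1]
        pr = np.array([cur.mean_map[r, c] for r, c in pres_ids])
        boyce_internal = evaluation.boyce(background, pr[np.isfinite(pr)])
        boyce_external = None
        if external is not None and len(external):
            er, ec = env.grid.index_of(external["lon"].to_numpy(),
                                       external["lat"].to_numpy())
            ok = (er >= 0)
            escores = cur.mean_map[er[ok], ec[ok]]
            escores = escores[np.isfinite(escores)]
            if len(escores):
                boyce_external = evaluation.boyce(background, escores).boyce
    except Exception as e:  # noqa: BLE001
        raise StageError("boyce", e)
    record("boyce", internal=boyce_internal.boyce, external=boyce_external,
           n_background=int(water.sum()))

    report["retained"] = retained
    report["modal_subset"] = list(tally.modal_subset)
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
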