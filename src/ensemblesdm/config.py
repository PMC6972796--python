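"""Declarative pipeline configuration.

A single config drives the whole run: either a synthetic virtual-
species world is simulated, or user-supplied files (occurrence CSV and
NetCDF raster stacks in the package schema) are ingested; the
downstream stages and their defaults mirror standard practice —
correlation threshold 0.8, FDR level 0.05, 1,000 absence resamples at
a 1:10 presence-absence ratio, 10 cross-validation runs holding out
15%, and retention thresholds of AUC 0.7 / TSS 0.5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class SimulateConfig:
    """Synthetic world: study conditions for the virtual species."""

    n_rows: int = 120
    n_cols: int = 120
    lon_min: float = -60.0
    lat_min: float = -30.0
    cell_size: float = 0.5
    n_layers: int = 24
    smoothness: float = 6.0
    inter_layer_corr: float = 0.9
    collinear_pairs: list[list[str]] = field(default_factory=lambda: [
        ["BO2_tempmin_bdmean", "BO2_tempmax_ss"],
        ["BO2_chlomin_ss", "BO2_chlomean_ss"],
        ["BO2_salinitymax_ss", "BO2_salinitymean_ss"],
    ])
    land_fraction: float = 0.2
    beta0: float = -5.5
    betas: dict[str, float] = field(default_factory=lambda: {
        "BO2_tempmin_bdmean": 1.4,
        "BO2_temprange_ss": -1.0,
        "BO2_chlomin_ss": 1.1,
        "BO2_salinitymax_ss": -0.8,
    })
    effort_centers: list[list[float]] = field(default_factory=lambda: [
        [-45.0, 10.0], [-20.0, 5.0], [-10.0, -15.0], [-50.0, -5.0],
    ])
    kernel_sd_deg: float = 6.0
    n_records: int = 10583
    prevalence_target: float = 73.0 / 10583.0
    online_n: int = 30
    zero_coord_fraction: float = 0.1
    imprecision_log_mean: float = 7.5
    imprecision_log_sd: float = 1.5
    external_n: int = 40
    # temperature deltas in layer (standardized) units per scenario
    scenarios: dict[str, dict[str, list]] = field(default_factory=lambda: {
        "2040-2050_rcp26": {"BO2_tempmin_bdmean": ["add", 0.3],
                            "BO2_tempmax_ss": ["add", 0.3]},
        "2040-2050_rcp85": {"BO2_tempmin_bdmean": ["add", 0.7],
                            "BO2_tempmax_ss": ["add", 0.7]},
        "2090-2100_rcp26": {"BO2_tempmin_bdmean": ["add", 0.6],
                            "BO2_tempmax_ss": ["add", 0.6]},
        "2090-2100_rcp85": {"BO2_tempmin_bdmean": ["add", 1.8],
                            "BO2_tempmax_ss": ["add", 1.8]},
    })


@dataclass
class FilesConfig:
    """User-supplied inputs in the package schema (optional mode)."""

    env: str = ""
    occurrences: str = ""
    external_presences: str = ""
    scenarios: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # "simulate" | "files"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    files: FilesConfig = field(default_factory=FilesConfig)
    # variable selection
    correlation_threshold: float = 0.8
    fdr_q: float = 0.05
    selection_repeats: int = 1000
    absence_ratio: int = 10
    # cross-validation & screening
    cv_runs: int = 10
    cv_test_fraction: float = 0.15
    auc_min: float = 0.7
    tss_min: float = 0.5
    range_tol: float = 0.05
    # ensemble members ("all" or explicit tags)
    algorithms: list[str] = field(default_factory=lambda: ["all"])
    max_imprecision_m: float = 10_000.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        for name, lo, hi in [("correlation_threshold", 0, 1), ("fdr_q", 0, 1),
                             ("cv_test_fraction", 0, 1), ("auc_min", 0, 1),
                             ("range_tol", 0, 1)]:
            v = getattr(self, name)
            if not (lo < v < hi or v in (lo, hi)):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not (-1 <= self.tss_min <= 1):
            raise ValueError("tss_min outside [-1, 1]")
        if self.selection_repeats < 1 or self.cv_runs < 1 or self.absence_ratio < 1:
            raise ValueError("counts must be >= 1")

    # ------------------------------------------------------------- yaml
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = SimulateConfig(**raw.pop("simulate", {}))
        files = FilesConfig(**raw.pop("files", {}))
        return cls(simulate=sim, files=files, **raw)
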