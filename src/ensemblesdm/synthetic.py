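"""Virtual-species worlds for validating the distribution-modeling pipeline.

The generator emulates the statistical structure of an open-ocean
presence-absence survey dataset: a stack of spatially autocorrelated
environmental layers (some deliberately collinear), a known logistic
suitability surface driven by a small subset of those layers, a large
spatially clustered survey sample with very low presence prevalence,
a handful of extra presence-only "online" records carrying reported
coordinate imprecision (some of it large enough to trip the cleaning
rules), and perturbed future-scenario stacks.

Because the true drivers and the true suitability are known, every
downstream stage — cleaning, thinning, variable selection, ensemble
screening, projection — can be validated without any data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import ConfigurationError, EnvStack, GridSpec
from .glmfit import expit

#: Bio-ORACLE v2.0 layer codes for the 24 candidate predictors used in
#: tropical-Atlantic whale-shark modeling: surface and mean-depth
#: temperature, surface chlorophyll, surface current velocity, and
#: surface and mean-depth salinity, each as max/mean/min/range.
BIO_ORACLE_V2_CODES = [
    "BO2_tempmax_ss", "BO2_tempmean_ss", "BO2_tempmin_ss", "BO2_temprange_ss",
    "BO2_tempmax_bdmean", "BO2_tempmean_bdmean", "BO2_tempmin_bdmean",
    "BO2_temprange_bdmean",
    "BO2_chlomax_ss", "BO2_chlomean_ss", "BO2_chlomin_ss", "BO2_chlorange_ss",
    "BO2_curvelmax_ss", "BO2_curvelmean_ss", "BO2_curvelmin_ss",
    "BO2_curvelrange_ss",
    "BO2_salinitymax_ss", "BO2_salinitymean_ss", "BO2_salinitymin_ss",
    "BO2_salinityrange_ss",
    "BO2_salinitymax_bdmean", "BO2_salinitymean_bdmean",
    "BO2_salinitymin_bdmean", "BO2_salinityrange_bdmean",
]


@dataclass
class TrueModel:
    """Known logistic environment-suitability relationship.

    suitability = expit(beta0 + sum_d beta_d * x_d) over the driver
    layers; the ground truth a virtual-species study validates against.
    """

    driver_names: list[str]
    beta0: float
    betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.driver_names) - set(self.betas)
        if missing:
            raise ConfigurationError(f"betas missing for drivers: {sorted(missing)}")


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Standardized Gaussian random field via smoothed white noise."""
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, sigma=smoothness, mode="wrap")
    z = (z - z.mean()) / z.std()
    return z


def _land_mask(rng: np.random.Generator, shape, fraction: float) -> np.ndarray:
    """Contiguous 'land' blobs covering roughly ``fraction`` of cells."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    f = _smooth_field(rng, shape, smoothness=max(shape) / 12)
    thresh = np.quantile(f, 1.0 - fraction)
    return f > thresh


def generate_env_layers(grid: GridSpec, n_layers: int, smoothness: float = 4.0,
                        inter_layer_corr: float = 0.0,
                        collinear_pairs: list[tuple[int, int]] | None = None,
                        layer_names: list[str] | None = None,
                        land_fraction: float = 0.2,
                        seed: int = 0) -> EnvStack:
    """Generate spatially autocorrelated environmental layers.

    Each layer is smoothed Gaussian noise with smoothing length
    ``smoothness`` (in cells).  For every (i, j) in
    ``collinear_pairs``, layer j is rebuilt as
    ``rho * layer_i + sqrt(1 - rho^2) * independent noise`` with
    ``rho = inter_layer_corr``, giving a controlled pairwise Pearson
    correlation.  A fraction of cells is masked as contiguous land
    blobs so every raster operation must handle nodata.
    Deterministic given ``seed``.
    """
    if n_layers < 1:
        raise ConfigurationError("n_layers must be >= 1")
    if not (0.0 <= inter_layer_corr < 1.0):
        raise ConfigurationError("inter_layer_corr must be in [0, 1)")
    if layer_names is None:
        if n_layers == len(BIO_ORACLE_V2_CODES):
            layer_names = list(BIO_ORACLE_V2_CODES)
        else:
            layer_names = [f"env{i:02d}" for i in range(n_layers)]
    if len(layer_names) != n_layers:
        raise ConfigurationError("layer_names length must equal n_layers")

    rng = np.random.default_rng(seed)
    fields = [_smooth_field(rng, grid.shape, smoothness) for _ in range(n_layers)]
    rho = inter_layer_corr
    for i, j in (collinear_pairs or []):
        eps = _smooth_field(rng, grid.shape, smoothness)
        fields[j] = rho * fields[i] + np.sqrt(1 - rho ** 2) * eps
    mask = _land_mask(rng, grid.shape, land_fraction)
    return EnvStack(grid, dict(zip(layer_names, fields)), mask)


def make_true_suitability(env: EnvStack, model: TrueModel) -> np.ndarray:
    """Per-cell logistic suitability; NaN where the stack is masked."""
    for d in model.driver_names:
        if d not in env.layers:
            raise ConfigurationError(f"driver {d!r} not in the stack")
    eta = np.full(env.grid.shape, model.beta0, dtype=float)
    for d in model.driver_names:
        eta = eta + model.betas[d] * env.layers[d]
    suit = expit(eta)
    suit[env.nodata_mask] = np.nan
    return suit


def _effort_field(grid: GridSpec, centers: list[tuple[float, float]],
                  kernel_sd_deg: float, mask: np.ndarray) -> np.ndarray:
    """Clustered survey-effort density: mixture of Gaussian kernels."""
    glon, glat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    eff = np.zeros(grid.shape)
    for clon, clat in centers:
        eff += np.exp(-((glon - clon) ** 2 + (glat - clat) ** 2)
                      / (2 * kernel_sd_deg ** 2))
    eff[mask] = 0.0
    total = eff.sum()
    if total <= 0:
        raise ConfigurationError("effort field is empty (all centers over land?)")
    return eff / total


def sample_survey(suit: np.ndarray, grid: GridSpec, nodata_mask: np.ndarray,
                  effort_centers: list[tuple[float, float]],
                  n_records: int, prevalence_target: float,
                  online_n: int = 0,
                  imprecision_dist: tuple[float, float] = (7.5, 1.5),
                  zero_coord_fraction: float = 0.0,
                  kernel_sd_deg: float = 3.0,
                  seed: int = 0) -> pd.DataFrame:
    """Draw a biased survey sample plus presence-only online records.

    Survey locations are drawn from a kernel-mixture effort field
    around ``effort_centers`` (fishing activity clusters spatially);
    detection at a visited cell is Bernoulli with the cell's true
    suitability rescaled so the expected prevalence over the effort
    field equals ``prevalence_target``.  Online records are
    presence-only, drawn proportionally to suitability over the whole
    water area, and carry a lognormal reported imprecision in meters
    (``imprecision_dist`` = (mean, sd) of log-imprecision) — some draws
    exceed 10,000 m so the cleaning rule has work to do.  A
    ``zero_coord_fraction`` of online records has lon = lat = 0 to
    exercise the bad-coordinate filter.  Deterministic given ``seed``.
    """
    if n_records < 1:
        raise ConfigurationError("n_records must be >= 1")
    if not effort_centers:
        raise ConfigurationError("effort_centers must be nonempty")
    if not (0.0 < prevalence_target < 1.0):
        raise ValueError("prevalence_target must be in (0, 1)")

    rng = np.random.default_rng(seed)
    eff = _effort_field(grid, effort_centers, kernel_sd_deg, nodata_mask)
    flat_eff = eff.ravel()
    suit_flat = np.where(np.isnan(suit.ravel()), 0.0, suit.ravel())

    cells = rng.choice(len(flat_eff), size=n_records, p=flat_eff)
    # rescale detection probability to hit the target prevalence in
    # expectation under the realized effort distribution
    expected = float(flat_eff @ suit_flat)
    scale = prevalence_target / expected if expected > 0 else 0.0
    p_detect = np.clip(suit_flat[cells] * scale, 0.0, 1.0)
    detected = (rng.random(n_records) < p_detect).astype(int)

    rows, cols = np.unravel_index(cells, grid.shape)
    # uniform position within the visited pixel
    lon = grid.lon_min + (cols + rng.random(n_records)) * grid.cell_size
    lat = grid.lat_max - (rows + rng.random(n_records)) * grid.cell_size
    survey = pd.DataFrame({"lon": lon, "lat": lat, "detected": detected,
                           "source": "survey", "imprecision_m": np.nan})

    frames = [survey]
    if online_n > 0:
        water = ~nodata_mask.ravel()
        p = np.where(water, suit_flat, 0.0)
        p = p / p.sum()
        ocells = rng.choice(len(p), size=online_n, p=p)
        orows, ocols = np.unravel_index(ocells, grid.shape)
        olon = grid.lon_min + (ocols + rng.random(online_n)) * grid.cell_size
        olat = grid.lat_max - (orows + rng.random(online_n)) * grid.cell_size
        mu, sd = imprecision_dist
        imp = rng.lognormal(mean=mu, sigma=sd, size=online_n)
        n_zero = int(round(zero_coord_fraction * online_n))
        if n_zero:
            zidx = rng.choice(online_n, size=n_zero, replace=False)
            olon[zidx] = 0.0
            olat[zidx] = 0.0
        frames.append(pd.DataFrame({"lon": olon, "lat": olat, "detected": 1,
                                    "source": "online", "imprecision_m": imp}))
    return pd.concat(frames, ignore_index=True)


def sample_external_presences(suit: np.ndarray, grid: GridSpec,
                              nodata_mask: np.ndarray, n: int,
                              seed: int = 0) -> pd.DataFrame:
    """Independent presence-only set for external model evaluation."""
    rng = np.random.default_rng(seed)
    suit_flat = np.where(np.isnan(suit.ravel()), 0.0, suit.ravel())
    p = np.where(~nodata_mask.ravel(), suit_flat, 0.0)
    p = p / p.sum()
    cells = rng.choice(len(p), size=n, p=p)
    rows, cols = np.unravel_index(cells, grid.shape)
    lon = grid.lon_min + (cols + rng.random(n)) * grid.cell_size
    lat = grid.lat_max - (rows + rng.random(n)) * grid.cell_size
    return pd.DataFrame({"lon": lon, "lat": lat, "detected": 1,
                         "source": "external_eval", "imprecision_m": np.nan})


def perturb_future(env: EnvStack, scenario: dict[str, tuple[str, float]]) -> EnvStack:
    """Apply additive/multiplicative deltas to named layers.

    ``scenario`` maps layer name -> ("add", delta) or ("mul", factor).
    Untouched layers are copied verbatim; grid and mask are shared
    unchanged.
    """
    for name in scenario:
        if name not in env.layers:
            raise KeyError(f"scenario references unknown layer {name!r}")
    out = env.copy()
    for name, (kind, value) in scenario.items():
        if kind == "add":
            out.layers[name] = out.layers[name] + value
        elif kind == "mul":
            out.layers[name] = out.layers[name] * value
        else:
            raise ValueError(f"unknown perturbation kind {kind!r}")
        out.layers[name][out.nodata_mask] = np.nan
    return out
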