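"""Resampling-stabilized predictor selection for presence-absence GLMs.

The selection pipeline mirrors the multi-stage GLM screen used in
distribution modeling practice (cf. fuzzySim's multGLM):

1. bivariate screen — each candidate is tested alone against the
   response with a likelihood-ratio test of the single-variable
   logistic model versus the null;
2. correlation filter — while any pair of candidates has |Pearson r|
   above a threshold (default 0.8), the less informative member
   (larger bivariate p) is dropped;
3. false-discovery-rate screen — Benjamini–Hochberg at level q
   (default 0.05) on the surviving bivariate p-values;
4. forward–backward stepwise selection by AIC from the intercept-only
   model, stopping when no single addition or removal strictly lowers
   the AIC.

Because the absence subsample (1:10 presence-absence ratio) is random,
the whole pipeline is repeated over many resamples and the modal
variable subset is taken forward (stability selection), together with
a representative resampling seed that reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .glmfit import LogisticFit, fit_logistic
from .occurrences import PixelDataset, sample_absences


@dataclass
class BivariateScreen:
    variable: str
    p_value: float
    deviance_explained: float


@dataclass
class SelectionResult:
    """Outcome of one pass of the four-stage selection pipeline.

    Invariant: final_subset ⊆ kept_after_fdr ⊆ kept_after_correlation.
    """

    kept_after_correlation: list[str]
    kept_after_fdr: list[str]
    final_subset: list[str]
    model: LogisticFit
    aic: float
    d_squared: float
    screens: list[BivariateScreen] = field(default_factory=list)


@dataclass
class StabilityTally:
    n_repeats: int
    subset_frequencies: dict[tuple[str, ...], int]
    modal_subset: tuple[str, ...]
    representative_seed: int


def screen_bivariate(X: np.ndarray, y: np.ndarray,
                     variable_names: list[str]) -> list[BivariateScreen]:
    """LRT of each single-variable logistic model against the null.

    p comes from chi-square(1) on the deviance drop; a constant
    variable gets p = 1 and zero explained deviance.
    """
    from scipy.stats import chi2

    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("response must contain both classes")
    out = []
    for j, name in enumerate(variable_names):
        x = X[:, j]
        if np.ptp(x) == 0:
            out.append(BivariateScreen(name, 1.0, 0.0))
            continue
        fit = fit_logistic(x[:, None], y)
        drop = max(fit.null_deviance - fit.deviance, 0.0)
        p = float(chi2.sf(drop, df=1))
        out.append(BivariateScreen(name, p, max(fit.d_squared, 0.0)))
    return out


def correlation_filter(X: np.ndarray, screens: list[BivariateScreen],
                       variable_names: list[str],
                       threshold: float = 0.8) -> list[str]:
    """Drop the less informative member of each highly correlated pair.

    Iterative: while any surviving pair has |Pearson r| > threshold,
    the variable with the largest bivariate p among those involved in
    an offending pair is dropped (ties: smaller explained deviance,
    then later position in the original order), and the remaining
    pairs are re-checked.
    """
    by_name = {s.variable: s for s in screens}
    names = list(variable_names)
    order = {n: i for i, n in enumerate(variable_names)}
    if X.shape[1] < 2:
        return names
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    alive = list(range(len(names)))
    while True:
        offenders: set[int] = set()
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                i, j = alive[ai], alive[bi]
                if abs(corr[i, j]) > threshold:
                    offenders.update((i, j))
        if not offenders:
            break
        worst = max(offenders, key=lambda i: (
            by_name[names[i]].p_value,
            -by_name[names[i]].deviance_explained,
            order[names[i]],
        ))
        alive.remove(worst)
    return [names[i] for i in alive]


def fdr_screen(screens: list[BivariateScreen], q: float = 0.05) -> list[str]:
    """Benjamini–Hochberg at level q on the bivariate p-values."""
    if not screens:
        return []
    pvals = np.array([s.p_value for s in screens])
    keep, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return [s.variable for s, k in zip(screens, keep) if k]


def stepwise_aic(X: np.ndarray, y: np.ndarray, candidate_names: list[str],
                 variable_names: list[str]):
    """Forward–backward stepwise logistic selection by AIC.

    Starts from the intercept-only model; at each step the single
    addition or removal with the lowest AIC is applied if it strictly
    improves on the current AIC.  Returns (final subset in insertion
    order, fitted model, AIC).
    """
    col = {n: variable_names.index(n) for n in candidate_names}
    y = np.asarray(y, dtype=float)
    included: list[str] = []
    current = fit_logistic(np.empty((len(y), 0)), y)
    cache: dict[tuple[str, ...], LogisticFit] = {(): current}

    def fit_for(subset: list[str]) -> LogisticFit:
        key = tuple(sorted(subset))
        if key not in cache:
            cache[key] = fit_logistic(X[:, [col[n] for n in subset]], y)
        return cache[key]

    while True:
        moves: list[tuple[float, list[str]]] = []
        for name in candidate_names:
            if name not in included:
                trial = included + [name]
                moves.append((fit_for(trial).aic, trial))
        for name in included:
            trial = [n for n in included if n != name]
            moves.append((fit_for(trial).aic, trial))
        if not moves:
            break
        best_aic, best_subset = min(moves, key=lambda t: (t[0], len(t[1])))
        if best_aic < current.aic:
            included = best_subset
            current = fit_for(included)
        else:
            break
    return included, current, current.aic


def select_variables(data: PixelDataset, threshold: float = 0.8,
                     q: float = 0.05) -> SelectionResult:
    """Full pipeline: screen -> correlation filter -> FDR -> stepwise AIC."""
    screens = screen_bivariate(data.X, data.y, data.variable_names)
    kept_corr = correlation_filter(data.X, screens, data.variable_names, threshold)
    corr_screens = [s for s in screens if s.variable in kept_corr]
    kept_fdr = fdr_screen(corr_screens, q)
    subset, model, aic = stepwise_aic(data.X, data.y, kept_fdr, data.variable_names)
    return SelectionResult(kept_after_correlation=kept_corr,
                           kept_after_fdr=kept_fdr, final_subset=subset,
                           model=model, aic=aic, d_squared=model.d_squared,
                           screens=screens)


def explained_deviance(model: LogisticFit) -> float:
    """D^2 = 1 - residual/null deviance (= McFadden's pseudo-R^2 here)."""
    return model.d_squared


def derive_repeat_seed(master_seed: int, repeat: int) -> int:
    """Independent, order-invariant per-repeat seed below 2^31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(repeat),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def stability_selection(thinned: PixelDataset, n_repeats: int = 1000,
                        ratio: int = 10, master_seed: int = 0,
                        threshold: float = 0.8, q: float = 0.05) -> StabilityTally:
    """Repeat absence resampling + selection; tally the chosen subsets.

    Subsets are canonicalized as sorted name tuples.  The modal subset
    is the one with the highest count (ties: fewer variables, then
    lexicographic), and ``representative_seed`` is the seed of the
    first repeat whose resample produced it, so the exact modeling
    sample can be regenerated.
    """
    if thinned.n_presence == 0 or thinned.n_absence == 0:
        raise ValueError("thinned data must contain both classes")
    tally: dict[tuple[str, ...], int] = {}
    first_seed: dict[tuple[str, ...], int] = {}
    for r in range(n_repeats):
        seed = derive_repeat_seed(master_seed, r)
        sample = sample_absences(thinned, ratio=ratio, seed=seed)
        res = select_variables(sample, threshold=threshold, q=q)
        key = tuple(sorted(res.final_subset))
        tally[key] = tally.get(key, 0) + 1
        first_seed.setdefault(key, seed)
    if not tally:
        raise RuntimeError("no repeat produced a selection result")
    modal = min(tally, key=lambda k: (-tally[k], len(k), k))
    return StabilityTally(n_repeats=n_repeats, subset_frequencies=tally,
                          modal_subset=modal,
                          representative_seed=first_seed[modal])
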