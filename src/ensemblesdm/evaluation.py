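"""Cross-validation, performance screening and the continuous Boyce index.

Members of the ensemble are cross-validated with repeated stratified
subsampling (default 10 runs, each reserving 15% of every class for
testing) and scored by AUC (threshold-independent discrimination) and
the true skill statistic TSS = sensitivity + specificity - 1 at the
threshold maximizing that sum.  Algorithms with mean test AUC below
0.7 or mean test TSS below 0.5 — strict "under", so the boundary
values are retained — or with many raw predictions outside [0, 1] are
excluded from the final ensemble.

The continuous Boyce index evaluates a final suitability map against
presence-only data over a geographic background: predicted-to-expected
presence frequency ratios are computed in a moving window (100 focal
values, width one tenth of the background score range) and rank-
correlated (Spearman) with suitability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from . import algorithms
from .occurrences import PixelDataset


@dataclass
class CVPlan:
    """Repeated stratified subsampling plan."""

    n_runs: int = 10
    test_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def run_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(s % (2 ** 31)) for s in ss.generate_state(self.n_runs)]


def make_splits(y: np.ndarray, plan: CVPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-run stratified train/test index pairs.

    Each run reserves ceil(test_fraction * n_class) indices per class
    for testing; runs are independent and deterministic given the
    plan's seed.
    """
    y = np.asarray(y, dtype=int)
    splits = []
    for seed in plan.run_seeds():
        rng = np.random.default_rng(seed)
        test_parts = []
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            n_test = int(np.ceil(plan.test_fraction * len(idx)))
            test_parts.append(rng.choice(idx, size=n_test, replace=False))
        test = np.sort(np.concatenate(test_parts))
        train = np.setdiff1d(np.arange(len(y)), test)
        splits.append((train, test))
    return splits


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_presence > score_absence) + 0.5 P(tie)."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined for single-class data")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def tss_max(y: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Max of sensitivity + specificity - 1 over candidate thresholds.

    A point is classified presence when its score >= threshold.
    Candidates are the distinct scores plus midpoints between
    consecutive distinct scores; ties in the maximum are broken toward
    the smallest threshold.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("TSS is undefined for single-class data")
    uniq = np.unique(scores)
    cands = np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]) \
        if len(uniq) > 1 else uniq
    cands = np.sort(cands)
    pos = scores[y == 1]
    neg = scores[y == 0]
    best_tss, best_thr = -np.inf, cands[0]
    for t in cands:
        sens = float((pos >= t).mean())
        spec = float((neg < t).mean())
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_thr = tss, float(t)
    return best_tss, best_thr


@dataclass
class EvalMetrics:
    algorithm: str
    auc_per_run: list[float]
    tss_per_run: list[float]
    threshold_per_run: list[float]
    range_violation_fraction: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc_per_run))

    @property
    def mean_tss(self) -> float:
        return float(np.mean(self.tss_per_run))


def evaluate_algorithms(tags: list[str], data: PixelDataset, plan: CVPlan,
                        seed: int = 0) -> list[EvalMetrics]:
    """Cross-validate each algorithm tag on the modeling dataset.

    Raw (unclamped) test predictions feed the range-violation count;
    metrics are computed on the raw scores (AUC and TSS are invariant
    to clamping at the candidate thresholds that matter).
    """
    splits = make_splits(data.y, plan)
    out = []
    for tag in tags:
        aucs, tsss, thrs = [], [], []
        n_out, n_tot = 0, 0
        failed = False
        for train, test in splits:
            try:
                model = algorithms.fit(algorithms.get_spec(tag, seed=seed),
                                       data.X[train], data.y[train],
                                       data.variable_names)
                raw = model.predict(data.X[test])
            except Exception:
                failed = True
                break
            n_out += int(((raw < -0.01) | (raw > 1.01)).sum())
            n_tot += len(raw)
            aucs.append(auc(data.y[test], raw))
            t, thr = tss_max(data.y[test], raw)
            tsss.append(t)
            thrs.append(thr)
        if failed or not aucs:
            out.append(EvalMetrics(tag, [0.0], [0.0], [0.0], 1.0))
            continue
        out.append(EvalMetrics(tag, aucs, tsss, thrs,
                               n_out / n_tot if n_tot else 0.0))
    return out


def screen_algorithms(metrics: list[EvalMetrics], auc_min: float = 0.7,
                      tss_min: float = 0.5,
                      range_tol: float = 0.05) -> list[str]:
    """Retain algorithms meeting all performance rules.

    "Under 0.7" / "under 0.5" are strict: mean AUC of exactly 0.7 or
    mean TSS of exactly 0.5 passes.  range_tol bounds the fraction of
    raw predictions outside [-0.01, 1.01] ("largely outside [0, 1]").
    """
    return [m.algorithm for m in metrics
            if m.mean_auc >= auc_min and m.mean_tss >= tss_min
            and m.range_violation_fraction <= range_tol]


@dataclass
class BoyceResult:
    n_focals: int
    window_width: float
    window_midpoints: np.ndarray
    pe_ratios: np.ndarray
    boyce: float


def boyce(background_scores: np.ndarray, presence_scores: np.ndarray,
          n_focals: int = 100, width_frac: float = 0.1,
          rm_duplicate: bool = True) -> BoyceResult:
    """Continuous Boyce index of presence-only accuracy.

    Windows of width ``width_frac * (max - min)`` of the background
    scores are centered at ``n_focals`` evenly spaced focal values
    spanning that range.  Per window, P is the share of presence
    scores inside and E the share of background scores inside; the
    index is the Spearman correlation of P/E (windows with E = 0 are
    dropped) against the focal suitability values.

    ``rm_duplicate`` keeps only the first window of each distinct P/E
    value before the correlation (the ecospat convention): long runs
    of tied ratios — typically zeros below the occupied score range —
    would otherwise drown the rank signal.
    """
    bg = np.asarray(background_scores, dtype=float)
    pr = np.asarray(presence_scores, dtype=float)
    bg = bg[np.isfinite(bg)]
    pr = pr[np.isfinite(pr)]
    if len(bg) == 0 or len(pr) == 0:
        raise ValueError("score sets must be nonempty")
    lo, hi = float(bg.min()), float(bg.max())
    if hi <= lo:
        raise ValueError("background scores span a zero range")
    width = width_frac * (hi - lo)
    focals = np.linspace(lo, hi, n_focals)
    P = np.empty(n_focals)
    E = np.empty(n_focals)
    for i, f in enumerate(focals):
        a, b = f - width / 2.0, f + width / 2.0
        P[i] = np.mean((pr >= a) & (pr <= b))
        E[i] = np.mean((bg >= a) & (bg <= b))
    ok = E > 0
    if ok.sum() < 3:
        raise ValueError("fewer than 3 usable windows for the Boyce index")
    F = P[ok] / E[ok]
    mids = focals[ok]
    if rm_duplicate:
        _, first = np.unique(F, return_index=True)
        keep = np.sort(first)
        F, mids = F[keep], mids[keep]
    if len(F) < 2 or np.ptp(F) == 0:
        rho = 0.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(mids, F).statistic
    return BoyceResult(n_focals=n_focals, window_width=width,
                       window_midpoints=mids, pe_ratios=F,
                       boyce=float(rho))
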