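"""Ensemble member algorithms behind a single fit/predict contract.

Four classic distribution-modeling algorithms are implemented from
first principles:

* ``glm`` — binomial-logit GLM (IRLS, ridge-stabilized on separation);
* ``bioclim`` — percentile envelope: per variable, how central the
  query is within the training presences' distribution, scored
  2*min(p, 1-p) and combined by the minimum across variables;
* ``domain`` — maximum Gower similarity to any training presence,
  with variable ranges taken from the presences;
* ``mahalanobis`` — squared Mahalanobis distance to the presence
  centroid under the presence covariance, mapped to [0, 1] through the
  chi-square survival function with df = number of variables.

The remaining families of the classic 19-algorithm ensemble are
adapters over scikit-learn estimators with documented defaults: their
hyperparameters are the host library's, not a bit-for-bit replica of
any other implementation.  Envelope methods (bioclim, domain,
mahalanobis) are presence-only: they train on the y = 1 rows alone.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import chi2

from .glmfit import fit_logistic


@dataclass(frozen=True)
class AlgorithmSpec:
    name: str
    family: str  # "native" or "adapter"
    hyperparameters: tuple = ()  # (key, value) pairs; hashable

    @property
    def hyper(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class FittedModel:
    """Algorithm tag + learned state + prediction contract.

    ``predict`` maps a (points x variables) matrix to suitability
    scores; native algorithms return values in [0, 1] by construction,
    adapters return probability-like scores that are range-checked by
    the evaluation stage.
    """

    spec: AlgorithmSpec
    variable_names: list[str]
    state: object
    presence_only: bool = False
    stabilized: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        raw = _PREDICTORS[self.spec.name](self.state, X)
        return np.asarray(raw, dtype=float)

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "FittedModel":
        with open(Path(path), "rb") as fh:
            return pickle.load(fh)


# --------------------------------------------------------------- native: glm

def _fit_glm(X, y, hyper):
    fit = fit_logistic(X, y)
    return fit, fit.stabilized


def predict_glm(state, X):
    return state.predict(X)


# ----------------------------------------------------------- native: bioclim

def _fit_bioclim(X, y, hyper):
    pres = X[y == 1]
    if len(pres) == 0:
        raise ValueError("bioclim needs at least one presence")
    return {"sorted": [np.sort(pres[:, j]) for j in range(X.shape[1])]}, False


def predict_bioclim(state, X):
    """Envelope centrality score, dismo convention.

    Per variable the query's midranked percentile p among training
    presences gives a tail score 2*min(p, 1-p); the suitability is the
    minimum across variables, so any variable outside the training
    range forces 0.
    """
    cols = state["sorted"]
    n = len(cols[0])
    scores = np.ones((X.shape[0], len(cols)))
    for j, svals in enumerate(cols):
        less = np.searchsorted(svals, X[:, j], side="left")
        leq = np.searchsorted(svals, X[:, j], side="right")
        p = (less + 0.5 * (leq - less)) / n
        scores[:, j] = 2.0 * np.minimum(p, 1.0 - p)
    return np.clip(scores.min(axis=1), 0.0, 1.0)


# ------------------------------------------------------------ native: domain

def _fit_domain(X, y, hyper):
    pres = X[y == 1]
    if len(pres) == 0:
        raise ValueError("domain needs at least one presence")
    rng = pres.max(axis=0) - pres.min(axis=0)
    if np.any(rng == 0):
        warnings.warn("domain: zero-range variable(s); excluded from the "
                      "Gower mean except for exact matches")
    return {"presences": pres, "range": rng}, False


def predict_domain(state, X):
    """Max Gower similarity to any training presence, clamped to [0,1]."""
    pres = state["presences"]
    rng = state["range"]
    ok = rng > 0
    best = np.zeros(X.shape[0])
    for t in pres:
        diff = np.abs(X - t)
        if ok.all():
            d = (diff / rng).mean(axis=1)
        else:
            # zero-range variables: 0 distance on exact match, else
            # dropped from the mean for that query
            parts = diff[:, ok] / rng[ok]
            zr = diff[:, ~ok] == 0
            counts = ok.sum() + zr.sum(axis=1)
            d = parts.sum(axis=1) / np.maximum(counts, 1)
        best = np.maximum(best, 1.0 - d)
    return np.clip(best, 0.0, 1.0)


# ------------------------------------------------------- native: mahalanobis

def _fit_mahalanobis(X, y, hyper):
    pres = X[y == 1]
    p = X.shape[1]
    if len(pres) < 2:
        raise ValueError("mahalanobis needs at least two presences")
    mean = pres.mean(axis=0)
    cov = np.cov(pres, rowvar=False).reshape(p, p)
    stabilized = False
    # diagonal shrinkage when presences are scarce or cov is singular
    if len(pres) < 3 * p or np.linalg.matrix_rank(cov) < p:
        lam = 0.1
        cov = (1 - lam) * cov + lam * np.diag(np.diag(cov) + 1e-8)
        stabilized = True
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
        stabilized = True
    return {"mean": mean, "prec": prec, "df": p}, stabilized


def predict_mahalanobis(state, X):
    """1 - chi-square CDF of D^2: monotone decreasing in distance."""
    diff = X - state["mean"]
    d2 = np.einsum("ij,jk,ik->i", diff, state["prec"], diff)
    return chi2.sf(np.maximum(d2, 0.0), df=state["df"])


# ----------------------------------------------------------------- adapters

def _spline_logistic(degree, n_knots, C=1.0):
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import SplineTransformer, StandardScaler
    return make_pipeline(
        StandardScaler(),
        SplineTransformer(degree=degree, n_knots=n_knots,
                          extrapolation="constant"),
        LogisticRegression(C=C, max_iter=2000),
    )


def _make_estimator(name, hyper):
    seed = hyper.get("seed", 0)
    if name in ("cart", "rpart"):
        from sklearn.tree import DecisionTreeClassifier
        # rpart-style pruning vs plain depth-limited CART
        if name == "cart":
            return DecisionTreeClassifier(max_depth=5, random_state=seed)
        return DecisionTreeClassifier(min_samples_leaf=7, ccp_alpha=1e-3,
                                      random_state=seed)
    if name == "rf":
        from sklearn.ensemble import RandomForestClassifier
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "brt":
        from sklearn.ensemble import GradientBoostingClassifier
        return GradientBoostingClassifier(random_state=seed)
    if name == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        return make_pipeline(StandardScaler(),
                             SVC(probability=True, random_state=seed))
    if name == "mlp":
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        return make_pipeline(StandardScaler(),
                             MLPClassifier(hidden_layer_sizes=(8,),
                                           max_iter=3000, random_state=seed))
    if name == "rbf":
        from sklearn.kernel_approximation import RBFSampler
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        return make_pipeline(StandardScaler(),
                             RBFSampler(gamma=0.5, n_components=100,
                                        random_state=seed),
                             LogisticRegression(max_iter=2000))
    if name == "fda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        return LinearDiscriminantAnalysis()
    if name == "mda":
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
        return QuadraticDiscriminantAnalysis(reg_param=0.1)
    if name == "gam":
        return _spline_logistic(degree=3, n_knots=5)
    if name == "mars":
        # piecewise-linear (hinge-like) basis, lightly regularized
        return _spline_logistic(degree=1, n_knots=5, C=0.5)
    raise KeyError(name)


def _fit_sklearn(name):
    def fit(X, y, hyper):
        est = _make_estimator(name, hyper)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        return est, False
    return fit


def _predict_sklearn(state, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return state.predict_proba(X)[:, 1]


def _fit_maxent_like(X, y, hyper):
    """Presence vs background exponential-family model.

    Logistic regression of the presence rows against all rows
    (the 'background'), on linear + quadratic features — a simple
    MaxEnt-flavored formulation, not the full feature-class machinery.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import PolynomialFeatures, StandardScaler
    bg = np.vstack([X[y == 1], X])
    lab = np.concatenate([np.ones((y == 1).sum()), np.zeros(len(X))])
    est = make_pipeline(StandardScaler(),
                        PolynomialFeatures(degree=2, include_bias=False),
                        LogisticRegression(C=1.0, max_iter=2000))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(bg, lab)
    return est, False


_FITTERS = {
    "glm": _fit_glm,
    "bioclim": _fit_bioclim,
    "bioclim_dismo": _fit_bioclim,  # alias: same envelope formulation
    "domain": _fit_domain,
    "mahalanobis": _fit_mahalanobis,
    "maxent_like": _fit_maxent_like,
}
_PREDICTORS = {
    "glm": predict_glm,
    "bioclim": predict_bioclim,
    "bioclim_dismo": predict_bioclim,
    "domain": predict_domain,
    "mahalanobis": predict_mahalanobis,
    "maxent_like": _predict_sklearn,
}
_ADAPTER_TAGS = ["brt", "cart", "fda", "gam", "mars", "mda", "mlp",
                 "rbf", "rf", "rpart", "svm"]
for _tag in _ADAPTER_TAGS:
    _FITTERS[_tag] = _fit_sklearn(_tag)
    _PREDICTORS[_tag] = _predict_sklearn

_NATIVE = {"glm", "bioclim", "bioclim_dismo", "domain", "mahalanobis"}
_PRESENCE_ONLY = {"bioclim", "bioclim_dismo", "domain", "mahalanobis"}


def registry(seed: int = 0) -> list[AlgorithmSpec]:
    """All available algorithm specs, native first."""
    tags = sorted(_FITTERS, key=lambda t: (t not in _NATIVE, t))
    return [AlgorithmSpec(name=t,
                          family="native" if t in _NATIVE else "adapter",
                          hyperparameters=(("seed", seed),))
            for t in tags]


def get_spec(name: str, seed: int = 0) -> AlgorithmSpec:
    if name not in _FITTERS:
        raise KeyError(f"unknown algorithm tag {name!r}; "
                       f"known: {sorted(_FITTERS)}")
    return AlgorithmSpec(name=name,
                         family="native" if name in _NATIVE else "adapter",
                         hyperparameters=(("seed", seed),))


def fit(spec: AlgorithmSpec | str, X: np.ndarray, y: np.ndarray,
        variable_names: list[str] | None = None) -> FittedModel:
    """Fit one ensemble member; envelope methods use presences only."""
    if isinstance(spec, str):
        spec = get_spec(spec)
    if spec.name not in _FITTERS:
        raise KeyError(f"unknown algorithm tag {spec.name!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary")
    state, stabilized = _FITTERS[spec.name](X, y, spec.hyper)
    names = variable_names or [f"x{j}" for j in range(X.shape[1])]
    return FittedModel(spec=spec, variable_names=list(names), state=state,
                       presence_only=spec.name in _PRESENCE_ONLY,
                       stabilized=stabilized)
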