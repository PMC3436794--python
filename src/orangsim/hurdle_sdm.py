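"""Hurdle boosted-regression-tree species distribution model.

The zero-augmented gridded nest counts are modelled as two separate
processes: a binomial part for presence vs absence across the landscape and
a Poisson part for abundance contingent on presence.  Each part is a boosted
ensemble of shallow regression trees governed by learning rate (lr), tree
complexity / interaction depth (tc), bag fraction (bf) and number of trees
(nt).  nt is selected as the minimizer of the mean 10-fold cross-validated
predictive deviance D_cv; lr and tc are grid-searched per component; the
optimized model is then compared against variants simplified by repeatedly
dropping the least influential predictor until D_cv degrades by more than
the original D_cv standard error.

The binomial part sees all rows (observed cells plus pseudoabsences); the
Poisson part is fit on presence cells only, with real-valued averaged counts
under the Poisson deviance (a quasi-likelihood reading).  Presence
probabilities convert to presence/absence at the maximum
sensitivity-plus-specificity (MaxSSS) threshold, which down-weights the
influence of pseudoabsences that may not be true absences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xgboost as xgb
from sklearn.metrics import cohen_kappa_score, roc_auc_score

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# deviances

def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Mean binomial deviance  -2 [ y ln p + (1-y) ln(1-p) ].

    Probabilities at exactly 0 or 1 are clamped by a small epsilon (a
    contradicting observation would otherwise yield infinite deviance).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same length")
    if np.any((p <= 0) | (p >= 1)):
        logger.debug("probabilities clamped to (%g, %g)", _EPS, 1 - _EPS)
    p = np.clip(p, _EPS, 1 - _EPS)
    return float(np.mean(-2.0 * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Mean Poisson deviance  2 [ y ln(y/mu) - (y - mu) ],  y ln(y/mu) := 0 at y=0.

    y may be real-valued (averaged repeat-survey counts).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    mu = np.clip(mu, _EPS, None)
    term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    return float(np.mean(2.0 * (term - (y - mu))))


_DEVIANCE = {"binomial": binomial_deviance, "poisson": poisson_deviance}
_OBJECTIVE = {"binomial": "binary:logistic", "poisson": "count:poisson"}


# ---------------------------------------------------------------------------
# configuration and model containers

@dataclass
class HurdleFitConfig:
    """Fitting-parameter space for the two boosted components."""

    lr_grid: tuple[float, ...] = (0.01, 0.005, 0.001)
    tc_grid: tuple[int, ...] = (1, 2, 3)
    bf: float = 0.7
    nt_grid: tuple[int, ...] = tuple(range(10, 15001, 25))
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_grid or not self.tc_grid or not self.nt_grid:
            raise ValueError("parameter grids must be non-empty")
        if not (0 < self.bf <= 1):
            raise ValueError("bag fraction must be in (0, 1]")
        if list(self.nt_grid) != sorted(set(self.nt_grid)):
            raise ValueError("nt_grid must be strictly increasing")


@dataclass
class BoostedComponent:
    """One fitted part (binomial or Poisson) of the hurdle model."""

    family: str
    booster: xgb.Booster
    lr: float
    tc: int
    bf: float
    nt: int
    predictors: list[str]
    relative_influence: dict[str, float]     # per cent, sums to 100
    d_cv: float
    se_d_cv: float
    d_cv_curve: np.ndarray
    nt_grid: tuple[int, ...]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor layer(s): {missing}")
        d = xgb.DMatrix(X[self.predictors].to_numpy(dtype=float),
                        feature_names=self.predictors, nthread=1)
        return self.booster.predict(d, iteration_range=(0, self.nt))


@dataclass
class HurdleModel:
    """Binomial + Poisson boosted components with a presence threshold."""

    binomial: BoostedComponent
    poisson: BoostedComponent
    presence_threshold: float

    def predict_presence(self, X: pd.DataFrame) -> np.ndarray:
        return self.binomial.predict(X)

    def predict_count(self, X: pd.DataFrame) -> np.ndarray:
        return self.poisson.predict(X)


@dataclass
class ModelMetrics:
    d_cv_binomial: float
    se_d_cv_binomial: float
    d_cv_poisson: float
    se_d_cv_poisson: float
    d_null_binomial: float
    d_resid_binomial: float
    d_null_poisson: float
    d_resid_poisson: float
    deviance_explained_binomial: float
    deviance_explained_poisson: float
    deviance_explained_pooled: float
    mse: float
    rmpe: float
    kappa: float
    auc: float
    kappa_threshold: float
    thresholds: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        return pd.Series(d)


# ---------------------------------------------------------------------------
# fitting

def _make_folds(y: np.ndarray, folds: int, seed: int, stratify: bool) -> np.ndarray:
    """Fold assignment per row; stratified by class for the binomial part."""
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} rows is fewer than {folds} CV folds")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if stratify:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            assign[idx] = np.arange(idx.size) % folds
    else:
        assign[rng.permutation(n)] = np.arange(n) % folds
    return assign


def _xgb_params(family: str, lr: float, tc: int, bf: float, seed: int) -> dict:
    return {"objective": _OBJECTIVE[family], "eta": lr, "max_depth": tc,
            "subsample": bf, "tree_method": "exact", "nthread": 1,
            "seed": seed, "verbosity": 0}


def fit_component(X: pd.DataFrame, y: np.ndarray, family: str,
                  lr: float, tc: int, bf: float,
                  nt_grid: tuple[int, ...], cv_folds: int,
                  seed: int) -> BoostedComponent:
    """Fit one boosted component, selecting nt by cross-validated deviance.

    For each fold a single staged ensemble is grown to max(nt_grid) and its
    held-out predictions are evaluated at every nt on the grid; D_cv(nt) is
    the across-fold mean held-out deviance and its SE the across-fold
    standard error. The returned component is refit on all rows at the
    argmin nt (first grid value on ties).
    """
    if family not in _DEVIANCE:
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(y, dtype=float)
    stratify = family == "binomial"
    if stratify and np.unique(y).size < 2:
        raise ValueError("binomial data must contain both classes")
    if family == "poisson" and np.any(y < 0):
        raise ValueError("poisson counts must be non-negative")
    predictors = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    deviance = _DEVIANCE[family]
    folds = _make_folds(y, cv_folds, seed, stratify)
    max_nt = max(nt_grid)
    params = _xgb_params(family, lr, tc, bf, seed)

    dev = np.empty((cv_folds, len(nt_grid)))
    for f in range(cv_folds):
        tr, te = folds != f, folds == f
        dtr = xgb.DMatrix(Xv[tr], label=y[tr], feature_names=predictors, nthread=1)
        dte = xgb.DMatrix(Xv[te], feature_names=predictors, nthread=1)
        booster = xgb.train(params, dtr, num_boost_round=max_nt)
        for j, nt in enumerate(nt_grid):
            pred = booster.predict(dte, iteration_range=(0, nt))
            dev[f, j] = deviance(y[te], pred)

    curve = dev.mean(axis=0)
    se_curve = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(curve))
    best_nt = nt_grid[best]

    dall = xgb.DMatrix(Xv, label=y, feature_names=predictors, nthread=1)
    booster = xgb.train(params, dall, num_boost_round=best_nt)
    gains = booster.get_score(importance_type="total_gain")
    total = sum(gains.values())
    influence = {p: 100.0 * gains.get(p, 0.0) / total if total > 0 else 0.0
                 for p in predictors}
    return BoostedComponent(family=family, booster=booster, lr=lr, tc=tc, bf=bf,
                            nt=best_nt, predictors=predictors,
                            relative_influence=influence,
                            d_cv=float(curve[best]), se_d_cv=float(se_curve[best]),
                            d_cv_curve=curve, nt_grid=tuple(nt_grid))


def split_hurdle_data(data: pd.DataFrame,
                      predictors: list[str]) -> tuple[pd.DataFrame, np.ndarray,
                                                      pd.DataFrame, np.ndarray]:
    """Split the gridded dataset into binomial and Poisson design matrices.

    The binomial part uses every row (pseudoabsences included, as absences);
    the Poisson part uses presence cells only — pseudoabsences carry no
    abundance information and are zero by construction.
    """
    yb = data["presence"].to_numpy(dtype=float)
    Xb = data[predictors]
    pres = data["presence"] == 1
    Xp = data.loc[pres, predictors]
    yp = data.loc[pres, "mean_count"].to_numpy(dtype=float)
    return Xb, yb, Xp, yp


def optimize_hurdle(data: pd.DataFrame, predictors: list[str],
                    config: HurdleFitConfig) -> HurdleModel:
    """Grid-search lr x tc independently per component; keep each D_cv winner.

    The presence threshold stored on the model is the MaxSSS threshold of the
    winning binomial component's in-sample probabilities.
    """
    Xb, yb, Xp, yp = split_hurdle_data(data, predictors)
    winners: dict[str, BoostedComponent] = {}
    for family, X, y in (("binomial", Xb, yb), ("poisson", Xp, yp)):
        best: BoostedComponent | None = None
        for lr in config.lr_grid:
            for tc in config.tc_grid:
                comp = fit_component(X, y, family, lr, tc, config.bf,
                                     config.nt_grid, config.cv_folds, config.seed)
                logger.info("%s lr=%g tc=%d -> nt=%d D_cv=%.4f",
                            family, lr, tc, comp.nt, comp.d_cv)
                if best is None or comp.d_cv < best.d_cv:
                    best = comp
        winners[family] = best
    thr = max_sss_threshold(winners["binomial"].predict(Xb), yb)
    return HurdleModel(binomial=winners["binomial"], poisson=winners["poisson"],
                       presence_threshold=thr)


@dataclass
class SimplificationReport:
    """Outcome of the backward predictor-elimination procedure."""

    drop_order: dict[str, list[str]]            # per component
    simplified: dict[str, BoostedComponent]     # per component
    saturated: dict[str, BoostedComponent]
    table: pd.DataFrame                         # four model-variant rows


def _simplify_component(comp: BoostedComponent, X: pd.DataFrame, y: np.ndarray,
                        config: HurdleFitConfig,
                        se_override: float | None = None,
                        ) -> tuple[BoostedComponent, list[str]]:
    """Drop least-influential predictors while D_cv stays within the original SE."""
    se0 = comp.se_d_cv if se_override is None else se_override
    current = comp
    dropped: list[str] = []
    while len(current.predictors) > 1:
        weakest = min(current.predictors, key=lambda p: current.relative_influence[p])
        kept = [p for p in current.predictors if p != weakest]
        trial = fit_component(X[kept], y, comp.family, comp.lr, comp.tc, comp.bf,
                              comp.nt_grid, config.cv_folds, config.seed)
        if trial.d_cv - comp.d_cv > se0:
            break
        dropped.append(weakest)
        current = trial
    return current, dropped


def simplify_hurdle(model: HurdleModel, data: pd.DataFrame,
                    config: HurdleFitConfig,
                    se_override: float | None = None,
                    ) -> tuple[HurdleModel, SimplificationReport]:
    """Backward-eliminate predictors per component and pick the best variant.

    Each component is simplified by iteratively removing its least
    influential predictor and refitting, stopping once the simplified D_cv
    exceeds the saturated D_cv by more than the saturated SE.  The four
    variants (saturated; binomial simplified; Poisson simplified; both) are
    tabulated, and the returned model takes, per component, whichever of
    saturated/simplified has the lower D_cv — so an all-signal model is kept
    saturated while noise predictors are shed.
    """
    predictors = model.binomial.predictors
    Xb, yb, Xp, yp = split_hurdle_data(data, predictors)
    simp_b, drop_b = _simplify_component(model.binomial, Xb, yb, config, se_override)
    Xp_full = data.loc[data["presence"] == 1, model.poisson.predictors]
    simp_p, drop_p = _simplify_component(model.poisson, Xp_full, yp, config,
                                         se_override)

    rows = []
    for label, b, p in (("saturated", model.binomial, model.poisson),
                        ("binomial", simp_b, model.poisson),
                        ("poisson", model.binomial, simp_p),
                        ("binomial and poisson", simp_b, simp_p)):
        rows.append({"variant": label,
                     "binomial_d_cv": b.d_cv, "binomial_se_d_cv": b.se_d_cv,
                     "poisson_d_cv": p.d_cv, "poisson_se_d_cv": p.se_d_cv,
                     "binomial_n_predictors": len(b.predictors),
                     "poisson_n_predictors": len(p.predictors)})
    table = pd.DataFrame(rows)

    best_b = simp_b if simp_b.d_cv < model.binomial.d_cv else model.binomial
    best_p = simp_p if simp_p.d_cv < model.poisson.d_cv else model.poisson
    thr = max_sss_threshold(best_b.predict(Xb), yb)
    best = HurdleModel(binomial=best_b, poisson=best_p, presence_threshold=thr)
    report = SimplificationReport(
        drop_order={"binomial": drop_b, "poisson": drop_p},
        simplified={"binomial": simp_b, "poisson": simp_p},
        saturated={"binomial": model.binomial, "poisson": model.poisson},
        table=table)
    return best, report


# ---------------------------------------------------------------------------
# thresholds and evaluation

def max_sss_threshold(p: np.ndarray, y: np.ndarray) -> float:
    """Threshold (among unique probabilities) maximizing sensitivity + specificity.

    Ties are broken by the smallest such threshold. Predictions use the rule
    ``p >= threshold`` for presence.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    pos, neg = y == 1, y == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    best_t, best_s = None, -np.inf
    for t in np.unique(p):                     # unique() is sorted ascending
        pred = p >= t
        sens = np.mean(pred[pos])
        spec = np.mean(~pred[neg])
        s = sens + spec
        if s > best_s + 1e-15:
            best_t, best_s = float(t), s
    return best_t


def _max_kappa_threshold(p: np.ndarray, y: np.ndarray) -> float:
    best_t, best_k = 0.5, -np.inf
    for t in np.unique(p):
        k = cohen_kappa_score(y, (p >= t).astype(int))
        if k > best_k + 1e-15:
            best_t, best_k = float(t), k
    return best_t


def evaluate(model: HurdleModel, data: pd.DataFrame) -> ModelMetrics:
    """Explanatory metrics for both hurdle parts.

    AUC is the rank statistic of the binomial probabilities; Kappa is
    computed at the mean of five candidate thresholds (0.5, observed
    prevalence, mean predicted probability, max-Kappa, MaxSSS).  mse and
    rmpe (mean absolute error over mean observed) evaluate the Poisson part
    on presence cells.  Deviance explained is 1 - D_resid/D_null per
    component; the pooled value shares a single ratio of summed deviances.
    """
    predictors = model.binomial.predictors
    yb = data["presence"].to_numpy(dtype=float)
    p = model.binomial.predict(data[predictors])
    pres = data["presence"] == 1
    yp = data.loc[pres, "mean_count"].to_numpy(dtype=float)
    mu = model.poisson.predict(data.loc[pres, model.poisson.predictors])

    auc = float(roc_auc_score(yb, p))
    thresholds = {
        "fixed_0.5": 0.5,
        "prevalence": float(yb.mean()),
        "mean_probability": float(p.mean()),
        "max_kappa": _max_kappa_threshold(p, yb),
        "max_sss": max_sss_threshold(p, yb),
    }
    t_mean = float(np.mean(list(thresholds.values())))
    kappa = float(cohen_kappa_score(yb.astype(int), (p >= t_mean).astype(int)))

    d_null_b = binomial_deviance(yb, np.full_like(yb, yb.mean()))
    d_resid_b = binomial_deviance(yb, p)
    d_null_p = poisson_deviance(yp, np.full_like(yp, yp.mean()))
    d_resid_p = poisson_deviance(yp, mu)
    mse = float(np.mean((mu - yp) ** 2))
    rmpe = float(np.mean(np.abs(mu - yp)) / yp.mean()) if yp.mean() > 0 else np.nan
    pooled = 1.0 - (d_resid_b + d_resid_p) / (d_null_b + d_null_p)
    return ModelMetrics(
        d_cv_binomial=model.binomial.d_cv, se_d_cv_binomial=model.binomial.se_d_cv,
        d_cv_poisson=model.poisson.d_cv, se_d_cv_poisson=model.poisson.se_d_cv,
        d_null_binomial=d_null_b, d_resid_binomial=d_resid_b,
        d_null_poisson=d_null_p, d_resid_poisson=d_resid_p,
        deviance_explained_binomial=1.0 - d_resid_b / d_null_b,
        deviance_explained_poisson=1.0 - d_resid_p / d_null_p,
        deviance_explained_pooled=pooled,
        mse=mse, rmpe=rmpe, kappa=kappa, auc=auc, kappa_threshold=t_mean,
        thresholds=thresholds)


# ---------------------------------------------------------------------------
# prediction and external validation

def predict_hurdle(model: HurdleModel,
                   predictors: dict[str, np.ndarray]) -> np.ndarray:
    """Expected-count raster: Poisson prediction where presence prob >= threshold.

    Cells below the presence threshold are exactly zero; elsewhere strictly
    positive. ``predictors`` maps layer name to an aligned 2-D array.
    """
    needed = set(model.binomial.predictors) | set(model.poisson.predictors)
    missing = sorted(n for n in needed if n not in predictors)
    if missing:
        raise KeyError(f"missing predictor layer(s): {missing}")
    shape = next(iter(predictors.values())).shape
    flat = pd.DataFrame({n: predictors[n].ravel() for n in sorted(needed)})
    p = model.binomial.predict(flat)
    mu = model.poisson.predict(flat)
    out = np.where(p >= model.presence_threshold, mu, 0.0)
    return out.reshape(shape)


@dataclass
class LinearFit:
    intercept: float
    slope: float


def cross_dataset_validation(predictions: np.ndarray,
                             independent_counts: np.ndarray,
                             ) -> tuple[LinearFit, LinearFit]:
    """Validate predictions against an independent count dataset.

    Returns the ordinary-least-squares and robust (Huber-weighted, iterated
    re-weighted least squares) linear fits of independent counts on
    predictions.
    """
    x = np.asarray(predictions, dtype=float)
    y = np.asarray(independent_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0:
        raise ValueError("predictions have zero variance")
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
    return (LinearFit(float(ols.params[0]), float(ols.params[1])),
            LinearFit(float(rlm.params[0]), float(rlm.params[1])))
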