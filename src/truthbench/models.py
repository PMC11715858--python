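"""Logistic fitting and the named candidate-model catalog.

Candidates are the models a practitioner might plausibly end up with
instead of the outcome-generating one: the true model itself, an
uninformative "flip a fair coin" reference, the true model augmented
with independent or correlated noise predictors, stepwise-AIC selections
with the causal predictor available or withheld, and post-hoc shrinkage
(van Houwelingen's heuristic shrinkage factor) applied to either.

Fitting is maximum likelihood via IRLS (statsmodels GLM/binomial).
Coefficients diverging past +/-15 on the log-odds scale are treated as
(quasi-)separation: they are capped, the fit is flagged non-converged,
and downstream measures are still computed from the capped predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .scenario import MULTIVARIATE, UNIVARIATE, SimDataset, _proxy_label

logger = logging.getLogger("truthbench")

COEF_CAP = 15.0
P_CLIP = 1e-10


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FittedLogistic:
    """A maximum-likelihood logistic fit on a training set."""

    variable_names: tuple[str, ...]
    coefficients: np.ndarray            # intercept first, log-odds scale
    df_model: int                       # non-intercept parameters
    train_loglik: float
    train_null_loglik: float
    converged: bool = True

    @property
    def train_lr_chi2(self) -> float:
        """Training likelihood-ratio statistic vs the intercept-only model."""
        return 2.0 * (self.train_loglik - self.train_null_loglik)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variable_names if v not in X.columns]
        if missing:
            raise KeyError(f"predictor table is missing column(s) {missing}")
        M = X[list(self.variable_names)].to_numpy(dtype=float)
        return self.coefficients[0] + M @ self.coefficients[1:]


@dataclass(frozen=True)
class CandidateSpec:
    """A named entry of the candidate catalog."""

    name: str
    variable_pool: tuple[str, ...] = ()
    forced_in: tuple[str, ...] = ()
    forced_out: tuple[str, ...] = ()
    transform: str = "none"             # none | stepAIC | shrink | flip-coin

    def __post_init__(self):
        if set(self.forced_in) & set(self.forced_out):
            raise ValueError("forced_in and forced_out overlap")
        if self.transform == "flip-coin" and self.variable_pool:
            raise ValueError("flip-coin takes no variables")
        if self.transform not in ("none", "stepAIC", "shrink", "flip-coin"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class PredictionSet:
    """Predicted risks on a test set, paired with observed outcomes."""

    p_hat: np.ndarray
    lp: np.ndarray
    y: np.ndarray
    candidate: CandidateSpec | None = None
    model: FittedLogistic | None = None


# ---------------------------------------------------------------------------
# fitting and prediction
# ---------------------------------------------------------------------------

def _null_loglik(y: np.ndarray) -> float:
    p = float(np.mean(y))
    n = len(y)
    if p in (0.0, 1.0):
        return 0.0
    return n * (p * np.log(p) + (1 - p) * np.log(1 - p))


def bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, P_CLIP, 1 - P_CLIP)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(X: pd.DataFrame, y: np.ndarray) -> FittedLogistic:
    """ML logistic fit of y on the columns of X (intercept always added).

    X may have zero columns (intercept-only model). Separation is handled
    by capping coefficients at +/-15 and flagging non-convergence.
    """
    y = np.asarray(y, dtype=float)
    if not 0 < y.mean() < 1:
        raise ValueError("both outcome classes must be present")
    names = tuple(X.columns)
    M = X.to_numpy(dtype=float).reshape(len(y), len(names))
    exog = np.column_stack([np.ones(len(y)), M])

    model = sm.GLM(y, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.converged)

    if np.any(np.abs(params) > COEF_CAP):
        params = np.clip(params, -COEF_CAP, COEF_CAP)
        converged = False
        logger.warning("separation suspected: coefficients capped at ±%g "
                       "for variables %s", COEF_CAP, names)
    loglik = bernoulli_loglik(expit(exog @ params), y)

    if not converged:
        logger.warning("logistic fit did not converge for variables %s", names)
    return FittedLogistic(
        variable_names=names,
        coefficients=params,
        df_model=len(names),
        train_loglik=loglik,
        train_null_loglik=_null_loglik(y),
        converged=converged,
    )


def predict_risk(model: FittedLogistic, X: pd.DataFrame,
                 y: np.ndarray | None = None,
                 candidate: CandidateSpec | None = None) -> PredictionSet:
    """Predicted risks expit(lp), clipped away from 0/1, on new data."""
    p = np.clip(expit(model.linear_predictor(X)), P_CLIP, 1 - P_CLIP)
    return PredictionSet(p_hat=p, lp=logit(p),
                         y=None if y is None else np.asarray(y),
                         candidate=candidate, model=model)


def flip_coin_model(y: np.ndarray,
                    candidate: CandidateSpec | None = None) -> PredictionSet:
    """The no-information reference: constant predicted risk 0.5."""
    y = np.asarray(y)
    n = len(y)
    if n < 1:
        raise ValueError("need at least one subject")
    return PredictionSet(p_hat=np.full(n, 0.5), lp=np.zeros(n), y=y,
                         candidate=candidate, model=None)


# ---------------------------------------------------------------------------
# stepwise AIC
# ---------------------------------------------------------------------------

def aic(model: FittedLogistic) -> float:
    return -2.0 * model.train_loglik + 2.0 * (model.df_model + 1)


def stepwise_aic(dataset: SimDataset, spec: CandidateSpec) -> FittedLogistic:
    """Bidirectional stepwise search minimising AIC.

    Starts from the model containing ``forced_in`` plus the whole
    ``variable_pool``; at each step the single addition or removal that
    most lowers AIC is taken (ties broken by variable-name order);
    ``forced_out`` columns are never added; ``forced_in`` columns start in
    the model but remain removable by the search. May reduce to the
    intercept-only model.
    """
    X, y = dataset.train_X, dataset.train_y
    pool = [v for v in dict.fromkeys(spec.forced_in + spec.variable_pool)
            if v not in spec.forced_out]
    if not pool:
        raise ValueError("variable_pool and forced_in are both empty")
    current = sorted(pool)
    cache: dict[tuple[str, ...], FittedLogistic] = {}

    def fitted(cols: Sequence[str]) -> FittedLogistic:
        key = tuple(cols)
        if key not in cache:
            cache[key] = fit_logistic(X[list(cols)], y)
        return cache[key]

    best = fitted(current)
    while True:
        moves: list[tuple[float, str, list[str]]] = []
        for v in current:                                   # removals
            cols = [c for c in current if c != v]
            moves.append((aic(fitted(cols)), v, cols))
        for v in sorted(pool):                              # additions
            if v not in current:
                cols = sorted(current + [v])
                moves.append((aic(fitted(cols)), v, cols))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1]))
        best_aic, _, best_cols = moves[0]
        if best_aic < aic(best) - 1e-10:
            current = best_cols
            best = fitted(current)
        else:
            break
    return best


# ---------------------------------------------------------------------------
# heuristic shrinkage
# ---------------------------------------------------------------------------

def heuristic_shrinkage(model: FittedLogistic | None) -> float:
    """Heuristic global shrinkage factor gamma = (chi2 - df) / chi2.

    chi2 is the training likelihood-ratio statistic; df the number of
    non-intercept parameters. Undefined (NaN) when there is no fitted
    model or chi2 is (numerically) zero; can be negative for near-null
    fits; never exceeds 1.
    """
    if model is None or model.df_model < 1:
        return float("nan")
    chi2 = model.train_lr_chi2
    if chi2 <= 1e-12:
        return float("nan")
    return (chi2 - model.df_model) / chi2


def shrink_model(model: FittedLogistic, train_X: pd.DataFrame,
                 train_y: np.ndarray) -> FittedLogistic:
    """Multiply slopes by the shrinkage factor and re-estimate the intercept.

    The intercept is refit by a one-parameter logistic model with the
    shrunken linear predictor as a fixed offset on the training data. The
    training log-likelihood is recomputed at the shrunken coefficients so
    downstream overfitting diagnostics refer to the model actually used.
    """
    gamma = heuristic_shrinkage(model)
    if not np.isfinite(gamma):
        warnings.warn("shrinkage factor undefined; model returned unchanged")
        return model
    y = np.asarray(train_y, dtype=float)
    slopes = gamma * model.coefficients[1:]
    M = train_X[list(model.variable_names)].to_numpy(dtype=float)
    offset = M @ slopes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(),
                     offset=offset).fit(maxiter=100, tol=1e-8)
    intercept = float(res.params[0])
    params = np.concatenate([[intercept], slopes])
    loglik = bernoulli_loglik(expit(intercept + offset), y)
    return FittedLogistic(
        variable_names=model.variable_names,
        coefficients=params,
        df_model=model.df_model,
        train_loglik=loglik,
        train_null_loglik=_null_loglik(y),
        converged=model.converged and bool(res.converged),
    )


# ---------------------------------------------------------------------------
# catalogs
# ---------------------------------------------------------------------------

def univariate_catalog(proxy_corrs: Sequence[float] = (0.3, 0.5, 0.8)
                       ) -> list[CandidateSpec]:
    """The 10 univariate candidates (true, flip-coin, noise-augmented,
    AIC-selected and shrunken, with the causal variable available or
    withheld)."""
    proxies = tuple(["proxy_ind"] + [_proxy_label(r) for r in proxy_corrs])
    cands = [
        CandidateSpec("TrueModel", variable_pool=("x1",)),
        CandidateSpec("FlipCoin", transform="flip-coin"),
        CandidateSpec("AddIndModel", variable_pool=("x1", "proxy_ind")),
    ]
    for rho in proxy_corrs:
        cands.append(CandidateSpec(
            f"Add{int(round(rho * 10)):02d}Model",
            variable_pool=("x1", _proxy_label(rho))))
    cands += [
        CandidateSpec("AICTrueModel", variable_pool=("x1",) + proxies,
                      transform="stepAIC"),
        CandidateSpec("ShrinkTrueModel", variable_pool=("x1",),
                      transform="shrink"),
        CandidateSpec("AICAddModel", variable_pool=proxies,
                      forced_out=("x1",), transform="stepAIC"),
        CandidateSpec("ShrinkAddModel", variable_pool=proxies,
                      forced_out=("x1",), transform="shrink"),
    ]
    return cands


def multivariate_catalog() -> list[CandidateSpec]:
    """The 12 multivariate candidates: true and flip-coin references,
    single-predictor submodels, the true model plus one extra variable,
    and "missing variable 1" models where x1 is replaced by proxies."""
    return [
        CandidateSpec("TrueModel", variable_pool=("x1", "x2")),
        CandidateSpec("FlipCoin", transform="flip-coin"),
        CandidateSpec("Variable1", variable_pool=("x1",)),
        CandidateSpec("Variable2", variable_pool=("x2",)),
        CandidateSpec("AddIndCont", variable_pool=("x1", "x2", "proxy_cont_ind")),
        CandidateSpec("AddCorrCont", variable_pool=("x1", "x2", "proxy_cont_corr")),
        CandidateSpec("AddCat", variable_pool=("x1", "x2", "proxy_bin_ind")),
        CandidateSpec("AddIndVar1", variable_pool=("proxy_ind", "x2"),
                      forced_out=("x1",)),
        CandidateSpec("AddCorrVar1", variable_pool=("proxy_corr_x1", "x2"),
                      forced_out=("x1",)),
        CandidateSpec("AddCorrVar2", variable_pool=("proxy_corr_x2", "x2"),
                      forced_out=("x1",)),
        CandidateSpec("AddIndCorrVar1",
                      variable_pool=("proxy_ind", "proxy_corr_x1", "x2"),
                      forced_out=("x1",)),
        CandidateSpec("AddIndCorrVar1AddCorrVar2",
                      variable_pool=("proxy_ind", "proxy_corr_x1",
                                     "proxy_corr_x2", "x2"),
                      forced_out=("x1",)),
    ]


def default_catalog(arity: str,
                    proxy_corrs: Sequence[float] = (0.3, 0.5, 0.8)
                    ) -> list[CandidateSpec]:
    if arity == UNIVARIATE:
        return univariate_catalog(proxy_corrs)
    if arity == MULTIVARIATE:
        return multivariate_catalog()
    raise ValueError(f"unknown arity {arity!r}")


def build_candidates(dataset: SimDataset,
                     catalog: Sequence[CandidateSpec] | None = None
                     ) -> dict[str, PredictionSet]:
    """Fit every catalog entry on the training set and score the test set."""
    if catalog is None:
        catalog = default_catalog(dataset.spec.arity, dataset.spec.proxy_corrs)
    out: dict[str, PredictionSet] = {}
    for cand in catalog:
        needed = set(cand.variable_pool) | set(cand.forced_in)
        missing = needed - set(dataset.train_X.columns)
        if missing:
            raise KeyError(
                f"candidate {cand.name!r} needs missing column(s) "
                f"{sorted(missing)}")
        if cand.transform == "flip-coin":
            out[cand.name] = flip_coin_model(dataset.test_y, candidate=cand)
            continue
        if cand.transform == "stepAIC":
            model = stepwise_aic(dataset, cand)
        else:
            cols = [v for v in cand.variable_pool if v not in cand.forced_out]
            model = fit_logistic(dataset.train_X[cols], dataset.train_y)
            if cand.transform == "shrink":
                model = shrink_model(model, dataset.train_X, dataset.train_y)
        out[cand.name] = predict_risk(model, dataset.test_X,
                                      y=dataset.test_y, candidate=cand)
    return out
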