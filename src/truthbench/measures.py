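"""The 25-measure performance panel for binary risk predictions.

Discrimination (C statistic, Somers' Dxy, Gini g-index), calibration
(calibration-in-the-large odds ratio, logistic-recalibration error
families Emax/E-mean, LOWESS-based Eavg and ECI, and the
likelihood-ratio unreliability/discrimination/quality indices U, D, Q),
and overall measures (Brier score, nine pseudo-R^2 flavours, the
heuristic global shrinkage factor, and the integrated discrimination
improvement against the null model).

Conventions that matter:

- U, D, Q follow the validation-probability dialect:
  D = (chi2_D - 1)/n with chi2_D the LR statistic of the free logistic
  recalibration against the test null model, and U = (chi2_U - 2)/n
  against the identity calibration (a=0, b=1); with a degenerate
  (constant) prediction only one parameter is free and 1 is subtracted.
  Q = D - U exactly.
- The calibration-in-the-large OR is predicted odds over observed odds.
- ECI is scaled by 100 (a mean squared calibration error in per-cent^2
  units); Eavg is on the probability scale.
- Likelihood-based measures are computed from test-set predictions; the
  global shrinkage factor comes from the candidate's *training* fit, as
  it quantifies overfitting.

Measures that are undefined for a given prediction set (e.g. the
shrinkage factor of the coin flip, or E-means under constant
predictions) are reported as NaN rather than failing the panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .models import (P_CLIP, FittedLogistic, PredictionSet, bernoulli_loglik,
                     heuristic_shrinkage)

logger = logging.getLogger("truthbench")

#: the panel's 25 slots, in report-row order
MEASURE_NAMES = (
    "AUC", "Dxy", "gIndex", "U", "D", "Q", "OR_caliLarge",
    "Emax_ab", "E_abMean", "Emax_01", "E_01Mean",
    "Eavg_LOWESS", "ECI_LOWESS", "brierScore",
    "R2_Nagelkerke", "R2_McFadden", "R2_McFaddenAdj", "R2_CoxSnell",
    "R2_AldrichNelson", "R2_VeallZimmermann", "R2_Efron",
    "R2_McKelveyZavoina", "R2_Tjur",
    "GlobalShrinkageFactor", "IDI_diff1",
)

_GRID_01 = np.arange(0.001, 0.9995, 0.001)


@dataclass
class CalibFit:
    """Logistic recalibration logit P(y=1) = a + b * logit(p_hat)."""

    a_hat: float
    b_hat: float
    loglik_free: float
    loglik_identity: float      # log-likelihood of p_hat as-is (a=0, b=1)
    loglik_null: float          # test intercept-only log-likelihood
    degenerate: bool = False    # constant p_hat, slope inestimable


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def c_statistic(p: np.ndarray, y: np.ndarray) -> float:
    """Concordance probability; ties count one half. NaN if one class."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def somers_dxy(p: np.ndarray, y: np.ndarray) -> float:
    return 2.0 * (c_statistic(p, y) - 0.5)


def g_index(lp: np.ndarray) -> float:
    """Gini mean difference of the linear predictor: the mean of
    |lp_i - lp_j| over all unordered pairs, via the sorted-order identity."""
    lp = np.sort(np.asarray(lp, dtype=float))
    n = len(lp)
    if n < 2:
        raise ValueError("need at least two subjects")
    # sum over pairs of |lp_i - lp_j| = sum of sorted gaps, each counted
    # k*(n-k) times; exact zero for constant input
    gaps = np.diff(lp)
    k = np.arange(1, n)
    return float(np.sum(gaps * k * (n - k)) / (n * (n - 1) / 2))


# ---------------------------------------------------------------------------
# calibration machinery
# ---------------------------------------------------------------------------

def _null_loglik(y: np.ndarray) -> float:
    p = float(np.mean(y))
    if p in (0.0, 1.0):
        return 0.0
    return len(y) * (p * np.log(p) + (1 - p) * np.log(1 - p))


def logistic_recalibration(p: np.ndarray, y: np.ndarray) -> CalibFit:
    """ML fit of logit P(y=1) = a + b*logit(p_hat) on the test set.

    Constant predictions make the slope inestimable; the fit degrades to
    an intercept-only model (offset zero) and is flagged degenerate.
    """
    p = np.clip(np.asarray(p, dtype=float), P_CLIP, 1 - P_CLIP)
    y = np.asarray(y, dtype=float)
    if not 0 < y.mean() < 1:
        raise ValueError("both outcome classes must be present")
    ll_ident = bernoulli_loglik(p, y)
    ll_null = _null_loglik(y)
    x = logit(p)
    if np.ptp(x) < 1e-12:
        return CalibFit(a_hat=float(logit(np.mean(y))), b_hat=float("nan"),
                        loglik_free=ll_null, loglik_identity=ll_ident,
                        loglik_null=ll_null, degenerate=True)
    exog = np.column_stack([np.ones(len(y)), x])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
            maxiter=100, tol=1e-8)
    a, b = (float(v) for v in res.params)
    ll_free = bernoulli_loglik(expit(a + b * x), y)
    # the free fit nests both reference models; guard numerics
    ll_free = max(ll_free, ll_ident, ll_null)
    return CalibFit(a_hat=a, b_hat=b, loglik_free=ll_free,
                    loglik_identity=ll_ident, loglik_null=ll_null)


def udq_indices(calib: CalibFit, n: int) -> tuple[float, float, float]:
    """Unreliability U, discrimination D and quality Q = D - U."""
    chi2_d = 2.0 * (calib.loglik_free - calib.loglik_null)
    d = (chi2_d - 1.0) / n
    chi2_u = 2.0 * (calib.loglik_free - calib.loglik_identity)
    u = (chi2_u - (1.0 if calib.degenerate else 2.0)) / n
    return u, d, d - u


def calibration_large_or(p: np.ndarray, y: np.ndarray) -> float:
    """Predicted-over-observed odds ratio (1 = mean calibration)."""
    pbar = float(np.mean(p))
    ybar = float(np.mean(y))
    if ybar in (0.0, 1.0):
        return float("nan")
    return (pbar / (1 - pbar)) / (ybar / (1 - ybar))


def calibration_errors_logistic(
        p: np.ndarray, y: np.ndarray,
        calib: CalibFit | None = None) -> tuple[float, float, float, float]:
    """(Emax_ab, E_abMean, Emax_01, E_01Mean): deviations |q - c(q)| of the
    logistic-recalibration curve c(q) = expit(a + b*logit(q)).

    "_ab": q over the observed prediction range [min p_hat, max p_hat]
    (maximum over that interval; mean over the observed predictions).
    "_01": q on the fixed grid 0.001(0.001)0.999. With degenerate
    (constant) predictions the curve collapses to the observed rate:
    both Emax values equal |p_const - rate| and the E-means are NaN.
    """
    p = np.clip(np.asarray(p, dtype=float), P_CLIP, 1 - P_CLIP)
    y = np.asarray(y, dtype=float)
    if calib is None:
        calib = logistic_recalibration(p, y)
    if calib.degenerate:
        emax = abs(float(p[0]) - float(np.mean(y)))
        return emax, float("nan"), emax, float("nan")

    def err(q):
        return np.abs(q - expit(calib.a_hat + calib.b_hat * logit(q)))

    lo, hi = float(p.min()), float(p.max())
    grid_ab = np.concatenate([_GRID_01[(_GRID_01 >= lo) & (_GRID_01 <= hi)],
                              [lo, hi]])
    emax_ab = float(err(grid_ab).max())
    e_ab_mean = float(err(p).mean())
    e01 = err(_GRID_01)
    return emax_ab, e_ab_mean, float(e01.max()), float(e01.mean())


def lowess_calibration(p: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Eavg, ECI) from a LOWESS smoother of outcomes on predictions.

    Span 2/3, zero robustness iterations. Eavg is the mean absolute and
    ECI (x100) the mean squared deviation between predicted risks and
    their smoothed observed counterparts.
    """
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) < 10:
        raise ValueError("need at least 10 subjects for the smoother")
    frac = 2 / 3
    _, counts = np.unique(p, return_counts=True)
    if np.ptp(p) < 1e-12:
        c = np.full(len(p), np.mean(y))
    elif counts.max() >= int(np.ceil(frac * len(p))):
        # a tie-cluster fills the whole bandwidth window: the local fit is
        # ill-posed (zero bandwidth), and its tricube limit for separated
        # clusters is the per-value event rate — interpolate that exactly
        c = pd.Series(y).groupby(pd.Series(p)).transform("mean").to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = lowess(y, p, frac=frac, it=0, return_sorted=False)
        if not np.all(np.isfinite(c)):
            logger.warning("LOWESS smoother failed; using per-value rates")
            c = pd.Series(y).groupby(pd.Series(p)).transform("mean").to_numpy()
    resid = p - c
    return float(np.mean(np.abs(resid))), float(100.0 * np.mean(resid ** 2))


# ---------------------------------------------------------------------------
# overall measures
# ---------------------------------------------------------------------------

def brier_score(p: np.ndarray, y: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((p - y) ** 2))


def pseudo_r2_panel(p: np.ndarray, y: np.ndarray, k: int = 0) -> dict[str, float]:
    """Nine pseudo-R^2 values from test-set predictions.

    ``k`` is the number of non-intercept terms of the candidate (used by
    the adjusted McFadden flavour). Likelihoods are evaluated at the
    predicted risks; the null likelihood at the observed event rate.
    """
    p = np.clip(np.asarray(p, dtype=float), P_CLIP, 1 - P_CLIP)
    y = np.asarray(y, dtype=float)
    n = len(y)
    out = {name: float("nan") for name in (
        "R2_Nagelkerke", "R2_McFadden", "R2_McFaddenAdj", "R2_CoxSnell",
        "R2_AldrichNelson", "R2_VeallZimmermann", "R2_Efron",
        "R2_McKelveyZavoina", "R2_Tjur")}
    ybar = float(y.mean())
    if ybar in (0.0, 1.0):
        return out

    lm = bernoulli_loglik(p, y)
    l0 = _null_loglik(y)
    chi2 = 2.0 * (lm - l0)
    out["R2_CoxSnell"] = 1.0 - np.exp(-chi2 / n)
    out["R2_Nagelkerke"] = out["R2_CoxSnell"] / (1.0 - np.exp(2.0 * l0 / n))
    out["R2_McFadden"] = 1.0 - lm / l0
    out["R2_McFaddenAdj"] = 1.0 - (lm - k) / l0
    out["R2_AldrichNelson"] = chi2 / (chi2 + n)
    out["R2_VeallZimmermann"] = (out["R2_AldrichNelson"]
                                 * (n - 2.0 * l0) / (-2.0 * l0))
    sse = float(np.sum((y - p) ** 2))
    sst = float(np.sum((y - ybar) ** 2))
    out["R2_Efron"] = 1.0 - sse / sst if sst > 0 else float("nan")
    v = float(np.var(logit(p), ddof=1)) if n > 1 else 0.0
    out["R2_McKelveyZavoina"] = v / (v + np.pi ** 2 / 3.0)
    out["R2_Tjur"] = float(p[y == 1].mean() - p[y == 0].mean())
    return out


def idi(p: np.ndarray, p_ref: np.ndarray, y: np.ndarray) -> float:
    """Integrated discrimination improvement: difference of discrimination
    slopes. Against the null model (constant observed rate) this equals
    the Tjur R^2 identically."""
    p = np.asarray(p, dtype=float)
    p_ref = np.asarray(p_ref, dtype=float)
    y = np.asarray(y)
    if y.sum() in (0, len(y)):
        return float("nan")
    ev, nev = y == 1, y == 0

    def slope(q):
        return float(q[ev].mean() - q[nev].mean())

    return slope(p) - slope(p_ref)


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def measure_panel(pred: PredictionSet,
                  measures: tuple[str, ...] | None = None) -> dict[str, float]:
    """All 25 measures (or a requested subset) for one prediction set.

    Individual measure failures are logged and reported as NaN; the panel
    itself never fails. The shrinkage factor comes from the candidate's
    training fit and is NaN for the coin flip.
    """
    if pred.y is None:
        raise ValueError("prediction set has no observed outcomes attached")
    wanted = MEASURE_NAMES if measures is None else tuple(measures)
    unknown = set(wanted) - set(MEASURE_NAMES)
    if unknown:
        raise ValueError(f"unknown measure(s) {sorted(unknown)}; "
                         f"valid names: {list(MEASURE_NAMES)}")
    p, y = pred.p_hat, np.asarray(pred.y)
    n = len(y)
    out: dict[str, float] = {}

    def safe(fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:   # degenerate input for this one measure
            logger.warning("measure failed (%s): %s", fn.__name__, exc)
            return float("nan")

    need = set(wanted)
    if {"AUC", "Dxy"} & need:
        auc = safe(c_statistic, p, y)
        out["AUC"] = auc
        out["Dxy"] = 2.0 * (auc - 0.5)
    if "gIndex" in need:
        out["gIndex"] = safe(g_index, pred.lp)
    if {"U", "D", "Q", "Emax_ab", "E_abMean", "Emax_01", "E_01Mean"} & need:
        calib = None
        try:
            calib = logistic_recalibration(p, y)
        except Exception as exc:
            logger.warning("recalibration failed: %s", exc)
        if calib is not None:
            u, d, q = udq_indices(calib, n)
            out.update(U=u, D=d, Q=q)
            res = safe(calibration_errors_logistic, p, y, calib)
            if not isinstance(res, tuple):
                res = (np.nan,) * 4
            out.update(zip(("Emax_ab", "E_abMean", "Emax_01", "E_01Mean"), res))
        else:
            out.update({k: float("nan") for k in
                        ("U", "D", "Q", "Emax_ab", "E_abMean",
                         "Emax_01", "E_01Mean")})
    if "OR_caliLarge" in need:
        out["OR_caliLarge"] = safe(calibration_large_or, p, y)
    if {"Eavg_LOWESS", "ECI_LOWESS"} & need:
        res = safe(lowess_calibration, p, y)
        out["Eavg_LOWESS"], out["ECI_LOWESS"] = (
            res if isinstance(res, tuple) else (np.nan, np.nan))
    if "brierScore" in need:
        out["brierScore"] = brier_score(p, y)
    r2_names = {m for m in wanted if m.startswith("R2_")}
    if r2_names:
        k = pred.model.df_model if pred.model is not None else 0
        out.update(pseudo_r2_panel(p, y, k=k))
    if "GlobalShrinkageFactor" in need:
        out["GlobalShrinkageFactor"] = heuristic_shrinkage(pred.model)
    if "IDI_diff1" in need:
        out["IDI_diff1"] = safe(idi, p, np.full(n, float(np.mean(y))), y)

    return {m: out[m] for m in wanted}
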