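"""Scenario grid and synthetic-data generation.

A scenario is one point of a factorial simulation design: a "true"
logistic model (intercept, one or two causal predictors with log-odds
effects) plus the correlation structure of non-causal proxy predictors.
Each scenario yields replicate datasets: causal predictors are drawn
first, the binary outcome is drawn from the true-model risk, proxy
predictors (independent or correlated with a causal predictor, but never
used in the outcome formula) are appended, and the rows are split 80/20
into a training and a testing set.

Correlations involving binary variables are targeted on the observed
(Pearson) scale through a latent-Gaussian threshold construction: the
latent correlation is solved (closed form for normal-vs-indicator,
bisection on the bivariate-normal orthant probability for
indicator-vs-indicator) so that the thresholded variables achieve the
requested Pearson correlation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

logger = logging.getLogger("truthbench")

#: admissible range of log-odds effects in the default design
BETA_RANGE = (0.0, float(np.log(4)))

#: proxy-correlation levels of the univariate candidate catalog
DEFAULT_PROXY_CORRS = (0.3, 0.5, 0.8)

UNIVARIATE = "univariate"
MULTIVARIATE = "multivariate"
CONTINUOUS = "continuous"
BINARY = "binary"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """One point of the simulation grid.

    Parameters are on the log-odds scale: the outcome is Bernoulli with
    P(y=1) = expit(beta0 + sum_k betas[k] * x_k [+ interaction]).
    """

    scenario_id: str
    arity: str                          # "univariate" | "multivariate"
    predictor_kinds: tuple[str, ...]    # each "continuous" | "binary"
    beta0: float
    betas: tuple[float, ...]
    interaction_beta: float | None = None
    binary_prevalence: float = 0.3
    causal_corr: float = 0.0
    proxy_corrs: tuple[float, ...] = DEFAULT_PROXY_CORRS
    n_total: int = 15_000
    train_fraction: float = 0.8
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.arity not in (UNIVARIATE, MULTIVARIATE):
            raise ValueError(f"unknown arity {self.arity!r}")
        if len(self.betas) != len(self.predictor_kinds):
            raise ValueError("betas and predictor_kinds must have equal length")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 < self.binary_prevalence < 1:
            raise ValueError("binary_prevalence must be in (0, 1)")
        if not 0 <= self.causal_corr < 1:
            raise ValueError("causal_corr must be in [0, 1)")
        for rho in self.proxy_corrs:
            if not 0 <= rho < 1:
                raise ValueError("proxy correlations must be in [0, 1)")
        lo, hi = BETA_RANGE
        for b in self.betas:
            if not lo - 1e-12 <= b <= hi + 1e-12:
                warnings.warn(
                    f"effect {b:.4f} outside the default range "
                    f"[log 1, log 4] in scenario {self.scenario_id}",
                    stacklevel=2,
                )

    @property
    def n_train(self) -> int:
        return int(np.floor(self.n_total * self.train_fraction))

    @property
    def n_test(self) -> int:
        return self.n_total - self.n_train

    @property
    def causal_columns(self) -> tuple[str, ...]:
        return tuple(f"x{i + 1}" for i in range(len(self.betas)))


@dataclass
class SimDataset:
    """One simulated train/test pair with causal and proxy predictors."""

    train_X: pd.DataFrame
    train_y: np.ndarray
    test_X: pd.DataFrame
    test_y: np.ndarray
    column_meta: dict[str, str]
    spec: ScenarioSpec
    rep_index: int

    @property
    def causal_columns(self) -> tuple[str, ...]:
        return self.spec.causal_columns

    @property
    def proxy_columns(self) -> tuple[str, ...]:
        return tuple(c for c in self.train_X.columns
                     if c not in self.causal_columns)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Train and test tables with the outcome in a column named ``y``."""
        train = self.train_X.copy()
        train["y"] = self.train_y
        test = self.test_X.copy()
        test["y"] = self.test_y
        return train, test


# ---------------------------------------------------------------------------
# RNG derivation
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) from a master seed and a key path."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

_GRID_FACTORS = ("betas", "beta0", "predictor_kinds", "binary_prevalence",
                 "causal_corr", "interaction_beta")


def build_grid(config: Mapping, master_seed: int = 0) -> list[ScenarioSpec]:
    """Materialise the Cartesian product of factor levels into scenarios.

    ``config`` maps each varied factor to its list of levels:

    - ``betas``: list of effect vectors (each a sequence of log-odds);
    - ``beta0``: list of intercepts;
    - ``predictor_kinds``: list of kind vectors;
    - ``binary_prevalence`` / ``causal_corr`` / ``interaction_beta``: scalars.

    Remaining keys (``arity``, ``n_total``, ``train_fraction``, ``n_reps``,
    ``proxy_corrs``, optional ``id_prefix``) are held fixed. Every scenario
    receives a deterministic child seed derived from ``master_seed`` and its
    position, so grids can be evaluated in any order or in parallel.
    """
    levels: dict[str, list] = {}
    for name in _GRID_FACTORS:
        if name in config:
            vals = list(config[name])
            if not vals:
                raise ValueError(f"factor {name!r} has an empty level list")
            levels[name] = vals
    if "betas" not in levels or "beta0" not in levels:
        raise ValueError("config must provide levels for 'betas' and 'beta0'")
    levels.setdefault("predictor_kinds", [(CONTINUOUS,) * len(levels["betas"][0])])
    levels.setdefault("binary_prevalence", [0.3])
    levels.setdefault("causal_corr", [0.0])
    levels.setdefault("interaction_beta", [None])

    arity = config.get("arity", UNIVARIATE)
    fixed = dict(
        arity=arity,
        n_total=int(config.get("n_total",
                               15_000 if arity == UNIVARIATE else 3_000)),
        train_fraction=float(config.get("train_fraction", 0.8)),
        n_reps=int(config.get("n_reps", 100)),
        proxy_corrs=tuple(config.get("proxy_corrs", DEFAULT_PROXY_CORRS)),
    )
    prefix = config.get("id_prefix", arity[:3])

    names = sorted(levels)
    specs = []
    for i, combo in enumerate(itertools.product(*(levels[n] for n in names))):
        kw = dict(zip(names, combo))
        kw["betas"] = tuple(float(b) for b in np.atleast_1d(kw["betas"]))
        kw["predictor_kinds"] = tuple(np.atleast_1d(kw["predictor_kinds"]))
        spec = ScenarioSpec(
            scenario_id=f"{prefix}-{i:04d}",
            seed=derive_seed(master_seed, i),
            **kw, **fixed,
        )
        specs.append(spec)
    return specs


def default_univariate_config() -> dict:
    """Default univariate factor levels (single causal predictor).

    Effects span odds ratios 1–4; intercepts span baseline risks 10–50%;
    the predictor is either standard normal or Bernoulli (prevalence 0.3
    or 0.5). The continuous and binary arms are separate configs so that
    the prevalence factor only multiplies the binary arm.
    """
    beta1 = [float(np.log(v)) for v in (1, 1.3, 1.7, 2, 2.5, 3, 4)]
    beta0 = [float(logit(v)) for v in (0.1, 0.2, 0.3, 0.5)]
    return {
        "continuous": {
            "arity": UNIVARIATE, "id_prefix": "uni-c",
            "betas": [(b,) for b in beta1], "beta0": beta0,
            "predictor_kinds": [(CONTINUOUS,)],
        },
        "binary": {
            "arity": UNIVARIATE, "id_prefix": "uni-b",
            "betas": [(b,) for b in beta1], "beta0": beta0,
            "predictor_kinds": [(BINARY,)],
            "binary_prevalence": [0.3, 0.5],
        },
    }


def default_multivariate_config() -> dict:
    """Default multivariate factor levels (two causal predictors).

    Mirrors the univariate effect levels without the exact-null level
    (a two-predictor causal model with both effects null is degenerate);
    the pair is both-continuous or continuous+binary, with causal
    correlation 0, 0.3 or 0.5. The candidate catalog's correlated proxies
    use a single strength, the first entry of ``proxy_corrs``.
    """
    b = [float(np.log(v)) for v in (1.3, 1.7, 2, 2.5, 3, 4)]
    beta0 = [float(logit(v)) for v in (0.1, 0.2, 0.3, 0.5)]
    return {
        "arity": MULTIVARIATE, "id_prefix": "multi",
        "betas": [(b1, b2) for b1 in b for b2 in b],
        "beta0": beta0,
        "predictor_kinds": [(CONTINUOUS, CONTINUOUS), (CONTINUOUS, BINARY)],
        "causal_corr": [0.0, 0.3, 0.5],
        "n_total": 3_000,
        "proxy_corrs": (0.5,),
    }


def default_grid(arity: str, master_seed: int = 0,
                 n_reps: int = 100) -> list[ScenarioSpec]:
    """The package's default scenario grid for one simulation arm."""
    if arity == UNIVARIATE:
        cfgs = default_univariate_config()
        specs = build_grid(cfgs["continuous"], derive_seed(master_seed, 0))
        specs += build_grid(cfgs["binary"], derive_seed(master_seed, 1))
    elif arity == MULTIVARIATE:
        specs = build_grid(default_multivariate_config(), derive_seed(master_seed, 2))
    else:
        raise ValueError(f"unknown arity {arity!r}")
    return [replace(s, n_reps=n_reps) for s in specs]


# ---------------------------------------------------------------------------
# latent-Gaussian correlation targeting
# ---------------------------------------------------------------------------

def _latent_corr_normal_indicator(rho: float, prev: float) -> float:
    """Latent corr r so that corr(Z, 1{Z' > c}) = rho, with P(Z' > c) = prev."""
    c = stats.norm.ppf(1 - prev)
    r = rho * np.sqrt(prev * (1 - prev)) / stats.norm.pdf(c)
    if abs(r) >= 1:
        raise ValueError(
            f"Pearson correlation {rho} is unattainable for a binary "
            f"variable with prevalence {prev}")
    return float(r)


def _latent_corr_indicator_pair(rho: float, p1: float, p2: float) -> float:
    """Latent corr r so that the phi-coefficient of the two thresholded
    indicators (prevalences p1, p2) equals rho."""
    if rho == 0:
        return 0.0
    c1, c2 = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
    denom = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(r):
        both = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, r], [r, 1]]).cdf([-c1, -c2])
        return (both - p1 * p2) / denom - rho

    lo, hi = -0.9999, 0.9999
    if gap(hi) < 0 or gap(lo) > 0:
        raise ValueError(
            f"phi-coefficient {rho} is unattainable for prevalences "
            f"({p1}, {p2})")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-8))


def _threshold(prev: float) -> float:
    """Latent threshold c with P(Z > c) = prev."""
    return float(stats.norm.ppf(1 - prev))


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------

def simulate_predictors(spec: ScenarioSpec, n: int,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw the causal predictor table (columns ``x1`` [, ``x2``]).

    Continuous predictors are standard normal; binary predictors are
    Bernoulli(``binary_prevalence``). For a correlated multivariate pair
    the draw goes through a Gaussian copula whose latent correlation is
    solved so the observed-scale Pearson correlation equals
    ``causal_corr``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    kinds = spec.predictor_kinds
    p = spec.binary_prevalence

    if len(kinds) == 2 and spec.causal_corr > 0:
        rho = spec.causal_corr
        if kinds == (CONTINUOUS, CONTINUOUS):
            r = rho
        elif BINARY in kinds and CONTINUOUS in kinds:
            r = _latent_corr_normal_indicator(rho, p)
        else:
            r = _latent_corr_indicator_pair(rho, p, p)
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
        cols = {}
        for j, kind in enumerate(kinds):
            cols[f"x{j + 1}"] = (z[:, j] if kind == CONTINUOUS
                                 else (z[:, j] > _threshold(p)).astype(float))
        return pd.DataFrame(cols)

    cols = {}
    for j, kind in enumerate(kinds):
        if kind == CONTINUOUS:
            cols[f"x{j + 1}"] = rng.standard_normal(n)
        else:
            cols[f"x{j + 1}"] = (rng.random(n) < p).astype(float)
    return pd.DataFrame(cols)


def simulate_proxy(target: np.ndarray, rho: float, kind: str,
                   rng: np.random.Generator,
                   prevalence: float | None = None) -> np.ndarray:
    """Draw a proxy column with Pearson correlation ``rho`` to ``target``.

    ``kind`` is the proxy's own kind. A binary *target* is mapped back to
    a latent normal (truncated-normal draw conditional on the indicator)
    before the usual z = r*z_t + sqrt(1-r^2)*eps construction; ``r`` is
    the latent correlation that delivers ``rho`` on the observed scale.
    ``prevalence`` sets a binary proxy's event rate (defaults to the
    target's own rate when the target is binary, else 0.5).
    """
    target = np.asarray(target, dtype=float)
    n = target.shape[0]
    target_binary = set(np.unique(target)) <= {0.0, 1.0}
    if rho == 0:
        if kind == CONTINUOUS:
            return rng.standard_normal(n)
        pv = prevalence if prevalence is not None else (
            float(target.mean()) if target_binary else 0.5)
        return (rng.random(n) < pv).astype(float)

    sd = target.std()
    if sd == 0:
        raise ValueError("correlation with a constant target is undefined")

    if target_binary:
        p_t = float(target.mean())
        c_t = _threshold(p_t)
        # latent normal consistent with the observed indicator
        z_t = np.where(
            target == 1,
            stats.truncnorm.rvs(c_t, np.inf, size=n, random_state=rng),
            stats.truncnorm.rvs(-np.inf, c_t, size=n, random_state=rng),
        )
        if kind == CONTINUOUS:
            r = _latent_corr_normal_indicator(rho, p_t)
            return r * z_t + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
        pv = prevalence if prevalence is not None else p_t
        r = _latent_corr_indicator_pair(rho, p_t, pv)
        z = r * z_t + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
        return (z > _threshold(pv)).astype(float)

    z_t = (target - target.mean()) / sd
    if kind == CONTINUOUS:
        return rho * z_t + np.sqrt(1 - rho ** 2) * rng.standard_normal(n)
    pv = prevalence if prevalence is not None else 0.5
    r = _latent_corr_normal_indicator(rho, pv)
    z = r * z_t + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
    return (z > _threshold(pv)).astype(float)


def simulate_outcome(spec: ScenarioSpec, predictors: pd.DataFrame,
                     rng: np.random.Generator) -> np.ndarray:
    """Bernoulli outcomes from the true-model risk expit(beta0 + X beta)."""
    X = predictors[list(spec.causal_columns)].to_numpy(dtype=float)
    lp = spec.beta0 + X @ np.asarray(spec.betas)
    if spec.interaction_beta is not None:
        if X.shape[1] != 2:
            raise ValueError("interaction term requires two causal predictors")
        lp = lp + spec.interaction_beta * X[:, 0] * X[:, 1]
    return (rng.random(len(lp)) < expit(lp)).astype(int)


def _proxy_label(rho: float) -> str:
    # one-decimal convention: rho=0.3 -> "proxy_c03"
    return f"proxy_c{int(round(rho * 10)):02d}"


def _attach_proxies(spec: ScenarioSpec, X: pd.DataFrame,
                    rng: np.random.Generator) -> dict[str, str]:
    """Append the proxy columns required by the candidate catalog; returns
    the per-column role metadata."""
    meta = {c: "causal" for c in spec.causal_columns}
    x1 = X["x1"].to_numpy()
    kind1 = spec.predictor_kinds[0]

    if spec.arity == UNIVARIATE:
        X["proxy_ind"] = simulate_proxy(x1, 0.0, kind1, rng,
                                        prevalence=spec.binary_prevalence)
        meta["proxy_ind"] = "proxy-independent"
        for rho in spec.proxy_corrs:
            name = _proxy_label(rho)
            X[name] = simulate_proxy(x1, rho, kind1, rng)
            meta[name] = f"proxy-correlated({rho}, x1)"
        return meta

    x2 = X["x2"].to_numpy()
    kind2 = spec.predictor_kinds[1]
    rho = spec.proxy_corrs[0]
    X["proxy_ind"] = simulate_proxy(x1, 0.0, kind1, rng,
                                    prevalence=spec.binary_prevalence)
    X["proxy_cont_ind"] = rng.standard_normal(len(X))
    X["proxy_bin_ind"] = (rng.random(len(X)) < spec.binary_prevalence).astype(float)
    X["proxy_corr_x1"] = simulate_proxy(x1, rho, kind1, rng)
    X["proxy_cont_corr"] = simulate_proxy(x1, rho, CONTINUOUS, rng)
    X["proxy_corr_x2"] = simulate_proxy(x2, rho, kind2, rng)
    meta.update({
        "proxy_ind": "proxy-independent",
        "proxy_cont_ind": "proxy-independent",
        "proxy_bin_ind": "proxy-independent",
        "proxy_corr_x1": f"proxy-correlated({rho}, x1)",
        "proxy_cont_corr": f"proxy-correlated({rho}, x1)",
        "proxy_corr_x2": f"proxy-correlated({rho}, x2)",
    })
    return meta


def make_dataset(spec: ScenarioSpec, rep_index: int) -> SimDataset:
    """One replicate dataset: simulate, attach proxies, split 80/20.

    Fully deterministic given ``(spec.seed, rep_index)``. Splits leaving a
    train or test side with a single outcome class are regenerated from
    the next substream (at most 100 attempts).
    """
    if rep_index >= spec.n_reps:
        raise ValueError(f"rep_index {rep_index} >= n_reps {spec.n_reps}")
    for attempt in range(100):
        rng = _rng(spec.seed, rep_index, attempt)
        X = simulate_predictors(spec, spec.n_total, rng)
        y = simulate_outcome(spec, X, rng)
        meta = _attach_proxies(spec, X, rng)
        perm = rng.permutation(spec.n_total)
        tr, te = perm[:spec.n_train], perm[spec.n_train:]
        y_tr, y_te = y[tr], y[te]
        if 0 < y_tr.mean() < 1 and 0 < y_te.mean() < 1:
            return SimDataset(
                train_X=X.iloc[tr].reset_index(drop=True),
                train_y=y_tr,
                test_X=X.iloc[te].reset_index(drop=True),
                test_y=y_te,
                column_meta=meta,
                spec=spec,
                rep_index=rep_index,
            )
        logger.warning("degenerate split for %s rep %d (attempt %d); "
                       "regenerating", spec.scenario_id, rep_index, attempt)
    raise RuntimeError(
        f"could not obtain a non-degenerate split for {spec.scenario_id} "
        f"rep {rep_index} in 100 attempts")
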