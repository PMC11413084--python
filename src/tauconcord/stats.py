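"""Inference layer: correlations, detection thresholds, concordance,
linearity comparison, gamma GLM, and subgroup analyses.

These are the statistical procedures used to relate tau-PET SUVR to
quantitative AT8 burden: Spearman rank correlations (the data are not
normally distributed), Youden-index detection thresholds for pathology given
binary PET positivity, exact (Clopper-Pearson) binomial confidence intervals
for PET/pathology concordance, nested linear-vs-polynomial model comparison
by residual sum of squares / AIC / F test, a gamma-family generalized linear
model of SUVR on pathology and covariates, and the PART (primary age-related
tauopathy) classification rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "DetectionThresholdResult",
    "ConcordanceResult",
    "ModelComparisonResult",
    "GlmResult",
    "PartClassification",
    "EmptySubsetError",
    "spearman_corr",
    "youden_detection_threshold",
    "concordance_accuracy",
    "clopper_pearson",
    "linear_vs_polynomial",
    "assign_sextiles",
    "fit_gamma_glm",
    "classify_part",
    "subgroup_spearman",
]


class EmptySubsetError(ValueError):
    """A subgroup filter matched no rows."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class DetectionThresholdResult:
    """Youden-optimal pathology cutpoint against binary PET positivity."""

    pathology_threshold_pct: float
    youden_j: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class ConcordanceResult:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    ci_low: float
    ci_high: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ModelComparisonResult:
    """Linear vs degree-d polynomial OLS comparison on grouped codes."""

    rss_linear: float
    rss_poly: float
    aic_linear: float
    aic_poly: float
    delta_aic: float
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    degree: int
    n: int


@dataclass
class GlmResult:
    """Per-predictor estimates from the gamma GLM of SUVR."""

    table: pd.DataFrame  # index: predictor; columns: estimate, t_value, p_value
    family: str
    link: str
    dispersion: float


@dataclass(frozen=True)
class PartClassification:
    category: Literal["none", "possible", "definite"]


# ---------------------------------------------------------------------------
# Spearman correlation

def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


_EXACT_PERMUTATION_MAX_N = 10


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, stat_obs: float) -> float:
    """Two-sided exact permutation p for the rank cross-product statistic."""
    n = rx.size
    rx_c = rx - rx.mean()
    total = 0
    extreme = 0
    chunk = 200_000
    perm_iter = itertools.permutations(ry)
    while True:
        block = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(perm_iter, chunk)),
            dtype=float,
        )
        if block.size == 0:
            break
        block = block.reshape(-1, n)
        stats_perm = (block - block.mean(axis=1, keepdims=True)) @ rx_c
        extreme += int(np.sum(np.abs(stats_perm) >= np.abs(stat_obs) - 1e-9))
        total += block.shape[0]
    return extreme / total


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of mid-ranks. The two-sided p-value uses
    an exact permutation distribution for n <= 10 and the t-distribution
    approximation t = rho sqrt((n-2)/(1-rho^2)) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman rho is undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_PERMUTATION_MAX_N:
        rx_c = rx - rx.mean()
        stat_obs = float(rx_c @ (ry - ry.mean()))
        p = _exact_spearman_p(rx, ry, stat_obs)
    else:
        denom = max(1.0 - rho * rho, 1e-300)
        t = rho * np.sqrt((n - 2) / denom)
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=max(min(p, 1.0), 1e-300), n=n)


# ---------------------------------------------------------------------------
# Youden detection threshold

def youden_detection_threshold(
    pathology_pct: Sequence[float], pet_positive: Sequence[bool]
) -> DetectionThresholdResult:
    """Pathology cutpoint maximizing Youden's J against PET positivity.

    Candidate cutpoints are midpoints between consecutive sorted unique
    pathology values; the decision rule is pathology >= t => predicted
    PET-positive. Ties in J are broken toward the smallest threshold.
    """
    path = np.asarray(pathology_pct, dtype=float)
    pos = np.asarray(pet_positive, dtype=bool)
    if path.shape != pos.shape:
        raise ValueError("inputs must have equal length")
    if pos.all() or not pos.any():
        raise ValueError("both PET-positive and PET-negative cases are required")
    u = np.unique(path)
    if u.size < 2:
        raise ValueError("at least two distinct pathology values are required")
    candidates = (u[:-1] + u[1:]) / 2.0

    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    best = None
    for t in candidates:
        pred = path >= t
        sens = float((pred & pos).sum()) / n_pos
        spec = float((~pred & ~pos).sum()) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return DetectionThresholdResult(
        pathology_threshold_pct=float(t),
        youden_j=float(j),
        sensitivity=sens,
        specificity=spec,
    )


# ---------------------------------------------------------------------------
# Concordance and exact binomial intervals

def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("require 0 <= successes <= n with n > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return low, high


def concordance_accuracy(
    path_positive: Sequence[bool], pet_positive: Sequence[bool], level: float = 0.95
) -> ConcordanceResult:
    """Agreement between pathology and PET positivity with an exact CI."""
    a = np.asarray(path_positive, dtype=bool)
    b = np.asarray(pet_positive, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    tp = int((a & b).sum())
    tn = int((~a & ~b).sum())
    fp = int((~a & b).sum())
    fn = int((a & ~b).sum())
    n = a.size
    acc = (tp + tn) / n
    low, high = clopper_pearson(tp + tn, n, level)
    return ConcordanceResult(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=acc, ci_low=low, ci_high=high)


# ---------------------------------------------------------------------------
# Linear vs polynomial nested comparison

def _ols_rss(x: np.ndarray, y: np.ndarray, degree: int) -> float:
    X = np.vander(x, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _gaussian_aic(n: int, rss: float, n_coef: int) -> float:
    # error variance counted as one additional parameter
    return n * np.log(2 * np.pi) + n * np.log(rss / n) + n + 2 * (n_coef + 1)


def linear_vs_polynomial(
    group_code: Sequence[float], y: Sequence[float], degree: int = 2
) -> ModelComparisonResult:
    """Compare a linear fit with a degree-``degree`` polynomial by OLS.

    Group codes are numeric scores (Braak I..VI or sextiles coded 1..6).
    Reports the residual sums of squares, Gaussian-likelihood AICs,
    delta AIC = AIC(poly) - AIC(linear), and the nested F test
    F = ((RSS1 - RSS2)/(d-1)) / (RSS2/(n-d-1)) with its upper-tail p-value.
    """
    x = np.asarray(group_code, dtype=float)
    yy = np.asarray(y, dtype=float)
    if x.shape != yy.shape:
        raise ValueError("inputs must have equal length")
    if degree < 2:
        raise ValueError("polynomial degree must be at least 2")
    n = x.size
    if n <= degree + 1:
        raise ValueError("too few observations for the polynomial model")
    rss1 = _ols_rss(x, yy, 1)
    rss2 = _ols_rss(x, yy, degree)
    rss2 = min(rss2, rss1)  # nesting guarantees this up to round-off
    # residuals at round-off level mean an exact fit: the F test is undefined
    if rss2 <= float(yy @ yy) * 1e-12 or not np.isfinite(rss2):
        raise ValueError("zero residual variance in the polynomial model; p undefined")
    df_num = degree - 1
    df_den = n - degree - 1
    f = ((rss1 - rss2) / df_num) / (rss2 / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    aic1 = _gaussian_aic(n, rss1, 2)
    aic2 = _gaussian_aic(n, rss2, degree + 1)
    return ModelComparisonResult(
        rss_linear=rss1,
        rss_poly=rss2,
        aic_linear=aic1,
        aic_poly=aic2,
        delta_aic=aic2 - aic1,
        f_stat=float(f),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
        degree=degree,
        n=n,
    )


def assign_sextiles(values: Sequence[float]) -> np.ndarray:
    """Rank-based split into six groups coded 1..6 (1 = lowest values).

    Group sizes are floor(n/6) or ceil(n/6); the first ``n mod 6`` groups
    take the extra observation. Ties keep their stable input order.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 6:
        raise ValueError("at least 6 observations are required for sextiles")
    order = np.argsort(v, kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, 6), start=1):
        labels[chunk] = g
    return labels


# ---------------------------------------------------------------------------
# Gamma GLM

def fit_gamma_glm(
    y: Sequence[float],
    predictors: pd.DataFrame,
    link: Literal["log", "identity"] = "log",
) -> GlmResult:
    """Gamma-family GLM of SUVR on pathology and covariates.

    Fitted by iteratively reweighted least squares (IRLS). ``predictors``
    typically holds tau neuropathology (% area), age (years), a male
    indicator, and the PET-to-post-mortem interval (months); an intercept is
    added. p-values use the large-sample normal approximation to the
    coefficient t-statistics, with the dispersion estimated from Pearson
    residuals.
    """
    yy = np.asarray(y, dtype=float)
    if np.any(yy <= 0):
        raise ValueError("gamma GLM requires strictly positive outcomes")
    X = sm.add_constant(predictors.astype(float), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    link_fn = {"log": sm.families.links.Log(), "identity": sm.families.links.Identity()}[link]
    with warnings.catch_warnings():
        # the identity link is a deliberate sensitivity option; statsmodels
        # warns that it does not respect the gamma domain
        warnings.filterwarnings("ignore", message=".*does not respect the domain.*")
        model = sm.GLM(yy, X, family=sm.families.Gamma(link=link_fn))
    res = model.fit()
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "t_value": res.tvalues,
            "p_value": res.pvalues,
        }
    )
    return GlmResult(table=table, family="gamma", link=link, dispersion=float(res.scale))


# ---------------------------------------------------------------------------
# PART classification and subgroup correlations

def classify_part(thal: int, braak: int) -> PartClassification:
    """Primary age-related tauopathy rule.

    Definite PART: Thal phase 0 with Braak stage I-IV; possible PART: Thal
    phase 1-2 with Braak stage I-IV; anything else is not PART.
    """
    if not 0 <= thal <= 5:
        raise ValueError("Thal phase must lie in 0..5")
    if not 0 <= braak <= 6:
        raise ValueError("Braak stage must lie in 0..6")
    if 1 <= braak <= 4:
        if thal == 0:
            return PartClassification("definite")
        if thal in (1, 2):
            return PartClassification("possible")
    return PartClassification("none")


def subgroup_spearman(
    table: pd.DataFrame,
    x: str,
    y: str,
    *,
    query: str | None = None,
    by: str | None = None,
    min_n: int = 3,
) -> Mapping[str, CorrelationResult]:
    """Spearman correlations on a filtered (optionally grouped) table.

    ``query`` is a pandas query string selecting the subgroup (for example
    ``"braak_stage <= 4"`` or ``"region == 'midbrain'"``); ``by`` groups the
    filtered rows (for example by region). An empty subgroup raises
    :class:`EmptySubsetError` rather than returning NaN.
    """
    sub = table.query(query) if query else table
    if sub.empty:
        raise EmptySubsetError(f"no rows match filter {query!r}")
    groups = sub.groupby(by) if by else [("all", sub)]
    out: dict[str, CorrelationResult] = {}
    for name, g in groups:
        g = g.dropna(subset=[x, y])
        if len(g) < min_n:
            raise EmptySubsetError(
                f"subgroup {name!r} has only {len(g)} usable rows (need >= {min_n})"
            )
        out[str(name)] = spearman_corr(g[x].to_numpy(), g[y].to_numpy())
    return out
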