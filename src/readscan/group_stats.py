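"""Group-difference statistics: unbiased effect sizes with exact CIs,
t-tests, JZS Bayes factors, robust percentage-bend correlations,
proportion-consistent readers, and the GLMM design/likelihood-ratio layer.

Sign convention throughout: effect sizes are computed as
(group1 - group2) / pooled SD with group1 = control, so a metric on which
the dyslexia group is larger or longer carries a negative sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats as sps

SIGN_CONVENTION = "positive = group1 (control) larger; negative = group2 (dyslexia) larger/longer"


@dataclass(frozen=True)
class SampleStats:
    mean: float
    sd: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SampleStats":
        v = np.asarray(values, dtype=float)
        return cls(float(v.mean()), float(v.std(ddof=1)), int(v.size))


@dataclass(frozen=True)
class EffectSizeResult:
    g: float
    ci95: tuple[float, float]
    n1: int
    n2: int
    sign_convention: str = SIGN_CONVENTION

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0 or hi < 0


def _pooled_sd(s1: SampleStats, s2: SampleStats) -> float:
    df = s1.n + s2.n - 2
    return math.sqrt(((s1.n - 1) * s1.sd ** 2 + (s2.n - 1) * s2.sd ** 2) / df)


def _nc_from_quantile(t_obs: float, df: float, q: float) -> float:
    """Noncentrality lambda such that the noncentral-t CDF at t_obs equals q.

    The CDF is strictly decreasing in lambda; solved by bisection/brentq to
    1e-8, bracketing around the observed statistic.
    """

    def f(nc: float) -> float:
        v = sps.nct.cdf(t_obs, df, nc)
        if math.isnan(v):  # far-tail numeric failure: saturate
            v = 0.0 if nc > t_obs else 1.0
        return v - q

    width = 4.0 + abs(t_obs)
    lo, hi = t_obs - width, t_obs + width
    while f(lo) < 0:
        lo -= width
    while f(hi) > 0:
        hi += width
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def hedges_g(
    sample1: SampleStats | tuple, sample2: SampleStats | tuple,
    alpha: float = 0.05,
) -> EffectSizeResult:
    """Unbiased standardized mean difference with the exact analytical CI.

    g = J * (m1 - m2) / s_pooled with the small-sample correction
    J = 1 - 3 / (4 df - 1); the CI inverts the noncentral-t distribution
    for the noncentrality parameter at the alpha/2 and 1-alpha/2 points and
    rescales by sqrt(1/n1 + 1/n2).  The CI endpoints carry no additional
    J shrink (they bound the standardized difference delta, the convention
    of the exact analytical method).
    """
    s1 = SampleStats(*sample1) if not isinstance(sample1, SampleStats) else sample1
    s2 = SampleStats(*sample2) if not isinstance(sample2, SampleStats) else sample2
    if s1.n < 2 or s2.n < 2:
        raise ValueError("need n >= 2 in each group")
    sp = _pooled_sd(s1, s2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    df = s1.n + s2.n - 2
    scale = math.sqrt(1.0 / s1.n + 1.0 / s2.n)
    d = (s1.mean - s2.mean) / sp
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    t_obs = d / scale
    if t_obs == 0.0:
        half = sps.t.ppf(1 - alpha / 2, df) * scale
        return EffectSizeResult(0.0, (-half, half), s1.n, s2.n)
    nc_lo = _nc_from_quantile(t_obs, df, 1 - alpha / 2)
    nc_hi = _nc_from_quantile(t_obs, df, alpha / 2)
    return EffectSizeResult(
        j * d, (nc_lo * scale, nc_hi * scale), s1.n, s2.n)


def hedges_g_from_values(values1, values2, alpha: float = 0.05) -> EffectSizeResult:
    return hedges_g(SampleStats.from_values(values1),
                    SampleStats.from_values(values2), alpha)


def independent_t(
    sample1: SampleStats | tuple, sample2: SampleStats | tuple,
) -> tuple[float, int, float]:
    """Pooled-variance two-sided independent-samples t-test."""
    s1 = SampleStats(*sample1) if not isinstance(sample1, SampleStats) else sample1
    s2 = SampleStats(*sample2) if not isinstance(sample2, SampleStats) else sample2
    sp = _pooled_sd(s1, s2)
    if sp == 0:
        raise ValueError("zero pooled SD")
    df = s1.n + s2.n - 2
    t = (s1.mean - s2.mean) / (sp * math.sqrt(1 / s1.n + 1 / s2.n))
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, float(p)


def one_sample_t_vs_chance(
    scores: Sequence[float], chance: float = 0.5, n_tests_bonferroni: int = 1,
) -> tuple[float, float, float]:
    """Two-sided one-sample t against a chance level, Bonferroni-adjusted.

    Returns (t, p_raw, p_adjusted) with p_adjusted = min(1, p_raw * n_tests).
    A zero-variance sample away from chance yields an infinite t and p -> 0.
    """
    v = np.asarray(scores, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 scores")
    sd = v.std(ddof=1)
    if sd == 0:
        if v.mean() == chance:
            return 0.0, 1.0, 1.0
        t = math.inf if v.mean() > chance else -math.inf
        return t, 0.0, 0.0
    t = (v.mean() - chance) / (sd / math.sqrt(v.size))
    p = float(2 * sps.t.sf(abs(t), v.size - 1))
    return float(t), p, min(1.0, p * n_tests_bonferroni)


@dataclass(frozen=True)
class BayesResult:
    bf10: float
    cauchy_width: float = 0.7


def jzs_bf(
    t: float, n1: int, n2: int | None = None, cauchy_width: float = 0.7,
) -> BayesResult:
    """Jeffreys-Zellner-Siow Bayes factor BF10 for a one- or two-sample t.

    BF10 = integral over delta of T_df(t; delta * sqrt(n_eff)) Cauchy(delta; 0, r)
    divided by T_df(t; 0), evaluated by adaptive quadrature.
    """
    if n2 is None:
        df, n_eff = n1 - 1, float(n1)
    else:
        df, n_eff = n1 + n2 - 2, n1 * n2 / (n1 + n2)
    if df < 1:
        raise ValueError("not enough observations")
    root_n = math.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return (sps.nct.pdf(t, df, delta * root_n)
                * sps.cauchy.pdf(delta, 0.0, cauchy_width))

    # split at the prior mode and the likelihood peak so the adaptive
    # quadrature cannot step over either
    breaks = sorted({0.0, t / root_n})
    limits = [-np.inf, *breaks, np.inf]
    num = err = 0.0
    for lo, hi in zip(limits, limits[1:]):
        part, perr = integrate.quad(integrand, lo, hi, limit=200)
        num += part
        err += perr
    if not np.isfinite(num) or (num > 0 and err / num > 1e-4):
        raise RuntimeError(f"BF integration failed: value={num}, abserr={err}")
    denom = sps.t.pdf(t, df)
    return BayesResult(float(num / denom), cauchy_width)


def _pb_location(x: np.ndarray, beta: float) -> float:
    """Percentage-bend measure of location (one-step winsorized estimate)."""
    med = np.median(x)
    w = np.sort(np.abs(x - med))
    omega = w[int(math.floor((1 - beta) * len(x))) - 1]
    if omega == 0:
        raise ValueError("bend scale is zero (over half the data at the median)")
    psi = (x - med) / omega
    i1 = int(np.sum(psi < -1))
    i2 = int(np.sum(psi > 1))
    sx = np.where(np.abs(psi) <= 1, x, 0.0)
    return (sx.sum() + omega * (i2 - i1)) / (len(x) - i1 - i2)


def percentage_bend_correlation(
    x: Sequence[float], y: Sequence[float], beta: float = 0.2,
) -> tuple[float, float]:
    """Robust correlation winsorizing ``beta`` of the standardized
    deviations in each variable (default 20% bending in each direction).

    p-value from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    n = x.size

    def psi_scores(v: np.ndarray) -> np.ndarray:
        w = np.sort(np.abs(v - np.median(v)))
        omega = w[int(math.floor((1 - beta) * n)) - 1]
        if omega == 0:
            raise ValueError("bend scale is zero "
                             "(over half the data at the median)")
        u = (v - _pb_location(v, beta)) / omega
        return np.clip(u, -1.0, 1.0)

    a, b = psi_scores(x), psi_scores(y)
    r = float(np.sum(a * b) / math.sqrt(np.sum(a ** 2) * np.sum(b ** 2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * math.sqrt((n - 2) / (1 - r ** 2))
    p = float(2 * sps.t.sf(abs(tstat), n - 2))
    return r, p


def proportion_consistent(
    participant_means: Sequence[float], reference_mean: float, direction: str,
) -> float:
    """Fraction of participants whose trial-averaged metric lies on the
    stated side of the other group's mean (``direction`` in greater/less)."""
    v = np.asarray(participant_means, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one participant mean")
    if direction == "greater":
        return float(np.mean(v > reference_mean))
    if direction == "less":
        return float(np.mean(v < reference_mean))
    raise ValueError("direction must be 'greater' or 'less'")


# ---------------------------------------------------------------------------
# GLMM design + likelihood-ratio orchestration (fitting is delegated)
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Declarative description of the reading-duration mixed model.

    Gamma-family response; deviation-coded (mean-centred) fixed effects for
    group, font and their interaction; maximal random-effects structure
    (by-participant font slopes, by-text group/font/interaction slopes),
    without random correlations.  The actual solver is supplied through an
    adapter (any backend accepting a coded trial table).
    """

    response: str = "reading_duration"
    family: str = "gamma"
    fixed_effects: tuple[str, ...] = ("group_c", "font_c", "group_x_font")
    random_effects: tuple[str, ...] = (
        "participant: intercept + font_c (no correlations)",
        "text: intercept + group_c + font_c + group_x_font (no correlations)",
    )


def build_design(trials: pd.DataFrame) -> tuple[DesignSpec, pd.DataFrame]:
    """Deviation-code group/font/interaction onto a single-trial table.

    Codes start at -1/2 vs +1/2 and are then mean-centred, so each coded
    column sums to ~0 even under mild imbalance.  Raises on single-level
    predictors; flags (raises) on collinear coded columns.
    """
    required = {"participant", "text", "group", "font", "reading_duration"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if (trials["reading_duration"] <= 0).any():
        raise ValueError("gamma-family response must be positive")
    coded = trials.copy()
    for col, name in (("group", "group_c"), ("font", "font_c")):
        levels = sorted(coded[col].unique())
        if len(levels) != 2:
            raise ValueError(f"predictor {col!r} needs exactly 2 levels, "
                             f"got {levels}")
        raw = np.where(coded[col] == levels[0], -0.5, 0.5)
        coded[name] = raw - raw.mean()
    inter = coded["group_c"] * coded["font_c"]
    coded["group_x_font"] = inter - inter.mean()
    cols = ["group_c", "font_c", "group_x_font"]
    x = coded[cols].to_numpy()
    if np.any(x.std(axis=0) == 0):
        raise ValueError("collinear predictor columns in design "
                         "(a coded column is constant)")
    corr = np.corrcoef(x, rowvar=False)
    mask = ~np.eye(3, dtype=bool)
    if np.any(np.abs(corr[mask]) > 0.99):
        raise ValueError("collinear predictor columns in design")
    return DesignSpec(), coded


@dataclass(frozen=True)
class LRTResult:
    chisq: float
    df: int
    p: float


def lrt(deviance_full: float, deviance_reduced: float, df_diff: int,
        tolerant: bool = True) -> LRTResult:
    """Likelihood-ratio (X^2) model comparison from two deviances."""
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    x2 = deviance_reduced - deviance_full
    if x2 < 0:
        if not tolerant:
            raise ValueError("reduced model fits better than full model")
        import warnings
        warnings.warn("negative X^2 clamped to 0", stacklevel=2)
        x2 = 0.0
    p = float(sps.chi2.sf(x2, df_diff))
    return LRTResult(float(x2), df_diff, p)
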