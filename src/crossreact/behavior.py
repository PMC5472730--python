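"""Design-derived chance levels, choice-accuracy tests, and power analysis.

Chance/optimal rates are exact enumerations of the offer design: every
(offer-1, offer-2) size pair is equiprobable, a choice is "correct" when the
chosen size is at least the unchosen size, and exact ties count as correct
under either choice.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import TaskConfig
from .errors import AnalysisError, ConfigError

__all__ = [
    "chance_correct_rate", "optimal_offer1_rate", "odds_ratio", "relative_risk",
    "split_odds_effect", "gof_chisq", "indep_chisq_2x2", "binom_test",
    "power_n_for_correlation", "fit_choice_curve", "ProportionTestResult",
    "ChoiceCurveFit",
]


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    p_value: float
    n: int
    effect_size: float | None
    sidedness: str
    test: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "p_value": self.p_value, "n": self.n,
                "effect_size": self.effect_size, "sidedness": self.sidedness,
                "test": self.test}


@dataclass
class ChoiceCurveFit:
    """Per-trial-type logistic fit of P(choose offer 1) on V1 - V2."""

    intercepts: dict[str, float]
    slopes: dict[str, float]
    grid: pd.DataFrame  # columns: trial_type, value_diff, p_choose1
    separation_flags: dict[str, bool]


def _design_pairs(task: TaskConfig):
    return list(itertools.product(task.offer1_sizes, task.offer2_sizes))


def chance_correct_rate(task: TaskConfig) -> float:
    """Expected percent correct of a coin-flip chooser over the offer design.

    A tie is correct whichever option is taken; a strict pair is correct with
    probability 1/2. The default 5x3 design gives 56.67%.
    """
    pairs = _design_pairs(task)
    p = [1.0 if a == b else 0.5 for a, b in pairs]
    return 100.0 * float(np.mean(p))


def optimal_offer1_rate(task: TaskConfig) -> float:
    """Percent of design pairs in which a reward maximizer takes offer 1.

    Exact ties are credited 1/2 (the maximizer is indifferent). The default
    design gives 40%.
    """
    pairs = _design_pairs(task)
    p = [1.0 if a > b else (0.5 if a == b else 0.0) for a, b in pairs]
    return 100.0 * float(np.mean(p))


def _check_prop(p: float) -> None:
    if not (0 < p < 1):
        raise AnalysisError(f"proportion {p} on boundary; effect size undefined")


def odds_ratio(p1: float, p2: float) -> float:
    """(p1/(1-p1)) / (p2/(1-p2)); errors on boundary proportions."""
    _check_prop(p1)
    _check_prop(p2)
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


def relative_risk(p1: float, p2: float) -> float:
    _check_prop(p1)
    _check_prop(p2)
    return p1 / p2


def split_odds_effect(k: int, n: int) -> float:
    """Sign-bias effect size for a k-of-n split: (k/(n-k))^2."""
    if not (0 < k < n):
        raise AnalysisError("split effect undefined for boundary splits")
    return (k / (n - k)) ** 2


def gof_chisq(k: int, n: int, p0: float, sided: str = "two-sided") -> ProportionTestResult:
    """Pearson goodness-of-fit chi-square of k successes in n against p0.

    One degree of freedom, no continuity correction. ``sided='greater'``
    halves the p-value when k exceeds expectation (doubled-tail convention
    otherwise).
    """
    if n <= 0 or k < 0 or k > n or not (0 < p0 < 1):
        raise AnalysisError("invalid goodness-of-fit inputs")
    exp1, exp0 = n * p0, n * (1 - p0)
    if exp1 == 0 or exp0 == 0:
        raise AnalysisError("expected cell count of zero")
    chi2 = (k - exp1) ** 2 / exp1 + ((n - k) - exp0) ** 2 / exp0
    p_two = float(stats.chi2.sf(chi2, df=1))
    if sided == "two-sided":
        p = p_two
    elif sided == "greater":
        p = p_two / 2 if k >= exp1 else 1 - p_two / 2
    elif sided == "less":
        p = p_two / 2 if k <= exp1 else 1 - p_two / 2
    else:
        raise AnalysisError(f"unknown sidedness {sided!r}")
    eff = None
    try:
        eff = odds_ratio(k / n, p0)
    except AnalysisError:
        pass
    return ProportionTestResult(float(chi2), p, n, eff, sided, "gof_chisq")


def indep_chisq_2x2(a: int, b: int, c: int, d: int) -> ProportionTestResult:
    """Pearson chi-square of independence for [[a, b], [c, d]], no correction.

    Effect size is the odds ratio of row-1 versus row-2 success proportions.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or table.sum() == 0:
        raise AnalysisError("invalid 2x2 table")
    res = stats.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq == 0):
        raise AnalysisError("expected cell count of zero")
    n = int(table.sum())
    p1 = a / (a + b)
    p2 = c / (c + d)
    eff = None
    if 0 < p1 < 1 and 0 < p2 < 1:
        eff = odds_ratio(p1, p2)
    return ProportionTestResult(float(res.statistic), float(res.pvalue), n, eff,
                                "two-sided", "indep_chisq_2x2")


def binom_test(k: int, n: int, p0: float, sided: str = "two-sided") -> ProportionTestResult:
    """Exact binomial test of k successes in n against success probability p0."""
    if n <= 0 or not (0 < p0 < 1):
        raise AnalysisError("invalid binomial-test inputs")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sided]
    res = stats.binomtest(k, n, p0, alternative=alt)
    phat = k / n
    eff = relative_risk(phat, p0) if 0 < phat < 1 else None
    return ProportionTestResult(phat, float(res.pvalue), n, eff, sided, "binom")


def power_n_for_correlation(r: float, alpha_two_sided: float = 0.05,
                            power: float = 0.85) -> int:
    """Minimum n to detect a correlation r via the Fisher-z approximation.

    n = ((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3, rounded to the nearest
    integer and floored at 4 (atanh needs n > 3). Detecting r = 0.386 at
    alpha = 0.05 with power 0.85 requires n = 57.
    """
    if not (0 < r < 1):
        raise AnalysisError("r must lie in (0, 1)")
    if not (0 < alpha_two_sided < 1 and 0 < power < 1):
        raise AnalysisError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha_two_sided / 2)
    zb = stats.norm.ppf(power)
    n = ((za + zb) / math.atanh(r)) ** 2 + 3
    return max(4, int(round(n)))


_SLOPE_CAP = 10.0  # per µl; far beyond any non-degenerate fit


def fit_choice_curve(trials: pd.DataFrame, value_grid: np.ndarray | None = None) -> ChoiceCurveFit:
    """Logistic regression of choosing offer 1 on the value difference V1 - V2.

    Fit separately per trial type by maximum likelihood (statsmodels Logit).
    Complete separation is flagged and the slope capped rather than allowed
    to diverge.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    intercepts, slopes, flags, rows = {}, {}, {}, []
    for tt, sub in trials.groupby("trial_type", sort=True):
        dv = (sub["offer1_size"] - sub["offer2_size"]).to_numpy(dtype=float)
        y = (sub["chosen_option"] == 1).to_numpy(dtype=float)
        if len(np.unique(dv)) < 2:
            raise AnalysisError(f"trial type {tt!r}: need >= 2 distinct value differences")
        X = sm.add_constant(dv)
        sep = len(np.unique(y)) < 2
        b0, b1 = np.nan, np.nan
        if not sep:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                try:
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                    b0, b1 = fit.params
                except Exception:
                    sep = True
            if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
                sep = True
        if sep or abs(b1) > _SLOPE_CAP:
            sep = True
            b1 = math.copysign(_SLOPE_CAP, b1 if np.isfinite(b1) else (2 * y.mean() - 1))
            if not np.isfinite(b0):
                b0 = 0.0
            warnings.warn(f"trial type {tt!r}: complete separation; slope capped")
        intercepts[tt], slopes[tt], flags[tt] = float(b0), float(b1), bool(sep)
        from scipy.special import expit
        grid = np.sort(np.unique(dv)) if value_grid is None else np.asarray(value_grid)
        p = np.clip(expit(b0 + b1 * grid), 1e-12, 1 - 1e-12)
        rows.append(pd.DataFrame({"trial_type": tt, "value_diff": grid, "p_choose1": p}))
    return ChoiceCurveFit(intercepts, slopes, pd.concat(rows, ignore_index=True), flags)
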