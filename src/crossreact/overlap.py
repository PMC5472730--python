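"""Coefficient-overlap statistics across epochs and trial types.

Whether two task variables engage the same population code is measured by
rank-correlating the per-neuron regression slopes obtained in two epochs:
the signed Spearman correlation indexes a shared coding scheme, the
correlation of absolute slopes indexes shared neuronal participation.
Significance is assessed both asymptotically and by a predictor-shuffle
permutation null that refits every neuron's regression with the predictor
vector randomly permuted (rates untouched), independently for the two
regressions of a pair.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

__all__ = ["RegressionSpec", "OverlapResult", "PermutationResult",
           "coeff_correlation", "permutation_null", "fisher_compare",
           "cooks_screen", "compare_strength"]


@dataclass
class RegressionSpec:
    """One epoch's regression: shared design, per-neuron responses.

    ``epoch_means`` is (trials x neurons); ``predictors`` is (trials x p)
    without the intercept; ``coef_index`` selects which predictor's slope
    enters the overlap statistic (0 = first predictor).
    """

    epoch_means: np.ndarray
    predictors: np.ndarray
    coef_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.epoch_means = np.asarray(self.epoch_means, dtype=float)
        self.predictors = np.asarray(self.predictors, dtype=float)
        if self.predictors.ndim == 1:
            self.predictors = self.predictors[:, None]
        if self.epoch_means.shape[0] != self.predictors.shape[0]:
            raise AnalysisError("means/predictor row mismatch")

    def slopes(self, perm: np.ndarray | None = None) -> np.ndarray:
        P = self.predictors if perm is None else self.predictors[perm]
        X = np.column_stack([np.ones(len(P)), P])
        beta, *_ = np.linalg.lstsq(X, self.epoch_means, rcond=None)
        return beta[1 + self.coef_index]


@dataclass
class OverlapResult:
    pair: str
    signed_r: float
    signed_p: float
    unsigned_r: float
    unsigned_p: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    cutoff: float  # 95th percentile of the null
    p_value: float  # (1 + #{null >= observed}) / (1 + n_iter)
    n_iter: int
    mode: str

    def to_dict(self) -> dict:
        return {"observed": self.observed, "cutoff": self.cutoff,
                "p_value": self.p_value, "n_iter": self.n_iter, "mode": self.mode,
                "null_quantiles": {q: float(np.quantile(self.null, q))
                                   for q in (0.025, 0.05, 0.5, 0.95, 0.975)}}


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    r, p = stats.spearmanr(a, b)
    return float(r), float(p)


def coeff_correlation(slopes_a: np.ndarray, slopes_b: np.ndarray,
                      pair: str = "") -> OverlapResult:
    """Signed and unsigned Spearman correlation of two slope vectors.

    Average ranks for ties; asymptotic two-sided p-values.
    """
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AnalysisError("slope vectors must be equal-length 1-D arrays")
    if len(a) < 4:
        raise AnalysisError("need at least 4 neurons")
    rs, ps = _spearman(a, b)
    ru, pu = _spearman(np.abs(a), np.abs(b))
    return OverlapResult(pair, rs, ps, ru, pu, len(a))


def _rank(x: np.ndarray) -> np.ndarray:
    # average ranks along the last axis
    return stats.rankdata(x, axis=-1)


def permutation_null(spec_a: RegressionSpec, spec_b: RegressionSpec,
                     n_iter: int = 1000, seed=None, mode: str = "signed",
                     observed: float | None = None) -> PermutationResult:
    """Predictor-shuffle null for the Spearman overlap of two slope vectors.

    Each iteration permutes the predictor rows independently within each
    regression, refits all neurons, and correlates the two shuffled slope
    vectors. The significance cutoff is the 95th percentile of the null.
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives a coarse null")
    rng = np.random.default_rng(seed)
    if observed is None:
        a0, b0 = spec_a.slopes(), spec_b.slopes()
        if mode == "unsigned":
            a0, b0 = np.abs(a0), np.abs(b0)
        observed = _spearman(a0, b0)[0]
    n_a, n_b = spec_a.epoch_means.shape[0], spec_b.epoch_means.shape[0]
    null = np.empty(n_iter)
    for i in range(n_iter):
        sa = spec_a.slopes(rng.permutation(n_a))
        sb = spec_b.slopes(rng.permutation(n_b))
        if mode == "unsigned":
            sa, sb = np.abs(sa), np.abs(sb)
        ra, rb = _rank(sa), _rank(sb)
        null[i] = np.corrcoef(ra, rb)[0, 1]
    cutoff = float(np.quantile(null, 0.95))
    p = (1 + int((null >= observed).sum())) / (1 + n_iter)
    return PermutationResult(float(observed), null, cutoff, p, n_iter, mode)


def fisher_compare(r1: float, n1: int, r2: float, n2: int,
                   dependent: bool = False, r_cross: float | None = None):
    """Compare two correlation coefficients through the Fisher z transform.

    Independent samples: z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
    Dependent samples (same units in both correlations) apply a Steiger-style
    correction using ``r_cross``, the correlation between the two shared
    coefficient vectors: the denominator becomes sqrt(2 (1 - r_cross)/(n - 3))
    with n = n1 = n2. Returns (z, two-sided p).
    """
    for r in (r1, r2):
        if not (-1 < r < 1):
            raise AnalysisError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise AnalysisError("need n > 3")
    d = math.atanh(r1) - math.atanh(r2)
    if dependent:
        if n1 != n2:
            raise AnalysisError("dependent comparison requires equal n")
        if r_cross is None or not (-1 < r_cross < 1):
            raise AnalysisError("dependent comparison requires r_cross in (-1, 1)")
        se = math.sqrt(2 * (1 - r_cross) / (n1 - 3))
    else:
        se = math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    z = d / se
    return z, 2 * stats.norm.sf(abs(z))


def cooks_screen(x: np.ndarray, y: np.ndarray, threshold: float | None = None):
    """Cook's distance of each point in the OLS fit of y on x.

    Returns (distances, flags) with flags marking D > threshold
    (default 4/n). Used to screen coefficient scatterplots for outliers.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n <= 3:
        raise AnalysisError("need more than 3 points")
    if np.ptp(x) == 0:
        raise AnalysisError("degenerate regressor")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    if fit.mse_resid <= 1e-24 * max(np.var(y), 1e-300):
        d = np.zeros(n)  # exact fit: no point is influential
    else:
        d = fit.get_influence().cooks_distance[0]
    thr = 4.0 / n if threshold is None else threshold
    return d, d > thr


def compare_strength(sq_a: np.ndarray, sq_b: np.ndarray, paired: bool = True):
    """t-test on squared coefficients across neurons, with Hedges' g.

    Squared slopes (or R²) index encoding strength irrespective of sign.
    Returns (t, two-sided p, hedges_g); g carries the small-sample correction
    J = 1 - 3/(4 df - 1).
    """
    a = np.asarray(sq_a, dtype=float)
    b = np.asarray(sq_b, dtype=float)
    if paired and a.shape != b.shape:
        raise AnalysisError("paired comparison requires equal lengths")
    if np.var(a) == 0 and np.var(b) == 0:
        raise AnalysisError("zero variance in both samples")
    if paired:
        t, p = stats.ttest_rel(a, b)
        df = len(a) - 1
        sd = np.std(a - b, ddof=1)
        g0 = (a - b).mean() / sd if sd > 0 else 0.0
    else:
        t, p = stats.ttest_ind(a, b)
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp = math.sqrt(((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df)
        g0 = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    j = 1 - 3 / (4 * df - 1)
    return float(t), float(p), float(j * g0)
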