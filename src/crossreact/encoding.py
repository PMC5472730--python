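"""Binned, z-scored firing rates and per-neuron tuning regressions.

Rates are computed in 10 ms bins aligned to the offer-1 cue and z-scored per
neuron over every bin the neuron was recorded (bins outside a trial's span
are missing, not zero). Tuning is ordinary least squares of the normalized
epoch-mean rate on the offer or outcome size in µl (optionally plus a binary
chose-offer-1 covariate); fits for all neurons in an epoch share the design
matrix, so they are solved as one batched least-squares problem.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import EpochWindow
from .errors import AnalysisError, ValidationError
from .behavior import binom_test, gof_chisq, split_odds_effect, ProportionTestResult

__all__ = ["RateTensor", "CoefficientSet", "TuningCensus", "bin_and_zscore",
           "psth", "epoch_mean", "fit_tuning", "sliding_tuning",
           "find_peak_window", "census", "select_trials"]


@dataclass
class RateTensor:
    """Z-scored rates, shape (neurons, trials, bins); NaN outside a trial's span."""

    rate: np.ndarray  # float32 (N, T, B)
    bin_ms: float
    t_start: float  # left edge of bin 0, ms relative to offer1_cue_on
    trial_ids: np.ndarray
    neuron_ids: np.ndarray
    raw_mean: np.ndarray  # per-neuron pre-normalization mean rate (Hz)
    raw_sd: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.rate.shape[2]

    @property
    def bin_starts(self) -> np.ndarray:
        return self.t_start + self.bin_ms * np.arange(self.n_bins)

    def trial_index(self, trial_ids) -> np.ndarray:
        pos = pd.Index(self.trial_ids)
        idx = pos.get_indexer(np.asarray(trial_ids))
        if (idx < 0).any():
            raise ValidationError("unknown trial_id in request")
        return idx


def bin_and_zscore(spikes: pd.DataFrame, trials: pd.DataFrame,
                   bin_ms: float = 10.0) -> RateTensor:
    """Count spikes per 10 ms bin, convert to Hz, z-score per neuron.

    Raises if a neuron has zero rate variance (no spikes, or a constant
    count pattern), since its z-scores would be undefined.
    """
    neuron_ids = np.unique(spikes["neuron_id"].to_numpy())
    trial_ids = trials["trial_id"].to_numpy()
    n_n, n_t = len(neuron_ids), len(trial_ids)

    t0 = float(trials["fixation_on"].min())
    t1 = float((trials["outcome_on"] + 750.0).max())
    n_b = int(np.ceil((t1 - t0) / bin_ms))

    n_pos = pd.Index(neuron_ids).get_indexer(spikes["neuron_id"].to_numpy())
    t_pos = pd.Index(trial_ids).get_indexer(spikes["trial_id"].to_numpy())
    if (t_pos < 0).any():
        bad = np.unique(spikes["trial_id"].to_numpy()[t_pos < 0])
        raise ValidationError(f"spike rows reference unknown trial_ids {bad[:5].tolist()}")
    b_pos = np.floor((spikes["spike_time_ms"].to_numpy() - t0) / bin_ms).astype(int)
    keep = (b_pos >= 0) & (b_pos < n_b)
    flat = (n_pos[keep] * n_t + t_pos[keep]) * n_b + b_pos[keep]
    counts = np.bincount(flat, minlength=n_n * n_t * n_b)
    rate = (counts.reshape(n_n, n_t, n_b) * (1000.0 / bin_ms)).astype(np.float32)

    # mask bins outside each trial's recorded span
    starts = t0 + bin_ms * np.arange(n_b)
    valid = ((starts[None, :] >= trials["fixation_on"].to_numpy()[:, None])
             & (starts[None, :] + bin_ms <= (trials["outcome_on"].to_numpy()
                                             + 750.0)[:, None]))
    rate[:, ~valid] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmean(rate, axis=(1, 2))
        sd = np.nanstd(rate, axis=(1, 2))
    dead = ~(sd > 0)
    if dead.any():
        raise AnalysisError(
            f"zero rate variance for neuron_ids {neuron_ids[dead].tolist()}")
    rate -= mu[:, None, None].astype(np.float32)
    rate /= sd[:, None, None].astype(np.float32)
    return RateTensor(rate, bin_ms, t0, trial_ids, neuron_ids, mu, sd)


def psth(rt: RateTensor, trials: pd.DataFrame, boxcar_ms: float = 200.0,
         group_by: str | None = None) -> dict:
    """Trial-averaged traces per condition, boxcar-smoothed along time.

    The boxcar is symmetric and truncated at the edges (the average runs over
    however many bins fall inside the series). Returns {group: (N, B) array}.
    """
    w = int(round(boxcar_ms / rt.bin_ms))
    if abs(w * rt.bin_ms - boxcar_ms) > 1e-9 or w < 1:
        raise AnalysisError("boxcar_ms must be a positive multiple of bin_ms")
    if group_by is None:
        groups = {"all": np.arange(len(rt.trial_ids))}
    else:
        groups = {}
        for key, sub in trials.groupby(group_by, sort=True):
            if len(sub) == 0:
                continue
            groups[key] = rt.trial_index(sub["trial_id"])
        if not groups:
            warnings.warn("no nonempty groups for psth")
    out = {}
    for key, idx in groups.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(rt.rate[:, idx, :], axis=1)
        out[key] = _boxcar(mean, w)
    return out


def _boxcar(x: np.ndarray, w: int) -> np.ndarray:
    """Truncated-edge moving average along the last axis, NaN-aware."""
    if w == 1:
        return x.copy()
    vals = np.nan_to_num(x, nan=0.0)
    cnts = (~np.isnan(x)).astype(float)
    kernel = np.ones(w)
    num = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, vals)
    den = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), -1, cnts)
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def epoch_mean(rt: RateTensor, trials: pd.DataFrame, window: EpochWindow,
               trial_ids=None) -> np.ndarray:
    """(trials x neurons) mean z-scored rate inside a per-trial-aligned window."""
    sub = trials if trial_ids is None else trials.set_index("trial_id").loc[
        np.asarray(trial_ids)].reset_index()
    ev = sub[window.align_event].to_numpy(dtype=float)
    start = ev + window.start_ms
    offs = np.round((start - rt.t_start) / rt.bin_ms).astype(int)
    n_w = int(round(window.width_ms / rt.bin_ms))
    if n_w < 1:
        raise AnalysisError("window narrower than one bin")
    if (offs < 0).any() or (offs + n_w > rt.n_bins).any():
        bad = sub["trial_id"].to_numpy()[(offs < 0) | (offs + n_w > rt.n_bins)]
        raise AnalysisError(f"window {window.name!r} outside recorded span for "
                            f"trials {bad[:5].tolist()}")
    t_idx = rt.trial_index(sub["trial_id"])
    cols = offs[:, None] + np.arange(n_w)[None, :]
    vals = rt.rate[:, t_idx[:, None], cols]  # (N, T, n_w)
    out = vals.mean(axis=2).T  # (T, N)
    if np.isnan(out).any():
        raise AnalysisError(f"window {window.name!r} touches unrecorded bins")
    return np.asarray(out, dtype=float)


@dataclass
class CoefficientSet:
    """Per-neuron slopes of one epoch x trial-type x model regression."""

    slope: np.ndarray
    p_value: np.ndarray
    r_squared: np.ndarray
    t_stat: np.ndarray
    neuron_ids: np.ndarray
    epoch: str
    trial_type: str
    predictor: str
    model: str  # "size-only" | "size+choice"
    selection: str  # "offer1-chosen" | "all"
    n_trials: int

    def __len__(self) -> int:
        return len(self.slope)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": self.neuron_ids, "epoch": self.epoch,
            "trial_type": self.trial_type, "model": self.model,
            "selection": self.selection, "B": self.slope, "p": self.p_value,
            "R2": self.r_squared,
        })


def select_trials(trials: pd.DataFrame, trial_type: str | None,
                  selection: str = "all") -> pd.DataFrame:
    sub = trials
    if trial_type is not None:
        sub = sub[sub["trial_type"] == trial_type]
    if selection == "offer1-chosen":
        sub = sub[sub["chosen_option"] == 1]
    elif selection != "all":
        raise AnalysisError(f"unknown trial selection {selection!r}")
    return sub


def batched_ols(X: np.ndarray, Y: np.ndarray):
    """OLS of every column of Y on the shared design X.

    Returns (beta (p x k), t, p_two_sided, r_squared); closed form via the
    normal equations, validated in the tests against statsmodels.
    """
    n, p = X.shape
    if n <= p:
        raise AnalysisError("more parameters than observations")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as e:
        raise AnalysisError("degenerate design matrix") from e
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p_two = 2 * stats.t.sf(np.abs(t), dof)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - (resid ** 2).sum(axis=0) / ss_tot
    return beta, t, p_two, r2


def fit_tuning(epoch_means: np.ndarray, design: pd.DataFrame,
               predictor: str, include_choice: bool = False,
               min_trials: int = 10, epoch: str = "", trial_type: str = "",
               selection: str = "all",
               neuron_ids: np.ndarray | None = None) -> CoefficientSet:
    """Per-neuron OLS slope of normalized epoch rate on a size predictor.

    ``design`` must align row-for-row with ``epoch_means`` and contain the
    predictor column (µl) and, when ``include_choice``, ``chosen_option``.
    """
    Y = np.asarray(epoch_means, dtype=float)
    n = Y.shape[0]
    if len(design) != n:
        raise AnalysisError("design/means row mismatch")
    if n < min_trials:
        raise AnalysisError(f"only {n} trials; minimum is {min_trials}")
    x = design[predictor].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise AnalysisError(f"constant predictor {predictor!r} in selection")
    cols = [np.ones(n), x]
    if include_choice:
        c = (design["chosen_option"].to_numpy() == 1).astype(float)
        if np.ptp(c) == 0:
            raise AnalysisError("constant choice covariate in selection")
        cols.append(c)
    X = np.column_stack(cols)
    beta, t, p, r2 = batched_ols(X, Y)
    if neuron_ids is None:
        neuron_ids = np.arange(Y.shape[1])
    return CoefficientSet(beta[1], p[1], r2, t[1], np.asarray(neuron_ids),
                          epoch, trial_type, predictor,
                          "size+choice" if include_choice else "size-only",
                          selection, n)


def sliding_tuning(rt: RateTensor, trials: pd.DataFrame, predictor: str,
                   align_event: str, span_ms: tuple[float, float],
                   window_ms: float = 300.0, step_ms: float = 50.0,
                   alpha: float = 0.05, include_choice: bool = False,
                   min_trials: int = 10) -> pd.DataFrame:
    """Tuned fraction and mean |t| in sliding windows along the trial.

    Windows are [c - w/2, c + w/2) around centers stepping through
    ``span_ms`` (relative to ``align_event``). Returns one row per window:
    center_ms, fraction_tuned, mean_abs_t, n_neurons.
    """
    rows = []
    centers = np.arange(span_ms[0] + window_ms / 2,
                        span_ms[1] - window_ms / 2 + 1e-9, step_ms)
    for c in centers:
        win = EpochWindow("sliding", align_event, c - window_ms / 2, c + window_ms / 2)
        em = epoch_mean(rt, trials, win)
        cs = fit_tuning(em, trials, predictor, include_choice=include_choice,
                        min_trials=min_trials)
        rows.append({"center_ms": float(c),
                     "fraction_tuned": float((cs.p_value < alpha).mean()),
                     "mean_abs_t": float(np.abs(cs.t_stat).mean()),
                     "n_neurons": len(cs)})
    return pd.DataFrame(rows)


def find_peak_window(centers_ms: np.ndarray, strength: np.ndarray,
                     epoch_bounds: tuple[float, float], width_ms: float,
                     align_event: str, name: str = "peak") -> EpochWindow:
    """Center a window of ``width_ms`` on the strongest encoding time.

    ``strength`` is typically the population mean |t| from sliding_tuning.
    The window is clipped so it stays inside ``epoch_bounds``; ties go to the
    earliest bin.
    """
    centers_ms = np.asarray(centers_ms, dtype=float)
    strength = np.asarray(strength, dtype=float)
    inside = (centers_ms >= epoch_bounds[0]) & (centers_ms <= epoch_bounds[1])
    if not inside.any() or np.all(np.isnan(strength[inside])):
        raise AnalysisError("no usable encoding-strength samples inside bounds")
    c = centers_ms[inside]
    s = strength[inside]
    peak = c[int(np.nanargmax(s))]
    lo = max(epoch_bounds[0], min(peak - width_ms / 2, epoch_bounds[1] - width_ms))
    return EpochWindow(name, align_event, lo, lo + width_ms)


@dataclass
class TuningCensus:
    """Population census of significantly tuned neurons in one regression."""

    n_tuned: int
    n_total: int
    fraction: float
    binomial: ProportionTestResult
    n_positive: int
    sign_split_effect: float | None
    sign_test: ProportionTestResult | None

    def to_dict(self) -> dict:
        return {"n_tuned": self.n_tuned, "n_total": self.n_total,
                "fraction": self.fraction, "binomial": self.binomial.to_dict(),
                "n_positive": self.n_positive,
                "sign_split_effect": self.sign_split_effect,
                "sign_test": self.sign_test.to_dict() if self.sign_test else None}


def census(coeffs: CoefficientSet, alpha: float = 0.05) -> TuningCensus:
    """Count tuned neurons, test the fraction against alpha, test sign bias."""
    if len(coeffs) == 0:
        raise AnalysisError("empty coefficient set")
    sig = coeffs.p_value < alpha
    k = int(sig.sum())
    n = len(coeffs)
    binom = binom_test(k, n, alpha, sided="greater")
    kpos = int((coeffs.slope[sig] > 0).sum())
    eff = None
    sign_test = None
    if 0 < kpos < k:
        eff = split_odds_effect(max(kpos, k - kpos), k)
        sign_test = gof_chisq(kpos, k, 0.5, sided="two-sided")
    return TuningCensus(k, n, k / n, binom, kpos, eff, sign_test)
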