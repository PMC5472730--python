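"""PCA trajectories and the described-vs-experienced distance analysis.

Epoch-averaged population states (five 300 ms epochs x two trial types) are
decomposed by PCA; the separation of the two trial types over the trial is
quantified by the Euclidean distance between their mean population vectors
in a sliding 300 ms window, against a trial-type label-shuffle null band.
Distances are computed in the full neuron space (a PC-subspace variant is
available via ``n_components``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .config import EpochWindow, trajectory_windows
from .encoding import RateTensor, epoch_mean
from .errors import AnalysisError

__all__ = ["TrajectoryResult", "epoch_state_matrix", "pca_trajectories",
           "distance_series", "distance_band"]


@dataclass
class TrajectoryResult:
    explained_variance_pct: np.ndarray  # all PCs, sums to 100
    coordinates: pd.DataFrame  # trial_type, epoch, pc1..pc3
    distance: pd.DataFrame | None = None  # center_ms, distance, null stats, p

    def to_dict(self) -> dict:
        d = {"explained_variance_pct": self.explained_variance_pct.tolist(),
             "coordinates": self.coordinates.to_dict(orient="list")}
        if self.distance is not None:
            d["distance"] = self.distance.to_dict(orient="list")
        return d


def epoch_state_matrix(rt: RateTensor, trials: pd.DataFrame,
                       windows: dict[str, EpochWindow] | None = None,
                       trial_types=("described", "experienced")):
    """(types x epochs) x neurons matrix of mean z-scored rates.

    Rows are ordered type-major in the given epoch order; returns
    (matrix, row_labels) with row_labels a list of (trial_type, epoch).
    """
    if windows is None:
        windows = trajectory_windows()
    rows, labels = [], []
    for tt in trial_types:
        sub = trials[trials["trial_type"] == tt]
        if len(sub) == 0:
            raise AnalysisError(f"no trials of type {tt!r}")
        for name, win in windows.items():
            em = epoch_mean(rt, sub, win)
            rows.append(em.mean(axis=0))
            labels.append((tt, name))
    return np.vstack(rows), labels


def pca_trajectories(state_matrix: np.ndarray, labels,
                     n_components: int = 3) -> TrajectoryResult:
    """Column-centered PCA of the epoch-state matrix; top-PC coordinates.

    No scaling (states are already z-scored rates). Component signs are fixed
    by making each loading vector's largest-magnitude element positive.
    """
    M = np.asarray(state_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise AnalysisError("need at least two state rows")
    if not np.any(M - M.mean(axis=0)):
        raise AnalysisError("state matrix has rank 0 after centering")
    k = min(M.shape[0] - 1, M.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(M)
    flip = np.sign(pca.components_[np.arange(k),
                                   np.argmax(np.abs(pca.components_), axis=1)])
    scores *= flip
    ev = 100.0 * pca.explained_variance_ratio_
    # pad so the vector always accounts for all the variance
    ev = np.append(ev, max(0.0, 100.0 - ev.sum())) if ev.sum() < 100 - 1e-9 else ev
    n_c = min(n_components, scores.shape[1])
    coords = pd.DataFrame(scores[:, :n_c],
                          columns=[f"pc{i+1}" for i in range(n_c)])
    coords.insert(0, "epoch", [e for _, e in labels])
    coords.insert(0, "trial_type", [t for t, _ in labels])
    return TrajectoryResult(ev, coords)


def _window_means(rt: RateTensor, trials: pd.DataFrame, window_ms: float,
                  step_ms: float, span_ms=None, min_coverage: float = 0.25):
    """Per-trial, per-window, per-neuron means on the common offer-cue clock.

    Returns (centers, A) with A of shape (windows, trials, neurons). The span
    defaults to cue onset through the median trial's end of outcome delivery.
    Because the choice period varies in duration, late windows fall beyond
    some trials' recorded span; those entries are NaN and the means over
    trials are NaN-aware. Windows where fewer than ``min_coverage`` of trials
    remain are dropped with a warning.
    """
    if span_ms is None:
        span_ms = (0.0, float(trials["outcome_on"].median() + 750.0))
    lo, hi = span_ms
    if hi - lo < window_ms:
        raise AnalysisError("span narrower than one window")
    centers = np.arange(lo + window_ms / 2, hi - window_ms / 2 + 1e-9, step_ms)
    t_idx = rt.trial_index(trials["trial_id"])
    n_w = int(round(window_ms / rt.bin_ms))
    A = np.empty((len(centers), len(t_idx), rt.rate.shape[0]), dtype=np.float32)
    for i, c in enumerate(centers):
        b0 = int(round((c - window_ms / 2 - rt.t_start) / rt.bin_ms))
        if b0 < 0 or b0 + n_w > rt.n_bins:
            raise AnalysisError("window outside recorded span")
        # a trial contributes only if the whole window is inside its span
        A[i] = rt.rate[:, t_idx, b0:b0 + n_w].mean(axis=2).T
    valid = ~np.isnan(A[:, :, 0])
    keep = valid.mean(axis=1) >= min_coverage
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} windows with coverage "
                      f"below {min_coverage:.0%}")
    if not keep.any():
        raise AnalysisError("no window has sufficient trial coverage")
    return centers[keep], A[keep]


def distance_series(rt: RateTensor, trials: pd.DataFrame,
                    window_ms: float = 300.0, step_ms: float = 100.0,
                    span_ms=None) -> pd.DataFrame:
    """Euclidean distance between the two trial types' mean states over time."""
    centers, A = _window_means(rt, trials, window_ms, step_ms, span_ms)
    is_d = (trials["trial_type"].to_numpy() == "described")
    if is_d.all() or not is_d.any():
        raise AnalysisError("both trial types required")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu_d = np.nanmean(A[:, is_d, :], axis=1)
        mu_e = np.nanmean(A[:, ~is_d, :], axis=1)
    dist = np.linalg.norm(mu_d - mu_e, axis=1)
    return pd.DataFrame({"center_ms": centers, "distance": dist})


def distance_band(rt: RateTensor, trials: pd.DataFrame, n_iter: int = 1000,
                  seed=None, window_ms: float = 300.0, step_ms: float = 100.0,
                  span_ms=None) -> pd.DataFrame:
    """Label-shuffle null band for the trial-type distance series.

    Each iteration permutes the described/experienced labels across trials
    and recomputes the distance series. Columns: center_ms, distance,
    null_mean, lo (2.5%), hi (97.5%), p ( (1 + #{null >= observed}) /
    (1 + n_iter), pointwise ).
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives a coarse null band")
    rng = np.random.default_rng(seed)
    centers, A = _window_means(rt, trials, window_ms, step_ms, span_ms)
    labels = (trials["trial_type"].to_numpy() == "described")
    if labels.all() or not labels.any():
        raise AnalysisError("both trial types required")
    n_t = len(labels)
    n_d = int(labels.sum())
    n_w, _, n_n = A.shape
    # NaN-aware group means via 0-filled values plus per-window valid counts
    # (validity is shared across neurons within a trial)
    M = (~np.isnan(A[:, :, 0])).astype(np.float64)  # (windows, trials)
    V = np.nan_to_num(A, nan=0.0).transpose(1, 0, 2).reshape(n_t, -1)

    def series(d_mask: np.ndarray) -> np.ndarray:
        d = d_mask.astype(np.float64)
        e = 1.0 - d
        cnt_d = M @ d
        cnt_e = M @ e
        if (cnt_d == 0).any() or (cnt_e == 0).any():
            raise AnalysisError("a window lost all trials of one type")
        mu_d = (d @ V).reshape(n_w, n_n) / cnt_d[:, None]
        mu_e = (e @ V).reshape(n_w, n_n) / cnt_e[:, None]
        return np.linalg.norm(mu_d - mu_e, axis=1)

    obs = series(labels)
    null = np.empty((n_iter, n_w))
    for i in range(n_iter):
        perm = rng.permutation(n_t)
        d_mask = np.zeros(n_t, dtype=bool)
        d_mask[perm[:n_d]] = True
        null[i] = series(d_mask)
    p = (1 + (null >= obs[None, :]).sum(axis=0)) / (1 + n_iter)
    return pd.DataFrame({
        "center_ms": centers,
        "distance": obs,
        "null_mean": null.mean(axis=0),
        "lo": np.quantile(null, 0.025, axis=0),
        "hi": np.quantile(null, 0.975, axis=0),
        "p": p,
    })
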