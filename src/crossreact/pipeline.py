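"""End-to-end analyses composed from the lower-level modules.

These are the session-level entry points the CLI and the reproduction
script drive: the four-pair coefficient-overlap analysis, the decoder
transfer matrix, and the trajectory/distance analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig, default_windows, EpochWindow
from .encoding import (RateTensor, bin_and_zscore, epoch_mean, fit_tuning,
                       sliding_tuning, find_peak_window, census, select_trials,
                       CoefficientSet)
from .decoding import build_states, cross_decode, transfer_decode, \
    DecodeResult, chance_band, _make_decoder
from .overlap import (RegressionSpec, coeff_correlation, permutation_null,
                      OverlapResult, PermutationResult)
from .state_space import epoch_state_matrix, pca_trajectories, distance_series, \
    distance_band

__all__ = ["fit_epoch_coefficients", "overlap_analysis", "decode_matrix",
           "trajectory_analysis", "OverlapReport", "refine_outcome_window"]

PAIRS = (  # (label, key_a, key_b): the four comparisons of the overlap analysis
    ("OFR.D-OTC.D", ("offer1", "described"), ("outcome", "described")),
    ("OFR.E-OTC.E", ("offer1", "experienced"), ("outcome", "experienced")),
    ("OTC.D-OTC.E", ("outcome", "described"), ("outcome", "experienced")),
    ("OFR.D-OFR.E", ("offer1", "described"), ("offer1", "experienced")),
)


def refine_outcome_window(rt: RateTensor, trials: pd.DataFrame,
                          min_trials: int = 10) -> EpochWindow:
    """Place the 400 ms outcome window on the peak of outcome-size encoding.

    Peak encoding is the sliding-window population mean |t| of the
    outcome-size regression on offer-1-chosen trials (both types pooled).
    """
    sub = select_trials(trials, None, "offer1-chosen")
    sl = sliding_tuning(rt, sub, "chosen_size", "outcome_on", (0.0, 750.0),
                        window_ms=300.0, step_ms=50.0, min_trials=min_trials)
    return find_peak_window(sl["center_ms"].to_numpy(),
                            sl["mean_abs_t"].to_numpy(), (0.0, 750.0), 400.0,
                            "outcome_on", name="outcome")


def fit_epoch_coefficients(rt: RateTensor, trials: pd.DataFrame,
                           windows=None, min_trials: int = 10,
                           include_choice: bool = False,
                           refine_outcome: bool = True
                           ) -> dict[tuple[str, str], CoefficientSet]:
    """The four coefficient sets of the overlap analysis.

    Offer-epoch slopes regress offer-1-epoch rates on offer-1 size; outcome
    slopes regress outcome-epoch rates on the delivered reward, restricted
    to offer-1-chosen trials (so the reward equals the offer-1 size) unless
    ``include_choice`` requests the all-trials size+choice variant.
    """
    if windows is None:
        windows = default_windows()
        if refine_outcome:
            windows = dict(windows)
            windows["outcome"] = refine_outcome_window(rt, trials, min_trials)
    out = {}
    for tt in ("described", "experienced"):
        sub = select_trials(trials, tt, "all")
        em = epoch_mean(rt, sub, windows["offer1"], sub["trial_id"])
        out[("offer1", tt)] = fit_tuning(
            em, sub, "offer1_size", min_trials=min_trials, epoch="offer1",
            trial_type=tt, selection="all", neuron_ids=rt.neuron_ids)
        sel = "all" if include_choice else "offer1-chosen"
        subo = select_trials(trials, tt, sel)
        emo = epoch_mean(rt, subo, windows["outcome"], subo["trial_id"])
        out[("outcome", tt)] = fit_tuning(
            emo, subo, "chosen_size", include_choice=include_choice,
            min_trials=min_trials, epoch="outcome", trial_type=tt,
            selection=sel, neuron_ids=rt.neuron_ids)
    return out


@dataclass
class OverlapReport:
    results: dict[str, OverlapResult]
    permutations: dict[str, PermutationResult]
    coefficients: dict[tuple[str, str], CoefficientSet]

    def to_dict(self) -> dict:
        return {"results": {k: v.to_dict() for k, v in self.results.items()},
                "permutations": {k: v.to_dict() for k, v in self.permutations.items()}}


def _spec_for(rt, trials, key, windows, include_choice, min_trials) -> RegressionSpec:
    epoch, tt = key
    if epoch == "offer1":
        sub = select_trials(trials, tt, "all")
        em = epoch_mean(rt, sub, windows["offer1"], sub["trial_id"])
        return RegressionSpec(em, sub["offer1_size"].to_numpy(dtype=float),
                              label=f"{epoch}/{tt}")
    sel = "all" if include_choice else "offer1-chosen"
    sub = select_trials(trials, tt, sel)
    em = epoch_mean(rt, sub, windows["outcome"], sub["trial_id"])
    preds = [sub["chosen_size"].to_numpy(dtype=float)]
    if include_choice:
        preds.append((sub["chosen_option"].to_numpy() == 1).astype(float))
    return RegressionSpec(em, np.column_stack(preds), label=f"{epoch}/{tt}")


def overlap_analysis(rt: RateTensor, trials: pd.DataFrame, cfg: RunConfig,
                     include_choice: bool = False, windows=None,
                     refine_outcome: bool = True) -> OverlapReport:
    """Four-pair signed/unsigned overlap with predictor-shuffle nulls."""
    if windows is None:
        windows = default_windows()
        if refine_outcome:
            windows = dict(windows)
            windows["outcome"] = refine_outcome_window(rt, trials, cfg.min_trials)
    coeffs = fit_epoch_coefficients(rt, trials, windows=windows,
                                    min_trials=cfg.min_trials,
                                    include_choice=include_choice)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x0EE1]))
    results, perms = {}, {}
    for label, ka, kb in PAIRS:
        res = coeff_correlation(coeffs[ka].slope, coeffs[kb].slope, pair=label)
        spec_a = _spec_for(rt, trials, ka, windows, include_choice, cfg.min_trials)
        spec_b = _spec_for(rt, trials, kb, windows, include_choice, cfg.min_trials)
        perm = permutation_null(spec_a, spec_b, n_iter=cfg.n_permutations,
                                seed=rng.integers(2**31), mode="signed",
                                observed=res.signed_r)
        results[label] = res
        perms[label] = perm
    return OverlapReport(results, perms, coeffs)


TRANSFERS = (  # (train_key, test_key) over (epoch, type)
    (("outcome", "described"), ("offer1", "described")),
    (("offer1", "described"), ("outcome", "described")),
    (("outcome", "experienced"), ("offer1", "experienced")),
    (("offer1", "experienced"), ("outcome", "experienced")),
    (("outcome", "described"), ("outcome", "experienced")),
    (("outcome", "experienced"), ("outcome", "described")),
    (("offer1", "described"), ("offer1", "experienced")),
    (("offer1", "experienced"), ("offer1", "described")),
)


def decode_matrix(rt: RateTensor, trials: pd.DataFrame, cfg: RunConfig,
                  decoder: str = "mlp", windows=None,
                  transfers=TRANSFERS, within: bool = False,
                  refine_outcome: bool = True):
    """States for the four conditions plus the transfer-decoding results.

    Returns (results, states) where results maps "train->test" labels to
    DecodeResult. ``within=True`` additionally runs the four-fold
    within-condition decodes that verify trainability.
    """
    if windows is None:
        windows = default_windows()
        if refine_outcome:
            windows = dict(windows)
            windows["outcome"] = refine_outcome_window(rt, trials, cfg.min_trials)
    ss = np.random.SeedSequence([cfg.seed, 0xDEC0])
    seeds = iter(np.random.default_rng(ss).integers(2**31, size=64))
    states = {}
    for tt in ("described", "experienced"):
        states[("offer1", tt)] = build_states(
            rt, trials, windows["offer1"], tt, n_states=cfg.n_states,
            seed=next(seeds), selection="all")
        states[("outcome", tt)] = build_states(
            rt, trials, windows["outcome"], tt, n_states=cfg.n_states,
            seed=next(seeds), selection="offer1-chosen")
    mlp_kwargs = {}
    if decoder == "mlp":
        mlp_kwargs = {"n_hidden": cfg.mlp.n_hidden,
                      "learning_rate": cfg.mlp.learning_rate,
                      "n_epochs": cfg.mlp.n_epochs,
                      "init_scale": cfg.mlp.init_scale}
    results: dict[str, DecodeResult] = {}
    if within:
        for key in states:
            res = cross_decode(states[key], None, folds=cfg.folds,
                               seed=next(seeds), decoder=decoder, **mlp_kwargs)
            results[f"{key[0]}/{key[1]}(within)"] = res
    # one fitted decoder per training condition, reused across its transfers
    models = {}
    for ka in dict.fromkeys(ka for ka, _ in transfers):  # ordered unique
        models[ka] = _make_decoder(decoder, next(seeds), **mlp_kwargs).fit(
            states[ka].X, states[ka].y)
    for ka, kb in transfers:
        results[f"{ka[0]}/{ka[1]}->{kb[0]}/{kb[1]}"] = transfer_decode(
            models[ka], states[ka], states[kb], decoder=decoder)
    return results, states


def trajectory_analysis(rt: RateTensor, trials: pd.DataFrame, cfg: RunConfig,
                        window_ms: float = 300.0, step_ms: float = 100.0):
    """PCA trajectory plus sliding distance with its label-shuffle band."""
    M, labels = epoch_state_matrix(rt, trials)
    traj = pca_trajectories(M, labels)
    band_seed = int(np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0xD157])).integers(2**31))
    traj.distance = distance_band(rt, trials, n_iter=cfg.n_permutations,
                                  seed=band_seed, window_ms=window_ms,
                                  step_ms=step_ms)
    return traj
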