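"""On-disk session artifacts: trial/spike tables (CSV) and result JSON.

Tables are comma-delimited with a one-line header; spike times are stored
per trial relative to the offer-1 cue. Result documents are JSON with a
schema version, the seed, and a configuration echo, so any reported
statistic can be traced to its run.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EVENT_NAMES
from .errors import FormatError, ReferentialError, ValidationError

__all__ = ["read_session", "write_session", "write_results", "read_results",
           "validate_trials", "validate_spikes"]

SCHEMA_VERSION = 1

TRIAL_COLUMNS = ("trial_id", "trial_type", "offer1_size", "offer2_size",
                 "offer1_side", "chosen_option", "chosen_size", "correct") + EVENT_NAMES
SPIKE_COLUMNS = ("neuron_id", "trial_id", "spike_time_ms")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing columns {missing}")
    if trials["trial_id"].duplicated().any():
        raise ValidationError("duplicate trial_id")
    chosen_ok = ((trials["chosen_size"] == trials["offer1_size"])
                 | (trials["chosen_size"] == trials["offer2_size"]))
    if not chosen_ok.all():
        bad = trials.loc[~chosen_ok, "trial_id"].tolist()[:5]
        raise ValidationError(f"chosen_size not among offers for trials {bad}")
    ev = trials[list(EVENT_NAMES)].to_numpy(dtype=float)
    if not (np.diff(ev, axis=1) > 0).all():
        bad = trials["trial_id"].to_numpy()[(np.diff(ev, axis=1) <= 0).any(axis=1)]
        raise ValidationError(f"non-monotone event times in trials {bad[:5].tolist()}")
    unchosen = np.where(trials["chosen_option"] == 1,
                        trials["offer2_size"], trials["offer1_size"])
    expect = trials["chosen_size"].to_numpy() >= unchosen
    if not (trials["correct"].to_numpy(dtype=bool) == expect).all():
        raise ValidationError("correct flag inconsistent with chosen/unchosen sizes")
    return trials


def validate_spikes(spikes: pd.DataFrame, trials: pd.DataFrame,
                    min_trials: int | None = None) -> pd.DataFrame:
    missing = [c for c in SPIKE_COLUMNS if c not in spikes.columns]
    if missing:
        raise FormatError(f"spike table missing columns {missing}")
    known = set(trials["trial_id"].tolist())
    orphan = ~spikes["trial_id"].isin(known)
    if orphan.any():
        bad = sorted(set(spikes.loc[orphan, "trial_id"].tolist()))[:5]
        raise ReferentialError(f"spike rows reference unknown trial_ids {bad}")
    ids = np.unique(spikes["neuron_id"].to_numpy())
    if not np.array_equal(ids, np.arange(len(ids))):
        raise ValidationError("neuron_ids must form a dense 0..N-1 set")
    if min_trials is not None:
        per_neuron = spikes.groupby("neuron_id")["trial_id"].nunique()
        low = per_neuron[per_neuron < min_trials]
        if len(low):
            raise ValidationError(
                f"neurons below the {min_trials}-trial minimum: "
                f"{low.index.tolist()[:5]}")
    return spikes


def read_session(trials_path, spikes_path, min_trials: int | None = None):
    """Read and validate (trials, spikes) CSV tables."""
    try:
        trials = pd.read_csv(trials_path)
        spikes = pd.read_csv(spikes_path)
    except (OSError, pd.errors.ParserError) as e:
        raise FormatError(f"cannot parse session tables: {e}") from e
    validate_trials(trials)
    validate_spikes(spikes, trials, min_trials=min_trials)
    return trials, spikes


def write_session(trials: pd.DataFrame, spikes: pd.DataFrame, out_dir,
                  ground_truth: pd.DataFrame | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    spikes.to_csv(out / "spikes.csv", index=False)
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if hasattr(o, "to_dict"):
            return o.to_dict()
        return super().default(o)


def write_results(result: dict, path, seed=None, config=None) -> None:
    """Serialize a result document with schema version, seed, config echo."""
    doc = {"schema_version": SCHEMA_VERSION, "seed": seed,
           "config": config.to_dict() if hasattr(config, "to_dict") else config,
           "results": result}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, cls=_Encoder)
        fh.write("\n")


def read_results(path) -> dict:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema version {doc.get('schema_version')}")
    return doc
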