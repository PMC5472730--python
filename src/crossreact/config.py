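"""Task design and run configuration.

The task is a two-option riskless choice: offer 1 is revealed either by a
learned color symbol ("described" trials) or by direct delivery of a water
aliquot ("experienced" trials); offer 2 is always symbolic. The two reveal
modes define two associative structures predicting the same rewards.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

from .errors import ConfigError

TRIAL_TYPES = ("described", "experienced")

#: Ordered trial events on the per-trial clock (offer1_cue_on = 0 ms).
EVENT_NAMES = (
    "fixation_on",
    "offer1_cue_on",
    "offer1_value_on",
    "offer2_on",
    "reappear_on",
    "choice_made",
    "outcome_on",
    "trial_end",
)


@dataclass(frozen=True)
class EpochWindow:
    """Half-open analysis window [start_ms, end_ms) relative to an alignment event."""

    name: str
    align_event: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ConfigError(f"window {self.name!r}: end must exceed start")
        if self.align_event not in EVENT_NAMES:
            raise ConfigError(f"window {self.name!r}: unknown event {self.align_event!r}")

    @property
    def width_ms(self) -> float:
        return self.end_ms - self.start_ms


def default_windows() -> dict[str, EpochWindow]:
    """Per-event analysis windows.

    The offer-1 value window is the 300 ms starting 200 ms after the value
    reveal. The outcome window is 400 ms wide and is meant to be re-centered
    on the detected encoding peak (see encoding.find_peak_window); its default
    sits mid-epoch. The offer-2 window is 300 ms, likewise peak-centered in
    real use. Because the choice period's duration varies trial by trial, the
    choice window is the 1000 ms ending at reward delivery (the 700 ms before
    the choice commits plus the 300 ms chosen-option feedback).
    """
    return {
        "offer1_cue": EpochWindow("offer1_cue", "offer1_cue_on", 0, 300),
        "offer1": EpochWindow("offer1", "offer1_value_on", 200, 500),
        "offer2": EpochWindow("offer2", "offer2_on", 100, 400),
        "choice": EpochWindow("choice", "choice_made", -700, 300),
        "outcome": EpochWindow("outcome", "outcome_on", 175, 575),
    }


def trajectory_windows() -> dict[str, EpochWindow]:
    """Five equal 300 ms epochs used for the state-space trajectory analysis."""
    return {
        "offer1_cue": EpochWindow("offer1_cue", "offer1_cue_on", 0, 300),
        "offer1": EpochWindow("offer1", "offer1_value_on", 200, 500),
        "offer2": EpochWindow("offer2", "offer2_on", 100, 400),
        "choice": EpochWindow("choice", "choice_made", -300, 0),
        "outcome": EpochWindow("outcome", "outcome_on", 225, 525),
    }


@dataclass(frozen=True)
class TaskConfig:
    """Offer sets and trial-phase durations of the choice task.

    Durations (ms): 500 cue, 750 offer-1 reveal, 500 offer 2, 200 re-fixation,
    variable choice period, 300 chosen-option feedback, 750 outcome, 1000 ITI.
    """

    offer1_sizes: tuple[float, ...] = (75.0, 100.0, 150.0, 200.0, 250.0)
    offer2_sizes: tuple[float, ...] = (150.0, 175.0, 200.0)
    trial_types: tuple[str, ...] = TRIAL_TYPES
    cue_ms: float = 500.0
    offer1_ms: float = 750.0
    offer2_ms: float = 500.0
    refixation_ms: float = 200.0
    feedback_ms: float = 300.0
    outcome_ms: float = 750.0
    iti_ms: float = 1000.0
    fixation_ms: float = 200.0
    color_map: Mapping[float, str] = field(
        default_factory=lambda: {75.0: "red", 100.0: "yellow", 150.0: "blue",
                                 200.0: "green", 250.0: "cyan"}
    )

    def __post_init__(self) -> None:
        if not self.offer1_sizes or not self.offer2_sizes:
            raise ConfigError("offer size sets must be nonempty")
        if any(s <= 0 for s in self.offer1_sizes + self.offer2_sizes):
            raise ConfigError("offer sizes must be positive")
        for d in (self.cue_ms, self.offer1_ms, self.offer2_ms, self.refixation_ms,
                  self.feedback_ms, self.outcome_ms, self.iti_ms, self.fixation_ms):
            if d <= 0:
                raise ConfigError("all epoch durations must be positive")


@dataclass(frozen=True)
class MLPParams:
    """Hyperparameters of the bespoke softmax decoder (125-40-5 by default)."""

    n_hidden: int = 40
    learning_rate: float = 0.005
    n_epochs: int = 1000
    init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.n_epochs < 1:
            raise ConfigError("decoder sizes/epochs must be positive")
        if self.learning_rate <= 0 or self.init_scale <= 0:
            raise ConfigError("learning rate and init scale must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide knobs; one root seed feeds every stochastic stage."""

    seed: int = 0
    n_permutations: int = 1000
    alpha: float = 0.05
    bin_ms: float = 10.0
    boxcar_ms: float = 200.0
    n_states: int = 500
    folds: int = 4
    min_trials: int = 10
    mlp: MLPParams = field(default_factory=MLPParams)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        for v in (self.n_permutations, self.n_states, self.folds, self.min_trials):
            if v < 1:
                raise ConfigError("counts must be positive")
        if self.bin_ms <= 0 or self.boxcar_ms <= 0:
            raise ConfigError("bin and boxcar widths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        mlp = d.pop("mlp", {})
        return cls(mlp=MLPParams(**mlp), **d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
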