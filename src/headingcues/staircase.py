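"""Adaptive 1-up-1-down staircases with variable step size.

Each trial block of the experiment runs four independent staircases,
randomly interleaved: one starting from each heading extreme (+/-50 deg)
for each of the two gaze directions (25 deg left / right).  Every staircase
is a 1-up-1-down track: a "right" response moves the next heading leftward
by the current step and vice versa, so the track converges on the point of
subjective equality (the 50% point of the psychometric function).

Step-size rules, starting from 8 deg:

* a response in the opposite direction from the previous one (a reversal)
  halves the step, down to a floor of 0.5 deg;
* three consecutive responses in the same direction double the step, up to
  a cap of 8 deg.  By default the run counter resets after a doubling so a
  long run doubles at most every third trial (``double_rule="reset"``);
  ``double_rule="raw"`` keeps counting and doubles on every further trial
  of the run.

Step adjustments take effect before the heading move they precede.  The
heading is clamped to +/-50 deg; tracks may cross zero, so either track can
deliver stimuli in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import StaircaseExhaustedError

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "TrialRecord",
    "TRIAL_COLUMNS",
    "init_staircase",
    "update_staircase",
    "run_block",
    "records_to_dataframe",
    "records_to_csv",
]

#: Fixed column order of trial-log CSVs.
TRIAL_COLUMNS = [
    "subject_id",
    "block_id",
    "modality",
    "vibration_amplitude",
    "coherence",
    "gaze",
    "staircase_id",
    "trial_index",
    "heading",
    "response",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive track (degrees unless noted)."""

    start_heading: float
    gaze: str = "right"
    initial_step: float = 8.0
    min_step: float = 0.5
    max_step: float = 8.0
    n_trials: int = 20
    heading_limit: float = 50.0
    double_rule: str = "reset"  # "reset" or "raw" run counting

    def __post_init__(self) -> None:
        if not (0 < self.min_step <= self.initial_step <= self.max_step):
            raise ValueError(
                f"require 0 < min_step <= initial_step <= max_step, got "
                f"{self.min_step}, {self.initial_step}, {self.max_step}"
            )
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if abs(self.start_heading) > self.heading_limit:
            raise ValueError(
                f"|start_heading| = {abs(self.start_heading)} exceeds "
                f"heading_limit = {self.heading_limit}"
            )
        if self.gaze not in ("left", "right"):
            raise ValueError(f"gaze must be 'left' or 'right', got {self.gaze!r}")
        if self.double_rule not in ("reset", "raw"):
            raise ValueError(f"double_rule must be 'reset' or 'raw', got {self.double_rule!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation and its binary response."""

    subject_id: str
    block_id: str
    modality: str
    vibration_amplitude: float
    coherence: float
    gaze: str
    staircase_id: str
    trial_index: int
    heading: float
    response: str

    def __post_init__(self) -> None:
        if self.response not in ("left", "right"):
            raise ValueError(f"response must be 'left' or 'right', got {self.response!r}")


@dataclass(frozen=True)
class StaircaseState:
    """Immutable state of one track; ``update_staircase`` returns a new state."""

    config: StaircaseConfig
    next_heading: float
    step: float
    last_response: Optional[str] = None
    consecutive_same: int = 0
    trial_index: int = 0
    history: tuple = field(default_factory=tuple)

    @property
    def finished(self) -> bool:
        return self.trial_index >= self.config.n_trials


def init_staircase(config: StaircaseConfig) -> StaircaseState:
    """Fresh track poised at its start heading with the initial step size."""
    return StaircaseState(config=config, next_heading=config.start_heading,
                          step=config.initial_step)


def update_staircase(state: StaircaseState, response: str) -> StaircaseState:
    """Advance one track by one response.

    The step-size rule fires first (halve on a reversal, double after three
    consecutive same-direction responses), then the new step moves the
    heading against the response, clamped to the heading limit.
    """
    if response not in ("left", "right"):
        raise ValueError(f"response must be 'left' or 'right', got {response!r}")
    cfg = state.config
    if state.finished:
        raise StaircaseExhaustedError(
            f"staircase already has {state.trial_index} of {cfg.n_trials} trials"
        )

    step = state.step
    if state.last_response is None:
        run = 1
    elif response != state.last_response:
        step = max(step / 2.0, cfg.min_step)
        run = 1
    else:
        run = state.consecutive_same + 1
        if run >= 3:
            step = min(step * 2.0, cfg.max_step)
            if cfg.double_rule == "reset":
                run = 0

    move = -step if response == "right" else step
    heading = float(np.clip(state.next_heading + move, -cfg.heading_limit, cfg.heading_limit))
    return replace(
        state,
        next_heading=heading,
        step=step,
        last_response=response,
        consecutive_same=run,
        trial_index=state.trial_index + 1,
        history=state.history + (response,),
    )


def _block_staircases(staircase: StaircaseConfig | None) -> dict:
    """The four canonical tracks of a block: gaze {left,right} x start {+50,-50}."""
    base = staircase or StaircaseConfig(start_heading=50.0)
    tracks = {}
    for gaze in ("left", "right"):
        for sign, tag in ((+1.0, "up"), (-1.0, "down")):
            cfg = replace(base, start_heading=sign * base.heading_limit, gaze=gaze)
            tracks[f"{gaze}_{tag}"] = init_staircase(cfg)
    return tracks


def run_block(
    observer,
    condition,
    seed,
    staircase: StaircaseConfig | None = None,
    subject_id: str = "s1",
    block_id: str = "block",
) -> list:
    """Simulate one trial block: 4 interleaved staircases of 20 trials each.

    ``observer`` supplies responses through :func:`headingcues.observer.respond`;
    ``condition`` is a :class:`headingcues.observer.ConditionSpec` whose gaze
    field is overridden per staircase.  The interleaving draws the next track
    uniformly at random among unfinished tracks, so each track's trajectory is
    independent of the interleaving order.  Deterministic under ``seed``.
    """
    from . import observer as obs_mod

    rng = np.random.default_rng(seed)
    tracks = _block_staircases(staircase)
    order = list(tracks)
    records: list[TrialRecord] = []
    while True:
        open_tracks = [k for k in order if not tracks[k].finished]
        if not open_tracks:
            break
        key = open_tracks[rng.integers(len(open_tracks))]
        state = tracks[key]
        cond = replace(condition, gaze=state.config.gaze)
        heading = state.next_heading
        response = obs_mod.respond(observer, cond, heading, rng)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                block_id=block_id,
                modality=condition.modality,
                vibration_amplitude=condition.vibration_amplitude,
                coherence=condition.coherence,
                gaze=state.config.gaze,
                staircase_id=key,
                trial_index=state.trial_index,
                heading=heading,
                response=response,
            )
        )
        tracks[key] = update_staircase(state, response)
    return records


def records_to_dataframe(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial records as a DataFrame with the fixed column order."""
    return pd.DataFrame([vars(r) for r in records], columns=TRIAL_COLUMNS)


def records_to_csv(records: Sequence[TrialRecord], path_or_buf) -> None:
    records_to_dataframe(records).to_csv(path_or_buf, index=False)
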