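"""Synthetic behavioral sessions.

Sessions are generated by the foraging agent on task geometry and timing
matching the experiment: 500–1000 ms fixation, a 6-s search limit, 200-ms
reward delay, 800-ms intertrial interval.  A trial is censored when its
cumulative simulated search time exceeds the limit or when the 25-saccade
cap is reached.  Pharmacological sessions are emulated through a
:class:`DrugProfile` that scales the agent's parameters (and, for eye
traces, saccade kinematics) with a rapid onset and a gradual exponential
recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional

import numpy as np

from .model import (
    MAX_SACCADES,
    ModelParams,
    N_OBJECTS,
    choose_next,
    update_memory,
)
from .session_io import Session, TrialRecord
from .stimuli import StimulusArray, generate_stimulus_array

__all__ = ["SessionTiming", "DrugProfile", "KinematicState", "generate_session"]


@dataclass(frozen=True)
class SessionTiming:
    """Trial timing in milliseconds.

    ``mean_isi_ms`` is the mean intersaccadic (fixation) interval during
    search; each saccade's time cost is that interval (gamma-distributed,
    shape 4) plus a nominal saccade duration.
    """

    fixation_min_ms: float = 500.0
    fixation_max_ms: float = 1000.0
    search_limit_ms: float = 6000.0
    reward_delay_ms: float = 200.0
    intertrial_ms: float = 800.0
    mean_isi_ms: float = 220.0
    saccade_duration_ms: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "fixation_min_ms",
            "fixation_max_ms",
            "search_limit_ms",
            "reward_delay_ms",
            "intertrial_ms",
            "mean_isi_ms",
            "saccade_duration_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fixation_max_ms < self.fixation_min_ms:
            raise ValueError("fixation_max_ms < fixation_min_ms")


@dataclass(frozen=True)
class KinematicState:
    """Saccade-kinematic modifiers in effect at one time point."""

    peak_velocity_scale: float = 1.0
    drift_magnitude_deg: float = 0.0
    isi_scale: float = 1.0


@dataclass(frozen=True)
class DrugProfile:
    """Phenomenological time course of an injected drug's effect.

    The effect level rises linearly from injection to its maximum at
    ``onset_minutes`` and afterwards decays exponentially with
    ``recovery_halflife_minutes``.  At full effect each model parameter is
    multiplied by its scale factor (capacity and decay are rounded and
    clipped back to their valid integer ranges; utility is clipped to
    [0, 1]).  Kinematic effects (peak-velocity suppression, postsaccadic
    drift, ISI inflation) follow the same time course.
    """

    capacity_scale: float = 1.0
    decay_scale: float = 1.0
    utility_scale: float = 1.0
    onset_minutes: float = 15.0
    recovery_halflife_minutes: float = 30.0
    peak_velocity_scale: float = 1.0
    drift_magnitude_deg: float = 0.0
    isi_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("capacity_scale", "decay_scale", "utility_scale",
                     "peak_velocity_scale", "isi_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.onset_minutes <= 0 or self.recovery_halflife_minutes <= 0:
            raise ValueError("onset and recovery times must be positive")
        if self.drift_magnitude_deg < 0:
            raise ValueError("drift_magnitude_deg must be non-negative")

    def effect(self, t_minutes: float) -> float:
        """Effect level in [0, 1] at ``t_minutes`` after injection."""
        if t_minutes < 0:
            return 0.0
        if t_minutes <= self.onset_minutes:
            return t_minutes / self.onset_minutes
        return math.exp(
            -math.log(2.0)
            * (t_minutes - self.onset_minutes)
            / self.recovery_halflife_minutes
        )

    def params_at(self, baseline: ModelParams, t_minutes: float) -> ModelParams:
        e = self.effect(t_minutes)
        cap = baseline.capacity * (1.0 + (self.capacity_scale - 1.0) * e)
        cap_i = int(min(15, max(1, round(cap))))
        dec = baseline.decay * (1.0 + (self.decay_scale - 1.0) * e)
        dec_i = int(min(cap_i, max(1, round(dec))))
        util = baseline.utility * (1.0 + (self.utility_scale - 1.0) * e)
        return ModelParams(cap_i, dec_i, float(min(1.0, max(0.0, util))))

    def kinematics_at(self, t_minutes: float) -> KinematicState:
        e = self.effect(t_minutes)
        return KinematicState(
            peak_velocity_scale=1.0 + (self.peak_velocity_scale - 1.0) * e,
            drift_magnitude_deg=self.drift_magnitude_deg * e,
            isi_scale=1.0 + (self.isi_scale - 1.0) * e,
        )


def _saccade_cost_ms(timing: SessionTiming, isi_scale: float,
                     rng: np.random.Generator) -> float:
    isi = rng.gamma(4.0, timing.mean_isi_ms * isi_scale / 4.0)
    return isi + timing.saccade_duration_ms


def generate_session(
    params: ModelParams,
    n_trials: int,
    timing: Optional[SessionTiming] = None,
    drug: Optional[DrugProfile] = None,
    rng: Optional[np.random.Generator] = None,
    subject: str = "synthetic",
    condition: str = "none",
    injection_trial: int = 0,
    max_saccades: int = MAX_SACCADES,
) -> Session:
    """Simulate a full behavioral session.

    If ``drug`` is given, the injection timestamp is the start of trial
    ``injection_trial`` (defaulting to session start) and the agent's
    parameters for each trial are the drug-modulated values at that trial's
    start time.  Per-trial wall-clock timestamps accumulate fixation,
    per-saccade intervals, reward delay and the intertrial interval, and
    searching is censored beyond the 6-s limit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if timing is None:
        timing = SessionTiming()
    if rng is None:
        rng = np.random.default_rng()
    if drug is not None and not (0 <= injection_trial <= n_trials):
        raise ValueError("injection_trial out of range")

    t_ms = 0.0
    injection_time: Optional[float] = None
    trials: List[TrialRecord] = []
    for i in range(n_trials):
        if drug is not None and i == injection_trial:
            injection_time = t_ms
        t_start = t_ms
        if drug is not None and injection_time is not None:
            minutes = (t_start - injection_time) / 60000.0
            trial_params = drug.params_at(params, minutes)
            isi_scale = drug.kinematics_at(minutes).isi_scale
        else:
            trial_params = params
            isi_scale = 1.0

        t_ms += rng.uniform(timing.fixation_min_ms, timing.fixation_max_ms)
        array = generate_stimulus_array(rng)
        target = array.target_index

        memory: List[int] = []
        current: Optional[int] = None
        choices: List[int] = []
        times: List[float] = []
        search_ms = 0.0
        found = False
        censored = False
        for _ in range(max_saccades):
            cost = _saccade_cost_ms(timing, isi_scale, rng)
            # at least one saccade always occurs; censoring applies afterwards
            if choices and search_ms + cost > timing.search_limit_ms:
                censored = True
                break
            search_ms = min(search_ms + cost, timing.search_limit_ms)
            c = choose_next(current, memory, trial_params, N_OBJECTS, rng)
            choices.append(c)
            times.append(t_ms + search_ms)
            if c == target:
                found = True
                break
            memory = update_memory(memory, c, trial_params, rng)
            current = c
        else:
            censored = True
        t_ms += search_ms if found else timing.search_limit_ms
        if found:
            t_ms += timing.reward_delay_ms
        t_ms += timing.intertrial_ms

        trials.append(
            TrialRecord(
                trial_id=i,
                array=array,
                choices=tuple(choices),
                found=found,
                censored=not found,
                t_start_ms=t_start,
                saccade_times_ms=tuple(times),
            )
        )
    return Session(
        subject=subject,
        condition=condition,
        trials=trials,
        injection_time_ms=injection_time,
    )
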