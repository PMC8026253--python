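"""The three 25-bin behavioral distributions used as the fitting target.

For a set of trials we compute

1. *revisit by position* — proportion of choices at saccade ordinal k
   (k = 1..25) that return to an already-inspected object, conditioned by
   default on trials that survive to ordinal k;
2. *revisit by distance* — histogram of index lags between a revisit and the
   most recent prior inspection of the same object (an A-B-A pattern has
   lag 2; lag 1 is impossible because the current object is never a
   candidate);
3. *saccade count* — histogram of per-trial choice counts.

Each vector is normalized to sum to one; a component with no mass (e.g. no
revisits under perfect memory) stays all-zero and is flagged.  The three
vectors concatenated in the order position ‖ distance ‖ count form the
75-bin vector consumed by model fitting.

Lags and counts beyond bin 25 are clipped into the last bin so that no
normalization mass is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Literal, Optional, Sequence

import numpy as np

from .model import TrialOutcome

__all__ = [
    "SummaryTriplet",
    "revisit_flags",
    "revisit_distances",
    "summarize",
    "TrialFeatures",
    "trial_features",
    "summarize_from_features",
]

N_BINS = 25


def revisit_flags(choices: Sequence[int]) -> List[bool]:
    """Flag each choice that returns to an object inspected earlier."""
    seen: set[int] = set()
    flags: List[bool] = []
    for c in choices:
        flags.append(c in seen)
        seen.add(c)
    return flags


def revisit_distances(choices: Sequence[int]) -> List[int]:
    """Index lag of each revisit from the most recent prior visit.

    The minimum possible lag is 2 (immediate self-return is excluded by the
    task: the currently fixated object is never a candidate).
    """
    last: dict[int, int] = {}
    lags: List[int] = []
    for i, c in enumerate(choices):
        if c in last:
            lags.append(i - last[c])
        last[c] = i
    return lags


@dataclass(frozen=True)
class SummaryTriplet:
    """Normalized 25-bin triplet plus raw counts and zero-component flags."""

    revisit_by_position: np.ndarray
    revisit_by_distance: np.ndarray
    saccade_count_dist: np.ndarray
    n_trials: int
    raw_position: np.ndarray
    raw_distance: np.ndarray
    raw_count: np.ndarray
    zero_flags: tuple[bool, bool, bool]

    def concat(self) -> np.ndarray:
        """The 75-bin vector (position ‖ distance ‖ count) used for fitting."""
        return np.concatenate(
            [self.revisit_by_position, self.revisit_by_distance, self.saccade_count_dist]
        )


@dataclass(frozen=True)
class TrialFeatures:
    """Per-trial summary contributions, reusable under trial reweighting.

    Storing one row per trial lets a bootstrap resample be summarized as a
    weighted column sum instead of a rescan of the choice sequences.
    """

    revisit_at: np.ndarray  # (n, 25) 0/1: revisit at ordinal k
    alive_at: np.ndarray    # (n, 25) 0/1: trial has >= k saccades
    lag_hist: np.ndarray    # (n, 25) revisit-lag histogram rows
    count_bin: np.ndarray   # (n,) saccade count clipped to 25

    @property
    def n_trials(self) -> int:
        return self.count_bin.shape[0]


def trial_features(
    trials: Sequence[TrialOutcome], n_bins: int = N_BINS
) -> TrialFeatures:
    n = len(trials)
    revisit_at = np.zeros((n, n_bins), dtype=np.float64)
    alive_at = np.zeros((n, n_bins), dtype=np.float64)
    lag_hist = np.zeros((n, n_bins), dtype=np.float64)
    count_bin = np.zeros(n, dtype=np.int64)
    for i, tr in enumerate(trials):
        choices = tr.choices
        m = len(choices)
        if m == 0:
            raise ValueError(f"trial {i} has no choices")
        count_bin[i] = min(m, n_bins)
        alive_at[i, : min(m, n_bins)] = 1.0
        for k, flag in enumerate(revisit_flags(choices)):
            if flag and k < n_bins:
                revisit_at[i, k] = 1.0
        for lag in revisit_distances(choices):
            lag_hist[i, min(lag, n_bins) - 1] += 1.0
    return TrialFeatures(revisit_at, alive_at, lag_hist, count_bin)


def _normalize(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    total = raw.sum()
    if total <= 0:
        return np.zeros_like(raw), True
    return raw / total, False


def summarize_from_features(
    features: TrialFeatures,
    weights: Optional[np.ndarray] = None,
    denominator: Literal["surviving", "all"] = "surviving",
) -> SummaryTriplet:
    """Aggregate per-trial features (optionally weighted) into a triplet."""
    n_bins = features.revisit_at.shape[1]
    if weights is None:
        weights = np.ones(features.n_trials)
    w = np.asarray(weights, dtype=np.float64)
    n_eff = int(round(w.sum()))
    if n_eff < 1:
        raise ValueError("need at least one (weighted) trial")

    rev = w @ features.revisit_at
    if denominator == "surviving":
        denom = w @ features.alive_at
    else:
        denom = np.full(n_bins, w.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, rev / np.maximum(denom, 1e-300), 0.0)
    pos, pos_zero = _normalize(prop)

    raw_dist = w @ features.lag_hist
    dist, dist_zero = _normalize(raw_dist)

    raw_count = np.zeros(n_bins)
    np.add.at(raw_count, features.count_bin - 1, w)
    cnt, cnt_zero = _normalize(raw_count)

    return SummaryTriplet(
        revisit_by_position=pos,
        revisit_by_distance=dist,
        saccade_count_dist=cnt,
        n_trials=n_eff,
        raw_position=prop,
        raw_distance=raw_dist,
        raw_count=raw_count,
        zero_flags=(pos_zero, dist_zero, cnt_zero),
    )


def summarize(
    trials: Sequence[TrialOutcome],
    n_bins: int = N_BINS,
    denominator: Literal["surviving", "all"] = "surviving",
) -> SummaryTriplet:
    """Compute the normalized summary triplet for a set of trials."""
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    return summarize_from_features(trial_features(trials, n_bins), None, denominator)
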