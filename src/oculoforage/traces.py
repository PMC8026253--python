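"""Synthetic 1-kHz eye traces realizing a trial's choice sequence.

Saccades follow the amplitude–peak-velocity main sequence
Ė = Ėmax·[1 − exp(τ·Amp)] with a raised-cosine (sin²) velocity profile, so
each movement's peak velocity matches the main sequence exactly and its
duration is 2·Amp/Ė.  Optional ingredients emulate drug effects and
measurement realism: exponential postsaccadic drift parameterized by its
100-ms displacement, Gaussian position noise, and out-of-window excursions
for exercising the trial-exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .oculomotor import EyeTrace, main_sequence_velocity
from .session_io import TrialRecord

__all__ = ["SyntheticTraceTruth", "generate_eye_trace"]

#: Time constant (ms) of the postsaccadic position creep.
DRIFT_TAU_MS = 30.0
#: Window (ms) over which the drift magnitude is defined.
DRIFT_WINDOW_MS = 100.0


@dataclass
class SyntheticTraceTruth:
    """Ground truth implanted in a synthetic trace, for round-trip checks."""

    choices: Tuple[int, ...]
    onsets_ms: np.ndarray
    offsets_ms: np.ndarray
    amplitudes_deg: np.ndarray
    peak_velocities: np.ndarray


def _saccade_positions(
    start: np.ndarray, end: np.ndarray, peak_velocity: float
) -> np.ndarray:
    """1-kHz positions of one saccade (excluding the start sample).

    Raised-cosine velocity profile: v(t) = Vp·sin²(πt/D), whose integral is
    Vp·D/2 = Amp, hence D = 2·Amp/Vp.
    """
    delta = end - start
    amp = float(np.hypot(*delta))
    dur_ms = 2.0 * amp / peak_velocity * 1000.0
    n = int(np.ceil(dur_ms))
    t = np.arange(1, n + 1, dtype=float)
    frac = np.clip(t / dur_ms, 0.0, 1.0)
    s = frac - np.sin(2 * np.pi * frac) / (2 * np.pi)
    return start[None, :] + s[:, None] * delta[None, :]


def generate_eye_trace(
    trial: TrialRecord,
    main_sequence: Tuple[float, float] = (500.0, -0.1),
    drift_magnitude: float = 0.0,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    fixation_ms: float = 500.0,
    mean_isi_ms: float = 220.0,
    isi_sd_ms: float = 30.0,
    min_isi_ms: float = 120.0,
    tail_ms: float = 250.0,
    peak_velocity_scale: float = 1.0,
    excursion: bool = False,
    return_truth: bool = False,
):
    """Render a trial's choice sequence as a two-channel gaze trace.

    ``main_sequence`` is (Ėmax, τ) with Ėmax > 0 and τ < 0;
    ``drift_magnitude`` is the postsaccadic displacement accumulated over
    100 ms, directed along each saccade; ``excursion`` inserts a gaze
    excursion far outside the stimulus field (for the exclusion rule).
    With ``return_truth`` the implanted event parameters are returned
    alongside the trace.
    """
    emax, tau = main_sequence
    if emax <= 0 or tau >= 0:
        raise ValueError("require emax > 0 and tau < 0")
    if rng is None:
        rng = np.random.default_rng()

    fix = np.asarray(trial.array.fixation, dtype=float)
    chunks: List[np.ndarray] = [np.tile(fix, (int(fixation_ms), 1))]
    n_so_far = int(fixation_ms)
    events = {"fixation_on": 0.0, "search_on": float(fixation_ms)}
    onsets, offsets, amps, vps = [], [], [], []

    pos = fix.copy()
    targets = [trial.array.sites[c] for c in trial.choices]
    if excursion:
        targets.insert(
            len(targets) // 2, np.array([30.0, 0.0])  # far outside the field
        )
    drift_total = (
        drift_magnitude / (1.0 - np.exp(-DRIFT_WINDOW_MS / DRIFT_TAU_MS))
        if drift_magnitude > 0
        else 0.0
    )
    last_dir = np.zeros(2)
    for site in targets:
        # fixation interval before the saccade (latency / intersaccadic)
        isi = max(min_isi_ms, rng.normal(mean_isi_ms, isi_sd_ms))
        hold = np.tile(pos, (int(round(isi)), 1))
        if drift_total > 0 and offsets:
            # exponential creep along the previous saccade direction
            t = np.arange(1, hold.shape[0] + 1, dtype=float)
            creep = drift_total * (1.0 - np.exp(-t / DRIFT_TAU_MS))
            hold = hold + creep[:, None] * last_dir[None, :]
            pos = hold[-1].copy()
        chunks.append(hold)
        n_so_far += hold.shape[0]

        site = np.asarray(site, dtype=float)
        amp = float(np.hypot(*(site - pos)))
        vp = peak_velocity_scale * float(main_sequence_velocity(np.array(amp), emax, tau))
        sac = _saccade_positions(pos, site, vp)
        onsets.append(float(n_so_far))
        chunks.append(sac)
        n_so_far += sac.shape[0]
        offsets.append(float(n_so_far - 1))
        amps.append(amp)
        vps.append(vp)
        last_dir = (site - pos) / max(amp, 1e-12)
        pos = site.copy()

    tail = np.tile(pos, (int(tail_ms), 1))
    if drift_total > 0 and offsets:
        t = np.arange(1, tail.shape[0] + 1, dtype=float)
        creep = drift_total * (1.0 - np.exp(-t / DRIFT_TAU_MS))
        tail = tail + creep[:, None] * last_dir[None, :]
    chunks.append(tail)
    n_so_far += tail.shape[0]
    events["search_off"] = float(n_so_far)

    samples = np.concatenate(chunks, axis=0)
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)
    trace = EyeTrace(samples=samples, events=events)
    if not return_truth:
        return trace
    truth = SyntheticTraceTruth(
        choices=tuple(trial.choices),
        onsets_ms=np.array(onsets),
        offsets_ms=np.array(offsets),
        amplitudes_deg=np.array(amps),
        peak_velocities=np.array(vps),
    )
    return trace, truth
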