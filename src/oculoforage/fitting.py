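"""Grid-search model fitting via a coefficient of determination.

The parameter space is exhaustively enumerated: capacity 1–15, decay
1–capacity, utility 0.00–1.00 in steps of 0.02 — 6,120 parameter sets in
all.  Each set is simulated by Monte Carlo and summarized into the
concatenated 75-bin vector S_i; the observed data give the vector M.  The
goodness of fit is

    CD_i = 1 − Σ_b (M_b − S_ib)² / Σ_b (M_b − mean(S_i))²,

where mean(S_i) is the grand mean of the *simulated* vector over its 75
bins.  CD equals 1 for a perfect match and may be negative; a fit with
CD < 0.7 is flagged unreliable.  An optional conventional-R² mode
(centering on mean(M)) is provided but is not the default.

Grid simulations depend only on (n_sim_trials, seed), never on the data, so
they are computed once and cached; bootstrap resampling and sliding-window
fits then reduce to cheap vectorized CD evaluations against the cached
matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Union

import numpy as np

from .model import MAX_SACCADES, ModelParams, N_OBJECTS, simulate_agent
from .session_io import Session
from .summaries import (
    SummaryTriplet,
    TrialFeatures,
    summarize,
    summarize_from_features,
    trial_features,
)

__all__ = [
    "RELIABLE_CD",
    "parameter_grid",
    "coefficient_of_determination",
    "GridSummaries",
    "compute_grid_summaries",
    "load_or_compute_grid",
    "FitResult",
    "fit",
    "BootstrapResult",
    "bootstrap_intervals",
    "WindowFit",
    "sliding_window_fit",
    "parameter_pair_distance",
    "normalization_scales",
]

#: Reliability threshold on the best-fit CD.
RELIABLE_CD = 0.7

UTILITY_STEP = 0.02
N_UTILITY = 51


class DegenerateReferenceError(ValueError):
    """The CD denominator vanished (constant reference vector)."""


def parameter_grid() -> List[ModelParams]:
    """All 6,120 parameter sets in deterministic (capacity, decay, utility) order."""
    grid: List[ModelParams] = []
    utilities = np.round(np.arange(N_UTILITY) * UTILITY_STEP, 2)
    for cap in range(1, 16):
        for dec in range(1, cap + 1):
            for u in utilities:
                grid.append(ModelParams(cap, dec, float(u)))
    return grid


def coefficient_of_determination(
    M: np.ndarray,
    S: np.ndarray,
    center: Literal["sim", "obs"] = "sim",
) -> float:
    """CD between an observed 75-bin vector M and a simulated vector S.

    ``center="sim"`` (default) centers the denominator deviations of M on
    the grand mean of S; ``center="obs"`` gives the conventional R² centered
    on mean(M).
    """
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if M.shape != S.shape:
        raise ValueError(f"shape mismatch: {M.shape} vs {S.shape}")
    mean = S.mean() if center == "sim" else M.mean()
    denom = ((M - mean) ** 2).sum()
    if denom <= 0:
        raise DegenerateReferenceError("constant reference vector; CD undefined")
    return float(1.0 - ((M - S) ** 2).sum() / denom)


def _cd_matrix(M: np.ndarray, S: np.ndarray,
               center: Literal["sim", "obs"] = "sim") -> np.ndarray:
    """Vectorized CD of one observed vector against many simulated rows."""
    M = np.asarray(M, dtype=float)
    num = ((M[None, :] - S) ** 2).sum(axis=1)
    if center == "sim":
        means = S.mean(axis=1)
    else:
        means = np.full(S.shape[0], M.mean())
    den = ((M[None, :] - means[:, None]) ** 2).sum(axis=1)
    if np.any(den <= 0):
        raise DegenerateReferenceError("constant reference vector; CD undefined")
    return 1.0 - num / den


@dataclass
class GridSummaries:
    """Cached 75-bin summary vectors for every grid parameter set."""

    params: List[ModelParams]
    matrix: np.ndarray  # (n_grid, 75)
    n_sim_trials: int
    seed: int
    max_saccades: int = MAX_SACCADES
    n_objects: int = N_OBJECTS

    @property
    def cache_id(self) -> str:
        return (
            f"grid_t{self.n_sim_trials}_s{self.seed}"
            f"_m{self.max_saccades}_o{self.n_objects}"
        )

    def save(self, directory: Union[str, Path]) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        path = directory / (self.cache_id + ".npz")
        np.savez_compressed(
            path,
            matrix=self.matrix,
            meta=json.dumps(
                {
                    "n_sim_trials": self.n_sim_trials,
                    "seed": self.seed,
                    "max_saccades": self.max_saccades,
                    "n_objects": self.n_objects,
                }
            ),
        )
        return path


def compute_grid_summaries(
    n_sim_trials: int = 5000,
    seed: int = 0,
    max_saccades: int = MAX_SACCADES,
    n_objects: int = N_OBJECTS,
) -> GridSummaries:
    """Simulate every grid parameter set once and summarize it.

    Each grid point gets an independent child stream spawned from ``seed``,
    so the whole matrix is a pure function of (n_sim_trials, seed).
    """
    grid = parameter_grid()
    children = np.random.SeedSequence(seed).spawn(len(grid))
    matrix = np.empty((len(grid), 75))
    for i, (p, ss) in enumerate(zip(grid, children)):
        rng = np.random.default_rng(ss)
        trials = simulate_agent(p, n_sim_trials, rng, n_objects, max_saccades)
        matrix[i] = summarize(trials).concat()
    return GridSummaries(grid, matrix, n_sim_trials, seed, max_saccades, n_objects)


def load_or_compute_grid(
    n_sim_trials: int = 5000,
    seed: int = 0,
    cache_dir: Optional[Union[str, Path]] = None,
    max_saccades: int = MAX_SACCADES,
    n_objects: int = N_OBJECTS,
) -> GridSummaries:
    """Return grid summaries, reusing an on-disk cache when available."""
    stub = GridSummaries([], np.empty(0), n_sim_trials, seed, max_saccades, n_objects)
    if cache_dir is not None:
        path = Path(cache_dir) / (stub.cache_id + ".npz")
        if path.exists():
            with np.load(path, allow_pickle=False) as z:
                matrix = z["matrix"]
            return GridSummaries(
                parameter_grid(), matrix, n_sim_trials, seed, max_saccades, n_objects
            )
    gs = compute_grid_summaries(n_sim_trials, seed, max_saccades, n_objects)
    if cache_dir is not None:
        gs.save(cache_dir)
    return gs


@dataclass
class FitResult:
    """Best-fit parameters with the full grid of CDs."""

    best_params: ModelParams
    best_cd: float
    grid_cds: np.ndarray  # (n_grid,), aligned with parameter_grid()
    n_sim_trials: int
    seed: int

    @property
    def reliable(self) -> bool:
        return self.best_cd >= RELIABLE_CD


def fit(
    observed: Union[SummaryTriplet, np.ndarray],
    n_sim_trials: int = 5000,
    seed: int = 0,
    cache: Optional[GridSummaries] = None,
    cache_dir: Optional[Union[str, Path]] = None,
    center: Literal["sim", "obs"] = "sim",
) -> FitResult:
    """Exhaustive grid search for the parameters maximizing CD.

    ``observed`` is a summary triplet (or its 75-bin concatenation).  Grid
    simulations come from ``cache`` if given, else from the on-disk cache,
    else are computed fresh.  Ties in the argmax break toward the earliest
    grid entry (lowest capacity, then decay, then utility).
    """
    M = observed.concat() if isinstance(observed, SummaryTriplet) else np.asarray(observed)
    if cache is None:
        cache = load_or_compute_grid(n_sim_trials, seed, cache_dir)
    cds = _cd_matrix(M, cache.matrix, center)
    best = int(np.argmax(cds))
    return FitResult(
        best_params=cache.params[best],
        best_cd=float(cds[best]),
        grid_cds=cds,
        n_sim_trials=cache.n_sim_trials,
        seed=cache.seed,
    )


@dataclass
class BootstrapResult:
    """Middle-95% bootstrap bands for the three fitted parameters.

    The point estimate is the fit of the unresampled data; the bounds are
    the 2.5th/97.5th percentiles of ``n_boot`` refits of resampled trials.
    """

    point: ModelParams
    lower: np.ndarray  # (capacity, decay, utility)
    upper: np.ndarray
    n_boot: int
    samples: np.ndarray  # (n_boot, 3)

    def contains(self, params: ModelParams) -> np.ndarray:
        v = np.array(params.astuple(), dtype=float)
        return (self.lower <= v) & (v <= self.upper)


def bootstrap_intervals(
    trials: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
    cache: Optional[GridSummaries] = None,
    denominator: Literal["surviving", "all"] = "surviving",
    center: Literal["sim", "obs"] = "sim",
) -> BootstrapResult:
    """Percentile bootstrap over trials, refitting each resample.

    Trials are resampled with replacement; each resample is summarized via
    reweighted per-trial features and refit against the cached grid.
    """
    if len(trials) < 2:
        raise ValueError("need at least 2 trials to bootstrap")
    if cache is None:
        cache = load_or_compute_grid()
    rng = np.random.default_rng(seed)
    feats = trial_features(trials)
    point = fit(summarize_from_features(feats, None, denominator),
                cache=cache, center=center)
    n = feats.n_trials
    samples = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        w = np.bincount(idx, minlength=n).astype(float)
        triplet = summarize_from_features(feats, w, denominator)
        cds = _cd_matrix(triplet.concat(), cache.matrix, center)
        samples[b] = cache.params[int(np.argmax(cds))].astuple()
    lower = np.percentile(samples, 2.5, axis=0)
    upper = np.percentile(samples, 97.5, axis=0)
    return BootstrapResult(point.best_params, lower, upper, n_boot, samples)


@dataclass
class WindowFit:
    """Fit of one pooled time window; unreliable windows carry no parameters."""

    t_start_minutes: float
    t_end_minutes: float
    n_trials: int
    result: Optional[FitResult]
    empty: bool

    @property
    def reliable(self) -> bool:
        return self.result is not None and self.result.reliable


def sliding_window_fit(
    sessions: Sequence[Session],
    window_minutes: float = 10.0,
    step_minutes: float = 5.0,
    cache: Optional[GridSummaries] = None,
    t_start_minutes: float = 0.0,
    t_end_minutes: Optional[float] = None,
    denominator: Literal["surviving", "all"] = "surviving",
    center: Literal["sim", "obs"] = "sim",
) -> List[WindowFit]:
    """Fit pooled trials in sliding post-injection windows.

    Trials from all sessions are pooled per window of ``window_minutes``
    advanced in ``step_minutes`` steps, each window is fit against the
    cached grid, and windows that are empty or fit with CD < 0.7 are flagged
    rather than trusted.
    """
    if window_minutes <= 0 or step_minutes <= 0:
        raise ValueError("window and step must be positive")
    if cache is None:
        cache = load_or_compute_grid()
    per_session = [
        (s.trials, s.trial_minutes_post_injection()) for s in sessions
    ]
    if t_end_minutes is None:
        t_end_minutes = max(float(m.max()) for _, m in per_session if m.size)
    fits: List[WindowFit] = []
    t = t_start_minutes
    while t < t_end_minutes:
        hi = t + window_minutes
        pooled = [
            tr
            for trials, mins in per_session
            for tr, m in zip(trials, mins)
            if t <= m < hi
        ]
        if not pooled:
            fits.append(WindowFit(t, hi, 0, None, empty=True))
        else:
            triplet = summarize(pooled, denominator=denominator)
            fits.append(
                WindowFit(t, hi, len(pooled),
                          fit(triplet, cache=cache, center=center), empty=False)
            )
        t += step_minutes
    return fits


def parameter_pair_distance(
    p1: ModelParams,
    p2: ModelParams,
    scales: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Squared sum of per-parameter differences normalized by ``scales``.

    Used to compare the dispersion of fitted parameters within one subject's
    sessions against the dispersion across subjects.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("normalization scales must be positive")
    d = (np.array(p1.astuple()) - np.array(p2.astuple())) / scales
    return float((d**2).sum())


def normalization_scales(params_list: Sequence[ModelParams]) -> np.ndarray:
    """Per-parameter standard deviation across a comparison set of sessions."""
    arr = np.array([p.astuple() for p in params_list], dtype=float)
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("a parameter is constant across sessions; scale undefined")
    return sd
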