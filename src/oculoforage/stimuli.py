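"""Stimulus-array geometry of the oculomotor foraging task.

Fifteen identical objects per trial are placed on a 7 × 11 grid with 4°
spacing (77 sites spanning roughly 25° × 40° of visual angle).  The grid
site nearest the fixation point is excluded, leaving 76 candidate sites from
which the 15 object locations are drawn uniformly without replacement; one
object is the rewarded target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GRID_ROWS",
    "GRID_COLS",
    "GRID_SPACING_DEG",
    "grid_sites",
    "candidate_sites",
    "StimulusArray",
    "generate_stimulus_array",
    "random_pair_distance_stat",
]

GRID_ROWS = 7
GRID_COLS = 11
GRID_SPACING_DEG = 4.0
N_SITES_PER_TRIAL = 15


def grid_sites() -> np.ndarray:
    """All 77 grid sites, centered on (0, 0), as an (77, 2) array in degrees."""
    xs = (np.arange(GRID_COLS) - (GRID_COLS - 1) / 2) * GRID_SPACING_DEG
    ys = (np.arange(GRID_ROWS) - (GRID_ROWS - 1) / 2) * GRID_SPACING_DEG
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def candidate_sites(fixation: Sequence[float] = (0.0, 0.0)) -> np.ndarray:
    """The 76 candidate sites: the full grid minus the site nearest fixation.

    The fixation point may be off-grid (the task also uses peripheral
    fixation positions); excluding the nearest grid site keeps the candidate
    count at 76 for any fixation.
    """
    sites = grid_sites()
    fx = np.asarray(fixation, dtype=float)
    nearest = int(np.argmin(np.hypot(*(sites - fx).T)))
    return np.delete(sites, nearest, axis=0)


@dataclass
class StimulusArray:
    """One trial's object layout: 15 distinct sites, target, fixation."""

    sites: np.ndarray
    target_index: int
    fixation: np.ndarray = field(
        default_factory=lambda: np.zeros(2)
    )

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float)
        self.fixation = np.asarray(self.fixation, dtype=float)
        n = self.sites.shape[0]
        if self.sites.shape != (N_SITES_PER_TRIAL, 2):
            raise ValueError(
                f"expected {N_SITES_PER_TRIAL} sites, got shape {self.sites.shape}"
            )
        if not (0 <= self.target_index < n):
            raise ValueError(f"target_index out of range: {self.target_index}")
        d = np.hypot(
            *(self.sites[:, None, :] - self.sites[None, :, :]).transpose(2, 0, 1)
        )
        iu = np.triu_indices(n, k=1)
        if d[iu].min() < GRID_SPACING_DEG - 1e-9:
            raise ValueError("sites closer than the 4° grid spacing")

    @property
    def target_site(self) -> np.ndarray:
        return self.sites[self.target_index]


def generate_stimulus_array(
    rng: np.random.Generator, fixation: Sequence[float] = (0.0, 0.0)
) -> StimulusArray:
    """Sample one trial's array: 15 of the 76 candidates, target uniform."""
    cand = candidate_sites(fixation)
    idx = rng.choice(cand.shape[0], size=N_SITES_PER_TRIAL, replace=False)
    target = int(rng.integers(0, N_SITES_PER_TRIAL))
    return StimulusArray(
        sites=cand[idx], target_index=target, fixation=np.asarray(fixation, float)
    )


def random_pair_distance_stat(
    session_arrays: Sequence[Sequence[StimulusArray]],
    pairs_per_iteration: int = 5,
    iterations: int = 100,
    rng: Optional[np.random.Generator] = None,
    mode: str = "within",
) -> np.ndarray:
    """Per-session mean distance between randomly chosen object pairs.

    For each session, every iteration draws ``pairs_per_iteration`` pairs of
    distinct object positions and the session statistic is the mean Euclidean
    distance over all iterations.  ``mode="within"`` (default) draws each
    iteration's pairs within a single randomly chosen trial's array, matching
    the per-trial structure of the task; ``mode="across"`` pools positions
    over the whole session.  This is the chance reference against which
    initial-saccade amplitudes are compared.

    Each trial may be given as a :class:`StimulusArray` or a bare (n, 2)
    position array.
    """
    if rng is None:
        rng = np.random.default_rng()

    def _sites(a) -> np.ndarray:
        return a.sites if isinstance(a, StimulusArray) else np.asarray(a, float)

    means = np.empty(len(session_arrays))
    for s, arrays in enumerate(session_arrays):
        if len(arrays) == 0:
            raise ValueError(f"session {s} has no trials")
        dists = np.empty((iterations, pairs_per_iteration))
        if mode == "within":
            for it in range(iterations):
                sites = _sites(arrays[rng.integers(0, len(arrays))])
                n = sites.shape[0]
                for p in range(pairs_per_iteration):
                    i, j = rng.choice(n, size=2, replace=False)
                    dists[it, p] = np.hypot(*(sites[i] - sites[j]))
        elif mode == "across":
            pool = np.concatenate([_sites(a) for a in arrays], axis=0)
            n = pool.shape[0]
            for it in range(iterations):
                for p in range(pairs_per_iteration):
                    i, j = rng.choice(n, size=2, replace=False)
                    dists[it, p] = np.hypot(*(pool[i] - pool[j]))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        means[s] = dists.mean()
    return means
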