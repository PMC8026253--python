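"""Stochastic memory-guided foraging agent.

The agent searches among ``n_objects`` identical items for a hidden target by
sequential choices ("saccades").  Its behavior is governed by three
parameters:

* **capacity** — maximal number of already-inspected items held in working
  memory (1–15);
* **decay** — order-of-forgetting: when the store is full, the evicted item
  is drawn uniformly among the ``decay`` oldest entries (1 = strictly
  oldest, ``capacity`` = uniformly random);
* **utility** — probability that a choice consults memory ("exploit": pick
  uniformly among unremembered, non-current items) rather than picking
  uniformly among all non-current items ("explore").

Two simulation paths are provided: a straightforward per-trial loop
(:func:`simulate_trial`) and a vectorized batch engine used by
:func:`simulate_agent` for the Monte-Carlo runs that model fitting needs.
Both implement the identical stochastic rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "TrialOutcome",
    "update_memory",
    "choose_next",
    "simulate_trial",
    "simulate_agent",
]

#: Number of search objects in the standard task.
N_OBJECTS = 15

#: Saccade cap per trial, matching the 25-bin summary support.
MAX_SACCADES = 25


@dataclass(frozen=True)
class ModelParams:
    """Parameter triplet (capacity, decay, utility) defining one agent."""

    capacity: int
    decay: int
    utility: float

    def __post_init__(self) -> None:
        if not (1 <= self.capacity <= 15):
            raise ValueError(f"capacity must be in [1, 15], got {self.capacity}")
        if not (1 <= self.decay <= self.capacity):
            raise ValueError(
                f"decay must be in [1, capacity={self.capacity}], got {self.decay}"
            )
        if not (0.0 <= self.utility <= 1.0):
            raise ValueError(f"utility must be in [0, 1], got {self.utility}")

    def astuple(self) -> tuple[int, int, float]:
        return (self.capacity, self.decay, self.utility)


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one simulated search trial.

    ``choices`` is the ordered sequence of inspected object indices.  If the
    target was found the final choice equals the target and terminates the
    trial; otherwise the trial is censored at the saccade cap.
    """

    choices: tuple[int, ...]
    target: int
    found: bool
    censored: bool

    @property
    def n_saccades(self) -> int:
        return len(self.choices)

    def __post_init__(self) -> None:
        if self.found and self.censored:
            raise ValueError("a found trial cannot be censored")


# ---------------------------------------------------------------------------
# Scalar reference implementation
# ---------------------------------------------------------------------------

def update_memory(
    memory: Sequence[int],
    new_item: int,
    params: ModelParams,
    rng: np.random.Generator,
    on_revisit: Literal["refresh", "ignore"] = "refresh",
) -> List[int]:
    """Register ``new_item`` into working memory, oldest entry first.

    If the item is already stored, its recency is refreshed (default) or the
    store is left untouched (``on_revisit="ignore"``).  If the store is at
    capacity and the item is new, one of the ``decay`` oldest entries is
    first evicted uniformly at random.
    """
    memory = list(memory)
    if new_item in memory:
        if on_revisit == "refresh":
            memory.remove(new_item)
            memory.append(new_item)
        return memory
    if len(memory) >= params.capacity:
        evict = int(rng.integers(0, params.decay))
        del memory[evict]
    memory.append(new_item)
    return memory


def choose_next(
    current: Optional[int],
    memory: Sequence[int],
    params: ModelParams,
    n_objects: int = N_OBJECTS,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Draw the next object to inspect.

    With probability ``utility`` the agent exploits memory: a uniform draw
    among objects neither remembered nor currently fixated.  Otherwise (or if
    no such object exists) it explores: a uniform draw among all objects
    except the current one.  At trial start ``current`` is ``None`` (gaze is
    on the fixation point, not an object) and all objects are candidates.
    """
    if n_objects < 2:
        raise ValueError("need at least 2 objects")
    if rng is None:
        rng = np.random.default_rng()
    remembered = set(memory)
    if rng.random() < params.utility:
        candidates = [
            o for o in range(n_objects) if o != current and o not in remembered
        ]
        if candidates:
            return int(candidates[rng.integers(0, len(candidates))])
    # explore (or exploit fallback when everything is remembered)
    candidates = [o for o in range(n_objects) if o != current]
    return int(candidates[rng.integers(0, len(candidates))])


def simulate_trial(
    params: ModelParams,
    n_objects: int = N_OBJECTS,
    max_saccades: int = MAX_SACCADES,
    rng: Optional[np.random.Generator] = None,
    target: Optional[int] = None,
    on_revisit: Literal["refresh", "ignore"] = "refresh",
) -> TrialOutcome:
    """Simulate one search trial.

    The target is drawn uniformly unless given.  The trial ends when the
    target is chosen (found) or after ``max_saccades`` choices (censored).
    The terminating choice triggers no memory update.
    """
    if max_saccades < 1:
        raise ValueError("max_saccades must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if target is None:
        target = int(rng.integers(0, n_objects))
    memory: List[int] = []
    current: Optional[int] = None
    choices: List[int] = []
    found = False
    for _ in range(max_saccades):
        c = choose_next(current, memory, params, n_objects, rng)
        choices.append(c)
        if c == target:
            found = True
            break
        memory = update_memory(memory, c, params, rng, on_revisit)
        current = c
    return TrialOutcome(
        choices=tuple(choices),
        target=target,
        found=found,
        censored=not found,
    )


# ---------------------------------------------------------------------------
# Vectorized batch engine
# ---------------------------------------------------------------------------

def _simulate_batch(
    params: ModelParams,
    n_trials: int,
    rng: np.random.Generator,
    n_objects: int = N_OBJECTS,
    max_saccades: int = MAX_SACCADES,
) -> List[TrialOutcome]:
    """Simulate ``n_trials`` independent trials with array operations.

    Memory is represented per trial as a membership mask plus a registration
    time per object; eviction ranks members by registration time and removes
    one of the ``decay`` oldest.  Statistically identical to
    :func:`simulate_trial` (with recency refresh on revisits); the random
    streams differ, so per-trial outcomes are not bit-matched across engines.
    """
    n = n_objects
    cap, decay, utility = params.capacity, params.decay, params.utility
    target = rng.integers(0, n, size=n_trials)
    memb = np.zeros((n_trials, n), dtype=bool)
    # registration step of each remembered object; +inf marks "not stored"
    reg = np.full((n_trials, n), np.inf)
    current = np.full(n_trials, -1, dtype=np.int64)  # -1: gaze on fixation
    done = np.zeros(n_trials, dtype=bool)
    found = np.zeros(n_trials, dtype=bool)
    obj = np.arange(n)
    per_step: List[np.ndarray] = []
    rows = np.arange(n_trials)

    for t in range(max_saccades):
        if done.all():
            break
        not_current = obj[None, :] != current[:, None]
        exploit_mask = not_current & ~memb
        n_exploit = exploit_mask.sum(axis=1)
        use_exploit = (rng.random(n_trials) < utility) & (n_exploit > 0)
        mask = np.where(use_exploit[:, None], exploit_mask, not_current)
        counts = mask.sum(axis=1)
        k = np.floor(rng.random(n_trials) * counts).astype(np.int64)
        choice = (mask.cumsum(axis=1) > k[:, None]).argmax(axis=1)

        step_rec = np.where(done, -1, choice).astype(np.int16)
        per_step.append(step_rec)

        hit = ~done & (choice == target)
        cont = ~done & ~hit

        # memory update on continuing trials
        present = memb[rows, choice] & cont
        reg[rows[present], choice[present]] = t  # recency refresh
        absent = cont & ~memb[rows, choice]
        full = absent & (memb.sum(axis=1) >= cap)
        if full.any():
            order = np.argsort(reg[full], axis=1, kind="stable")
            j = rng.integers(0, decay, size=int(full.sum()))
            evict = order[np.arange(order.shape[0]), j]
            fr = rows[full]
            memb[fr, evict] = False
            reg[fr, evict] = np.inf
        memb[rows[absent], choice[absent]] = True
        reg[rows[absent], choice[absent]] = t

        current[cont] = choice[cont]
        found |= hit
        done |= hit

    steps = np.stack(per_step, axis=1) if per_step else np.empty((n_trials, 0), int)
    outcomes: List[TrialOutcome] = []
    for i in range(n_trials):
        row = steps[i]
        seq = row[row >= 0]
        outcomes.append(
            TrialOutcome(
                choices=tuple(int(c) for c in seq),
                target=int(target[i]),
                found=bool(found[i]),
                censored=not bool(found[i]),
            )
        )
    return outcomes


def simulate_agent(
    params: ModelParams,
    n_trials: int = 5000,
    rng: Optional[np.random.Generator] = None,
    n_objects: int = N_OBJECTS,
    max_saccades: int = MAX_SACCADES,
    engine: Literal["vector", "loop"] = "vector",
) -> List[TrialOutcome]:
    """Run a Monte-Carlo batch of independent trials under one parameter set.

    ``engine="vector"`` (default) uses the array implementation;
    ``engine="loop"`` runs :func:`simulate_trial` per trial and serves as the
    reference path.  Either is reproducible under a fixed seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if engine == "vector":
        return _simulate_batch(params, n_trials, rng, n_objects, max_saccades)
    return [
        simulate_trial(params, n_objects, max_saccades, rng) for _ in range(n_trials)
    ]
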