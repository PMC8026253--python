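"""End-to-end pipeline: generate → summarize → fit → bootstrap → timecourse.

All randomness derives from one top-level seed through named stage streams
(:func:`stage_rng`), so any stage can be re-run in isolation and the JSON
report it writes is reproducible byte for byte from its provenance block.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np

from .fitting import (
    GridSummaries,
    bootstrap_intervals,
    fit,
    load_or_compute_grid,
    sliding_window_fit,
)
from .model import ModelParams
from .session_io import Session, write_session
from .summaries import summarize
from .synth import DrugProfile, SessionTiming, generate_session

__all__ = ["PipelineConfig", "stage_rng", "run_pipeline", "ConfigError"]

#: Fixed stage order; each stage gets the spawn stream at its index.
STAGES = ("generate", "grid", "fit", "bootstrap", "timecourse")


class ConfigError(ValueError):
    """Invalid pipeline configuration (raised before any stage runs)."""


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage random stream: child ``STAGES.index(stage)`` of the seed."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return np.random.default_rng(children[STAGES.index(stage)])


@dataclass
class PipelineConfig:
    """Everything a full run needs; validated up front."""

    seed: int = 0
    params: tuple[int, int, float] = (10, 2, 0.9)
    n_trials: int = 500
    n_sessions: int = 3
    grid_sim_trials: int = 500
    n_boot: int = 200
    window_minutes: float = 10.0
    step_minutes: float = 5.0
    drug: Optional[DrugProfile] = None
    out_dir: Optional[str] = None
    run_bootstrap: bool = True
    run_timecourse: bool = False
    cache_dir: Optional[str] = None

    def validate(self) -> ModelParams:
        try:
            p = ModelParams(*self.params)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"bad params {self.params}: {e}") from e
        if self.n_trials < 1 or self.n_sessions < 1:
            raise ConfigError("n_trials and n_sessions must be >= 1")
        if self.n_boot < 1 or self.grid_sim_trials < 1:
            raise ConfigError("n_boot and grid_sim_trials must be >= 1")
        if self.step_minutes > self.window_minutes:
            raise ConfigError(
                f"window step ({self.step_minutes} min) exceeds window length "
                f"({self.window_minutes} min)"
            )
        if self.run_timecourse and self.drug is None:
            raise ConfigError("timecourse stage requires a drug profile")
        return p


def _checksum(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the configured stages and return (and optionally write) a report."""
    params = config.validate()
    report: Dict = {
        "provenance": {
            "seed": config.seed,
            "stages": list(STAGES),
            "config": {
                k: (asdict(v) if isinstance(v, DrugProfile) else v)
                for k, v in asdict(config).items()
            },
        },
        "stages": {},
    }

    rng = stage_rng(config.seed, "generate")
    sessions: List[Session] = [
        generate_session(
            params,
            config.n_trials,
            SessionTiming(),
            drug=config.drug,
            rng=rng,
            subject=f"synth{i}",
            condition="none" if config.drug is None else "ketamine-1.0",
        )
        for i in range(config.n_sessions)
    ]
    all_trials = [t for s in sessions for t in s.trials]
    report["stages"]["generate"] = {
        "n_sessions": len(sessions),
        "n_trials": len(all_trials),
        "checksum": _checksum(
            [[list(t.choices) for t in s.trials] for s in sessions]
        ),
    }

    triplet = summarize(all_trials)
    report["stages"]["summarize"] = {
        "n_trials": triplet.n_trials,
        "zero_flags": list(triplet.zero_flags),
        "checksum": _checksum(triplet.concat().round(12).tolist()),
    }

    grid_seed = int(
        np.random.SeedSequence(config.seed).spawn(len(STAGES))[
            STAGES.index("grid")
        ].generate_state(1)[0]
        % (2**31)
    )
    cache: GridSummaries = load_or_compute_grid(
        config.grid_sim_trials, grid_seed, cache_dir=config.cache_dir
    )
    fr = fit(triplet, cache=cache)
    report["stages"]["fit"] = {
        "best_params": list(fr.best_params.astuple()),
        "best_cd": fr.best_cd,
        "reliable": fr.reliable,
        "grid_seed": grid_seed,
        "n_sim_trials": cache.n_sim_trials,
        "cache_id": cache.cache_id,
    }

    if config.run_bootstrap:
        boot_seed = int(
            stage_rng(config.seed, "bootstrap").integers(0, 2**31)
        )
        br = bootstrap_intervals(
            all_trials, n_boot=config.n_boot, seed=boot_seed, cache=cache
        )
        report["stages"]["bootstrap"] = {
            "point": list(br.point.astuple()),
            "lower": br.lower.tolist(),
            "upper": br.upper.tolist(),
            "n_boot": br.n_boot,
            "seed": boot_seed,
        }

    if config.run_timecourse:
        wfs = sliding_window_fit(
            sessions,
            window_minutes=config.window_minutes,
            step_minutes=config.step_minutes,
            cache=cache,
        )
        report["stages"]["timecourse"] = [
            {
                "t_start_minutes": w.t_start_minutes,
                "t_end_minutes": w.t_end_minutes,
                "n_trials": w.n_trials,
                "empty": w.empty,
                "reliable": w.reliable,
                "best_params": (
                    list(w.result.best_params.astuple()) if w.result else None
                ),
                "best_cd": w.result.best_cd if w.result else None,
            }
            for w in wfs
        ]

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(sessions):
            write_session(s, out / f"session_{i}.csv")
        with open(out / "report.json", "w") as f:
            json.dump(report, f, indent=2, sort_keys=True)
    return report
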