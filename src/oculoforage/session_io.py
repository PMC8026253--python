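"""Session containers and the on-disk session dialect.

A session file is a CSV preceded by a single JSON header line
(``# {"schema": ...}``) carrying the schema version, subject, condition and
injection time.  One CSV row per trial; site coordinates and choice
sequences are semicolon-joined fields.  The format is diff-able and opens in
a spreadsheet.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .stimuli import StimulusArray

__all__ = ["TrialRecord", "Session", "read_session", "write_session", "SessionFormatError"]

SCHEMA_VERSION = 1

CONDITIONS = (
    "none",
    "saline",
    "ketamine-0.7",
    "ketamine-1.0",
    "ketamine-1.5",
    "medetomidine",
)


class SessionFormatError(ValueError):
    """Raised for malformed session files, with row-level context."""


@dataclass
class TrialRecord:
    """One trial: stimulus array, ordered choices, outcome, timing."""

    trial_id: int
    array: StimulusArray
    choices: tuple[int, ...]
    found: bool
    censored: bool
    t_start_ms: float
    saccade_times_ms: tuple[float, ...] = ()
    excluded: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        n = self.array.sites.shape[0]
        for c in self.choices:
            if not (0 <= c < n):
                raise SessionFormatError(
                    f"trial {self.trial_id}: choice {c} out of range for {n} objects"
                )
        if self.found and self.censored:
            raise SessionFormatError(
                f"trial {self.trial_id}: found and censored are mutually exclusive"
            )
        if self.saccade_times_ms and len(self.saccade_times_ms) != len(self.choices):
            raise SessionFormatError(
                f"trial {self.trial_id}: {len(self.saccade_times_ms)} saccade times "
                f"for {len(self.choices)} choices"
            )


@dataclass
class Session:
    """An ordered collection of trials with subject/condition metadata.

    ``injection_time_ms`` is the session time of drug (or saline) injection;
    ``None`` for purely behavioral sessions.
    """

    subject: str
    condition: str
    trials: List[TrialRecord]
    injection_time_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionFormatError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        starts = [t.t_start_ms for t in self.trials]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise SessionFormatError("trial timestamps must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial_minutes_post_injection(self) -> np.ndarray:
        """Trial start times in minutes relative to injection (0 if none)."""
        t0 = self.injection_time_ms or 0.0
        return np.array([(t.t_start_ms - t0) / 60000.0 for t in self.trials])


def _join_pts(pts: np.ndarray) -> str:
    # repr keeps full float precision so files round-trip losslessly
    return ";".join(f"{float(x)!r}:{float(y)!r}" for x, y in pts)


def _parse_pts(s: str, row: int) -> np.ndarray:
    try:
        return np.array([[float(v) for v in p.split(":")] for p in s.split(";")])
    except Exception as e:  # noqa: BLE001
        raise SessionFormatError(f"row {row}: bad site field {s!r}: {e}") from e


def write_session(session: Session, path: Union[str, Path]) -> None:
    path = Path(path)
    header = {
        "schema": SCHEMA_VERSION,
        "subject": session.subject,
        "condition": session.condition,
        "injection_time_ms": session.injection_time_ms,
    }
    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_id": t.trial_id,
                "t_start_ms": f"{float(t.t_start_ms)!r}",
                "sites": _join_pts(t.array.sites),
                "fixation": (
                    f"{float(t.array.fixation[0])!r}:{float(t.array.fixation[1])!r}"
                ),
                "target_index": t.array.target_index,
                "choices": ";".join(str(c) for c in t.choices),
                "saccade_times_ms": ";".join(
                    f"{float(x)!r}" for x in t.saccade_times_ms
                ),
                "found": int(t.found),
                "censored": int(t.censored),
                "excluded": int(t.excluded),
                "exclude_reason": t.exclude_reason,
            }
        )
    df = pd.DataFrame(rows)
    with open(path, "w") as f:
        f.write("# " + json.dumps(header) + "\n")
        df.to_csv(f, index=False)


def read_session(path: Union[str, Path]) -> Session:
    path = Path(path)
    with open(path) as f:
        first = f.readline()
        if not first.startswith("# "):
            raise SessionFormatError(f"{path}: missing JSON header line")
        try:
            header = json.loads(first[2:])
        except json.JSONDecodeError as e:
            raise SessionFormatError(f"{path}: bad JSON header: {e}") from e
        if header.get("schema") != SCHEMA_VERSION:
            raise SessionFormatError(
                f"{path}: schema version {header.get('schema')!r}, "
                f"expected {SCHEMA_VERSION}"
            )
        df = pd.read_csv(
            f,
            dtype={"exclude_reason": str},
            keep_default_na=False,
            float_precision="round_trip",
        )
    trials: List[TrialRecord] = []
    for i, row in df.iterrows():
        fx = [float(v) for v in str(row["fixation"]).split(":")]
        array = StimulusArray(
            sites=_parse_pts(row["sites"], i),
            target_index=int(row["target_index"]),
            fixation=np.array(fx),
        )
        choices = tuple(
            int(c) for c in str(row["choices"]).split(";") if c != ""
        )
        times = tuple(
            float(x) for x in str(row["saccade_times_ms"]).split(";") if x != ""
        )
        trials.append(
            TrialRecord(
                trial_id=int(row["trial_id"]),
                array=array,
                choices=choices,
                found=bool(int(row["found"])),
                censored=bool(int(row["censored"])),
                t_start_ms=float(row["t_start_ms"]),
                saccade_times_ms=times,
                excluded=bool(int(row["excluded"])),
                exclude_reason=str(row["exclude_reason"]),
            )
        )
    return Session(
        subject=str(header["subject"]),
        condition=str(header["condition"]),
        trials=trials,
        injection_time_ms=header.get("injection_time_ms"),
    )
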