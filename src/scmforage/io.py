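"""File formats: trial-log CSV round-tripping, schema validation, run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .scheduler import SessionSchedule, TRIAL_TYPES
from .synth import TRIAL_LOG_COLUMNS

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_trial_log",
    "read_trial_log",
    "write_schedule",
    "RunManifest",
]

SCHEMA_VERSION = 1
_HEADER = f"# scmforage trial-log v{SCHEMA_VERSION}"


class SchemaError(ValueError):
    pass


def write_trial_log(log: pd.DataFrame, path: str | Path) -> None:
    """Write a trial log as versioned CSV; peck trains are semicolon-joined."""
    out = log.copy()
    out["peck_times"] = out["peck_times"].map(
        lambda v: ""
        if v is None or (np.isscalar(v) and pd.isna(v))
        else ";".join(f"{t:.4f}" for t in np.asarray(v))
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        out.to_csv(fh, index=False)


def _parse_pecks(cell) -> np.ndarray | None:
    if cell is None or (np.isscalar(cell) and pd.isna(cell)) or cell == "":
        return None
    return np.array([float(x) for x in str(cell).split(";")])


def read_trial_log(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Rejects files with an unknown schema version or missing columns, and
    rows violating basic invariants (non-positive latency, unknown trial
    type, chosen option not among those offered) with their row numbers.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# scmforage trial-log"):
            raise SchemaError(f"{path}: missing trial-log header line")
        if first != _HEADER:
            raise SchemaError(f"{path}: unsupported schema version: {first!r}")
        df = pd.read_csv(fh)
    if df.empty:
        raise SchemaError(f"{path}: no trial rows")
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad: list[str] = []
    for i, row in df.iterrows():
        if not (row["latency_s"] > 0):
            bad.append(f"row {i}: non-positive latency {row['latency_s']}")
        if row["trial_type"] not in TRIAL_TYPES:
            bad.append(f"row {i}: unknown trial_type {row['trial_type']!r}")
        chosen = row["chosen_option"]
        if pd.notna(chosen):
            offered = {row["option_left"], row["option_right"]}
            if chosen not in offered:
                bad.append(f"row {i}: chosen option {chosen!r} was not offered")
    if bad:
        raise SchemaError(f"{path}: invalid rows:\n  " + "\n  ".join(bad))
    df["peck_times"] = df["peck_times"].map(_parse_pecks)
    df["option_left"] = df["option_left"].where(pd.notna(df["option_left"]), None)
    df["option_right"] = df["option_right"].where(pd.notna(df["option_right"]), None)
    df["chosen_option"] = df["chosen_option"].where(pd.notna(df["chosen_option"]), None)
    return df[TRIAL_LOG_COLUMNS + [c for c in df.columns if c not in TRIAL_LOG_COLUMNS]]


def write_schedule(schedule: SessionSchedule, path: str | Path) -> None:
    rows = [
        {
            "trial_index": t.index,
            "subsession": t.subsession,
            "context": t.context,
            "trial_type": t.trial_type,
            "option_left": t.option_left or "",
            "option_right": t.option_right or "",
            "planned_iti_s": t.planned_iti_s,
        }
        for t in schedule.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run: config snapshot, root seed,
    output digests and per-stage timings. (config, seed) determines every
    output byte."""

    seed: int
    config: dict
    version: str = "0.1.0"
    stages: dict[str, float] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)

    def record_file(self, path: str | Path) -> None:
        p = Path(path)
        self.digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
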