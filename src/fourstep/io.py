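"""File formats for the pipeline.

Game records travel as JSONL (one game per line, append-friendly);
Two-Step trial tables, summary metrics and ratings as CSV; probe sets
as board strings with a JSON provenance header; run configuration as
YAML. Everything written by the pipeline can be read back by it, and
reads validate their content (game records are replayed move by move,
trial tables are checked against the transition mapping).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .board import Board, GameRecord
from .metrics import ProbeSet
from .twostep_task import COMMON, RARE, TRIAL_COLUMNS, common_state

_REQUIRED_GAME_KEYS = {
    "subject_id", "participant_color", "moves", "opponent_category", "outcome"
}


def write_game_records(records: list[GameRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps({
                "subject_id": rec.subject_id,
                "participant_color": rec.participant_color,
                "moves": list(map(int, rec.moves)),
                "opponent_category": rec.opponent_category,
                "outcome": rec.outcome,
            }) + "\n")


def read_game_records(path) -> list[GameRecord]:
    """Read and validate a JSONL game-record file; every record is
    replayed from the empty board and must reproduce its outcome."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(f"line {lineno}: malformed JSON ({e})") from e
            missing = _REQUIRED_GAME_KEYS - obj.keys()
            if missing:
                raise ValueError(f"line {lineno}: missing keys {sorted(missing)}")
            rec = GameRecord(
                subject_id=obj["subject_id"],
                participant_color=int(obj["participant_color"]),
                moves=[int(m) for m in obj["moves"]],
                opponent_category=int(obj["opponent_category"]),
                outcome=obj["outcome"],
            )
            try:
                rec.replay()
            except ValueError as e:
                raise ValueError(f"line {lineno}: {e}") from e
            records.append(rec)
    return records


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial-table CSV and check internal consistency: required
    columns present, and state2 consistent with (choice1, transition)
    under the fixed common mapping. Missing RTs are allowed (NaN)."""
    df = pd.read_csv(path)
    required = [c for c in TRIAL_COLUMNS if c != "rt2_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    if "rt2_ms" not in df.columns:
        df["rt2_ms"] = np.nan
    for idx, row in enumerate(df.itertuples(index=False)):
        expected = common_state(int(row.choice1))
        if row.transition == RARE:
            expected = 3 - expected
        elif row.transition != COMMON:
            raise ValueError(
                f"trial row {idx}: bad transition label {row.transition!r}"
            )
        if int(row.state2) != expected:
            raise ValueError(
                f"trial row {idx}: state2={row.state2} inconsistent with "
                f"choice1={row.choice1}, transition={row.transition}"
            )
    return df


def write_probe_set(probes: ProbeSet, path) -> None:
    """JSON provenance header line, then one board string per line."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"provenance": probes.provenance}) + "\n")
        for board in probes:
            fh.write(board.to_string() + "\n")


def read_probe_set(path) -> ProbeSet:
    with open(path) as fh:
        header = json.loads(fh.readline())
        boards = [Board.from_string(line.strip())
                  for line in fh if line.strip()]
    return ProbeSet(boards=boards, provenance=header.get("provenance", {}))


def write_stats_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    if "seed" in cfg and not isinstance(cfg["seed"], int):
        raise ValueError("config field 'seed' must be an integer")
    for key in ("out_dir",):
        if key in cfg and not isinstance(cfg[key], str):
            raise ValueError(f"config field {key!r} must be a string")
    return cfg


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
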