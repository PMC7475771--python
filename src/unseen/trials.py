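"""Trial data model, factorial design generator, and CSV readers/writers.

A trial is one presentation in the masking task: one of four stimulus
conditions (left arrow, right arrow, non-arrow, stimulus absent) under one
of five TMS time conditions, with active or sham stimulation, followed by
three mandatory unspeeded responses ("did you see the arrow?", "did you
see something?", "left or right?").  Trials travel as a long-format pandas
DataFrame, one row per trial.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

TMS_MODES: tuple[str, ...] = ("active", "sham")
#: BIP = the 110 ms pulse present in every active condition; E30/E70 add an
#: early pulse (feed-forward phase), L150/L190 a late pulse (recurrent phase).
TMS_TIMES: tuple[str, ...] = ("BIP_only", "E30_BIP", "E70_BIP", "BIP_L150", "BIP_L190")
EARLY_TIMES: tuple[str, ...] = ("E30_BIP", "E70_BIP")
LATE_TIMES: tuple[str, ...] = ("BIP_L150", "BIP_L190")
STIMULI: tuple[str, ...] = ("arrow_left", "arrow_right", "non_arrow", "absent")
ARROW_STIMULI: tuple[str, ...] = ("arrow_left", "arrow_right")
YESNO: tuple[str, ...] = ("yes", "no")
DIRECTIONS: tuple[str, ...] = ("left", "right")

#: Canonical column order for trial tables on disk.
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "block_index",
    "tms_mode",
    "tms_time",
    "stimulus",
    "resp_arrow",
    "resp_something",
    "resp_direction",
    "question_order",
    "blink",
)

_ENUM_DOMAINS: dict[str, tuple[str, ...]] = {
    "tms_mode": TMS_MODES,
    "tms_time": TMS_TIMES,
    "stimulus": STIMULI,
    "resp_arrow": YESNO,
    "resp_something": YESNO,
    "resp_direction": DIRECTIONS,
}

N_QUESTION_ORDERS = 6
#: Blocks sharing one question order are run consecutively.
BLOCKS_PER_QUESTION_ORDER = 4


class TrialParseError(ValueError):
    """A trial table failed structural validation."""


class DesignError(ValueError):
    """A design specification violates the factorial constraints."""


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of one participant's session set.

    Defaults reproduce the study design: 12 active + 12 sham blocks of 80
    trials, each block containing 4 repetitions of each of the 20 unique
    (stimulus x TMS time) conditions, for 1920 trials per participant.
    """

    n_participants: int = 1
    blocks_active: int = 12
    blocks_sham: int = 12
    trials_per_block: int = 80
    reps_per_condition: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        n_conditions = len(STIMULI) * len(TMS_TIMES)
        if self.trials_per_block != self.reps_per_condition * n_conditions:
            raise DesignError(
                f"trials_per_block ({self.trials_per_block}) must equal "
                f"reps_per_condition x {n_conditions} "
                f"({self.reps_per_condition * n_conditions})"
            )
        if self.n_participants < 1 or self.blocks_active < 0 or self.blocks_sham < 0:
            raise DesignError("participant and block counts must be positive")

    @property
    def n_blocks(self) -> int:
        return self.blocks_active + self.blocks_sham

    @property
    def trials_per_participant(self) -> int:
        return self.n_blocks * self.trials_per_block


def _block_modes(spec: DesignSpec, rng: np.random.Generator) -> np.ndarray:
    """Active/sham labels per block, balanced within question-order sets.

    With the default 12+12 blocks each consecutive set of 4 same-question
    blocks receives 2 active and 2 sham in random order (equal active and
    control counts per question order).  For unbalanced specs a globally
    shuffled assignment with exact overall counts is used instead.
    """
    n = spec.n_blocks
    if spec.blocks_active == spec.blocks_sham and n % BLOCKS_PER_QUESTION_ORDER == 0:
        per_set = BLOCKS_PER_QUESTION_ORDER
        modes = []
        for _ in range(n // per_set):
            half = per_set // 2
            chunk = np.array(["active"] * half + ["sham"] * half, dtype=object)
            modes.append(rng.permutation(chunk))
        return np.concatenate(modes)
    pool = np.array(
        ["active"] * spec.blocks_active + ["sham"] * spec.blocks_sham, dtype=object
    )
    return rng.permutation(pool)


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Generate the trial scaffold of the factorial design (responses unset).

    Per participant: each block holds ``reps_per_condition`` repetitions of
    every (stimulus, tms_time) pair in randomized order; question orders are
    a random permutation of the six orders, each maintained over four
    consecutive blocks; active/sham assignment is balanced per question
    order.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    conditions = [(s, t) for s in STIMULI for t in TMS_TIMES]
    base = np.array(conditions * spec.reps_per_condition, dtype=object)

    frames = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:02d}"
        modes = _block_modes(spec, rng)
        order_cycle = rng.permutation(np.arange(1, N_QUESTION_ORDERS + 1))
        records_stim = []
        records_time = []
        block_idx = np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block)
        q_orders = np.empty(spec.n_blocks, dtype=int)
        for b in range(spec.n_blocks):
            perm = rng.permutation(len(base))
            shuffled = base[perm]
            records_stim.append([c[0] for c in shuffled])
            records_time.append([c[1] for c in shuffled])
            q_orders[b] = order_cycle[
                (b // BLOCKS_PER_QUESTION_ORDER) % N_QUESTION_ORDERS
            ]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "block_index": block_idx,
                    "tms_mode": np.repeat(modes, spec.trials_per_block),
                    "tms_time": np.concatenate(records_time),
                    "stimulus": np.concatenate(records_stim),
                    "resp_arrow": "",
                    "resp_something": "",
                    "resp_direction": "",
                    "question_order": np.repeat(q_orders, spec.trials_per_block),
                    "blink": False,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out[list(TRIAL_COLUMNS)]


def _load_column_map(column_map: Mapping[str, str] | str | Path | None) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise TrialParseError(f"column map {column_map!r} is not a mapping")
        return {str(k): str(v) for k, v in loaded.items()}
    return dict(column_map)


def read_trials(
    path: str | Path | Iterable[str | Path],
    column_map: Mapping[str, str] | str | Path | None = None,
    require_responses: bool = True,
) -> pd.DataFrame:
    """Read and validate one or more long-format trial CSVs.

    Parameters
    ----------
    path
        A CSV path, or an iterable of paths (per-block or per-session files
        are concatenated in the order given).
    column_map
        Optional mapping ``{foreign_name: canonical_name}`` (dict, or path
        to a YAML/JSON file) adapting a foreign layout to the canonical
        schema.
    require_responses
        When True (default) the three response columns must contain valid
        tokens on every row; set False to read response-less design
        scaffolds.

    Raises
    ------
    TrialParseError
        On a missing column, an unknown enum token (reported with its row
        number), or an empty file.
    """
    if isinstance(path, (str, Path)):
        paths: Sequence[str | Path] = [path]
    else:
        paths = list(path)
    mapping = _load_column_map(column_map)
    parts = []
    for p in paths:
        if os.path.getsize(p) == 0:
            raise TrialParseError(f"{p}: empty file")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        if df.empty and df.columns.size == 0:
            raise TrialParseError(f"{p}: no header row")
        if mapping:
            df = df.rename(columns=mapping)
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise TrialParseError(f"{p}: missing column(s) {missing}")
        parts.append(df[list(TRIAL_COLUMNS)])
    out = pd.concat(parts, ignore_index=True)
    return validate_trials(out, require_responses=require_responses)


def validate_trials(df: pd.DataFrame, require_responses: bool = True) -> pd.DataFrame:
    """Validate tokens/types of a trial table; returns a typed copy.

    An *illogical* response pattern (arrow "yes" with something "no") is a
    valid row — it feeds an exclusion rule — and is never rejected here.
    """
    df = df.copy()
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing column(s) {missing}")
    for col, domain in _ENUM_DOMAINS.items():
        values = df[col].astype(str)
        allowed = set(domain)
        if not require_responses and col.startswith("resp_"):
            allowed = allowed | {""}
        bad = ~values.isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialParseError(
                f"column {col!r}: unknown token {values.iloc[row]!r} at row {row}"
            )
        df[col] = values
    try:
        df["block_index"] = df["block_index"].astype(int)
        df["question_order"] = df["question_order"].astype(int)
    except ValueError as exc:
        raise TrialParseError(f"non-integer block_index/question_order: {exc}") from exc
    if (df["block_index"] < 1).any():
        raise TrialParseError("block_index must be >= 1")
    if (~df["question_order"].isin(range(1, N_QUESTION_ORDERS + 1))).any():
        raise TrialParseError("question_order must be in 1..6")
    blink = df["blink"]
    if blink.dtype != bool:
        tokens = blink.astype(str).str.strip().str.lower()
        bad = ~tokens.isin({"true", "false", "0", "1"})
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrialParseError(f"column 'blink': unknown token at row {row}")
        df["blink"] = tokens.isin({"true", "1"})
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as canonical CSV (stable column order and tokens)."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialParseError(f"missing column(s) {missing}")
    df[list(TRIAL_COLUMNS)].to_csv(path, index=False)


def is_illogical(df: pd.DataFrame) -> pd.Series:
    """Boolean mask of illogical trials: arrow "yes" with something "no"."""
    return (df["resp_arrow"] == "yes") & (df["resp_something"] == "no")
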