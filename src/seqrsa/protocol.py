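"""Dual-domain serial reaction time task (SRTT) protocol generator.

The experiment interleaves three conditions within each scanning run:

* ``SQ_MOT`` — motor sequence: the eight key presses follow a fixed cyclic
  sequence while the stream of cue objects is random.
* ``SQ_OBJ`` — object sequence: the stream of cue objects follows a fixed
  cyclic sequence while the key presses are random.
* ``RD``     — random: both streams are random.

Every block is one stream of 8 elements; the object-to-key mapping shown at
the bottom of the screen changes between streams, which is what
orthogonalises the two sequence-learning domains.  A scanning run holds 5
streams of each condition (15 blocks, 120 cue events) plus three 10 s rest
periods; eight runs give 40 stream repetitions per condition.

All randomness flows through :class:`numpy.random.Generator`, and the whole
protocol is a pure function of ``(seed, n_subjects)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("SQ_MOT", "SQ_OBJ", "RD")

#: Canonical motor sequence (keys 1-8; 1 and 8 are the little fingers).
CANONICAL_MOTOR_SEQUENCE: tuple[int, ...] = (4, 7, 3, 8, 6, 2, 5, 1)

#: Canonical object sequence (two objects from each of four categories).
CANONICAL_OBJECT_SEQUENCE: tuple[str, ...] = (
    "pineapple", "plane", "giraffe", "saw", "elephant", "banana", "axe", "car",
)

#: Semantic category of each object, two per category.
OBJECT_CATEGORIES: dict[str, str] = {
    "pineapple": "fruit", "banana": "fruit",
    "plane": "vehicle", "car": "vehicle",
    "giraffe": "animal", "elephant": "animal",
    "saw": "tool", "axe": "tool",
}

N_KEYS = 8
N_POSITIONS = 8
BLOCKS_PER_CONDITION = 5
N_RUNS = 8
REST_DURATION_S = 10.0
ISI_RANGE_S = (1.5, 2.5)
BEHAVIORAL_RSI_S = 0.75

EVENT_COLUMNS = [
    "subject", "run", "block", "condition", "position",
    "key", "object", "onset_s", "isi_s",
]


@dataclass(frozen=True)
class SequencePair:
    """A subject's rotated motor and object sequences.

    ``subject_rotation`` r means the subject's sequence starts at element r
    of the canonical cyclic order; the cyclic structure is shared by all
    subjects while the slot-to-item assignment differs.
    """

    motor_sequence: tuple[int, ...]
    object_sequence: tuple[str, ...]
    subject_rotation: int

    def __post_init__(self) -> None:
        if sorted(self.motor_sequence) != list(range(1, N_KEYS + 1)):
            raise ValueError("motor_sequence must be a permutation of 1..8")
        if len(set(self.object_sequence)) != N_POSITIONS:
            raise ValueError("object_sequence must hold 8 distinct objects")

    def slot_of_key(self, key: int) -> int:
        """Learned ordinal slot (1-8) of a key in the motor sequence."""
        return self.motor_sequence.index(key) + 1

    def slot_of_object(self, obj: str) -> int:
        """Learned ordinal slot (1-8) of an object in the object sequence."""
        return self.object_sequence.index(obj) + 1


@dataclass(frozen=True)
class MappingEpoch:
    """Object-to-key bijection in force during one 8-element stream."""

    stream_index: int
    object_to_key: dict[str, int]

    def __post_init__(self) -> None:
        keys = sorted(self.object_to_key.values())
        if keys != list(range(1, N_KEYS + 1)) or len(self.object_to_key) != N_KEYS:
            raise ValueError("object_to_key must be a bijection of 8 objects onto keys 1..8")


@dataclass
class RunSchedule:
    """One scanning run: condition order, rest placement and its events."""

    run: int
    condition_order: list[str]
    rest_after_block: list[int]   # rest follows these block indices (1-based)
    events: pd.DataFrame

    @property
    def duration_s(self) -> float:
        last = self.events.iloc[-1]
        return float(last["onset_s"] + last["isi_s"])


@dataclass
class SubjectProtocol:
    """All schedules and behavioral sessions for one subject."""

    subject: int
    sequences: SequencePair
    runs: list[RunSchedule]
    behavior: pd.DataFrame = field(repr=False, default=None)

    @property
    def events(self) -> pd.DataFrame:
        """Concatenated scanner events across the 8 runs."""
        return pd.concat([r.events for r in self.runs], ignore_index=True)


def rotate(sequence, rotation: int):
    """Cyclic rotation starting at element ``rotation`` (0-based)."""
    return tuple(sequence[(rotation + i) % len(sequence)] for i in range(len(sequence)))


def make_sequence_pair(
    subject_rotation: int,
    motor_sequence=CANONICAL_MOTOR_SEQUENCE,
    object_sequence=CANONICAL_OBJECT_SEQUENCE,
) -> SequencePair:
    """Rotate the canonical sequences to a subject's starting point.

    Parameters
    ----------
    subject_rotation
        Offset 0-7; every subject shares the cyclic order but starts at a
        different element so that no key/object is tied to the same slot
        across subjects.
    """
    if not 0 <= subject_rotation < N_POSITIONS:
        raise ValueError(f"subject_rotation must be in 0..7, got {subject_rotation}")
    return SequencePair(
        motor_sequence=rotate(motor_sequence, subject_rotation),
        object_sequence=rotate(object_sequence, subject_rotation),
        subject_rotation=subject_rotation,
    )


def _sample_condition_order(rng: np.random.Generator, max_consecutive: int = 2,
                            max_attempts: int = 10_000) -> list[str]:
    """15 blocks, 5 per condition, no condition > max_consecutive in a row."""
    blocks = list(
        itertools.chain.from_iterable([c] * BLOCKS_PER_CONDITION for c in CONDITIONS)
    )
    for _ in range(max_attempts):
        order = list(rng.permutation(blocks))
        ok = all(
            len(set(order[i:i + max_consecutive + 1])) > 1
            for i in range(len(order) - max_consecutive)
        )
        if ok:
            return order
    raise RuntimeError(
        f"no condition order satisfying max_consecutive={max_consecutive} "
        f"found in {max_attempts} attempts"
    )


def _sample_rest_slots(rng: np.random.Generator, n_blocks: int = 15,
                       n_rest: int = 3) -> list[int]:
    """Rest follows blocks i (1-based, i < n_blocks); no two rests adjacent."""
    gaps = np.arange(1, n_blocks)
    while True:
        chosen = np.sort(rng.choice(gaps, size=n_rest, replace=False))
        if np.all(np.diff(chosen) > 1):
            return chosen.tolist()


def _random_stream(rng: np.random.Generator, items, exclude=None):
    """Uniform permutation of ``items``, resampled to avoid ``exclude`` values."""
    exclude = [tuple(e) for e in (exclude or [])]
    while True:
        perm = tuple(rng.permutation(np.asarray(items, dtype=object)))
        if perm not in exclude:
            return perm


def _stream_items(
    condition: str,
    sequences: SequencePair,
    rng: np.random.Generator,
    prev_mapping: dict | None,
    exclude_learned: bool,
):
    """Keys and objects for one 8-element stream of the given condition.

    Each stream's object/key pairing is the mapping epoch; consecutive
    streams must use distinct mappings, and (optionally) random streams must
    not reproduce the learned sequence of that domain.
    """
    for _ in range(10_000):
        if condition == "SQ_MOT":
            keys = sequences.motor_sequence
            objects = _random_stream(
                rng, CANONICAL_OBJECT_SEQUENCE,
                exclude=[sequences.object_sequence] if exclude_learned else None,
            )
        elif condition == "SQ_OBJ":
            objects = sequences.object_sequence
            keys = _random_stream(
                rng, sequences.motor_sequence,
                exclude=[sequences.motor_sequence] if exclude_learned else None,
            )
        else:
            keys = _random_stream(
                rng, sequences.motor_sequence,
                exclude=[sequences.motor_sequence] if exclude_learned else None,
            )
            objects = _random_stream(
                rng, CANONICAL_OBJECT_SEQUENCE,
                exclude=[sequences.object_sequence] if exclude_learned else None,
            )
        mapping = dict(zip(objects, keys))
        if mapping != prev_mapping:
            return [int(k) for k in keys], list(objects), mapping
    raise RuntimeError("could not draw a stream with a fresh object-key mapping")


def build_run_schedule(
    run: int,
    sequences: SequencePair,
    rng: np.random.Generator,
    subject: int = 1,
    max_consecutive: int = 2,
    isi_range: tuple[float, float] = ISI_RANGE_S,
    exclude_learned: bool = True,
) -> RunSchedule:
    """Build one scanning run: 15 streams, 120 cue events, 3 rest periods."""
    order = _sample_condition_order(rng, max_consecutive=max_consecutive)
    rest_after = _sample_rest_slots(rng)
    rows = []
    t = 0.0
    prev_mapping: dict | None = None
    for block_idx, condition in enumerate(order, start=1):
        keys, objects, prev_mapping = _stream_items(
            condition, sequences, rng, prev_mapping, exclude_learned
        )
        for pos in range(1, N_POSITIONS + 1):
            isi = float(rng.uniform(*isi_range))
            rows.append({
                "subject": subject, "run": run, "block": block_idx,
                "condition": condition, "position": pos,
                "key": keys[pos - 1], "object": objects[pos - 1],
                "onset_s": round(t, 6), "isi_s": round(isi, 6),
            })
            t += isi
        if block_idx in rest_after:
            t += REST_DURATION_S
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return RunSchedule(run=run, condition_order=order,
                       rest_after_block=rest_after, events=events)


def _behavioral_session(
    subject: int, session: int, trained_condition: str,
    sequences: SequencePair, rng: np.random.Generator,
    exclude_learned: bool,
) -> pd.DataFrame:
    """One day-1 session: 4 random, 20 training, 4 test blocks (RSI 0.75 s)."""
    phases = (
        [("random", "RD")] * 4
        + [("training", trained_condition)] * 20
        + [("test", trained_condition)] * 4
    )
    rows = []
    prev_mapping: dict | None = None
    for block_idx, (phase, condition) in enumerate(phases, start=1):
        for _rep in range(BLOCKS_PER_CONDITION):
            keys, objects, prev_mapping = _stream_items(
                condition, sequences, rng, prev_mapping, exclude_learned
            )
            for pos in range(1, N_POSITIONS + 1):
                rows.append({
                    "subject": subject, "session": session, "phase": phase,
                    "block": block_idx, "condition": condition, "position": pos,
                    "key": keys[pos - 1], "object": objects[pos - 1],
                    "rsi_s": BEHAVIORAL_RSI_S,
                })
    return pd.DataFrame(rows)


def build_full_protocol(
    n_subjects: int,
    seed: int,
    exclude_learned: bool = True,
    with_behavior: bool = True,
) -> list[SubjectProtocol]:
    """Generate the complete protocol for a cohort.

    Each subject gets a rotation ``(subject - 1) % 8``, eight scanning runs
    (40 stream repetitions per condition in total) and, optionally, the two
    behavioral training sessions (motor-first for odd subjects, object-first
    for even — recorded as metadata only).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    subjects = []
    root = np.random.SeedSequence(seed)
    for subject, child in enumerate(root.spawn(n_subjects), start=1):
        rng = np.random.default_rng(child)
        sequences = make_sequence_pair((subject - 1) % N_POSITIONS)
        runs = [
            build_run_schedule(run, sequences, rng, subject=subject,
                               exclude_learned=exclude_learned)
            for run in range(1, N_RUNS + 1)
        ]
        behavior = None
        if with_behavior:
            first = "SQ_MOT" if subject % 2 else "SQ_OBJ"
            second = "SQ_OBJ" if subject % 2 else "SQ_MOT"
            behavior = pd.concat(
                [
                    _behavioral_session(subject, 1, first, sequences, rng, exclude_learned),
                    _behavioral_session(subject, 2, second, sequences, rng, exclude_learned),
                ],
                ignore_index=True,
            )
        subjects.append(SubjectProtocol(subject=subject, sequences=sequences,
                                        runs=runs, behavior=behavior))
    return subjects


# ---------------------------------------------------------------------------
# BIDS-style events TSV round trip
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "onset", "duration", "trial_type", "subject", "run", "block",
    "position", "key", "object", "isi_s",
]


def events_filename(subject: int, run: int) -> str:
    return f"sub-{subject:02d}_run-{run:02d}_events.tsv"


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write a TrialEvent table as a BIDS-dialect events TSV.

    Cue events are modelled as delta functions, so ``duration`` is 0 for
    every row; the condition goes into ``trial_type``.
    """
    out = pd.DataFrame({
        "onset": events["onset_s"],
        "duration": 0.0,
        "trial_type": events["condition"],
        "subject": events["subject"],
        "run": events["run"],
        "block": events["block"],
        "position": events["position"],
        "key": events["key"],
        "object": events["object"],
        "isi_s": events["isi_s"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an events TSV back into the TrialEvent layout.

    Raises
    ------
    ValueError
        If a required column is missing, or a row fails to parse (the error
        names the 1-based data line).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    numeric = {"onset": float, "duration": float, "isi_s": float,
               "subject": int, "run": int, "block": int, "position": int, "key": int}
    for col, typ in numeric.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}: malformed value in column '{col}' at data line {bad + 1}"
            ) from None
    return pd.DataFrame({
        "subject": df["subject"], "run": df["run"], "block": df["block"],
        "condition": df["trial_type"], "position": df["position"],
        "key": df["key"], "object": df["object"],
        "onset_s": df["onset"], "isi_s": df["isi_s"],
    })
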