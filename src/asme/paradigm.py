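"""Stimulus paradigm: 30-class QWERTY/stream layout and pseudorandomized schedules.

The speller maps the three QWERTY keyboard rows onto three auditory streams
(top row -> high-pitched stream, middle -> mid, bottom -> low).  A *sequence*
presents each of the 30 classes exactly once, interleaved as ten triplets that
cycle the streams in the fixed order low, mid, high; within each stream the
ten class order is an independent uniform permutation per sequence.  A *trial*
is ``n_sequences`` consecutive sequences attending one target class; a *run*
holds several trials; a *session* is a plan of offline (training) and online
(evaluation) runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

Stream = Literal["low", "mid", "high"]
Row = Literal["bottom", "middle", "top"]

#: fixed stream cycling order within each triplet of a sequence
STREAM_ORDER: tuple[Stream, ...] = ("low", "mid", "high")

_ROW_OF_STREAM: dict[Stream, Row] = {"low": "bottom", "mid": "middle", "high": "top"}

#: keyboard rows; symbols: comma joins the middle row, space/delete/period the bottom
_TOP = list("QWERTYUIOP")
_MIDDLE = list("ASDFGHJKL") + [","]
_BOTTOM = list("ZXCVBNM") + ["<space>", "<delete>", "."]

N_CLASSES = 30
CLASSES_PER_STREAM = 10
DEFAULT_SOA_S = 0.2
DEFAULT_N_SEQUENCES = 15


@dataclass(frozen=True)
class StimulusClass:
    """One selectable letter/symbol and its stream/row assignment."""

    class_id: int
    label: str
    stream: Stream

    @property
    def row(self) -> Row:
        return _ROW_OF_STREAM[self.stream]


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus presentation within a trial."""

    run: int
    trial: int
    sequence: int  # 1-based
    slot: int  # 0..29 position within the sequence
    class_id: int
    stream: Stream
    onset_s: float  # seconds from trial start
    is_target: bool


@dataclass
class TrialSchedule:
    """Ordered stimulus events for one letter-selection trial."""

    target: int
    soa_s: float
    n_sequences: int
    events: list[StimulusEvent]

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self, layout: Sequence[StimulusClass] | None = None) -> pd.DataFrame:
        layout = default_layout() if layout is None else list(layout)
        labels = {c.class_id: c.label for c in layout}
        rows = [
            {
                "onset_s": e.onset_s,
                "run": e.run,
                "trial": e.trial,
                "sequence": e.sequence,
                "slot": e.slot,
                "class_id": e.class_id,
                "label": labels[e.class_id],
                "stream": e.stream,
                "is_target": e.is_target,
            }
            for e in self.events
        ]
        return pd.DataFrame(rows)


@dataclass
class SessionPlan:
    """Targets for every trial of a session, split into offline/online runs.

    ``runs`` is a list of ``(phase, targets)`` with phase ``"offline"`` or
    ``"online"`` and targets a list of class ids (one per trial).
    """

    runs: list[tuple[str, list[int]]]
    seed: int
    soa_s: float = DEFAULT_SOA_S
    n_sequences: int = DEFAULT_N_SEQUENCES

    @property
    def offline_runs(self) -> list[list[int]]:
        return [t for phase, t in self.runs if phase == "offline"]

    @property
    def online_runs(self) -> list[list[int]]:
        return [t for phase, t in self.runs if phase == "online"]

    def to_yaml(self) -> str:
        doc = {
            "seed": int(self.seed),
            "soa_s": float(self.soa_s),
            "n_sequences": int(self.n_sequences),
            "runs": [
                {"phase": phase, "targets": [int(t) for t in targets]}
                for phase, targets in self.runs
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SessionPlan":
        doc = yaml.safe_load(text)
        runs = [(r["phase"], list(r["targets"])) for r in doc["runs"]]
        return cls(
            runs=runs,
            seed=doc["seed"],
            soa_s=doc.get("soa_s", DEFAULT_SOA_S),
            n_sequences=doc.get("n_sequences", DEFAULT_N_SEQUENCES),
        )


def default_layout() -> list[StimulusClass]:
    """The 30-class layout: class ids run top row (Q..P), middle (A..L, comma),
    bottom (Z..M, space, delete, period); streams high/mid/low respectively."""
    classes: list[StimulusClass] = []
    for labels, stream in ((_TOP, "high"), (_MIDDLE, "mid"), (_BOTTOM, "low")):
        for label in labels:
            classes.append(StimulusClass(len(classes), label, stream))
    assert len(classes) == N_CLASSES
    return classes


def layout_by_stream(layout: Sequence[StimulusClass]) -> dict[Stream, list[int]]:
    out: dict[Stream, list[int]] = {s: [] for s in STREAM_ORDER}
    for c in layout:
        out[c.stream].append(c.class_id)
    return out


def _child_rng(master_seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-trial generator: SeedSequence(master, spawn_key=path)."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=path))


def make_trial_schedule(
    layout: Sequence[StimulusClass],
    target: int,
    n_sequences: int = DEFAULT_N_SEQUENCES,
    soa_s: float = DEFAULT_SOA_S,
    rng_seed: int | np.random.Generator = 0,
    run: int = 0,
    trial: int = 0,
) -> TrialSchedule:
    """Generate one trial's pseudorandomized stimulus schedule.

    Each sequence holds ten triplets cycling the streams low, mid, high; the
    ten stimuli of each stream are an independent uniform permutation per
    sequence.  Onsets lie on the SOA grid: event ``i`` starts at ``i * soa_s``.
    """
    if n_sequences < 1:
        raise ValueError(f"n_sequences must be >= 1, got {n_sequences}")
    if soa_s <= 0:
        raise ValueError(f"soa_s must be positive, got {soa_s}")
    ids = {c.class_id for c in layout}
    if target not in ids:
        raise ValueError(f"unknown target class_id {target}")

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    streams = layout_by_stream(layout)
    events: list[StimulusEvent] = []
    gi = 0
    for seq in range(1, n_sequences + 1):
        perms = {s: rng.permutation(streams[s]) for s in STREAM_ORDER}
        for triplet in range(CLASSES_PER_STREAM):
            for slot_in_triplet, stream in enumerate(STREAM_ORDER):
                cid = int(perms[stream][triplet])
                events.append(
                    StimulusEvent(
                        run=run,
                        trial=trial,
                        sequence=seq,
                        slot=triplet * len(STREAM_ORDER) + slot_in_triplet,
                        class_id=cid,
                        stream=stream,
                        onset_s=gi * soa_s,
                        is_target=cid == target,
                    )
                )
                gi += 1
    return TrialSchedule(target=target, soa_s=soa_s, n_sequences=n_sequences, events=events)


def make_session_plan(
    layout: Sequence[StimulusClass],
    seed: int,
    offline_runs: int = 6,
    online_runs: int = 3,
    trials_per_run: int = 5,
    online_targets: Sequence[int] | None = None,
    soa_s: float = DEFAULT_SOA_S,
    n_sequences: int = DEFAULT_N_SEQUENCES,
) -> SessionPlan:
    """Plan a session: offline targets cover all 30 classes once (seeded
    permutation partitioned into runs); online targets default to a seeded
    choice of ``online_runs * trials_per_run`` distinct classes."""
    n_classes = len(layout)
    if offline_runs * trials_per_run < n_classes:
        raise ValueError(
            f"{offline_runs} offline runs x {trials_per_run} trials cannot cover "
            f"{n_classes} classes"
        )
    if offline_runs * trials_per_run != n_classes:
        raise ValueError(
            "default plan requires offline_runs * trials_per_run == class count"
        )
    rng = _child_rng(seed, 0)
    ids = np.array(sorted(c.class_id for c in layout))
    offline_order = rng.permutation(ids)
    runs: list[tuple[str, list[int]]] = [
        ("offline", [int(t) for t in offline_order[i * trials_per_run : (i + 1) * trials_per_run]])
        for i in range(offline_runs)
    ]

    n_online = online_runs * trials_per_run
    if online_targets is None:
        online_targets = rng.choice(ids, size=n_online, replace=False)
    online_targets = [int(t) for t in online_targets]
    if len(online_targets) != n_online:
        raise ValueError(f"need {n_online} online targets, got {len(online_targets)}")
    for i in range(online_runs):
        runs.append(("online", online_targets[i * trials_per_run : (i + 1) * trials_per_run]))
    return SessionPlan(runs=runs, seed=seed, soa_s=soa_s, n_sequences=n_sequences)


def session_schedules(
    plan: SessionPlan, layout: Sequence[StimulusClass] | None = None
) -> list[list[TrialSchedule]]:
    """Deterministic schedules for every run of a plan (child seed per trial)."""
    layout = default_layout() if layout is None else list(layout)
    out: list[list[TrialSchedule]] = []
    for run_idx, (_phase, targets) in enumerate(plan.runs):
        run_scheds = []
        for trial_idx, target in enumerate(targets):
            rng = _child_rng(plan.seed, 1, run_idx, trial_idx)
            run_scheds.append(
                make_trial_schedule(
                    layout,
                    target,
                    n_sequences=plan.n_sequences,
                    soa_s=plan.soa_s,
                    rng_seed=rng,
                    run=run_idx,
                    trial=trial_idx,
                )
            )
        out.append(run_scheds)
    return out


def events_to_tsv(frames: pd.DataFrame | Sequence[pd.DataFrame], path) -> None:
    """Write stimulus events as a TSV (one row per stimulus, '.' decimal)."""
    if not isinstance(frames, pd.DataFrame):
        frames = pd.concat(list(frames), ignore_index=True)
    frames.to_csv(path, sep="\t", index=False)


def events_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def layout_to_yaml(layout: Sequence[StimulusClass]) -> str:
    return yaml.safe_dump(
        [
            {"class_id": c.class_id, "label": c.label, "stream": c.stream, "row": c.row}
            for c in layout
        ],
        sort_keys=False,
        allow_unicode=True,
    )
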