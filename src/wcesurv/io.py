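"""Reading and writing trial event tables and event-type catalogs.

The trial table is a long-format CSV with one row per (subject, event-time,
event-type) and the header ``subject_id,arm,time,event_type``.  Event-free
subjects appear with a single sentinel row whose ``event_type`` is ``NONE``
and whose ``time`` equals the follow-up length, so the sample size of each
arm is recoverable from the file alone.

The event-type catalog maps each event type to a severity weight in (0, 1];
exactly one type — the terminal one (death) — carries weight 1.  Catalogs are
read from CSV (``event_type,weight,terminal``) or YAML.

The method requires complete follow-up: every subject is observed to the end
of follow-up or to a terminal event, and files carrying an explicit censoring
marker are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NO_EVENT_SENTINEL = "NONE"
#: event_type values that denote right censoring; their presence is an error.
CENSOR_MARKERS = frozenset({"CENSOR", "CENSORED", "CENS", "LOST", "LTFU"})


class ValidationError(ValueError):
    """Raised when an input table or catalog violates the method's contract."""


@dataclass(frozen=True)
class EventTypeCatalog:
    """Ordered set of event types with severity weights and a terminal marker.

    Parameters
    ----------
    types
        Event-type labels, e.g. ``("REMI", "CHF", "SHK", "DTH")``.
    weights
        Severity weight per type, each in (0, 1].  Exactly one weight must be
        1.0 and it must belong to the terminal type.
    terminal_index
        Position of the terminal (death) type in ``types``.
    """

    types: tuple[str, ...]
    weights: tuple[float, ...]
    terminal_index: int

    def __post_init__(self) -> None:
        if len(self.types) != len(set(self.types)):
            raise ValidationError("event-type labels must be unique")
        if len(self.weights) != len(self.types):
            raise ValidationError("weights and types must have equal length")
        for label, w in zip(self.types, self.weights):
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"weight for {label!r} is {w}; weights must lie in (0, 1]"
                )
        if not 0 <= self.terminal_index < len(self.types):
            raise ValidationError("terminal_index out of range")
        ones = [i for i, w in enumerate(self.weights) if w == 1.0]
        if ones != [self.terminal_index]:
            raise ValidationError(
                "exactly one type must have weight 1.0 and be marked terminal"
            )
        if NO_EVENT_SENTINEL in self.types or CENSOR_MARKERS & set(self.types):
            raise ValidationError("reserved label used as an event type")

    @property
    def weight_vector(self) -> np.ndarray:
        """Severity weights W as a float array of length K."""
        return np.asarray(self.weights, dtype=float)

    @property
    def terminal_type(self) -> str:
        return self.types[self.terminal_index]

    @property
    def n_types(self) -> int:
        return len(self.types)

    def weight_of(self, label: str) -> float:
        return self.weights[self.types.index(label)]

    def index_of(self, label: str) -> int:
        return self.types.index(label)

    @classmethod
    def mace_default(cls) -> "EventTypeCatalog":
        """The four-component MACE catalog with stakeholder severity weights:
        recurrent MI 0.2, heart failure 0.3, cardiogenic shock 0.5, death 1.0.
        """
        return cls(("REMI", "CHF", "SHK", "DTH"), (0.2, 0.3, 0.5, 1.0), 3)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "EventTypeCatalog":
        required = {"event_type", "weight", "terminal"}
        if not required <= set(frame.columns):
            raise ValidationError(
                f"catalog needs columns {sorted(required)}, got {list(frame.columns)}"
            )
        terminal = frame["terminal"].astype(bool).to_numpy()
        if terminal.sum() != 1:
            raise ValidationError("catalog must mark exactly one terminal type")
        return cls(
            tuple(str(t) for t in frame["event_type"]),
            tuple(float(w) for w in frame["weight"]),
            int(np.flatnonzero(terminal)[0]),
        )

    @classmethod
    def read(cls, path: str | Path) -> "EventTypeCatalog":
        """Read a catalog from CSV (``event_type,weight,terminal``) or YAML."""
        path = Path(path)
        if path.suffix.lower() in {".yml", ".yaml"}:
            spec = yaml.safe_load(path.read_text())
            frame = pd.DataFrame(spec["event_types"])
            return cls.from_frame(frame)
        return cls.from_frame(pd.read_csv(path))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "event_type": self.types,
                "weight": self.weights,
                "terminal": [i == self.terminal_index for i in range(self.n_types)],
            }
        ).to_csv(path, index=False)


@dataclass
class SubjectHistory:
    """One subject's complete follow-up: ordered (time, event-type) pairs.

    Times are days in (0, followup].  A terminal event, if present, occurs at
    most once and is the last event.  There is no censoring: the subject is
    observed to ``followup`` or to the terminal event.
    """

    subject_id: str
    arm: str
    events: list[tuple[float, str]] = field(default_factory=list)
    followup: float = 30.0

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e[0])

    def validate(self, catalog: EventTypeCatalog) -> None:
        terminal = catalog.terminal_type
        last_time = 0.0
        seen = set()
        for time, label in self.events:
            if label not in catalog.types:
                raise ValidationError(
                    f"subject {self.subject_id}: unknown event type {label!r}"
                )
            if not (0.0 < time <= self.followup) or not math.isfinite(time):
                raise ValidationError(
                    f"subject {self.subject_id}: time {time} outside (0, {self.followup}]"
                )
            if (time, label) in seen:
                raise ValidationError(
                    f"subject {self.subject_id}: duplicate row ({time}, {label})"
                )
            seen.add((time, label))
            last_time = time
        terminal_times = [t for t, lab in self.events if lab == terminal]
        if len(terminal_times) > 1:
            raise ValidationError(
                f"subject {self.subject_id}: more than one terminal event"
            )
        if terminal_times and terminal_times[0] < last_time:
            raise ValidationError(
                f"subject {self.subject_id}: event after terminal event at "
                f"day {terminal_times[0]:g}"
            )

    @property
    def is_event_free(self) -> bool:
        return not self.events

    def first_event_time(self) -> float | None:
        return self.events[0][0] if self.events else None


TrialArms = dict[str, list[SubjectHistory]]


def _histories_from_frame(
    frame: pd.DataFrame, catalog: EventTypeCatalog, followup: float
) -> TrialArms:
    required = ["subject_id", "arm", "time", "event_type"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"trial table missing columns {missing}")
    extra_censor = {"censored", "censor", "status"} & set(frame.columns)
    if extra_censor:
        raise ValidationError(
            f"column(s) {sorted(extra_censor)} look like censoring indicators; "
            "the weighted composite endpoint method excludes right censoring"
        )

    arms: TrialArms = {}
    by_subject: dict[str, SubjectHistory] = {}
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        sid = str(row.subject_id)
        arm = str(row.arm)
        label = str(row.event_type).strip()
        if label.upper() in CENSOR_MARKERS:
            raise ValidationError(
                f"row {row_no}: censoring marker {label!r}; the weighted composite "
                "endpoint method excludes right censoring"
            )
        try:
            time = float(row.time)
        except (TypeError, ValueError):
            raise ValidationError(f"row {row_no}: non-numeric time {row.time!r}")
        if sid not in by_subject:
            hist = SubjectHistory(sid, arm, [], followup)
            by_subject[sid] = hist
            arms.setdefault(arm, []).append(hist)
        hist = by_subject[sid]
        if hist.arm != arm:
            raise ValidationError(f"row {row_no}: subject {sid} appears in two arms")
        if label == NO_EVENT_SENTINEL:
            continue  # roster row: keeps n recoverable, contributes no event
        if label not in catalog.types:
            raise ValidationError(f"row {row_no}: unknown event type {label!r}")
        if not (0.0 < time <= followup):
            raise ValidationError(
                f"row {row_no}: time {time:g} outside (0, {followup:g}]"
            )
        hist.events.append((time, label))

    for hist in by_subject.values():
        hist.events.sort(key=lambda e: e[0])
        hist.validate(catalog)
    return arms


def read_trial_table(
    path: str | Path, catalog: EventTypeCatalog, followup: float
) -> TrialArms:
    """Read a long-format trial CSV into per-arm lists of :class:`SubjectHistory`.

    Raises :class:`ValidationError`, naming the offending row, for unknown
    event types, times outside (0, followup], events after a terminal event,
    duplicate identical rows, or explicit censoring markers.
    """
    # round_trip parsing keeps write/read an exact identity on float times
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return _histories_from_frame(frame, catalog, followup)


def write_trial_table(
    arms: TrialArms | Iterable[SubjectHistory],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write histories to the trial CSV, emitting NONE roster rows for
    event-free subjects."""
    if isinstance(arms, Mapping):
        histories: list[SubjectHistory] = [h for hs in arms.values() for h in hs]
    else:
        histories = list(arms)
    rows = []
    for hist in histories:
        if hist.is_event_free:
            rows.append((hist.subject_id, hist.arm, hist.followup, NO_EVENT_SENTINEL))
        else:
            for time, label in hist.events:
                rows.append((hist.subject_id, hist.arm, time, label))
    frame = pd.DataFrame(rows, columns=["subject_id", "arm", "time", "event_type"])
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)


def subjects_per_arm(arms: TrialArms) -> dict[str, int]:
    return {arm: len(hs) for arm, hs in arms.items()}
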