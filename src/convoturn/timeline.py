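"""Communicative-state containers: IPUs, turns, overlaps-within, FTOs.

Conventions
-----------
All intervals are half-open ``[start, end)`` in seconds (floats); FTO values
are reported in milliseconds. A *turn* is a sequence of connected
inter-pausal units (IPUs) from one speaker, including internal pauses,
bounded by floor transfers. An *overlap-within* is speech uttered
completely within the other interlocutor's turn; it does not transfer the
floor. The floor-transfer offset (FTO) between consecutive turns is
``onset(incoming) - offset(outgoing)``: positive for a gap, negative for an
overlapped start.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

__all__ = [
    "IPU",
    "Turn",
    "OverlapWithin",
    "FTORecord",
    "ConversationTimeline",
    "TimelineSummary",
    "summarize_timeline",
]


@dataclass(frozen=True)
class IPU:
    """A maximal stretch of one speaker's speech, gaps merged below a threshold."""

    speaker_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"IPU end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Turn:
    """Connected IPUs of one speaker, with internal pauses, between floor transfers."""

    speaker_id: str
    ipus: list[IPU]
    internal_pauses: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ipus:
            raise ValueError("a turn requires at least one IPU")
        if any(ipu.speaker_id != self.speaker_id for ipu in self.ipus):
            raise ValueError("all IPUs of a turn must share its speaker")
        for ps, pe in self.internal_pauses:
            if not (self.start < ps < pe < self.end):
                raise ValueError("internal pauses must lie strictly inside the turn")

    @property
    def start(self) -> float:
        return self.ipus[0].start

    @property
    def end(self) -> float:
        return self.ipus[-1].end

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def speech_duration(self) -> float:
        """Total IPU (speech-only) duration, pauses excluded."""
        return sum(ipu.duration for ipu in self.ipus)


@dataclass
class OverlapWithin:
    """Speech nested entirely inside the other speaker's turn."""

    speaker_id: str
    start: float
    end: float
    host_turn_index: int
    rel_offset: float  # start - host turn start

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("overlap-within end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


class FTORecord(NamedTuple):
    """One floor transfer: value in ms, outgoing and incoming speakers, index."""

    value: float
    from_speaker: str
    to_speaker: str
    transfer_index: int


class TimelineSummary(NamedTuple):
    n_turns: int
    n_overlaps_within: int
    duration_s: float
    turn_change_count: int


@dataclass
class ConversationTimeline:
    """Turns, overlaps-within and FTOs of one dyadic conversation segment."""

    turns: list[Turn]
    overlaps_within: list[OverlapWithin] = field(default_factory=list)
    ftos: list[FTORecord] = field(default_factory=list)
    segment_id: str = "segment"
    total_duration: float | None = None

    def __post_init__(self) -> None:
        if self.total_duration is None:
            ends = [t.end for t in self.turns] + [o.end for o in self.overlaps_within]
            self.total_duration = max(ends) if ends else 0.0

    def validate(self, atol: float = 1e-6) -> None:
        """Check all structural invariants; raise ValueError on violation."""
        for prev, nxt in zip(self.turns[:-1], self.turns[1:]):
            if prev.speaker_id == nxt.speaker_id:
                raise ValueError("consecutive turns must alternate speakers")
        if self.turns and len(self.ftos) != len(self.turns) - 1:
            raise ValueError("len(ftos) must equal len(turns) - 1")
        for i, rec in enumerate(self.ftos):
            expect = (self.turns[i + 1].start - self.turns[i].end) * 1000.0
            if abs(rec.value - expect) > atol * 1000.0:
                raise ValueError(f"FTO {i} value {rec.value} != turn-gap {expect}")
            if rec.from_speaker == rec.to_speaker:
                raise ValueError("FTO endpoints must differ in speaker")
        for ov in self.overlaps_within:
            host = self.turns[ov.host_turn_index]
            if ov.speaker_id == host.speaker_id:
                raise ValueError("overlap-within speaker must differ from its host")
            if ov.start < host.start - atol or ov.end > host.end + atol:
                raise ValueError("overlap-within must lie inside its host turn")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "segment_id": self.segment_id,
            "total_duration": self.total_duration,
            "turns": [
                {
                    "speaker": t.speaker_id,
                    "ipus": [[i.start, i.end] for i in t.ipus],
                    "internal_pauses": [list(p) for p in t.internal_pauses],
                }
                for t in self.turns
            ],
            "overlaps_within": [
                {
                    "speaker": o.speaker_id,
                    "start": o.start,
                    "end": o.end,
                    "host_turn_index": o.host_turn_index,
                    "rel_offset": o.rel_offset,
                }
                for o in self.overlaps_within
            ],
            "ftos": [rec._asdict() for rec in self.ftos],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConversationTimeline":
        turns = [
            Turn(
                speaker_id=t["speaker"],
                ipus=[IPU(t["speaker"], s, e) for s, e in t["ipus"]],
                internal_pauses=[tuple(p) for p in t["internal_pauses"]],
            )
            for t in d["turns"]
        ]
        overlaps = [
            OverlapWithin(
                speaker_id=o["speaker"],
                start=o["start"],
                end=o["end"],
                host_turn_index=o["host_turn_index"],
                rel_offset=o["rel_offset"],
            )
            for o in d["overlaps_within"]
        ]
        ftos = [FTORecord(**rec) for rec in d["ftos"]]
        return cls(
            turns=turns,
            overlaps_within=overlaps,
            ftos=ftos,
            segment_id=d.get("segment_id", "segment"),
            total_duration=d.get("total_duration"),
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load_json(cls, path: str | Path) -> "ConversationTimeline":
        return cls.from_dict(json.loads(Path(path).read_text()))


def summarize_timeline(timeline: ConversationTimeline) -> TimelineSummary:
    """Basic counts: turns, overlaps-within, duration, turn changes (= FTOs)."""
    return TimelineSummary(
        n_turns=len(timeline.turns),
        n_overlaps_within=len(timeline.overlaps_within),
        duration_s=float(timeline.total_duration),
        turn_change_count=len(timeline.ftos),
    )
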