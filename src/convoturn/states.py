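"""Communicative-state classification: IPU building, turn/overlap assignment, FTOs.

The classifier walks both speakers' IPUs in chronological order and keeps
track of who holds the floor. An IPU of the non-floor-holding speaker is an
overlap-within when it lies entirely inside a single IPU of the floor
holder: the host speaks throughout, so the interjection never holds the
floor alone. In every other case — the IPU starts in the host's silence,
outlasts the host's vocalisation, or bridges a host pause — there is a
moment where the interjector speaks alone, and the floor transfers: a
positive FTO when a silent gap separates the turns, a negative FTO when
the incoming turn starts while the outgoing speaker is still talking.
This is the segment-logic (gap / pause / overlap-between / overlap-within)
convention of the turn-taking literature.
"""

from __future__ import annotations

from .timeline import IPU, Turn, OverlapWithin, FTORecord, ConversationTimeline
from .vad import ActivityMask, mask_to_intervals

__all__ = ["build_ipus", "classify_states", "extract_ftos", "DEFAULT_MAX_IPU_GAP_MS"]

#: Within-speaker silences at or below this merge into a single IPU.
DEFAULT_MAX_IPU_GAP_MS = 180.0

#: Onsets closer than this count as simultaneous for tie-breaking (ms).
_SIMULTANEITY_MS = 1.0


def build_ipus(mask: ActivityMask, max_ipu_gap_ms: float = DEFAULT_MAX_IPU_GAP_MS) -> list[IPU]:
    """Merge speech runs separated by at most ``max_ipu_gap_ms`` into IPUs."""
    gap_s = max_ipu_gap_ms / 1000.0
    merged: list[list[float]] = []
    for s, e in mask_to_intervals(mask):
        if merged and s - merged[-1][1] <= gap_s + 1e-12:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [IPU(mask.speaker_id, s, e) for s, e in merged]


def _validate_disjoint(ipus: list[IPU], label: str) -> None:
    for a, b in zip(ipus[:-1], ipus[1:]):
        if b.start < a.end:
            raise ValueError(f"IPUs of speaker {label} must be disjoint and ordered")


def classify_states(
    ipus_a: list[IPU],
    ipus_b: list[IPU],
    segment_id: str = "segment",
    total_duration: float | None = None,
) -> ConversationTimeline:
    """Assign every IPU to a turn or an overlap-within and extract FTOs.

    Raises
    ------
    ValueError
        If both IPU lists are empty ("no speech") or either list is
        internally overlapping.
    """
    if not ipus_a and not ipus_b:
        raise ValueError("no speech: both IPU lists are empty")
    _validate_disjoint(ipus_a, "A")
    _validate_disjoint(ipus_b, "B")

    lists = {}
    if ipus_a:
        lists[ipus_a[0].speaker_id] = list(ipus_a)
    if ipus_b:
        lists[ipus_b[0].speaker_id] = list(ipus_b)
    idx = {s: 0 for s in lists}
    order = sorted(lists)  # deterministic label order for ties

    def remaining(s: str) -> IPU | None:
        return lists[s][idx[s]] if idx[s] < len(lists[s]) else None

    def pick_next() -> IPU:
        cands = [(s, remaining(s)) for s in order if remaining(s) is not None]
        cands.sort(key=lambda c: c[1].start)
        if len(cands) == 2:
            a, b = cands[0][1], cands[1][1]
            if abs(a.start - b.start) < _SIMULTANEITY_MS / 1000.0 and b.end > a.end:
                # simultaneous onsets: the speaker who continues longer wins
                cands = [cands[1], cands[0]]
        s, ipu = cands[0]
        idx[s] += 1
        return ipu

    turns: list[Turn] = []
    overlaps: list[OverlapWithin] = []
    cur_speaker: str | None = None
    cur_ipus: list[IPU] = []
    cur_pauses: list[tuple[float, float]] = []

    def close_turn() -> None:
        nonlocal cur_ipus, cur_pauses
        turns.append(Turn(speaker_id=cur_speaker, ipus=cur_ipus, internal_pauses=cur_pauses))
        cur_ipus, cur_pauses = [], []

    eps = 1e-9

    def nested_in_host_ipu(start: float, end: float) -> bool:
        """Does [start, end] lie entirely inside one floor-holder IPU?"""
        return any(
            ipu.start - eps <= start and end <= ipu.end + eps
            for ipu in lists[cur_speaker]
        )

    n_total = sum(len(v) for v in lists.values())
    for _ in range(n_total):
        ipu = pick_next()
        if cur_speaker is None:
            cur_speaker = ipu.speaker_id
            cur_ipus = [ipu]
        elif ipu.speaker_id == cur_speaker:
            prev_end = cur_ipus[-1].end
            if ipu.start > prev_end:
                cur_pauses.append((prev_end, ipu.start))
            cur_ipus.append(ipu)
        else:
            if nested_in_host_ipu(ipu.start, ipu.end):
                overlaps.append(
                    OverlapWithin(
                        speaker_id=ipu.speaker_id,
                        start=ipu.start,
                        end=ipu.end,
                        host_turn_index=len(turns),
                        rel_offset=ipu.start - cur_ipus[0].start,
                    )
                )
            else:
                close_turn()
                cur_speaker = ipu.speaker_id
                cur_ipus = [ipu]
    close_turn()

    timeline = ConversationTimeline(
        turns=turns,
        overlaps_within=overlaps,
        segment_id=segment_id,
        total_duration=total_duration,
    )
    timeline.ftos = extract_ftos(timeline)
    timeline.validate()
    return timeline


def extract_ftos(timeline: ConversationTimeline) -> list[FTORecord]:
    """Floor-transfer offsets in ms between consecutive turns.

    Fewer than two turns yield an empty list.
    """
    records = []
    for i, (out_t, in_t) in enumerate(zip(timeline.turns[:-1], timeline.turns[1:])):
        records.append(
            FTORecord(
                value=(in_t.start - out_t.end) * 1000.0,
                from_speaker=out_t.speaker_id,
                to_speaker=in_t.speaker_id,
                transfer_index=i,
            )
        )
    return records
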