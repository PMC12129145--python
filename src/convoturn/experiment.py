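"""Presentation-list construction for the listening experiment.

The design: 32 conversation segments (4 speaker pairs x 8 segments), each
manipulated under one of the four FTO schemes such that every scheme is
applied to exactly two randomly chosen segments of every pair (8 stimuli
per scheme per list). Ten lists are generated; each list redraws the NHQ
(and hence HIN) FTO values, so 80 distinct NHQ renderings exist across
lists. Participants hear the 32 stimuli of one list in randomised order
and rate naturalness, flow and ease-of-following on a five-anchor visual
analogue scale, with a self-paced break after every eighth stimulus.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seeds import child_seed

__all__ = ["SegmentRef", "PresentationList", "build_lists", "describe_protocol"]

N_PAIRS = 4
SEGMENTS_PER_PAIR = 8
SCHEMES = ("conLow", "conNHQ", "NHQ", "HIN")


@dataclass(frozen=True)
class SegmentRef:
    """One selectable conversation segment of one speaker pair."""

    pair_id: int
    segment_idx: int
    duration_s: float = 32.2
    n_transfers: int = 18

    def __post_init__(self) -> None:
        if not 12 <= self.n_transfers <= 25:
            raise ValueError("segments carry 12-25 turn changes")
        if not 29.0 <= self.duration_s <= 36.9:
            raise ValueError("segment durations lie in 29.0-36.9 s")


@dataclass
class PresentationList:
    """One participant-facing list: 32 (segment, scheme, seed) stimuli."""

    list_id: int
    assignments: list[tuple[SegmentRef, str, int]]
    order: list[int]  # presentation permutation over assignment indices

    def validate(self) -> None:
        if len(self.assignments) != N_PAIRS * SEGMENTS_PER_PAIR:
            raise ValueError("a list must contain exactly 32 stimuli")
        if sorted(self.order) != list(range(len(self.assignments))):
            raise ValueError("order must be a permutation of the stimuli")
        per_scheme: dict[str, int] = {s: 0 for s in SCHEMES}
        per_pair_scheme: dict[tuple[int, str], int] = {}
        seen = set()
        for seg, scheme, _seed in self.assignments:
            key = (seg.pair_id, seg.segment_idx)
            if key in seen:
                raise ValueError(f"segment {key} used more than once")
            seen.add(key)
            per_scheme[scheme] += 1
            per_pair_scheme[(seg.pair_id, scheme)] = (
                per_pair_scheme.get((seg.pair_id, scheme), 0) + 1
            )
        if any(v != SEGMENTS_PER_PAIR for v in per_scheme.values()):
            raise ValueError(f"expected 8 stimuli per scheme, got {per_scheme}")
        if any(v != 2 for v in per_pair_scheme.values()):
            raise ValueError("every (pair, scheme) cell must hold exactly 2 segments")


def build_lists(
    segments: list[SegmentRef], n_lists: int = 10, master_seed: int = 0
) -> list[PresentationList]:
    """Build counterbalanced presentation lists, reproducible from the seed.

    Requires exactly 4 pairs x 8 segments. Within each list and pair, the
    8 segments are randomly permuted over the four schemes (2 each); NHQ and
    HIN stimulus seeds differ across lists so FTO draws never repeat.
    """
    by_pair: dict[int, list[SegmentRef]] = {}
    for seg in segments:
        by_pair.setdefault(seg.pair_id, []).append(seg)
    if len(by_pair) != N_PAIRS or any(
        len(v) != SEGMENTS_PER_PAIR for v in by_pair.values()
    ):
        raise ValueError(
            "segment inventory must hold exactly 4 pairs with 8 segments each; got "
            + str({k: len(v) for k, v in sorted(by_pair.items())})
        )
    lists = []
    for lid in range(1, n_lists + 1):
        rng = np.random.default_rng(child_seed(master_seed, "list", lid))
        assignments: list[tuple[SegmentRef, str, int]] = []
        for pair_id in sorted(by_pair):
            segs = list(by_pair[pair_id])
            rng.shuffle(segs)
            for i, seg in enumerate(segs):
                scheme = SCHEMES[i // 2]
                stim_seed = child_seed(master_seed, "stim", lid, pair_id, seg.segment_idx)
                assignments.append((seg, scheme, stim_seed))
        order = list(rng.permutation(len(assignments)))
        plist = PresentationList(list_id=lid, assignments=assignments, order=[int(i) for i in order])
        plist.validate()
        lists.append(plist)
    return lists


def describe_protocol() -> dict:
    """Static metadata of the rating protocol: attributes, anchors, breaks."""
    return {
        "attributes": [
            {
                "name": "naturalness",
                "question": "How natural did you find the conversation?",
                "anchors": ("Completely natural", "Completely unnatural"),
                "midpoint": "neither/nor",
            },
            {
                "name": "flow",
                "question": "How free-flowing did you find the conversation?",
                "anchors": ("Not at all free-flowing", "Completely free-flowing"),
                "midpoint": "neither/nor",
            },
            {
                "name": "ease_of_following",
                "question": "How easy was it for you to follow the conversation?",
                "anchors": ("Very difficult", "Very easy"),
                "midpoint": "neither/nor",
            },
        ],
        "vas_scale": {"min": 1.0, "max": 5.0, "n_anchor_points": 5},
        "break_after_trials": (8, 16, 24),
        "n_trials": 32,
    }


def save_lists_json(lists: list[PresentationList], path: str | Path) -> None:
    payload = [
        {
            "list_id": pl.list_id,
            "order": pl.order,
            "assignments": [
                {
                    "pair_id": seg.pair_id,
                    "segment_idx": seg.segment_idx,
                    "duration_s": seg.duration_s,
                    "n_transfers": seg.n_transfers,
                    "scheme": scheme,
                    "seed": seed,
                }
                for seg, scheme, seed in pl.assignments
            ],
        }
        for pl in lists
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def save_lists_csv(lists: list[PresentationList], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["list_id", "trial_idx", "pair_id", "segment_idx", "scheme", "seed"])
        for pl in lists:
            for trial_idx, a_idx in enumerate(pl.order):
                seg, scheme, seed = pl.assignments[a_idx]
                w.writerow([pl.list_id, trial_idx, seg.pair_id, seg.segment_idx, scheme, seed])
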