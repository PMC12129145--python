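"""Synthetic dyadic conversations and listener ratings with known ground truth.

The conversation generator emulates the study conditions of the stimulus
corpus: ~30 s two-speaker segments with 12-25 turn changes, lognormal turn
durations (median 1.5 s), occasional within-turn pauses of 100-1200 ms
(some exceeding the 300 ms compression threshold), nested overlaps-within,
and surrogate speech — amplitude-modulated noise bursts or harmonic tones —
at >= 30 dB above a low room-tone floor, so the energy-threshold VAD sees a
realistic contrast. The emitted timeline is exact, which makes every later
pipeline stage testable against ground truth.

The rating generator stands in for human listeners: a linear mixed model
with a per-scheme shift, an optional slope on the stimulus's realised FTO
median, a participant random intercept, an optional gender-by-scheme
interaction, and i.i.d. residual noise, truncated to the 1-5 VAS range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import AudioTrack
from .fto import LogisticParams, sample_ftos, summarize, transform_to_distribution
from .fto import NHQ_LOGISTIC, HIN_LOGISTIC, CONNHQ_FTO_MS, CONLOW_FTO_MS
from .timeline import IPU, ConversationTimeline, OverlapWithin, Turn
from .states import extract_ftos

__all__ = [
    "ConvGenParams",
    "RatingGenParams",
    "generate_synthetic_conversation",
    "generate_stimulus_metadata",
    "generate_synthetic_ratings",
    "ATTRIBUTES",
    "VAS_MIN",
    "VAS_MAX",
]

ATTRIBUTES = ("naturalness", "flow", "ease_of_following")
VAS_MIN, VAS_MAX = 1.0, 5.0


@dataclass(frozen=True)
class ConvGenParams:
    """Study-condition parameters of the conversation generator."""

    n_transfers: int | None = None  # None: uniform 12-25
    turn_dur_median_s: float = 1.5
    turn_dur_log_sd: float = 0.4
    internal_pause_prob: float = 0.3
    internal_pause_range_ms: tuple[float, float] = (100.0, 1200.0)
    overlap_within_prob: float = 0.15
    gap_dist: LogisticParams = field(default_factory=lambda: LogisticParams(200.0, 150.0))
    gap_clip_ms: tuple[float, float] = (-100.0, 1500.0)
    speech_surrogate: str = "noise_burst"  # or "harmonic_vowel"
    sample_rate: int = 48000
    speech_rms: float = 0.1
    floor_rms: float = 1e-3  # room tone, -60 dB FS
    lead_s: float = 0.3
    tail_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.internal_pause_prob <= 1.0:
            raise ValueError("internal_pause_prob must lie in [0, 1]")
        if not 0.0 <= self.overlap_within_prob <= 1.0:
            raise ValueError("overlap_within_prob must lie in [0, 1]")
        if self.speech_surrogate not in ("noise_burst", "harmonic_vowel"):
            raise ValueError("speech_surrogate must be noise_burst or harmonic_vowel")


def _snap(t: float, sr: int) -> float:
    return round(t * sr) / sr


def _plan_timeline(
    params: ConvGenParams, rng: np.random.Generator, segment_id: str
) -> ConversationTimeline:
    sr = params.sample_rate
    n_transfers = (
        params.n_transfers
        if params.n_transfers is not None
        else int(rng.integers(12, 26))
    )
    n_turns = n_transfers + 1
    speakers = ["A" if i % 2 == 0 else "B" for i in range(n_turns)]

    turns: list[Turn] = []
    overlaps: list[OverlapWithin] = []
    t = params.lead_s
    for k, spk in enumerate(speakers):
        speech = float(
            np.exp(np.log(params.turn_dur_median_s) + params.turn_dur_log_sd * rng.normal())
        )
        speech = max(speech, 0.6)
        ipu_durs = [speech]
        pause_durs: list[float] = []
        if rng.uniform() < params.internal_pause_prob:
            # split the speech into two IPUs around one internal pause
            frac = rng.uniform(0.3, 0.7)
            ipu_durs = [speech * frac, speech * (1.0 - frac)]
            pause_durs = [float(rng.uniform(*params.internal_pause_range_ms)) / 1000.0]
        ipus = []
        pauses = []
        cur = _snap(t, sr)
        for i, d in enumerate(ipu_durs):
            end = _snap(cur + d, sr)
            ipus.append(IPU(spk, cur, end))
            if i < len(pause_durs):
                nxt = _snap(end + pause_durs[i], sr)
                pauses.append((end, nxt))
                cur = nxt
        turn = Turn(speaker_id=spk, ipus=ipus, internal_pauses=pauses)
        turns.append(turn)

        # nested overlap-within by the other speaker, inside one host IPU,
        # well clear (>= 300 ms) of the host turn edges so IPU merging and
        # floor-transfer logic cannot confuse it with an adjacent turn
        if rng.uniform() < params.overlap_within_prob:
            host_ipu = max(ipus, key=lambda i: i.duration)
            lo = max(host_ipu.start + 0.05, turn.start + 0.3)
            hi = min(host_ipu.end - 0.05, turn.end - 0.3)
            if hi - lo > 0.25:
                dur = float(rng.uniform(0.2, min(0.5, hi - lo - 0.01)))
                start = _snap(float(rng.uniform(lo, hi - dur)), sr)
                overlaps.append(
                    OverlapWithin(
                        speaker_id="B" if spk == "A" else "A",
                        start=start,
                        end=_snap(start + dur, sr),
                        host_turn_index=k,
                        rel_offset=start - turn.start,
                    )
                )

        if k < n_transfers:
            gap_ms = float(
                np.clip(sample_ftos(params.gap_dist, 1, rng)[0], *params.gap_clip_ms)
            )
            t = turn.end + gap_ms / 1000.0

    total = turns[-1].end + params.tail_s
    tl = ConversationTimeline(
        turns=turns, overlaps_within=overlaps, segment_id=segment_id, total_duration=total
    )
    tl.ftos = extract_ftos(tl)
    tl.validate()
    return tl


def _surrogate_speech(
    n: int, sr: int, rng: np.random.Generator, kind: str, target_rms: float
) -> np.ndarray:
    t = np.arange(n) / sr
    # syllabic-rate amplitude modulation, never fully silent
    env = 0.55 + 0.45 * np.sin(2 * np.pi * 3.5 * t + rng.uniform(0, 2 * np.pi))
    if kind == "noise_burst":
        carrier = rng.normal(size=n)
    else:  # harmonic_vowel
        f0 = rng.uniform(100.0, 220.0)
        carrier = sum(
            (1.0 / h) * np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
            for h in range(1, 6)
        )
    x = env * carrier
    x *= target_rms / np.sqrt(np.mean(np.square(x)))
    # short edge ramps so boundaries are click-free
    r = min(int(0.005 * sr), n // 2)
    if r > 0:
        x[:r] *= np.linspace(0, 1, r, endpoint=False)
        x[-r:] *= np.linspace(1, 0, r)
    return x


def generate_synthetic_conversation(
    params: ConvGenParams | None = None, seed: int | None = None, segment_id: str = "synthetic"
) -> tuple[AudioTrack, AudioTrack, ConversationTimeline]:
    """Generate a two-speaker conversation with an exact ground-truth timeline.

    Same seed gives bit-identical audio; different seeds differ.
    """
    params = params or ConvGenParams()
    rng = np.random.default_rng(seed)
    tl = _plan_timeline(params, rng, segment_id)
    sr = params.sample_rate
    n = int(np.ceil(tl.total_duration * sr))
    buffers = {
        "A": rng.normal(scale=params.floor_rms, size=n),
        "B": rng.normal(scale=params.floor_rms, size=n),
    }

    def paint(spk: str, start: float, end: float) -> None:
        i0, i1 = round(start * sr), round(end * sr)
        buffers[spk][i0:i1] += _surrogate_speech(
            i1 - i0, sr, rng, params.speech_surrogate, params.speech_rms
        )

    for turn in tl.turns:
        for ipu in turn.ipus:
            paint(turn.speaker_id, ipu.start, ipu.end)
    for ov in tl.overlaps_within:
        paint(ov.speaker_id, ov.start, ov.end)

    track_a = AudioTrack(buffers["A"], sr, "A")
    track_b = AudioTrack(buffers["B"], sr, "B")
    return track_a, track_b, tl


# ------------------------------------------------------------------- ratings


@dataclass(frozen=True)
class RatingGenParams:
    """Parameters of the synthetic listener-rating model (VAS units, 1-5)."""

    n_participants: int = 44
    n_female: int = 20
    grand_mean: float = 3.2
    condition_effects: dict = field(
        default_factory=lambda: {"conLow": 0.5, "conNHQ": 0.5, "NHQ": 0.0, "HIN": -0.8}
    )
    fto_median_slope: float = 0.0  # rating units per ms of realised FTO median
    participant_sd: float = 0.4
    residual_sd: float = 0.5
    interaction_effects: dict | None = None  # {(gender, scheme): shift}

    def __post_init__(self) -> None:
        if self.participant_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.n_female <= self.n_participants:
            raise ValueError("n_female must not exceed n_participants")


def generate_stimulus_metadata(
    lists,
    nhq_params: LogisticParams = NHQ_LOGISTIC,
    hin_params: LogisticParams = HIN_LOGISTIC,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Realised FTO summaries per stimulus of each presentation list.

    Draws each stimulus's FTO sequence the way the manipulator would
    (constant for conLow/conNHQ; NHQ draws, affine-transformed for HIN)
    without rendering audio, and summarises it as median and IQR. Useful
    for exercising the ratings analysis at scale.
    """
    rows = []
    for plist in lists:
        for trial, (seg, scheme_name, stim_seed) in enumerate(plist.assignments):
            n = seg.n_transfers
            if scheme_name == "conLow":
                values = np.full(n, CONLOW_FTO_MS)
            elif scheme_name == "conNHQ":
                values = np.full(n, CONNHQ_FTO_MS)
            else:
                values = sample_ftos(nhq_params, n, np.random.default_rng(stim_seed))
                if scheme_name == "HIN":
                    values = transform_to_distribution(values, nhq_params, hin_params)
            summ = summarize(values)
            rows.append(
                {
                    "list_id": plist.list_id,
                    "trial": trial,
                    "scheme": scheme_name,
                    "segment_id": f"p{seg.pair_id}s{seg.segment_idx}",
                    "stimulus_seed": stim_seed,
                    "realized_fto_median_ms": summ.median,
                    "realized_fto_iqr_ms": summ.iqr,
                }
            )
    return pd.DataFrame(rows)


def generate_synthetic_ratings(
    stimuli: pd.DataFrame,
    params: RatingGenParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate VAS ratings of every stimulus by a panel of listeners.

    Each participant is assigned one presentation list (round-robin) and
    rates all its stimuli on all three attributes. The rating equals
    ``grand_mean + condition_effect + slope * fto_median + participant
    intercept + interaction + residual``, truncated to [1, 5].
    """
    params = params or RatingGenParams()
    rng = np.random.default_rng(seed)
    list_ids = sorted(stimuli["list_id"].unique())
    intercepts = rng.normal(scale=params.participant_sd, size=params.n_participants)
    rows = []
    for p in range(params.n_participants):
        gender = "female" if p < params.n_female else "male"
        lid = list_ids[p % len(list_ids)]
        trials = stimuli[stimuli["list_id"] == lid]
        for _, st in trials.iterrows():
            base = (
                params.grand_mean
                + params.condition_effects.get(st["scheme"], 0.0)
                + params.fto_median_slope * st["realized_fto_median_ms"]
                + intercepts[p]
            )
            if params.interaction_effects:
                base += params.interaction_effects.get((gender, st["scheme"]), 0.0)
            for attr in ATTRIBUTES:
                value = base + rng.normal(scale=params.residual_sd)
                rows.append(
                    {
                        "participant": f"P{p:03d}",
                        "gender": gender,
                        "list_id": lid,
                        "trial": st["trial"],
                        "scheme": st["scheme"],
                        "segment_id": st["segment_id"],
                        "attribute": attr,
                        "value": float(np.clip(value, VAS_MIN, VAS_MAX)),
                        "realized_fto_median_ms": st["realized_fto_median_ms"],
                        "realized_fto_iqr_ms": st["realized_fto_iqr_ms"],
                    }
                )
    return pd.DataFrame(rows)
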