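"""Re-timing and re-rendering of classified conversation segments.

Four floor-transfer-offset (FTO) manipulation schemes are supported:

- ``conLow``  — every floor transfer set to a constant 50 ms,
- ``conNHQ``  — constant 190 ms (the empirical NHQ median),
- ``NHQ``     — FTOs drawn i.i.d. from the NHQ logistic distribution,
- ``HIN``     — NHQ draws scale-and-shifted onto the HIN distribution.

Per turn the pipeline (1) equalises loudness by scaling each turn so the
RMS over its inter-pausal units (speech only, pauses excluded) hits a fixed
target, (2) repeatedly halves internal pauses longer than 300 ms until they
are shorter than 300 ms, (3) re-attaches overlaps-within at their original
offset relative to their (compressed) host turn, and (4) schedules the next
turn's onset at the previous turn's offset plus the scheme's FTO. The
result is rendered as a mono waveform at 48 kHz with 200 ms of leading
silence; overlapping regions are summed and the whole signal is globally
peak-normalised only if it would clip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import AudioTrack, rms, write_wav
from .fto import (
    CONLOW_FTO_MS,
    CONNHQ_FTO_MS,
    HIN_LOGISTIC,
    NHQ_LOGISTIC,
    LogisticParams,
    sample_ftos,
    transform_to_distribution,
)
from .timeline import IPU, ConversationTimeline, OverlapWithin, Turn
from .states import extract_ftos

__all__ = [
    "SCHEME_NAMES",
    "ManipulationScheme",
    "RenderConfig",
    "RenderedConversation",
    "equalize_loudness",
    "compress_pauses",
    "schedule_turns",
    "render_audio",
    "manipulate_segment",
    "make_paired_nhq_hin",
]

SCHEME_NAMES = ("conLow", "conNHQ", "NHQ", "HIN")


@dataclass(frozen=True)
class ManipulationScheme:
    """One of the four FTO manipulation schemes with its parameters."""

    name: str
    constant_fto_ms: float | None = None
    source_dist: LogisticParams | None = None
    target_dist: LogisticParams | None = None

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ValueError(f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}")
        if self.name in ("conLow", "conNHQ"):
            if self.constant_fto_ms is None or self.source_dist or self.target_dist:
                raise ValueError(f"{self.name} carries a constant FTO and no distributions")
        elif self.name == "NHQ":
            if self.source_dist is None or self.constant_fto_ms is not None:
                raise ValueError("NHQ carries a source distribution and no constant")
        else:  # HIN
            if self.source_dist is None or self.target_dist is None:
                raise ValueError("HIN carries both source and target distributions")

    @classmethod
    def conlow(cls) -> "ManipulationScheme":
        return cls("conLow", constant_fto_ms=CONLOW_FTO_MS)

    @classmethod
    def connhq(cls) -> "ManipulationScheme":
        return cls("conNHQ", constant_fto_ms=CONNHQ_FTO_MS)

    @classmethod
    def nhq(cls, source: LogisticParams = NHQ_LOGISTIC) -> "ManipulationScheme":
        return cls("NHQ", source_dist=source)

    @classmethod
    def hin(
        cls,
        source: LogisticParams = NHQ_LOGISTIC,
        target: LogisticParams = HIN_LOGISTIC,
    ) -> "ManipulationScheme":
        return cls("HIN", source_dist=source, target_dist=target)

    @classmethod
    def by_name(cls, name: str) -> "ManipulationScheme":
        return {
            "conLow": cls.conlow,
            "conNHQ": cls.connhq,
            "NHQ": cls.nhq,
            "HIN": cls.hin,
        }[name]()


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for manipulated stimuli."""

    leading_silence_ms: float = 200.0
    max_internal_pause_ms: float = 300.0
    target_rms: float = 0.05  # ~ -26 dB FS
    sample_rate: int = 48000
    overlap_clamp_fraction: float = 0.9
    ramp_ms: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_rms < 1.0:
            raise ValueError("target_rms must lie in (0, 1)")
        if self.leading_silence_ms < 0 or self.max_internal_pause_ms < 0:
            raise ValueError("durations must be non-negative")


@dataclass
class RenderedConversation:
    """A manipulated stimulus: waveform, realised timing, and provenance.

    ``stems`` holds the per-speaker contributions to the mono mix (before
    any global peak normalisation), handy for re-running detection on the
    rendered output.
    """

    waveform: np.ndarray
    sample_rate: int
    realized_timeline: ConversationTimeline
    realized_ftos: list[float]
    scheme: ManipulationScheme
    segment_id: str
    seed: int | None = None
    stems: dict[str, np.ndarray] | None = None

    @property
    def duration(self) -> float:
        return self.waveform.size / self.sample_rate

    def save(self, wav_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the mono WAV plus a JSON sidecar with timing metadata."""
        write_wav(wav_path, self.waveform, self.sample_rate)
        if sidecar_path is not None:
            meta = {
                "segment_id": self.segment_id,
                "scheme": self.scheme.name,
                "seed": self.seed,
                "realized_ftos_ms": list(self.realized_ftos),
                "realized_timeline": self.realized_timeline.to_dict(),
            }
            Path(sidecar_path).write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------- step 1


def equalize_loudness(
    turn_audio: np.ndarray, ipu_sample_mask: np.ndarray, target_rms: float
) -> tuple[np.ndarray, float]:
    """Scale a turn so the RMS over its IPU samples equals ``target_rms``.

    One gain per turn, applied uniformly (pause samples included); the RMS
    is computed over speech samples only. Returns (scaled audio, gain).
    """
    speech = np.asarray(turn_audio)[np.asarray(ipu_sample_mask, dtype=bool)]
    if speech.size == 0 or np.all(speech == 0):
        raise ValueError("silent turn: cannot equalize loudness")
    gain = target_rms / rms(speech)
    return turn_audio * gain, gain


def _turn_gain(turn: Turn, track: AudioTrack, target_rms: float) -> float:
    speech = np.concatenate([track.slice_seconds(i.start, i.end) for i in turn.ipus])
    if speech.size == 0 or np.all(speech == 0):
        raise ValueError(f"silent turn at {turn.start:.3f}s: cannot equalize loudness")
    return target_rms / rms(speech)


# --------------------------------------------------------------------- step 2


def _compress_pause_duration(d_ms: float, max_ms: float = 300.0) -> float:
    """Halve a pause duration until it is shorter than ``max_ms``.

    Pauses of at most ``max_ms`` are untouched (the trigger is strictly
    "longer than"): 1000 -> 250, 600 -> 150, 300 -> 300.
    """
    if d_ms > max_ms:
        while d_ms >= max_ms:
            d_ms /= 2.0
    return d_ms


def compress_pauses(turn: Turn, max_internal_pause_ms: float = 300.0) -> Turn:
    """Shorten a turn's long internal pauses by repeated halving.

    IPU durations (and their audio) are unchanged; each IPU after a
    compressed pause shifts left by the time removed so far. The turn start
    is preserved and the end moves left by the total removed time.
    """
    removed = 0.0
    new_ipus = [IPU(turn.speaker_id, turn.ipus[0].start, turn.ipus[0].end)]
    new_pauses: list[tuple[float, float]] = []
    for prev, nxt in zip(turn.ipus[:-1], turn.ipus[1:]):
        gap_ms = (nxt.start - prev.end) * 1000.0
        new_gap_ms = _compress_pause_duration(gap_ms, max_internal_pause_ms)
        removed += (gap_ms - new_gap_ms) / 1000.0
        start = nxt.start - removed
        new_ipus.append(IPU(turn.speaker_id, start, start + nxt.duration))
        if new_gap_ms > 0:
            new_pauses.append((new_ipus[-2].end, new_ipus[-1].start))
    return Turn(speaker_id=turn.speaker_id, ipus=new_ipus, internal_pauses=new_pauses)


# --------------------------------------------------------------------- step 4


@dataclass
class _ScheduledIPU:
    """An IPU placement: where it lands in the output and where its audio lives."""

    speaker_id: str
    out_start: float
    src_start: float
    src_end: float
    gain: float
    sample_rate: int = 48000

    @property
    def duration(self) -> float:
        # sample-exact duration, matching the slice the renderer will copy
        sr = self.sample_rate
        return (round(self.src_end * sr) - round(self.src_start * sr)) / sr

    @property
    def out_end(self) -> float:
        return self.out_start + self.duration


@dataclass
class _Schedule:
    turns: list[list[_ScheduledIPU]]  # per turn, in order
    turn_speakers: list[str]
    turn_pauses: list[list[tuple[float, float]]]
    overlaps: list[_ScheduledIPU]
    overlap_hosts: list[int]
    assigned_ftos: list[float]


def _draw_fto(
    scheme: ManipulationScheme,
    rng: np.random.Generator,
    prev_turn_dur_ms: float,
    clamp_fraction: float,
) -> float:
    if scheme.constant_fto_ms is not None:
        return scheme.constant_fto_ms
    bound = -clamp_fraction * prev_turn_dur_ms
    for _ in range(10):
        x = float(sample_ftos(scheme.source_dist, 1, rng)[0])
        if scheme.name == "HIN":
            x = float(transform_to_distribution([x], scheme.source_dist, scheme.target_dist)[0])
        if x >= bound:
            return x
    return bound


def _clamp_ftos(
    values: np.ndarray, turns: list[Turn], clamp_fraction: float
) -> list[float]:
    """Clamp pre-drawn FTOs to the maximum admissible overlap per transfer."""
    out = []
    for k, v in enumerate(values):
        bound = -clamp_fraction * turns[k].duration * 1000.0
        out.append(float(max(v, bound)))
    return out


def schedule_turns(
    timeline: ConversationTimeline,
    scheme: ManipulationScheme,
    config: RenderConfig,
    rng: np.random.Generator | int | None = None,
    tracks: dict[str, AudioTrack] | None = None,
    fto_values_ms: list[float] | None = None,
) -> _Schedule:
    """Compress pauses, assign new FTOs and compute output-time placements.

    ``fto_values_ms`` overrides the scheme's own draw (used for the paired
    NHQ/HIN construction); values are still clamped so an incoming turn
    never starts before 90 % of its predecessor has elapsed.
    """
    if len(timeline.turns) < 2:
        raise ValueError("scheduling requires at least two turns")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    compressed = [compress_pauses(t, config.max_internal_pause_ms) for t in timeline.turns]
    gains = [
        _turn_gain(orig, tracks[orig.speaker_id], config.target_rms) if tracks else 1.0
        for orig in timeline.turns
    ]

    sr = config.sample_rate

    def snap(t: float) -> float:
        return round(t * sr) / sr

    n_transfers = len(compressed) - 1
    if fto_values_ms is not None:
        if len(fto_values_ms) != n_transfers:
            raise ValueError(
                f"got {len(fto_values_ms)} FTO values for {n_transfers} transfers"
            )
        ftos_ms = _clamp_ftos(
            np.asarray(fto_values_ms, dtype=float), compressed, config.overlap_clamp_fraction
        )
    else:
        ftos_ms = None  # drawn sequentially below

    sched_turns: list[list[_ScheduledIPU]] = []
    turn_pauses: list[list[tuple[float, float]]] = []
    assigned: list[float] = []
    onset = config.leading_silence_ms / 1000.0
    for k, (orig, comp) in enumerate(zip(timeline.turns, compressed)):
        onset = snap(onset)
        shift = onset - comp.start
        placed = [
            _ScheduledIPU(
                speaker_id=comp.speaker_id,
                out_start=snap(ipu.start + shift),
                # audio is sourced at the ORIGINAL ipu position
                src_start=orig_ipu.start,
                src_end=orig_ipu.end,
                gain=gains[k],
                sample_rate=sr,
            )
            for ipu, orig_ipu in zip(comp.ipus, orig.ipus)
        ]
        sched_turns.append(placed)
        turn_pauses.append(
            [(snap(a + shift), snap(b + shift)) for a, b in comp.internal_pauses]
        )
        turn_end = placed[-1].out_end
        if k < n_transfers:
            if ftos_ms is not None:
                fto = ftos_ms[k]
            else:
                fto = _draw_fto(
                    scheme, rng, comp.duration * 1000.0, config.overlap_clamp_fraction
                )
            fto = snap(fto / 1000.0) * 1000.0  # sample-grid rounding
            assigned.append(fto)
            onset = turn_end + fto / 1000.0

    # step 3: overlaps-within keep their original offset to the host turn start
    sched_overlaps: list[_ScheduledIPU] = []
    overlap_hosts: list[int] = []
    for ov in timeline.overlaps_within:
        host_idx = ov.host_turn_index
        host_start = sched_turns[host_idx][0].out_start
        out_start = snap(host_start + ov.rel_offset)
        src_start, src_end = ov.start, ov.end
        # truncate on collision with the next scheduled turn onset
        if host_idx + 1 < len(sched_turns):
            limit = sched_turns[host_idx + 1][0].out_start - 0.001
            if out_start + (src_end - src_start) > limit:
                src_end = max(src_start, src_start + (limit - out_start))
        if src_end <= src_start:
            continue  # fully squeezed out; drop
        if tracks is not None:
            ov_audio = tracks[ov.speaker_id].slice_seconds(ov.start, ov.end)
            if ov_audio.size == 0 or np.all(ov_audio == 0):
                raise ValueError("silent overlap-within: cannot equalize loudness")
            ov_gain = config.target_rms / rms(ov_audio)
        else:
            ov_gain = 1.0
        sched_overlaps.append(
            _ScheduledIPU(
                speaker_id=ov.speaker_id,
                out_start=out_start,
                src_start=src_start,
                src_end=src_end,
                gain=ov_gain,
                sample_rate=sr,
            )
        )
        overlap_hosts.append(host_idx)

    return _Schedule(
        turns=sched_turns,
        turn_speakers=[t.speaker_id for t in compressed],
        turn_pauses=turn_pauses,
        overlaps=sched_overlaps,
        overlap_hosts=overlap_hosts,
        assigned_ftos=assigned,
    )


# --------------------------------------------------------------------- render


def _ramp(n_samples: int, ramp_len: int) -> np.ndarray:
    """Linear fade-in/out envelope to avoid clicks at cut points."""
    env = np.ones(n_samples)
    r = min(ramp_len, n_samples // 2)
    if r > 0:
        env[:r] = np.linspace(0.0, 1.0, r, endpoint=False)
        env[n_samples - r :] = np.linspace(1.0, 0.0, r)
    return env


def _schedule_to_timeline(schedule: _Schedule, segment_id: str) -> ConversationTimeline:
    turns = []
    for placed, speaker, pauses in zip(
        schedule.turns, schedule.turn_speakers, schedule.turn_pauses
    ):
        ipus = [IPU(speaker, p.out_start, p.out_end) for p in placed]
        turns.append(Turn(speaker_id=speaker, ipus=ipus, internal_pauses=pauses))
    overlaps = []
    for p, host in zip(schedule.overlaps, schedule.overlap_hosts):
        host_start = turns[host].start
        host_end = turns[host].end
        # metadata records the within-host extent; audio that a compressed
        # host can no longer contain is rendered but not listed here
        start = p.out_start
        end = min(p.out_end, host_end)
        if end <= start or start >= host_end:
            continue
        overlaps.append(
            OverlapWithin(
                speaker_id=p.speaker_id,
                start=start,
                end=end,
                host_turn_index=host,
                rel_offset=start - host_start,
            )
        )
    tl = ConversationTimeline(turns=turns, overlaps_within=overlaps, segment_id=segment_id)
    tl.ftos = extract_ftos(tl)
    return tl


def render_audio(
    schedule: _Schedule,
    tracks: dict[str, AudioTrack],
    config: RenderConfig,
    scheme: ManipulationScheme,
    segment_id: str = "segment",
    seed: int | None = None,
) -> RenderedConversation:
    """Place scheduled speech into a mono buffer and package the result.

    Overlapping regions are summed; if the mix would clip, one global gain
    normalises the peak to 0.99. Silence between placements is exact zeros.
    """
    sr = config.sample_rate
    all_placed = [p for turn in schedule.turns for p in turn] + schedule.overlaps
    if not all_placed:
        raise ValueError("empty schedule")
    end = max(p.out_end for p in all_placed)
    n_out = int(np.ceil(end * sr)) + 1
    stems = {spk: np.zeros(n_out) for spk in tracks}
    ramp_len = int(round(config.ramp_ms / 1000.0 * sr))
    for p in all_placed:
        src_track = tracks[p.speaker_id]
        seg = src_track.slice_seconds(p.src_start, p.src_end)
        if seg.size == 0:
            raise ValueError(
                f"no source audio for IPU [{p.src_start:.3f}, {p.src_end:.3f}) "
                f"of speaker {p.speaker_id}"
            )
        seg = seg * p.gain * _ramp(seg.size, ramp_len)
        i0 = int(round(p.out_start * sr))
        stems[p.speaker_id][i0 : i0 + seg.size] += seg
    out = np.sum(list(stems.values()), axis=0)
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out *= 0.99 / peak
    timeline = _schedule_to_timeline(schedule, segment_id)
    timeline.validate()
    return RenderedConversation(
        waveform=out,
        sample_rate=sr,
        realized_timeline=timeline,
        realized_ftos=[rec.value for rec in timeline.ftos],
        scheme=scheme,
        segment_id=segment_id,
        seed=seed,
        stems=stems,
    )


def manipulate_segment(
    track_a: AudioTrack,
    track_b: AudioTrack,
    timeline: ConversationTimeline,
    scheme: ManipulationScheme,
    config: RenderConfig | None = None,
    seed: int | None = None,
    fto_values_ms: list[float] | None = None,
) -> RenderedConversation:
    """Full manipulation of one classified segment under one scheme.

    Composition of loudness equalisation, pause compression, FTO
    re-scheduling and rendering, per turn in timeline order.
    """
    config = config or RenderConfig()
    tracks = {track_a.speaker_id: track_a, track_b.speaker_id: track_b}
    rng = np.random.default_rng(seed)
    schedule = schedule_turns(
        timeline, scheme, config, rng=rng, tracks=tracks, fto_values_ms=fto_values_ms
    )
    return render_audio(
        schedule, tracks, config, scheme, segment_id=timeline.segment_id, seed=seed
    )


def make_paired_nhq_hin(
    segment_1: tuple[AudioTrack, AudioTrack, ConversationTimeline],
    segment_2: tuple[AudioTrack, AudioTrack, ConversationTimeline],
    nhq_params: LogisticParams = NHQ_LOGISTIC,
    hin_params: LogisticParams = HIN_LOGISTIC,
    config: RenderConfig | None = None,
    seed: int | None = None,
) -> tuple[RenderedConversation, RenderedConversation]:
    """Manipulate two segments as an NHQ/HIN pair sharing one draw sequence.

    Segment 1 receives raw NHQ draws. Segment 2 receives the same sequence
    scale-and-shifted onto the HIN distribution, truncated or extended with
    fresh draws to match its own transfer count, so that with equal counts
    its FTOs are the elementwise affine image of segment 1's.
    """
    config = config or RenderConfig()
    rng = np.random.default_rng(seed)
    a1, b1, tl1 = segment_1
    a2, b2, tl2 = segment_2
    n1 = len(tl1.turns) - 1
    n2 = len(tl2.turns) - 1

    nhq_scheme = ManipulationScheme.nhq(nhq_params)
    draws1 = sample_ftos(nhq_params, n1, rng)
    rend1 = manipulate_segment(
        a1, b1, tl1, nhq_scheme, config, seed=seed, fto_values_ms=list(draws1)
    )
    raw1 = np.asarray(rend1.realized_ftos)  # post-clamp, sample-rounded

    if n2 <= n1:
        raw2 = raw1[:n2]
    else:
        raw2 = np.concatenate([raw1, sample_ftos(nhq_params, n2 - n1, rng)])
    hin_values = transform_to_distribution(raw2, nhq_params, hin_params)
    hin_scheme = ManipulationScheme.hin(nhq_params, hin_params)
    rend2 = manipulate_segment(
        a2, b2, tl2, hin_scheme, config, seed=seed, fto_values_ms=list(hin_values)
    )
    return rend1, rend2
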