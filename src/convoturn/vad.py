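"""Energy-threshold voice activity detection.

A track is segmented into short analysis windows (5 ms by default) and a
window is marked as speech when more than a fixed fraction (15 %) of its
sample-level log-energies exceed the track-wide median sample log-energy
plus an offset (5 dB). Because the threshold is relative to the median,
the decision is invariant to a global gain change of the recording.

Sample log-energy is ``10*log10(x**2)`` floored at ``energy_floor_db``
(default -120 dB) so that digital silence is well defined: an all-zero
track has constant log-energy and the threshold can never be exceeded.

A light post-hoc smoothing pass removes single-window flicker: interior
silence runs shorter than ``min_silence_ms`` are filled, then speech runs
shorter than ``min_speech_ms`` are dropped. Both default to 25 ms, far
below the 300 ms pause rule used downstream, so smoothing cannot create
or destroy linguistically relevant pauses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .audio import AudioTrack

__all__ = [
    "VadParams",
    "ActivityMask",
    "detect_voice_activity",
    "mask_to_intervals",
    "write_intervals_csv",
    "write_intervals_textgrid",
    "read_textgrid_intervals",
]


@dataclass(frozen=True)
class VadParams:
    """Detection parameters; defaults follow the 5 ms / 15 % / +5 dB rule."""

    window_ms: float = 5.0
    exceed_fraction: float = 0.15
    offset_db: float = 5.0
    min_speech_ms: float = 25.0
    min_silence_ms: float = 25.0
    energy_floor_db: float = -120.0

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if not 0.0 < self.exceed_fraction < 1.0:
            raise ValueError("exceed_fraction must lie strictly in (0, 1)")


@dataclass
class ActivityMask:
    """Boolean speech/non-speech decision per analysis window."""

    flags: np.ndarray
    window_ms: float
    sample_rate: int
    n_samples: int
    speaker_id: str = "A"

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        expected = int(np.ceil(self.n_samples / (self.window_ms / 1000.0 * self.sample_rate)))
        if self.flags.size != expected:
            raise ValueError(
                f"mask has {self.flags.size} flags; expected ceil(duration/window) = {expected}"
            )

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def _sample_log_energy(x: np.ndarray, floor_db: float) -> np.ndarray:
    e = np.square(x)
    floor_lin = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(e, floor_lin))


def _runs(flags: np.ndarray):
    """Yield (value, start_idx, stop_idx) run-length triples."""
    if flags.size == 0:
        return
    change = np.flatnonzero(np.diff(flags.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flags.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield bool(flags[a]), int(a), int(b)


def _smooth(flags: np.ndarray, min_speech_w: int, min_silence_w: int) -> np.ndarray:
    out = flags.copy()
    # fill short interior silences first so fragmented speech reconnects
    for val, a, b in list(_runs(out)):
        if not val and a > 0 and b < out.size and (b - a) < min_silence_w:
            out[a:b] = True
    for val, a, b in list(_runs(out)):
        if val and (b - a) < min_speech_w:
            out[a:b] = False
    return out


def detect_voice_activity(track: AudioTrack, params: VadParams | None = None) -> ActivityMask:
    """Run energy-threshold VAD on one speaker track.

    Returns one flag per window; the final partial window is evaluated over
    its available samples. Deterministic for fixed input.
    """
    params = params or VadParams()
    x = track.samples
    win = int(round(params.window_ms / 1000.0 * track.sample_rate))
    if win < 1:
        raise ValueError("window_ms yields fewer than one sample per window at this rate")

    log_e = _sample_log_energy(x, params.energy_floor_db)
    threshold = float(np.median(log_e)) + params.offset_db
    above = log_e > threshold

    n_windows = int(np.ceil(x.size / win))
    flags = np.zeros(n_windows, dtype=bool)
    for w in range(n_windows):
        seg = above[w * win : (w + 1) * win]
        flags[w] = seg.mean() > params.exceed_fraction

    min_speech_w = max(1, int(round(params.min_speech_ms / params.window_ms)))
    min_silence_w = max(1, int(round(params.min_silence_ms / params.window_ms)))
    flags = _smooth(flags, min_speech_w, min_silence_w)

    return ActivityMask(
        flags=flags,
        window_ms=params.window_ms,
        sample_rate=track.sample_rate,
        n_samples=x.size,
        speaker_id=track.speaker_id,
    )


def mask_to_intervals(mask: ActivityMask) -> list[tuple[float, float]]:
    """Convert a mask to half-open (start_s, end_s) speech intervals."""
    w_s = mask.window_ms / 1000.0
    out = []
    for val, a, b in _runs(mask.flags):
        if val:
            out.append((a * w_s, min(b * w_s, mask.duration)))
    return out


def write_intervals_csv(path: str | Path, speaker_id: str, intervals) -> None:
    with open(path, "w") as fh:
        fh.write("speaker,start_s,end_s\n")
        for s, e in intervals:
            fh.write(f"{speaker_id},{s:.6f},{e:.6f}\n")


def write_intervals_textgrid(
    path: str | Path, tiers: dict[str, list[tuple[float, float, str]]], total_duration: float
) -> None:
    """Write labelled intervals as a Praat long-format TextGrid.

    ``tiers`` maps tier name to (start, end, label) triples; unlabelled gaps
    are filled with empty-label intervals.
    """
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {total_duration:.6f}",
        "tiers? <exists>",
        f"size = {len(tiers)}",
        "item []:",
    ]
    for t_idx, (name, marked) in enumerate(tiers.items(), start=1):
        # fill gaps with empty intervals
        full: list[tuple[float, float, str]] = []
        cursor = 0.0
        for s, e, lab in sorted(marked):
            if s > cursor + 1e-9:
                full.append((cursor, s, ""))
            full.append((s, e, lab))
            cursor = e
        if cursor < total_duration - 1e-9:
            full.append((cursor, total_duration, ""))
        if not full:
            full = [(0.0, total_duration, "")]
        lines += [
            f"    item [{t_idx}]:",
            '        class = "IntervalTier"',
            f'        name = "{name}"',
            "        xmin = 0",
            f"        xmax = {total_duration:.6f}",
            f"        intervals: size = {len(full)}",
        ]
        for i_idx, (s, e, lab) in enumerate(full, start=1):
            lines += [
                f"        intervals [{i_idx}]:",
                f"            xmin = {s:.6f}",
                f"            xmax = {e:.6f}",
                f'            text = "{lab}"',
            ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_textgrid_intervals(path: str | Path) -> dict[str, list[tuple[float, float, str]]]:
    """Read interval tiers from a long-format TextGrid written by this package."""
    tiers: dict[str, list[tuple[float, float, str]]] = {}
    name = None
    in_interval = False
    xmin = xmax = 0.0
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.startswith("name ="):
            name = line.split("=", 1)[1].strip().strip('"')
            tiers[name] = []
            in_interval = False
        elif line.startswith("intervals ["):
            in_interval = True
        elif in_interval and line.startswith("xmin ="):
            xmin = float(line.split("=")[1])
        elif in_interval and line.startswith("xmax ="):
            xmax = float(line.split("=")[1])
        elif in_interval and line.startswith("text =") and name is not None:
            label = line.split("=", 1)[1].strip().strip('"')
            tiers[name].append((xmin, xmax, label))
    return tiers
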