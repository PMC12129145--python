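"""Diagnostic plots for FTO distributions and manipulated timelines."""

from __future__ import annotations

import numpy as np

from .fto import LogisticParams, CONNHQ_FTO_MS, CONLOW_FTO_MS
from .timeline import ConversationTimeline

__all__ = ["plot_fto_distributions", "plot_timeline"]


def plot_fto_distributions(
    dists: dict[str, LogisticParams],
    samples: dict[str, np.ndarray] | None = None,
    show_constants: bool = True,
    ax=None,
):
    """Overlay fitted logistic FTO densities (and optional sample histograms)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    lo = min(p.mu - 5 * p.sigma for p in dists.values())
    hi = max(p.mu + 5 * p.sigma for p in dists.values())
    x = np.linspace(lo, hi, 1000)
    for name, p in dists.items():
        ax.plot(x, p.frozen().pdf(x), label=f"{name} (mu={p.mu:.0f}, sigma={p.sigma:.0f})")
    if samples:
        for name, vals in samples.items():
            ax.hist(vals, bins=60, density=True, alpha=0.3, label=f"{name} sample")
    if show_constants:
        ax.axvline(CONNHQ_FTO_MS, ls="--", color="tab:cyan", label="conNHQ (190 ms)")
        ax.axvline(CONLOW_FTO_MS, ls="--", color="tab:blue", label="conLow (50 ms)")
    ax.set_xlabel("floor-transfer offset (ms)")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def plot_timeline(timeline: ConversationTimeline, ax=None):
    """Piano-roll view of turns, internal pauses and overlaps-within."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    rows = {"A": 1.0, "B": 0.0}
    colors = {"A": "tab:blue", "B": "tab:red"}
    for turn in timeline.turns:
        for ipu in turn.ipus:
            ax.broken_barh(
                [(ipu.start, ipu.duration)],
                (rows[turn.speaker_id], 0.8),
                color=colors.get(turn.speaker_id, "gray"),
            )
        for ps, pe in turn.internal_pauses:
            ax.broken_barh(
                [(ps, pe - ps)],
                (rows[turn.speaker_id], 0.8),
                color=colors.get(turn.speaker_id, "gray"),
                alpha=0.2,
            )
    for ov in timeline.overlaps_within:
        ax.broken_barh(
            [(ov.start, ov.duration)],
            (rows[ov.speaker_id] + 0.2, 0.4),
            color="gray",
            alpha=0.8,
        )
    ax.set_yticks([0.4, 1.4], ["B", "A"])
    ax.set_xlabel("time (s)")
    ax.set_title(timeline.segment_id)
    return ax
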