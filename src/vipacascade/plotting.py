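"""Figure helpers: extinction curves, enhancement insets, trade-off maps."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import EnhancementCurve, ExtinctionCurve, TradeoffPoint

__all__ = ["plot_extinction", "plot_enhancement", "plot_tradeoff"]


def plot_extinction(curves: Mapping[str, ExtinctionCurve], ax=None):
    """dB extinction profiles over the central FSR, one labelled line each."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for label, curve in curves.items():
        ax.plot(curve.freq_ghz, curve.level_db, label=label, lw=1.0)
    ax.set_xlabel("frequency shift (GHz)")
    ax.set_ylabel("relative intensity (dB)")
    ax.legend(frameon=False, fontsize=8)
    ax.figure.tight_layout()
    return ax.figure


def plot_enhancement(curve: EnhancementCurve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 2.6))
    ax.plot(curve.freq_ghz, curve.delta_db, lw=1.0)
    ax.set_xlabel("frequency shift (GHz)")
    ax.set_ylabel("contrast enhancement (dB)")
    ax.figure.tight_layout()
    return ax.figure


def plot_tradeoff(points: Sequence[TradeoffPoint], ax=None):
    """Peak transmission vs contrast enhancement, one line per stage count."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    by_stages: dict[int, list[TradeoffPoint]] = {}
    for p in points:
        by_stages.setdefault(p.n_stages, []).append(p)
    for k in sorted(by_stages):
        pts = [p for p in by_stages[k] if p.attainable]
        ax.plot(
            [p.enhancement_db for p in pts],
            [p.peak_transmission for p in pts],
            marker="o",
            ms=3,
            label=f"{k} stage{'s' if k > 1 else ''}",
        )
    ax.set_xlabel("contrast enhancement (dB)")
    ax.set_ylabel("peak transmission")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False, fontsize=8)
    ax.figure.tight_layout()
    return ax.figure
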