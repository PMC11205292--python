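"""Raster plots of two-module recordings with burst spans and propagation arrows."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .burst_analysis import BurstCatalog
from .io_core import ElectrodeMap, SpikeTrainSet
from .propagation import PropagationResult


def raster_plot(
    sts: SpikeTrainSet,
    emap: ElectrodeMap,
    src_cat: Optional[BurstCatalog] = None,
    tgt_cat: Optional[BurstCatalog] = None,
    prop: Optional[PropagationResult] = None,
    out_path: Optional[str | Path] = None,
    t_range: Optional[tuple] = None,
):
    """Spike raster (Source rows on top) with burst spans shaded and
    Source->Target propagation pairs marked by arrows."""
    order = sorted(emap.electrodes("source")) + sorted(emap.electrodes("target"))
    fig, ax = plt.subplots(figsize=(10, 0.25 * max(len(order), 8) + 1.5))
    for row, eid in enumerate(order):
        t = sts.spikes.get(eid)
        if t is not None and t.size:
            ax.plot(t, [row] * t.size, "|", color="k", markersize=3)
    n_src = len(emap.electrodes("source"))
    for cat, lo, hi, color in (
        (src_cat, -0.5, n_src - 0.5, "tab:blue"),
        (tgt_cat, n_src - 0.5, len(order) - 0.5, "tab:green"),
    ):
        if cat is None:
            continue
        for b in cat.bursts:
            ax.axvspan(b.onset_s, b.offset_s, ymin=(lo + 0.5) / len(order),
                       ymax=(hi + 0.5) / len(order), alpha=0.2, color=color, lw=0)
    if prop is not None and src_cat is not None and tgt_cat is not None:
        for i, j, _lag in prop.pairs_st:
            s = src_cat.bursts[int(i)]
            t = tgt_cat.bursts[int(j)]
            ax.annotate(
                "", xy=(t.onset_s, n_src), xytext=(s.onset_s, n_src - 1),
                arrowprops=dict(arrowstyle="->", color="tab:red"),
            )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(order, fontsize=6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("electrode")
    if t_range:
        ax.set_xlim(*t_range)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return None
    return fig
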