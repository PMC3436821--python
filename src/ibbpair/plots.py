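"""Forest-plot rendering for per-subject and combined fold-change estimates."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .inference import ForestRecord

__all__ = ["forest_plot"]


def forest_plot(records: Sequence[ForestRecord], path: str, title: str = "") -> None:
    """Draw a forest plot: interval lines per subject, weight rectangles,
    and a diamond for the combined estimate (log2 fold-change axis)."""
    if not records:
        raise ValueError("no records to plot")
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(records) + 1.5))
    log2 = 1.4426950408889634  # 1/ln(2)
    for i, rec in enumerate(records):
        y = len(records) - 1 - i
        lo = rec.ci_low * log2
        hi = rec.ci_high * log2
        mid = rec.log_fold * log2
        if rec.label == "combined":
            half = 0.2
            ax.fill(
                [lo, mid, hi, mid], [y, y + half, y, y - half],
                color="tab:blue", alpha=0.8,
            )
        else:
            ax.plot([lo, hi], [y, y], color="black", lw=1.2)
            size = 0.1 + 0.25 * rec.weight
            ax.add_patch(
                plt.Rectangle(
                    (mid - size / 2, y - size / 2), size, size, color="black"
                )
            )
        ax.text(-0.02, y, rec.label, transform=ax.get_yaxis_transform(),
                ha="right", va="center")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel("log2 fold change (before / after)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
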