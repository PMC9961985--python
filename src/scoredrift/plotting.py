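"""Static plots: side-by-side score histograms and per-center timelines."""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .histogram import N_BINS, ScoreHistogram

__all__ = ["plot_histogram_pair", "plot_center_timeline"]

_SCORES = np.arange(1, N_BINS + 1)


def plot_histogram_pair(
    center: ScoreHistogram,
    reference: ScoreHistogram,
    path: str | Path,
    *,
    title: str = "",
    pcc: float | None = None,
    annotate_diffs: bool = False,
) -> Path:
    """Side-by-side relative-frequency bars for a window and its reference,
    with the PCC in the title and, optionally, the per-score difference in
    percentage points printed above each pair of bars."""
    c = center.probabilities() * 100
    r = reference.probabilities() * 100
    width = 0.4
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar(_SCORES - width / 2, c, width, label="center", color="#33658a")
    ax.bar(_SCORES + width / 2, r, width, label="reference", color="#f6ae2d")
    if annotate_diffs:
        for x, (ci, ri) in zip(_SCORES, zip(c, r)):
            ax.text(
                x, max(ci, ri) + 0.5, f"{ci - ri:+.2f}",
                ha="center", va="bottom", fontsize=7,
            )
    ax.set_xticks(_SCORES)
    ax.set_xlabel("suspicion score")
    ax.set_ylabel("share of reports (%)")
    label = title or "score distribution"
    if pcc is not None:
        label += f"  (PCC = {pcc:.3f})"
    ax.set_title(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_center_timeline(
    center_id: str,
    monthly_records: Sequence[Mapping[str, Any]],
    path: str | Path,
    *,
    pcc_threshold: float = 0.95,
    alpha: float = 0.05,
) -> Path:
    """Monthly PCC, χ² p-value and normalized WD traces for one center.

    Deviation months are marked; the PCC panel draws the decision threshold.
    Reads only fields already present in the structured result records.
    """
    months = [r["window"] for r in monthly_records]
    x = np.arange(len(months))
    pcc = [r.get("pcc") for r in monthly_records]
    pval = [r.get("chi2_pvalue") for r in monthly_records]
    wd = [r.get("wd_normalized") for r in monthly_records]
    deviating = [r["alert_level"] == "deviation" for r in monthly_records]

    fig, axes = plt.subplots(3, 1, figsize=(9, 7), sharex=True)
    panels = [
        (pcc, "PCC", pcc_threshold),
        (pval, "χ² p-value", alpha),
        (wd, "WD (normalized)", None),
    ]
    for ax, (values, label, threshold) in zip(axes, panels):
        y = np.array([np.nan if v is None else v for v in values], dtype=float)
        ax.plot(x, y, marker="o", color="#33658a", lw=1.2)
        if threshold is not None:
            ax.axhline(threshold, color="#c1121f", ls="--", lw=1, label=f"threshold {threshold}")
            ax.legend(frameon=False, fontsize=8)
        for xi, dev in zip(x, deviating):
            if dev:
                ax.axvline(xi, color="#c1121f", alpha=0.15, lw=6)
        ax.set_ylabel(label)
    axes[-1].set_xticks(x)
    axes[-1].set_xticklabels(months, rotation=45, ha="right", fontsize=8)
    fig.suptitle(f"{center_id}: monthly monitoring timeline")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
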