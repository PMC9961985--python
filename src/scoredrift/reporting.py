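"""Render monitoring results as text tables and a Markdown report.

The renderer is strictly presentational: every number it prints is taken
verbatim from the structured result records produced by the monitoring
engine — nothing is recomputed here.
"""

from __future__ import annotations

from typing import Any, Mapping, Sequence

import pandas as pd

from .engine import GLOBAL_WINDOW

__all__ = [
    "records_to_dataframe",
    "render_global_table",
    "render_summary_table",
    "render_bin_diff_table",
    "render_alert_table",
    "render_report",
]


def records_to_dataframe(records: Sequence[Mapping[str, Any]]) -> pd.DataFrame:
    """Flatten result records (one per center x window) into a DataFrame."""
    rows = []
    for rec in records:
        row = {k: v for k, v in rec.items() if k not in ("bin_diffs", "causes", "flags")}
        row["causes"] = ";".join(rec.get("causes") or [])
        row["flags"] = ";".join(rec.get("flags") or [])
        diffs = rec.get("bin_diffs")
        for i in range(10):
            row[f"diff_{i + 1}"] = None if diffs is None else diffs[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _fmt(value: Any, digits: int = 3) -> str:
    if value is None or (isinstance(value, float) and value != value):
        return "—"
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return str(value)


def _markdown_table(header: Sequence[str], rows: Sequence[Sequence[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    lines += ["| " + " | ".join(row) + " |" for row in rows]
    return "\n".join(lines)


def _globals(records: Sequence[Mapping[str, Any]]) -> list[Mapping[str, Any]]:
    return [r for r in records if r["window"] == GLOBAL_WINDOW]


def render_global_table(records: Sequence[Mapping[str, Any]]) -> str:
    """Per-center global PCC / χ² p-value / normalized WD table."""
    rows = [
        [
            rec["center_id"],
            str(rec["stream_key"]),
            _fmt(rec.get("reference_key")),
            str(rec["n_center"]),
            _fmt(rec.get("pcc")),
            _fmt(rec.get("chi2_pvalue")),
            _fmt(rec.get("wd_normalized"), 4),
            rec["alert_level"],
        ]
        for rec in _globals(records)
    ]
    return _markdown_table(
        ["Center", "Stream", "Reference", "n", "PCC", "χ² p-value", "WD (norm.)", "Alert"],
        rows,
    )


def render_summary_table(summaries: Sequence[Mapping[str, Any]]) -> str:
    """Monthly-PCC mean and standard deviation per center."""
    rows = [
        [
            s["center_id"],
            str(s["n_months"]),
            _fmt(s["pcc_mean"]),
            _fmt(s["pcc_sd"]),
            _fmt(s["pcc_min"]),
            _fmt(s["pcc_max"]),
        ]
        for s in summaries
    ]
    return _markdown_table(
        ["Center", "Months", "PCC mean", "PCC sd", "PCC min", "PCC max"], rows
    )


def render_bin_diff_table(records: Sequence[Mapping[str, Any]]) -> str:
    """Score-by-score center-minus-reference differences (percentage points)."""
    rows = []
    for rec in _globals(records):
        diffs = rec.get("bin_diffs")
        if diffs is None:
            continue
        rows.append([rec["center_id"]] + [f"{d:+.2f}" for d in diffs])
    return _markdown_table(["Center"] + [str(s) for s in range(1, 11)], rows)


def render_alert_table(records: Sequence[Mapping[str, Any]]) -> str:
    """Every deviation-level alert with its window, severity and causes."""
    rows = [
        [
            rec["center_id"],
            rec["window"],
            _fmt(rec.get("pcc")),
            _fmt(rec.get("chi2_pvalue")),
            _fmt(rec.get("wd_normalized"), 4),
            rec["severity"],
            ", ".join(rec.get("causes") or []),
        ]
        for rec in records
        if rec["alert_level"] == "deviation"
    ]
    if not rows:
        return "_No deviation alerts._"
    return _markdown_table(
        ["Center", "Window", "PCC", "χ² p-value", "WD (norm.)", "Severity", "Causes"],
        rows,
    )


def render_report(
    records: Sequence[Mapping[str, Any]],
    summaries: Sequence[Mapping[str, Any]] = (),
    manifest: Mapping[str, Any] | None = None,
) -> str:
    """Assemble the full Markdown monitoring report."""
    n_dev = sum(r["alert_level"] == "deviation" for r in records)
    parts = [
        "# Score-distribution monitoring report",
        "",
        f"Windows evaluated: {len(records)}; deviation alerts: {n_dev}.",
        "",
        "## Global analysis",
        "",
        render_global_table(records),
        "",
        "## Monthly PCC summary",
        "",
        "Mean of monthly PCCs (differs from the global PCC computed on the "
        "pooled distribution).",
        "",
        render_summary_table(summaries) if summaries else "_No monthly summaries._",
        "",
        "## Score-by-score differences (global, percentage points)",
        "",
        render_bin_diff_table(records),
        "",
        "## Alerts",
        "",
        render_alert_table(records),
        "",
    ]
    if manifest is not None:
        parts += [
            "---",
            f"Produced by scoredrift {manifest.get('version', '?')} "
            f"({manifest.get('command', '?')}, seeds {manifest.get('seeds', [])}).",
            "",
        ]
    return "\n".join(parts)
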