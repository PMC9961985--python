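"""Monitoring engine: reference matching, windowing, evaluation, alerting.

The pipeline mirrors how post-market surveillance of a scoring AI is run in
practice: each center's report stream is matched to the reference
distribution for its (AI version, modality, manufacturer) key, sliced into
one global window plus calendar-month windows, scored with the metric
battery, and graded by a threshold rule — a window whose histogram
correlation falls below the configured threshold (default 0.95), whose χ²
p-value falls below α (default 0.05), or whose stream key disagrees with
the reference key, is flagged as a deviation requiring investigation.
Severity of a deviation is graded from the normalized Wasserstein distance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .histogram import ScoreHistogram, build_histogram
from .metrics import MetricResult, bin_differences, chi2_gof, pcc, wasserstein
from .records import MatchKey, ReferenceDistribution, ScoreReport

__all__ = [
    "GLOBAL_WINDOW",
    "MonitoringConfig",
    "ComparisonResult",
    "Alert",
    "CenterSummary",
    "MonitoringRun",
    "match_reference",
    "diagnose_mismatch",
    "windowize",
    "evaluate_window",
    "classify",
    "summarize_center",
    "run_monitoring",
]

GLOBAL_WINDOW = "global"

# Alert cause codes
CAUSE_PCC = "pcc-below-threshold"
CAUSE_CHI2 = "chi2-significant"
CAUSE_UNMATCHED = "unmatched-reference"
MISMATCH_VERSION = "wrong-version"
MISMATCH_MODALITY = "wrong-modality"
MISMATCH_MANUFACTURER = "wrong-manufacturer"

# Result flags
FLAG_INSUFFICIENT = "insufficient-data"
FLAG_PCC_UNDEFINED = "pcc-undefined"
FLAG_CHI2_DEGENERATE = "chi2-degenerate"


@dataclass(frozen=True)
class MonitoringConfig:
    """Tunable thresholds of the deviation rule.

    pcc_threshold
        Windows with histogram correlation below this are deviations; 0.95
        is a conservative margin above the 0.9 that empirically separates
        normal from abnormal behavior.
    alpha
        Significance level of the χ² goodness-of-fit test.
    min_window_n
        Monthly windows with fewer reports are flagged ``insufficient-data``
        and never raise metric-based alerts — guards against hasty
        conclusions drawn from a handful of cases.
    min_expected
        Expected-count floor for χ² bin pooling.
    severity_cutpoints
        Two increasing cutpoints on the normalized Wasserstein distance
        splitting deviation severity into low / moderate / high.
    """

    pcc_threshold: float = 0.95
    alpha: float = 0.05
    min_window_n: int = 50
    min_expected: float = 5.0
    severity_cutpoints: tuple[float, float] = (0.02, 0.10)

    def __post_init__(self) -> None:
        if not 0.0 < self.pcc_threshold <= 1.0:
            raise ValueError("pcc_threshold must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_window_n < 1:
            raise ValueError("min_window_n must be positive")
        lo, hi = self.severity_cutpoints
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("severity_cutpoints must be strictly increasing in (0, 1)")


@dataclass(frozen=True)
class ComparisonResult:
    """All measured quantities for one (center, window, reference) comparison."""

    center_id: str
    window: str                       # "global" or "YYYY-MM"
    stream_key: MatchKey
    reference_key: MatchKey | None
    n_center: int
    n_reference: int
    metrics: MetricResult | None
    bin_diffs: tuple[float, ...] | None
    flags: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = {
            "center_id": self.center_id,
            "window": self.window,
            "stream_key": str(self.stream_key),
            "reference_key": None if self.reference_key is None else str(self.reference_key),
            "n_center": self.n_center,
            "n_reference": self.n_reference,
            "flags": sorted(self.flags),
        }
        if self.metrics is not None:
            d.update(self.metrics.to_dict())
        else:
            d.update(
                dict.fromkeys(
                    ["pcc", "chi2_stat", "chi2_pvalue", "chi2_df", "wd_raw", "wd_normalized"]
                )
            )
        d["bin_diffs"] = None if self.bin_diffs is None else list(self.bin_diffs)
        return d


@dataclass(frozen=True)
class Alert:
    """Deviation decision for one comparison.

    ``level`` is ``"deviation"`` exactly when ``causes`` is non-empty;
    ``severity`` grades a deviation's normalized Wasserstein distance and is
    ``"not-applicable"`` otherwise.
    """

    level: Literal["none", "deviation"]
    severity: Literal["low", "moderate", "high", "not-applicable"]
    causes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.level == "deviation") != bool(self.causes):
            raise ValueError("level is 'deviation' iff causes is non-empty")

    def to_dict(self) -> dict:
        return {
            "alert_level": self.level,
            "severity": self.severity,
            "causes": list(self.causes),
        }


def match_reference(
    stream_key: MatchKey, registry: Sequence[ReferenceDistribution]
) -> ReferenceDistribution | None:
    """Find the registry entry whose key equals the stream's matching key.

    Returns ``None`` when no entry matches — an alertable condition (an
    unsupported manufacturer or an unregistered version can itself be the
    source of an alert), never an exception.
    """
    for entry in registry:
        if entry.key == stream_key:
            return entry
    return None


def diagnose_mismatch(stream_key: MatchKey, reference_key: MatchKey) -> list[str]:
    """Annotate on which key components a stream and a reference disagree."""
    causes = []
    if stream_key.version != reference_key.version:
        causes.append(MISMATCH_VERSION)
    if stream_key.modality != reference_key.modality:
        causes.append(MISMATCH_MODALITY)
    if stream_key.manufacturer != reference_key.manufacturer:
        causes.append(MISMATCH_MANUFACTURER)
    return causes


def windowize(
    reports: Sequence[ScoreReport], mode: Literal["global", "monthly"]
) -> list[tuple[str, list[ScoreReport]]]:
    """Slice a report stream into analysis windows.

    ``global`` yields a single window holding every report; ``monthly``
    partitions by calendar month of the report date into chronologically
    sorted ``YYYY-MM`` windows covering every report exactly once.
    """
    if mode == "global":
        return [(GLOBAL_WINDOW, list(reports))]
    if mode != "monthly":
        raise ValueError(f"unknown windowing mode {mode!r}")
    buckets: dict[str, list[ScoreReport]] = defaultdict(list)
    for r in reports:
        buckets[r.month].append(r)
    return sorted(buckets.items())


def evaluate_window(
    window: ScoreHistogram,
    reference: ReferenceDistribution,
    config: MonitoringConfig,
    *,
    center_id: str = "",
    window_label: str = GLOBAL_WINDOW,
    stream_key: MatchKey | None = None,
) -> ComparisonResult:
    """Run the full metric battery on one window against its reference.

    Windows smaller than ``config.min_window_n`` are flagged
    ``insufficient-data``; their metrics are still computed (when non-empty)
    for display, but the flag suppresses metric-based alerting downstream.
    An empty window carries no metrics at all.
    """
    flags: set[str] = set()
    n = window.total
    if n < config.min_window_n:
        flags.add(FLAG_INSUFFICIENT)

    metrics: MetricResult | None = None
    diffs: tuple[float, ...] | None = None
    if n > 0:
        r = pcc(window, reference.histogram)
        reason = None
        if r is None:
            flags.add(FLAG_PCC_UNDEFINED)
            reason = "zero across-bin variance in one of the histograms"
        try:
            stat, pval, df = chi2_gof(window, reference.histogram, config.min_expected)
        except ValueError:
            flags.add(FLAG_CHI2_DEGENERATE)
            stat, pval, df = math.nan, math.nan, 0
        wd_raw, wd_norm = wasserstein(window, reference.histogram)
        metrics = MetricResult(
            pcc=r,
            chi2_stat=stat,
            chi2_pvalue=pval,
            chi2_df=df,
            wd_raw=wd_raw,
            wd_normalized=wd_norm,
            pcc_undefined_reason=reason,
        )
        diffs = tuple(bin_differences(window, reference.histogram))

    return ComparisonResult(
        center_id=center_id,
        window=window_label,
        stream_key=stream_key if stream_key is not None else reference.key,
        reference_key=reference.key,
        n_center=n,
        n_reference=reference.n_exams,
        metrics=metrics,
        bin_diffs=diffs,
        flags=frozenset(flags),
    )


def classify(
    result: ComparisonResult,
    mismatches: Iterable[str] = (),
    config: MonitoringConfig = MonitoringConfig(),
) -> Alert:
    """Apply the deviation rule to one comparison.

    A window is a deviation when any of these hold: its PCC is below the
    threshold, its χ² p-value is below α, its stream key mismatches the
    reference key, or no reference matched at all.  Key-level causes
    (mismatch, unmatched) fire regardless of window size because they are
    configuration errors, not sampling noise; metric-based causes are
    suppressed on windows flagged ``insufficient-data``.
    """
    causes: list[str] = []
    if result.reference_key is None:
        causes.append(CAUSE_UNMATCHED)
    causes.extend(f"reference-mismatch:{m}" for m in mismatches)

    sufficient = FLAG_INSUFFICIENT not in result.flags
    m = result.metrics
    if sufficient and m is not None:
        if m.pcc is not None and m.pcc < config.pcc_threshold:
            causes.append(CAUSE_PCC)
        if not math.isnan(m.chi2_pvalue) and m.chi2_pvalue < config.alpha:
            causes.append(CAUSE_CHI2)

    if not causes:
        return Alert(level="none", severity="not-applicable")

    severity = "not-applicable"
    if m is not None:
        lo, hi = config.severity_cutpoints
        wd = m.wd_normalized
        severity = "low" if wd < lo else ("moderate" if wd < hi else "high")
    return Alert(level="deviation", severity=severity, causes=tuple(causes))


@dataclass(frozen=True)
class CenterSummary:
    """Monthly-PCC summary for one center (mean, population sd, min, max).

    The mean of monthly PCCs is a different quantity from the single global
    PCC computed on the center's pooled distribution; both are reported.
    """

    center_id: str
    n_months: int
    pcc_mean: float
    pcc_sd: float
    pcc_min: float
    pcc_max: float
    note: str = (
        "mean of monthly PCCs; differs from the global PCC computed on the "
        "pooled distribution"
    )

    def to_dict(self) -> dict:
        return {
            "center_id": self.center_id,
            "n_months": self.n_months,
            "pcc_mean": self.pcc_mean,
            "pcc_sd": self.pcc_sd,
            "pcc_min": self.pcc_min,
            "pcc_max": self.pcc_max,
        }


def summarize_center(results: Sequence[ComparisonResult]) -> CenterSummary:
    """Summarize a center's monthly PCCs (population standard deviation).

    Only monthly windows with a defined PCC contribute; raises
    ``ValueError`` when there are none.
    """
    monthly = [
        r
        for r in results
        if r.window != GLOBAL_WINDOW and r.metrics is not None and r.metrics.pcc is not None
    ]
    if not monthly:
        raise ValueError("no monthly windows with a defined PCC")
    values = [r.metrics.pcc for r in monthly]  # type: ignore[union-attr]
    k = len(values)
    mean = sum(values) / k
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / k)
    return CenterSummary(
        center_id=monthly[0].center_id,
        n_months=k,
        pcc_mean=mean,
        pcc_sd=sd,
        pcc_min=min(values),
        pcc_max=max(values),
    )


@dataclass
class MonitoringRun:
    """Everything one monitoring pass produced."""

    results: list[ComparisonResult] = field(default_factory=list)
    alerts: list[Alert] = field(default_factory=list)
    summaries: list[CenterSummary] = field(default_factory=list)

    @property
    def n_deviations(self) -> int:
        return sum(a.level == "deviation" for a in self.alerts)

    def records(self) -> list[dict]:
        """One flat dict per (comparison, alert) pair, ready for tabulation."""
        return [
            {**r.to_dict(), **a.to_dict()}
            for r, a in zip(self.results, self.alerts)
        ]


def run_monitoring(
    reports: Sequence[ScoreReport],
    registry: Sequence[ReferenceDistribution],
    config: MonitoringConfig = MonitoringConfig(),
    force_reference: dict[str, MatchKey] | None = None,
) -> MonitoringRun:
    """Monitor a multi-center report stream end to end.

    Reports are grouped by (center, matching key) — a center that upgraded
    its AI mid-stream is monitored as two separate streams — then each group
    is evaluated globally and per calendar month against its matched
    reference, classified, and summarized.

    ``force_reference`` maps a center id to a registry key to use instead of
    automatic matching; evaluating against a deliberately wrong key is how
    reference-mismatch detection is exercised, and the resulting mismatch
    annotations are attached to every alert of that center.
    """
    groups: dict[tuple[str, MatchKey], list[ScoreReport]] = defaultdict(list)
    for r in reports:
        groups[(r.center_id, r.match_key)].append(r)

    run = MonitoringRun()
    for (center_id, stream_key), group in sorted(
        groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
    ):
        if force_reference and center_id in force_reference:
            reference = match_reference(force_reference[center_id], registry)
        else:
            reference = match_reference(stream_key, registry)
        if reference is None:
            # no baseline to compare against: emit one unmatched alert per window
            for label, window_reports in windowize(group, "global") + windowize(
                group, "monthly"
            ):
                result = ComparisonResult(
                    center_id=center_id,
                    window=label,
                    stream_key=stream_key,
                    reference_key=None,
                    n_center=len(window_reports),
                    n_reference=0,
                    metrics=None,
                    bin_diffs=None,
                )
                run.results.append(result)
                run.alerts.append(classify(result, (), config))
            continue

        mismatches = diagnose_mismatch(stream_key, reference.key)
        center_results = []
        for label, window_reports in windowize(group, "global") + windowize(
            group, "monthly"
        ):
            result = evaluate_window(
                build_histogram(window_reports),
                reference,
                config,
                center_id=center_id,
                window_label=label,
                stream_key=stream_key,
            )
            center_results.append(result)
            run.results.append(result)
            run.alerts.append(classify(result, mismatches, config))
        try:
            run.summaries.append(summarize_center(center_results))
        except ValueError:
            pass
    return run
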