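"""Synthetic reference registries and multi-center report streams.

No clinical report logs are distributable, so every pipeline stage is
exercised against generated data with known ground truth: streams of
integer suspicion scores drawn month by month from a configurable 10-bin
categorical distribution, with calendar-month timestamps and per-center
volumes spanning the orders of magnitude seen in real deployments
(from ~90 to ~1,700 reports per month).

The default base distribution is right-skewed — in a screening population
the large majority of exams are unremarkable, so most mass sits at the low
suspicion scores and decays monotonically toward 10.  It is an invented
stand-in for a real retrospective-evaluation distribution; all analytic
expectations used in tests are closed forms valid for any base.

Drift is injected with :class:`ShiftSpec`: a fraction of one score's
probability mass is moved to another score, optionally only in listed
months — the canonical "half of the score-4 population now scores k"
malfunction scenario whose Wasserstein distance has the exact closed form
``fraction * mass * |k - 4|``.

Everything is deterministic given its seed; generators record their
realized per-month bin tallies so downstream metrics always have an exact
oracle input.
"""

from __future__ import annotations

import calendar
import datetime
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .histogram import N_BINS, ScoreHistogram
from .records import MatchKey, ReferenceDistribution, ScoreReport

__all__ = [
    "DEFAULT_BASE_PROBS",
    "GeneratorSpec",
    "ShiftSpec",
    "GeneratedStream",
    "apply_shift",
    "generate_reference",
    "generate_stream",
    "month_range",
    "default_workspace_spec",
]

#: Invented right-skewed base over scores 1..10 (screening populations are
#: dominated by low-suspicion exams); sums to 1 exactly.
DEFAULT_BASE_PROBS = (
    0.45, 0.15, 0.095, 0.075, 0.055, 0.045, 0.04, 0.035, 0.03, 0.025,
)


def month_range(start: str, n_months: int) -> tuple[str, ...]:
    """``n_months`` consecutive ``YYYY-MM`` labels starting at ``start``."""
    year, month = (int(p) for p in start.split("-"))
    labels = []
    for _ in range(n_months):
        labels.append(f"{year:04d}-{month:02d}")
        month += 1
        if month == 13:
            month, year = 1, year + 1
    return tuple(labels)


def _check_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if p.shape != (N_BINS,):
        raise ValueError(f"base_probs must have {N_BINS} entries")
    if (p < 0).any():
        raise ValueError("base_probs must be non-negative")
    if abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("base_probs must sum to 1 within 1e-12")
    return p


@dataclass(frozen=True)
class ShiftSpec:
    """Move ``fraction`` of ``from_score``'s probability mass to ``to_score``.

    ``months`` limits the shift to the listed ``YYYY-MM`` windows; ``None``
    applies it to the whole stream.
    """

    from_score: int
    to_score: int
    fraction: float
    months: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for s in (self.from_score, self.to_score):
            if not 1 <= s <= N_BINS:
                raise ValueError(f"score {s} outside 1..{N_BINS}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.fraction > 0 and self.from_score == self.to_score:
            raise ValueError("from_score must differ from to_score")

    def applies_to(self, month: str) -> bool:
        return self.months is None or month in self.months


def apply_shift(probs: Sequence[float], shift: ShiftSpec | None) -> np.ndarray:
    """Shifted categorical distribution (a copy; the input is untouched)."""
    p = _check_probs(probs).copy()
    if shift is None or shift.fraction == 0.0:
        return p
    moved = shift.fraction * p[shift.from_score - 1]
    p[shift.from_score - 1] -= moved
    p[shift.to_score - 1] += moved
    return p


@dataclass(frozen=True)
class GeneratorSpec:
    """A stated world for one stream: what to draw, how much, and when.

    ``month_weights`` splits ``n_reports`` across ``months`` (largest-
    remainder allocation so the total is exact); equal weights by default.
    The seed is a required argument — there is no implicit randomness.
    """

    seed: int
    n_reports: int
    months: tuple[str, ...]
    base_probs: tuple[float, ...] = DEFAULT_BASE_PROBS
    month_weights: tuple[float, ...] | None = None
    ai_version: str = "1.2"
    modality: str = "FFDM"
    manufacturer: str = "Hologic"
    center_id: str = "SYN-1"

    def __post_init__(self) -> None:
        _check_probs(self.base_probs)
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.months:
            raise ValueError("at least one month required")
        if self.month_weights is not None:
            w = np.asarray(self.month_weights, dtype=float)
            if w.shape != (len(self.months),):
                raise ValueError("month_weights must align with months")
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("month_weights must be non-negative, one positive")

    @property
    def stream_key(self) -> MatchKey:
        return MatchKey.from_parts(self.ai_version, self.modality, self.manufacturer)

    def monthly_volumes(self) -> np.ndarray:
        """Integer per-month volumes summing exactly to ``n_reports``."""
        k = len(self.months)
        w = (
            np.ones(k) / k
            if self.month_weights is None
            else np.asarray(self.month_weights, dtype=float)
        )
        w = w / w.sum()
        exact = w * self.n_reports
        volumes = np.floor(exact).astype(int)
        remainder = self.n_reports - volumes.sum()
        order = np.argsort(-(exact - volumes))  # largest remainders first
        volumes[order[:remainder]] += 1
        return volumes


def generate_reference(spec: GeneratorSpec, provenance: str = "") -> ReferenceDistribution:
    """One multinomial draw of ``n_reports`` scores from the base distribution,
    packaged as a synthetic retrospective-evaluation reference."""
    rng = np.random.default_rng(spec.seed)
    bins = rng.multinomial(spec.n_reports, _check_probs(spec.base_probs))
    return ReferenceDistribution(
        key=spec.stream_key,
        histogram=ScoreHistogram.from_counts(bins),
        n_exams=spec.n_reports,
        provenance=provenance or f"synthetic retrospective evaluation (seed {spec.seed})",
    )


@dataclass(frozen=True)
class GeneratedStream:
    """A generated report stream plus its exact ground truth.

    ``tallies`` holds the realized per-month bin counts (the generator's own
    bookkeeping, usable as an exact oracle downstream) and ``month_probs``
    the categorical distribution each month was drawn from.
    """

    reports: tuple[ScoreReport, ...]
    tallies: Mapping[str, tuple[int, ...]]
    month_probs: Mapping[str, tuple[float, ...]]

    def pooled_tally(self) -> tuple[int, ...]:
        pooled = np.zeros(N_BINS, dtype=int)
        for t in self.tallies.values():
            pooled += np.asarray(t, dtype=int)
        return tuple(int(c) for c in pooled)


def generate_stream(spec: GeneratorSpec, shift: ShiftSpec | None = None) -> GeneratedStream:
    """Draw a monthly report stream, optionally with an injected shift.

    Per month: the bin tally is one multinomial draw of that month's volume
    from the (possibly shifted) base distribution, report dates are uniform
    over the month's days, and report order is shuffled so scores are not
    sorted within a month.  Identical ``(spec, shift)`` inputs produce
    identical streams.
    """
    rng = np.random.default_rng(spec.seed)
    volumes = spec.monthly_volumes()
    reports: list[ScoreReport] = []
    tallies: dict[str, tuple[int, ...]] = {}
    month_probs: dict[str, tuple[float, ...]] = {}

    for label, volume in zip(spec.months, volumes):
        probs = apply_shift(
            spec.base_probs, shift if (shift and shift.applies_to(label)) else None
        )
        month_probs[label] = tuple(float(v) for v in probs)
        tally = rng.multinomial(volume, probs)
        tallies[label] = tuple(int(c) for c in tally)

        scores = np.repeat(np.arange(1, N_BINS + 1), tally)
        rng.shuffle(scores)
        year, month = (int(p) for p in label.split("-"))
        n_days = calendar.monthrange(year, month)[1]
        days = np.sort(rng.integers(1, n_days + 1, size=volume))
        reports.extend(
            ScoreReport(
                score=int(s),
                manufacturer=spec.manufacturer,
                modality=spec.modality,
                ai_version=spec.ai_version,
                center_id=spec.center_id,
                timestamp=datetime.date(year, month, int(d)),
            )
            for s, d in zip(scores, days)
        )
    return GeneratedStream(tuple(reports), tallies, month_probs)


def default_workspace_spec(seed: int = 20210401) -> dict:
    """A 4-center demo world with realistic deployment volumes.

    Three reference entries (FFDM v1.2, FFDM v1.3, DBT v2.0, 13k-25k exams
    each) and four centers whose monthly volumes span ~90 to ~1,700 reports
    over 6-13 months, one of them running a patch release (2.0.1) that must
    match its 2.0 reference.  Center streams are drawn from the *realized*
    reference distribution (see ``workspace.build_workspace``), so with no
    shift injected the world is an exact null.
    """
    return {
        "seed": seed,
        "reference": {
            "base_probs": list(DEFAULT_BASE_PROBS),
            "entries": [
                {"ai_version": "1.2", "modality": "FFDM", "manufacturer": "Hologic", "n_exams": 13433},
                {"ai_version": "1.3", "modality": "FFDM", "manufacturer": "Hologic", "n_exams": 25330},
                {"ai_version": "2.0", "modality": "DBT", "manufacturer": "Hologic", "n_exams": 14187},
            ],
        },
        "centers": [
            {"center_id": "C-1", "ai_version": "1.2", "modality": "FFDM",
             "manufacturer": "Hologic", "start_month": "2021-04", "n_months": 11,
             "reports_per_month": 1679},
            {"center_id": "C-2", "ai_version": "1.3", "modality": "FFDM",
             "manufacturer": "Hologic", "start_month": "2021-10", "n_months": 6,
             "reports_per_month": 1038},
            {"center_id": "C-3", "ai_version": "2.0.1", "modality": "DBT",
             "manufacturer": "Hologic", "start_month": "2021-10", "n_months": 13,
             "reports_per_month": 854},
            {"center_id": "C-4", "ai_version": "1.2", "modality": "FFDM",
             "manufacturer": "Hologic", "start_month": "2021-07", "n_months": 9,
             "reports_per_month": 87},
        ],
    }
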