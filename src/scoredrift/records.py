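"""Core record types for AI score-report streams and reference registries.

A deployed mammography AI emits one anonymized report per analyzed exam,
carrying an integer suspicion score (1 = low, 10 = high suspicion of
malignancy) together with the metadata needed to pick the right reference
baseline: mammography-unit manufacturer, image modality (FFDM or DBT),
the AI version that produced the score, the reporting center, and a
timestamp.  Monitoring compares the stream's score distribution against a
reference distribution keyed by (AI version major.minor, modality,
manufacturer).
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field

__all__ = [
    "MODALITIES",
    "SCORE_MIN",
    "SCORE_MAX",
    "RecordError",
    "ScoreReport",
    "MatchKey",
    "ReferenceDistribution",
    "parse_date",
    "version_major_minor",
]

SCORE_MIN = 1
SCORE_MAX = 10
MODALITIES = frozenset({"FFDM", "DBT"})

# Reason codes attached to rejected records.
OUT_OF_RANGE_SCORE = "out-of-range-score"
BAD_SCORE = "bad-score"
UNKNOWN_MODALITY = "unknown-modality"
UNPARSEABLE_TIMESTAMP = "unparseable-timestamp"
MISSING_FIELD = "missing-field"
BAD_VERSION = "bad-version"

# Leading "major.minor" with an optional trailing patch / variant suffix,
# e.g. "1.2", "2.0.1", "1.2-US".
_VERSION_RE = re.compile(r"^\s*(\d+)\.(\d+)([.\-].*)?\s*$")


class RecordError(ValueError):
    """A record violates an invariant; carries a machine-readable reason code."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


def version_major_minor(ai_version: str) -> str:
    """Reduce a dotted AI version string to its ``major.minor`` matching key.

    Deployed builds carry patch components ("2.0.1") or market suffixes
    ("1.2-US") while references are registered per major.minor release, so
    matching is done on the first two numeric components.

    Raises :class:`RecordError` (code ``bad-version``) when the string does
    not start with two dot-separated numeric components.
    """
    m = _VERSION_RE.match(ai_version or "")
    if m is None:
        raise RecordError(BAD_VERSION, f"cannot parse AI version {ai_version!r}")
    return f"{m.group(1)}.{m.group(2)}"


def parse_date(value: str | datetime.date | datetime.datetime) -> datetime.date:
    """Parse an ISO-8601 date or date-time down to day precision."""
    if isinstance(value, datetime.datetime):
        return value.date()
    if isinstance(value, datetime.date):
        return value
    text = str(value).strip()
    try:
        return datetime.date.fromisoformat(text[:10])
    except ValueError:
        pass
    try:
        return datetime.datetime.fromisoformat(text).date()
    except ValueError as exc:
        raise RecordError(
            UNPARSEABLE_TIMESTAMP, f"cannot parse timestamp {text!r}"
        ) from exc


def _norm_token(token: str) -> str:
    return token.strip().casefold()


@dataclass(frozen=True, slots=True)
class ScoreReport:
    """One anonymized AI output record: a score plus its matching metadata."""

    score: int
    manufacturer: str
    modality: str
    ai_version: str
    center_id: str
    timestamp: datetime.date

    def validate(self) -> "ScoreReport":
        """Check all invariants, raising :class:`RecordError` on the first failure."""
        if not isinstance(self.score, int) or isinstance(self.score, bool):
            raise RecordError(BAD_SCORE, f"score {self.score!r} is not an integer")
        if not SCORE_MIN <= self.score <= SCORE_MAX:
            raise RecordError(
                OUT_OF_RANGE_SCORE,
                f"score {self.score} outside [{SCORE_MIN}, {SCORE_MAX}]",
            )
        if self.modality not in MODALITIES:
            raise RecordError(
                UNKNOWN_MODALITY,
                f"modality {self.modality!r} not in {sorted(MODALITIES)}",
            )
        for name in ("manufacturer", "center_id"):
            if not str(getattr(self, name)).strip():
                raise RecordError(MISSING_FIELD, f"empty field {name!r}")
        version_major_minor(self.ai_version)
        if not isinstance(self.timestamp, datetime.date):
            raise RecordError(
                UNPARSEABLE_TIMESTAMP, f"timestamp {self.timestamp!r} is not a date"
            )
        return self

    @property
    def match_key(self) -> "MatchKey":
        return MatchKey.from_parts(self.ai_version, self.modality, self.manufacturer)

    @property
    def month(self) -> str:
        """Calendar-month window label, ``YYYY-MM``."""
        return f"{self.timestamp.year:04d}-{self.timestamp.month:02d}"


@dataclass(frozen=True, slots=True)
class MatchKey:
    """Normalized (AI version major.minor, modality, manufacturer) matching key.

    Manufacturer tokens are trimmed and compared case-insensitively because
    vendor strings in DICOM-derived logs vary in casing; the display form
    (first casing seen) is kept for reporting.
    """

    version: str
    modality: str
    manufacturer: str          # casefolded, used for equality
    manufacturer_display: str = field(default="", compare=False)

    @classmethod
    def from_parts(cls, ai_version: str, modality: str, manufacturer: str) -> "MatchKey":
        if modality not in MODALITIES:
            raise RecordError(UNKNOWN_MODALITY, f"modality {modality!r} unknown")
        manufacturer = str(manufacturer)
        if not manufacturer.strip():
            raise RecordError(MISSING_FIELD, "empty manufacturer")
        return cls(
            version=version_major_minor(ai_version),
            modality=modality,
            manufacturer=_norm_token(manufacturer),
            manufacturer_display=manufacturer.strip(),
        )

    def __str__(self) -> str:
        name = self.manufacturer_display or self.manufacturer
        return f"{name} ({self.modality}), V {self.version}"


@dataclass(frozen=True)
class ReferenceDistribution:
    """A reference score distribution from a retrospective evaluation.

    The histogram of scores obtained by running a specific AI version on a
    retrospective dataset for one (modality, manufacturer) combination; it
    encodes the behavior expected from the deployed tool and is the control
    point deviations are measured against.
    """

    key: MatchKey
    histogram: "ScoreHistogram"  # noqa: F821 - imported at call sites
    n_exams: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.n_exams <= 0:
            raise RecordError(MISSING_FIELD, "n_exams must be positive")
        if self.n_exams != self.histogram.total:
            raise RecordError(
                "count-mismatch",
                f"n_exams {self.n_exams} != histogram total {self.histogram.total}",
            )
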