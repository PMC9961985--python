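"""Readers and writers for AI report logs and the reference registry.

Two interchangeable report-log dialects are supported, both round-trippable:

* delimited text with a named header row (comma- or tab-separated,
  auto-detected from the header line) with columns
  ``score, manufacturer, modality, ai_version, center_id, date``;
* line-delimited JSON with the same field names.

The reference registry is a single JSON document::

    {"entries": [
        {"ai_version": "1.2", "modality": "FFDM", "manufacturer": "Hologic",
         "n_exams": 13433, "bins": [<10 ints, summing to n_exams>],
         "provenance": "retrospective evaluation, 2006-2019"},
        ...]}

Malformed report records are never silently dropped: every rejected line is
returned in a rejection log with its line number and a reason code.
Registry entries whose bin counts disagree with ``n_exams`` are rejected
per entry, while duplicate (version, modality, manufacturer) keys are a
fatal error because matching would become ambiguous.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .histogram import N_BINS, ScoreHistogram
from .records import (
    MISSING_FIELD,
    BAD_SCORE,
    MatchKey,
    RecordError,
    ReferenceDistribution,
    ScoreReport,
    parse_date,
)

__all__ = [
    "REPORT_FIELDS",
    "Rejection",
    "ReadResult",
    "read_reports",
    "write_reports",
    "read_reference_registry",
    "write_reference_registry",
    "DuplicateKeyError",
]

REPORT_FIELDS = ("score", "manufacturer", "modality", "ai_version", "center_id", "date")


class DuplicateKeyError(ValueError):
    """Two registry entries share a (version, modality, manufacturer) key."""


@dataclass(frozen=True, slots=True)
class Rejection:
    """One rejected input line: where, why, and the raw payload."""

    line_number: int
    code: str
    message: str
    raw: str = ""


@dataclass
class ReadResult:
    """Accepted records plus the complete rejection log for one read."""

    reports: list[ScoreReport]
    rejections: list[Rejection]

    @property
    def n_input_lines(self) -> int:
        return len(self.reports) + len(self.rejections)


def _open_text(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # caller owns the handle
    return open(source, "r", encoding="utf-8", newline=""), True


def _record_from_fields(fields: dict) -> ScoreReport:
    for name in REPORT_FIELDS:
        value = fields.get(name)
        if value is None or str(value).strip() == "":
            raise RecordError(MISSING_FIELD, f"missing field {name!r}")
    raw_score = fields["score"]
    try:
        score = int(str(raw_score).strip())
    except (TypeError, ValueError) as exc:
        raise RecordError(BAD_SCORE, f"score {raw_score!r} is not an integer") from exc
    report = ScoreReport(
        score=score,
        manufacturer=str(fields["manufacturer"]).strip(),
        modality=str(fields["modality"]).strip(),
        ai_version=str(fields["ai_version"]).strip(),
        center_id=str(fields["center_id"]).strip(),
        timestamp=parse_date(fields["date"]),
    )
    return report.validate()


def _sniff_format(header: str) -> str:
    stripped = header.lstrip()
    if stripped.startswith("{"):
        return "jsonl"
    return "\t" if "\t" in header else ","


def read_reports(source: str | Path | IO[str]) -> ReadResult:
    """Read a report log, validating every record.

    Accepts delimited text with a header (separator auto-detected) or
    line-delimited JSON; the dialect is sniffed from the first line.
    Returns the accepted :class:`ScoreReport` records together with a log
    of every rejected line; an unreadable source raises ``OSError``.
    """
    handle, owned = _open_text(source)
    try:
        first = handle.readline()
        if first == "":
            return ReadResult([], [])
        kind = _sniff_format(first)
        if kind == "jsonl":
            lines = [first] + handle.readlines()
            return _read_jsonl(lines)
        return _read_delimited(first, handle, delimiter=kind)
    finally:
        if owned:
            handle.close()


def _read_delimited(header: str, handle: IO[str], delimiter: str) -> ReadResult:
    columns = [c.strip() for c in next(csv.reader([header], delimiter=delimiter))]
    reports: list[ScoreReport] = []
    rejections: list[Rejection] = []
    reader = csv.reader(handle, delimiter=delimiter)
    for line_number, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        raw = delimiter.join(row)
        if len(row) != len(columns):
            rejections.append(
                Rejection(line_number, MISSING_FIELD, f"expected {len(columns)} fields, got {len(row)}", raw)
            )
            continue
        fields = dict(zip(columns, row))
        try:
            reports.append(_record_from_fields(fields))
        except RecordError as exc:
            rejections.append(Rejection(line_number, exc.code, str(exc), raw))
    return ReadResult(reports, rejections)


def _read_jsonl(lines: Iterable[str]) -> ReadResult:
    reports: list[ScoreReport] = []
    rejections: list[Rejection] = []
    for line_number, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        try:
            fields = json.loads(line)
        except json.JSONDecodeError as exc:
            rejections.append(Rejection(line_number, "bad-json", str(exc), line.rstrip("\n")))
            continue
        if not isinstance(fields, dict):
            rejections.append(Rejection(line_number, "bad-json", "not an object", line.rstrip("\n")))
            continue
        try:
            reports.append(_record_from_fields(fields))
        except RecordError as exc:
            rejections.append(Rejection(line_number, exc.code, str(exc), line.rstrip("\n")))
    return ReadResult(reports, rejections)


def _report_row(report: ScoreReport) -> dict:
    return {
        "score": report.score,
        "manufacturer": report.manufacturer,
        "modality": report.modality,
        "ai_version": report.ai_version,
        "center_id": report.center_id,
        "date": report.timestamp.isoformat(),
    }


def write_reports(
    reports: Sequence[ScoreReport],
    destination: str | Path | IO[str],
    fmt: str = "csv",
) -> None:
    """Write reports as ``csv``, ``tsv`` or ``jsonl`` (round-trips with
    :func:`read_reports`)."""
    if fmt not in ("csv", "tsv", "jsonl"):
        raise ValueError(f"unknown format {fmt!r}")
    handle, owned = (
        (destination, False)
        if hasattr(destination, "write")
        else (open(destination, "w", encoding="utf-8", newline=""), True)
    )
    try:
        if fmt == "jsonl":
            for r in reports:
                handle.write(json.dumps(_report_row(r)) + "\n")
        else:
            writer = csv.DictWriter(
                handle, fieldnames=REPORT_FIELDS, delimiter="\t" if fmt == "tsv" else ","
            )
            writer.writeheader()
            for r in reports:
                writer.writerow(_report_row(r))
    finally:
        if owned:
            handle.close()


def read_reference_registry(
    source: str | Path | IO[str],
) -> tuple[list[ReferenceDistribution], list[Rejection]]:
    """Load the reference registry, validating each entry.

    Entries whose bins do not sum to ``n_exams`` (or that are otherwise
    malformed) are rejected with a diagnostic; a duplicate matching key
    raises :class:`DuplicateKeyError` because it would make reference
    matching ambiguous.
    """
    handle, owned = _open_text(source)
    try:
        document = json.load(handle)
    finally:
        if owned:
            handle.close()
    entries = document.get("entries") if isinstance(document, dict) else None
    if not isinstance(entries, list):
        raise ValueError("registry document must be an object with an 'entries' list")

    references: list[ReferenceDistribution] = []
    rejections: list[Rejection] = []
    seen: set[MatchKey] = set()
    for index, entry in enumerate(entries):
        try:
            key = MatchKey.from_parts(
                entry["ai_version"], entry["modality"], entry["manufacturer"]
            )
            bins = entry["bins"]
            if len(bins) != N_BINS:
                raise RecordError("bad-bins", f"expected {N_BINS} bins, got {len(bins)}")
            histogram = ScoreHistogram.from_counts(bins)
            n_exams = int(entry["n_exams"])
            reference = ReferenceDistribution(
                key=key,
                histogram=histogram,
                n_exams=n_exams,
                provenance=str(entry.get("provenance", "")),
            )
        except KeyError as exc:
            rejections.append(Rejection(index, MISSING_FIELD, f"missing field {exc}"))
            continue
        except RecordError as exc:
            rejections.append(Rejection(index, exc.code, str(exc)))
            continue
        except (TypeError, ValueError) as exc:
            rejections.append(Rejection(index, "bad-entry", str(exc)))
            continue
        if reference.key in seen:
            raise DuplicateKeyError(f"duplicate registry key {reference.key}")
        seen.add(reference.key)
        references.append(reference)
    return references, rejections


def write_reference_registry(
    references: Sequence[ReferenceDistribution],
    destination: str | Path | IO[str],
) -> None:
    """Serialize a registry to the JSON document format read back by
    :func:`read_reference_registry`."""
    entries = [
        {
            "ai_version": ref.key.version,
            "modality": ref.key.modality,
            "manufacturer": ref.key.manufacturer_display or ref.key.manufacturer,
            "n_exams": ref.n_exams,
            "bins": list(ref.histogram.bins),
            "provenance": ref.provenance,
        }
        for ref in references
    ]
    payload = json.dumps({"entries": entries}, indent=2)
    if hasattr(destination, "write"):
        destination.write(payload + "\n")
    else:
        Path(destination).write_text(payload + "\n", encoding="utf-8")
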