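"""Build complete demo worlds from a simulation spec, in memory or on disk.

A simulation spec is a plain mapping (usually loaded from YAML) describing
one seeded world: the reference registry entries to synthesize and the
center streams to draw.  By default each center stream is sampled from the
*realized* empirical distribution of its matched reference entry — not from
the underlying base probabilities — so a no-shift world is an exact null
for the χ² test (expected counts are derived from the very distribution
the stream was drawn from).  A center may instead declare its own
``base_probs``, or a ``shift`` to inject drift.

All sub-seeds are derived deterministically from the spec's single seed.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .engine import MonitoringConfig
from .io import write_reference_registry, write_reports
from .records import MatchKey, ReferenceDistribution
from .synthetic import (
    DEFAULT_BASE_PROBS,
    GeneratedStream,
    GeneratorSpec,
    ShiftSpec,
    generate_reference,
    generate_stream,
    month_range,
)

__all__ = ["World", "build_world", "build_workspace", "write_manifest"]

MANIFEST_NAME = "manifest.json"


def _subseeds(seed: int, n: int) -> list[int]:
    # deterministic child seeds, kept below 2**31
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def _parse_shift(raw: Mapping[str, Any] | None) -> ShiftSpec | None:
    if not raw:
        return None
    months = raw.get("months")
    return ShiftSpec(
        from_score=int(raw["from_score"]),
        to_score=int(raw["to_score"]),
        fraction=float(raw["fraction"]),
        months=None if months is None else tuple(str(m) for m in months),
    )


@dataclass
class World:
    """One realized synthetic world: registry plus per-center streams."""

    seed: int
    references: list[ReferenceDistribution]
    streams: list[tuple[GeneratorSpec, ShiftSpec | None, GeneratedStream]]

    def all_reports(self) -> list:
        reports: list = []
        for _, _, stream in self.streams:
            reports.extend(stream.reports)
        return reports


def build_world(spec: Mapping[str, Any], seed: int | None = None) -> World:
    """Realize a simulation spec into references and report streams.

    ``seed`` overrides the spec's own seed when given.  Raises
    ``ValueError`` with a field-level message on an invalid spec.
    """
    try:
        world_seed = int(seed if seed is not None else spec["seed"])
        ref_spec = spec["reference"]
        center_specs = spec["centers"]
    except KeyError as exc:
        raise ValueError(f"simulation spec missing field {exc}") from exc
    if not center_specs:
        raise ValueError("simulation spec declares no centers")

    ref_base = tuple(float(p) for p in ref_spec.get("base_probs") or DEFAULT_BASE_PROBS)
    entries = ref_spec.get("entries") or []
    if not entries:
        raise ValueError("simulation spec declares no reference entries")
    seeds = _subseeds(world_seed, len(entries) + len(center_specs))

    references: list[ReferenceDistribution] = []
    for entry, sub in zip(entries, seeds):
        try:
            gspec = GeneratorSpec(
                seed=sub,
                n_reports=int(entry["n_exams"]),
                months=("1900-01",),  # references are not windowed
                base_probs=tuple(float(p) for p in entry.get("base_probs") or ref_base),
                ai_version=str(entry["ai_version"]),
                modality=str(entry["modality"]),
                manufacturer=str(entry["manufacturer"]),
            )
        except KeyError as exc:
            raise ValueError(f"reference entry missing field {exc}") from exc
        references.append(generate_reference(gspec))

    streams: list[tuple[GeneratorSpec, ShiftSpec | None, GeneratedStream]] = []
    for entry, sub in zip(center_specs, seeds[len(entries):]):
        try:
            key = MatchKey.from_parts(
                str(entry["ai_version"]), str(entry["modality"]), str(entry["manufacturer"])
            )
            months = month_range(str(entry["start_month"]), int(entry["n_months"]))
            n_reports = int(entry["reports_per_month"]) * len(months)
        except KeyError as exc:
            raise ValueError(f"center entry missing field {exc}") from exc

        if entry.get("base_probs"):
            base = tuple(float(p) for p in entry["base_probs"])
        else:
            matched = next((r for r in references if r.key == key), None)
            base = (
                tuple(matched.histogram.probabilities())
                if matched is not None
                else ref_base
            )
        gspec = GeneratorSpec(
            seed=sub,
            n_reports=n_reports,
            months=months,
            base_probs=base,
            ai_version=str(entry["ai_version"]),
            modality=str(entry["modality"]),
            manufacturer=str(entry["manufacturer"]),
            center_id=str(entry["center_id"]),
        )
        shift = _parse_shift(entry.get("shift"))
        streams.append((gspec, shift, generate_stream(gspec, shift)))
    return World(world_seed, references, streams)


def write_manifest(
    out_dir: str | Path,
    command: str,
    inputs: Mapping[str, Any],
    config: Mapping[str, Any],
    seeds: Sequence[int] = (),
) -> Path:
    """Record how an output directory was produced (exactly one per directory)."""
    path = Path(out_dir) / MANIFEST_NAME
    payload = {
        "tool": "scoredrift",
        "version": __version__,
        "command": command,
        "created": datetime.datetime.now().isoformat(timespec="seconds"),
        "inputs": dict(inputs),
        "config": dict(config),
        "seeds": list(seeds),
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return path


def build_workspace(
    spec: Mapping[str, Any],
    out_dir: str | Path,
    seed: int | None = None,
    config: MonitoringConfig | None = None,
) -> World:
    """Write a complete demo workspace: registry, per-center logs, ground
    truth, a monitoring config, and a manifest."""
    world = build_world(spec, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_reference_registry(world.references, out / "registry.json")

    log_paths = {}
    for gspec, _, stream in world.streams:
        path = out / f"reports-{gspec.center_id}.csv"
        write_reports(stream.reports, path, fmt="csv")
        log_paths[gspec.center_id] = path.name

    ground_truth = {
        gspec.center_id: {
            "stream_key": str(gspec.stream_key),
            "shift": None
            if shift is None
            else {
                "from_score": shift.from_score,
                "to_score": shift.to_score,
                "fraction": shift.fraction,
                "months": None if shift.months is None else list(shift.months),
            },
            "tallies": {m: list(t) for m, t in stream.tallies.items()},
            "month_probs": {m: list(p) for m, p in stream.month_probs.items()},
        }
        for gspec, shift, stream in world.streams
    }
    (out / "ground_truth.json").write_text(
        json.dumps(ground_truth, indent=2) + "\n", encoding="utf-8"
    )

    cfg = config or MonitoringConfig()
    config_doc = {
        "pcc_threshold": cfg.pcc_threshold,
        "alpha": cfg.alpha,
        "min_window_n": cfg.min_window_n,
        "min_expected": cfg.min_expected,
        "severity_cutpoints": list(cfg.severity_cutpoints),
    }
    (out / "config.yaml").write_text(
        yaml.safe_dump(config_doc, sort_keys=False), encoding="utf-8"
    )

    write_manifest(
        out,
        command="simulate",
        inputs={"registry": "registry.json", "report_logs": log_paths},
        config=config_doc,
        seeds=[world.seed],
    )
    return world
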