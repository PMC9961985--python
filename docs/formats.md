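# File formats

## Report logs

One record per analyzed exam. Two interchangeable, round-trippable
dialects; the reader sniffs the dialect from the first line.

### Delimited text (CSV or TSV)

Header row required; separator auto-detected from the header (tab if the
header contains one, comma otherwise). Columns, in any order:

| column         | type    | constraints                                      |
|----------------|---------|--------------------------------------------------|
| `score`        | integer | 1..10                                            |
| `manufacturer` | string  | non-empty; compared case-insensitively, trimmed  |
| `modality`     | string  | `FFDM` or `DBT`                                  |
| `ai_version`   | string  | ≥ 2 dotted numeric components (`1.2`, `2.0.1`, `1.2-US`) |
| `center_id`    | string  | non-empty                                        |
| `date`         | string  | ISO-8601 date or date-time; stored at day precision |

```csv
score,manufacturer,modality,ai_version,center_id,date
3,Hologic,FFDM,1.2,US-1,2021-04-02
10,Fuji,DBT,2.0.1,US-2,2021-04-30
```

### Line-delimited JSON

One JSON object per line with the same field names:

```json
{"score": 3, "manufacturer": "Hologic", "modality": "FFDM", "ai_version": "1.2", "center_id": "US-1", "date": "2021-04-02"}
```

Malformed records are rejected line by line with a reason code
(`out-of-range-score`, `bad-score`, `unknown-modality`,
`unparseable-timestamp`, `missing-field`, `bad-version`, `bad-json`);
accepted + rejected always equals the number of input lines.

## Reference registry

A single JSON document; schema in `registry.schema.json`.

```json
{
  "entries": [
    {
      "ai_version": "1.2",
      "modality": "FFDM",
      "manufacturer": "Hologic",
      "n_exams": 13433,
      "bins": [6104, 2064, 1241, 972, 723, 656, 525, 457, 375, 316],
      "provenance": "retrospective evaluation, 2006-2019"
    }
  ]
}
```

`bins` are the counts for scores 1..10 and must sum to `n_exams`
(violations reject the entry). Matching keys — (`ai_version` reduced to
major.minor, `modality`, `manufacturer` case-folded) — must be unique
across entries; a duplicate is a fatal error.

## Monitoring outputs

`scoredrift monitor --out DIR` writes:

* `results.csv` / `results.jsonl` — one record per (center, window):
  key fields, `n_center`, `n_reference`, `pcc`, `chi2_stat`,
  `chi2_pvalue`, `chi2_df`, `wd_raw`, `wd_normalized`, the ten
  `bin_diffs` percentage points, `flags`, `alert_level`, `severity`,
  `causes`;
* `summaries.json` — per-center monthly-PCC mean/sd/min/max;
* `summary.md` — the human-readable tables;
* `rejections.csv` — every rejected input record with source, line and
  reason;
* `plots/hist-<center>-global.png` — side-by-side score histograms;
* `manifest.json` — inputs, configuration, tool version, timestamp.

`scoredrift report` renders `report.md` plus `timeline-<center>.png`
strictly from these files.

## Simulation spec (YAML)

```yaml
seed: 99
reference:
  base_probs: null          # default right-skewed base
  entries:
    - {ai_version: "1.2", modality: FFDM, manufacturer: Hologic, n_exams: 8000}
centers:
  - center_id: C-A
    ai_version: "1.2"
    modality: FFDM
    manufacturer: Hologic
    start_month: "2021-04"
    n_months: 3
    reports_per_month: 600
    # base_probs: [...]     # optional: draw from these instead of the
                            # realized reference distribution
    shift:                  # optional drift injection
      from_score: 4
      to_score: 10
      fraction: 0.5
      months: ["2021-05"]   # null = whole stream
```
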