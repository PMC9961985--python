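"""Reference matching, windowing, evaluation, the deviation rule, summaries."""

import datetime
import statistics

import numpy as np
import pytest

from scoredrift import (
    Alert,
    ComparisonResult,
    GeneratorSpec,
    MatchKey,
    MetricResult,
    MonitoringConfig,
    ScoreHistogram,
    ScoreReport,
    build_histogram,
    classify,
    diagnose_mismatch,
    evaluate_window,
    generate_stream,
    match_reference,
    month_range,
    run_monitoring,
    summarize_center,
    windowize,
)
from scoredrift.workspace import build_world
from scoredrift.synthetic import default_workspace_spec
from .conftest import make_hist


def key(version, modality, manufacturer="Hologic"):
    return MatchKey.from_parts(version, modality, manufacturer)


def report(score=5, day=1, month=4, year=2021, center="US-1", version="1.2"):
    return ScoreReport(score, "Hologic", "FFDM", version, center,
                       datetime.date(year, month, day))


def metric(pcc=0.99, pvalue=0.5, wd_norm=0.01):
    return MetricResult(pcc=pcc, chi2_stat=1.0, chi2_pvalue=pvalue, chi2_df=9,
                        wd_raw=wd_norm * 9, wd_normalized=wd_norm)


def result(pcc=0.99, pvalue=0.5, wd_norm=0.01, n=1000, flags=()):
    return ComparisonResult(
        center_id="US-1", window="2021-04", stream_key=key("1.2", "FFDM"),
        reference_key=key("1.2", "FFDM"), n_center=n, n_reference=13433,
        metrics=metric(pcc, pvalue, wd_norm), bin_diffs=(0.0,) * 10,
        flags=frozenset(flags),
    )


class TestMatching:
    def test_patch_release_matches_major_minor_reference(self, reference):
        # a 2.0.1 deployment must pair with the registered 2.0 reference
        ref_20 = type(reference)(
            key=key("2.0", "DBT"), histogram=reference.histogram,
            n_exams=reference.n_exams,
        )
        assert match_reference(key("2.0.1", "DBT"), [ref_20]) is ref_20

    def test_absent_key_is_unmatched_not_an_error(self, reference):
        assert match_reference(key("1.2", "FFDM", "Fuji"), [reference]) is None

    def test_manufacturer_matching_is_case_insensitive(self, reference):
        assert match_reference(key("1.2", "FFDM", "  hOlOgIc "), [reference]) is reference

    @pytest.mark.parametrize(
        "stream,ref,expected",
        [
            (("1.2", "FFDM", "Hologic"), ("2.0", "DBT", "Hologic"),
             ["wrong-version", "wrong-modality"]),
            (("1.2", "FFDM", "Hologic"), ("1.2", "FFDM", "Hologic"), []),
            (("1.2", "FFDM", "Hologic"), ("1.3", "FFDM", "Fuji"),
             ["wrong-version", "wrong-manufacturer"]),
            (("1.3", "FFDM", "Hologic"), ("1.3", "FFDM", "Fuji"),
             ["wrong-manufacturer"]),
        ],
    )
    def test_mismatch_diagnosis(self, stream, ref, expected):
        assert diagnose_mismatch(key(*stream), key(*ref)) == expected


class TestWindowize:
    def test_calendar_partition(self):
        reports = [report(day=2), report(day=30), report(day=1, month=5)]
        windows = windowize(reports, "monthly")
        assert [(label, len(rs)) for label, rs in windows] == [
            ("2021-04", 2), ("2021-05", 1)
        ]

    def test_global_is_one_window(self):
        reports = [report(day=2), report(day=30), report(day=1, month=5)]
        assert [(w, len(rs)) for w, rs in windowize(reports, "global")] == [("global", 3)]

    def test_eleven_month_stream_yields_eleven_windows(self):
        spec = GeneratorSpec(seed=3, n_reports=11 * 200,
                             months=month_range("2021-04", 11))
        stream = generate_stream(spec)
        windows = windowize(list(stream.reports), "monthly")
        assert [label for label, _ in windows] == list(month_range("2021-04", 11))
        # partition: disjoint and exhaustive
        assert sum(len(rs) for _, rs in windows) == len(stream.reports)


class TestEvaluateWindow:
    def test_identity_window(self, reference):
        res = evaluate_window(reference.histogram, reference, MonitoringConfig())
        assert res.metrics.pcc == pytest.approx(1.0, abs=1e-12)
        assert res.metrics.chi2_stat == pytest.approx(0.0, abs=1e-9)
        assert res.metrics.wd_raw == 0.0
        assert res.flags == frozenset()

    def test_half_of_bin4_moved_to_ten(self, reference):
        bins = list(reference.histogram.bins)
        moved = bins[3] // 2
        bins[3] -= moved
        bins[9] += moved
        res = evaluate_window(make_hist(bins), reference, MonitoringConfig())
        mu4 = reference.histogram.bins[3] / reference.n_exams
        expected = (moved / reference.histogram.bins[3]) * mu4 * 6
        assert res.metrics.wd_raw == pytest.approx(expected, abs=1e-12)

    def test_null_windows_rarely_lose_correlation(self, reference, rng):
        """Windows drawn from the reference itself keep PCC > 0.99 in at
        least 99 of 100 seeded draws at n = 5,000."""
        probs = reference.histogram.probabilities()
        draws = rng.multinomial(5000, probs, size=100)
        high = sum(
            evaluate_window(make_hist(d), reference, MonitoringConfig()).metrics.pcc
            > 0.99
            for d in draws
        )
        assert high >= 99

    def test_small_window_flagged_but_still_measured(self, reference, rng):
        draw = rng.multinomial(30, reference.histogram.probabilities())
        res = evaluate_window(make_hist(draw), reference, MonitoringConfig())
        assert "insufficient-data" in res.flags
        assert res.metrics is not None

    def test_empty_window_has_no_metrics(self, reference):
        res = evaluate_window(make_hist([0] * 10), reference, MonitoringConfig())
        assert res.metrics is None
        assert "insufficient-data" in res.flags

    def test_uniform_window_flags_undefined_pcc(self, reference):
        res = evaluate_window(make_hist([60] * 10), reference, MonitoringConfig())
        assert res.metrics.pcc is None
        assert "pcc-undefined" in res.flags


class TestClassify:
    def test_healthy_global_window(self):
        alert = classify(result(pcc=0.998, pvalue=0.853))
        assert alert.level == "none"
        assert alert.causes == ()

    def test_threshold_rule_fires_on_pcc_alone(self):
        alert = classify(result(pcc=0.94, pvalue=0.20))
        assert alert.level == "deviation"
        assert alert.causes == ("pcc-below-threshold",)

    def test_exactly_at_threshold_is_not_a_deviation(self):
        assert classify(result(pcc=0.95)).level == "none"
        assert classify(result(pcc=0.95 - 1e-9)).level == "deviation"

    def test_mismatch_is_always_a_cause(self):
        alert = classify(result(pcc=0.374), ["wrong-manufacturer"])
        assert alert.level == "deviation"
        assert "reference-mismatch:wrong-manufacturer" in alert.causes
        assert "pcc-below-threshold" in alert.causes

    def test_insufficient_data_suppresses_metric_causes(self):
        alert = classify(result(pcc=0.5, pvalue=0.001, flags=["insufficient-data"]))
        assert alert.level == "none"

    def test_monotone_in_pcc(self):
        """Lowering the PCC (all else fixed) never turns a deviation into none."""
        previously_deviating = False
        for p in np.linspace(1.0, 0.0, 41):
            deviating = classify(result(pcc=float(p))).level == "deviation"
            assert deviating or not previously_deviating
            previously_deviating = deviating

    def test_severity_graded_from_normalized_wd(self):
        cfg = MonitoringConfig()
        assert classify(result(pcc=0.9, wd_norm=0.01), config=cfg).severity == "low"
        assert classify(result(pcc=0.9, wd_norm=0.05), config=cfg).severity == "moderate"
        assert classify(result(pcc=0.9, wd_norm=0.30), config=cfg).severity == "high"

    def test_alert_invariant_enforced(self):
        with pytest.raises(ValueError):
            Alert(level="deviation", severity="low", causes=())


class TestSummaries:
    def monthly(self, pccs):
        return [
            ComparisonResult(
                center_id="US-1", window=f"2021-{i + 1:02d}",
                stream_key=key("1.2", "FFDM"), reference_key=key("1.2", "FFDM"),
                n_center=1000, n_reference=13433, metrics=metric(pcc=p),
                bin_diffs=(0.0,) * 10,
            )
            for i, p in enumerate(pccs)
        ]

    def test_two_month_summary(self):
        s = summarize_center(self.monthly([0.9, 1.0]))
        assert (s.pcc_mean, s.pcc_min, s.pcc_max) == (pytest.approx(0.95), 0.9, 1.0)

    def test_single_month_population_sd_is_zero(self):
        s = summarize_center(self.monthly([0.97]))
        assert s.pcc_mean == pytest.approx(0.97)
        assert s.pcc_sd == 0.0

    def test_matches_independent_computation(self, rng):
        pccs = list(0.95 + 0.04 * rng.random(12))
        s = summarize_center(self.monthly(pccs))
        assert s.pcc_mean == pytest.approx(statistics.fmean(pccs), abs=1e-12)
        assert s.pcc_sd == pytest.approx(statistics.pstdev(pccs), abs=1e-12)

    def test_no_defined_pccs_errors(self):
        with pytest.raises(ValueError):
            summarize_center([])


class TestRunMonitoring:
    def test_null_world_end_to_end(self):
        world = build_world(default_workspace_spec(seed=1))
        run = run_monitoring(world.all_reports(), world.references)
        assert len(run.summaries) == 4
        # every report lands in exactly one monthly window
        monthly_n = sum(
            r.n_center for r in run.results if r.window != "global"
        )
        assert monthly_n == len(world.all_reports())
        # global windows at these volumes stay tightly correlated
        for r in run.results:
            if r.window == "global":
                assert r.metrics.pcc > 0.99

    def test_forced_wrong_reference_annotates_mismatch(self, reference):
        spec = GeneratorSpec(seed=9, n_reports=2000, months=("2021-04", "2021-05"),
                             ai_version="1.3", center_id="US-2")
        stream = generate_stream(spec)
        run = run_monitoring(
            list(stream.reports),
            [reference],  # registry only has the 1.2 reference
            force_reference={"US-2": reference.key},
        )
        assert all(a.level == "deviation" for a in run.alerts)
        assert all(
            "reference-mismatch:wrong-version" in a.causes for a in run.alerts
        )

    def test_unmatched_stream_raises_alert_not_crash(self):
        spec = GeneratorSpec(seed=9, n_reports=500, months=("2021-04",),
                             manufacturer="Fuji", center_id="US-9")
        stream = generate_stream(spec)
        run = run_monitoring(list(stream.reports), [])
        assert all(a.level == "deviation" for a in run.alerts)
        assert all("unmatched-reference" in a.causes for a in run.alerts)
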