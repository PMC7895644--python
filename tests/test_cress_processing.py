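"""Plausibility cleaning, outlier substitution, and the corrected-series
pipeline."""

import numpy as np
import pytest

from smoketop.cress_processing import (
    CleaningParams,
    OutlierRule,
    ccress_pipeline,
    clean_cress,
    correct_ipis,
)
from smoketop.session_model import (
    CressLog,
    CressRecord,
    TopographySeries,
    ValidationError,
)
from smoketop.synthetic_session import (
    CressArtifactConfig,
    simulate_cress_log,
    simulate_session,
)
from smoketop.topography import events_to_topography


def _log(pairs):
    return CressLog(records=tuple(CressRecord(pd_ms=p, ipi_ms=i) for p, i in pairs))


class TestCleanCress:
    def test_five_ms_fragment_merged_into_preceding(self):
        """Hand-traced merge: fragment's PD and flanking IPI are absorbed."""
        log = _log([(1500, 0), (5, 200), (1200, 3000)])
        cleaned, report = clean_cress(log, CleaningParams())
        assert len(cleaned) == 2
        # 1500 + 5 + 200 = 1705; following gap untouched
        assert [r.pd_ms for r in cleaned] == [1705, 1200]
        assert [r.ipi_ms for r in cleaned] == [0, 3000]
        assert any(r["action"] == "merge_into_preceding" for r in report)

    def test_first_record_fragment_merges_forward(self):
        log = _log([(5, 65000), (1500, 400), (1200, 3000)])
        cleaned, report = clean_cress(
            log, CleaningParams(leading_ipi_rule="drop_if_over_ms")
        )
        # leading 65000 dropped first, then 5 ms fragment absorbed forward:
        # next pd 1500 + 5 + its 400 gap = 1905, carrying the (zeroed) lead
        assert [r.pd_ms for r in cleaned] == [1905, 1200]
        assert [r.ipi_ms for r in cleaned] == [0, 3000]
        actions = [r["action"] for r in report]
        assert "drop_leading_ipi" in actions and "merge_into_following" in actions

    def test_leading_interval_dropped_only_over_threshold(self):
        log = _log([(1500, 65000), (1200, 3000)])
        cleaned, report = clean_cress(log, CleaningParams())
        assert cleaned.records[0].ipi_ms == 0
        log2 = _log([(1500, 5000), (1200, 3000)])
        _, report2 = clean_cress(log2, CleaningParams())
        assert report2 == []

    def test_artifact_free_log_unchanged(self):
        log = _log([(1500, 30000), (1200, 3000), (1100, 8000)])
        cleaned, report = clean_cress(log, CleaningParams())
        assert cleaned == log
        assert report == []

    def test_merge_conserves_total_recorded_time(self, short_config):
        _, truth, _ = simulate_session(short_config)
        art = CressArtifactConfig(
            seed=2, split_probability=0.6, jitter_sd_ms=0.0, leading_ipi_ms=30000
        )
        log = simulate_cress_log(truth, art)
        before = sum(r.pd_ms for r in log) + sum(r.ipi_ms for r in log)
        cleaned, _ = clean_cress(log, CleaningParams(merge_fragments=True))
        after = sum(r.pd_ms for r in cleaned) + sum(r.ipi_ms for r in cleaned)
        assert after == pytest.approx(before, abs=1.0)
        assert len(cleaned) < len(log)

    def test_delete_mode_moves_time_into_following_gap(self):
        log = _log([(1500, 0), (5, 200), (1200, 3000)])
        cleaned, report = clean_cress(log, CleaningParams(merge_fragments=False))
        assert [r.pd_ms for r in cleaned] == [1500, 1200]
        assert [r.ipi_ms for r in cleaned] == [0, 3205]
        assert report[0]["action"] == "delete"


class TestCorrectIpis:
    def test_range_rule_substitutes_mean_of_remaining(self):
        series = TopographySeries(
            pd_ms=[1000] * 6,
            ipi_ms=[5, 20000, 21000, 22000, 90000],
            source="cress",
        )
        rule = OutlierRule(method="range", min_ipi_ms=1000, max_ipi_ms=60000)
        corrected, flags = correct_ipis(series, rule)
        assert list(corrected.ipi_ms) == [21000, 20000, 21000, 22000, 21000]
        assert list(flags) == [True, False, False, False, True]
        assert corrected.pd_ms == series.pd_ms

    def test_no_flags_is_identity(self):
        series = TopographySeries(
            pd_ms=[1000] * 4, ipi_ms=[20000, 21000, 22000], source="cress"
        )
        corrected, flags = correct_ipis(series, OutlierRule())
        assert corrected.ipi_ms == series.ipi_ms
        assert not flags.any()

    def test_mad_rule_all_equal_is_identity(self):
        series = TopographySeries(
            pd_ms=[1000] * 5, ipi_ms=[20000] * 4, source="cress"
        )
        corrected, flags = correct_ipis(series, OutlierRule(method="mad"))
        assert corrected.ipi_ms == series.ipi_ms
        assert not flags.any()

    def test_mad_rule_flags_gross_outlier(self):
        series = TopographySeries(
            pd_ms=[1000] * 6,
            ipi_ms=[20000, 21000, 22000, 20500, 500000],
            source="cress",
        )
        corrected, flags = correct_ipis(series, OutlierRule(method="mad", mad_k=3))
        assert flags[-1] and not flags[:-1].any()
        assert corrected.ipi_ms[-1] == pytest.approx(np.mean([20000, 21000, 22000, 20500]))

    def test_all_flagged_raises(self):
        series = TopographySeries(pd_ms=[1000] * 3, ipi_ms=[5, 7], source="cress")
        with pytest.raises(ValidationError):
            correct_ipis(series, OutlierRule(method="range", min_ipi_ms=1000, max_ipi_ms=60000))

    def test_idempotent_under_same_rule(self):
        series = TopographySeries(
            pd_ms=[1000] * 6,
            ipi_ms=[5, 20000, 21000, 22000, 90000],
            source="cress",
        )
        rule = OutlierRule(method="range", min_ipi_ms=1000, max_ipi_ms=60000)
        once, _ = correct_ipis(series, rule)
        twice, flags2 = correct_ipis(once, rule)
        assert twice.ipi_ms == once.ipi_ms
        assert not flags2.any()

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            OutlierRule(min_ipi_ms=5000, max_ipi_ms=1000)


class TestCcressPipeline:
    def test_artifact_free_log_recovers_truth_exactly(self, short_config):
        _, truth, _ = simulate_session(short_config)
        art = CressArtifactConfig(split_probability=0.0, jitter_sd_ms=0.0)
        log = simulate_cress_log(truth, art)
        result = ccress_pipeline(log)
        truth_series = events_to_topography(truth)
        assert result.series.pd_ms == truth_series.pd_ms
        assert result.series.ipi_ms == truth_series.ipi_ms
        assert result.series.source == "cress_corrected"

    def test_split_artifacts_are_repaired(self, short_config):
        _, truth, _ = simulate_session(short_config)
        art = CressArtifactConfig(seed=1, split_probability=0.4, jitter_sd_ms=0.0)
        log = simulate_cress_log(truth, art)
        assert len(log) > len(truth)  # seeded: at least one split occurred
        result = ccress_pipeline(log)
        truth_series = events_to_topography(truth)
        assert result.series.n_puffs == len(truth)
        np.testing.assert_allclose(result.series.pd_ms, truth_series.pd_ms)
        np.testing.assert_allclose(result.series.ipi_ms, truth_series.ipi_ms)

    def test_fully_implausible_log_errors_on_empty_reference_set(self):
        log = _log([(5, 65000), (4, 200), (6, 300)])
        with pytest.raises(ValidationError):
            ccress_pipeline(log)

    def test_correction_never_hurts_on_seeded_replicates(self, short_config):
        """Corrected-vs-truth agreement >= raw-vs-truth in >= 95/100 replicates."""
        from smoketop.agreement import pearson_r2

        def profile_r2(a, b):
            n_pd = min(len(a.pd_ms), len(b.pd_ms))
            n_ipi = min(len(a.ipi_ms), len(b.ipi_ms))
            return pearson_r2(
                list(a.pd_ms[:n_pd]) + list(a.ipi_ms[:n_ipi]),
                list(b.pd_ms[:n_pd]) + list(b.ipi_ms[:n_ipi]),
            )

        wins = 0
        for seed in range(100):
            cfg = short_config.model_copy(update={"seed": seed + 500})
            _, truth, _ = simulate_session(cfg)
            art = CressArtifactConfig(seed=seed, split_probability=0.15, jitter_sd_ms=50)
            log = simulate_cress_log(truth, art)
            truth_series = events_to_topography(truth)
            raw = ccress_raw = None
            from smoketop.topography import cress_to_topography

            raw = cress_to_topography(log, drop_leading_ipi=True)
            corrected = ccress_pipeline(log).series
            if profile_r2(corrected, truth_series) >= profile_r2(raw, truth_series) - 1e-12:
                wins += 1
        assert wins >= 95
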