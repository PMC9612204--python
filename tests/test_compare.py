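"""Comparison statistics against hand and enumeration oracles, reliability
aggregation, impedance/metadata summaries and report assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capcompare.compare import (
    IncompleteReportError,
    UndefinedCorrelationError,
    build_report,
    channel_reliability,
    impedance_summary,
    ks_normality,
    mann_whitney_u,
    metadata_summary,
    pearson_r,
    prep_time_ratio,
    rmsd,
)
from capcompare.preprocess import ChannelRating, InsufficientDataError, RatingReason, Verdict
from capcompare.synthdata import CapType, SubjectMetadata


def _rating(channel, good):
    return ChannelRating(channel, Verdict.GOOD if good else Verdict.BAD,
                         RatingReason.NONE if good else RatingReason.ARTIFACT,
                         0.0 if good else 1.0)


class TestChannelReliability:
    def test_three_of_four_sequences(self):
        recs = [("dry", "equidistant_64", f"seg{i}", _rating("1L", i != 0)) for i in range(4)]
        table = channel_reliability(recs).table
        assert table.loc[0, "reliability"] == pytest.approx(0.75)

    def test_all_good_is_one(self):
        recs = [("gel", "l", "s", _rating("Cz", True)) for _ in range(6)]
        assert channel_reliability(recs).table.loc[0, "reliability"] == 1.0

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(0)
        recs = [
            ("dry", "l", f"s{i}", _rating(f"ch{j}", rng.random() > 0.3))
            for i in range(5) for j in range(4)
        ]
        t1 = channel_reliability(recs).table
        t2 = channel_reliability(list(reversed(recs))).table
        assert t1["reliability"].between(0, 1).all()
        pd.testing.assert_frame_equal(t1, t2)

    def test_simulated_binomial_recovery(self, ten_twenty):
        # 20 subjects x 4 segments at bad-probability 0.2: the automated
        # rating should recover per-channel reliability near 0.8 with
        # binomial sampling spread (n = 80 ratings per channel)
        from capcompare.preprocess import apply_filters, rate_channels
        from capcompare.synthdata import SegmentKind, short_config, simulate_session

        cfg = short_config(n_subjects=20, seed=31,
                           bad_channel_prob={"gel": 0.2, "dry": 0.2})
        recs = []
        for i in range(20):
            rec, _ = simulate_session(cfg, f"S{i}", CapType.GEL, ten_twenty)
            filt = apply_filters(rec)
            for seg in rec.segments:
                exclude = None
                offset = 0.0
                if seg.kind is SegmentKind.BLINK:
                    exclude = [(t - seg.start - 0.3, t - seg.start + 0.3)
                               for t in seg.trigger_times]
                    first = seg.trigger_times[0] - seg.start
                    offset = (first - 0.5) % 1.0
                ratings = rate_channels(
                    filt.segment_data(seg.kind), rec.sampling_rate,
                    labels=rec.layout.labels, exclude_spans=exclude,
                    window_offset_s=offset,
                )
                recs.extend(("gel", "l", seg.kind.value, r) for r in ratings)
        table = channel_reliability(recs).table
        p, n = 0.8, 80
        ci = 1.96 * np.sqrt(p * (1 - p) / n)
        within = np.abs(table["reliability"] - p) <= ci
        # ~95% of channels inside the binomial CI; the grand mean inside too
        assert within.mean() >= 0.85
        assert abs(table["reliability"].mean() - p) <= ci

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            channel_reliability([])


class TestAgreementMetrics:
    def test_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert rmsd(x, x) == 0.0

    def test_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_values(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 2.0, 5.0])
        assert rmsd(x, y) == pytest.approx(np.sqrt((1 + 0 + 4) / 3))
        # hand product-moment computation
        xm, ym = x - x.mean(), y - y.mean()
        r_hand = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
        assert pearson_r(x, y) == pytest.approx(r_hand, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r(np.ones(5), np.arange(5.0))

    @given(
        a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        assert pearson_r(a * x + b, y) == pytest.approx(pearson_r(x, y), abs=1e-9)


def exact_u_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Brute-force two-sided U-test p-value by full enumeration of labelings."""
    pooled = np.concatenate([x, y])
    n_a = len(x)
    nm = n_a * len(y)

    def u_of(idx_a):
        a = pooled[list(idx_a)]
        b = np.delete(pooled, list(idx_a))
        return sum((ai > b).sum() + 0.5 * (ai == b).sum() for ai in a)

    u_obs = u_of(range(n_a))
    lo, hi = min(u_obs, nm - u_obs), max(u_obs, nm - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        u = u_of(combo)
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


class TestMannWhitney:
    def test_spec_example_2_of_6(self):
        res = mann_whitney_u(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0)

    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = mann_whitney_u(x, x.copy())
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_sweep(self):
        # all tie-free sample-size pairs with n_a + n_b <= 10
        rng = np.random.default_rng(12)
        for n_a in range(1, 9):
            for n_b in range(1, 11 - n_a):
                x = rng.standard_normal(n_a)
                y = rng.standard_normal(n_b)
                ours = mann_whitney_u(x, y).p_value
                brute = exact_u_pvalue(x, y)
                assert ours == pytest.approx(brute, abs=1e-12), (n_a, n_b)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8) + 0.5
        exact = mann_whitney_u(x, y).p_value  # tie-free -> exact path
        from scipy import stats

        approx = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert approx == pytest.approx(exact, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u(np.array([]), np.array([1.0]))


class TestKsNormality:
    def test_uniform_rejected(self):
        rng = np.random.default_rng(5)
        res = ks_normality(rng.uniform(0, 1, 500))
        assert res.decision == "reject"

    def test_normal_calibration(self):
        # fraction of false rejections at alpha=0.05 across 100 seeds
        accept = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = ks_normality(rng.standard_normal(500))
            accept += res.p_value > 0.05
        assert accept >= 90

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(20))

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            ks_normality(np.arange(5.0))


def _meta(subject, cap, prep, imp_start, imp_end):
    return SubjectMetadata(
        subject_id=subject, cap_type=cap, prep_time=prep, acquisition_time=20.0,
        attention_start=3.0, attention_end=3.0, comfort_start=2.0, comfort_end=2.0,
        impedance_start=imp_start, impedance_end=imp_end,
    )


class TestImpedanceSummary:
    def test_start_end_average(self):
        m = _meta("S1", CapType.GEL, 30.0, {"Cz": 100.0}, {"Cz": 200.0})
        out = impedance_summary([m])
        assert out.loc[0, "mean"] == pytest.approx(150.0)

    def test_mismatched_electrode_sets_rejected(self):
        m = _meta("S1", CapType.GEL, 30.0, {"Cz": 100.0, "Pz": 50.0}, {"Cz": 200.0})
        with pytest.raises(ValueError, match="disagree"):
            impedance_summary([m])

    def test_simulated_dry_exceeds_gel(self, study):
        _, _, report = study
        imp = report.sections["impedance"]
        grand = imp.groupby("cap")["grand_mean"].first()
        assert grand["dry"] > grand["gel"]


class TestMetadataSummary:
    def test_printed_grand_averages_give_38_percent_ratio(self):
        # the study's printed grand averages: gel 32.3 min, dry 12.4 min
        table = pd.DataFrame(
            [{"cap": "gel", "prep_time": 32.3}, {"cap": "dry", "prep_time": 12.4}]
        )
        out = metadata_summary(table)
        assert out["prep_time_ratio"] == pytest.approx(0.38)
        assert out["prep_time_reduction_pct"] == 62

    def test_identical_caps_ratio_one(self):
        table = pd.DataFrame(
            [{"cap": "gel", "prep_time": 20.0}, {"cap": "dry", "prep_time": 20.0}]
        )
        out = metadata_summary(table)
        assert out["prep_time_ratio"] == 1.0
        assert out["prep_time_reduction_pct"] == 0

    def test_single_subject_degenerate_sd_flag(self):
        table = pd.DataFrame(
            [{"cap": "gel", "prep_time": 20.0}, {"cap": "dry", "prep_time": 10.0}]
        )
        out = metadata_summary(table)
        assert out["degenerate_sd"] is True
        assert out["per_cap"]["gel"]["prep_time"]["sd"] == 0.0

    def test_ratio_helper(self):
        assert prep_time_ratio(32.3, 12.4) == (0.38, 62)


class TestBuildReport:
    def test_missing_stage_rejected(self):
        with pytest.raises(IncompleteReportError, match="comparison_metrics"):
            build_report(
                {"metadata_summary": {}, "reliability": {}, "impedance": {},
                 "test_results": {}},
                "abc", 0,
            )

    def test_report_serializes_and_is_deterministic(self, study):
        _, _, report = study
        doc1 = report.to_json()
        doc2 = report.to_json()
        assert doc1 == doc2
        assert '"provenance"' in doc1
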