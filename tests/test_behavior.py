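"""Experiment-side statistics: attention vectors, correlations, t-tests."""

import numpy as np
import pandas as pd
import pytest

from attnalloc import (
    AOI,
    AttentionVector,
    FixationTable,
    KeypressLog,
    Model,
    ValueProfile,
    allocate,
    correlation_matrix,
    fixation_attention,
    full_report,
    keypress_attention,
    one_sample_ttest,
)

from conftest import (
    EYETRACK_MEANS_PERCENT,
    KEYPRESS_MEANS_PERCENT,
    MATSUI_PERCENT,
    PROPOSED_PERCENT,
)

LABELS = ("a", "b", "c", "d")
AOIS = [
    AOI("a", 0, 0, 100, 100),
    AOI("b", 100, 0, 200, 100),
    AOI("c", 0, 100, 100, 200),
    AOI("d", 100, 100, 200, 200),
]


def make_keylog(ratios_by_pid: dict, n_events: int = 10) -> KeypressLog:
    """Log with exactly n_events overloads per AOI and the requested
    per-AOI correct-response ratios (ratios must be multiples of 1/n)."""
    rows = []
    for pid, ratios in ratios_by_pid.items():
        for aoi, ratio in zip(LABELS, ratios):
            n_correct = round(ratio * n_events)
            for j in range(n_events):
                ok = j < n_correct
                rows.append((pid, 1000.0 * j, aoi, ok, ok))
    return KeypressLog(pd.DataFrame(rows, columns=["participant", "time_ms", "aoi", "responded", "correct"]))


class TestKeypressAttention:
    def test_two_aoi_even_ratios(self):
        rows = [("p1", 0.0, aoi, ok, ok) for aoi in ("a", "b") for ok in (True, False)]
        log = KeypressLog(pd.DataFrame(rows, columns=["participant", "time_ms", "aoi", "responded", "correct"]))
        vec = keypress_attention(log, ("a", "b"))
        np.testing.assert_allclose(vec.fractions, [0.5, 0.5], atol=1e-12)

    def test_reference_ratio_normalization(self):
        # O = (0.12, 0.23, 0.67, 0.89) normalizes near (but not exactly to)
        # the published participant-averaged group means
        log = make_keylog({"p1": (0.12, 0.23, 0.67, 0.89)}, n_events=100)
        vec = keypress_attention(log, LABELS)
        np.testing.assert_allclose(
            vec.percent, [6.2827, 12.0419, 35.0785, 46.5969], atol=5e-3
        )

    def test_all_correct_uniform(self):
        log = make_keylog({"p1": (1.0, 1.0, 1.0, 1.0)})
        np.testing.assert_allclose(keypress_attention(log, LABELS).fractions, 0.25)

    def test_zero_overload_aoi_excludes_participant(self):
        log = make_keylog({"p1": (0.5, 0.5, 0.5, 0.5)})
        # p2 has no events at AOI 'd'
        extra = pd.DataFrame(
            [("p2", 0.0, aoi, True, True) for aoi in ("a", "b", "c")],
            columns=log.data.columns,
        )
        log2 = KeypressLog(pd.concat([log.data, extra], ignore_index=True))
        vec = keypress_attention(log2, LABELS)
        assert vec.excluded == ("p2",)
        np.testing.assert_allclose(vec.fractions, 0.25, atol=1e-12)

    def test_correct_implies_responded_enforced(self):
        df = pd.DataFrame(
            [("p1", 0.0, "a", False, True)],
            columns=["participant", "time_ms", "aoi", "responded", "correct"],
        )
        with pytest.raises(ValueError):
            KeypressLog(df)


class TestFixationAttention:
    @staticmethod
    def table(points, pid="p1"):
        return FixationTable(
            pd.DataFrame(
                [(pid, 100.0 * i, 200.0, x, y) for i, (x, y) in enumerate(points)],
                columns=["participant", "start_ms", "duration_ms", "x", "y"],
            )
        )

    def test_equal_counts_uniform(self):
        pts = [(50, 50), (150, 50), (50, 150), (150, 150)]
        vec = fixation_attention(self.table(pts), AOIS)
        np.testing.assert_allclose(vec.percent, 25.0, atol=1e-12)

    def test_counts_already_percent(self):
        pts = (
            [(50, 50)] * 6 + [(150, 50)] * 9 + [(50, 150)] * 35 + [(150, 150)] * 50
        )
        vec = fixation_attention(self.table(pts), AOIS)
        np.testing.assert_allclose(vec.percent, [6, 9, 35, 50], atol=1e-12)

    def test_boundary_point_assigned_to_exactly_one_aoi(self):
        # (100, 50) sits on the shared vertical edge: half-open rectangles
        # put it in 'b', never in 'a'
        vec = fixation_attention(self.table([(100.0, 50.0), (0.0, 0.0)]), AOIS)
        np.testing.assert_allclose(vec.fractions, [0.5, 0.5, 0.0, 0.0])

    def test_outside_fixations_dropped(self):
        vec = fixation_attention(self.table([(50, 50), (999, 999)]), AOIS)
        np.testing.assert_allclose(vec.fractions, [1.0, 0.0, 0.0, 0.0])

    def test_no_in_aoi_fixations_error(self):
        with pytest.raises(ValueError):
            fixation_attention(self.table([(999, 999)]), AOIS)

    def test_duration_weighting_option(self):
        df = pd.DataFrame(
            [("p1", 0.0, 300.0, 50, 50), ("p1", 400.0, 100.0, 150, 50)],
            columns=["participant", "start_ms", "duration_ms", "x", "y"],
        )
        vec = fixation_attention(FixationTable(df), AOIS, duration_weighted=True)
        np.testing.assert_allclose(vec.fractions, [0.75, 0.25, 0.0, 0.0])

    def test_overlapping_aois_rejected(self):
        bad = AOIS[:3] + [AOI("d", 50, 50, 200, 200)]
        with pytest.raises(ValueError, match="overlap"):
            fixation_attention(self.table([(10, 10)]), bad)


def _vec(name, values):
    arr = np.asarray(values, dtype=float)
    return AttentionVector(name, LABELS, arr / arr.sum())


class TestCorrelation:
    def test_self_correlation_is_one(self):
        vs = {"x": _vec("x", MATSUI_PERCENT), "y": _vec("y", MATSUI_PERCENT)}
        entry = correlation_matrix(vs)[0]
        assert entry.r == pytest.approx(1.0, abs=1e-12)

    def test_model_pair_reproduces_published_value(self):
        vs = {"m": _vec("m", MATSUI_PERCENT), "p": _vec("p", PROPOSED_PERCENT)}
        entry = correlation_matrix(vs)[0]
        assert round(entry.r, 3) == 0.939
        assert entry.p == pytest.approx(0.061, abs=5e-4)

    def test_key_eye_group_means_reproduce_published_value(self):
        vs = {
            "key": _vec("key", KEYPRESS_MEANS_PERCENT),
            "eye": _vec("eye", EYETRACK_MEANS_PERCENT),
        }
        entry = correlation_matrix(vs)[0]
        assert round(entry.r, 3) == 0.996
        assert entry.p < 0.01

    def test_affine_invariance_percent_vs_fraction(self):
        a = {"x": _vec("x", MATSUI_PERCENT), "y": _vec("y", PROPOSED_PERCENT)}
        b = {
            "x": AttentionVector("x", LABELS, np.asarray(MATSUI_PERCENT) / 100.0 / (MATSUI_PERCENT.sum() / 100.0)),
            "y": _vec("y", PROPOSED_PERCENT * 7.0),
        }
        assert correlation_matrix(a)[0].r == pytest.approx(correlation_matrix(b)[0].r, abs=1e-12)

    def test_zero_variance_reported_undefined(self):
        vs = {"flat": AttentionVector("flat", LABELS, np.full(4, 0.25)),
              "y": _vec("y", PROPOSED_PERCENT)}
        entry = correlation_matrix(vs)[0]
        assert np.isnan(entry.r) and entry.p is None

    def test_requires_two_vectors_of_length_three(self):
        with pytest.raises(ValueError):
            correlation_matrix({"x": _vec("x", MATSUI_PERCENT)})


class TestOneSampleTTest:
    def test_mean_equal_to_test_value(self):
        res = one_sample_ttest([0.3, 0.4, 0.35, 0.35], 0.35)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.mean_difference == pytest.approx(0.0, abs=1e-12)

    def test_published_group_row(self):
        """A 14-participant sample with the published mean/sd reproduces the
        published mean difference at print rounding."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=14)
        x = (x - x.mean()) / x.std(ddof=1) * 0.0523 + 0.3534
        res = one_sample_ttest(x, 0.3573, sample_name="key", aoi="0.7")
        assert res.mean_difference == pytest.approx(-0.0039, abs=5e-5)
        assert res.df == 13

    def test_symmetric_sample(self):
        res = one_sample_ttest([0.30] * 7 + [0.40] * 7, 0.35)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(-res.ci_high, abs=1e-12)

    def test_ci_excludes_zero_iff_significant(self, rng):
        for _ in range(20):
            x = rng.normal(0.4, 0.05, size=12)
            res = one_sample_ttest(x, 0.37)
            excludes = res.ci_low > 0 or res.ci_high < 0
            assert excludes == (res.p < 0.05)

    def test_zero_variance_undefined(self):
        res = one_sample_ttest([0.4, 0.4, 0.4], 0.3)
        assert res.t is None and res.p is None

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_sample_ttest([0.4], 0.3)
        with pytest.raises(ValueError):
            one_sample_ttest([0.4, 0.5], 1.3)


class TestFullReport:
    @pytest.fixture
    def profile(self):
        return ValueProfile(list(zip(LABELS, (0.1, 0.3, 0.7, 0.9))))

    def test_model_only_report(self, profile):
        report = full_report(profile)
        assert set(report.vectors) == {"model_matsui", "model_proposed"}
        np.testing.assert_allclose(
            report.vectors["model_proposed"].percent, PROPOSED_PERCENT, atol=5e-3
        )
        assert round(report.correlation("model_matsui", "model_proposed").r, 3) == 0.939

    def test_empty_keylog_gives_partial_report(self, profile):
        empty = KeypressLog(pd.DataFrame(columns=["participant", "time_ms", "aoi", "responded", "correct"]))
        report = full_report(profile, keylog=empty)
        assert "key" not in report.vectors

    def test_label_mismatch_reported(self, profile):
        bad = [AOI("a", 0, 0, 100, 100), AOI("b", 100, 0, 200, 100),
               AOI("c", 0, 100, 100, 200), AOI("wrong", 100, 100, 200, 200)]
        with pytest.raises(ValueError, match="wrong"):
            full_report(profile, fixations=None, aois=bad)

    def test_per_participant_sums(self, profile):
        log = make_keylog({"p1": (0.2, 0.4, 0.6, 0.8), "p2": (0.1, 0.5, 0.5, 0.9)})
        vec = keypress_attention(log, LABELS)
        sums = vec.per_participant.sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        assert abs(vec.fractions.sum() - 1.0) < 1e-9
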