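"""Metric oracles: accuracy/F1 vs sklearn, t tests vs closed form, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import wearaffect as wa

# Published per-participant accuracies / F1s of the three model types, used
# here as inputs to the summary statistics (the summary row is the oracle).
PERSONALIZED_ACC = [
    68.36, 82.32, 99.99, 99.90, 98.02, 99.57, 100.00, 100.00, 100.00, 93.69,
    100.00, 98.34, 99.81, 100.00, 85.83,
]
INCLUSIVE_ACC = [
    82.69, 67.12, 82.81, 82.86, 82.94, 54.57, 82.05, 53.72, 51.86, 82.05,
    60.86, 53.53, 53.26, 53.47, 60.43,
]
EXCLUSIVE_ACC = [
    53.94, 81.91, 82.81, 82.31, 74.67, 54.03, 83.23, 53.70, 51.83, 79.85,
    62.11, 53.60, 65.35, 53.54, 81.91,
]


class TestConfusionMatrixMetrics:
    def test_accuracy_examples(self):
        assert wa.accuracy(np.diag([5, 5, 5])) == 100.0
        assert wa.accuracy(np.array([[3, 1, 0], [0, 0, 0], [0, 0, 0]])) == 75.0
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        assert wa.accuracy(cm) == 80.0

    def test_macro_f1_hand_computed(self):
        # per-class F1: 0.8000, 0.7059, 0.8696 -> macro 79.18%
        cm = np.array([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        assert wa.f1_score(cm) == pytest.approx(79.18, abs=0.005)

    def test_perfect_diagonal(self):
        assert wa.f1_score(np.diag([7, 3, 2])) == 100.0

    def test_degenerate_class_zero_convention(self, caplog):
        # class 2 never predicted, never true -> F1 contribution 0, flagged
        cm = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        with caplog.at_level("WARNING", logger="wearaffect.metrics"):
            val = wa.f1_score(cm)
        assert val == pytest.approx(100.0 * (1 + 1 + 0) / 3)
        assert "convention" in caplog.text

    def test_balanced_matrix_accuracy_equals_macro_f1(self):
        # symmetric confusion across balanced classes
        cm = np.array([[8, 1, 1], [1, 8, 1], [1, 1, 8]])
        assert wa.accuracy(cm) == pytest.approx(wa.f1_score(cm))

    def test_oracle_equivalence_with_sklearn(self):
        from sklearn.metrics import accuracy_score, f1_score as sk_f1

        rng = np.random.default_rng(4)
        for _ in range(20):
            y_true = rng.integers(0, 3, size=200)
            y_pred = rng.integers(0, 3, size=200)
            cm = wa.confusion_matrix(y_true, y_pred)
            assert wa.accuracy(cm) == pytest.approx(
                100 * accuracy_score(y_true, y_pred)
            )
            assert wa.f1_score(cm) == pytest.approx(
                100 * sk_f1(y_true, y_pred, average="macro"), abs=1e-9
            )
            assert wa.f1_score(cm, averaging="weighted") == pytest.approx(
                100 * sk_f1(y_true, y_pred, average="weighted"), abs=1e-9
            )

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            wa.accuracy(np.zeros((3, 3)))


class TestSummarize:
    def test_closed_form(self):
        mean, sd = wa.summarize([80.0, 90.0])
        assert mean == 85.0
        assert sd == pytest.approx(7.0711, abs=1e-4)

    def test_identical_values(self):
        assert wa.summarize([5, 5, 5])[1] == 0.0

    def test_published_personalized_column(self):
        """Feeding the published per-participant accuracies reproduces the
        published mean (SD): 95.06 (9.24)."""
        mean, sd = wa.summarize(PERSONALIZED_ACC)
        assert round(mean, 2) == 95.06
        assert round(sd, 2) == 9.24

    @pytest.mark.parametrize(
        "column,expected_mean,expected_sd",
        [
            (INCLUSIVE_ACC, 66.95, 13.76),
            (EXCLUSIVE_ACC, 67.65, 13.48),
        ],
    )
    def test_published_generalized_columns(self, column, expected_mean, expected_sd):
        mean, sd = wa.summarize(column)
        assert round(mean, 2) == expected_mean
        assert round(sd, 2) == expected_sd


class TestTTests:
    def test_unpaired_closed_form(self):
        # pooled-variance two-sample t: t = 7.348 with 4 df
        r = wa.t_test([90, 95, 100], [60, 65, 70], paired=False)
        se = np.sqrt(25.0 * (1 / 3 + 1 / 3))
        t_hand = 30.0 / se
        assert r.t == pytest.approx(t_hand, abs=1e-9)
        assert r.t == pytest.approx(7.348, abs=5e-4)
        p_hand = 2 * (1 - sps.t.cdf(t_hand, df=4))
        assert r.p == pytest.approx(p_hand, abs=1e-6)

    def test_identical_vectors_paired_undefined(self):
        r = wa.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert not r.defined
        assert np.isnan(r.p)

    def test_constant_shift(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([1.5, 2.5, 3.5])
        paired = wa.t_test(a, b, paired=True)
        assert not paired.defined  # zero-variance differences flagged
        unpaired = wa.t_test(a, b, paired=False)
        assert unpaired.defined and np.isfinite(unpaired.p)

    def test_published_columns_significance_pattern(self):
        """Personalized vs either generalized model differs at P < .001;
        the two generalized models do not differ (P > .05)."""
        vectors = {
            "personalized": np.array(PERSONALIZED_ACC),
            "participant_inclusive": np.array(INCLUSIVE_ACC),
            "participant_exclusive": np.array(EXCLUSIVE_ACC),
        }
        df = wa.pairwise_t_tests(vectors, paired=True)
        get = lambda a, b: df[
            (df.protocol_a == a) & (df.protocol_b == b)
        ].p.item()
        assert get("personalized", "participant_inclusive") < 0.001
        assert get("personalized", "participant_exclusive") < 0.001
        assert get("participant_inclusive", "participant_exclusive") > 0.05

    def test_bonferroni_scales_p(self):
        vectors = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([2.0, 1.0, 4.0, 3.0]),
            "c": np.array([4.0, 3.0, 2.0, 1.0]),
        }
        raw = wa.pairwise_t_tests(vectors)
        adj = wa.pairwise_t_tests(vectors, bonferroni=True)
        for i in range(len(raw)):
            if raw.defined[i] and raw.p[i] * 3 <= 1:
                assert adj.p[i] == pytest.approx(raw.p[i] * 3)

    def test_misaligned_vectors_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            wa.pairwise_t_tests({"a": np.arange(3), "b": np.arange(4)})


class TestModalityProfiles:
    def test_injected_outlier_flagged(self, small_cohort):
        cohort = wa.generate_cohort(small_cohort.config)
        # +5 cross-participant SDs on the EDA-like channel during stress
        rec = cohort.recordings[0]
        base = wa.modality_profiles(cohort)
        ref = base[(base.state == "stress") & (base.modality == "eda")]
        shift = 5.5 * ref["mean"].std(ddof=1)
        rec.signals[1, rec.labels == 1] += shift
        df = wa.modality_profiles(cohort)
        cell = df[
            (df.participant == rec.participant_id)
            & (df.state == "stress")
            & (df.modality == "eda")
        ]
        assert bool(cell.flagged.item())

    def test_homogeneous_cohort_few_flags(self):
        cfg = wa.CohortConfig(
            n_participants=8, sampling_rate=32.0, duration=120.0,
            heterogeneity=0.0, seed=13,
        )
        df = wa.modality_profiles(wa.generate_cohort(cfg))
        rate = df.flagged.mean()
        # leave-one-out z at k=2 has a ~10% null exceedance for 8 subjects
        assert rate < 0.2

    def test_single_participant_no_flags(self, small_cohort):
        solo = wa.Cohort(small_cohort.recordings[:1], small_cohort.config)
        with pytest.warns(UserWarning, match="single participant"):
            df = wa.modality_profiles(solo)
        assert df.flagged.isna().all()

    def test_windowed_input_accepted(self, small_ws):
        df = wa.modality_profiles(small_ws)
        assert {"participant", "state", "modality", "mean", "sd"} <= set(df.columns)


class TestClassBalance:
    def test_default_cohort_inside_emulated_ranges(self, small_ws):
        per, ranges = wa.class_balance_report(small_ws)
        r = ranges.set_index("state")
        # window-level fractions may drift ~1 interval from the sample-level
        # targets; the neutral range of the emulated study is 51.8-54.0
        assert 50.5 <= r.loc["neutral", "min_pct"]
        assert r.loc["neutral", "max_pct"] <= 55.5

    def test_balanced_toy(self):
        X = np.zeros((30, 8, 64))
        y = np.tile([0, 1, 2], 10)
        ws = wa.WindowedDataset(
            X=X, y=y, participant=np.full(30, "A"), start=np.arange(30) * 32
        )
        per, _ = wa.class_balance_report(ws)
        for s in ("neutral", "stress", "amusement"):
            assert per[s].item() == pytest.approx(100 / 3)

    def test_single_class_degenerate_warning(self):
        X = np.zeros((10, 8, 64))
        ws = wa.WindowedDataset(
            X=X,
            y=np.zeros(10, dtype=np.int64),
            participant=np.full(10, "A"),
            start=np.arange(10) * 32,
        )
        with pytest.warns(UserWarning, match="degenerate"):
            per, _ = wa.class_balance_report(ws)
        assert per["neutral"].item() == 100.0
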