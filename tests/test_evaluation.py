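"""One-vs-rest metrics, stratified errors, Wilcoxon signed-ranks."""

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from anotext.evaluation import (
    ConfusionCounts,
    LabelRecord,
    metric_table,
    metrics,
    one_vs_rest_counts,
    read_labels,
    round2,
    stratified_errors,
    wilcoxon_matched_pairs,
)


def rec(i, expert, pred_rnn, pred_dict, group="pathological"):
    return LabelRecord(f"d{i}", group, expert, pred_rnn, pred_dict)


class TestCounts:
    def test_hand_tally(self):
        records = [rec(0, 1, 1, 1), rec(1, 1, -1, -1), rec(2, -1, -1, -1),
                   rec(3, 0, 1, 0)]
        c = one_vs_rest_counts(records, "dict", 1)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 0, 2)

    def test_all_correct(self):
        records = [rec(0, 1, 1, 1), rec(1, -1, -1, -1)]
        c = one_vs_rest_counts(records, "rnn", 1)
        assert c.FN == c.FP == 0

    def test_label_never_present_nor_predicted(self):
        records = [rec(i, 1, 1, 1) for i in range(5)]
        c = one_vs_rest_counts(records, "rnn", 0)
        assert (c.TP, c.FN, c.FP, c.TN) == (0, 0, 0, 5)

    @given(st.lists(st.tuples(st.sampled_from([-1, 0, 1]),
                              st.sampled_from([-1, 1]),
                              st.sampled_from([-1, 0, 1])),
                    min_size=1, max_size=30),
           st.sampled_from([-1, 0, 1]))
    @settings(max_examples=60, deadline=None, derandomize=True,
          suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_counts_partition_records(self, triples, label):
        records = [rec(i, e, r, d) for i, (e, r, d) in enumerate(triples)]
        for method in ("rnn", "dict"):
            c = one_vs_rest_counts(records, method, label)
            assert c.total == len(records)


class TestMetrics:
    def test_forced_arithmetic(self):
        row = metrics(ConfusionCounts(TP=8, TN=8, FP=2, FN=2))
        assert row.TPR == row.PPV == row.F1 == pytest.approx(0.8)

    def test_zero_denominator_is_undefined(self):
        row = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert row.TPR is None and row.PPV is None and row.F1 is None
        assert row.TNR == 1.0

    def test_f1_identity_random_tables(self, rng):
        """F1 = 2*TP/(2TP+FP+FN) == 2*PPV*TPR/(PPV+TPR) wherever defined."""
        for _ in range(300):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 40, size=4))
            row = metrics(ConfusionCounts(tp, tn, fp, fn))
            if row.TPR is not None and row.PPV is not None and (row.PPV + row.TPR):
                harmonic = 2 * row.PPV * row.TPR / (row.PPV + row.TPR)
                assert row.F1 == pytest.approx(harmonic)

    def test_against_sklearn(self, rng):
        """Independent cross-check of TPR/PPV/F1 on random label vectors."""
        from sklearn.metrics import f1_score, precision_score, recall_score

        y_true = rng.choice([-1, 0, 1], size=60)
        y_pred = rng.choice([-1, 0, 1], size=60)
        records = [rec(i, int(t), 1, int(p))
                   for i, (t, p) in enumerate(zip(y_true, y_pred))]
        for label in (-1, 0, 1):
            row = metrics(one_vs_rest_counts(records, "dict", label))
            t = (y_true == label).astype(int)
            p = (y_pred == label).astype(int)
            assert row.TPR == pytest.approx(recall_score(t, p))
            if row.PPV is not None:
                assert row.PPV == pytest.approx(
                    precision_score(t, p, zero_division=np.nan))
            if row.F1 is not None:
                assert row.F1 == pytest.approx(f1_score(t, p))


class TestMetricTable:
    def test_neutral_row_dashes_and_mean_over_defined(self):
        records = [rec(0, 1, 1, 1), rec(1, 0, -1, 0), rec(2, -1, -1, -1)]
        table = metric_table(records, "rnn")
        neutral = table["neutral"]
        assert neutral.TPR is None and neutral.PPV is None and neutral.F1 is None
        assert neutral.TNR is not None and neutral.NPV is not None
        mean = table["mean"]
        tprs = [table["positive"].TPR, table["negative"].TPR]
        assert mean.TPR == round2(sum(tprs) / 2)

    def test_single_record_degenerate(self):
        table = metric_table([rec(0, 1, 1, 1)], "rnn")
        assert table["positive"].TPR == 1.0
        assert table["mean"].TPR == 1.0


class TestStratifiedErrors:
    def test_all_correct_toy_set(self):
        records = [rec(i, 1, 1, 1) for i in range(4)]
        table = stratified_errors(records, "rnn")
        assert table.overall == 0.0
        assert all(v == 0.0 for v in table.by_group["pathological"].values())

    def test_three_errors_among_positive(self):
        records = [rec(i, 1, 1 if i >= 3 else -1, 1) for i in range(10)]
        table = stratified_errors(records, "rnn")
        assert table.by_group["pathological"][1] == pytest.approx(30.0)

    def test_group_total_is_sum_of_labels(self):
        records = [rec(0, 1, -1, 1), rec(1, -1, 1, -1), rec(2, 0, 1, 0),
                   rec(3, 1, 1, -1, group="control"), rec(4, -1, -1, -1, group="control")]
        for method in ("rnn", "dict"):
            table = stratified_errors(records, method)
            for group, labmap in table.by_group.items():
                assert table.group_total[group] == pytest.approx(sum(labmap.values()))

    def test_overall_weighted_over_groups(self):
        records = [rec(0, 1, -1, 1), rec(1, 1, 1, 1),
                   rec(2, 1, 1, 1, group="control"), rec(3, 1, 1, 1, group="control")]
        table = stratified_errors(records, "rnn")
        assert table.overall == pytest.approx(25.0)


def brute_force_wilcoxon_p(diff):
    """Two-sided exact p by full enumeration of the 2^n sign assignments."""
    from scipy.stats import rankdata

    diff = np.asarray([d for d in diff if d != 0.0])
    n = diff.size
    ranks = rankdata(np.abs(diff))
    w_obs = ranks[diff > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_matched_pairs([1, 2, 3], [1, 2, 3])
        assert res.degenerate and res.p_value == 1.0 and res.n_effective == 0

    def test_all_positive_n5(self):
        """All five differences positive: one tail has mass 1/32."""
        res = wilcoxon_matched_pairs([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.n_effective == 5
        assert res.p_value == pytest.approx(2 / 32)

    def test_exact_equals_enumeration_without_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = wilcoxon_matched_pairs(a, b)
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(a - b))

    def test_exact_equals_enumeration_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            a = rng.integers(-2, 3, size=n).astype(float)
            b = rng.integers(-2, 3, size=n).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_matched_pairs(a, b)
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(a - b))

    def test_matches_scipy_exact_in_tie_free_case(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = wilcoxon_matched_pairs(a, b)
        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        res = wilcoxon_matched_pairs(a, b)
        assert not res.exact
        from scipy.stats import wilcoxon as scipy_wilcoxon

        ref = scipy_wilcoxon(a, b, alternative="two-sided", method="approx",
                             correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            wilcoxon_matched_pairs([1, 2], [1])
        with pytest.raises(ValueError):
            wilcoxon_matched_pairs([], [])


def test_read_labels_roundtrip(tmp_path):
    p = tmp_path / "labels.tsv"
    p.write_text("# comment\ndoc_id\tgroup\texpert\trnn\tdict\n"
                 "d1\tpathological\t1\t-1\t0\n")
    records = read_labels(p)
    assert records == [LabelRecord("d1", "pathological", 1, -1, 0)]


def test_label_record_validation():
    with pytest.raises(ValueError):
        LabelRecord("d", "pathological", 1, 0, 1)   # rnn cannot be neutral
    with pytest.raises(ValueError):
        LabelRecord("d", "elsewhere", 1, 1, 1)
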