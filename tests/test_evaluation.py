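import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wmhseg.errors import ContractViolation, ParameterError
from wmhseg.evaluation import (
    ConfusionCounts,
    assign_volume_group,
    boxplot_summary,
    compare_models,
    confusion_counts,
    dsc,
    longitudinal_report,
    longitudinal_split,
    ppv,
    sensitivity,
    wmh_volume,
)
from wmhseg.io import Volume


def _brute_force_counts(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        pw, tw = p == 2, t == 2
        tp += pw and tw
        fp += pw and not tw
        fn += tw and not pw
        tn += not pw and not tw
    return ConfusionCounts(tp, fp, fn, tn)


def test_confusion_counts_perfect_prediction():
    truth = np.zeros((10, 10, 1), dtype=int)
    truth.ravel()[:5] = 2
    c = confusion_counts(truth, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 95)


def test_confusion_counts_all_negative_prediction():
    truth = np.zeros((4, 4, 1), int)
    truth[0, :2, 0] = 2
    c = confusion_counts(np.zeros_like(truth), truth)
    assert c.tp == 0 and c.fn == 2


def test_labels_zero_and_one_both_negative():
    truth = np.full((3, 3, 1), 2, int)
    a = confusion_counts(np.zeros((3, 3, 1), int), truth)
    b = confusion_counts(np.ones((3, 3, 1), int), truth)
    assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


def test_confusion_shape_mismatch():
    with pytest.raises(ContractViolation):
        confusion_counts(np.zeros((2, 2, 2)), np.zeros((3, 2, 2)))


def test_metrics_against_bruteforce_oracle(rng):
    for _ in range(5):
        pred = rng.integers(0, 3, size=(10, 10, 3))
        truth = rng.integers(0, 3, size=(10, 10, 3))
        fast = confusion_counts(pred, truth)
        slow = _brute_force_counts(pred, truth)
        assert fast == slow
        assert dsc(fast) == pytest.approx(
            2 * slow.tp / (2 * slow.tp + slow.fp + slow.fn), abs=1e-12
        )


def test_metric_hand_values():
    c = ConfusionCounts(tp=2, fp=1, fn=1, tn=6)
    assert dsc(c) == pytest.approx(4 / 6, abs=1e-12)
    assert sensitivity(c) == pytest.approx(2 / 3, abs=1e-12)
    assert ppv(c) == pytest.approx(2 / 3, abs=1e-12)
    perfect = ConfusionCounts(tp=5, fp=0, fn=0, tn=5)
    assert dsc(perfect) == sensitivity(perfect) == ppv(perfect) == 1.0
    disjoint = ConfusionCounts(tp=0, fp=3, fn=4, tn=3)
    assert dsc(disjoint) == sensitivity(disjoint) == ppv(disjoint) == 0.0


def test_zero_denominator_conventions():
    empty_both = ConfusionCounts(0, 0, 0, 10)
    assert dsc(empty_both) == 1.0  # two empty masks agree perfectly
    with pytest.warns(RuntimeWarning):
        assert sensitivity(empty_both) == 0.0
    with pytest.warns(RuntimeWarning):
        assert ppv(empty_both) == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(tp=st.integers(1, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
def test_dsc_is_harmonic_mean_of_sens_and_ppv(tp, fp, fn):
    c = ConfusionCounts(tp, fp, fn, 10)
    s, p = sensitivity(c), ppv(c)
    assert dsc(c) == pytest.approx(2 * s * p / (s + p), abs=1e-12)


def test_wmh_volume_arithmetic():
    labels = np.zeros((20, 10, 10), int)
    labels.ravel()[:1000] = 2
    v = Volume.from_voxel_size(labels, (1, 1, 5))
    assert wmh_volume(v) == pytest.approx(5000.0)
    assert wmh_volume(v, voxel_size=(2, 1, 5)) == pytest.approx(10_000.0)
    assert wmh_volume(Volume.from_voxel_size(np.zeros((4, 4, 4), int))) == 0.0
    with pytest.raises(ParameterError):
        wmh_volume(v, voxel_size=(0, 1, 1))


@pytest.mark.parametrize(
    "volume,name",
    [(12_000, "Large"), (10_000, "Large"), (5_000, "Medium"), (4_000, "Medium"),
     (3_999.9, "Small"), (1, "Small")],
)
def test_volume_group_boundaries(volume, name):
    assert assign_volume_group(volume).name == name


def test_volume_groups_partition_without_gaps():
    names = {assign_volume_group(float(v)).name for v in range(1, 20_001, 7)}
    assert names == {"Small", "Medium", "Large"}
    assert assign_volume_group(0.5) is None


def test_compare_models_identical_samples():
    scores = [0.5, 0.6, 0.7, 0.55, 0.65]
    rep = compare_models({"a": scores, "b": scores})
    assert rep["pairwise"]["p_value"].iloc[0] == pytest.approx(1.0)
    rep5 = compare_models({f"m{i}": scores for i in range(5)})
    assert rep5["kruskal"]["statistic"] == pytest.approx(0.0)
    assert rep5["anova_table"]["df"].iloc[0] == 4


def test_compare_models_detects_shifted_distributions(rng):
    a = rng.normal(0.5, 0.01, 30)
    b = rng.normal(0.8, 0.01, 30)
    c = rng.normal(0.2, 0.01, 30)
    rep = compare_models({"a": a, "b": b, "c": c})
    assert rep["kruskal"]["p_value"] < 0.01
    assert (rep["pairwise"]["p_value"] < 0.01).all()


def test_compare_models_needs_two_models():
    with pytest.raises(ParameterError):
        compare_models({"only": [0.1, 0.2]})


def _catalog(n_subj=10, years=(1, 2, 3)):
    rows = [
        {"subject": f"s{i}", "year": y, "scan_id": f"s{i}_y{y}"}
        for i in range(n_subj)
        for y in years
    ]
    return pd.DataFrame(rows)


def test_longitudinal_split_counting():
    split = longitudinal_split(_catalog())
    assert len(split.train) == 10
    assert sum(len(v) for v in split.test_by_year.values()) == 20
    assert set(split.test_by_year) == {2, 3}


def test_longitudinal_split_drops_subjects_without_year1():
    cat = _catalog()
    cat = cat[~((cat.subject == "s0") & (cat.year == 1))]
    with pytest.warns(RuntimeWarning):
        split = longitudinal_split(cat)
    assert "s0_y2" not in split.test_by_year[2]
    assert len(split.train) == 9


def test_longitudinal_split_requires_followup():
    with pytest.raises(ParameterError):
        longitudinal_split(_catalog(years=(1,)))


def test_longitudinal_report_two_year_summary():
    split = longitudinal_split(_catalog(n_subj=3))
    scores = {sid: 0.6 for ids in split.test_by_year.values() for sid in ids}
    rep = longitudinal_report(split, scores)
    assert list(rep["year"]) == [2, 3]
    assert (rep["mean_dsc"] == 0.6).all()


def test_boxplot_summary_fields(rng):
    s = boxplot_summary(rng.uniform(size=100))
    assert set(s) == {"n", "mean", "median", "q1", "q3", "min", "max", "std"}
    assert s["q1"] <= s["median"] <= s["q3"]
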