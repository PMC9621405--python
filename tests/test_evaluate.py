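import numpy as np
import pandas as pd
import pytest

from cxrlabel.evaluate import (
    ConfusionCounts,
    bootstrap_ci,
    confusion,
    macro_average,
    metrics,
    metrics_table,
    prevalence_summary,
    round_half_up,
    stratified_split,
)
from cxrlabel.labeler import LABEL_COLUMNS


def _frame(values, ids=None):
    """Label table from an (n, 5) 0/1 array."""
    values = np.asarray(values)
    df = pd.DataFrame(values, columns=list(LABEL_COLUMNS))
    df.insert(0, "study_id", ids or [f"d{i}" for i in range(len(df))])
    df["status"] = "auto"
    return df


def _random_frame(rng, n):
    # abnormal = OR of regions so rows satisfy the label invariant
    regions = rng.integers(0, 2, size=(n, 4))
    abnormal = regions.max(axis=1).reshape(-1, 1)
    return _frame(np.hstack([regions, abnormal]))


# -------------------------------------------------------------- confusion

def test_confusion_perfect_prediction():
    truth = _frame([[1, 0, 0, 0, 1]] * 3 + [[0, 0, 0, 0, 0]] * 7)
    counts = confusion(truth, truth)
    assert counts["chest_wall"] == ConfusionCounts(tp=3, fp=0, tn=7, fn=0)
    assert counts["pleura"] == ConfusionCounts(tp=0, fp=0, tn=10, fn=0)


def test_confusion_counts_misses():
    truth = _frame([[0, 1, 0, 0, 1]] * 2 + [[0, 0, 0, 0, 0]] * 3)
    pred = _frame([[0, 0, 0, 0, 0]] * 5)
    counts = confusion(pred, truth)
    assert counts["pleura"].fn == 2
    assert counts["pleura"].total == 5


def test_confusion_aligns_on_study_id():
    truth = _frame([[1, 0, 0, 0, 1], [0, 0, 0, 0, 0]], ids=["a", "b"])
    pred = _frame([[0, 0, 0, 0, 0], [1, 0, 0, 0, 1]], ids=["b", "a"])
    counts = confusion(pred, truth)
    assert counts["chest_wall"] == ConfusionCounts(tp=1, fp=0, tn=1, fn=0)


def test_confusion_rejects_disjoint_ids_and_pending():
    truth = _frame([[0, 0, 0, 0, 0]], ids=["a"])
    pred = _frame([[0, 0, 0, 0, 0]], ids=["z"])
    with pytest.raises(ValueError, match="study_id"):
        confusion(pred, truth)
    pending = _frame([[0, 0, 0, 0, 0]], ids=["a"])
    pending["status"] = "manual_pending"
    with pytest.raises(ValueError, match="manual_pending"):
        confusion(pending, truth)


# ---------------------------------------------------------------- metrics

@pytest.mark.parametrize(
    "counts, expected",
    [
        (ConfusionCounts(71, 0, 2930, 0), (1.0, 1.0, 1.0)),
        (ConfusionCounts(67, 1, 2933, 0), (0.9853, 1.0, 0.9926)),
        (ConfusionCounts(652, 1, 2347, 1), (0.9985, 0.9985, 0.9985)),
        (ConfusionCounts(235, 0, 2766, 0), (1.0, 1.0, 1.0)),
        (ConfusionCounts(848, 0, 2153, 0), (1.0, 1.0, 1.0)),
    ],
)
def test_metrics_published_evaluation_rows(counts, expected):
    """Recomputing the labeler-evaluation table from its raw confusion
    counts reproduces every printed metric cell at 4-decimal rounding."""
    m = metrics(counts)
    got = tuple(round_half_up(v, 4) for v in (m.precision, m.recall, m.f1))
    assert got == expected


def test_metrics_zero_denominator_convention():
    m = metrics(ConfusionCounts(0, 0, 5, 0))
    assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
    assert m.degenerate
    m0 = metrics(ConfusionCounts(0, 0, 5, 0), zero_division=0.0)
    assert (m0.precision, m0.recall, m0.f1) == (0.0, 0.0, 0.0)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_agree_with_sklearn(seed):
    from sklearn.metrics import f1_score, precision_score, recall_score

    rng = np.random.default_rng(seed)
    pred, truth = _random_frame(rng, 300), _random_frame(rng, 300)
    counts = confusion(pred, truth)
    for cls in LABEL_COLUMNS:
        m = metrics(counts[cls])
        t, p = truth[cls], pred[cls]
        assert m.precision == pytest.approx(precision_score(t, p))
        assert m.recall == pytest.approx(recall_score(t, p))
        assert m.f1 == pytest.approx(f1_score(t, p))


def test_macro_average():
    per_class = {
        "a": metrics(ConfusionCounts(1, 0, 1, 0)),  # f1 = 1.0
        "b": metrics(ConfusionCounts(1, 1, 0, 1)),  # f1 = 0.5
    }
    assert macro_average(per_class).f1 == pytest.approx(0.75)
    single = {"a": per_class["a"]}
    assert macro_average(single).f1 == 1.0
    with pytest.raises(ValueError):
        macro_average({})


# -------------------------------------------------------------- bootstrap

def test_bootstrap_constant_statistic_degenerate_interval():
    truth = _frame([[1, 0, 0, 0, 1]] * 30 + [[0, 0, 0, 0, 0]] * 70)
    low, high = bootstrap_ci(truth, truth, "f1", "chest_wall", n_replicates=200, seed=0)
    assert (low, high) == (1.0, 1.0)


def test_bootstrap_deterministic_for_fixed_seed():
    rng = np.random.default_rng(3)
    pred, truth = _random_frame(rng, 200), _random_frame(rng, 200)
    a = bootstrap_ci(pred, truth, "f1", "abnormal", n_replicates=300, seed=42)
    b = bootstrap_ci(pred, truth, "f1", "abnormal", n_replicates=300, seed=42)
    assert a == b
    c = bootstrap_ci(pred, truth, "f1", "abnormal", n_replicates=300, seed=43)
    assert a != c


def test_bootstrap_single_replicate_returns_point():
    rng = np.random.default_rng(4)
    pred, truth = _random_frame(rng, 100), _random_frame(rng, 100)
    low, high = bootstrap_ci(pred, truth, "f1", "abnormal", n_replicates=1, seed=9)
    assert low == high


def test_bootstrap_brackets_point_estimate():
    rng = np.random.default_rng(5)
    truth = _random_frame(rng, 500)
    # flip ~5% of abnormal predictions
    pred = truth.copy()
    flip = rng.random(500) < 0.05
    pred.loc[flip, "abnormal"] = 1 - pred.loc[flip, "abnormal"]
    pred.loc[flip, list(LABEL_COLUMNS[:4])] = 0
    pred["abnormal"] = np.maximum(
        pred["abnormal"], pred[list(LABEL_COLUMNS[:4])].max(axis=1)
    )
    point = metrics(confusion(pred, truth)["abnormal"]).f1
    low, high = bootstrap_ci(pred, truth, "f1", "abnormal", n_replicates=500, seed=6)
    assert low <= point <= high


def test_bootstrap_degenerate_fixture_rejected():
    empty = _frame([[0, 0, 0, 0, 0]] * 5)
    with pytest.raises(ValueError, match="larger"):
        bootstrap_ci(empty, empty, "f1", "pleura", n_replicates=50, seed=0)


# ------------------------------------------------------- stratified split

def test_split_sizes_and_partition():
    rng = np.random.default_rng(7)
    manifest = _random_frame(rng, 10)
    train, val = stratified_split(manifest, train_fraction=0.7, seed=1)
    assert len(train) == 7 and len(val) == 3
    combined = pd.concat([train, val]).sort_values("study_id")
    pd.testing.assert_frame_equal(
        combined.reset_index(drop=True),
        manifest.sort_values("study_id").reset_index(drop=True),
    )


def test_split_preserves_prevalence_within_one_point(clean_corpus):
    _, truth = clean_corpus
    train, val = stratified_split(truth, train_fraction=0.7, seed=2)
    for cls in LABEL_COLUMNS:
        full = truth[cls].mean()
        assert abs(train[cls].mean() - full) <= 0.01
        assert abs(val[cls].mean() - full) <= 0.01


def test_split_deterministic():
    rng = np.random.default_rng(8)
    manifest = _random_frame(rng, 300)
    a1, _ = stratified_split(manifest, seed=5)
    a2, _ = stratified_split(manifest, seed=5)
    pd.testing.assert_frame_equal(a1, a2)


def test_split_all_negative_falls_back_to_random(caplog):
    manifest = _frame([[0, 0, 0, 0, 0]] * 20)
    with caplog.at_level("WARNING"):
        train, val = stratified_split(manifest, seed=3)
    assert len(train) == 14 and len(val) == 6
    assert any("no positives" in rec.message for rec in caplog.records)


def test_split_rejects_pending_rows():
    manifest = _frame([[0, 0, 0, 0, 0]] * 4)
    manifest.loc[0, "status"] = "manual_pending"
    with pytest.raises(ValueError, match="manual_pending"):
        stratified_split(manifest)


# ------------------------------------------------------------- prevalence

@pytest.mark.parametrize(
    "pos, neg, expected",
    [(2824, 7178, 28.23), (237, 9765, 2.37), (0, 10, 0.0)],
)
def test_prevalence_percentages(pos, neg, expected):
    manifest = _frame(
        [[0, 0, 0, 0, 1]] * pos + [[0, 0, 0, 0, 0]] * neg
    )
    row = prevalence_summary(manifest).set_index("class").loc["abnormal"]
    assert row["positives"] == pos and row["negatives"] == neg
    assert row["percent_positive"] == pytest.approx(expected)


def test_prevalence_empty_manifest_rejected():
    with pytest.raises(ValueError, match="empty"):
        prevalence_summary(_frame(np.zeros((0, 5), dtype=int)))


# ----------------------------------------------------------- table output

def test_metrics_table_schema():
    truth = _frame(
        [[1, 0, 0, 0, 1]] * 5
        + [[0, 1, 0, 0, 1]] * 5
        + [[0, 0, 1, 0, 1]] * 5
        + [[0, 0, 0, 1, 1]] * 5
        + [[0, 0, 0, 0, 0]] * 10
    )
    table = metrics_table(truth, truth, n_replicates=50, seed=1)
    assert list(table.columns) == [
        "class", "tp", "fp", "tn", "fn",
        "precision", "recall", "f1", "ci_low", "ci_high",
    ]
    assert table["class"].iloc[-1] == "macro_average"
    assert (table["f1"].iloc[:5] == 1.0).all()
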