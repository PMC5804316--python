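import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score
import statsmodels.api as sm

import bnetbench as bb
from bnetbench.errors import DegenerateLabelsError, DomainError

from oracles import grid_logistic_oracle, is_separable, pair_counting_auc


def _mv(x, y, **kw):
    names = tuple(f"c{i}" for i in range(len(x)))
    defaults = dict(metric_name="m", scheme_name="s")
    defaults.update(kw)
    return bb.MetricVector(names, tuple(x), tuple(y), **defaults)


# ---------------------------------------------------------------------------
# fit_logistic
# ---------------------------------------------------------------------------


def test_symmetric_data_gives_flat_fit():
    fit = bb.fit_logistic([0, 0, 1, 1], [0, 1, 0, 1])
    assert fit.intercept == pytest.approx(0.0, abs=1e-8)
    assert fit.slope == pytest.approx(0.0, abs=1e-8)
    assert not fit.penalised


def test_separable_data_triggers_penalised_fit():
    fit = bb.fit_logistic([0.0, 1.0], [0, 1])
    assert fit.penalised
    assert fit.converged
    assert fit.slope > 0
    assert np.isfinite([fit.intercept, fit.slope]).all()


def test_mle_matches_grid_search_oracle_on_small_dataset():
    # interleaved labels: genuinely non-separable, so a finite MLE exists
    x, y = [0.0, 1.0, 2.0, 3.0], [0, 1, 0, 1]
    fit = bb.fit_logistic(x, y)
    b0, b1 = grid_logistic_oracle(x, y)
    assert fit.intercept == pytest.approx(b0, abs=1e-3)
    assert fit.slope == pytest.approx(b1, abs=1e-3)


def test_mle_matches_grid_oracle_on_random_nonseparable_datasets(rng):
    """Self-written Newton MLE vs an independent shrinking-grid maximiser."""
    checked = 0
    while checked < 12:
        n = int(rng.integers(6, 13))
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)
        if len(np.unique(y)) < 2 or is_separable(x, y):
            continue
        fit = bb.fit_logistic(x, y)
        b0, b1 = grid_logistic_oracle(x, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-3)
        assert fit.slope == pytest.approx(b1, abs=1e-3)
        assert not fit.penalised
        checked += 1


def test_mle_matches_statsmodels_logit(rng):
    x = rng.normal(size=40)
    y = (rng.random(40) < 1 / (1 + np.exp(-(0.5 + 1.5 * x)))).astype(int)
    fit = bb.fit_logistic(x, y)
    reference = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    assert fit.intercept == pytest.approx(reference.params[0], abs=1e-5)
    assert fit.slope == pytest.approx(reference.params[1], abs=1e-5)


def test_constant_predictor_gets_zero_slope():
    fit = bb.fit_logistic([2.0, 2.0, 2.0, 2.0], [0, 1, 1, 0])
    assert fit.slope == 0.0
    assert bb.predict_prob(fit, 2.0) == pytest.approx(0.5)


def test_single_class_labels_raise():
    with pytest.raises(DegenerateLabelsError):
        bb.fit_logistic([0.0, 1.0], [1, 1])


def test_nonfinite_x_raises():
    with pytest.raises(DomainError):
        bb.fit_logistic([0.0, np.nan, 1.0], [0, 1, 0])


# ---------------------------------------------------------------------------
# predict_prob
# ---------------------------------------------------------------------------


def test_predict_prob_values_and_limits():
    flat = bb.LogisticFit(0.0, 0.0, True, False)
    unit = bb.LogisticFit(0.0, 1.0, True, False)
    assert bb.predict_prob(flat, 7.3) == pytest.approx(0.5)
    assert bb.predict_prob(unit, 0.0) == pytest.approx(0.5)
    probs = [bb.predict_prob(unit, x) for x in (1.0, 10.0, 100.0, 1e6)]
    assert all(a < b or b == 1.0 for a, b in zip(probs, probs[1:]))
    assert probs[-1] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# loocv_probabilities
# ---------------------------------------------------------------------------


def test_loocv_yields_one_probability_per_compound():
    data = _mv([1.0, 2.0, 3.0, 4.0, 10.0], [0, 0, 0, 1, 1])
    probs = bb.loocv_probabilities(data)
    assert set(probs) == set(data.compounds)
    assert all(0.0 <= p <= 1.0 for p in probs.values())


def test_loocv_is_permutation_equivariant(rng):
    x = list(rng.normal(size=8))
    y = [0, 1, 0, 1, 1, 0, 0, 1]
    data = _mv(x, y)
    perm = list(rng.permutation(8))
    shuffled = bb.MetricVector(
        tuple(data.compounds[i] for i in perm),
        tuple(x[i] for i in perm),
        tuple(y[i] for i in perm),
        metric_name="m",
        scheme_name="s",
    )
    assert bb.loocv_probabilities(data) == pytest.approx(
        bb.loocv_probabilities(shuffled)
    )


def test_loocv_saturates_for_non_boundary_compounds():
    """Compounds far from the class boundary get near-0/near-1 probabilities.

    Boundary compounds are predicted by fold models whose decision
    threshold shifts with the held-out point, so only the interior of
    each class is guaranteed to saturate.
    """
    data = _mv([1.0, 2.0, 3.0, 4.0, 10.0], [0, 0, 0, 1, 1])
    probs = bb.loocv_probabilities(data)
    assert probs["c0"] < 1e-6 and probs["c1"] < 1e-6  # deep negatives
    assert probs["c4"] > 1 - 1e-6  # deep positive


def test_loocv_matches_fold_by_fold_statsmodels_refits(rng):
    """Dual route: our LOOCV vs an explicit loop of statsmodels fits."""
    x = rng.normal(size=30)
    y = (rng.random(30) < 1 / (1 + np.exp(-(0.2 + 1.5 * x)))).astype(int)
    if len(np.unique(y)) < 2:
        y[:2] = [0, 1]
    data = _mv(list(x), list(y))
    ours = bb.loocv_probabilities(data)
    for i, compound in enumerate(data.compounds):
        mask = np.ones(30, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2 or is_separable(x[mask], y[mask]):
            continue
        ref = sm.Logit(y[mask], sm.add_constant(x[mask])).fit(disp=0)
        expected = 1 / (1 + np.exp(-(ref.params[0] + ref.params[1] * x[i])))
        assert ours[compound] == pytest.approx(expected, abs=1e-6)


def test_loocv_single_class_fold_falls_back_to_positive_rate():
    # one positive: its fold trains on negatives only
    data = _mv([0.0, 1.0, 2.0, 5.0], [0, 0, 0, 1])
    events: list[str] = []
    probs = bb.loocv_probabilities(data, events=events)
    assert probs["c3"] == pytest.approx(0.0)  # training positive rate
    assert any("single-class" in e for e in events)


# ---------------------------------------------------------------------------
# roc_auc
# ---------------------------------------------------------------------------


def test_auc_perfect_separation_and_ties():
    names = ("a", "b", "c", "d")
    assert bb.roc_auc(
        dict(zip(names, [0.9, 0.8, 0.2, 0.1])), dict(zip(names, [1, 1, 0, 0]))
    ) == pytest.approx(1.0)
    assert bb.roc_auc(
        dict(zip(names, [0.3] * 4)), dict(zip(names, [1, 1, 0, 0]))
    ) == pytest.approx(0.5)


def test_auc_pair_enumeration_example():
    scores = {"a": 0.8, "b": 0.6, "c": 0.4}
    labels = {"a": 1, "b": 0, "c": 1}
    # 2 positive x 1 negative pairs: one concordant, one discordant
    assert bb.roc_auc(scores, labels) == pytest.approx(0.5)


def test_auc_matches_pair_counting_and_sklearn_on_random_instances(rng):
    """Midrank AUC vs exhaustive pair counting and sklearn, 200 instances with ties."""
    for _ in range(200):
        n = int(rng.integers(4, 15))
        scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        y = (rng.random(n) < 0.5).astype(int)
        if len(np.unique(y)) < 2:
            continue
        names = [f"c{i}" for i in range(n)]
        ours = bb.roc_auc(dict(zip(names, scores)), dict(zip(names, y)))
        assert ours == pytest.approx(pair_counting_auc(scores, y), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


@given(
    scores=st.lists(st.floats(min_value=-5, max_value=5), min_size=4, max_size=12),
    labels=st.lists(st.integers(0, 1), min_size=4, max_size=12),
)
def test_auc_label_complement_identity(scores, labels):
    n = min(len(scores), len(labels))
    scores, labels = scores[:n], labels[:n]
    if len(set(labels)) < 2:
        return
    names = [f"c{i}" for i in range(n)]
    s = dict(zip(names, scores))
    auc = bb.roc_auc(s, dict(zip(names, labels)))
    flipped = bb.roc_auc(s, dict(zip(names, [1 - l for l in labels])))
    assert auc + flipped == pytest.approx(1.0)


@given(
    scores=st.lists(
        st.integers(-500, 500).map(lambda v: v / 100.0),
        min_size=4,
        max_size=12,
        unique=True,
    ),
    labels=st.lists(st.integers(0, 1), min_size=12, max_size=12),
)
def test_auc_invariant_under_increasing_transform(scores, labels):
    labels = labels[: len(scores)]
    if len(set(labels)) < 2:
        return
    names = [f"c{i}" for i in range(len(scores))]
    y = dict(zip(names, labels))
    raw = bb.roc_auc(dict(zip(names, scores)), y)
    warped = bb.roc_auc(dict(zip(names, np.exp(scores))), y)
    assert raw == pytest.approx(warped)


def test_auc_single_class_raises():
    with pytest.raises(DegenerateLabelsError):
        bb.roc_auc({"a": 1.0, "b": 2.0}, {"a": 1, "b": 1})


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------


def test_evaluate_perfect_monotone_metric_small_panel():
    """A perfectly separating metric on n=6 scores 8/9, not 1.

    The two boundary folds train on mirror-image sets whose decision
    thresholds sit essentially on the held-out point, so both boundary
    compounds are predicted ~0.5; their cross-fold pair comes out
    discordant, leaving 8 of the 9 positive/negative pairs concordant.
    At realistic panel sizes the cell approaches 1.
    """
    data = _mv([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [0, 0, 0, 1, 1, 1])
    table = bb.evaluate([data])
    assert table.cells[("dataset", "m")] == pytest.approx(8.0 / 9, abs=1e-9)


def test_evaluate_perfect_monotone_metric_large_panel():
    """With many compounds the boundary-fold artifact is negligible: AUC ~ 1."""
    n = 40
    data = _mv([float(i) for i in range(n)], [0] * (n // 2) + [1] * (n // 2))
    table = bb.evaluate([data])
    assert table.cells[("dataset", "m")] >= 0.99


def test_evaluate_constant_metric_exposes_loocv_pessimism():
    """A constant metric scores 0 under leave-one-out, the known artifact.

    Every fold predicts its training positive rate, which is lower by
    1/(n-1) exactly when the held-out compound is positive; the
    out-of-sample scores are therefore perfectly anti-ordered.
    """
    data = _mv([2.0] * 6, [0, 0, 0, 1, 1, 1])
    table = bb.evaluate([data])
    assert table.cells[("dataset", "m")] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_is_rank_invariant_across_metrics(rng):
    """Two metrics that are increasing transforms of each other tie exactly."""
    x = rng.normal(size=20)
    y = (rng.random(20) < 1 / (1 + np.exp(-2 * x))).astype(int)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    raw = _mv(list(x), list(y), metric_name="raw")
    warped = _mv(list(np.expm1(x) + 3 * x), list(y), metric_name="warped")
    table = bb.evaluate([raw, warped])
    assert table.cells[("dataset", "raw")] == pytest.approx(
        table.cells[("dataset", "warped")]
    )


def test_evaluate_scale_invariance(rng):
    x = list(rng.normal(size=15))
    y = [0, 1] * 7 + [1]
    table1 = bb.evaluate([_mv(x, y)])
    table2 = bb.evaluate([_mv([7.3 * v for v in x], y)])
    assert table1.cells[("dataset", "m")] == pytest.approx(
        table2.cells[("dataset", "m")]
    )


def test_evaluate_records_degenerate_cell_as_unavailable():
    good = _mv([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1], metric_name="good")
    bad = _mv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1], metric_name="bad")
    table = bb.evaluate([good, bad])
    assert table.cells[("dataset", "bad")] is None
    assert table.cells[("dataset", "good")] is not None
    records = table.to_records()
    assert {r["metric"] for r in records} == {"good", "bad"}
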