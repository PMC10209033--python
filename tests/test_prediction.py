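import numpy as np
import pytest

from aspmine.prediction import (
    DEFAULT_LOG10_C_GRID,
    FeatureSpec,
    build_feature_matrix,
    compute_metrics,
    kmer_feature_spec,
    leave_category_out_cv,
    select_C,
    train_linear_svm,
)
from aspmine.synthetic import PlantedMotif, generate_dataset, small_profile

from conftest import make_dataset


# ---------------------------------------------------------------- features


def test_binary_indicator_features():
    spec = FeatureSpec(["MK", "RR", "WWW"])
    fm = build_feature_matrix([("a", "MKRREL")], spec)
    assert fm.X.tolist() == [[1.0, 1.0, 0.0]]


def test_kmer_ratio_features():
    spec = FeatureSpec(["A", "B"], kind="kmer_ratio", k=1)
    fm = build_feature_matrix([("a", "AAB")], spec)
    assert fm.X.tolist() == [[2 / 3, 1 / 3]]


def test_kmer_ratio_short_sequence_warns_zero_row():
    spec = FeatureSpec(["AAA"], kind="kmer_ratio", k=3)
    with pytest.warns(UserWarning, match="shorter than k"):
        fm = build_feature_matrix([("a", "AA")], spec)
    assert fm.X.tolist() == [[0.0]]


def test_kmer_spec_small_k_is_ratio_over_observed():
    ds = make_dataset([("a", "AAB", "c", 1), ("b", "BCC", "c", -1)])
    spec = kmer_feature_spec(ds, 1)
    assert spec.kind == "kmer_ratio" and spec.patterns == ["A", "B", "C"]
    assert len(kmer_feature_spec(ds, 2).patterns) <= 4


def test_kmer6_spec_respects_support_threshold():
    shared = "MKRREL"
    ds = make_dataset([
        ("a", shared + "AAA", "c", 1),
        ("b", "CCC" + shared, "c", 1),
        ("c", shared + "DDD", "c", -1),
    ])
    spec = kmer_feature_spec(ds, 6, support_threshold=2)
    assert shared in spec.patterns and spec.kind == "binary_indicator"
    with pytest.warns(UserWarning, match="empty feature spec"):
        empty = kmer_feature_spec(ds, 6, support_threshold=99)
    assert empty.patterns == []


# ---------------------------------------------------------------- SVM


def test_svm_separates_separable_data():
    X = np.array([[0.0, 0.0], [1.0, 1.0]])
    y = np.array([-1, 1])
    model = train_linear_svm(X, C=100.0, y=y)
    assert np.all(np.sign(model.decision(X)) == y)


def test_svm_weights_shrink_as_c_vanishes():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 4))
    y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
    norms = [
        np.linalg.norm(train_linear_svm(X, C=c, y=y).weights)
        for c in (10.0, 0.1, 1e-3, 1e-5)
    ]
    assert norms == sorted(norms, reverse=True)
    assert norms[-1] < 1e-2


def test_svm_single_class_errors():
    with pytest.raises(ValueError, match="both classes"):
        train_linear_svm(np.ones((3, 2)), C=1.0, y=np.array([1, 1, 1]))


def hinge_objective(w, b, X, y, C):
    margins = 1 - y * (X @ w + b)
    return 0.5 * w @ w + C * np.maximum(0.0, margins).sum()


def test_svm_objective_matches_convex_solver_oracle():
    """Independent QP oracle: slack-variable formulation solved by SLSQP."""
    from scipy.optimize import minimize

    rng = np.random.default_rng(3)
    X = rng.normal(size=(20, 3))
    y = np.where(X @ np.array([1.0, -0.5, 0.2]) > 0, 1, -1).astype(float)
    C = 1.0
    model = train_linear_svm(X, C=C, y=y)
    obj_svm = hinge_objective(model.weights, model.intercept, X, y, C)

    d, n = 3, 20
    def fun(z):
        w, b, xi = z[:d], z[d], z[d + 1:]
        return 0.5 * w @ w + C * xi.sum()
    cons = [
        {"type": "ineq", "fun": lambda z, i=i: z[d + 1 + i]} for i in range(n)
    ] + [
        {"type": "ineq",
         "fun": lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1 + z[d + 1 + i]}
        for i in range(n)
    ]
    z0 = np.zeros(d + 1 + n)
    z0[d + 1:] = 1.0
    res = minimize(fun, z0, constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-10})
    assert abs(obj_svm - res.fun) < 1e-4


# ---------------------------------------------------------------- metrics


def test_metrics_perfect_classifier():
    scores = np.array([2.0, 1.0, -1.0, -2.0])
    labels = np.array([1, 1, -1, -1])
    m = compute_metrics(scores, labels)
    assert (m.auc, m.auc10, m.f1, m.mcc) == (1.0, 1.0, 1.0, 1.0)


def test_metrics_hand_computed_confusion():
    # TP=2, FP=1, TN=1, FN=0 at threshold 0 -> F1 = 2*2/(2*2+1+0) = 0.8
    scores = np.array([1.0, 0.5, 0.1, -0.5])
    labels = np.array([1, 1, -1, -1])
    m = compute_metrics(scores, labels)
    assert m.confusion == {"TP": 2, "FP": 1, "TN": 1, "FN": 0}
    assert m.f1 == pytest.approx(0.8)
    from sklearn.metrics import matthews_corrcoef

    assert m.mcc == pytest.approx(
        matthews_corrcoef(labels, np.where(scores >= 0, 1, -1)))


def test_auc_equals_mann_whitney_oracle():
    from scipy.stats import mannwhitneyu

    rng = np.random.default_rng(7)
    for trial in range(5):
        labels = np.where(rng.random(60) < 0.4, 1, -1)
        if len(set(labels)) < 2:
            continue
        scores = rng.normal(size=60) + 0.5 * (labels == 1)
        scores[:10] = np.round(scores[:10], 1)  # force some ties
        m = compute_metrics(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == -1]).statistic
        assert m.auc == pytest.approx(
            u / ((labels == 1).sum() * (labels == -1).sum()), abs=1e-12)


def test_random_scores_give_chance_auc():
    rng = np.random.default_rng(11)
    labels = np.where(rng.random(10_000) < 0.5, 1, -1)
    scores = rng.normal(size=10_000)
    m = compute_metrics(scores, labels)
    assert m.auc == pytest.approx(0.5, abs=0.02)
    assert abs(m.mcc) < 0.05


def test_constant_scores_auc10_at_chance_level():
    labels = np.array([1, -1, 1, -1])
    m = compute_metrics(np.zeros(4), labels)
    assert m.auc == pytest.approx(0.5)
    assert m.auc10 <= 0.1 + 1e-12  # diagonal ROC: 10 * (0.1^2)/2 = 0.05


def test_single_class_auc_is_nan_with_warning():
    with pytest.warns(UserWarning, match="single class"):
        m = compute_metrics(np.array([1.0, -1.0]), np.array([1, 1]))
    assert np.isnan(m.auc)


def test_roc_is_monotone():
    rng = np.random.default_rng(2)
    labels = np.where(rng.random(50) < 0.5, 1, -1)
    m = compute_metrics(rng.normal(size=50), labels)
    assert np.all(np.diff(m.fpr) >= 0) and np.all(np.diff(m.tpr) >= 0)


# ---------------------------------------------------------------- C selection & CV


def _flat_metric_dataset():
    """Two paired categories, trivially separable by one indicator."""
    rows = []
    for c in ("c1", "c2", "c3"):
        for i in range(4):
            rows.append((f"{c}p{i}", "WWWW" + "ACDE" * 3, c, 1))
            rows.append((f"{c}n{i}", "HHHH" + "ACDE" * 3, c, -1))
    return make_dataset(rows)


def test_default_grid_has_ten_points_step_four_ninths():
    assert len(DEFAULT_LOG10_C_GRID) == 10
    assert DEFAULT_LOG10_C_GRID[0] == pytest.approx(-27 / 9)
    assert DEFAULT_LOG10_C_GRID[-1] == pytest.approx(9 / 9)
    steps = np.diff(DEFAULT_LOG10_C_GRID)
    assert np.allclose(steps, 4 / 9)


def test_select_c_tie_rule_prefers_smallest():
    ds = _flat_metric_dataset()
    spec = FeatureSpec(["WWWW"])
    c = select_C(ds, lambda d, s: spec, metric="auc", max_extensions=1)
    # AUC is constant in C here; the tie rule picks the smallest grid value
    # after one failed downward extension
    assert np.log10(c) == pytest.approx(-27 / 9 - 4 / 9)


def test_lco_cv_folds_partition_paired_proteins(planted_fixture):
    ds, _ = planted_fixture
    cv = leave_category_out_cv(ds, feature_source="kmer1", seed=0,
                               select_c_metric=None)
    held_out = [i for f in cv.folds for i in f.ids]
    paired_ids = [r.id for r in ds if r.category.startswith("paired")]
    assert sorted(held_out) == sorted(paired_ids)
    assert len(cv.folds) == 5


def test_no_feature_leakage_from_held_out_category():
    """A motif unique to one category must vanish from that fold's features."""
    from aspmine.synthetic import CategorySpec, GeneratorConfig

    motif = PlantedMotif("WQHKWDY", 1.0, 0.0, categories=("paired_0",))
    config = GeneratorConfig(seed=21, categories=(
        CategorySpec("paired_0", 30, 10), CategorySpec("paired_1", 10, 10),
        CategorySpec("paired_2", 10, 10), CategorySpec("posonly_0", 10, 0),
        CategorySpec("negonly_0", 0, 30)), motifs=(motif,))
    ds, _ = generate_dataset(config)
    from aspmine.prediction import asp_feature_spec

    with_cat = asp_feature_spec(ds, m_perms=50, seed=1)
    without = asp_feature_spec(
        ds.subset([i for i, r in enumerate(ds) if r.category != "paired_0"]),
        m_perms=50, seed=1)
    in_full = [p for p in with_cat.patterns if p in motif.seq or motif.seq in p]
    in_held = [p for p in without.patterns if p in motif.seq or motif.seq in p]
    assert in_full and not in_held


def test_lco_cv_determinism(planted_fixture):
    ds, _ = planted_fixture
    kw = dict(feature_source="asp", m_perms=30, seed=5, select_c_metric=None)
    a = leave_category_out_cv(ds, **kw)
    b = leave_category_out_cv(ds, **kw)
    assert a.metrics_json() == b.metrics_json()


def test_lco_cv_requires_two_paired_categories():
    ds = make_dataset([("a", "AAAA", "only", 1), ("b", "CCCC", "only", -1)])
    with pytest.raises(ValueError, match="paired"):
        leave_category_out_cv(ds)
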