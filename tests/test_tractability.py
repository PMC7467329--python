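"""Feature extraction, stratified split, consensus forest and class bins."""

import numpy as np
import pandas as pd
import pytest

from targetlens.synthetic import generate_synthetic_targets
from targetlens.tractability import (
    build_feature_matrix,
    classify_tractability,
    evaluate,
    feature_importances,
    predict_tractability,
    stratified_split,
    train_forest,
    vote_fraction,
)


def _gaussian_clusters(n=300, sep=6.0, n_noise=4, seed=0):
    """Two well-separated Gaussian blobs plus noise columns."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X0 = rng.normal(0.0, 1.0, size=(half, 2))
    X1 = rng.normal(sep, 1.0, size=(n - half, 2))
    X = np.vstack([X0, X1])
    X = np.hstack([X, rng.normal(0.0, 1.0, size=(n, n_noise))])
    y = np.array([0] * half + [1] * (n - half))
    cols = ["signal_a", "signal_b"] + [f"noise_{i}" for i in range(n_noise)]
    order = rng.permutation(n)
    return pd.DataFrame(X[order], columns=cols), y[order]


# --- feature matrix ------------------------------------------------------

def test_feature_matrix_shape_and_columns(rich_record):
    df = build_feature_matrix([rich_record])
    assert len(df) == 1
    assert df.index[0] == "HAND1"
    assert not df.isna().any().any()
    assert df.loc["HAND1", "n_structures"] == 2
    assert df.loc["HAND1", "best_pocket_score"] == pytest.approx(0.7)
    assert df.loc["HAND1", "score_structure"] == pytest.approx(0.65)


def test_feature_matrix_dark_records_all_zero_counts():
    recs = generate_synthetic_targets(10, "dark", seed=2)
    df = build_feature_matrix(recs)
    assert (df["n_structures"] == 0).all()
    assert (df["n_bioactivities"] == 0).all()
    assert (df["n_pockets"] == 0).all()


def test_feature_matrix_duplicate_genes_rejected(rich_record):
    with pytest.raises(ValueError, match="duplicate"):
        build_feature_matrix([rich_record, rich_record])


def test_feature_matrix_deterministic_column_order():
    recs = generate_synthetic_targets(5, "mixed", seed=4)
    a = build_feature_matrix(recs)
    b = build_feature_matrix(list(reversed(recs)))
    assert list(a.columns) == list(b.columns)
    pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


# --- stratified split ----------------------------------------------------

def test_split_balanced_classes():
    y = np.array([1] * 10 + [0] * 10)
    train, test = stratified_split(y, 0.7, seed=0)
    assert len(train) == 14 and len(test) == 6
    assert y[train].sum() == 7 and y[test].sum() == 3
    assert sorted(np.concatenate([train, test])) == list(range(20))


def test_split_deterministic_per_seed():
    y = np.array([0, 1] * 25)
    a = stratified_split(y, 0.7, seed=9)
    b = stratified_split(y, 0.7, seed=9)
    assert (a[0] == b[0]).all() and (a[1] == b[1]).all()
    c = stratified_split(y, 0.7, seed=10)
    assert not (a[0] == c[0]).all()


def test_split_published_cohort_sizes():
    y = np.array([1] * 399 + [0] * 400)
    train, test = stratified_split(y, 0.7, seed=1)
    assert len(train) == 559 and len(test) == 240
    # per-class ratios preserved within one member
    assert y[train].sum() == 279 and (1 - y[train]).sum() == 280
    assert abs(y[train].mean() - y.mean()) < 1 / len(train)


def test_split_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        stratified_split(np.array([1, 1, 1]), 0.7, seed=0)
    with pytest.raises(ValueError):
        stratified_split(np.array([0, 1, 1, 1]), 0.7, seed=0)
    with pytest.raises(ValueError):
        stratified_split(np.array([0, 0, 1, 1]), 1.2, seed=0)


# --- forest --------------------------------------------------------------

def test_forest_separable_training_accuracy():
    X, y = _gaussian_clusters(n=500, seed=1)
    model = train_forest(X, y, n_trees=100, seed=1)
    assert model.n_trees == 100
    acc, conf = evaluate(model, X, y)
    assert acc >= 0.99
    assert sum(conf.values()) == len(y)


def test_forest_reproducible_per_seed():
    X, y = _gaussian_clusters(n=200, seed=2)
    f1 = vote_fraction(train_forest(X, y, n_trees=50, seed=3), X)
    f2 = vote_fraction(train_forest(X, y, n_trees=50, seed=3), X)
    assert (f1 == f2).all()


def test_forest_rejects_single_class():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
    with pytest.raises(ValueError):
        train_forest(X, np.ones(10, dtype=int), seed=0)


def test_vote_fraction_extremes_and_column_contract():
    X, y = _gaussian_clusters(n=400, sep=8.0, seed=4)
    model = train_forest(X, y, n_trees=100, seed=4)
    deep_pos = pd.DataFrame(
        [[8.0, 8.0, 0, 0, 0, 0]], columns=X.columns
    )
    deep_neg = pd.DataFrame(
        [[0.0, 0.0, 0, 0, 0, 0]], columns=X.columns
    )
    assert vote_fraction(model, deep_pos)[0] >= 0.9
    assert vote_fraction(model, deep_neg)[0] <= 0.1
    with pytest.raises(ValueError, match="columns"):
        vote_fraction(model, deep_pos.rename(columns={"signal_a": "oops"}))


def test_single_tree_votes_are_binary():
    X, y = _gaussian_clusters(n=100, seed=5)
    model = train_forest(X, y, n_trees=1, seed=5)
    fracs = vote_fraction(model, X)
    assert set(np.unique(fracs)) <= {0.0, 1.0}


def test_permuted_labels_give_chance_accuracy():
    accs = []
    for seed in range(20):
        X, y = _gaussian_clusters(n=150, seed=100 + seed)
        rng = np.random.default_rng(seed)
        y_perm = rng.permutation(y)
        tr, te = stratified_split(y_perm, 0.7, seed=seed)
        model = train_forest(X.iloc[tr], y_perm[tr], n_trees=60, seed=seed)
        acc, _ = evaluate(model, X.iloc[te], y_perm[te])
        accs.append(acc)
    assert abs(float(np.mean(accs)) - 0.5) <= 0.1


# --- class bins ----------------------------------------------------------

@pytest.mark.parametrize(
    "fraction,label",
    [
        (0.75, "Tractable"),
        (0.61, "Tractable"),
        (0.60, "Challenging"),
        (0.50, "Challenging"),
        (0.40, "Challenging"),
        (0.39, "Intractable"),
        (0.10, "Intractable"),
        (0.0, "Intractable"),
        (1.0, "Tractable"),
    ],
)
def test_class_bins(fraction, label):
    assert classify_tractability(fraction) == label


def test_class_bins_partition_and_monotone():
    fractions = np.linspace(0, 1, 2001)
    labels = [classify_tractability(f) for f in fractions]
    order = {"Intractable": 0, "Challenging": 1, "Tractable": 2}
    ranks = [order[l] for l in labels]
    assert ranks == sorted(ranks)
    assert set(labels) == {"Intractable", "Challenging", "Tractable"}
    with pytest.raises(ValueError):
        classify_tractability(1.5)


def test_predict_tractability_labels_consistent():
    X, y = _gaussian_clusters(n=200, seed=6)
    model = train_forest(X, y, n_trees=40, seed=6)
    preds = predict_tractability(model, X.head(10))
    for p in preds:
        assert p.label == classify_tractability(p.vote_fraction)


# --- evaluation & importances -------------------------------------------

def test_evaluate_mismatched_lengths_rejected():
    X, y = _gaussian_clusters(n=60, seed=7)
    model = train_forest(X, y, n_trees=20, seed=7)
    with pytest.raises(ValueError, match="mismatch"):
        evaluate(model, X, y[:-5])


def test_separable_holdout_accuracy_over_seeds():
    accs = []
    for seed in range(10):
        X, y = _gaussian_clusters(n=200, sep=6.0, seed=200 + seed)
        tr, te = stratified_split(y, 0.7, seed=seed)
        model = train_forest(X.iloc[tr], y[tr], n_trees=60, seed=seed)
        acc, _ = evaluate(model, X.iloc[te], y[te])
        accs.append(acc)
    assert min(accs) >= 0.95


def test_importances_sorted_normalized_and_signal_first():
    X, y = _gaussian_clusters(n=400, sep=6.0, n_noise=6, seed=8)
    model = train_forest(X, y, n_trees=100, seed=8)
    ranking = feature_importances(model)
    names = [n for n, _ in ranking]
    values = [v for _, v in ranking]
    assert values == sorted(values, reverse=True)
    assert all(v >= 0 for v in values)
    assert sum(values) == pytest.approx(1.0)
    assert set(names[:2]) == {"signal_a", "signal_b"}


def test_all_noise_importances_near_uniform():
    # with no signal at all, no column should dominate the forest
    maxima = []
    n_cols = 8
    for seed in range(20):
        rng = np.random.default_rng(300 + seed)
        X = pd.DataFrame(
            rng.normal(size=(120, n_cols)),
            columns=[f"noise_{i}" for i in range(n_cols)],
        )
        y = rng.integers(0, 2, size=120)
        if y.sum() < 2 or y.sum() > 118:
            continue
        model = train_forest(X, y, n_trees=40, seed=seed)
        maxima.append(feature_importances(model)[0][1])
    assert float(np.mean(maxima)) <= 3.0 / n_cols


def test_tractability_descriptors_recovered_on_profiled_cohort():
    # positives defined by rich druggability+chemistry evidence: those
    # descriptor families must appear among the top-ranked importances
    from targetlens.synthetic import make_labeled_cohort

    recs, y = make_labeled_cohort(n_tractable=150, n_background=150, seed=13)
    X = build_feature_matrix(recs)
    model = train_forest(X, y, n_trees=100, seed=13)
    top = [name for name, _ in feature_importances(model)[:8]]
    chem_drug = {
        "score_chemistry", "score_druggability", "n_ligands", "n_bioactivities",
        "n_binding_rows", "best_pocket_score", "n_ligandable_pockets",
        "best_potency_nM",
    }
    assert len(chem_drug & set(top)) >= 2
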