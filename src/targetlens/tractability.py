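"""Consensus-vote random-forest tractability classification.

A target's aggregated evidence is flattened into a numeric descriptor row
(counts, maxima and the eight area scores).  A random forest trained on a
labeled tractable/background cohort then votes tree-by-tree; the fraction of
trees predicting "tractable" is both a confidence readout and the basis of a
three-class binning:

    Tractable     vote fraction strictly above 0.60
    Challenging   0.40 <= fraction <= 0.60
    Intractable   strictly below 0.40

The binary accuracy decision (for evaluation) uses the ordinary 0.5
majority, distinct from the reporting bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .records import TargetRecord
from .scoring import AREA_NAMES, all_area_scores
from .pockets import LIGANDABILITY_CUTOFF, best_pocket_score

__all__ = [
    "CLASS_BINS",
    "ForestModel",
    "TractabilityPrediction",
    "build_feature_matrix",
    "classify_tractability",
    "evaluate",
    "feature_importances",
    "stratified_split",
    "train_forest",
    "vote_fraction",
]

#: (lower bound, upper bound) of the Challenging band; both ends inclusive.
CLASS_BINS = (0.40, 0.60)

#: Columns imputed with the column median (score-like); all others with 0.
_MEDIAN_IMPUTED = ("best_coverage",)

_COUNT_COLUMNS = (
    "n_structures",
    "n_pockets",
    "n_ligandable_pockets",
    "n_bioactivities",
    "n_binding_rows",
    "n_ligands",
    "n_diseases",
    "n_genetics",
    "n_tissues",
    "n_high_expression",
    "n_genotypes",
    "n_lethal_genotypes",
    "n_abnormal_genotypes",
    "isoform_count",
    "variant_count",
    "n_publications",
    "antibody_count",
    "n_safety_flags",
)


@dataclass(frozen=True)
class TractabilityPrediction:
    """Consensus vote fraction plus its three-class label."""

    vote_fraction: float
    label: str


def classify_tractability(fraction: float) -> str:
    """Bin a vote fraction into Tractable / Challenging / Intractable."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"vote fraction must be in [0, 1], got {fraction}")
    lo, hi = CLASS_BINS
    if fraction > hi:
        return "Tractable"
    if fraction < lo:
        return "Intractable"
    return "Challenging"


def build_feature_matrix(records) -> pd.DataFrame:
    """Flatten records into the descriptor matrix (index = gene name).

    Missing numeric values are imputed with 0 for counts and the column
    median for score-like columns; column order is fixed and deterministic.
    """
    records = list(records)
    if not records:
        raise ValueError("no records given")
    names = [r.gene_name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names in feature matrix: {dupes}")
    rows = []
    for r in records:
        scores = all_area_scores(r)
        potencies = [
            a.value
            for a in r.bioactivities
            if a.activity_type in ("Ki", "Kd", "IC50", "EC50")
        ]
        row = {
            "n_structures": len(r.structures),
            "best_coverage": max((s.coverage for s in r.structures), default=np.nan),
            "n_pockets": len(r.pockets),
            "best_pocket_score": best_pocket_score(r.pockets, r.pocket_similarity),
            "n_ligandable_pockets": sum(
                1 for p in r.pockets if p.ligandability_score > LIGANDABILITY_CUTOFF
            ),
            "n_bioactivities": len(r.bioactivities),
            "n_binding_rows": sum(
                1 for a in r.bioactivities if a.activity_type in ("Ki", "Kd")
            ),
            "n_ligands": len({a.ligand_id for a in r.bioactivities}),
            "best_potency_nM": min(potencies, default=0.0),
            "n_diseases": len(r.disease_associations),
            "max_disease_score": max(
                (s for _, s in r.disease_associations), default=0.0
            ),
            "n_genetics": len(r.genetic_associations),
            "max_genetic_score": max(
                (s for _, s in r.genetic_associations), default=0.0
            ),
            "n_tissues": len(r.expression),
            "n_high_expression": sum(1 for lv in r.expression.values() if lv.code == 3),
            "n_genotypes": len(r.genotypes),
            "n_lethal_genotypes": sum(1 for g in r.genotypes if g.lethal),
            "n_abnormal_genotypes": sum(1 for g in r.genotypes if g.abnormal),
            "isoform_count": r.isoform_count,
            "variant_count": r.variant_count,
            "n_publications": len(r.publications),
            "antibody_count": r.antibody_count,
            "n_safety_flags": len(r.safety_flags),
        }
        row.update({f"score_{k}": v for k, v in scores.as_dict().items()})
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(names, name="gene_name"))
    for col in df.columns:
        if df[col].isna().any():
            if col in _COUNT_COLUMNS or df[col].isna().all():
                fill = 0.0
            else:
                fill = float(df[col].median(skipna=True))
            df[col] = df[col].fillna(fill)
    return df


def stratified_split(labels, train_fraction: float = 0.7, seed: int = 0):
    """Class-stratified train/test index split.

    Each class contributes ``round(class_size * train_fraction)`` members to
    the training set; indices are disjoint, exhaustive, and deterministic
    per seed.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present for a stratified split")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        rng.shuffle(idx)
        # round-half-even is numpy's round; use arithmetic rounding so
        # 279.3 -> 279 and 280.0 -> 280 regardless of parity
        n_train = int(math.floor(idx.size * train_fraction + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return train, test


@dataclass
class ForestModel:
    """A trained consensus forest plus the column contract it was fit on."""

    forest: RandomForestClassifier
    columns: tuple[str, ...]
    positive_class: int = 1

    @property
    def n_trees(self) -> int:
        return len(self.forest.estimators_)


def train_forest(
    X: pd.DataFrame,
    y,
    n_trees: int = 200,
    max_features: str | int | float = "sqrt",
    seed: int = 0,
) -> ForestModel:
    """Fit the consensus random forest.

    Each tree sees a bootstrap sample and, at every split, a random subset
    of features (default: square root of the feature count).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(np.asarray(X, dtype=float), y)
    return ForestModel(forest=forest, columns=tuple(X.columns))


def _check_columns(model: ForestModel, X: pd.DataFrame) -> np.ndarray:
    if tuple(X.columns) != model.columns:
        missing = set(model.columns) - set(X.columns)
        extra = set(X.columns) - set(model.columns)
        raise ValueError(
            f"feature columns do not match the training contract "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})"
        )
    return np.asarray(X, dtype=float)


def vote_fraction(model: ForestModel, row: pd.DataFrame) -> np.ndarray:
    """Per-row fraction of trees voting the tractable class."""
    X = _check_columns(model, row)
    pos = list(model.forest.classes_).index(model.positive_class)
    votes = np.zeros(X.shape[0])
    for tree in model.forest.estimators_:
        votes += (tree.predict(X) == model.forest.classes_[pos]).astype(float)
    return votes / model.n_trees


def predict_tractability(model: ForestModel, X: pd.DataFrame) -> list[TractabilityPrediction]:
    """Vote fractions and class labels for every row of X."""
    fracs = vote_fraction(model, X)
    return [
        TractabilityPrediction(vote_fraction=float(f), label=classify_tractability(float(f)))
        for f in fracs
    ]


def evaluate(model: ForestModel, X: pd.DataFrame, y) -> tuple[float, dict[str, int]]:
    """Majority-vote accuracy and confusion counts on a test set."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("empty test set")
    if len(y) != len(X):
        raise ValueError(f"label/row mismatch: {len(y)} labels for {len(X)} rows")
    fracs = vote_fraction(model, X)
    pred = (fracs > 0.5).astype(int)
    truth = (y == model.positive_class).astype(int)
    confusion = {
        "tp": int(np.sum((pred == 1) & (truth == 1))),
        "fp": int(np.sum((pred == 1) & (truth == 0))),
        "fn": int(np.sum((pred == 0) & (truth == 1))),
        "tn": int(np.sum((pred == 0) & (truth == 0))),
    }
    accuracy = (confusion["tp"] + confusion["tn"]) / len(y)
    return accuracy, confusion


def feature_importances(model: ForestModel) -> list[tuple[str, float]]:
    """Impurity-based importances, normalized and sorted descending."""
    try:
        imp = model.forest.feature_importances_
    except Exception as exc:  # sklearn raises NotFittedError
        raise ValueError("model is not trained") from exc
    total = imp.sum()
    if total > 0:
        imp = imp / total
    pairs = sorted(zip(model.columns, imp), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(v)) for name, v in pairs]
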