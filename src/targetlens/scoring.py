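"""Area-specific evidence scores and the signed-weight MPO ranking score.

Target knowledge is summarized into eight categories — druggability,
structure, biology, chemistry, diseases, genetics, information and safety —
each scored from 0 to 1 by a rule set of saturating indicators: every rule
extracts a non-negative quantity from the record, saturates it at a cap
(``min(x / cap, 1)``) and contributes with a positive sub-weight; the
category score is the sub-weight-normalized sum.  An all-empty record scores
0 in every category (the safety score, like the rest, measures *benign
evidence*: it rises only when safety-relevant data exist and look clean).

The multi-parameter optimization (MPO) score combines the eight area scores
under user-chosen signed weights:

    MPO = sum_a |w_a| * d_a / sum_a |w_a|,   d_a = s_a   if w_a > 0
                                             d_a = 1-s_a if w_a < 0

Zero-weight categories are excluded entirely, negative weights deprioritize
categories where evidence is abundant, and the score is invariant to
rescaling all weights by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .ligands import _BINDING_TYPES
from .pockets import LIGANDABILITY_CUTOFF, best_pocket_score
from .records import TargetRecord

__all__ = [
    "AREA_NAMES",
    "AreaRule",
    "AreaRuleSet",
    "AreaScores",
    "DEFAULT_RULES",
    "MpoWeights",
    "all_area_scores",
    "area_score",
    "axis_qualities",
    "mpo_score",
    "quality_color",
    "saturating_indicator",
]

AREA_NAMES = (
    "druggability",
    "structure",
    "biology",
    "chemistry",
    "diseases",
    "genetics",
    "information",
    "safety",
)

#: Potency threshold (nM) under which a compound counts as chemically enabling.
POTENT_NM = 100.0


def saturating_indicator(count: float, cap: float) -> float:
    """``min(count / cap, 1)`` — linear up to the cap, then saturated."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return min(count / cap, 1.0)


@dataclass(frozen=True)
class AreaRule:
    """One scored indicator: extractor, saturation cap, positive sub-weight."""

    name: str
    extract: Callable[[TargetRecord], float]
    cap: float
    weight: float = 1.0

    def __post_init__(self):
        if self.cap <= 0:
            raise ValueError(f"rule {self.name!r}: cap must be positive")
        if self.weight <= 0:
            raise ValueError(f"rule {self.name!r}: sub-weight must be positive")


AreaRuleSet = Mapping[str, Sequence[AreaRule]]


@dataclass(frozen=True)
class AreaScores:
    """The eight category scores, each in [0, 1]."""

    druggability: float = 0.0
    structure: float = 0.0
    biology: float = 0.0
    chemistry: float = 0.0
    diseases: float = 0.0
    genetics: float = 0.0
    information: float = 0.0
    safety: float = 0.0

    def __post_init__(self):
        for name in AREA_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"area score {name!r} must be in [0, 1], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in AREA_NAMES}


@dataclass(frozen=True)
class MpoWeights:
    """Signed per-category MPO weights; at least one must be nonzero."""

    druggability: float = 1.0
    structure: float = 1.0
    biology: float = 1.0
    chemistry: float = 1.0
    diseases: float = 1.0
    genetics: float = 1.0
    information: float = 1.0
    safety: float = 1.0

    def __post_init__(self):
        if all(getattr(self, name) == 0 for name in AREA_NAMES):
            raise ValueError("MPO weights must not all be zero")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in AREA_NAMES}


# ---------------------------------------------------------------------------
# Default rule set.  Caps are the evidence levels past which more of the same
# signal no longer changes the assessment; all of them live here so the scored
# surface has a single editable source of truth.
# ---------------------------------------------------------------------------

def _n_potent(r: TargetRecord) -> float:
    return sum(
        1
        for a in r.bioactivities
        if a.activity_type in ("Ki", "Kd", "IC50", "EC50") and a.value <= POTENT_NM
    )


def _n_binding_ligands(r: TargetRecord) -> float:
    return len({a.ligand_id for a in r.bioactivities if a.activity_type in _BINDING_TYPES})


def _best_coverage(r: TargetRecord) -> float:
    return max((s.coverage for s in r.structures), default=0.0)


def _has_good_resolution(r: TargetRecord) -> float:
    return float(
        any(s.resolution is not None and s.resolution <= 2.5 for s in r.structures)
    )


def _n_ligandable_pockets(r: TargetRecord) -> float:
    return sum(1 for p in r.pockets if p.ligandability_score > LIGANDABILITY_CUTOFF)


def _benign_genotype_fraction(r: TargetRecord) -> float:
    if not r.genotypes:
        return 0.0
    return sum(1 for g in r.genotypes if not g.abnormal) / len(r.genotypes)


def _no_lethal_evidence(r: TargetRecord) -> float:
    return float(bool(r.genotypes) and not any(g.lethal for g in r.genotypes))


def _clean_flag_evidence(r: TargetRecord) -> float:
    has_data = bool(r.genotypes or r.expression)
    return float(has_data and not r.safety_flags)


def _restricted_expression(r: TargetRecord) -> float:
    # Narrow high-level expression limits off-tissue exposure; only counts
    # when expression was actually measured.
    if not r.expression:
        return 0.0
    high = sum(1 for lv in r.expression.values() if lv.code >= 2)
    return 1.0 - high / len(r.expression)


DEFAULT_RULES: dict[str, tuple[AreaRule, ...]] = {
    "druggability": (
        AreaRule(
            "best_pocket_score",
            lambda r: best_pocket_score(r.pockets, r.pocket_similarity),
            cap=1.0,
            weight=3.0,
        ),
        AreaRule("ligandable_pockets", _n_ligandable_pockets, cap=3.0, weight=1.0),
    ),
    "structure": (
        AreaRule("structure_count", lambda r: len(r.structures), cap=5.0, weight=2.0),
        AreaRule("best_chain_coverage", _best_coverage, cap=1.0, weight=1.0),
        AreaRule("high_resolution", _has_good_resolution, cap=1.0, weight=1.0),
    ),
    "biology": (
        AreaRule("antibody_count", lambda r: r.antibody_count, cap=5.0, weight=1.0),
        AreaRule("isoform_count", lambda r: r.isoform_count, cap=4.0, weight=1.0),
        AreaRule("variant_count", lambda r: r.variant_count, cap=10.0, weight=1.0),
        AreaRule(
            "expression_breadth", lambda r: len(r.expression), cap=15.0, weight=1.0
        ),
    ),
    "chemistry": (
        AreaRule("potent_compounds", _n_potent, cap=10.0, weight=2.0),
        AreaRule("binding_ligands", _n_binding_ligands, cap=10.0, weight=1.0),
        AreaRule(
            "bioactivity_rows", lambda r: len(r.bioactivities), cap=50.0, weight=1.0
        ),
    ),
    "diseases": (
        AreaRule(
            "association_count",
            lambda r: len(r.disease_associations),
            cap=5.0,
            weight=1.0,
        ),
        AreaRule(
            "best_association",
            lambda r: max((s for _, s in r.disease_associations), default=0.0),
            cap=1.0,
            weight=2.0,
        ),
    ),
    "genetics": (
        AreaRule(
            "association_count",
            lambda r: len(r.genetic_associations),
            cap=3.0,
            weight=1.0,
        ),
        AreaRule(
            "best_significance",
            lambda r: max((s for _, s in r.genetic_associations), default=0.0),
            cap=1.0,
            weight=2.0,
        ),
    ),
    "information": (
        AreaRule(
            "publication_count", lambda r: len(r.publications), cap=200.0, weight=1.0
        ),
    ),
    "safety": (
        AreaRule("benign_genotypes", _benign_genotype_fraction, cap=1.0, weight=2.0),
        AreaRule("no_lethal_evidence", _no_lethal_evidence, cap=1.0, weight=1.0),
        AreaRule("no_safety_flags", _clean_flag_evidence, cap=1.0, weight=1.0),
        AreaRule("restricted_expression", _restricted_expression, cap=1.0, weight=1.0),
    ),
}


def area_score(
    record: TargetRecord, category: str, rules: AreaRuleSet | None = None
) -> float:
    """Score one evidence category from 0 (no evidence) to 1 (saturated)."""
    rules = rules if rules is not None else DEFAULT_RULES
    if category not in AREA_NAMES:
        raise ValueError(f"unknown category {category!r}; expected one of {AREA_NAMES}")
    rule_list = rules.get(category, ())
    if not rule_list:
        return 0.0
    total_w = sum(rule.weight for rule in rule_list)
    acc = 0.0
    for rule in rule_list:
        acc += rule.weight * saturating_indicator(rule.extract(record), rule.cap)
    return acc / total_w


def all_area_scores(record: TargetRecord, rules: AreaRuleSet | None = None) -> AreaScores:
    """Apply :func:`area_score` to every category."""
    return AreaScores(**{name: area_score(record, name, rules) for name in AREA_NAMES})


def mpo_score(scores: AreaScores, weights: MpoWeights) -> float:
    """Signed-weight multi-parameter optimization score in [0, 1]."""
    s = scores.as_dict()
    w = weights.as_dict()
    num = 0.0
    denom = 0.0
    for name in AREA_NAMES:
        wa = w[name]
        if wa == 0:
            continue
        desirability = s[name] if wa > 0 else 1.0 - s[name]
        num += abs(wa) * desirability
        denom += abs(wa)
    if denom == 0:
        raise ValueError("MPO weights must not all be zero")
    return num / denom


def quality_color(quality: float) -> tuple[float, float, float]:
    """Linear red (0 = risk / poor) to green (1 = clean / good) RGB ramp."""
    if not 0.0 <= quality <= 1.0:
        raise ValueError(f"quality must be in [0, 1], got {quality}")
    return (1.0 - quality, quality, 0.0)


def axis_qualities(record: TargetRecord) -> dict[str, float]:
    """Quality values in [0, 1] for the four quality-bearing plot axes.

    Druggability: best pocket ligandability.  Genetics: best association
    significance.  Chemistry: share of potency measurements at or under the
    potent-compound threshold.  Safety: benign fraction of safety evidence
    (1 when genotypes are clean and no flags; 0 with lethal phenotypes).
    """
    potencies = [
        a.value
        for a in record.bioactivities
        if a.activity_type in ("Ki", "Kd", "IC50", "EC50")
    ]
    chem = (
        sum(1 for v in potencies if v <= POTENT_NM) / len(potencies)
        if potencies
        else 0.0
    )
    if record.genotypes:
        safety = _benign_genotype_fraction(record)
        if any(g.lethal for g in record.genotypes):
            safety = 0.0
        if record.safety_flags:
            safety = min(safety, 0.5)
    else:
        safety = 0.5 if not record.safety_flags else 0.0
    return {
        "druggability": best_pocket_score(record.pockets, record.pocket_similarity),
        "genetics": max((s for _, s in record.genetic_associations), default=0.0),
        "chemistry": chem,
        "safety": safety,
    }
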