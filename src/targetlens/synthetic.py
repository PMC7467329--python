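"""Seeded synthetic target cohorts emulating harvested knowledge bundles.

The generator replaces live database harvesting: it draws
:class:`~targetlens.records.TargetRecord` instances whose richness follows one
of three profiles.

``drugged``
    Well-characterized, chemically enabled targets: several solved
    structures with mostly ligandable pockets, a substantial body of
    Ki/Kd/IC50 bioactivities, disease and genetic associations, broad
    expression data, mouse genotypes and a large literature.
``dark``
    Minimally annotated proteins: no structures, no pockets, no recorded
    bioactivities, and only sporadic associations, expression measurements
    or publications.
``mixed``
    A cohort combining ``drugged``, ``dark`` and an intermediate
    ``partial`` stratum (some structural or chemical evidence but not
    both rich) in the fixed proportions of :data:`MIXED_PROPORTIONS`.

All draw distributions live in :data:`PROFILE_PARAMS` so tests and docs cite
one source of truth.  Every call is deterministic for a fixed
``(n, profile, seed)``.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

from .records import (
    ExpressionLevel,
    GenotypeEntry,
    LigandActivity,
    PocketReport,
    PocketSimilarity,
    Publication,
    StructureEntry,
    TargetRecord,
)

__all__ = [
    "MIXED_PROPORTIONS",
    "PROFILE_PARAMS",
    "TISSUE_PANEL",
    "generate_synthetic_targets",
    "make_labeled_cohort",
]

TISSUE_PANEL = (
    "cerebral cortex", "hippocampus", "cerebellum", "spinal cord", "retina",
    "heart muscle", "skeletal muscle", "liver", "kidney", "lung",
    "pancreas", "stomach", "colon", "spleen", "thymus",
    "testis", "ovary", "placenta", "skin", "bone marrow",
)

#: Draw parameters per profile.  Counts are Poisson unless noted; scores are
#: Beta; potencies are log-normal (nM).  ``partial`` exists only inside the
#: ``mixed`` cohort.
PROFILE_PARAMS = {
    "drugged": dict(
        structures_lam=6.0, structures_min=1,
        coverage_beta=(8.0, 2.0), resolution_mu=math.log(2.2), resolution_sd=0.25,
        pockets_per_structure=(1, 4), pocket_beta=(4.0, 2.0),
        ligands_lam=30.0, ligands_min=5, rows_per_ligand=(1, 4),
        potency_mu=math.log(100.0), potency_sd=1.5,
        type_probs={"Ki": 0.35, "Kd": 0.15, "IC50": 0.35, "EC50": 0.05,
                    "percent_inhibition": 0.05, "ADME": 0.03, "other": 0.02},
        diseases=(2, 9), disease_beta=(3.0, 1.5),
        genetics=(1, 5), genetic_beta=(2.0, 2.0),
        tissues=(12, 20), expr_probs=(0.10, 0.25, 0.35, 0.30),
        genotypes=(1, 5), p_abnormal=0.4, p_lethal=0.15,
        pubs_range=(50, 400), isoforms=(1, 7), variants_lam=8.0,
        antibodies_lam=6.0, p_safety_flag=0.2,
        p_homolog=0.0,
    ),
    "partial": dict(
        structures_lam=0.8, structures_min=0,
        coverage_beta=(4.0, 3.0), resolution_mu=math.log(2.6), resolution_sd=0.3,
        pockets_per_structure=(0, 3), pocket_beta=(2.0, 3.0),
        ligands_lam=3.0, ligands_min=0, rows_per_ligand=(1, 2),
        potency_mu=math.log(2000.0), potency_sd=1.2,
        type_probs={"Ki": 0.15, "Kd": 0.05, "IC50": 0.55, "EC50": 0.10,
                    "percent_inhibition": 0.10, "ADME": 0.03, "other": 0.02},
        diseases=(0, 5), disease_beta=(2.0, 2.0),
        genetics=(0, 3), genetic_beta=(2.0, 3.0),
        tissues=(6, 14), expr_probs=(0.25, 0.35, 0.25, 0.15),
        genotypes=(0, 3), p_abnormal=0.4, p_lethal=0.15,
        pubs_range=(2, 80), isoforms=(0, 4), variants_lam=3.0,
        antibodies_lam=2.0, p_safety_flag=0.1,
        p_homolog=0.3,
    ),
    "dark": dict(
        structures_lam=0.0, structures_min=0,
        coverage_beta=(2.0, 2.0), resolution_mu=math.log(3.0), resolution_sd=0.3,
        pockets_per_structure=(0, 1), pocket_beta=(2.0, 4.0),
        ligands_lam=0.0, ligands_min=0, rows_per_ligand=(1, 2),
        potency_mu=math.log(10000.0), potency_sd=1.0,
        type_probs={"IC50": 1.0},
        diseases=(0, 2), disease_beta=(1.5, 4.0),
        genetics=(0, 2), genetic_beta=(1.5, 4.0),
        tissues=(0, 6), expr_probs=(0.5, 0.3, 0.15, 0.05),
        genotypes=(0, 2), p_abnormal=0.4, p_lethal=0.15,
        pubs_range=(0, 5), isoforms=(0, 3), variants_lam=1.0,
        antibodies_lam=0.5, p_safety_flag=0.0,
        p_homolog=0.1,
    ),
}

#: Stratum mix of the ``mixed`` profile (largest-remainder exact counts).
MIXED_PROPORTIONS = {"drugged": 0.3, "partial": 0.4, "dark": 0.3}

_SAFETY_FLAGS = (
    "cardiotoxicity alert", "hERG liability", "on-target CNS risk",
    "reproductive toxicity", "immune suppression",
)
_METHODS = ("X-ray", "EM", "NMR")
_GENOTYPES = ("knockout", "knockdown", "conditional knockout", "point mutation")


def _beta(rng, ab):
    return float(np.clip(rng.beta(*ab), 0.0, 1.0))


def _make_record(rng: np.random.Generator, index: int, stratum: str) -> TargetRecord:
    p = PROFILE_PARAMS[stratum]
    gene = f"SYN{index + 1:04d}"

    n_struct = p["structures_min"] + (
        int(rng.poisson(p["structures_lam"])) if p["structures_lam"] > 0 else 0
    )
    structures, pockets = [], []
    for s in range(n_struct):
        sid = f"{gene}-{s + 1:02d}"
        structures.append(
            StructureEntry(
                structure_id=sid,
                method=str(rng.choice(_METHODS, p=[0.7, 0.2, 0.1])),
                resolution=float(
                    np.clip(rng.lognormal(p["resolution_mu"], p["resolution_sd"]), 0.9, 4.5)
                ),
                coverage=_beta(rng, p["coverage_beta"]),
            )
        )
        lo, hi = p["pockets_per_structure"]
        for k in range(int(rng.integers(lo, hi))):
            pockets.append(
                PocketReport(
                    structure_id=sid,
                    pocket_index=k + 1,
                    ligandability_score=_beta(rng, p["pocket_beta"]),
                    volume=float(rng.uniform(150.0, 1800.0)),
                    alpha_sphere_count=int(rng.integers(15, 120)),
                )
            )

    pocket_similarity = None
    if n_struct == 0 and rng.random() < p["p_homolog"]:
        homolog_pockets = [
            PocketReport(
                structure_id=f"HOM-{gene}",
                pocket_index=k + 1,
                ligandability_score=_beta(rng, (3.0, 2.0)),
            )
            for k in range(int(rng.integers(1, 3)))
        ]
        pocket_similarity = PocketSimilarity(
            homolog_id=f"HOM-{gene}",
            sequence_identity=float(rng.uniform(30.0, 90.0)),
            pockets=homolog_pockets,
        )

    types = list(p["type_probs"])
    probs = np.array([p["type_probs"][t] for t in types])
    probs = probs / probs.sum()
    bioactivities = []
    n_ligands = p["ligands_min"] + (
        int(rng.poisson(p["ligands_lam"])) if p["ligands_lam"] > 0 else 0
    )
    for li in range(n_ligands):
        lig = f"CPD-{gene}-{li + 1:03d}"
        props = {
            "MW": float(rng.normal(380.0, 60.0)),
            "cLogP": float(rng.normal(2.5, 1.2)),
            "cLogD": float(rng.normal(1.8, 1.2)),
            "TPSA": float(np.clip(rng.normal(75.0, 25.0), 5.0, 220.0)),
            "HBD": float(rng.integers(0, 5)),
            "pKa": float(np.clip(rng.normal(8.0, 1.5), 2.0, 12.0)),
        }
        for _ in range(int(rng.integers(*p["rows_per_ligand"]))):
            atype = str(rng.choice(types, p=probs))
            if atype == "percent_inhibition":
                value = float(rng.uniform(5.0, 100.0))
            elif atype in ("ADME", "other"):
                value = float(rng.uniform(0.1, 100.0))
            else:
                value = float(np.clip(rng.lognormal(p["potency_mu"], p["potency_sd"]),
                                      0.01, 1e7))
            bioactivities.append(
                LigandActivity(
                    ligand_id=lig,
                    target_id=str(rng.choice([gene, f"OFF{int(rng.integers(1, 6))}"],
                                             p=[0.7, 0.3])),
                    activity_type=atype,
                    value=value,
                    properties=props,
                )
            )

    diseases = [
        (f"disease:{int(rng.integers(1, 500)):04d}", round(_beta(rng, p["disease_beta"]), 4))
        for _ in range(int(rng.integers(*p["diseases"])) if p["diseases"][1] > 0 else 0)
    ]
    genetics = [
        (f"trait:{int(rng.integers(1, 300)):04d}", round(_beta(rng, p["genetic_beta"]), 4))
        for _ in range(int(rng.integers(*p["genetics"])) if p["genetics"][1] > 0 else 0)
    ]

    lo, hi = p["tissues"]
    n_tissue = int(rng.integers(lo, hi + 1))
    tissues = rng.choice(len(TISSUE_PANEL), size=n_tissue, replace=False)
    expression = {
        TISSUE_PANEL[t]: ExpressionLevel(code=int(rng.choice(4, p=p["expr_probs"])))
        for t in sorted(tissues)
    }

    genotypes = []
    for g in range(int(rng.integers(*p["genotypes"])) if p["genotypes"][1] > 0 else 0):
        abnormal = bool(rng.random() < p["p_abnormal"])
        lethal = bool(abnormal and rng.random() < p["p_lethal"] / p["p_abnormal"])
        genotypes.append(
            GenotypeEntry(
                genotype=str(rng.choice(_GENOTYPES)),
                phenotypes=(["abnormal phenotype"] if abnormal else []),
                lethal=lethal,
                abnormal=abnormal,
            )
        )

    n_pubs = int(rng.integers(p["pubs_range"][0], p["pubs_range"][1] + 1))
    base = _dt.date(1985, 1, 1)
    pubs = [
        Publication(
            date=base + _dt.timedelta(days=int(rng.integers(0, 14600))),
            title=f"Study {j + 1} of {gene}",
        )
        for j in range(n_pubs)
    ]

    flags = (
        [str(rng.choice(_SAFETY_FLAGS))] if rng.random() < p["p_safety_flag"] else []
    )

    return TargetRecord(
        gene_name=gene,
        uniprot_id=f"P{10000 + index:05d}",
        structures=structures,
        pockets=pockets,
        pocket_similarity=pocket_similarity,
        bioactivities=bioactivities,
        disease_associations=diseases,
        genetic_associations=genetics,
        expression=expression,
        genotypes=genotypes,
        isoform_count=int(rng.integers(*p["isoforms"])) if p["isoforms"][1] > 0 else 0,
        variant_count=int(rng.poisson(p["variants_lam"])),
        publications=pubs,
        safety_flags=flags,
        antibody_count=int(rng.poisson(p["antibodies_lam"])),
    )


def _mixed_strata(n: int, rng: np.random.Generator) -> list[str]:
    """Exact largest-remainder allocation of n records to the mixed strata."""
    names = sorted(MIXED_PROPORTIONS)
    raw = {k: MIXED_PROPORTIONS[k] * n for k in names}
    counts = {k: int(math.floor(raw[k])) for k in names}
    short = n - sum(counts.values())
    for k in sorted(names, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    strata = [k for k in names for _ in range(counts[k])]
    rng.shuffle(strata)
    return strata


def mixed_stratum_counts(n: int) -> dict[str, int]:
    """Exact per-stratum counts the ``mixed`` profile produces for size n."""
    names = sorted(MIXED_PROPORTIONS)
    raw = {k: MIXED_PROPORTIONS[k] * n for k in names}
    counts = {k: int(math.floor(raw[k])) for k in names}
    short = n - sum(counts.values())
    for k in sorted(names, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_synthetic_targets(
    n: int, profile: str = "mixed", seed: int = 0
) -> list[TargetRecord]:
    """Draw ``n`` synthetic target records under the given profile.

    Deterministic for fixed ``(n, profile, seed)``.  ``profile`` is one of
    ``drugged``, ``dark`` or ``mixed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if profile not in ("drugged", "dark", "mixed"):
        raise ValueError(
            f"unknown profile {profile!r}; expected 'drugged', 'dark' or 'mixed'"
        )
    rng = np.random.default_rng(seed)
    if profile == "mixed":
        strata = _mixed_strata(n, rng)
    else:
        strata = [profile] * n
    return [_make_record(rng, i, s) for i, s in enumerate(strata)]


def make_labeled_cohort(
    n_tractable: int = 399,
    n_background: int = 400,
    seed: int = 0,
) -> tuple[list[TargetRecord], np.ndarray]:
    """Build a labeled training cohort for the tractability classifier.

    Mirrors the published construction: a positive class of clinically
    actionable (well-drugged) targets and a background class sampled from the
    remaining proteome after removing the druggable genome — emulated here as
    a half dark / half partially-annotated mixture.  Returns the records and
    a binary label vector (1 = tractable).
    """
    rng = np.random.default_rng(seed)
    records = []
    labels = []
    for i in range(n_tractable):
        records.append(_make_record(rng, i, "drugged"))
        labels.append(1)
    n_dark = n_background // 2
    strata = ["dark"] * n_dark + ["partial"] * (n_background - n_dark)
    rng.shuffle(strata)
    for j, s in enumerate(strata):
        records.append(_make_record(rng, n_tractable + j, s))
        labels.append(0)
    return records, np.asarray(labels, dtype=int)
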