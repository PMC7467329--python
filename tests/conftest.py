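import datetime

import pytest

from targetlens.records import (
    ExpressionLevel,
    GenotypeEntry,
    LigandActivity,
    PocketReport,
    Publication,
    StructureEntry,
    TargetRecord,
)

POCKET_INFO_TWO_BLOCKS = """\
Pocket 1 :
\tScore : \t0.491
\tDruggability Score : \t0.62
\tNumber of Alpha Spheres : \t48
\tTotal SASA : \t151.982
\tVolume : \t871.03

Pocket 2 :
\tScore : \t0.213
\tDruggability Score : \t0.31
\tNumber of Alpha Spheres : \t22
\tVolume : \t240.5
"""


@pytest.fixture
def pocket_info_text():
    return POCKET_INFO_TWO_BLOCKS


@pytest.fixture
def empty_record():
    return TargetRecord(gene_name="EMPTY1")


@pytest.fixture
def rich_record():
    """A documented hand-auditable record used by the scoring oracles."""
    return TargetRecord(
        gene_name="HAND1",
        uniprot_id="P00001",
        structures=[
            StructureEntry(structure_id="S1", method="X-ray", resolution=2.0, coverage=0.8),
            StructureEntry(structure_id="S2", method="EM", resolution=3.2, coverage=0.5),
        ],
        pockets=[
            PocketReport(structure_id="S1", pocket_index=1, ligandability_score=0.7),
            PocketReport(structure_id="S1", pocket_index=2, ligandability_score=0.3),
        ],
        bioactivities=[
            LigandActivity(ligand_id="L1", target_id="HAND1", activity_type="Ki", value=50.0),
            LigandActivity(ligand_id="L1", target_id="OFF1", activity_type="Ki", value=200.0),
            LigandActivity(ligand_id="L2", target_id="HAND1", activity_type="Kd", value=80.0),
        ],
        disease_associations=[("disease:0001", 0.9), ("disease:0002", 0.4)],
        genetic_associations=[("trait:0001", 0.6)],
        expression={
            "liver": ExpressionLevel(label="High"),
            "kidney": ExpressionLevel(label="Low"),
            "lung": ExpressionLevel(label="Not observed"),
        },
        genotypes=[
            GenotypeEntry(genotype="knockout", phenotypes=[], lethal=False, abnormal=False),
            GenotypeEntry(
                genotype="knockdown",
                phenotypes=["abnormal gait"],
                lethal=False,
                abnormal=True,
            ),
        ],
        isoform_count=2,
        variant_count=5,
        publications=[
            Publication(date=datetime.date(2018, 1, 1), title="old"),
            Publication(date=datetime.date(2020, 6, 1), title="new"),
            Publication(date=None, title="undated"),
        ],
        safety_flags=[],
        antibody_count=3,
    )
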