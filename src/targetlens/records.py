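"""Per-target knowledge records: data model, validation and bundle I/O.

A :class:`TargetRecord` aggregates everything the toolkit knows about one
protein target — structures, detected pockets, bioactivities, disease and
genetic associations, tissue expression, mouse genotypes, publications and
safety annotations.  Records normally arrive as JSON "bundles" (one file per
target) or, for list-mode ranking, as rows of a flat delimited table carrying
only scalar indicator counts.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ACTIVITY_TYPES",
    "BundleValidationError",
    "ExpressionLevel",
    "GenotypeEntry",
    "LigandActivity",
    "PocketReport",
    "PocketSimilarity",
    "Publication",
    "StructureEntry",
    "TargetRecord",
    "decode_expression_level",
    "encode_expression_level",
    "load_target_bundle",
    "load_target_table",
    "write_target_bundle",
]

#: Tissue expression encoding: label <-> integer code.
EXPRESSION_CODES = {
    "high": 3,
    "medium": 2,
    "low": 1,
    "not observed": 0,
}
EXPRESSION_LABELS = {3: "High", 2: "Medium", 1: "Low", 0: "Not observed"}

#: Closed set of bioactivity record types.  Ki/Kd are equilibrium binding
#: constants; IC50/EC50 are dose-response readouts; the rest are bucketed.
ACTIVITY_TYPES = ("Ki", "Kd", "IC50", "EC50", "percent_inhibition", "ADME", "other")

POTENCY_TYPES = ("Ki", "Kd", "IC50", "EC50")


class BundleValidationError(ValueError):
    """A target bundle failed validation; the message names field and value."""


def encode_expression_level(label: str) -> int:
    """Map a tissue expression label to its integer code.

    The encoding is ``High=3, Medium=2, Low=1, Not observed=0``; matching is
    case-insensitive.
    """
    code = EXPRESSION_CODES.get(str(label).strip().lower())
    if code is None:
        accepted = ", ".join(EXPRESSION_LABELS[c] for c in (3, 2, 1, 0))
        raise ValueError(
            f"unrecognized expression label {label!r}; accepted labels: {accepted}"
        )
    return code


def decode_expression_level(code: int) -> str:
    """Inverse of :func:`encode_expression_level` on {0, 1, 2, 3}."""
    try:
        return EXPRESSION_LABELS[int(code)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unrecognized expression code {code!r}; accepted: 0-3") from exc


class ExpressionLevel(BaseModel):
    """A tissue expression level with its fixed label/code pairing."""

    model_config = ConfigDict(extra="ignore", frozen=True)

    label: str
    code: int = Field(ge=0, le=3)

    @model_validator(mode="before")
    @classmethod
    def _fill_pair(cls, data):
        if isinstance(data, str):
            data = {"label": data}
        if isinstance(data, int):
            data = {"code": data}
        if isinstance(data, dict):
            data = dict(data)
            if "label" in data and "code" not in data:
                data["code"] = encode_expression_level(data["label"])
            elif "code" in data and "label" not in data:
                data["label"] = decode_expression_level(data["code"])
        return data

    @model_validator(mode="after")
    def _check_bijection(self):
        canonical = encode_expression_level(self.label)
        if canonical != self.code:
            raise ValueError(
                f"expression label {self.label!r} must carry code {canonical}, got {self.code}"
            )
        return self


class GenotypeEntry(BaseModel):
    """One mouse genotype (knockout, knockdown, ...) and its phenotypes."""

    model_config = ConfigDict(extra="ignore")

    genotype: str
    phenotypes: list[str] = Field(default_factory=list)
    lethal: bool = False
    abnormal: bool = False

    @model_validator(mode="after")
    def _lethal_implies_abnormal(self):
        if self.lethal and not self.abnormal:
            raise ValueError(
                f"genotype {self.genotype!r}: lethal=True requires abnormal=True"
            )
        return self


class StructureEntry(BaseModel):
    """One experimental 3D structure of the target."""

    model_config = ConfigDict(extra="ignore")

    structure_id: str
    method: str = "X-ray"
    resolution: Optional[float] = Field(default=None, gt=0)
    coverage: float = Field(default=0.0, ge=0.0, le=1.0)


class PocketReport(BaseModel):
    """One detected binding pocket and its ligandability score."""

    model_config = ConfigDict(extra="ignore")

    structure_id: str
    pocket_index: int = Field(ge=1)
    ligandability_score: float = Field(ge=0.0, le=1.0)
    volume: Optional[float] = Field(default=None, ge=0.0)
    alpha_sphere_count: Optional[int] = Field(default=None, ge=0)


class PocketSimilarity(BaseModel):
    """Sequence-search fallback: a structurally characterized homolog."""

    model_config = ConfigDict(extra="ignore")

    homolog_id: str
    sequence_identity: float = Field(ge=0.0, le=100.0)
    pockets: list[PocketReport] = Field(default_factory=list)


class LigandActivity(BaseModel):
    """One bioactivity measurement of a ligand against a target.

    ``value`` is in nM for the potency types (Ki, Kd, IC50, EC50).
    ``properties`` optionally carries physicochemical descriptors of the
    ligand (MW, cLogP, TPSA, ...) used for CNS desirability scoring.
    """

    model_config = ConfigDict(extra="ignore")

    ligand_id: str
    target_id: str
    activity_type: str
    value: float
    properties: dict[str, float] = Field(default_factory=dict)

    @field_validator("activity_type")
    @classmethod
    def _known_type(cls, v):
        if v not in ACTIVITY_TYPES:
            raise ValueError(
                f"activity_type {v!r} not in accepted set {ACTIVITY_TYPES}"
            )
        return v

    @model_validator(mode="after")
    def _positive_potency(self):
        if self.activity_type in POTENCY_TYPES and not self.value > 0:
            raise ValueError(
                f"ligand {self.ligand_id!r}: potency value must be > 0, got {self.value}"
            )
        return self


class Publication(BaseModel):
    """A literature record; ``date`` may be absent (sorts last by recency)."""

    model_config = ConfigDict(extra="ignore")

    date: Optional[_dt.date] = None
    title: str = ""


def _score_pair_list(name):
    """Validator factory: list of (id, score in [0, 1]) pairs."""

    def _check(cls, v):
        out = []
        for item in v:
            if isinstance(item, dict):
                key = item.get("id") or item.get("disease") or item.get("trait")
                score = item.get("score")
            else:
                key, score = item
            score = float(score)
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"{name} score for {key!r} must be in [0, 1], got {score}"
                )
            out.append((str(key), score))
        return out

    return _check


class TargetRecord(BaseModel):
    """Aggregated knowledge bundle for one target."""

    model_config = ConfigDict(extra="ignore", validate_assignment=True)

    gene_name: str
    uniprot_id: Optional[str] = None
    structures: list[StructureEntry] = Field(default_factory=list)
    pockets: list[PocketReport] = Field(default_factory=list)
    pocket_similarity: Optional[PocketSimilarity] = None
    bioactivities: list[LigandActivity] = Field(default_factory=list)
    disease_associations: list[tuple[str, float]] = Field(default_factory=list)
    genetic_associations: list[tuple[str, float]] = Field(default_factory=list)
    expression: dict[str, ExpressionLevel] = Field(default_factory=dict)
    genotypes: list[GenotypeEntry] = Field(default_factory=list)
    isoform_count: int = Field(default=0, ge=0)
    variant_count: int = Field(default=0, ge=0)
    publications: list[Publication] = Field(default_factory=list)
    safety_flags: list[str] = Field(default_factory=list)
    antibody_count: int = Field(default=0, ge=0)

    _check_diseases = field_validator("disease_associations", mode="before")(
        classmethod(_score_pair_list("disease association"))
    )
    _check_genetics = field_validator("genetic_associations", mode="before")(
        classmethod(_score_pair_list("genetic association"))
    )

    @field_validator("gene_name")
    @classmethod
    def _nonempty_gene(cls, v):
        if not str(v).strip():
            raise ValueError("gene_name must be a non-empty string")
        return str(v).strip()

    @model_validator(mode="after")
    def _unique_pocket_index(self):
        seen = set()
        for p in self.pockets:
            key = (p.structure_id, p.pocket_index)
            if key in seen:
                raise ValueError(
                    f"duplicate pocket index {p.pocket_index} for structure {p.structure_id!r}"
                )
            seen.add(key)
        return self

    def expression_code(self, tissue: str) -> int:
        """Numeric expression code for a tissue; absent tissues read as 0."""
        level = self.expression.get(tissue)
        return level.code if level is not None else 0


_KNOWN_BUNDLE_KEYS = set(TargetRecord.model_fields)


def load_target_bundle(path, format: str = "json") -> TargetRecord:
    """Load and validate a single-target bundle.

    Parameters
    ----------
    path
        File holding the bundle.
    format
        ``"json"`` (canonical, full record) or ``"tabular"`` (one-row
        delimited file carrying only the scalar indicator columns).

    Unknown top-level fields are ignored with a logged warning.  A missing
    ``gene_name`` or an out-of-range score is a hard error naming the field.
    """
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            data = json.load(fh)
        return record_from_dict(data, source=str(path))
    if format == "tabular":
        rows = load_target_table(path)
        if len(rows) != 1:
            raise BundleValidationError(
                f"{path}: tabular single-target bundle must hold exactly one row, got {len(rows)}"
            )
        return rows[0]
    raise ValueError(f"unknown bundle format {format!r}; expected 'json' or 'tabular'")


def record_from_dict(data: dict, source: str = "<dict>") -> TargetRecord:
    """Validate a raw mapping into a :class:`TargetRecord`."""
    if not isinstance(data, dict):
        raise BundleValidationError(f"{source}: bundle must be a JSON object")
    if "gene_name" not in data:
        raise BundleValidationError(f"{source}: bundle is missing required field 'gene_name'")
    unknown = set(data) - _KNOWN_BUNDLE_KEYS
    if unknown:
        logger.warning("%s: ignoring unknown bundle fields: %s", source, sorted(unknown))
    try:
        return TargetRecord.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise BundleValidationError(f"{source}: field {loc}: {first['msg']}") from exc


def write_target_bundle(record: TargetRecord, path) -> Path:
    """Serialize a record to its canonical JSON bundle form."""
    path = Path(path)
    path.write_text(record.model_dump_json(indent=1))
    return path


#: Column dictionary of the flat list-mode table (scalar indicators only).
TABLE_COLUMNS = (
    "gene_name",
    "uniprot_id",
    "isoform_count",
    "variant_count",
    "antibody_count",
    "safety_flags",
)


def load_target_table(path, sep: str = ",") -> list[TargetRecord]:
    """Read a flat delimited list-mode table into minimal records.

    One row per target; only the scalar indicator columns of
    :data:`TABLE_COLUMNS` are recognized (``safety_flags`` is
    semicolon-joined).  Duplicate gene names are a hard error.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if "gene_name" not in df.columns:
        raise BundleValidationError(f"{path}: table is missing required column 'gene_name'")
    unknown = [c for c in df.columns if c not in TABLE_COLUMNS]
    if unknown:
        logger.warning("%s: ignoring unknown table columns: %s", path, unknown)
    records = []
    for _, row in df.iterrows():
        data = {"gene_name": row["gene_name"]}
        if row.get("uniprot_id"):
            data["uniprot_id"] = row["uniprot_id"]
        for col in ("isoform_count", "variant_count", "antibody_count"):
            if str(row.get(col, "")).strip():
                data[col] = int(float(row[col]))
        if str(row.get("safety_flags", "")).strip():
            data["safety_flags"] = [
                f.strip() for f in row["safety_flags"].split(";") if f.strip()
            ]
        records.append(record_from_dict(data, source=str(path)))
    names = [r.gene_name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise BundleValidationError(f"{path}: duplicate gene names: {dupes}")
    return records
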