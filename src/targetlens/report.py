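"""Report rendering: single-target workbook and list-mode ranking table.

The single-target workbook mirrors the classic aggregated-profile layout:
one worksheet per evidence domain (literature, diseases, associations,
expression, genotypes, structures, pockets, bioactivity classes, ...) with
the radar profile embedded on the Main sheet.  The list report is one row
per target with area scores, the MPO ranking score and the tractability
readout, sorted for prioritization.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from openpyxl import Workbook
from openpyxl.styles import Font, PatternFill

from .ligands import ligand_profile
from .pockets import flag_ligandable
from .records import GenotypeEntry, TargetRecord
from .scoring import AREA_NAMES, AreaScores, MpoWeights, axis_qualities, mpo_score
from .tractability import TractabilityPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PUBLICATION_CAP",
    "SHEET_NAMES",
    "ReportConfig",
    "genotype_color",
    "render_list_report",
    "render_single_report",
]

#: Most-recent-first cap on the literature worksheet.
DEFAULT_PUBLICATION_CAP = 500

#: Fixed worksheet set of the single-target workbook.  "Variants-Mutants"
#: uses a hyphen because "/" is illegal in worksheet names.
SHEET_NAMES = (
    "Main",
    "Pubmed search",
    "Diseases",
    "Open target association",
    "Expression",
    "Genotypes",
    "Isoforms",
    "Variants-Mutants",
    "Structure",
    "Pockets",
    "Binding",
    "Dose-response",
    "Percent-Inhibition",
    "ADME",
    "Other bioactivities",
    "BindingDB",
    "Commercial compounds",
)

_GREEN = "FF92D050"
_RED = "FFFF5050"


class ReportConfig:
    """Rendering options shared by the three output modes."""

    def __init__(
        self,
        mode: str = "single",
        output_dir: str | Path = ".",
        weights: Optional[MpoWeights] = None,
        publication_cap: int = DEFAULT_PUBLICATION_CAP,
        list_columns: Optional[Sequence[str]] = None,
    ):
        if mode not in ("single", "list", "plot"):
            raise ValueError(f"unknown report mode {mode!r}")
        if publication_cap <= 0:
            raise ValueError(f"publication cap must be positive, got {publication_cap}")
        self.mode = mode
        self.output_dir = Path(output_dir)
        self.weights = weights if weights is not None else MpoWeights()
        self.publication_cap = int(publication_cap)
        self.list_columns = list(list_columns) if list_columns else None


def genotype_color(entry: GenotypeEntry) -> str:
    """Color tag for a genotype row: green (benign), red (lethal), none."""
    if entry.lethal:
        return "red"
    if not entry.abnormal:
        return "green"
    return "none"


def _write_rows(ws, header, rows):
    ws.append(list(header))
    for cell in ws[1]:
        cell.font = Font(bold=True)
    for row in rows:
        ws.append(list(row))


def render_single_report(
    record: TargetRecord,
    scores: AreaScores,
    prediction: Optional[TractabilityPrediction],
    config: ReportConfig,
    path: str | Path | None = None,
) -> Path:
    """Write the multi-sheet single-target workbook; returns its path."""
    path = (
        Path(path)
        if path is not None
        else config.output_dir / f"{record.gene_name}_report.xlsx"
    )
    path.parent.mkdir(parents=True, exist_ok=True)

    wb = Workbook()
    wb.remove(wb.active)
    sheets = {name: wb.create_sheet(name) for name in SHEET_NAMES}

    main = sheets["Main"]
    main["A1"] = "Gene"
    main["B1"] = record.gene_name
    main["A2"] = "UniProt"
    main["B2"] = record.uniprot_id or ""
    main["A3"] = "MPO score"
    main["B3"] = round(mpo_score(scores, config.weights), 4)
    if prediction is not None:
        main["A4"] = "Tractability vote %"
        main["B4"] = round(100.0 * prediction.vote_fraction, 1)
        main["A5"] = "Tractability class"
        main["B5"] = prediction.label
    row0 = 7
    main.cell(row=row0 - 1, column=1, value="Area scores").font = Font(bold=True)
    for i, name in enumerate(AREA_NAMES):
        main.cell(row=row0 + i, column=1, value=name)
        main.cell(row=row0 + i, column=2, value=round(getattr(scores, name), 4))
    _embed_spider(main, record, scores)

    dated = sorted(
        record.publications,
        key=lambda p: (p.date is None, -(p.date.toordinal() if p.date else 0)),
    )
    _write_rows(
        sheets["Pubmed search"],
        ("Date", "Title"),
        (
            (p.date.isoformat() if p.date else "", p.title)
            for p in dated[: config.publication_cap]
        ),
    )

    _write_rows(
        sheets["Diseases"],
        ("Disease", "Association score"),
        record.disease_associations,
    )
    _write_rows(
        sheets["Open target association"],
        ("Disease", "Overall association score"),
        record.disease_associations,
    )
    _write_rows(
        sheets["Expression"],
        ("Tissue", "Level", "Code"),
        (
            (tissue, lv.label, lv.code)
            for tissue, lv in sorted(record.expression.items())
        ),
    )

    geno = sheets["Genotypes"]
    _write_rows(
        geno,
        ("Genotype", "Phenotypes", "Lethal", "Abnormal"),
        (
            (g.genotype, "; ".join(g.phenotypes), g.lethal, g.abnormal)
            for g in record.genotypes
        ),
    )
    fills = {"green": PatternFill("solid", fgColor=_GREEN), "red": PatternFill("solid", fgColor=_RED)}
    for i, g in enumerate(record.genotypes):
        tag = genotype_color(g)
        if tag in fills:
            for cell in geno[i + 2]:
                cell.fill = fills[tag]

    _write_rows(sheets["Isoforms"], ("Isoform count",), [(record.isoform_count,)])
    _write_rows(sheets["Variants-Mutants"], ("Variant count",), [(record.variant_count,)])
    _write_rows(
        sheets["Structure"],
        ("Structure", "Method", "Resolution (A)", "Chain coverage"),
        (
            (s.structure_id, s.method, s.resolution, round(s.coverage, 3))
            for s in record.structures
        ),
    )

    pocket_rows = [
        (
            p.structure_id,
            p.pocket_index,
            round(p.ligandability_score, 3),
            flag_ligandable(p),
            p.volume,
            p.alpha_sphere_count,
        )
        for p in record.pockets
    ]
    if record.pocket_similarity is not None:
        for p in record.pocket_similarity.pockets:
            pocket_rows.append(
                (
                    f"{p.structure_id} (homolog, "
                    f"{record.pocket_similarity.sequence_identity:.0f}% identity)",
                    p.pocket_index,
                    round(p.ligandability_score, 3),
                    flag_ligandable(p),
                    p.volume,
                    p.alpha_sphere_count,
                )
            )
    _write_rows(
        sheets["Pockets"],
        ("Structure", "Pocket", "Ligandability score", "Ligandable", "Volume", "Alpha spheres"),
        pocket_rows,
    )

    profiles = ligand_profile(record.bioactivities)
    binding_rows = []
    for a in record.bioactivities:
        if a.activity_type in ("Ki", "Kd"):
            prof = profiles.get(a.ligand_id, {})
            cns = prof.get("cns_mpo")
            binding_rows.append(
                (
                    a.ligand_id,
                    a.target_id,
                    a.activity_type,
                    a.value,
                    round(prof.get("selectivity_entropy", 0.0), 4),
                    prof.get("best_target", ""),
                    round(cns, 3) if cns is not None else "",
                )
            )
    _write_rows(
        sheets["Binding"],
        ("Ligand", "Target", "Type", "Potency (nM)", "Selectivity entropy", "Best target", "CNS MPO"),
        binding_rows,
    )

    buckets = {
        "Dose-response": ("IC50", "EC50"),
        "Percent-Inhibition": ("percent_inhibition",),
        "ADME": ("ADME",),
        "Other bioactivities": ("other",),
    }
    for sheet, types in buckets.items():
        _write_rows(
            sheets[sheet],
            ("Ligand", "Target", "Type", "Value"),
            (
                (a.ligand_id, a.target_id, a.activity_type, a.value)
                for a in record.bioactivities
                if a.activity_type in types
            ),
        )

    _write_rows(sheets["BindingDB"], ("Ligand", "Target", "Type", "Value (nM)"), [])
    _write_rows(sheets["Commercial compounds"], ("Ligand", "Supplier link"), [])

    wb.save(path)
    logger.info("wrote single-target report %s", path)
    return path


def _embed_spider(ws, record: TargetRecord, scores: AreaScores) -> None:
    """Render the radar profile to an in-memory PNG and anchor it on Main."""
    import io

    from openpyxl.drawing.image import Image as XLImage

    from .plots import spider_plot_figure

    fig = spider_plot_figure(scores, axis_qualities(record), title=record.gene_name)
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90)
    import matplotlib.pyplot as plt

    plt.close(fig)
    buf.seek(0)
    img = XLImage(buf)
    ws.add_image(img, "D2")


def render_list_report(
    records: Sequence[TargetRecord],
    scores: Sequence[AreaScores],
    predictions: Sequence[Optional[TractabilityPrediction]],
    config: ReportConfig,
    path: str | Path | None = None,
) -> Path:
    """Write the one-row-per-target prioritization table (CSV).

    Rows are sorted by MPO score descending with an alphabetical gene-name
    tie-break.
    """
    if not records:
        raise ValueError("no records to report")
    names = [r.gene_name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate gene names in list report: {dupes}")
    rows = []
    for rec, sc, pred in zip(records, scores, predictions):
        row = {"gene_name": rec.gene_name, "uniprot_id": rec.uniprot_id or ""}
        row.update({f"score_{k}": round(v, 4) for k, v in sc.as_dict().items()})
        row["mpo_score"] = round(mpo_score(sc, config.weights), 4)
        row["tractability_vote_pct"] = (
            round(100.0 * pred.vote_fraction, 1) if pred is not None else ""
        )
        row["tractability_class"] = pred.label if pred is not None else ""
        row["n_structures"] = len(rec.structures)
        row["n_pockets"] = len(rec.pockets)
        row["n_bioactivities"] = len(rec.bioactivities)
        row["n_publications"] = len(rec.publications)
        row["antibody_count"] = rec.antibody_count
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["mpo_score", "gene_name"], ascending=[False, True], kind="mergesort"
    )
    if config.list_columns:
        keep = ["gene_name"] + [c for c in config.list_columns if c in df.columns]
        df = df[list(dict.fromkeys(keep))]
    path = Path(path) if path is not None else config.output_dir / "target_ranking.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    logger.info("wrote list report %s (%d targets)", path, len(df))
    return path
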