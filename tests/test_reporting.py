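"""Workbook, ranking-table and radar-plot rendering plus the CLI."""

import datetime

import pytest
from click.testing import CliRunner
from openpyxl import load_workbook

from targetlens.cli import main as cli_main
from targetlens.plots import SPIDER_AXIS_ORDER, render_spider_plot, spider_plot_figure
from targetlens.records import GenotypeEntry, Publication, TargetRecord, write_target_bundle
from targetlens.report import (
    SHEET_NAMES,
    ReportConfig,
    genotype_color,
    render_list_report,
    render_single_report,
)
from targetlens.scoring import AreaScores, MpoWeights, all_area_scores
from targetlens.synthetic import generate_synthetic_targets
from targetlens.tractability import TractabilityPrediction


def test_workbook_sheet_names_golden(tmp_path, empty_record):
    cfg = ReportConfig(mode="single", output_dir=tmp_path)
    path = render_single_report(empty_record, all_area_scores(empty_record), None, cfg)
    wb = load_workbook(path)
    assert tuple(wb.sheetnames) == SHEET_NAMES


def test_empty_record_sheets_have_headers_only(tmp_path, empty_record):
    cfg = ReportConfig(mode="single", output_dir=tmp_path)
    path = render_single_report(empty_record, all_area_scores(empty_record), None, cfg)
    wb = load_workbook(path)
    for name in ("Structure", "Pockets", "Binding", "Genotypes"):
        ws = wb[name]
        assert ws.max_row == 1  # header only


def test_publication_cap_most_recent_first(tmp_path):
    pubs = [
        Publication(date=datetime.date(1990, 1, 1) + datetime.timedelta(days=10 * i),
                    title=f"p{i}")
        for i in range(1000)
    ]
    rec = TargetRecord(gene_name="CAPPED", publications=pubs)
    cfg = ReportConfig(mode="single", output_dir=tmp_path)
    path = render_single_report(rec, all_area_scores(rec), None, cfg)
    ws = load_workbook(path)["Pubmed search"]
    assert ws.max_row == 501  # header + exactly 500 rows
    dates = [ws.cell(row=i, column=1).value for i in range(2, ws.max_row + 1)]
    assert dates == sorted(dates, reverse=True)
    assert dates[0] == pubs[-1].date.isoformat()


@pytest.mark.parametrize(
    "lethal,abnormal,expected",
    [(False, False, "green"), (True, True, "red"), (False, True, "none")],
)
def test_genotype_color_rule(lethal, abnormal, expected):
    entry = GenotypeEntry(genotype="knockout", lethal=lethal, abnormal=abnormal)
    assert genotype_color(entry) == expected


def test_genotype_rows_filled_per_color(tmp_path):
    rec = TargetRecord(
        gene_name="GENO",
        genotypes=[
            GenotypeEntry(genotype="ko", lethal=False, abnormal=False),
            GenotypeEntry(genotype="kd", lethal=True, abnormal=True),
            GenotypeEntry(genotype="cko", lethal=False, abnormal=True),
        ],
    )
    cfg = ReportConfig(mode="single", output_dir=tmp_path)
    path = render_single_report(rec, all_area_scores(rec), None, cfg)
    ws = load_workbook(path)["Genotypes"]
    fills = [ws.cell(row=r, column=1).fill for r in (2, 3, 4)]
    assert fills[0].fgColor.rgb == "FF92D050"  # green
    assert fills[1].fgColor.rgb == "FFFF5050"  # red
    assert fills[2].patternType is None


def test_single_report_includes_prediction(tmp_path, rich_record):
    cfg = ReportConfig(mode="single", output_dir=tmp_path)
    pred = TractabilityPrediction(vote_fraction=0.72, label="Tractable")
    path = render_single_report(rich_record, all_area_scores(rich_record), pred, cfg)
    main = load_workbook(path)["Main"]
    assert main["B4"].value == 72.0
    assert main["B5"].value == "Tractable"


# --- list report ---------------------------------------------------------

def _fixed_scores(values):
    names = ("druggability", "structure", "biology", "chemistry",
             "diseases", "genetics", "information", "safety")
    return AreaScores(**{k: v for k, v in zip(names, [values] * 8)})


def test_list_report_sorted_by_mpo_then_gene(tmp_path):
    import pandas as pd

    recs = [TargetRecord(gene_name=g) for g in ("B2", "A1", "C3", "A0")]
    scores = [_fixed_scores(v) for v in (0.5, 0.9, 0.1, 0.9)]
    cfg = ReportConfig(mode="list", output_dir=tmp_path)
    path = render_list_report(recs, scores, [None] * 4, cfg)
    df = pd.read_csv(path)
    assert list(df["gene_name"]) == ["A0", "A1", "B2", "C3"]
    assert df["mpo_score"].between(0, 1).all()


def test_list_report_row_conservation(tmp_path):
    import pandas as pd

    recs = generate_synthetic_targets(95, "mixed", seed=17)
    scores = [all_area_scores(r) for r in recs]
    cfg = ReportConfig(mode="list", output_dir=tmp_path)
    path = render_list_report(recs, scores, [None] * len(recs), cfg)
    df = pd.read_csv(path)
    assert len(df) == 95
    assert df["mpo_score"].between(0, 1).all()


def test_list_report_duplicate_genes_rejected(tmp_path):
    recs = [TargetRecord(gene_name="A"), TargetRecord(gene_name="A")]
    cfg = ReportConfig(mode="list", output_dir=tmp_path)
    with pytest.raises(ValueError, match="duplicate"):
        render_list_report(recs, [_fixed_scores(0.5)] * 2, [None, None], cfg)


# --- spider plot ---------------------------------------------------------

def test_spider_plot_eight_axes_and_extents(tmp_path):
    import matplotlib.pyplot as plt

    fig = spider_plot_figure(_fixed_scores(0.0))
    meta = fig.targetlens_axes
    assert len(meta) == 8 and tuple(meta) == SPIDER_AXIS_ORDER
    assert all(m["score"] == 0.0 for m in meta.values())
    plt.close(fig)

    fig = spider_plot_figure(_fixed_scores(1.0), {"safety": 0.0})
    meta = fig.targetlens_axes
    assert all(m["score"] == 1.0 for m in meta.values())
    assert meta["safety"]["color"] == (1.0, 0.0, 0.0)  # pure red at quality 0
    plt.close(fig)

    out = render_spider_plot(_fixed_scores(0.7), {}, tmp_path / "s.png")
    assert out.exists() and out.stat().st_size > 0


# --- CLI -----------------------------------------------------------------

def _write_bundles(tmp_path, n=3):
    paths = []
    for rec in generate_synthetic_targets(n, "mixed", seed=21):
        paths.append(str(write_target_bundle(rec, tmp_path / f"{rec.gene_name}.json")))
    return paths


def test_cli_list_mode(tmp_path):
    paths = _write_bundles(tmp_path, 5)
    out = tmp_path / "out"
    result = CliRunner().invoke(
        cli_main,
        ["--mode", "list", "-o", str(out), "--no-predict", *paths],
    )
    assert result.exit_code == 0, result.output
    assert (out / "target_ranking.csv").exists()


def test_cli_plot_mode(tmp_path):
    paths = _write_bundles(tmp_path, 1)
    out = tmp_path / "plots"
    result = CliRunner().invoke(cli_main, ["--mode", "plot", "-o", str(out), *paths])
    assert result.exit_code == 0, result.output
    pngs = list(out.glob("*_spider.png"))
    assert len(pngs) == 1


def test_cli_single_mode_synthetic(tmp_path):
    out = tmp_path / "single"
    result = CliRunner().invoke(
        cli_main,
        ["--mode", "single", "--synthetic", "1", "--profile", "drugged",
         "--seed", "4", "-o", str(out), "--no-predict"],
    )
    assert result.exit_code == 0, result.output
    assert len(list(out.glob("*_report.xlsx"))) == 1


def test_cli_weight_flags(tmp_path):
    paths = _write_bundles(tmp_path, 3)
    out = tmp_path / "w"
    result = CliRunner().invoke(
        cli_main,
        ["--mode", "list", "-o", str(out), "--no-predict",
         "--weight", "structure=100", "--weight", "druggability=150",
         "--weight", "chemistry=-100", *paths],
    )
    assert result.exit_code == 0, result.output


def test_cli_unknown_mode_and_missing_input():
    runner = CliRunner()
    assert runner.invoke(cli_main, ["--mode", "bogus"]).exit_code != 0
    result = runner.invoke(cli_main, ["--mode", "list"])
    assert result.exit_code != 0
    assert "bundle" in result.output.lower() or "usage" in result.output.lower()


def test_report_config_validation():
    with pytest.raises(ValueError):
        ReportConfig(mode="triple")
    with pytest.raises(ValueError):
        ReportConfig(mode="single", publication_cap=0)
    cfg = ReportConfig(mode="single", weights=MpoWeights())
    assert cfg.publication_cap == 500
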