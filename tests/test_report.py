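"""Report surfaces, family tallies, and end-to-end pipeline behavior."""

import numpy as np
import pandas as pd
import pytest

import dgekit as dk
from dgekit.diffexpr import DEResult
from dgekit.mapping import MappingStats
from dgekit.report import (
    PipelineConfig,
    count_upregulated_by_family,
    library_stats_frame,
    percent_expansion,
    render_library_stats,
    run_pipeline,
    stats_cells,
    summarize_family_counts,
)


def make_stats(**kw):
    base = dict(
        library_id="lib",
        total_raw=1000,
        total_clean=900,
        distinct_clean=100,
        distinct_gene_mapped=40,
        distinct_unambiguous=30,
        genes_detected=25,
        distinct_genome_only=35,
        total_unknown=90,
        distinct_unknown=25,
        n_reference_genes=50,
    )
    base.update(kw)
    return MappingStats(**base)


class TestStatsRendering:
    def test_percentages_recomputable_from_counts(self):
        """Cross-sheet consistency: every printed percentage equals an
        independent recomputation from the count cells."""
        stats = make_stats()
        cells = stats_cells(stats)
        from dgekit._util import percent

        denom = {
            "Distinct tag mapping to gene": stats.distinct_clean,
            "Distinct unambiguous tag mapping to gene": stats.distinct_clean,
            "Unambiguous tag-mapped genes": stats.n_reference_genes,
            "Distinct tag mapping to genome": stats.distinct_clean,
            "Total unknown tag": stats.total_clean,
            "Distinct unknown tag": stats.distinct_clean,
        }
        for label, (count, pct) in cells.items():
            if pct is not None:
                assert pct == percent(count, denom[label])

    def test_text_and_frame_agree(self):
        stats = make_stats()
        text = render_library_stats([stats])
        frame = library_stats_frame([stats])
        for label in frame.index:
            assert label in text
        assert "40.0" in text  # 40/100 gene-mapped

    def test_rounding_is_half_away_from_zero(self):
        # 0.125 of distinct -> 12.5; banker's rounding would print 12.4/12.5 issues at 1 dp
        stats = make_stats(distinct_clean=1000, distinct_gene_mapped=125)
        assert stats.pct_gene_mapped == 12.5
        stats = make_stats(distinct_clean=10000, distinct_gene_mapped=1245)
        assert stats.pct_gene_mapped == 12.5  # 12.45 rounds up, not to even


class TestFamilyCounts:
    def test_percent_expansion_examples(self):
        assert percent_expansion(71, 51) == 39
        assert percent_expansion(196, 106) == 85
        assert percent_expansion(10, 10) == 0

    def test_summary_and_detection(self):
        table = {f"c{i}": ("CCE", "B") for i in range(3)}
        table |= {f"p{i}": ("P450", "CYP4") for i in range(5)}
        table |= {"g0": ("GST", "Delta")}
        s = summarize_family_counts(table, detected_genes={"c0", "p0", "p1"})
        assert s.family_totals == {"CCE": 3, "P450": 5, "GST": 1}
        assert s.class_totals[("P450", "CYP4")] == 5
        assert s.total == 9 and s.detected == 3
        assert s.pct_detected == 33

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            summarize_family_counts({"g": ("LIPASE", "x")})

    def test_upregulated_tally(self):
        fams = {"a": ("CCE", "B"), "b": ("GST", "Delta"), "c": ("P450", "CYP6")}
        res = [
            DEResult("a", 1, 9, 10, 10, 1, 9, 3.2, 1e-6, 1e-5, True),
            DEResult("b", 9, 1, 10, 10, 9, 1, -3.2, 1e-6, 1e-5, True),  # down
            DEResult("c", 5, 5, 10, 10, 5, 5, 0.0, 1.0, 1.0, False),    # null
            DEResult("zz", 1, 9, 10, 10, 1, 9, 3.2, 1e-6, 1e-5, True),  # no family
        ]
        out = count_upregulated_by_family(res, fams)
        assert out == {"CCE": 1, "P450": 0, "GST": 0, "total": 1}


SMALL_SYNTH = dict(
    n_genes=80,
    n_spike=5,
    fold_range=[8, 8],
    libraries=[
        {"id": "egg", "stage": "egg", "strain": "SG", "depth": 30000},
        {"id": "larva_a", "stage": "larva", "strain": "SG", "depth": 30000},
        {"id": "larva_b", "stage": "larva", "strain": "S-lab", "depth": 30000, "condition": "B"},
    ],
    n_terms=6,
    term_size_range=[5, 15],
    n_taxa=6,
    alignment_length=120,
    mutation_rate=0.3,
)


class TestPipeline:
    def test_end_to_end_outputs(self, tmp_path):
        cfg = PipelineConfig(seed=7, outdir=str(tmp_path / "o"), synthetic=dict(SMALL_SYNTH), bootstrap_reps=50)
        res = run_pipeline(cfg)
        for name in (
            "library_stats.tsv", "library_stats.txt", "abundance_distribution.tsv",
            "counts.tsv", "tpm.tsv", "stage_specific.tsv", "correlation.tsv",
            "saturation.tsv", "de_table.tsv", "tree.nwk", "distances.phylip",
            "run_log.txt",
        ):
            assert (tmp_path / "o" / name).exists(), name
        assert "seed: 7" in (tmp_path / "o" / "run_log.txt").read_text()

    def test_rerun_byte_identical(self, tmp_path):
        cfg1 = PipelineConfig(seed=11, outdir=str(tmp_path / "a"), synthetic=dict(SMALL_SYNTH), bootstrap_reps=20)
        cfg2 = PipelineConfig(seed=11, outdir=str(tmp_path / "b"), synthetic=dict(SMALL_SYNTH), bootstrap_reps=20)
        run_pipeline(cfg1)
        run_pipeline(cfg2)
        for f in sorted((tmp_path / "a").rglob("*")):
            if f.is_file():
                twin = tmp_path / "b" / f.relative_to(tmp_path / "a")
                assert twin.read_bytes() == f.read_bytes(), f.name

    def test_disabled_thresholds_keep_every_gene(self, tmp_path):
        cfg = PipelineConfig(
            seed=5, outdir=str(tmp_path / "o"), synthetic=dict(SMALL_SYNTH),
            fdr_max=1.0, min_abs_log2=1e-12, bootstrap_reps=20,
        )
        res = run_pipeline(cfg)
        de = pd.read_csv(tmp_path / "o" / "de_table.tsv", sep="\t")
        # every tested gene is in the table and essentially all are "called"
        assert len(de) == len(res["de"])
        assert de["significant"].mean() > 0.9

    def test_table_sheet_percentages_recompute(self, tmp_path):
        cfg = PipelineConfig(seed=3, outdir=str(tmp_path / "o"), synthetic=dict(SMALL_SYNTH), bootstrap_reps=20)
        res = run_pipeline(cfg)
        sheet = pd.read_csv(tmp_path / "o" / "library_stats.tsv", sep="\t", index_col=0)
        from dgekit._util import percent

        for stats in res["stats"]:
            n = sheet[f"{stats.library_id}_N"]
            pct = sheet[f"{stats.library_id}_pct"]
            assert float(pct["Distinct tag mapping to gene"]) == percent(
                int(n["Distinct tag mapping to gene"]), int(n["Distinct clean tag"])
            )
            assert float(pct["Total unknown tag"]) == percent(
                int(n["Total unknown tag"]), int(n["Total clean tag"])
            )

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            PipelineConfig(fdr_max=0)


class TestCli:
    def test_simulate_clean_map_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from dgekit.cli import main

        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "--n-genes", "30", "--depth", "20000",
                                 "--seed", "3", "--outdir", str(out)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["clean", str(out / "library_raw.tsv"), str(out / "clean.tsv")])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["map", str(out / "clean.tsv"), "--reference-dir", str(out),
                                 "--out-prefix", str(out / "m")])
        assert r.exit_code == 0, r.output
        counts = pd.read_csv(out / "m_counts.tsv", sep="\t")
        assert counts["count"].sum() > 0

    def test_tree_command(self, tmp_path):
        from click.testing import CliRunner

        from dgekit import io as dio
        from dgekit.cli import main

        aln = dk.generate_alignment(5, length=80, mutation_rate=0.3, seed=4)
        dio.write_alignment(aln, tmp_path / "aln.fasta")
        runner = CliRunner()
        r = runner.invoke(main, ["tree", str(tmp_path / "aln.fasta"),
                                 "--bootstrap-reps", "20", "--seed", "1",
                                 "--out", str(tmp_path / "t.nwk")])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "t.nwk").read_text().strip().endswith(";")
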