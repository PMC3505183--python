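"""Report surfaces and pipeline orchestration.

Renders the standard DGE report artifacts — per-library sequencing/mapping
statistics, tag-abundance distributions, stage-specificity tables, DE and
enrichment tables, trees — and runs the whole pipeline from a single
declarative YAML config. Every number in a rendered report is recomputable
from the machine-readable sheets written next to it, and a rerun with the
same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import io as dio
from ._util import round_half_up, spawn_seeds
from .clean import DEFAULT_BINS, abundance_distribution, extract_clean_tags
from .diffexpr import DEResult, call_de_genes
from .enrichment import enrich_terms
from .expression import detect_stage_specific, pearson_correlation, saturation_curve
from .mapping import MappingStats, build_tag_index, classify_library
from .phylogeny import bootstrap_support, neighbor_joining, p_distance_matrix
from .simulate import (
    generate_alignment,
    generate_annotation,
    generate_reference,
    lognormal_profile,
    simulate_library,
    spike_differential,
    uniform_profile,
)
from .types import ExpressionMatrix, TagLibrary

FAMILY_VOCABULARY = ("CCE", "P450", "GST")

#: Row labels of the library-statistics sheet, in print order.
STATS_ROWS = [
    "Total raw tag",
    "Total clean tag",
    "Distinct clean tag",
    "Distinct tag mapping to gene",
    "Distinct unambiguous tag mapping to gene",
    "Unambiguous tag-mapped genes",
    "Distinct tag mapping to genome",
    "Total unknown tag",
    "Distinct unknown tag",
]


def stats_cells(stats: MappingStats) -> dict[str, tuple[int, Optional[float]]]:
    """(count, percentage-or-None) per statistics row for one library."""
    return {
        "Total raw tag": (stats.total_raw, None),
        "Total clean tag": (stats.total_clean, None),
        "Distinct clean tag": (stats.distinct_clean, None),
        "Distinct tag mapping to gene": (stats.distinct_gene_mapped, stats.pct_gene_mapped),
        "Distinct unambiguous tag mapping to gene": (
            stats.distinct_unambiguous,
            stats.pct_unambiguous,
        ),
        "Unambiguous tag-mapped genes": (stats.genes_detected, stats.pct_genes_detected),
        "Distinct tag mapping to genome": (stats.distinct_genome_only, stats.pct_genome_only),
        "Total unknown tag": (stats.total_unknown, stats.pct_total_unknown),
        "Distinct unknown tag": (stats.distinct_unknown, stats.pct_distinct_unknown),
    }


def library_stats_frame(stats_list: list[MappingStats]) -> pd.DataFrame:
    """Statistics sheet: one row per label, N/% column pair per library."""
    data: dict[str, list] = {}
    for stats in stats_list:
        cells = stats_cells(stats)
        data[f"{stats.library_id}_N"] = [cells[r][0] for r in STATS_ROWS]
        data[f"{stats.library_id}_pct"] = [
            "" if cells[r][1] is None else f"{cells[r][1]:.1f}" for r in STATS_ROWS
        ]
    return pd.DataFrame(data, index=STATS_ROWS)


def render_library_stats(stats_list: list[MappingStats]) -> str:
    frame = library_stats_frame(stats_list)
    header = ["statistic"] + list(frame.columns)
    lines = ["\t".join(header)]
    for label in frame.index:
        lines.append("\t".join([label] + [str(v) for v in frame.loc[label]]))
    return "\n".join(lines) + "\n"


def percent_expansion(a: int, b: int) -> int:
    """Percent increase of a over b, rounded to the nearest integer."""
    if b <= 0:
        raise ValueError("comparison total must be positive")
    return int(round_half_up(100.0 * (a - b) / b, 0))


@dataclass
class FamilySummary:
    family_totals: dict[str, int]
    class_totals: dict[tuple[str, str], int]
    total: int
    detected: Optional[int] = None

    @property
    def pct_detected(self) -> Optional[int]:
        if self.detected is None:
            return None
        return int(round_half_up(100.0 * self.detected / self.total, 0))


def summarize_family_counts(
    gene_family_table: dict[str, tuple[str, str]],
    detected_genes: Optional[set[str]] = None,
    vocabulary: tuple[str, ...] = FAMILY_VOCABULARY,
) -> FamilySummary:
    """Per-family and per-class gene tallies from a gene -> (family, class) map.

    ``detected_genes``, when given, adds the detected-in-any-library count
    and its integer percentage. Unknown family labels are rejected.
    """
    family_totals: dict[str, int] = {f: 0 for f in vocabulary}
    class_totals: dict[tuple[str, str], int] = {}
    for gene, (family, cls) in gene_family_table.items():
        if family not in vocabulary:
            raise ValueError(f"unknown family label {family!r} for gene {gene}")
        family_totals[family] += 1
        class_totals[(family, cls)] = class_totals.get((family, cls), 0) + 1
    total = sum(family_totals.values())
    detected = (
        sum(1 for g in gene_family_table if g in detected_genes)
        if detected_genes is not None
        else None
    )
    return FamilySummary(family_totals, class_totals, total, detected)


def count_upregulated_by_family(
    de_results: list[DEResult],
    gene_family_table: dict[str, tuple[str, str]],
    vocabulary: tuple[str, ...] = FAMILY_VOCABULARY,
) -> dict[str, int]:
    """Significantly up-regulated genes per family; key 'total' sums them."""
    out = {f: 0 for f in vocabulary}
    for r in de_results:
        if r.significant and r.log2_ratio > 0 and r.gene_id in gene_family_table:
            family = gene_family_table[r.gene_id][0]
            if family not in vocabulary:
                raise ValueError(f"unknown family label {family!r}")
            out[family] += 1
    out["total"] = sum(out.values())
    return out


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "count_1": r.x,
                "count_2": r.y,
                "tpm_1": r.tpm1,
                "tpm_2": r.tpm2,
                "log2_ratio": r.log2_ratio,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    seed: int = 42
    outdir: str = "dge_out"
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    bootstrap_reps: int = 1000
    support_display_min: float = 70.0
    max_mismatch: int = 1
    plots: bool = False
    synthetic: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.min_abs_log2, self.bootstrap_reps, self.support_display_min) <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k not in ("outdir", "plots")}
        blob = yaml.safe_dump(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _synthetic_inputs(cfg: PipelineConfig):
    """Generate reference, raw libraries, annotation and alignment per config."""
    syn = cfg.synthetic
    seeds = spawn_seeds(cfg.seed, 4 + len(syn.get("libraries", [])))
    ref = generate_reference(
        n_genes=syn.get("n_genes", 300),
        length_range=tuple(syn.get("length_range", (200, 400))),
        spacer=syn.get("spacer", 100),
        seed=seeds[0],
    )
    if syn.get("profile", "lognormal") == "uniform":
        base = uniform_profile(ref)
    else:
        base = lognormal_profile(ref, sigma=syn.get("profile_sigma", 2.0), seed=seeds[0].spawn(1)[0])
    prof_a, prof_b = spike_differential(
        base,
        n_de=syn.get("n_spike", 20),
        fold_range=tuple(syn.get("fold_range", (8.0, 8.0))),
        seed=seeds[1],
    )
    noise = syn.get("noise", {})
    libraries: list[TagLibrary] = []
    for k, spec in enumerate(syn.get("libraries", [])):
        profile = prof_b if spec.get("condition", "A") == "B" else prof_a
        libraries.append(
            simulate_library(
                ref,
                profile,
                depth=spec.get("depth", 500_000),
                error_rate=noise.get("error_rate", 0.005),
                adaptor_rate=noise.get("adaptor_rate", 0.005),
                singleton_rate=noise.get("singleton_rate", 0.02),
                seed=seeds[4 + k],
                library_id=spec["id"],
                stage=spec.get("stage", "other"),
                strain=spec.get("strain", ""),
            )
        )
    annotation = generate_annotation(
        ref,
        n_terms=syn.get("n_terms", 20),
        term_size_range=tuple(syn.get("term_size_range", (5, 20))),
        seed=seeds[2],
    )
    alignment = (
        generate_alignment(
            n_taxa=syn.get("n_taxa", 8),
            length=syn.get("alignment_length", 200),
            mutation_rate=syn.get("mutation_rate", 0.3),
            seed=seeds[3],
        )
        if syn.get("alignment", True)
        else None
    )
    truth = prof_b.de_truth
    return ref, libraries, annotation, alignment, truth


def _file_inputs(cfg: PipelineConfig):
    paths = cfg.paths
    ref = dio.read_reference(paths["reference_dir"], paths.get("reference_prefix", "ref"))
    libraries = [
        dio.read_library(
            spec["path"],
            library_id=spec.get("id"),
            stage=spec.get("stage", "other"),
            strain=spec.get("strain", ""),
        )
        for spec in paths.get("libraries", [])
    ]
    annotation = dio.read_annotation(paths["annotation"]) if "annotation" in paths else None
    alignment = dio.read_alignment(paths["alignment"]) if "alignment" in paths else None
    return ref, libraries, annotation, alignment, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute clean -> map -> quantify -> DE -> enrichment (-> phylogeny).

    Writes TSV sheets, a text statistics report, and newick/PHYLIP files
    under ``cfg.outdir``; returns the in-memory results keyed by stage.
    Reruns with the same config are byte-identical.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic:
        ref, raw_libs, annotation, alignment, truth = _synthetic_inputs(cfg)
        dio.write_reference(ref, out / "inputs")
        for lib in raw_libs:
            dio.write_library(lib, out / "inputs" / f"{lib.library_id}_raw.tsv")
        if annotation is not None:
            dio.write_annotation(annotation, out / "inputs" / "annotation.tsv")
        if alignment is not None:
            dio.write_alignment(alignment, out / "inputs" / "alignment.fasta")
    else:
        ref, raw_libs, annotation, alignment, truth = _file_inputs(cfg)
    if not raw_libs:
        raise ValueError("no libraries configured")

    index = build_tag_index(ref)

    clean_libs = [extract_clean_tags(lib) for lib in raw_libs]
    stats_list: list[MappingStats] = []
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    abundance_rows = []
    for lib in clean_libs:
        stats, gene_counts = classify_library(lib, index, cfg.max_mismatch)
        stats_list.append(stats)
        counts[lib.library_id] = gene_counts
        totals[lib.library_id] = lib.total_clean
        dist = abundance_distribution(lib, DEFAULT_BINS)
        for (lo, hi), t, d in zip(dist.bins, dist.total_tags, dist.distinct_tags):
            label = f"[{lo},{hi}]" if hi is not None else f">{lo - 1}"
            abundance_rows.append((lib.library_id, label, t, d))

    frame = library_stats_frame(stats_list)
    frame.to_csv(out / "library_stats.tsv", sep="\t", index_label="statistic")
    (out / "library_stats.txt").write_text(render_library_stats(stats_list))
    pd.DataFrame(
        abundance_rows, columns=["library_id", "bin", "total_tags", "distinct_tags"]
    ).to_csv(out / "abundance_distribution.tsv", sep="\t", index=False)

    lib_ids = [lib.library_id for lib in clean_libs]
    genes = ref.gene_ids
    count_df = pd.DataFrame(
        {lid: [counts[lid].get(g, 0) for g in genes] for lid in lib_ids}, index=genes
    )
    matrix = ExpressionMatrix(counts=count_df, library_totals=totals)
    matrix.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
    matrix.tpm.to_csv(out / "tpm.tsv", sep="\t", index_label="gene_id", float_format="%.6g")

    results: dict = {"stats": stats_list, "matrix": matrix, "reference": ref}

    if len(lib_ids) >= 2:
        specific = detect_stage_specific(matrix, lib_ids)
        pd.DataFrame(
            sorted(specific.items()), columns=["gene_id", "library_id"]
        ).to_csv(out / "stage_specific.tsv", sep="\t", index=False)
        results["stage_specific"] = specific

        corr_rows = [
            (a, b, f"{pearson_correlation(matrix, a, b):.4f}")
            for i, a in enumerate(lib_ids)
            for b in lib_ids[i + 1 :]
        ]
        pd.DataFrame(corr_rows, columns=["library_1", "library_2", "pearson_r"]).to_csv(
            out / "correlation.tsv", sep="\t", index=False
        )
        results["correlations"] = corr_rows

    sat_seeds = spawn_seeds(cfg.seed + 1, len(clean_libs))
    sat_rows = []
    for lib, sseed in zip(clean_libs, sat_seeds):
        for size, n_genes in saturation_curve(lib, index, seed=sseed):
            sat_rows.append((lib.library_id, size, n_genes))
    pd.DataFrame(sat_rows, columns=["library_id", "subsample", "genes_detected"]).to_csv(
        out / "saturation.tsv", sep="\t", index=False
    )
    results["saturation"] = sat_rows

    de_pair = None
    if cfg.synthetic:
        b_libs = [s["id"] for s in cfg.synthetic.get("libraries", []) if s.get("condition") == "B"]
        a_libs = [s["id"] for s in cfg.synthetic.get("libraries", []) if s.get("condition", "A") == "A"]
        if a_libs and b_libs:
            de_pair = (a_libs[-1], b_libs[0])
    elif cfg.paths.get("de_pair"):
        de_pair = tuple(cfg.paths["de_pair"])

    if de_pair:
        de = call_de_genes(matrix, de_pair[0], de_pair[1], cfg.fdr_max, cfg.min_abs_log2)
        de_frame(de).to_csv(out / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
        results["de"] = de
        results["de_pair"] = de_pair

        if annotation is not None:
            detected = set(
                matrix.counts.index[
                    (matrix.counts[de_pair[0]] > 0) | (matrix.counts[de_pair[1]] > 0)
                ]
            )
            de_set = {r.gene_id for r in de if r.significant}
            if detected and de_set:
                enr = enrich_terms(de_set, detected, annotation)
                pd.DataFrame(
                    [
                        {
                            "term": r.term_id,
                            "a": r.a,
                            "b": r.b,
                            "c": r.c,
                            "d": r.d,
                            "method": r.method,
                            "p_value": r.p_value,
                            "benjamini_q": r.benjamini_q,
                        }
                        for r in enr
                    ]
                ).to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
                results["enrichment"] = enr

    if alignment is not None:
        dm = p_distance_matrix(alignment)
        dio.write_phylip_matrix(dm, out / "distances.phylip")
        tree = (
            bootstrap_support(alignment, cfg.bootstrap_reps, seed=cfg.seed + 2)
            if alignment.n_taxa >= 4
            else neighbor_joining(dm)
        )
        (out / "tree.nwk").write_text(tree.newick(support_min=cfg.support_display_min) + "\n")
        results["tree"] = tree

    if truth is not None:
        pd.DataFrame(
            sorted(truth.items()), columns=["gene_id", "true_fold_change"]
        ).to_csv(out / "inputs" / "de_truth.tsv", sep="\t", index=False, float_format="%.6g")

    log = [
        "dgekit run log",
        f"seed: {cfg.seed}",
        f"config_digest: {cfg.digest()}",
        f"fdr_max: {cfg.fdr_max}",
        f"min_abs_log2: {cfg.min_abs_log2}",
        f"max_mismatch: {cfg.max_mismatch}",
        f"bootstrap_reps: {cfg.bootstrap_reps}",
        f"libraries: {', '.join(lib_ids)}",
    ]
    (out / "run_log.txt").write_text("\n".join(log) + "\n")

    if cfg.plots:
        _write_plots(out, stats_list, abundance_rows, sat_rows, matrix, results.get("de_pair"))

    return results


def _write_plots(out, stats_list, abundance_rows, sat_rows, matrix, de_pair):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    df = pd.DataFrame(abundance_rows, columns=["library_id", "bin", "total", "distinct"])
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for lid, sub in df.groupby("library_id"):
        axes[0].plot(sub["bin"], sub["total"], marker="o", label=lid)
        axes[1].plot(sub["bin"], sub["distinct"], marker="o", label=lid)
    axes[0].set_title("Total clean tags per abundance bin")
    axes[1].set_title("Distinct clean tags per abundance bin")
    for ax in axes:
        ax.set_xlabel("copy-number bin")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "abundance_distribution.png", dpi=120)
    plt.close(fig)

    sat = pd.DataFrame(sat_rows, columns=["library_id", "size", "genes"])
    fig, ax = plt.subplots(figsize=(6, 4))
    for lid, sub in sat.groupby("library_id"):
        ax.plot(sub["size"], sub["genes"], marker=".", label=lid)
    ax.set_xlabel("clean tags sampled")
    ax.set_ylabel("genes detected")
    ax.set_title("Sequencing saturation")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "saturation.png", dpi=120)
    plt.close(fig)

    if de_pair:
        a, b = de_pair
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(np.log10(matrix.tpm[a]), np.log10(matrix.tpm[b]), s=4, alpha=0.5)
        ax.set_xlabel(f"log10 TPM {a}")
        ax.set_ylabel(f"log10 TPM {b}")
        ax.set_title("Library correlation")
        fig.tight_layout()
        fig.savefig(out / "correlation.png", dpi=120)
        plt.close(fig)
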