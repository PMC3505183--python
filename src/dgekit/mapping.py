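"""CATG-anchored tag index and <=1-mismatch tag classification.

Every CATG + 17-base window of every transcript (sense strand) and of the
genome (both strands) is hashed. A clean tag is looked up exactly first and,
failing that, through all single-position substitution variants. The
exact-hit tier always beats the 1-mismatch tier — a mismatch models a
sequencing error, it does not arbitrate between hits — and within a tier
gene hits beat genome-only hits. The resulting categories partition a
library's distinct clean tags:

  UNAMBIGUOUS_GENE  exactly one gene hit (the unit of gene-level counting)
  AMBIGUOUS_GENE    two or more gene hits
  GENOME_ONLY       no gene hit, but a genomic window matches
  UNKNOWN           no hit anywhere
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._util import ANCHOR, DNA, TAG_LEN, percent, revcomp
from .types import SyntheticReference, TagAnnotation, TagCategory, TagLibrary

_VALID = set(DNA)


def _windows(seq: str):
    """Yield (start, 21-mer) for every CATG with >= 17 bases after it."""
    pos = seq.find(ANCHOR)
    while pos != -1:
        if pos + TAG_LEN <= len(seq):
            yield pos, seq[pos : pos + TAG_LEN]
        pos = seq.find(ANCHOR, pos + 1)


@dataclass
class TagIndex:
    gene_windows: dict[str, frozenset[str]]
    genome_windows: dict[str, set[tuple[int, str]]]
    n_reference_genes: int


def build_tag_index(
    ref: SyntheticReference | dict[str, str],
    genome: str | None = None,
    n_reference_genes: int | None = None,
) -> TagIndex:
    """Index all tag windows of a reference.

    Accepts a :class:`SyntheticReference` or a plain ``gene_id -> transcript``
    mapping plus an optional genome string. Transcripts shorter than 21 bases
    cannot host a window and are skipped with a warning. Genome windows are
    taken from both strands; a minus-strand window is stored as its tag-space
    (reverse-complement) sequence with the plus-strand start coordinate.
    """
    if isinstance(ref, SyntheticReference):
        transcripts = ref.transcripts
        genome = ref.genome if genome is None else genome
    else:
        transcripts = dict(ref)
    if not transcripts:
        raise ValueError("no transcripts to index")
    n_ref = n_reference_genes if n_reference_genes is not None else len(transcripts)

    gene_windows: dict[str, set[str]] = {}
    for gid, seq in transcripts.items():
        if len(seq) < TAG_LEN:
            warnings.warn(f"transcript {gid!r} shorter than {TAG_LEN} nt; skipped", stacklevel=2)
            continue
        for _, w in _windows(seq):
            gene_windows.setdefault(w, set()).add(gid)

    genome_windows: dict[str, set[tuple[int, str]]] = {}
    if genome:
        for pos, w in _windows(genome):
            genome_windows.setdefault(w, set()).add((pos, "+"))
        rc = revcomp(genome)
        for pos, w in _windows(rc):
            plus_start = len(genome) - (pos + TAG_LEN)
            genome_windows.setdefault(w, set()).add((plus_start, "-"))

    return TagIndex(
        gene_windows={w: frozenset(g) for w, g in gene_windows.items()},
        genome_windows=genome_windows,
        n_reference_genes=n_ref,
    )


def _variants(tag: str):
    for i in range(TAG_LEN):
        orig = tag[i]
        for b in DNA:
            if b != orig:
                yield tag[:i] + b + tag[i + 1 :]


def map_tag(tag: str, index: TagIndex, max_mismatch: int = 1) -> TagAnnotation:
    """Classify one 21-mer against the index (see module docstring)."""
    if len(tag) != TAG_LEN or not set(tag) <= _VALID:
        raise ValueError(f"malformed tag {tag!r}: need a 21-mer over ACGT")
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")

    def annotate(genes: frozenset[str], genomic: bool, mm: int) -> TagAnnotation:
        if len(genes) == 1:
            cat = TagCategory.UNAMBIGUOUS_GENE
        elif len(genes) >= 2:
            cat = TagCategory.AMBIGUOUS_GENE
        elif genomic:
            cat = TagCategory.GENOME_ONLY
        else:
            cat = TagCategory.UNKNOWN
        return TagAnnotation(tag=tag, category=cat, gene_hits=genes, best_mismatch=mm)

    genes = index.gene_windows.get(tag, frozenset())
    genomic = tag in index.genome_windows
    if genes or genomic:
        return annotate(genes, genomic, 0)
    if max_mismatch == 1:
        hit_genes: set[str] = set()
        genomic = False
        for v in _variants(tag):
            g = index.gene_windows.get(v)
            if g:
                hit_genes |= g
            if v in index.genome_windows:
                genomic = True
        if hit_genes or genomic:
            return annotate(frozenset(hit_genes), genomic, 1)
    return TagAnnotation(tag=tag, category=TagCategory.UNKNOWN, gene_hits=frozenset(), best_mismatch=max_mismatch)


@dataclass
class MappingStats:
    """Distinct- and total-tag mapping statistics for one library.

    Percentage denominators follow the reporting convention: distinct-tag
    rows use distinct clean tags, the total-unknown row uses total clean
    tags, and the tag-mapped-genes row uses the reference gene count.
    """

    library_id: str
    total_raw: int
    total_clean: int
    distinct_clean: int
    distinct_gene_mapped: int
    distinct_unambiguous: int
    genes_detected: int
    distinct_genome_only: int
    total_unknown: int
    distinct_unknown: int
    n_reference_genes: int

    @property
    def pct_gene_mapped(self) -> float:
        return percent(self.distinct_gene_mapped, self.distinct_clean)

    @property
    def pct_unambiguous(self) -> float:
        return percent(self.distinct_unambiguous, self.distinct_clean)

    @property
    def pct_genes_detected(self) -> float:
        return percent(self.genes_detected, self.n_reference_genes)

    @property
    def pct_genome_only(self) -> float:
        return percent(self.distinct_genome_only, self.distinct_clean)

    @property
    def pct_total_unknown(self) -> float:
        return percent(self.total_unknown, self.total_clean)

    @property
    def pct_distinct_unknown(self) -> float:
        return percent(self.distinct_unknown, self.distinct_clean)


def classify_library(
    clean_library: TagLibrary, index: TagIndex, max_mismatch: int = 1
) -> tuple[MappingStats, dict[str, int]]:
    """Classify every distinct clean tag and accumulate per-gene counts.

    Gene-level counts sum the copies of UNAMBIGUOUS_GENE tags only; ambiguous
    tags are tallied in the statistics but never attributed to a gene.
    """
    gene_counts: dict[str, int] = {}
    n_gene = n_unamb = n_genome = n_unknown = 0
    total_unknown = 0
    for tag, count in clean_library.clean.items():
        ann = map_tag(tag, index, max_mismatch)
        if ann.category is TagCategory.UNAMBIGUOUS_GENE:
            n_gene += 1
            n_unamb += 1
            (gid,) = ann.gene_hits
            gene_counts[gid] = gene_counts.get(gid, 0) + count
        elif ann.category is TagCategory.AMBIGUOUS_GENE:
            n_gene += 1
        elif ann.category is TagCategory.GENOME_ONLY:
            n_genome += 1
        else:
            n_unknown += 1
            total_unknown += count
    stats = MappingStats(
        library_id=clean_library.library_id,
        total_raw=clean_library.total_raw,
        total_clean=clean_library.total_clean,
        distinct_clean=clean_library.distinct_clean,
        distinct_gene_mapped=n_gene,
        distinct_unambiguous=n_unamb,
        genes_detected=len(gene_counts),
        distinct_genome_only=n_genome,
        total_unknown=total_unknown,
        distinct_unknown=n_unknown,
        n_reference_genes=index.n_reference_genes,
    )
    return stats, gene_counts
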