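"""Core containers shared across the pipeline.

The pipeline's unit of data is the *tag*: a 21-mer consisting of the NlaIII
anchor ``CATG`` plus the 17 downstream bases, cut from the 3'-most anchor
site of a transcript. Libraries are multisets of tags (sequence -> count);
expression is quantified per gene from tags that map unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class TagLibrary:
    """One sequencing library: raw and clean tag->count maps plus metadata.

    ``raw`` holds everything delivered by the sequencer (adaptor reads,
    singletons, malformed tags included); ``clean`` only tags surviving the
    filters: length 21, CATG prefix, ACGT alphabet, copy number >= 2.
    """

    library_id: str
    stage: str = "other"
    strain: str = ""
    raw: dict[str, int] = field(default_factory=dict)
    clean: dict[str, int] = field(default_factory=dict)
    low_quality: set[str] = field(default_factory=set)

    @property
    def total_raw(self) -> int:
        return sum(self.raw.values())

    @property
    def total_clean(self) -> int:
        return sum(self.clean.values())

    @property
    def distinct_clean(self) -> int:
        return len(self.clean)


@dataclass
class SyntheticReference:
    """Toy gene set: transcripts, a genome with spacers, and coordinates."""

    genes: list[tuple[str, str]]
    genome: str
    coordinates: dict[str, tuple[int, int]]
    canonical_tags: dict[str, Optional[str]] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    @property
    def transcripts(self) -> dict[str, str]:
        return dict(self.genes)


@dataclass
class ExpressionProfile:
    """Ground-truth relative abundances plus per-gene true fold changes."""

    abundance: dict[str, float]
    de_truth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.abundance.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"abundances must sum to 1 (got {total!r})")
        if any(a < 0 for a in self.abundance.values()):
            raise ValueError("abundances must be non-negative")
        if not self.de_truth:
            self.de_truth = {g: 1.0 for g in self.abundance}
        if any(f <= 0 for f in self.de_truth.values()):
            raise ValueError("fold changes must be > 0")


class TagCategory(str, Enum):
    UNAMBIGUOUS_GENE = "UNAMBIGUOUS_GENE"
    AMBIGUOUS_GENE = "AMBIGUOUS_GENE"
    GENOME_ONLY = "GENOME_ONLY"
    UNKNOWN = "UNKNOWN"


@dataclass
class TagAnnotation:
    tag: str
    category: TagCategory
    gene_hits: frozenset[str]
    best_mismatch: int


@dataclass
class ExpressionMatrix:
    """Gene x library unambiguous counts and TPM values.

    TPM = count * 1e6 / library total clean tags; genes with zero count are
    floored at TPM 0.01 (the conventional pseudo-level for "not detected").
    """

    counts: pd.DataFrame  # genes x libraries, int
    library_totals: dict[str, int]
    tpm: pd.DataFrame = field(init=False)

    TPM_FLOOR = 0.01

    def __post_init__(self) -> None:
        from .expression import tpm_normalize

        cols = {}
        for lib in self.counts.columns:
            cols[lib] = tpm_normalize(self.counts[lib].to_dict(), self.library_totals[lib])
        self.tpm = pd.DataFrame(cols, index=self.counts.index)[self.counts.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class AnnotationMap:
    """Flat gene -> set-of-terms table (GO/KEGG style labels, no DAG)."""

    gene_terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out

    def genes_for(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}
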