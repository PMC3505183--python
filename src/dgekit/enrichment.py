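"""Term enrichment of a DE gene set against an expressed-gene background.

Each term gets a 2x2 table — (DE, non-DE) x (in term, not in term) over the
background — tested by a 1-df chi-square without continuity correction, or
by the two-sided Fisher exact test (point-probability method) whenever any
expected cell count falls below 5, where the chi-square approximation is
unreliable. P-values are Benjamini step-up corrected across all tested
terms. Terms are flat labels: no ontology graph propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .diffexpr import benjamini_hochberg
from .types import AnnotationMap


def expected_counts(table: np.ndarray) -> np.ndarray:
    """E_ij = row_i * col_j / total for a 2x2 table of non-negative ints."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative counts")
    total = t.sum()
    if total == 0:
        raise ValueError("table total must be positive")
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / total


@dataclass
class EnrichmentResult:
    term_id: str
    a: int  # DE genes with the term
    b: int  # DE genes without the term
    c: int  # non-DE background genes with the term
    d: int  # non-DE background genes without the term
    method: str  # "chi_square" | "fisher_exact"
    p_value: float
    benjamini_q: float = float("nan")

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _test_table(table: np.ndarray) -> tuple[str, float]:
    if expected_counts(table).min() < 5:
        return "fisher_exact", float(sps.fisher_exact(table, alternative="two-sided")[1])
    if table[0].sum() == 0 or table[1].sum() == 0 or table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return "chi_square", 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return "chi_square", float(p)


def enrich_terms(
    de_genes: set[str],
    background: set[str],
    annotation: AnnotationMap,
) -> list[EnrichmentResult]:
    """Enrichment of every term with at least one background gene.

    ``de_genes`` must be a subset of ``background``; annotations outside the
    background are ignored. Results are sorted by q, then p, then term id.
    """
    if not de_genes <= background:
        raise ValueError("de_genes must be a subset of background")
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    n_de = len(de_genes)
    n_bg = len(background)
    results: list[EnrichmentResult] = []
    for term in sorted(annotation.terms()):
        members = annotation.genes_for(term) & background
        if not members:
            continue
        a = len(members & de_genes)
        b = n_de - a
        c = len(members) - a
        d = (n_bg - n_de) - c
        table = np.array([[a, b], [c, d]])
        method, p = _test_table(table)
        results.append(EnrichmentResult(term, a, b, c, d, method, p))
    if results:
        q = benjamini_hochberg([r.p_value for r in results])
        for r, qi in zip(results, q):
            r.benjamini_q = float(qi)
    results.sort(key=lambda r: (r.benjamini_q, r.p_value, r.term_id))
    return results
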