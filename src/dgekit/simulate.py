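"""Synthetic references, tag libraries, annotations, and alignments.

This module generates toy data with the statistical structure the rest of
the pipeline assumes, so every downstream stage is testable without any
external download. The emulation is counts-level: a library is a multiset of
21-mer tags (CATG anchor + 17 bases), not reads with quality strings.

A simulated raw library is a multinomial draw over the canonical tags of a
reference, weighted by an expression profile, with three noise channels
layered on top: per-base sequencing errors, a fixed adaptor sequence, and
random unique 21-mers that appear once each (singleton noise). The total
raw tag count always equals the requested depth exactly.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Optional

import numpy as np

from ._util import ANCHOR, DNA, TAG_LEN, rng_from
from .phylogeny import PhyloTree, ProteinAlignment, TreeNode
from .types import AnnotationMap, ExpressionProfile, SyntheticReference, TagLibrary

# Adaptor baked into the generator and shared with the cleaning filter.
ADAPTOR = "TCGTATGCCGTCTTCTGCTTG"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BASE_IDX = {b: i for i, b in enumerate(DNA)}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=length)])


def canonical_tag(transcript: str) -> Optional[str]:
    """21-mer at the 3'-most CATG that leaves >= 17 downstream bases."""
    pos = transcript.rfind(ANCHOR)
    while pos != -1 and pos + TAG_LEN > len(transcript):
        pos = transcript.rfind(ANCHOR, 0, pos)
    if pos == -1:
        return None
    return transcript[pos : pos + TAG_LEN]


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (200, 400),
    spacer: int = 100,
    seed: int = 0,
) -> SyntheticReference:
    """Toy gene set plus a genome built by joining transcripts with random
    spacers (one spacer before each gene and one trailing).

    Every transcript is guaranteed a CATG anchor with >= 17 downstream bases
    (one is written in if the random draw lacks it), so every gene has a
    canonical tag. Spacers are unconstrained random sequence and may contain
    their own CATG windows, which exercises genome-only tag classification.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 25:
        raise ValueError("minimum transcript length must be >= 25 to host CATG + 17 bases")
    if hi < lo:
        raise ValueError("length_range must satisfy min <= max")
    rng = rng_from(seed)
    width = max(1, len(str(n_genes - 1)))
    genes: list[tuple[str, str]] = []
    for k in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        t = _random_dna(rng, length)
        if canonical_tag(t) is None:
            p = int(rng.integers(0, length - TAG_LEN + 1))
            t = t[:p] + ANCHOR + t[p + len(ANCHOR) :]
        genes.append((f"G{str(k).zfill(width)}", t))

    parts = []
    coords: dict[str, tuple[int, int]] = {}
    offset = 0
    for gid, t in genes:
        sp = _random_dna(rng, spacer)
        parts.append(sp)
        offset += spacer
        parts.append(t)
        coords[gid] = (offset, offset + len(t))
        offset += len(t)
    parts.append(_random_dna(rng, spacer))
    genome = "".join(parts)

    tags = {gid: canonical_tag(t) for gid, t in genes}
    return SyntheticReference(genes=genes, genome=genome, coordinates=coords, canonical_tags=tags)


def uniform_profile(ref: SyntheticReference) -> ExpressionProfile:
    n = len(ref.genes)
    return ExpressionProfile({g: 1.0 / n for g in ref.gene_ids})


def lognormal_profile(
    ref: SyntheticReference, sigma: float = 2.0, seed: int = 0
) -> ExpressionProfile:
    """Skewed abundances (relative abundance proportional to exp(N(0, sigma^2))).

    Real tag libraries are dominated by a few very abundant transcripts while
    most genes sit near the detection floor; sigma around 2 reproduces that
    spread (several orders of magnitude between the quartiles).
    """
    rng = rng_from(seed)
    w = np.exp(rng.normal(0.0, sigma, size=len(ref.genes)))
    w /= w.sum()
    return ExpressionProfile({g: float(x) for g, x in zip(ref.gene_ids, w)})


def _truncated_error_counts(rng: np.random.Generator, n: int, error_rate: float) -> np.ndarray:
    """Numbers of flipped bases for n erroneous tags: Binomial(21, e) given >= 1."""
    pmf = np.array(
        [
            math.comb(TAG_LEN, k) * error_rate**k * (1 - error_rate) ** (TAG_LEN - k)
            for k in range(1, TAG_LEN + 1)
        ]
    )
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, TAG_LEN + 1), size=n, p=pmf)


def _mutate_tag(rng: np.random.Generator, tag: str, k: int) -> str:
    positions = rng.choice(TAG_LEN, size=k, replace=False)
    out = list(tag)
    for p in positions:
        out[p] = DNA[(_BASE_IDX[out[p]] + 1 + int(rng.integers(0, 3))) % 4]
    return "".join(out)


def simulate_library(
    ref: SyntheticReference,
    profile: ExpressionProfile,
    depth: int = 3_500_000,
    error_rate: float = 0.005,
    adaptor_rate: float = 0.005,
    singleton_rate: float = 0.02,
    seed: int = 0,
    library_id: str = "lib",
    stage: str = "other",
    strain: str = "",
) -> TagLibrary:
    """Draw a raw tag library of exactly ``depth`` tags.

    Composition: a (depth)-sized multinomial over (adaptor, singleton, gene)
    channels; gene tags are a multinomial over canonical tags weighted by the
    profile, each base then flipped with ``error_rate``; singleton tags are
    random unique 21-mers occurring once each.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    for r, name in ((error_rate, "error_rate"), (adaptor_rate, "adaptor_rate"), (singleton_rate, "singleton_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if adaptor_rate + singleton_rate > 1.0:
        raise ValueError("adaptor_rate + singleton_rate must not exceed 1")
    unknown = set(profile.abundance) - set(ref.gene_ids)
    if unknown:
        raise ValueError(f"profile references unknown gene_ids: {sorted(unknown)[:5]}")

    rng = rng_from(seed)
    expressed = [g for g, a in profile.abundance.items() if a > 0]
    for g in expressed:
        if ref.canonical_tags.get(g) is None:
            raise ValueError(f"gene {g} is tagless and cannot emit tags")
    probs = np.array([profile.abundance[g] for g in expressed])
    probs = probs / probs.sum()

    n_adapt, n_single, n_gene = rng.multinomial(
        depth, [adaptor_rate, singleton_rate, 1.0 - adaptor_rate - singleton_rate]
    )
    raw: Counter[str] = Counter()
    if n_adapt:
        raw[ADAPTOR] += int(n_adapt)

    gene_counts = rng.multinomial(n_gene, probs) if n_gene else np.zeros(len(probs), int)
    p_any_err = 1.0 - (1.0 - error_rate) ** TAG_LEN
    for g, c in zip(expressed, gene_counts):
        c = int(c)
        if c == 0:
            continue
        tag = ref.canonical_tags[g]
        n_err = int(rng.binomial(c, p_any_err)) if error_rate > 0 else 0
        if c - n_err:
            raw[tag] += c - n_err
        if n_err:
            for k in _truncated_error_counts(rng, n_err, error_rate):
                raw[_mutate_tag(rng, tag, int(k))] += 1

    made = 0
    while made < n_single:
        t = _random_dna(rng, TAG_LEN)
        if t not in raw:
            raw[t] += 1
            made += 1

    lib = TagLibrary(library_id=library_id, stage=stage, strain=strain, raw=dict(raw))
    assert lib.total_raw == depth
    return lib


def spike_differential(
    profile: ExpressionProfile,
    n_de: int,
    fold_range: tuple[float, float] = (4.0, 16.0),
    seed: int = 0,
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Condition-A and condition-B profiles with ``n_de`` genes truly changed.

    Fold magnitudes are drawn uniformly in ``fold_range`` with randomized
    direction; ``de_truth`` stores the B/A abundance ratio (1.0 for nulls).
    Both outputs are renormalized to sum to one.
    """
    genes = list(profile.abundance)
    if n_de > len(genes):
        raise ValueError("n_de exceeds the number of genes")
    lo, hi = fold_range
    if lo <= 1.0:
        raise ValueError("fold_range lower bound must exceed 1")
    if hi < lo:
        raise ValueError("fold_range must satisfy lo <= hi")
    rng = rng_from(seed)
    chosen = list(rng.choice(genes, size=n_de, replace=False)) if n_de else []
    truth = {g: 1.0 for g in genes}
    b = dict(profile.abundance)
    for g in chosen:
        f = float(rng.uniform(lo, hi))
        if rng.random() < 0.5:
            f = 1.0 / f
        truth[g] = f
        b[g] = profile.abundance[g] * f
    za = sum(profile.abundance.values())
    zb = sum(b.values())
    prof_a = ExpressionProfile({g: a / za for g, a in profile.abundance.items()}, dict(truth))
    prof_b = ExpressionProfile({g: a / zb for g, a in b.items()}, dict(truth))
    return prof_a, prof_b


def generate_annotation(
    ref: SyntheticReference,
    n_terms: int,
    term_size_range: tuple[int, int] = (5, 20),
    enriched_term: Optional[tuple[str, list[str]]] = None,
    seed: int = 0,
) -> AnnotationMap:
    """Random flat gene->term table; ``enriched_term`` pins one term to an
    exact gene subset (ground truth for enrichment recovery tests)."""
    lo, hi = term_size_range
    n_genes = len(ref.genes)
    if hi > n_genes:
        raise ValueError("term sizes cannot exceed the number of genes")
    rng = rng_from(seed)
    gene_terms: dict[str, set[str]] = {}
    width = max(1, len(str(max(n_terms - 1, 0))))
    for k in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(ref.gene_ids, size=size, replace=False)
        term = f"T{str(k).zfill(width)}"
        for g in members:
            gene_terms.setdefault(g, set()).add(term)
    if enriched_term is not None:
        term, members = enriched_term
        unknown = set(members) - set(ref.gene_ids)
        if unknown:
            raise ValueError(f"enriched_term lists unknown genes: {sorted(unknown)[:5]}")
        for g in list(gene_terms):
            gene_terms[g].discard(term)
        for g in members:
            gene_terms.setdefault(g, set()).add(term)
        gene_terms = {g: ts for g, ts in gene_terms.items() if ts}
    return AnnotationMap(gene_terms)


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, len(AMINO_ACIDS), size=length)


def _evolve(rng: np.random.Generator, seq: np.ndarray, p_sub: float) -> np.ndarray:
    out = seq.copy()
    hits = rng.random(len(seq)) < p_sub
    n = int(hits.sum())
    if n:
        # substitute to a uniformly chosen *different* residue
        shift = rng.integers(1, len(AMINO_ACIDS), size=n)
        out[hits] = (out[hits] + shift) % len(AMINO_ACIDS)
    return out


def generate_alignment(
    n_taxa: int,
    length: int = 200,
    mutation_rate: float = 0.05,
    gap_rate: float = 0.0,
    guide_tree: Optional[PhyloTree] = None,
    seed: int = 0,
) -> ProteinAlignment:
    """Aligned protein rows evolved from one ancestral sequence.

    Without a guide tree each taxon mutates independently from the ancestor
    (star phylogeny), each site substituting with probability
    ``mutation_rate``. With a guide tree, sequences evolve along its
    branches with per-site substitution probability 1 - exp(-rate * length),
    so longer branches accumulate proportionally more change. Gaps are
    sprinkled independently per cell at ``gap_rate``.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = rng_from(seed)
    aa = np.array(list(AMINO_ACIDS))
    root_seq = _random_protein(rng, length)
    seqs: dict[str, np.ndarray] = {}
    if guide_tree is None:
        taxa = [f"tx{k}" for k in range(n_taxa)]
        for t in taxa:
            seqs[t] = _evolve(rng, root_seq, mutation_rate)
    else:
        if len(guide_tree.taxa) != n_taxa:
            raise ValueError("guide tree leaf count does not match n_taxa")

        def down(node: TreeNode, seq: np.ndarray) -> None:
            for child in node.children:
                p_sub = 1.0 - np.exp(-mutation_rate * max(child.length, 0.0))
                cseq = _evolve(rng, seq, p_sub)
                if child.is_leaf():
                    seqs[child.name] = cseq
                else:
                    down(child, cseq)

        down(guide_tree.root, root_seq)
        taxa = sorted(seqs)

    rows = []
    for t in taxa:
        chars = aa[seqs[t]]
        if gap_rate > 0:
            gaps = rng.random(length) < gap_rate
            chars = np.where(gaps, "-", chars)
        rows.append("".join(chars))
    return ProteinAlignment(list(taxa), rows)
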