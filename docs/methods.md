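# Methods

`dgekit` implements counts-level analysis of digital gene expression (DGE)
tag libraries of the NlaIII kind: each transcript contributes a *tag*, the
21-mer starting at the 3'-most `CATG` site (the 4-base anchor plus 17
downstream bases), and a library is simply a multiset of such tags. The
package covers the full analysis chain — cleaning, mapping, quantification,
differential expression, enrichment — plus the distance phylogenetics used
to classify gene families, and a synthetic-data generator that makes every
stage testable without external downloads.

## Tag model and cleaning

A *clean tag* is a well-formed 21-mer (CATG anchor, ACGT alphabet) that is
not adaptor-derived, not flagged low-quality, and observed at least twice in
its library. Filters run in a fixed order — adaptor, empty/whitespace,
low-quality flag, malformed (length ≠ 21, missing anchor, non-ACGT), then
copy-number 1 — so a removed tag is attributed to the most specific rule.
The singleton filter is applied per library, last, which means an adaptor
read seen once counts as adaptor-removed, not singleton-removed. "Low
quality" is an input flag per tag: the package works at counts level and
deliberately does not model per-base quality strings, so callers carrying
FASTQ-derived data decide the flagging themselves (default: no flags).

Cleaning is idempotent and order-independent; both are property-tested.

Abundance distributions bin distinct tags by copy number. Default bins are
[2,5], [6,10], [11,20], [21,50], [51,100], >100: the ends are the
informative ones (low-copy tags dominate distinct-tag counts, >100-copy
tags dominate the total-tag mass in deep libraries) and the middle bins
simply interpolate on a roughly logarithmic scale.

## Mapping

All CATG-anchored windows of every transcript (sense strand only — DGE
chemistry reads the sense tag) and of the genome (both strands; minus-strand
windows stored as their tag-space reverse complement) are hashed exactly.
A tag is looked up exactly first; failing that, through all 3×21
single-substitution variants, i.e. at most one mismatch. Two precedence
rules resolve multiple hits:

1. **Tier before identity.** An exact hit always beats a 1-mismatch hit,
   even when the exact hit is ambiguous and a mismatch hit would be unique.
   The mismatch allowance models a sequencing error; it is not an
   arbitrator between genes.
2. **Gene before genome.** Within a tier, a tag hitting both a transcript
   window and a bare genomic window is gene-mapped.

Categories partition a library's distinct clean tags: unambiguous-gene
(exactly one gene), ambiguous-gene (≥ 2), genome-only, unknown. Gene-level
expression counts sum unambiguous tags only; ambiguous tags appear in the
statistics but are never attributed. The genome-only category is exclusive
of gene-mapped tags (the published per-library percentages — gene-mapped in
the mid-30s and genome-mapped around 31% of distinct tags simultaneously —
are only consistent with exclusive counting).

Reported percentages use three denominators: distinct-tag rows divide by
distinct clean tags, the total-unknown row by total clean tags, and the
tag-mapped-genes row by the reference gene count. Display rounding is one
decimal, half away from zero; underlying sheets keep full precision.

## Quantification

TPM = count × 10⁶ / total clean tags of the library. The denominator is
*total* clean tags, not mapped tags: with the published egg-library total of
3,759,150 clean tags a single-copy gene gives 10⁶/3,759,150 = 0.266, which
prints as 0.27 and reproduces the published per-stage minimum TPMs exactly
(0.27/0.26/0.28/0.27 for egg/larva/pupa/adult totals); a mapped-tag
denominator does not. Undetected genes (zero unambiguous tags) are floored
at TPM 0.01 so ratios remain finite; detection means count > 0.

Library reliability is summarized by Pearson r of log₁₀(TPM) over genes
detected in at least one of the pair, the undetected partner contributing
its floor. The log scale is a declared convention (published replicate
scatter plots are on log axes); r on raw TPM would be dominated by the few
most abundant genes.

Saturation curves subsample the clean tag pool without replacement at a
grid of sizes (default ten equal steps), *nested* — one shuffle, prefixes —
so the detected-gene count is non-decreasing by construction rather than by
averaging.

## Differential expression

For a gene with x tags among N1 and y among N2 clean tags, the null
probability of y given x is

    p(y | x) = (N2/N1)^y · (x+y)! / ( x!·y!·(1 + N2/N1)^(x+y+1) )

— a negative-binomial mass in y that sums exactly to 1. The exponent
x+y+1 matters: a variant circulating in some reprints omits the +1 and does
not normalize. Evaluation is in log-space via log-gamma throughout; naive
factorials overflow far below realistic counts.

The two-sided p-value is min(1, 2·min(P(Y ≥ y | x), P(X ≥ x | y))): the
upper tail and the same tail with the libraries' roles exchanged, both
including the observed count. These two quantities are exactly the lower
and upper tails of Binomial(x+y, N2/(N1+N2)) at y, so the p-value is
exactly invariant under exchanging (x, N1) with (y, N2) — the property a
symmetric two-library comparison must have. (Conditioning both tails on
the same observed x instead would break exchange symmetry by one point
mass at small counts; the binomial-tail identity is also how the tails are
computed, via the regularized incomplete beta function, which is stable at
any N2/N1 ratio.) Under the null the test is slightly conservative at
small counts, which the suite checks by calibration simulation.

Multiple testing uses the Benjamini–Hochberg step-up adjustment (the
standard choice where a concrete FDR procedure is not dictated), preserving
input order and cross-checked against statsmodels. A gene is called DE at
FDR ≤ 0.001 and |log₂ ratio| ≥ 1, the ratio taken on floored TPMs and
oriented second library over first (treated/resistant over reference).
Genes undetected in both libraries are not tested: their floored ratio is 0
and their p is 1 by construction.

## Enrichment

Each term yields a 2×2 table over the background — (DE, non-DE) × (in
term, not in term) — where the background is the set of genes *detected* in
the relevant libraries, not the whole reference: undetectable genes carry
no information about the DE set. The test is a 1-df chi-square without
continuity correction, falling back to the two-sided Fisher exact test
(point-probability method: sum of all tables with probability ≤ the
observed, the convention of R and scipy) whenever any expected cell count
is below 5. P-values are Benjamini step-up corrected across tested terms.
Terms are flat labels; no ontology-graph propagation is attempted.

A note on the chi-square/Fisher relationship: the two agree asymptotically
at a fixed standardized deviation as the table grows, and the suite tests
exactly that (the relative gap shrinks monotonically with scale and is
below 2% once expected counts reach the thousands). The agreement is *not*
uniform: at any table size there are tables, increasingly far in the tail,
where the relative gap between the exact and asymptotic p exceeds 10%. The
fallback rule is therefore a guard against small-count breakdown, not a
statement that the two tests coincide elsewhere.

## Phylogenetics

Protein alignments are consumed, not built (alignment construction is a
solved problem and out of scope). Distances are p-distances with pairwise
deletion: mismatches divided by the sites where *neither* sequence of the
pair has a gap. A pair with zero comparable sites is an error naming the
pair. Ambiguity codes (B, Z, X) mismatch everything but an identical code —
a declared convention, since the classic distance-tool behavior here is
undocumented.

Trees are built by classic neighbor-joining (Q-criterion, standard branch
lengths), with ties in Q broken by the lowest (row, column) index pair so
results are reproducible; additive matrices are recovered exactly, branch
lengths included (property-tested against a path-length oracle on random
trees, and against scikit-bio's NJ on non-additive input). Negative branch
lengths are kept internally and clamped to zero only at newick
serialization.

Bootstrap support resamples alignment columns with replacement, rebuilds a
p-distance NJ tree per replicate, and scores each internal edge of the
full-data tree by the percentage of replicate trees containing the same
bipartition (bipartition identity, not node identity, so the score is
invariant to rerooting). Replicates producing an incomparable pair are
dropped; ≥ 10% drops aborts. The display convention mirrors the field's
figures: supports below 70% can be suppressed at serialization.

Query sequences are assigned to the clade of their nearest labeled
reference leaf by patristic distance; exact ties between clades leave the
query unassigned.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- **Reference**: random transcripts (default 200–400 nt) each guaranteed a
  canonical tag (a CATG window is written in if the draw lacks one),
  concatenated into a genome with random spacers (default 100 nt) that may
  contain their own CATG windows — deliberately, so genome-only
  classifications are exercised.
- **Libraries**: exactly `depth` tags, multinomial over canonical tags
  weighted by an expression profile, with three noise channels: per-base
  errors (each base flips with probability `error_rate`), a fixed adaptor
  sequence shared with the cleaning filter, and singleton noise (random
  unique 21-mers occurring once). Defaults — error 0.5%, adaptor 0.5%,
  singleton 2% — are plausible magnitudes for this chemistry chosen once as
  generator conventions; published library statistics do not report their
  underlying rates. Default depth 3.5 × 10⁶ matches real library scale;
  tests and the demo run at 10⁵–10⁶ so the suite completes in minutes, with
  the deep-library properties (abundance-distribution shape, saturation
  plateau, replicate correlation) exercised at 3–3.5 × 10⁶ where they are
  claims about depth.
- **Profiles**: uniform, or log-normal (σ = 2 by default) reproducing the
  skew of real libraries — a few dominant transcripts, most genes near the
  detection floor. Differential truth is spiked by multiplying chosen
  genes' abundances by a fold drawn in a given range with random direction,
  then renormalizing; `de_truth` records the nominal B/A ratio.
- **Annotations**: random flat gene→term tables, optionally with one term
  pinned to an exact gene set as enrichment ground truth.
- **Alignments**: rows evolved from one ancestral sequence, either a star
  phylogeny or along a guide tree with per-site substitution probability
  1 − exp(−rate · branch length); gaps sprinkled independently per cell.

All generators are bit-reproducible for a fixed seed. What the generator
does **not** emulate: read-level quality strings, restriction-digest
partiality, PCR duplication bias, antisense transcription, splice variants
sharing windows beyond what random sequence produces, and biological
between-replicate overdispersion (libraries are exact multinomial draws).
Passing tests therefore demonstrate the pipeline's correctness under its
own stated model, not robustness to those real-data artifacts; in
particular, real replicate correlations and DE false-positive rates will be
less favorable than the multinomial ideal.

## Numerical and design choices

- Display rounding is half-away-from-zero everywhere (one decimal for
  percentages, two for TPM, integers for expansion percentages); sheets
  keep full precision.
- The count test is exact, not asymptotic; no dispersion-modelling DE
  framework is layered on top, since the method under study is the
  Poisson-derived exact statistic itself.
- Percent expansion of family counts is 100·(a−b)/b rounded to the nearest
  integer.
- The pipeline writes no timestamps; a rerun with the same config and seed
  is byte-identical, and the run log records the seed and a config digest
  (output location excluded) instead.
- Problem sizes in the demo config (5 libraries × 5 × 10⁵ tags, 300 genes,
  200 bootstrap replicates) are chosen so a full end-to-end run takes
  seconds on one core while still exercising every stage; they are
  conventions of the demo, and every size is a config knob.

## Known limitations

- The 1-mismatch search is a hash of exact windows probed with substitution
  variants: transparent and fast at tag scale, but not a general aligner
  (no indels, no splice awareness).
- Enrichment treats terms as independent flat labels; correlated terms
  (ontology ancestors/descendants) will co-enrich.
- NJ returns one tree; near-ties in Q on non-additive data are resolved
  deterministically but arbitrarily, as in any NJ implementation.
- The AC test assumes fixed library totals; it does not model biological
  replication (no overdispersion parameter).
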