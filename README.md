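# dgekit

Digital gene expression (DGE) tag profiling and distance phylogenetics,
as used to profile transcriptomes and classify detoxification gene
families (cytochrome P450s, glutathione S-transferases,
carboxyl/cholinesterases) in mosquitoes.

DGE libraries count short restriction-anchored cDNA tags — here the 21-mer
`CATG` + 17 bases cut at the 3'-most NlaIII site of each transcript — as a
measure of absolute transcript abundance. `dgekit` implements the complete
analysis chain for such libraries, plus the tree-building used to place
gene-family members into functional clades:

- **Cleaning** — adaptor/empty/low-quality/malformed/singleton filters
  turning raw tag counts into clean tags (21-mer, CATG anchor, copy ≥ 2).
- **Mapping** — a CATG-anchored hash index over transcripts and genome
  (both strands), classifying each distinct tag as unambiguous-gene,
  ambiguous-gene, genome-only, or unknown with at most one mismatch.
- **Quantification** — TPM (transcripts per million clean tags):
  `count × 10⁶ / total clean tags`, floored at 0.01 for undetected genes;
  stage-specific detection calls, library Pearson correlation on log₁₀ TPM,
  and nested-subsampling saturation curves.
- **Differential expression** — the Audic–Claverie exact test for counts in
  two libraries,

      p(y|x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) ),

  evaluated in log-space, with an exactly exchange-symmetric two-sided
  p-value, Benjamini–Hochberg FDR, and calls at FDR ≤ 0.001 and
  |log₂Ratio| ≥ 1.
- **Enrichment** — 2×2 chi-square term enrichment against the
  detected-gene background, with a two-sided Fisher exact fallback
  whenever any expected count is below 5, Benjamini-corrected.
- **Phylogenetics** — p-distance with pairwise deletion, neighbor-joining,
  column-bootstrap supports keyed by bipartition, and nearest-reference
  clade assignment.
- **Synthetic data** — generators for toy references, tag libraries with
  realistic noise (sequencing errors, adaptor contamination, singleton
  noise, spiked fold changes), annotations, and alignments, so the whole
  pipeline is testable end to end without downloads.

See `docs/methods.md` for the model, conventions, and limitations.

## Worked example

Simulate two libraries from one skewed expression profile with five genes
spiked 8-fold, then run cleaning, mapping, quantification and the exact
test:

```python
import pandas as pd
import dgekit as dk
from dgekit.types import ExpressionMatrix

ref = dk.generate_reference(n_genes=100, seed=7)
profile = dk.lognormal_profile(ref, sigma=2.0, seed=8)
prof_a, prof_b = dk.spike_differential(profile, n_de=5, fold_range=(8, 8), seed=9)
index = dk.build_tag_index(ref)

counts, totals = {}, {}
for lib_id, prof, seed in (("control", prof_a, 10), ("treated", prof_b, 11)):
    raw = dk.simulate_library(ref, prof, depth=200_000, seed=seed, library_id=lib_id)
    clean = dk.extract_clean_tags(raw)
    stats, gene_counts = dk.classify_library(clean, index)
    print(f"{lib_id}: {stats.total_raw} raw -> {stats.total_clean} clean tags, "
          f"{stats.distinct_clean} distinct, {stats.genes_detected} genes detected")
    counts[lib_id] = [gene_counts.get(g, 0) for g in ref.gene_ids]
    totals[lib_id] = clean.total_clean

matrix = ExpressionMatrix(counts=pd.DataFrame(counts, index=ref.gene_ids),
                          library_totals=totals)
results = dk.call_de_genes(matrix, "control", "treated")
for r in results:
    if r.significant:
        print(f"  {r.gene_id} x={r.x} y={r.y} log2={r.log2_ratio:+.2f} FDR={r.fdr:.3g}")
```

prints

```
control: 200000 raw -> 189848 clean tags, 1493 distinct, 99 genes detected
treated: 200000 raw -> 189743 clean tags, 1441 distinct, 99 genes detected
  G84 x=9117 y=1032 log2=-3.14 FDR=0
  G40 x=2632 y=19817 log2=+2.91 FDR=0
  G11 x=218 y=26 log2=-3.07 FDR=2.07e-37
  G28 x=5 y=45 log2=+3.17 FDR=6.94e-08
```

Roughly 5% of each library is noise (errors, adaptor, singletons) and is
removed by cleaning. Four of the five spiked genes are recovered with the
correct direction (log₂ near ±3); the fifth sits too low in the skewed
profile to reach the count threshold — exactly the behavior expected of an
exact count test at this depth. No null gene is called.

The same analysis runs from the command line via the `dgekit` CLI
(`simulate`, `clean`, `map`, `quantify`, `de`, `enrich`, `tree`), or end to
end from one config:

```sh
dgekit all examples/demo_config.yaml
```

which writes library statistics, abundance distributions, counts/TPM
matrices, stage-specificity and correlation tables, saturation curves, the
DE and enrichment tables, and a bootstrapped newick tree into `demo_out/`,
byte-identically on rerun.

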