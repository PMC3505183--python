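# Demo pipeline config: five synthetic tag libraries emulating a
# developmental series (egg/larva/pupa/adult of one strain) plus a second
# larval library from a contrasting strain carrying 20 spiked 8-fold
# expression changes. Run with:  dgekit all examples/demo_config.yaml
seed: 42
outdir: demo_out
fdr_max: 0.001
min_abs_log2: 1.0
bootstrap_reps: 200
support_display_min: 70
max_mismatch: 1
plots: false
synthetic:
  n_genes: 300
  length_range: [200, 400]
  spacer: 100
  n_spike: 20
  fold_range: [8, 8]
  noise: {error_rate: 0.005, adaptor_rate: 0.005, singleton_rate: 0.02}
  libraries:
    - {id: egg, stage: egg, strain: SG, depth: 500000}
    - {id: larva_SG, stage: larva, strain: SG, depth: 500000}
    - {id: pupa, stage: pupa, strain: SG, depth: 500000}
    - {id: adult, stage: adult, strain: SG, depth: 500000}
    - {id: larva_Slab, stage: larva, strain: S-lab, depth: 500000, condition: B}
  n_terms: 20
  term_size_range: [5, 20]
  n_taxa: 10
  alignment_length: 250
  mutation_rate: 0.3
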