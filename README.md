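# mitopop

Population analysis of disease-causing mitochondrial DNA mutations, as a
tested, reusable pipeline: variant extraction from whole mitogenomes,
haplogroup classification with quality control, pathogenicity scoring,
trinucleotide mutational signatures and CpG statistics, a co-occurrence
model for multi-mutation genomes, and rho-based sequence dating — all
exercisable end to end on synthetic cohorts with known truth.

## Who this is for

Mitochondrial population geneticists and clinical mtDNA researchers who
want to ask, on a cohort of complete mitogenome consensus sequences:
which sequences carry known disease-causing mutations, how do those
mutations distribute over the haplogroup phylogeny, do they cluster on
particular backgrounds, and are they enriched on *young* maternal
lineages (the footprint of purifying selection)?

## The methods at the core

* **Variant extraction.** Each sample is globally aligned to a circular
  reference (rCRS- or RSRS-like) with a banded affine-gap
  Needleman–Wunsch; major-allele substitutions m.POS REF>ALT are read off
  mismatch columns, with IUPAC-ambiguous columns and indels excluded from
  all statistics. Every substitution carries its 5'/3' reference context,
  resolved circularly.
* **Haplogroup classification.** Variant profiles are scored against a
  marker-annotated tree by path-marker coverage; QC keeps a sample when
  coverage ≥ 0.90, the assignment is unambiguous, and two independent
  classification runs agree. A sequence is *sub-haplogroup tagged* when
  every expected marker down to a terminal haplogroup is present.
* **Pathogenicity.** Substitutions are annotated synonymous /
  non-synonymous under the vertebrate mitochondrial genetic code (AGA/AGG
  stop, ATA Met, TGA Trp); NS changes in protein genes and substitutions
  in tRNA genes receive precomputed scores in [0, 1] from lookup tables,
  aggregated per sequence as an arithmetic mean (protein and tRNA streams
  kept separate). Disease-causing status is membership in a curated
  catalog (accepted iff reported more than once with disease, or
  documented segregating heteroplasmy).
* **Co-occurrence model.** Under independence, the number K of
  disease-causing mutations on one genome is Poisson-binomial over the
  per-mutation carrier frequencies p_i; the expected count of genomes
  with K ≥ 2 is n·P(K ≥ 2) from the exact dynamic program, compared with
  the observed count by Fisher's exact test.
* **Rho dating.** A clade's age proxy is ρ = mean symmetric-difference
  distance of its members' variant sets from the clade's root haplotype,
  with heuristic standard error σ = √(ρ/n) (star genealogy) or
  σ² = Σ_b m_b·n_b²/n² over an estimated genealogy.
* **Signatures.** Substitutions are strand-collapsed to the six
  pyrimidine classes (C>A, C>G, C>T, T>A, T>C, T>G) × 16 flanking
  contexts = 96 classes; CpG% tracks the fraction of variants at CpG
  dinucleotides (either strand, circular) against the reference's context
  availability.

## Worked example

Simulate a cohort and run the full pipeline:

```bash
mitopop simulate --seed 3 --out sim --samples-per-group 60 --selection 0.5
cat > run.yaml <<EOF
samples_fasta: sim/samples.fasta
reference_fasta: sim/reference.fasta
annotation_tsv: sim/annotation.tsv
tree_tsv: sim/tree.tsv
score_tsv: sim/scores.tsv
catalog_tsv: sim/catalog.tsv
out_dir: out
band: 16
EOF
mitopop run --config run.yaml
cat out/report.txt
```

The report printed by this exact invocation contains (abridged):

```
## Carrier proportions (>=1 disease-causing mutation)
L: 2(3.3%) of 60 sequences
M: 3(5.0%) of 60 sequences
N: 2(3.3%) of 60 sequences

## Co-occurrence of >=2 disease-causing mutations
L: observed 0, expected 0.02, inf-fold deficit, Fisher p 1

## Age (rho) vs pathogenicity
carriers mean rho 12.582 (n=7) vs non-carriers 13.820 (n=173);
Wilcoxon p 0.01662; score-rho r 0.019 (p 0.7956)
after removing main pathogenic allele: r 0.047 (p 0.5282)
```

Reading it: 2–5% of simulated sequences carry an injected pathogenic
allele (matching the configured carrier frequencies); no genome carries
two, against an expectation of only ~0.02 by chance at this cohort size;
and with the selection knob at 0.5 the seven carrier sequences sit on
younger clades (lower rho, Wilcoxon p ≈ 0.017) — an association that
disappears once each sequence's main pathogenic allele is removed in
silico, exactly the signature of selection acting on the allele rather
than the background sequence.

Intermediates (`variants.tsv`, `assignments.tsv`, `profiles.tsv`,
`allele_frequencies.tsv`, `association_scan.tsv`, `spectrum_*.tsv`,
`rho.tsv`) are TSV files from which every report number can be
re-derived. All coordinates are 1-based inclusive.

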