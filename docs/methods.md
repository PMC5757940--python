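# Methods

This note documents the models, conventions and deliberate design
choices behind mitopop, in the order the pipeline applies them.

## Alignment and variant calling

Samples are assumed to be in reference register: public mitogenome
records conventionally begin at reference position 1, so rotation
detection is out of scope and a pre-check drops any sample whose
alignment identity falls below 0.95 (such sequences are likely rotated or
misassembled; calling variants from them would fabricate hundreds of
spurious substitutions).

The aligner is a banded, affine-gap global dynamic program (Gotoh three
matrices, numba-jitted). Defaults: match +1, mismatch −1, gap open −5,
gap extend −1, band 200. A length-k gap scores open + k·extend = −(5+k);
the first gapped base pays both the opening and the extension penalty.
Within the band the score is the global optimum; the precondition
|len(sample) − len(ref)| ≤ band is enforced with an error that advises a
larger band. Traceback ties are broken diagonal > up > left, making
variant calls deterministic; gap runs are then left-aligned within
homopolymers (the placement convention of mtDNA nomenclature). For
substitution-only cohorts a band of 16 is ample and roughly 12× faster
than the default; both are exposed.

Variant semantics: one substitution per mismatch column with an
unambiguous sample base; columns where the sample carries an IUPAC
ambiguity code become `kind="ambiguous"` records that never enter any
downstream statistic (a consensus base that is not a single major allele
should not fabricate one); gap runs collapse to single
insertion/deletion records that are loaded but likewise excluded
everywhere (signatures, scores, distances). Contexts attached to
substitutions are reference bases, resolved circularly across the
origin.

## Haplogroup classification and QC

Classification scores every tree node by *marker coverage*: the fraction
of the markers expected on the root→node path (back mutations resolved
by the `!` convention — a `!`-suffixed marker cancels its earlier
expectation) that the profile contains. The best node maximizes
coverage, with ties broken by depth, then found-marker count, then node
name; a tie surviving to the name stage flags the assignment ambiguous.
This is a simplification of production classifiers' weighted measures
(e.g. Kulczynski similarity) with identical behaviour on complete
profiles, which is the regime the simulator and the QC stratum operate
in. An empty profile sits at the root with vacuous coverage 1.

"Sub-haplogroup tagged" is operationalized as: best node is a leaf and
coverage is exactly 1.0. The dual-classifier concordance QC reruns
classification with the opposite tie-break order — a deliberately cheap
stand-in for running two independent tools — and drops a sample when
coverage < 0.90, either run is ambiguous, or the two best nodes differ.

## Genetic code and scoring

Codons are reconstructed from the reference using each gene's strand and
reading-frame offset and translated with the vertebrate mitochondrial
code (NCBI table 2 via Biopython). A substitution overlapping two genes
in different frames yields one hit per gene with independent NS flags;
the pathogenicity of such a variant is the maximum over its scored hits
(the most damaging interpretation; the alternative — the mean — blurs a
damaging change with a silent one). Scores are lookups only: NS protein
hits from the amino-acid substitution table, tRNA-gene substitutions
from the per-position table; nothing is imputed for missing entries, and
positions without table entries (e.g. the control region) are thereby
implicitly excluded from score means. Protein and tRNA scores are never
averaged together; they derive from different scoring systems and are
analyzed as separate streams.

Per-sequence aggregation is the arithmetic mean of available scores.
The optional `exclude` argument removes one variant key before
averaging; the age analysis uses it to remove each sequence's main
(highest-scored) pathogenic allele in silico and re-test the
association. The per-sequence mean includes all scored population
variants (disease-flagged ones too); excluding them is exposed via the
same mechanism rather than a second convention.

NS/S ratios count *unique* variants per group — each distinct
substitution once, however many sequences carry it — because the
comparison is between variant inventories of phylogenies, not sequence
mutation loads. A variant is NS if non-synonymous in at least one
overlapping gene.

## Population statistics

Classical tests are delegated to scipy with fixed conventions: Fisher's
exact test two-sided by the probability-mass rule (the R convention);
Welch's t with Satterthwaite degrees of freedom; the Wilcoxon rank-sum
test as Mann–Whitney, exact for small tie-free samples and otherwise the
normal approximation with tie and continuity corrections. Pearson
correlations report (r, r², p) with p from the t transform on n−2 df.
Reports print p-values below 2.2e−16 as "< 2.2e-16" (the R convention);
functions always return full precision. Allele-frequency log-ratios use
log2(AF1/AF2) with the Haldane–Anscombe correction (+0.5 to all four
counts) applied and flagged whenever either carrier count is zero.

**Co-occurrence.** The null model for genomes carrying ≥ 2
disease-causing mutations is independence of mutations across a genome:
K ~ Poisson-binomial over the per-mutation carrier frequencies estimated
within the group, P(K ≥ 2) by the exact O(m²) dynamic program, expected
count n·P(K ≥ 2). Significance mimics a Fisher test on the pseudo 2×2
table [observed, n−observed; round(expected), n−round(expected)] with
half-up rounding (documented because the construction is a reporting
convention, not a likelihood-ratio test). The fold is reported signed:
expected/observed for a deficit, observed/expected for an excess — old
macro-haplogroups are expected to show a deficit (purifying selection),
and leaving the direction explicit avoids baking an interpretation into
a ratio.

**Association scan.** For each accepted mutation observed on ≥ 2
haplogroups ("recurrent") and each haplogroup at the chosen level, a
Fisher 2×2 of carrier status × membership. Raw p-values are flagged at
the configured threshold (default 0.01, the scan's reporting
convention); Bonferroni over all (mutation, haplogroup) tests in the
scan is reported alongside because no named procedure exists for this
family and Bonferroni is the conservative default.

## Signatures, CpG, rho

The 96-class spectrum collapses every substitution to the pyrimidine
strand (purine-reference changes are reverse complemented, contexts
swapped and complemented), giving six substitution types × 16 contexts
in the canonical substitution-major, 5'-then-3' order. Spectra default
to counting each unique variant once per group, since group-level
spectra compare variant inventories; a per-occurrence weighting is a
caller-side choice (pass per-sequence variant lists instead).

A position is "at a CpG" when it lies in a 5'-CG-3' dinucleotide on
either strand of the circular reference. Because "CpG%" is sometimes
annotated as "%C>T", both numerators are always computed: all variants
at CpG sites (default) and only C:G>T:A transitions at CpG sites.
Enrichment is tested by Fisher against the reference's context
availability (fraction of positions in CpG dinucleotides).

Rho uses the symmetric difference between a member's substitution-key
set and the clade's root haplotype, so a back mutation relative to the
root counts once; ambiguous calls and indels never contribute. The
default standard error assumes a star genealogy, σ = √(ρ/n). The
parsimony-tree mode builds the trivial genealogy obtained by pooling
variants with identical carrier sets into single branches and applies
σ² = Σ_b m_b·n_b²/n²; on a perfect star (all variants private) the two
coincide. No conversion to calendar years is performed — any
mutation-rate calibration is user-supplied post-processing.

## The simulator

The generator's defaults are the package's study conditions: a 6 kb
circular reference carrying four 900 b protein genes, one overlapping
300 b pair in different frames, and four tRNAs; a depth-4 binary marker
tree per macro group (16 leaves each, 3 markers per branch); 300
sequences per group; Ti/Tv 20 (mitochondria are strongly
transition-biased) with CpG transitions 5× hotter; Poisson(3) private
mutations per lineage; six pathogenic NS alleles with per-group total
carrier frequencies 2.2% / 7.8% / 5.2% (a low-/high-/mid-prevalence
three-group cohort, mirroring the ordering seen in global population
data); scores drawn Beta(2,3) for the background table (mean 0.4),
Beta(5,2) for pathogenic alleles (mean ≈ 0.7) and Beta(1,9) for tRNA
sites (mean 0.1). These sizes keep the full test suite within minutes
while leaving every statistic well-powered.

Age structure is deliberately minimal: the oldest half of each macro
group's leaves draws private mutations at twice the base rate, so old
clades have distinguishably higher rho; the selection knob s converts a
pathogenic carrier on an old clade back to a non-carrier with
probability s. This is a stand-in for purifying selection over time,
not a demographic model.

Mutations never recur within a lineage (infinite sites along one
root→leaf history) but pathogenic alleles are injected across lineages
and groups, which is what makes them "recurrent" for the association
analyses. Marker and private draws exclude the pathogenic positions, so
carrier status is exactly the injection indicator and configured
frequencies are recovered as clean binomial draws. Emitted FASTA applies
the variant set to the reference; optional IUPAC ambiguity injection
corrupts random positions to exercise the QC path.

What the simulator does **not** emulate — and hence what passing tests
do not show about real data: realistic human demography or tree shape,
heteroplasmy, indels, rotated or partial assemblies, sequencing error
beyond uniform ambiguity injection, linkage between pathogenic alleles
and specific backgrounds (beyond the selection knob), and control-region
hypervariability.

## Validation conditions and their power

The validation suite (mitopop.validation, mirrored by
scripts/acceptance.py) runs at these sizes, chosen as the package's
study conditions: haplogroup recovery on 900 sequences; carrier-
frequency recovery at n = 1,000 per group, checked per injected
(allele, group) pair against exact binomial 99% CIs plus a
Bonferroni-corrected family-wise 99% band across the 18 pairs (a strict
all-pairs-at-99% rule would fail ~17% of correct runs by construction);
rho calibration over 200 replicate 25-tip clades with Poisson(3)
privates, within 3 SE of 3; CpG null/enrichment over 100 replicates
each; selection direction over 200 replicate cohorts of 1,000 at
s = 0.8; and exact variant-set recovery for 1,000 aligned sequences.

For the selection check, the acceptance property is the *direction* of
the Wilcoxon comparison (carriers younger). At realistic carrier
frequencies a cohort of 1,000 yields only ~30 carriers, which caps the
power of a p < 0.05-qualified detection near 80% (a two-group
proportion-shift calculation gives z ≈ 3.5 before rank-tie losses); the
significant-detection rate is therefore reported as a secondary
diagnostic rather than the acceptance property. Raising the simulated
carrier frequencies would buy significance at the cost of realism.

## Known limitations

* The classifier's coverage score ignores markers observed off-path
  (private variants neither help nor hurt), so heavily mutated samples
  can still classify confidently; real tools penalize unexplained
  variants.
* Rho granularity equals the clade level chosen for dating; with few
  major clades the per-sequence age is coarse.
* The co-occurrence pseudo-table test inherits the discreteness of
  rounding the expectation; for very small expectations the Fisher p is
  conservative.
* Wrap-around genes are supported in annotation and codon
  reconstruction, but the bundled simulator never generates them.
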