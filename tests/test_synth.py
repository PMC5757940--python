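import numpy as np
import pytest

from mitopop.patho import classify_ns_s
from mitopop.refdata import ReferenceGenome
from mitopop.synth import (
    ConfigError,
    SimulationConfig,
    simulate_cohort,
    simulate_reference,
)
from mitopop.variantcall import (
    Variant,
    banded_global_align,
    call_variants,
    substitution_keys,
)


class TestReferenceSimulation:
    def test_fixed_seed_is_byte_identical(self):
        c = SimulationConfig(seed=5, cohort_sizes={"L": 20})
        b1, b2 = simulate_reference(c), simulate_reference(c)
        assert b1.reference.sequence == b2.reference.sequence
        assert b1.score_table.protein_scores == b2.score_table.protein_scores
        co1 = simulate_cohort(c, b1)
        co2 = simulate_cohort(c, b2)
        assert co1.sequences == co2.sequences
        assert {s: t.variant_keys for s, t in co1.truth.samples.items()} == {
            s: t.variant_keys for s, t in co2.truth.samples.items()
        }

    def test_requested_gene_layout(self):
        c = SimulationConfig(
            seed=1, n_protein_genes=2, protein_gene_length=300,
            include_overlapping_pair=False, cohort_sizes={"L": 5},
        )
        b = simulate_reference(c)
        prots = [g for g in b.reference.genes if g.kind == "protein"]
        assert len(prots) == 2
        for g in prots:
            assert (g.end - g.start + 1) == 300

    def test_layout_exceeding_reference_rejected(self):
        c = SimulationConfig(
            seed=1, reference_length=2000, n_protein_genes=4,
            cohort_sizes={"L": 5},
        )
        with pytest.raises(ConfigError, match="layout"):
            simulate_reference(c)

    def test_score_table_covers_every_ns_substitution(self):
        """Every possible NS change in protein gene space has an entry."""
        c = SimulationConfig(seed=2, cohort_sizes={"L": 5})
        b = simulate_reference(c)
        ref = b.reference
        missing = 0
        for gene in ref.genes:
            if gene.kind != "protein":
                continue
            for pos in gene.positions(ref.length):
                refb = ref.base(pos)
                for alt in "ACGT":
                    if alt == refb:
                        continue
                    v = Variant(pos, refb, alt, "substitution")
                    for hit in classify_ns_s(v, ref):
                        if hit.ns_flag and b.score_table.protein(
                            hit.gene, hit.aa_position, hit.ref_aa, hit.alt_aa
                        ) is None:
                            missing += 1
        assert missing == 0

    def test_catalog_lists_pathogenic_plus_decoys(self):
        c = SimulationConfig(seed=3, cohort_sizes={"L": 5})
        b = simulate_reference(c)
        assert b.catalog.accepted_keys == {s.key for s in b.pathogenic}
        assert len(b.catalog) > len(b.pathogenic)  # decoys + indel entry


class TestCohortSimulation:
    def test_truth_matches_emitted_fasta(self):
        """Re-deriving variants from the FASTA reproduces the truth sets
        exactly at zero ambiguity injection."""
        c = SimulationConfig(seed=7, cohort_sizes={"L": 10, "M": 10})
        b = simulate_reference(c)
        cohort = simulate_cohort(c, b, sequences=True)
        for sid, seq in cohort.sequences:
            aln = banded_global_align(seq, b.reference, sample_id=sid, band=16)
            keys = substitution_keys(call_variants(aln, b.reference))
            assert keys == set(cohort.truth.samples[sid].variant_keys)

    def test_ambiguity_injection_recorded_and_emitted(self):
        c = SimulationConfig(seed=8, cohort_sizes={"L": 5},
                             ambiguity_rate=0.01)
        b = simulate_reference(c)
        cohort = simulate_cohort(c, b, sequences=True)
        amb_chars = set("RYSWKM")
        any_amb = False
        for sid, seq in cohort.sequences:
            truth = cohort.truth.samples[sid]
            for pos in truth.ambiguous_positions:
                assert seq[pos - 1] in amb_chars
                any_amb = True
        assert any_amb

    def test_selection_reduces_carriers_on_old_clades(self):
        def old_young_carriers(s):
            c = SimulationConfig(
                seed=9, cohort_sizes={"L": 400, "M": 400, "N": 400},
                selection_s=s,
            )
            b = simulate_reference(c)
            cohort = simulate_cohort(c, b, sequences=False)
            old = sum(1 for t in cohort.truth.samples.values()
                      if t.old and t.pathogenic_keys)
            young = sum(1 for t in cohort.truth.samples.values()
                        if not t.old and t.pathogenic_keys)
            return old, young

        old0, young0 = old_young_carriers(0.0)
        old8, young8 = old_young_carriers(0.8)
        # selection removes only old-clade carriers
        assert old8 < old0
        assert old8 / (old8 + young8) < old0 / (old0 + young0)

    def test_increasing_selection_lowers_carrier_age(self):
        """Mean age rank of carriers decreases monotonically in s."""
        means = []
        for s in (0.0, 0.5, 0.9):
            old_frac = []
            for rep in range(5):
                c = SimulationConfig(
                    seed=100 + rep, selection_s=s,
                    cohort_sizes={"L": 300, "M": 300, "N": 300},
                )
                b = simulate_reference(c)
                cohort = simulate_cohort(c, b, sequences=False)
                carriers = [t for t in cohort.truth.samples.values()
                            if t.pathogenic_keys]
                old_frac.append(
                    np.mean([t.old for t in carriers]) if carriers else np.nan
                )
            means.append(np.nanmean(old_frac))
        assert means[0] > means[1] > means[2]

    def test_variant_truth_has_context_and_cpg(self):
        c = SimulationConfig(seed=10, cohort_sizes={"L": 20})
        b = simulate_reference(c)
        cohort = simulate_cohort(c, b, sequences=False)
        from mitopop.sigdate import is_cpg_position
        for key, vt in cohort.truth.variants.items():
            assert 0 <= vt.context_class < 96
            pos = int(key[2:-3])
            assert vt.cpg == is_cpg_position(b.reference, pos)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(marker_dropout=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(cpg_transition_multiplier=0.5)
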