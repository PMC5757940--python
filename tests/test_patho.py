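import pytest

from conftest import make_profile
from mitopop.patho import (
    classify_ns_s,
    flag_disease,
    main_pathogenic_allele,
    mean_pathogenicity,
    annotate_profile,
    ns_s_fisher,
    ns_s_ratio,
    score_variant,
    translate_codon,
    AnnotatedVariant,
)
from mitopop.refdata import CatalogEntry, DiseaseCatalog, ScoreTable
from mitopop.variantcall import Variant


class TestMitochondrialCode:
    def test_wobble_position_synonymous(self, coding_ref):
        # FWD codon 2 is GCT (Ala); third position T>C keeps Ala
        v = Variant(16, "T", "C", "substitution")
        (hit,) = classify_ns_s(v, coding_ref)
        assert (hit.gene, hit.ref_aa, hit.alt_aa) == ("FWD", "A", "A")
        assert not hit.ns_flag

    def test_tga_is_tryptophan_not_stop(self, coding_ref):
        # FWD codon 3 is TGG (Trp); G>A gives TGA = Trp under the
        # vertebrate mitochondrial code (a stop in the standard code)
        v = Variant(19, "G", "A", "substitution")
        (hit,) = classify_ns_s(v, coding_ref)
        assert hit.ref_aa == "W" and hit.alt_aa == "W"
        assert not hit.ns_flag
        assert translate_codon("TGA") == "W"
        assert translate_codon("AGA") == "*"  # mitochondrial stop
        assert translate_codon("ATA") == "M"

    def test_nonsynonymous_change_flagged(self, coding_ref):
        # FWD codon 2 GCT: first position G>C gives CCT (Pro)
        v = Variant(14, "G", "C", "substitution")
        (hit,) = classify_ns_s(v, coding_ref)
        assert (hit.ref_aa, hit.alt_aa) == ("A", "P")
        assert hit.ns_flag

    def test_reverse_strand_gene_complemented(self, coding_ref):
        # REV coding seq ATG ATG TAA from positions 39..31; genomic 36
        # is coding index 3 (codon 2 pos 1): ref base T -> coding A
        v = Variant(36, "T", "C", "substitution")
        (hit,) = classify_ns_s(v, coding_ref)
        assert hit.gene == "REV"
        assert hit.ref_aa == "M"
        assert hit.alt_aa == "V"  # coding alt = comp(C) = G: ATG -> GTG (Val)
        assert hit.ns_flag

    def test_overlapping_genes_hit_independently(self, coding_ref):
        # position 55 lies in OLP1 (frame 0 from 51) and OLP2 (from 53)
        v = Variant(55, coding_ref.base(55), "T", "substitution")
        hits = classify_ns_s(v, coding_ref)
        assert {h.gene for h in hits} == {"OLP1", "OLP2"}
        assert hits[0].codon_index != hits[1].codon_index or (
            hits[0].ref_aa != hits[1].ref_aa
        )

    def test_non_coding_position_has_no_hits(self, coding_ref):
        assert classify_ns_s(Variant(2, "A", "G", "substitution"),
                             coding_ref) == []


class TestScoring:
    def _av(self, coding_ref, pos, alt):
        v = Variant(pos, coding_ref.base(pos), alt, "substitution")
        av = AnnotatedVariant(variant=v)
        av.gene_hits = classify_ns_s(v, coding_ref)
        av.trna_genes = [
            g.gene for g in coding_ref.genes_at(pos) if g.kind == "tRNA"
        ]
        return av

    def test_ns_lookup(self, coding_ref):
        av = self._av(coding_ref, 14, "C")  # FWD A2P
        table = ScoreTable({("FWD", 2, "A", "P"): 0.62})
        score_variant(av, table)
        assert av.pathogenicity == 0.62

    def test_synonymous_only_scores_absent(self, coding_ref):
        av = self._av(coding_ref, 16, "C")  # Ala->Ala
        table = ScoreTable({("FWD", 2, "A", "A"): 0.5})
        score_variant(av, table)
        assert av.pathogenicity is None

    def test_overlap_takes_maximum(self, coding_ref):
        av = self._av(coding_ref, 55, "T")
        assert len(av.gene_hits) == 2
        h1, h2 = av.gene_hits
        table = ScoreTable({
            (h1.gene, h1.aa_position, h1.ref_aa, h1.alt_aa): 0.3,
            (h2.gene, h2.aa_position, h2.ref_aa, h2.alt_aa): 0.7,
        })
        score_variant(av, table)
        assert av.pathogenicity == 0.7

    def test_trna_stream_separate(self, coding_ref):
        av = self._av(coding_ref, 70, "G")  # inside TRNX
        table = ScoreTable({}, {(70, "G"): 0.4})
        score_variant(av, table)
        assert av.trna_pathogenicity == 0.4
        assert av.pathogenicity is None


class TestMeanPathogenicity:
    def test_plain_mean(self):
        p = make_profile("s", ["m.10A>G", "m.20C>T"],
                         scores={"m.10A>G": 0.2, "m.20C>T": 0.6})
        assert mean_pathogenicity(p) == pytest.approx(0.4)

    def test_exclusion_recomputes_mean(self):
        p = make_profile(
            "s", ["m.10A>G", "m.20C>T", "m.30G>A"],
            accepted={"m.10A>G"},
            scores={"m.10A>G": 0.9, "m.20C>T": 0.2, "m.30G>A": 0.3},
        )
        assert mean_pathogenicity(p, exclude="m.10A>G") == pytest.approx(0.25)

    def test_no_scores_is_absent(self):
        p = make_profile("s", ["m.10A>G"])
        assert mean_pathogenicity(p) is None

    def test_unknown_exclude_key_rejected(self):
        p = make_profile("s", ["m.10A>G"], scores={"m.10A>G": 0.5})
        with pytest.raises(KeyError):
            mean_pathogenicity(p, exclude="m.99T>C")

    def test_exclusion_matches_brute_force(self):
        scores = {f"m.{i}A>G": s for i, s in
                  zip(range(10, 60, 10), (0.1, 0.3, 0.5, 0.7, 0.9))}
        p = make_profile("s", list(scores), scores=scores)
        for k in scores:
            remaining = [v for kk, v in scores.items() if kk != k]
            assert mean_pathogenicity(p, exclude=k) == pytest.approx(
                sum(remaining) / len(remaining)
            )


class TestDiseaseFlags:
    CAT = DiseaseCatalog([
        CatalogEntry("m.10A>G", "g", True, False),
        CatalogEntry("m.20C>T", "g", False, True),
        CatalogEntry("m.30G>A", "g", False, False),   # rejected
    ])

    def test_accepted_variant_counted(self):
        p = make_profile("s", ["m.10A>G", "m.99T>C"])
        assert flag_disease(p, self.CAT) == 1

    def test_rejected_variant_not_counted(self):
        p = make_profile("s", ["m.30G>A"])
        assert flag_disease(p, self.CAT) == 0

    def test_two_accepted_counted(self):
        p = make_profile("s", ["m.10A>G", "m.20C>T"])
        assert flag_disease(p, self.CAT) == 2
        assert p.disease_count == 2

    def test_main_pathogenic_allele_is_highest_scored(self):
        p = make_profile(
            "s", ["m.10A>G", "m.20C>T"],
            accepted={"m.10A>G", "m.20C>T"},
            scores={"m.10A>G": 0.3, "m.20C>T": 0.8},
        )
        assert main_pathogenic_allele(p) == "m.20C>T"


class TestNsSRatio:
    def test_unique_variant_counting(self, coding_ref):
        # two samples share one NS and one S variant; counted once each
        vs = [Variant(14, "G", "C", "substitution"),   # NS (A->P)
              Variant(16, "T", "C", "substitution")]   # S
        profiles = [
            annotate_profile(f"s{i}", vs, coding_ref) for i in range(2)
        ]
        r = ns_s_ratio(profiles, grouping={"s0": "G", "s1": "G"})["G"]
        assert (r.ns, r.s) == (1, 1)
        assert r.ratio == 1.0

    def test_zero_synonymous_flagged_infinite(self, coding_ref):
        vs = [Variant(14, "G", "C", "substitution")]
        profiles = [annotate_profile("s0", vs, coding_ref)]
        r = ns_s_ratio(profiles, grouping={"s0": "G"})["G"]
        assert r.infinite

    def test_fisher_on_count_pair_matches_enumeration(self):
        from mitopop.patho import NsSRatio

        p = ns_s_fisher(NsSRatio("a", 3, 1), NsSRatio("b", 1, 3))
        assert p == pytest.approx(34 / 70)
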