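import math

import numpy as np
import pytest

from conftest import make_profile
from mitopop.refdata import ReferenceGenome, revcomp
from mitopop.sigdate import (
    CLASS_LABELS,
    age_pathogenicity_association,
    class_index,
    cpg_fraction,
    is_cpg_position,
    rho,
    spectrum_96,
)
from mitopop.variantcall import Variant


class TestSpectrum96:
    def test_pyrimidine_substitution_binned_directly(self):
        v = Variant(5, "C", "T", "substitution", context5="A", context3="G")
        spec = spectrum_96([v])
        assert spec.total == 1
        assert spec.counts[CLASS_LABELS.index("A[C>T]G")] == 1

    def test_purine_substitution_reverse_complemented(self):
        # G>A with 5'T and 3'C maps to C>T with 5'G and 3'A
        v = Variant(5, "G", "A", "substitution", context5="T", context3="C")
        spec = spectrum_96([v])
        assert spec.counts[CLASS_LABELS.index("G[C>T]A")] == 1

    def test_empty_set_has_undefined_frequencies(self):
        spec = spectrum_96([])
        assert spec.total == 0
        assert spec.frequencies is None

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(0)
        variants = []
        for _ in range(50):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            variants.append(
                Variant(1, ref, alt, "substitution",
                        context5=rng.choice(list("ACGT")),
                        context3=rng.choice(list("ACGT")))
            )
        spec = spectrum_96(variants)
        assert spec.frequencies.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_invariant_under_reverse_complement_of_input(self, seed):
        """Reverse-complementing every variant (alleles and swapped,
        complemented contexts) leaves the spectrum unchanged."""
        rng = np.random.default_rng(seed)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        variants, rc_variants = [], []
        for _ in range(40):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            c5, c3 = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
            variants.append(
                Variant(1, ref, alt, "substitution", context5=c5, context3=c3)
            )
            rc_variants.append(
                Variant(1, comp[ref], comp[alt], "substitution",
                        context5=comp[c3], context3=comp[c5])
            )
        s1, s2 = spectrum_96(variants), spectrum_96(rc_variants)
        assert np.array_equal(s1.counts, s2.counts)

    def test_missing_context_rejected(self):
        with pytest.raises(ValueError, match="context"):
            spectrum_96([Variant(1, "C", "T", "substitution")])


class TestCpG:
    REF = ReferenceGenome("toy", "ACGT")

    def test_c_of_cg_is_cpg(self):
        assert is_cpg_position(self.REF, 2)   # C followed by G
        assert is_cpg_position(self.REF, 3)   # the G of the CG

    def test_non_cpg_position(self):
        assert not is_cpg_position(self.REF, 4)
        assert not is_cpg_position(self.REF, 1)

    def test_singleton_cpg_percent(self):
        v = Variant(2, "C", "T", "substitution")
        st = cpg_fraction([v], self.REF)
        assert st.percent == 100.0
        assert st.percent_c_to_t == 100.0

    def test_mixed_set_percent(self):
        vs = [Variant(2, "C", "T", "substitution"),
              Variant(4, "T", "A", "substitution")]
        st = cpg_fraction(vs, self.REF)
        assert st.percent == 50.0

    def test_c_to_t_numerator_restricts(self):
        vs = [Variant(2, "C", "A", "substitution")]  # CpG but transversion
        st = cpg_fraction(vs, self.REF)
        assert st.percent == 100.0
        assert st.percent_c_to_t == 0.0

    def test_empty_set_undefined(self):
        st = cpg_fraction([], self.REF)
        assert not st.defined
        with pytest.raises(ValueError):
            _ = st.percent

    def test_circular_cg_across_origin(self):
        ref = ReferenceGenome("toy", "GTTC")  # C(4) followed by G(1)
        assert is_cpg_position(ref, 4)
        assert is_cpg_position(ref, 1)


class TestRho:
    def test_all_at_root(self):
        est = rho([set(), set()], set())
        assert est.rho == 0.0 and est.sigma == 0.0

    def test_star_mode_formula(self):
        clade = [
            {"m.1A>G"},
            {"m.1A>G", "m.2C>T"},
            {"m.1A>G", "m.2C>T", "m.3G>A"},
            {"m.4T>C", "m.5A>G"},
        ]
        est = rho(clade, set())
        assert est.rho == pytest.approx(2.0)
        assert est.sigma == pytest.approx(math.sqrt(2.0 / 4))

    def test_parsimony_tree_sigma_saillard_example(self):
        # two tips share one mutation and carry one private each
        clade = [{"m.1A>G", "m.2C>T"}, {"m.1A>G", "m.3G>A"}]
        est = rho(clade, set(), mode="parsimony-tree")
        assert est.rho == pytest.approx(2.0)
        # branches: shared (m=1, n=2), two private (m=1, n=1)
        assert est.sigma == pytest.approx(math.sqrt((4 + 1 + 1) / 4))

    def test_tree_mode_equals_star_on_perfect_star(self):
        clade = [{f"m.{i}A>G"} for i in range(1, 6)]
        star = rho(clade, set(), mode="star")
        tree = rho(clade, set(), mode="parsimony-tree")
        assert tree.sigma == pytest.approx(star.sigma)

    def test_back_mutation_counts_once_via_symmetric_difference(self):
        root = {"m.1A>G", "m.2C>T"}
        est = rho([{"m.2C>T"}], root)  # lost m.1A>G relative to root
        assert est.rho == 1.0

    def test_empty_clade_rejected(self):
        with pytest.raises(ValueError):
            rho([], set())


class TestAgeAssociation:
    def _profiles(self, carrier_rho, noncarrier_rho):
        profiles, rho_of = [], {}
        for i, r in enumerate(carrier_rho):
            sid = f"c{i}"
            profiles.append(make_profile(
                sid, ["m.10A>G"], accepted={"m.10A>G"},
                scores={"m.10A>G": 0.9}))
            rho_of[sid] = r
        for i, r in enumerate(noncarrier_rho):
            sid = f"n{i}"
            profiles.append(make_profile(
                sid, ["m.20C>T"], scores={"m.20C>T": 0.2}))
            rho_of[sid] = r
        return profiles, rho_of

    def test_carriers_on_young_clades_detected(self):
        rng = np.random.default_rng(0)
        profiles, rho_of = self._profiles(
            carrier_rho=list(rng.normal(3, 0.3, 30)),
            noncarrier_rho=list(rng.normal(6, 0.3, 30)),
        )
        res = age_pathogenicity_association(profiles, rho_of)
        assert res.carriers_younger
        assert res.wilcoxon_p < 1e-6
        assert res.score_rho_r < 0  # high scores on young sequences

    def test_degenerate_constant_rho_not_evaluable(self):
        profiles, rho_of = self._profiles([2.0] * 3, [2.0] * 3)
        with pytest.raises(ValueError):
            age_pathogenicity_association(profiles, rho_of)

    def test_one_empty_group_rejected(self):
        profiles, rho_of = self._profiles([2.0, 3.0], [])
        with pytest.raises(ValueError, match="empty"):
            age_pathogenicity_association(profiles, rho_of)
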