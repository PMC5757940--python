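import math

import numpy as np
import pytest

from _oracles import fisher_enum_p, poisson_binomial_enum, wilcoxon_exact_p
from conftest import make_profile
from mitopop.popstats import (
    allele_frequencies,
    association_scan,
    cooccurrence,
    fisher_2x2,
    log2_af_ratio,
    pearson_r2,
    poisson_binomial_pmf,
    prob_two_or_more,
    welch_t,
    wilcoxon_rank,
)
from mitopop.refdata import CatalogEntry, DiseaseCatalog


class TestAlleleFrequencies:
    def test_carrier_fraction(self):
        profiles = [
            make_profile("s1", ["m.10A>G"], macro="L"),
            make_profile("s2", ["m.10A>G"], macro="L"),
            make_profile("s3", [], macro="L"),
            make_profile("s4", [], macro="L"),
        ]
        afs = allele_frequencies(profiles)
        assert afs[("L", "m.10A>G")].af == 0.5

    def test_unobserved_variant_absent_from_table(self):
        profiles = [make_profile("s1", ["m.10A>G"], macro="L"),
                    make_profile("s2", [], macro="M")]
        afs = allele_frequencies(profiles)
        assert ("M", "m.10A>G") not in afs


class TestLog2Ratio:
    def test_exact_power_of_two(self):
        v, corrected = log2_af_ratio(40, 100, 10, 100)
        assert v == pytest.approx(2.0)
        assert not corrected

    def test_equal_frequencies_zero(self):
        v, _ = log2_af_ratio(5, 50, 10, 100)
        assert v == pytest.approx(0.0)

    def test_zero_count_haldane_anscombe(self):
        v, corrected = log2_af_ratio(0, 100, 5, 100)
        assert corrected
        assert v == pytest.approx(math.log2((0.5 / 101) / (5.5 / 101)))


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2, 3, 4, 5]
        r, r2, p = pearson_r2(x, [2 * v + 1 for v in x])
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        x = [-2.0, -1, 0, 1, 2]
        y = [4.0, 1, 0, 1, 4]  # even function of x
        r, _, _ = pearson_r2(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2, 4, 5, 9])
        y = np.array([2.0, 1, 5, 4, 8])
        r, r2, p = pearson_r2(x, y)
        rx, ry = x - x.mean(), y - y.mean()
        r_direct = (rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
        assert r == pytest.approx(r_direct)
        from scipy import stats
        t = r_direct * math.sqrt(3 / (1 - r_direct ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r2([1.0, 1, 1], [1.0, 2, 3])


class TestFisher:
    def test_symmetric_table_p_one(self):
        _, p = fisher_2x2([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    def test_three_one_table_exact_fraction(self):
        oratio, p = fisher_2x2([[3, 1], [1, 3]])
        assert p == pytest.approx(34 / 70)
        assert oratio == pytest.approx(9.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            a += 1
            d += 1
        _, p = fisher_2x2([[a, b], [c, d]])
        assert p == pytest.approx(fisher_enum_p(a, b, c, d), abs=1e-10)

    def test_large_table_against_log_gamma_oracle(self):
        _, p = fisher_2x2([[520, 480], [430, 570]])
        assert p == pytest.approx(fisher_enum_p(520, 480, 430, 570), rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2([[0, 0], [1, 2]])


class TestWelchAndWilcoxon:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_matches_hand_formula_4_plus_4(self):
        x = np.array([1.0, 2, 3, 6])
        y = np.array([2.0, 4, 4, 8])
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / 4, y.var(ddof=1) / 4
        assert t == pytest.approx((x.mean() - y.mean()) / math.sqrt(vx + vy))
        assert df == pytest.approx(
            (vx + vy) ** 2 / (vx ** 2 / 3 + vy ** 2 / 3)
        )

    def test_welch_reduces_to_pooled_t_for_equal_variance_equal_n(self):
        x = np.array([1.0, 2, 3, 4])
        y = x + 1.5  # same sample variance, same n
        t, df, _ = welch_t(x, y)
        sp2 = x.var(ddof=1)  # pooled variance equals either sample's
        t_pooled = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(t_pooled)
        assert df == pytest.approx(6.0)

    def test_wilcoxon_fully_separated_exact_p(self):
        w, p = wilcoxon_rank([1.0, 2, 3], [4.0, 5, 6])
        assert w == 0.0  # no x exceeds any y
        assert p == pytest.approx(0.1)
        assert p == pytest.approx(
            wilcoxon_exact_p([1.0, 2, 3], [4.0, 5, 6])
        )

    def test_wilcoxon_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_rank([2.0, 2.0], [2.0, 2.0])


class TestPoissonBinomial:
    def test_two_events_product(self):
        assert prob_two_or_more([0.1, 0.2]) == pytest.approx(0.02)

    def test_single_event_impossible(self):
        assert prob_two_or_more([0.3]) == 0.0

    def test_three_equal_events_binomial_expansion(self):
        # 3*0.01*0.9 + 0.001
        assert prob_two_or_more([0.1, 0.1, 0.1]) == pytest.approx(0.028)

    @pytest.mark.parametrize("seed", range(5))
    def test_pmf_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=int(rng.integers(1, 9)))
        pmf = poisson_binomial_pmf(p)
        enum = poisson_binomial_enum(list(p))
        assert np.allclose(pmf, enum, atol=1e-12)
        assert pmf.sum() == pytest.approx(1.0)

    def test_pmf_matches_scipy_cross_check(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, size=15)
        pmf = poisson_binomial_pmf(p)
        ref = stats.poisson_binom.pmf(np.arange(16), p)
        assert np.allclose(pmf, ref, atol=1e-12)


CATALOG = DiseaseCatalog([
    CatalogEntry("m.10A>G", "g", True, False),
    CatalogEntry("m.20C>T", "g", True, False),
])


class TestCooccurrence:
    def _cohort(self, n, freq1, freq2, both):
        """n profiles; given carrier counts for the two catalog variants,
        of which ``both`` carry both."""
        profiles = []
        for i in range(n):
            keys = []
            if i < both:
                keys = ["m.10A>G", "m.20C>T"]
            elif i < freq1:
                keys = ["m.10A>G"]
            elif i < freq1 + freq2 - both:
                keys = ["m.20C>T"]
            profiles.append(
                make_profile(f"s{i}", keys,
                             accepted={"m.10A>G", "m.20C>T"})
            )
        return profiles

    def test_expectation_from_product(self):
        profiles = self._cohort(100, 10, 20, 0)
        r = cooccurrence(profiles, CATALOG, group="G")
        assert r.p_ge2 == pytest.approx(0.02)
        assert r.expected_ge2 == pytest.approx(2.0)
        assert r.observed_ge2 == 0
        assert r.direction == "deficit"

    def test_single_mutation_no_cooccurrence_possible(self):
        catalog = DiseaseCatalog([CatalogEntry("m.10A>G", "g", True, False)])
        profiles = [make_profile(f"s{i}", ["m.10A>G"] if i < 3 else [],
                                 accepted={"m.10A>G"}) for i in range(10)]
        r = cooccurrence(profiles, catalog)
        assert r.p_ge2 == 0.0
        assert r.expected_ge2 == 0.0

    def test_excess_direction_and_fold(self):
        profiles = self._cohort(100, 10, 20, 8)
        r = cooccurrence(profiles, CATALOG)
        assert r.observed_ge2 == 8
        assert r.direction == "excess"
        assert r.fold == pytest.approx(8 / r.expected_ge2)


class TestAssociationScan:
    def _cohort(self):
        profiles = []
        haplogroup_of = {}
        # variant m.10A>G: 10 carriers all in H1 (recurrent across H1+H2
        # needs >=2 haplogroups: put 9 in H1, 1 in H2)
        for i in range(60):
            hg = "H1" if i < 20 else ("H2" if i < 40 else "H3")
            carries = (i < 9) or (i == 25)
            profiles.append(
                make_profile(f"s{i}", ["m.10A>G"] if carries else [],
                             accepted={"m.10A>G"})
            )
            haplogroup_of[f"s{i}"] = hg
        return profiles, haplogroup_of

    def test_clustered_variant_flagged_at_its_haplogroup(self):
        profiles, hg = self._cohort()
        tests = association_scan(profiles, CATALOG, hg, raw_threshold=0.01)
        by_hg = {t.haplogroup: t for t in tests if t.key == "m.10A>G"}
        assert by_hg["H1"].p_raw == min(t.p_raw for t in by_hg.values())
        assert by_hg["H1"].significant
        assert all(t.p_bonferroni >= t.p_raw for t in tests)

    def test_uniform_variant_not_flagged(self):
        profiles = []
        hg = {}
        for i in range(60):
            hg[f"s{i}"] = ("H1", "H2", "H3")[i % 3]
            profiles.append(
                make_profile(f"s{i}", ["m.10A>G"] if i < 12 else [],
                             accepted={"m.10A>G"})
            )
        tests = association_scan(profiles, CATALOG, hg, raw_threshold=0.01)
        assert tests and not any(t.significant for t in tests)

    def test_no_recurrent_variants_empty_scan(self):
        profiles = [make_profile("s0", ["m.10A>G"], accepted={"m.10A>G"}),
                    make_profile("s1", [], accepted={"m.10A>G"})]
        hg = {"s0": "H1", "s1": "H2"}
        assert association_scan(profiles, CATALOG, hg) == []
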