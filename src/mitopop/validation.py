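"""Study-condition validation runs: oracle equivalences and recovery rates.

These functions execute the package's methods under its default study
conditions and measure how well known truth is recovered. They back both
the acceptance test suite and ``scripts/acceptance.py``; each returns
plain numbers computed at call time.

Problem sizes are desk-scale by design: cohorts of 300–1,000 sequences,
100–200 replicates, a 6 kb reference. The methods note discusses what
these sizes do and do not demonstrate.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from mitopop import haplo, popstats, sigdate, variantcall
from mitopop.synth import (
    CohortBundle,
    ReferenceBundle,
    SimulationConfig,
    simulate_cohort,
    simulate_reference,
)


def _sub_seed(seed: int, k: int) -> int:
    """Derived seed < 2^31, deterministic in (seed, k)."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------

def fisher_enumeration_error(max_total: int = 30) -> tuple[float, int]:
    """Max |p_implementation − p_enumeration| over every 2x2 table with
    positive margins and total ≤ ``max_total``.

    The oracle enumerates all tables with the observed margins and sums
    hypergeometric probabilities not exceeding the observed table's
    (with R's relative-error tie tolerance).
    """
    worst = 0.0
    n_tables = 0
    for total in range(1, max_total + 1):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                        continue
                    n_tables += 1
                    _, p_impl = popstats.fisher_2x2([[a, b], [c, d]])
                    r1, c1, n = a + b, a + c, total
                    lo = max(0, c1 - (n - r1))
                    hi = min(r1, c1)
                    ks = np.arange(lo, hi + 1)
                    pmf = stats.hypergeom.pmf(ks, n, c1, r1)
                    p_obs = pmf[a - lo]
                    p_oracle = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
                    worst = max(worst, abs(p_impl - min(1.0, p_oracle)))
    return worst, n_tables


def poisson_binomial_mc_max_z(
    seed: int, n_draws: int = 10 ** 6, max_len: int = 20, n_vectors: int = 3
) -> float:
    """Max |DP − Monte-Carlo| in Monte-Carlo standard errors for
    P(K ≥ 2) over random probability vectors."""
    rng = np.random.default_rng(_sub_seed(seed, 101))
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(2, max_len + 1))
        p = rng.uniform(0.0, 0.5, size=m)
        exact = popstats.prob_two_or_more(p)
        draws = rng.random((n_draws, m)) < p
        mc = float((draws.sum(axis=1) >= 2).mean())
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_draws)
        worst = max(worst, abs(exact - mc) / se)
    return worst


# ---------------------------------------------------------------------------
# Simulated-cohort recovery
# ---------------------------------------------------------------------------

def make_bundle(config: SimulationConfig) -> tuple[ReferenceBundle, CohortBundle]:
    bundle = simulate_reference(config)
    cohort = simulate_cohort(config, bundle, sequences=False)
    return bundle, cohort


def haplogroup_recovery_pct(seed: int, per_group: int = 300) -> tuple[float, int]:
    """% of simulated samples whose true leaf haplogroup is recovered by
    classification at zero marker dropout."""
    config = SimulationConfig(
        seed=_sub_seed(seed, 1),
        cohort_sizes={"L": per_group, "M": per_group, "N": per_group},
    )
    _, cohort = make_bundle(config)
    ok = sum(
        haplo.classify(set(st.variant_keys), cohort.tree).best_node == st.leaf
        for st in cohort.truth.samples.values()
    )
    n = len(cohort.truth.samples)
    return 100.0 * ok / n, n


def carrier_frequency_recovery(
    seed: int, per_group: int = 1000
) -> tuple[float, bool, int]:
    """Recovery of injected pathogenic carrier frequencies.

    Returns (fraction of injected (allele, group) pairs whose observed
    carrier count falls inside its exact binomial 99% CI, whether every
    pair falls inside the Bonferroni family-wise 99% band, number of
    pairs). Selection, dropout and ambiguity are off, so observed counts
    are exact binomial draws at the configured frequencies.
    """
    config = SimulationConfig(
        seed=_sub_seed(seed, 2),
        cohort_sizes={"L": per_group, "M": per_group, "N": per_group},
    )
    bundle, cohort = make_bundle(config)
    observed: dict[tuple[str, str], int] = {}
    for st in cohort.truth.samples.values():
        for key in st.pathogenic_keys:
            observed[(key, st.group)] = observed.get((key, st.group), 0) + 1
    pairs = [
        (spec.key, g, f)
        for spec in bundle.pathogenic
        for g, f in spec.carrier_freq.items()
        if f > 0
    ]
    n_pairs = len(pairs)
    alpha_fw = 0.01 / n_pairs
    in_99 = 0
    all_in_family = True
    for key, g, f in pairs:
        obs = observed.get((key, g), 0)
        lo, hi = stats.binom.ppf([0.005, 0.995], per_group, f)
        in_99 += lo <= obs <= hi
        lo_f, hi_f = stats.binom.ppf(
            [alpha_fw / 2, 1 - alpha_fw / 2], per_group, f
        )
        if not lo_f <= obs <= hi_f:
            all_in_family = False
    return in_99 / n_pairs, all_in_family, n_pairs


def rho_calibration(
    seed: int, lam: float = 3.0, n_replicates: int = 200, clade_size: int = 25
) -> tuple[float, float]:
    """Mean rho over replicate clades whose tips carry Poisson(lam)
    private mutations, and the 3-SE acceptance band half-width.

    Each replicate simulates one single-leaf clade (no age structure, no
    pathogenic alleles); rho is measured against the leaf's root
    haplotype so only private mutations contribute.
    """
    rhos = []
    for r in range(n_replicates):
        config = SimulationConfig(
            seed=_sub_seed(seed, 1000 + r),
            cohort_sizes={"L": clade_size},
            tree_depth=1,
            branching=1,
            private_mutation_rate=lam,
            old_age_multiplier=1.0,
            n_pathogenic=0,
            pathogenic_group_freq={},
        )
        _, cohort = make_bundle(config)
        by_leaf: dict[str, list[set[str]]] = {}
        for st in cohort.truth.samples.values():
            by_leaf.setdefault(st.leaf, []).append(set(st.variant_keys))
        (leaf, keys), = by_leaf.items()
        root = haplo.root_haplotype(cohort.tree, leaf)
        rhos.append(sigdate.rho(keys, root).rho)
    mean_rho = float(np.mean(rhos))
    # SE of the replicate mean: per-replicate Var(rho_hat) = lam / clade_size
    se = math.sqrt(lam / clade_size / n_replicates)
    return mean_rho, 3 * se


def cpg_null_pass_pct(
    seed: int, multiplier: float, n_replicates: int = 100, per_group: int = 100
) -> float:
    """% of replicate cohorts where the CpG enrichment Fisher test behaves
    as the generative model dictates.

    multiplier == 1: no enrichment, pass = p > 0.01;
    multiplier > 1: enrichment, pass = p <= 0.01 with CpG% above the
    context-availability baseline.
    """
    passed = 0
    for r in range(n_replicates):
        config = SimulationConfig(
            seed=_sub_seed(seed, 2000 + r),
            cohort_sizes={"L": per_group},
            tree_depth=3,
            cpg_transition_multiplier=multiplier,
            n_pathogenic=0,
            pathogenic_group_freq={},
        )
        bundle, cohort = make_bundle(config)
        ref = bundle.reference
        unique = [
            variantcall.Variant(*variantcall.parse_variant_key(k), "substitution")
            for k in cohort.truth.variants
        ]
        pct, baseline, p = sigdate.cpg_enrichment_test(unique, ref)
        if multiplier == 1.0:
            passed += p > 0.01
        else:
            passed += p <= 0.01 and pct > baseline
    return 100.0 * passed / n_replicates


def selection_direction_pct(
    seed: int,
    s: float = 0.8,
    n_replicates: int = 200,
    cohort_size: int = 1000,
) -> tuple[float, float]:
    """% of replicates where the Wilcoxon comparison of rho between
    disease-mutation carriers and non-carriers comes out in the right
    direction (carriers younger), and the % where it is additionally
    significant at p < 0.05.

    Each replicate simulates a cohort with purifying selection ``s``
    against carriers on the oldest half of clades, estimates rho per
    major clade, and assigns each sequence its clade's rho. With realistic
    low carrier frequencies (a few % per group) the direction is
    essentially always recovered while the per-replicate significance is
    power-limited by the ~30 carriers a cohort of 1,000 yields.
    """
    per_group = cohort_size // 3
    direction = detected = 0
    for r in range(n_replicates):
        config = SimulationConfig(
            seed=_sub_seed(seed, 3000 + r),
            cohort_sizes={"L": per_group, "M": per_group,
                          "N": cohort_size - 2 * per_group},
            selection_s=s,
        )
        bundle, cohort = make_bundle(config)
        tree = cohort.tree
        by_major: dict[str, list[str]] = {}
        for sid, st in cohort.truth.samples.items():
            major = tree.major_of(st.leaf)
            by_major.setdefault(major, []).append(sid)
        rho_of: dict[str, float] = {}
        for major, sids in by_major.items():
            root = haplo.root_haplotype(tree, major)
            est = sigdate.rho(
                [set(cohort.truth.samples[sid].variant_keys) for sid in sids],
                root,
                clade=major,
            )
            for sid in sids:
                rho_of[sid] = est.rho
        carrier = [
            rho_of[sid] for sid, st in cohort.truth.samples.items()
            if st.pathogenic_keys
        ]
        noncarrier = [
            rho_of[sid] for sid, st in cohort.truth.samples.items()
            if not st.pathogenic_keys
        ]
        if not carrier or not noncarrier:
            continue
        try:
            _, p = popstats.wilcoxon_rank(carrier, noncarrier)
        except ValueError:
            continue
        d = np.mean(carrier) < np.mean(noncarrier)
        direction += d
        detected += d and p < 0.05
    return 100.0 * direction / n_replicates, 100.0 * detected / n_replicates


def varcall_exactness_pct(
    seed: int, n_sequences: int = 1000, band: int = 16
) -> tuple[float, int]:
    """% of simulated sequences whose substitution set is recovered
    exactly by banded alignment + variant calling (zero ambiguity
    injection, so truth and calls must agree to the variant)."""
    per_group = n_sequences // 3
    config = SimulationConfig(
        seed=_sub_seed(seed, 4),
        cohort_sizes={"L": per_group, "M": per_group,
                      "N": n_sequences - 2 * per_group},
    )
    bundle = simulate_reference(config)
    cohort = simulate_cohort(config, bundle, sequences=True)
    ref = bundle.reference
    exact = 0
    for sid, seq in cohort.sequences:
        aln = variantcall.banded_global_align(seq, ref, sample_id=sid, band=band)
        keys = variantcall.substitution_keys(variantcall.call_variants(aln, ref))
        exact += keys == set(cohort.truth.samples[sid].variant_keys)
    return 100.0 * exact / len(cohort.sequences), len(cohort.sequences)
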