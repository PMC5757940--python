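"""Population statistics for mtDNA variant cohorts.

Carrier frequencies, quality-control correlations, group comparisons, the
co-occurrence model for genomes carrying two or more disease-causing
mutations, and the variant-by-haplogroup association scan.

Standard tests are delegated to scipy with the conventions the analyses
assume (two-sided Fisher by the R rule — sum of hypergeometric
probabilities not exceeding the observed table's; Welch's t;
Mann–Whitney/Wilcoxon rank test with tie and continuity corrections).

The co-occurrence model is this module's own: under the null that
disease-causing mutations arise independently on a genome, the number of
such mutations a sequence carries is Poisson-binomial over the
per-mutation carrier frequencies; the expectation of sequences with ≥2
mutations is ``n * P(K ≥ 2)``, computed by the exact dynamic program, and
observed-vs-expected significance comes from a Fisher test on the pseudo
2x2 table with the expectation rounded half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from mitopop.patho import SequenceProfile
from mitopop.refdata import DiseaseCatalog

#: R prints p-values below this as "< 2.2e-16"; reports follow suit while
#: every function returns full precision.
R_P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    return "< 2.2e-16" if p < R_P_FLOOR else f"{p:.4g}"


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlleleFrequency:
    group: str
    key: str
    carriers: int
    group_size: int

    @property
    def af(self) -> float:
        return self.carriers / self.group_size


def allele_frequencies(
    profiles: Sequence[SequenceProfile],
    grouping: Mapping[str, str] | None = None,
) -> dict[tuple[str, str], AlleleFrequency]:
    """Carrier frequency of every observed substitution per group.

    A sample carries a variant at most once (major alleles); a variant
    appears in the table only for groups where it was observed at least
    once, with frequency carriers/group size.
    """
    group_of = {
        p.sample_id: (grouping[p.sample_id] if grouping else p.macro)
        for p in profiles
    }
    sizes: dict[str, int] = {}
    for g in group_of.values():
        sizes[g] = sizes.get(g, 0) + 1
    for g, n in sizes.items():
        if n == 0:
            raise ValueError(f"empty group {g!r}")
    counts: dict[tuple[str, str], int] = {}
    for p in profiles:
        g = group_of[p.sample_id]
        for key in p.substitution_keys:
            counts[(g, key)] = counts.get((g, key), 0) + 1
    return {
        (g, k): AlleleFrequency(g, k, c, sizes[g])
        for (g, k), c in counts.items()
    }


def carrier_count(
    afs: Mapping[tuple[str, str], AlleleFrequency], group: str, key: str
) -> int:
    af = afs.get((group, key))
    return af.carriers if af else 0


def log2_af_ratio(
    carriers1: int, size1: int, carriers2: int, size2: int
) -> tuple[float, bool]:
    """log2 of the allele-frequency ratio between two groups.

    When either carrier count is zero the Haldane–Anscombe correction
    (+0.5 to all four 2x2 counts, i.e. AF = (c + 0.5)/(n + 1)) is applied;
    the second return value flags that correction.
    """
    if size1 <= 0 or size2 <= 0:
        raise ValueError("group sizes must be positive")
    corrected = carriers1 == 0 or carriers2 == 0
    if corrected:
        af1 = (carriers1 + 0.5) / (size1 + 1)
        af2 = (carriers2 + 0.5) / (size2 + 1)
    else:
        af1 = carriers1 / size1
        af2 = carriers2 / size2
    return math.log2(af1 / af2), corrected


# ---------------------------------------------------------------------------
# Classical tests (scipy-backed)
# ---------------------------------------------------------------------------

def pearson_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson correlation: (r, r², two-sided p).

    p comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.statistic) ** 2, float(res.pvalue)


def fisher_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test: (sample odds ratio, p).

    p follows the R convention: the sum of hypergeometric probabilities of
    all tables with the observed margins whose probability does not exceed
    the observed table's. The odds ratio is the unconditional sample OR
    (ad/bc), infinite when bc = 0.
    """
    ((a, b), (c, d)) = [[int(v) for v in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("zero margin in 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    oratio = math.inf if b * c == 0 else (a * d) / (b * c)
    return oratio, float(p)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test: (U of x, p).

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with tie and continuity corrections. Degenerate input
    (all pooled values identical) is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each sample needs n >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate input: all pooled values identical")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Poisson-binomial co-occurrence model
# ---------------------------------------------------------------------------

def poisson_binomial_pmf(p: Sequence[float]) -> np.ndarray:
    """Exact PMF of the number of successes among independent Bernoulli(p_i).

    Classic O(m²) dynamic program: fold each mutation's carrier
    probability into the distribution one at a time. Returns an array of
    length m+1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1:i + 2] = pmf[1:i + 2] * (1 - pi) + pmf[0:i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def prob_two_or_more(p: Sequence[float]) -> float:
    """P(K >= 2) for the Poisson-binomial count K over frequencies p."""
    p = np.asarray(p, dtype=float)
    if p.size < 2:
        return 0.0  # fewer than two events: K >= 2 impossible
    pmf = poisson_binomial_pmf(p)
    return float(min(1.0, max(0.0, 1.0 - pmf[0] - pmf[1])))


def _round_half_up(x: float) -> int:
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CooccurrenceResult:
    group: str
    n: int
    observed_ge2: int
    expected_ge2: float
    p_ge2: float          # model P(K>=2)
    fold: float           # signed: >1 means observed deficit (expected/observed)
    direction: str        # "deficit" | "excess" | "equal"
    p_value: float


def cooccurrence(
    profiles: Sequence[SequenceProfile],
    catalog: DiseaseCatalog,
    group: str = "",
) -> CooccurrenceResult:
    """Observed vs expected sequences with >= 2 disease-causing mutations.

    Per-mutation carrier frequencies are estimated within the group; under
    independence the expected count is ``n * P(K >= 2)`` from the exact
    Poisson-binomial. ``fold`` is expected/observed when observed <
    expected (a deficit, as reported for old macro-haplogroups) and
    observed/expected otherwise; the Fisher p compares observed and
    rounded-expected counts of ≥2-mutation sequences.
    """
    n = len(profiles)
    if n == 0:
        raise ValueError("empty group")
    accepted = sorted(catalog.accepted_keys)
    freqs = []
    for key in accepted:
        carriers = sum(1 for p in profiles if key in p.substitution_keys)
        if carriers:
            freqs.append(carriers / n)
    p_ge2 = prob_two_or_more(freqs)
    expected = n * p_ge2
    observed = sum(1 for p in profiles if p.disease_count >= 2)
    if observed == 0 and expected == 0:
        fold, direction, p_value = 1.0, "equal", 1.0
    else:
        exp_r = _round_half_up(expected)
        if observed <= expected:
            fold = expected / observed if observed else math.inf
            direction = "deficit" if observed < expected else "equal"
        else:
            fold = observed / expected if expected else math.inf
            direction = "excess"
        if observed == exp_r:
            p_value = 1.0  # identical pseudo-table rows (incl. both zero)
        else:
            _, p_value = fisher_2x2(
                [[observed, n - observed], [exp_r, n - exp_r]]
            )
    return CooccurrenceResult(
        group=group, n=n, observed_ge2=observed, expected_ge2=expected,
        p_ge2=p_ge2, fold=fold, direction=direction, p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Haplogroup association scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationTest:
    key: str
    haplogroup: str
    carriers_in: int
    noncarriers_in: int
    carriers_out: int
    noncarriers_out: int
    odds_ratio: float
    p_raw: float
    p_bonferroni: float
    significant: bool


def association_scan(
    profiles: Sequence[SequenceProfile],
    catalog: DiseaseCatalog,
    haplogroup_of: Mapping[str, str],
    raw_threshold: float = 0.01,
) -> list[AssociationTest]:
    """Scan recurrent disease-causing mutations for haplogroup clustering.

    A mutation is *recurrent* when observed on >= 2 haplogroups (at the
    level encoded by ``haplogroup_of``). For each recurrent mutation and
    each haplogroup, a Fisher 2x2 of carrier status x membership gives a
    raw p; Bonferroni adjusts over all (mutation, haplogroup) tests in the
    scan, and ``significant`` flags raw p below the configured threshold
    (the reporting convention for this scan).
    """
    groups = sorted(set(haplogroup_of.values()))
    accepted = sorted(catalog.accepted_keys)
    carriers_by_key: dict[str, set[str]] = {}
    for p in profiles:
        hg = haplogroup_of.get(p.sample_id)
        if hg is None:
            continue
        for key in p.substitution_keys:
            if key in catalog.accepted_keys:
                carriers_by_key.setdefault(key, set()).add(p.sample_id)
    recurrent = [
        key for key in accepted
        if len({haplogroup_of[s] for s in carriers_by_key.get(key, ())}) >= 2
    ]
    members: dict[str, set[str]] = {g: set() for g in groups}
    for sid, g in haplogroup_of.items():
        members[g].add(sid)
    total = len(haplogroup_of)
    tests: list[AssociationTest] = []
    n_tests = len(recurrent) * len(groups)
    for key in recurrent:
        carriers = carriers_by_key[key]
        for g in groups:
            a = len(carriers & members[g])
            b = len(carriers) - a
            c = len(members[g]) - a
            d = total - a - b - c
            oratio, p = fisher_2x2([[a, b], [c, d]])
            tests.append(
                AssociationTest(
                    key=key, haplogroup=g,
                    carriers_in=a, carriers_out=b,
                    noncarriers_in=c, noncarriers_out=d,
                    odds_ratio=oratio, p_raw=p,
                    p_bonferroni=min(1.0, p * n_tests),
                    significant=p < raw_threshold,
                )
            )
    return tests


def recurrence_summary(
    profiles: Sequence[SequenceProfile],
    catalog: DiseaseCatalog,
    level_of: Mapping[str, str],
) -> dict[str, object]:
    """How many accepted mutations observed in the cohort recur across the
    groups of a haplogroup level (and how many are group-private)."""
    carriers_groups: dict[str, set[str]] = {}
    for p in profiles:
        g = level_of.get(p.sample_id)
        if g is None:
            continue
        for key in p.substitution_keys & catalog.accepted_keys:
            carriers_groups.setdefault(key, set()).add(g)
    observed = len(carriers_groups)
    shared = sum(1 for gs in carriers_groups.values() if len(gs) >= 2)
    return {
        "observed_mutations": observed,
        "shared": shared,
        "private": observed - shared,
    }


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def write_af_table(
    path: str | Path, afs: Mapping[tuple[str, str], AlleleFrequency]
) -> None:
    with open(path, "w") as fh:
        fh.write("group\tkey\tcarriers\tgroup_size\taf\n")
        for (g, k), af in sorted(afs.items()):
            fh.write(f"{g}\t{k}\t{af.carriers}\t{af.group_size}\t{af.af:.6g}\n")


def write_scan(path: str | Path, tests: Iterable[AssociationTest]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "key\thaplogroup\tcarriers_in\tcarriers_out\tnoncarriers_in\t"
            "noncarriers_out\todds_ratio\tp_raw\tp_bonferroni\tsignificant\n"
        )
        for t in tests:
            fh.write(
                f"{t.key}\t{t.haplogroup}\t{t.carriers_in}\t{t.carriers_out}"
                f"\t{t.noncarriers_in}\t{t.noncarriers_out}\t"
                f"{t.odds_ratio:.4g}\t{format_p(t.p_raw)}\t"
                f"{format_p(t.p_bonferroni)}\t{int(t.significant)}\n"
            )
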