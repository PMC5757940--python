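"""Mutational signatures, CpG statistics, and rho-based clade dating.

**96-class signature.** Every substitution is mapped to the pyrimidine
strand: a change at a purine reference base (A or G) is reverse
complemented — ref, alt and both flanking bases — so the six
distinguishable substitution types are C>A, C>G, C>T, T>A, T>C and T>G.
Combined with the 4 x 4 possible 5'/3' reference contexts this yields the
standard 96 trinucleotide classes.

**CpG.** A variant is "at a CpG" when its reference position lies in a
5'-CG-3' dinucleotide on either strand of the circular reference (the
position is the C of a CG, or the G — i.e. the C of the reverse-strand
CG). CpG transitions arise from deamination of methylated cytosine and
run an order of magnitude hotter than other sites.

**Rho dating.** The age proxy of a clade is rho: the mean number of
substitutions separating each member from the clade's root haplotype,
counted as the symmetric difference of variant-key sets so that back
mutations count once. The heuristic standard error is
``sigma = sqrt(rho / n)`` under a star genealogy, or the
genealogy-weighted form ``sigma² = (1/n²) · Σ_b m_b · n_b²`` (branch b
carrying m_b mutations above n_b descendant tips) when a genealogy is
estimated; here the genealogy is the trivial one obtained by pooling
variants with identical carrier sets into one branch. No conversion to
calendar years is performed — rho is reported in mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from mitopop.patho import SequenceProfile, main_pathogenic_allele, mean_pathogenicity
from mitopop.popstats import pearson_r2, wilcoxon_rank, fisher_2x2
from mitopop.refdata import ReferenceGenome
from mitopop.variantcall import Variant, parse_variant_key

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Class labels in canonical order: substitution-major, then 5' base, then
#: 3' base, e.g. ``A[C>A]A, A[C>A]C, ...``.
CLASS_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)


def class_index(ref: str, alt: str, context5: str, context3: str) -> int:
    """96-class index of a substitution, collapsing to the pyrimidine strand."""
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        context5, context3 = _COMP[context3], _COMP[context5]
    sub = f"{ref}>{alt}"
    return (
        SUBSTITUTION_CLASSES.index(sub) * 16
        + BASES.index(context5) * 4
        + BASES.index(context3)
    )


@dataclass
class SignatureSpectrum:
    counts: np.ndarray           # length 96, nonnegative ints
    reference_used: str

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray | None:
        """Counts normalized to sum 1; None (undefined) for an empty spectrum."""
        t = self.total
        return self.counts / t if t else None

    def by_substitution(self) -> dict[str, float]:
        """Relative frequency of the six substitution types."""
        t = self.total
        if not t:
            return {s: 0.0 for s in SUBSTITUTION_CLASSES}
        return {
            s: float(self.counts[i * 16:(i + 1) * 16].sum()) / t
            for i, s in enumerate(SUBSTITUTION_CLASSES)
        }


def spectrum_96(
    variants: Iterable[Variant], reference_used: str = "rCRS-like"
) -> SignatureSpectrum:
    """Bin substitutions (with reference context) into the 96 classes.

    Non-substitution records are ignored; a substitution lacking context
    is an error since its class is undefined.
    """
    counts = np.zeros(96, dtype=np.int64)
    for v in variants:
        if v.kind != "substitution":
            continue
        if not v.context5 or not v.context3:
            raise ValueError(f"substitution {v.key} lacks flanking context")
        counts[class_index(v.ref, v.alt, v.context5, v.context3)] += 1
    return SignatureSpectrum(counts=counts, reference_used=reference_used)


# ---------------------------------------------------------------------------
# CpG
# ---------------------------------------------------------------------------

def is_cpg_position(ref: ReferenceGenome, position: int) -> bool:
    """True when the position lies in a CG dinucleotide on either strand
    (circular): it is the C of a CG, or the G following a C."""
    b = ref.base(position)
    if b == "C":
        return ref.base(position + 1 if position < ref.length else 1) == "G"
    if b == "G":
        return ref.base(position - 1 if position > 1 else ref.length) == "C"
    return False


@dataclass(frozen=True)
class CpGStats:
    n_total: int
    n_cpg: int
    n_cpg_c_to_t: int   # CpG variants that are C:G>T:A transitions

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def percent(self) -> float:
        """CpG% with all CpG-site variants in the numerator."""
        if not self.defined:
            raise ValueError("CpG% undefined for an empty variant set")
        return 100.0 * self.n_cpg / self.n_total

    @property
    def percent_c_to_t(self) -> float:
        """CpG% restricted to C:G>T:A transitions at CpG sites."""
        if not self.defined:
            raise ValueError("CpG% undefined for an empty variant set")
        return 100.0 * self.n_cpg_c_to_t / self.n_total


def cpg_fraction(
    variants: Iterable[Variant], ref: ReferenceGenome
) -> CpGStats:
    """CpG statistics of a substitution set (both numerator definitions)."""
    n_total = n_cpg = n_ct = 0
    for v in variants:
        if v.kind != "substitution":
            continue
        n_total += 1
        if is_cpg_position(ref, v.position):
            n_cpg += 1
            if (v.ref, v.alt) in (("C", "T"), ("G", "A")):
                n_ct += 1
    return CpGStats(n_total=n_total, n_cpg=n_cpg, n_cpg_c_to_t=n_ct)


def cpg_context_fraction(ref: ReferenceGenome) -> float:
    """Fraction of reference positions lying in a CpG dinucleotide —
    the availability baseline for enrichment tests."""
    n = sum(1 for pos in range(1, ref.length + 1) if is_cpg_position(ref, pos))
    return n / ref.length


def cpg_enrichment_test(
    variants: Iterable[Variant], ref: ReferenceGenome
) -> tuple[float, float, float]:
    """Fisher test of variant CpG% against reference context availability.

    Returns (CpG% of variants, baseline %, two-sided p) comparing the
    variant set's CpG/non-CpG split to the reference's position split.
    """
    st = cpg_fraction(variants, ref)
    if not st.defined:
        raise ValueError("empty variant set")
    ref_cpg = sum(
        1 for pos in range(1, ref.length + 1) if is_cpg_position(ref, pos)
    )
    _, p = fisher_2x2(
        [[st.n_cpg, st.n_total - st.n_cpg],
         [ref_cpg, ref.length - ref_cpg]]
    )
    return st.percent, 100.0 * ref_cpg / ref.length, p


# ---------------------------------------------------------------------------
# Rho dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhoEstimate:
    clade: str
    n: int
    rho: float
    sigma: float
    genealogy_mode: str  # "star" | "parsimony-tree"


def rho(
    clade_keys: Sequence[set[str] | frozenset[str]],
    root_haplotype: set[str],
    mode: str = "star",
    clade: str = "",
) -> RhoEstimate:
    """Rho and its heuristic standard error for one clade.

    ``clade_keys`` holds each member's substitution-key set; the distance
    of a member is the size of its symmetric difference with the root
    haplotype. Modes: ``star`` (sigma = sqrt(rho/n)) or
    ``parsimony-tree`` (branches from pooling identical carrier sets,
    sigma² = Σ m_b·n_b² / n²).
    """
    if mode not in ("star", "parsimony-tree"):
        raise ValueError(f"unknown genealogy mode {mode!r}")
    n = len(clade_keys)
    if n == 0:
        raise ValueError("empty clade")
    diffs = [set(keys) ^ root_haplotype for keys in clade_keys]
    distances = [len(d) for d in diffs]
    rho_hat = sum(distances) / n
    if mode == "star":
        sigma = math.sqrt(rho_hat / n)
    else:
        carriers: dict[str, list[int]] = {}
        for i, d in enumerate(diffs):
            for key in d:
                carriers.setdefault(key, []).append(i)
        branches: dict[frozenset[int], int] = {}
        for key, tip_list in carriers.items():
            b = frozenset(tip_list)
            branches[b] = branches.get(b, 0) + 1
        sigma = math.sqrt(
            sum(m_b * len(b) ** 2 for b, m_b in branches.items()) / n ** 2
        )
    return RhoEstimate(clade=clade, n=n, rho=rho_hat, sigma=sigma,
                       genealogy_mode=mode)


def clade_rho_per_sample(
    profiles: Sequence[SequenceProfile],
    clade_of: Mapping[str, str],
    root_haplotypes: Mapping[str, set[str]],
    mode: str = "star",
) -> tuple[dict[str, RhoEstimate], dict[str, float]]:
    """Rho per clade plus the per-sample lookup (each sequence inherits the
    rho of its clade)."""
    members: dict[str, list[SequenceProfile]] = {}
    for p in profiles:
        clade = clade_of.get(p.sample_id)
        if clade is not None:
            members.setdefault(clade, []).append(p)
    estimates = {
        clade: rho(
            [p.substitution_keys for p in ps],
            root_haplotypes.get(clade, set()),
            mode=mode,
            clade=clade,
        )
        for clade, ps in members.items()
    }
    per_sample = {
        p.sample_id: estimates[clade_of[p.sample_id]].rho
        for p in profiles if clade_of.get(p.sample_id) in estimates
    }
    return estimates, per_sample


@dataclass(frozen=True)
class AgeAssociation:
    n_carriers: int
    n_noncarriers: int
    carrier_mean_rho: float
    noncarrier_mean_rho: float
    carriers_younger: bool
    wilcoxon_w: float
    wilcoxon_p: float
    score_rho_r: float
    score_rho_p: float
    score_rho_r_excl: float | None
    score_rho_p_excl: float | None


def age_pathogenicity_association(
    profiles: Sequence[SequenceProfile],
    rho_of: Mapping[str, float],
) -> AgeAssociation:
    """Relate sequence age (clade rho) to pathogenicity.

    Wilcoxon rank test compares rho between disease-mutation carriers and
    non-carriers; Pearson correlation relates per-sequence mean
    pathogenicity to rho, once as-is and once after removing each
    sequence's main (highest-scored) pathogenic allele in silico. Raises
    on degenerate input (one group empty, or constant rho).
    """
    carrier_rho, noncarrier_rho = [], []
    xs, ys = [], []
    xs_ex, ys_ex = [], []
    for p in profiles:
        r = rho_of.get(p.sample_id)
        if r is None:
            continue
        (carrier_rho if p.disease_count > 0 else noncarrier_rho).append(r)
        ms = p.mean_score
        if ms is not None:
            xs.append(ms)
            ys.append(r)
        main = main_pathogenic_allele(p)
        ms_ex = mean_pathogenicity(p, exclude=main) if main else ms
        if ms_ex is not None:
            xs_ex.append(ms_ex)
            ys_ex.append(r)
    if not carrier_rho or not noncarrier_rho:
        raise ValueError("one of the carrier/non-carrier groups is empty")
    w, wp = wilcoxon_rank(carrier_rho, noncarrier_rho)
    r_, _, p_ = pearson_r2(xs, ys)
    try:
        r_ex, _, p_ex = pearson_r2(xs_ex, ys_ex)
    except ValueError:
        r_ex = p_ex = None
    return AgeAssociation(
        n_carriers=len(carrier_rho),
        n_noncarriers=len(noncarrier_rho),
        carrier_mean_rho=float(np.mean(carrier_rho)),
        noncarrier_mean_rho=float(np.mean(noncarrier_rho)),
        carriers_younger=float(np.mean(carrier_rho)) < float(np.mean(noncarrier_rho)),
        wilcoxon_w=w,
        wilcoxon_p=wp,
        score_rho_r=r_,
        score_rho_p=p_,
        score_rho_r_excl=r_ex,
        score_rho_p_excl=p_ex,
    )


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------

def write_spectrum(path: str | Path, spectrum: SignatureSpectrum) -> None:
    freqs = spectrum.frequencies
    with open(path, "w") as fh:
        fh.write(f"# 96-class spectrum; reference = {spectrum.reference_used}\n")
        fh.write("class\tfive_prime\tthree_prime\tcount\tfrequency\n")
        for i, label in enumerate(CLASS_LABELS):
            freq = "" if freqs is None else f"{freqs[i]:.6f}"
            fh.write(
                f"{label}\t{label[0]}\t{label[-1]}\t{int(spectrum.counts[i])}"
                f"\t{freq}\n"
            )


def write_rho(path: str | Path, estimates: Iterable[RhoEstimate]) -> None:
    with open(path, "w") as fh:
        fh.write("clade\tn\trho\tsigma\tgenealogy_mode\n")
        for e in estimates:
            fh.write(
                f"{e.clade}\t{e.n}\t{e.rho:.4f}\t{e.sigma:.4f}\t"
                f"{e.genealogy_mode}\n"
            )
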