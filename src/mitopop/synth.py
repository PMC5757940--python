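"""Synthetic mitogenome cohorts with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at desk scale:

* a circular random reference with in-frame protein genes (optionally one
  overlapping pair in different reading frames, as in real mtDNA), tRNA
  genes and a gene-free control region;
* a pathogenicity score table covering *every* possible non-synonymous
  substitution in gene space (scores ~ Beta), plus per-position tRNA
  scores, so lookups never silently miss;
* a rooted haplogroup tree — one macro node per cohort group, each
  carrying a balanced subtree — whose branches carry defining marker
  substitutions;
* sample sequences evolved by (i) inheriting the root→leaf markers,
  (ii) adding Poisson-distributed private mutations placed under a
  context-dependent substitution model (transitions favoured by the
  Ti/Tv ratio; CpG-site transitions further multiplied), with leaves in
  the *oldest half* of each macro clade drawing private mutations at
  twice the base rate so clades have distinguishable rho ages;
* pathogenic alleles injected per group at configured carrier
  frequencies, with an optional purifying-selection knob ``s`` that
  converts carriers on old clades back to non-carriers with probability
  ``s``;
* optional marker dropout and IUPAC-ambiguity injection to exercise the
  QC paths.

Mutations never recur within a lineage (infinite sites along one
root→leaf+private history) but the same pathogenic variant is injected
across lineages and groups, producing the recurrent mutations the
association analyses need. All randomness flows from the single config
seed; identical configs give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mitopop.haplo import HaploTree
from mitopop.refdata import (
    CatalogEntry,
    DiseaseCatalog,
    GeneAnnotation,
    ReferenceGenome,
    ScoreTable,
)
from mitopop.patho import classify_ns_s
from mitopop.sigdate import class_index, is_cpg_position
from mitopop.variantcall import Variant, parse_variant_key

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"
# IUPAC code for an unordered base pair
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PathogenicSpec:
    """One injected pathogenic allele: key, per-group carrier frequency,
    and its pathogenicity score (overrides the score table)."""

    key: str
    carrier_freq: Mapping[str, float]
    score: float


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the package's study conditions.

    Defaults give a 6 kb circular reference with four 900 b protein genes,
    one overlapping 300 b pair, four tRNAs; a depth-4 binary tree per
    macro group (16 leaves each) with 3 markers per branch; 300 sequences
    per group; mtDNA-like Ti/Tv of 20 with CpG transitions 5x hotter; a
    mean of 3 private mutations per lineage (doubled on the oldest half of
    clades); and six pathogenic alleles whose per-group total carrier
    frequencies mirror a low-/mid-/mid-prevalence three-group cohort.
    """

    seed: int = 0
    reference_length: int = 6000
    n_protein_genes: int = 4
    protein_gene_length: int = 900
    include_overlapping_pair: bool = True
    n_trna_genes: int = 4
    trna_gene_length: int = 70
    tree_depth: int = 4
    branching: int = 2
    markers_per_branch: int = 3
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"L": 300, "M": 300, "N": 300}
    )
    private_mutation_rate: float = 3.0
    old_age_multiplier: float = 2.0
    cpg_transition_multiplier: float = 5.0
    ti_tv_ratio: float = 20.0
    n_pathogenic: int = 6
    pathogenic_group_freq: Mapping[str, float] = field(
        default_factory=lambda: {"L": 0.022, "M": 0.078, "N": 0.052}
    )
    pathogenic: Sequence[PathogenicSpec] | None = None
    selection_s: float = 0.0
    marker_dropout: float = 0.0
    ambiguity_rate: float = 0.0
    score_beta: tuple[float, float] = (2.0, 3.0)
    trna_score_beta: tuple[float, float] = (1.0, 9.0)
    pathogenic_score_beta: tuple[float, float] = (5.0, 2.0)

    def __post_init__(self) -> None:
        for name, v in (
            ("selection_s", self.selection_s),
            ("marker_dropout", self.marker_dropout),
            ("ambiguity_rate", self.ambiguity_rate),
        ):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.cpg_transition_multiplier < 1.0:
            raise ConfigError("cpg_transition_multiplier must be >= 1")
        if any(n <= 0 for n in self.cohort_sizes.values()):
            raise ConfigError("cohort sizes must be positive")
        if self.protein_gene_length % 3:
            raise ConfigError("protein_gene_length must be divisible by 3")
        for f in self.pathogenic_group_freq.values():
            if not 0.0 <= f <= 1.0:
                raise ConfigError("pathogenic group frequencies must be in [0,1]")


@dataclass
class ReferenceBundle:
    reference: ReferenceGenome
    score_table: ScoreTable
    catalog: DiseaseCatalog
    pathogenic: list[PathogenicSpec]


@dataclass
class SampleTruth:
    sample_id: str
    group: str
    leaf: str
    age_rank: int
    old: bool
    variant_keys: frozenset[str]
    pathogenic_keys: frozenset[str]
    ambiguous_positions: tuple[int, ...]


@dataclass
class VariantTruth:
    key: str
    group_counts: dict[str, int]
    context_class: int
    cpg: bool


@dataclass
class TruthTable:
    samples: dict[str, SampleTruth]
    variants: dict[str, VariantTruth]


@dataclass
class CohortBundle:
    tree: HaploTree
    sequences: list[tuple[str, str]]
    truth: TruthTable
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Reference, score table, catalog
# ---------------------------------------------------------------------------

def _lay_genes(config: SimulationConfig) -> list[GeneAnnotation]:
    genes = []
    cursor = 101
    for i in range(config.n_protein_genes):
        end = cursor + config.protein_gene_length - 1
        genes.append(GeneAnnotation(f"PG{i + 1}", cursor, end, "+", "protein", 0))
        cursor = end + 31
    if config.include_overlapping_pair:
        # two 300 b genes offset by 151 b: overlap in different frames
        genes.append(GeneAnnotation("OLA", cursor, cursor + 299, "+", "protein", 0))
        genes.append(
            GeneAnnotation("OLB", cursor + 151, cursor + 450, "+", "protein", 0)
        )
        cursor = cursor + 481
    for i in range(config.n_trna_genes):
        end = cursor + config.trna_gene_length - 1
        genes.append(GeneAnnotation(f"TRN{i + 1}", cursor, end, "+", "tRNA", 0))
        cursor = end + 31
    if cursor > config.reference_length - 50:
        raise ConfigError(
            f"gene layout needs {cursor} bases but reference has only "
            f"{config.reference_length}"
        )
    return genes


def simulate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Random circular reference + annotation + complete score table +
    disease catalog, all deterministic in ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[0])
    seq = "".join(rng.choice(list(_BASES), size=config.reference_length))
    ref = ReferenceGenome("synthref", seq, _lay_genes(config))

    protein_scores: dict[tuple[str, int, str, str], float] = {}
    ns_keys: list[tuple[str, float]] = []  # (variant key, placeholder)
    for gene in ref.genes:
        if gene.kind != "protein":
            continue
        for pos in gene.positions(ref.length):
            refb = ref.base(pos)
            for alt in _BASES:
                if alt == refb:
                    continue
                v = Variant(pos, refb, alt, "substitution")
                for hit in classify_ns_s(v, ref):
                    if hit.gene != gene.gene or not hit.ns_flag:
                        continue
                    key = (hit.gene, hit.aa_position, hit.ref_aa, hit.alt_aa)
                    if key not in protein_scores:
                        protein_scores[key] = float(
                            rng.beta(*config.score_beta)
                        )
    trna_scores: dict[tuple[int, str], float] = {}
    for gene in ref.genes:
        if gene.kind != "tRNA":
            continue
        for pos in gene.positions(ref.length):
            refb = ref.base(pos)
            for alt in _BASES:
                if alt != refb:
                    trna_scores[(pos, alt)] = float(
                        rng.beta(*config.trna_score_beta)
                    )

    pathogenic = list(config.pathogenic) if config.pathogenic else None
    if pathogenic is None:
        pathogenic = _draw_pathogenic(config, ref, rng)
    # pathogenic alleles override their table entries with a high score
    for spec in pathogenic:
        pos, refb, alt = parse_variant_key(spec.key)
        v = Variant(pos, refb, alt, "substitution")
        for hit in classify_ns_s(v, ref):
            if hit.ns_flag:
                protein_scores[
                    (hit.gene, hit.aa_position, hit.ref_aa, hit.alt_aa)
                ] = spec.score

    table = ScoreTable(protein_scores, trna_scores)
    entries = [
        CatalogEntry(spec.key, _gene_of(ref, spec.key), True, False)
        for spec in pathogenic
    ]
    # decoy candidates that failed curation, plus one unusable indel entry
    decoys = 0
    while decoys < 3:
        key = _draw_ns_key(config, ref, rng)
        if key not in {e.key for e in entries}:
            entries.append(CatalogEntry(key, _gene_of(ref, key), False, False))
            decoys += 1
    entries.append(CatalogEntry("m.50delA", "-", True, False, usable=False))
    return ReferenceBundle(
        reference=ref,
        score_table=table,
        catalog=DiseaseCatalog(entries),
        pathogenic=pathogenic,
    )


def _gene_of(ref: ReferenceGenome, key: str) -> str:
    pos, _, _ = parse_variant_key(key)
    genes = ref.genes_at(pos)
    return genes[0].gene if genes else "-"


def _draw_ns_key(
    config: SimulationConfig, ref: ReferenceGenome, rng: np.random.Generator
) -> str:
    """A random substitution key that is non-synonymous in >= 1 gene."""
    protein_pos = [
        p for g in ref.genes if g.kind == "protein"
        for p in g.positions(ref.length)
    ]
    while True:
        pos = int(rng.choice(protein_pos))
        refb = ref.base(pos)
        alt = str(rng.choice([b for b in _BASES if b != refb]))
        v = Variant(pos, refb, alt, "substitution")
        if any(h.ns_flag for h in classify_ns_s(v, ref)):
            return v.key


def _draw_pathogenic(
    config: SimulationConfig, ref: ReferenceGenome, rng: np.random.Generator
) -> list[PathogenicSpec]:
    specs: list[PathogenicSpec] = []
    used_pos: set[int] = set()
    per_variant = {
        g: f / config.n_pathogenic
        for g, f in config.pathogenic_group_freq.items()
    }
    while len(specs) < config.n_pathogenic:
        key = _draw_ns_key(config, ref, rng)
        pos, _, _ = parse_variant_key(key)
        if pos in used_pos:
            continue
        used_pos.add(pos)
        specs.append(
            PathogenicSpec(
                key=key,
                carrier_freq=dict(per_variant),
                score=float(rng.beta(*config.pathogenic_score_beta)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Mutation model
# ---------------------------------------------------------------------------

class _MutationModel:
    """Context-dependent substitution sampler over the reference.

    Site weight = P(transition)·m_p + P(transversion), where m_p is the
    CpG multiplier at CpG sites and 1 elsewhere; given the site, the
    mutation is a transition with probability P(ts)·m_p / weight.
    """

    def __init__(self, ref: ReferenceGenome, config: SimulationConfig) -> None:
        self.ref = ref
        n = ref.length
        r = config.ti_tv_ratio
        p_ts = r / (r + 1.0)
        self.cpg = np.array(
            [is_cpg_position(ref, p) for p in range(1, n + 1)], dtype=bool
        )
        mult = np.where(self.cpg, config.cpg_transition_multiplier, 1.0)
        self.p_ts_site = p_ts * mult / (p_ts * mult + (1 - p_ts))
        weights = p_ts * mult + (1 - p_ts)
        self.cum = np.cumsum(weights)
        self.total = self.cum[-1]

    def draw(self, rng: np.random.Generator, exclude: set[int]) -> Variant:
        """One substitution at a position not in ``exclude`` (1-based)."""
        while True:
            pos = int(
                np.searchsorted(self.cum, rng.random() * self.total, side="right")
            ) + 1
            if pos in exclude:
                continue
            refb = self.ref.base(pos)
            if rng.random() < self.p_ts_site[pos - 1]:
                alt = _TRANSITION[refb]
            else:
                choices = [
                    b for b in _BASES if b != refb and b != _TRANSITION[refb]
                ]
                alt = choices[int(rng.integers(2))]
            return Variant(pos, refb, alt, "substitution")


# ---------------------------------------------------------------------------
# Tree and cohort
# ---------------------------------------------------------------------------

def _build_tree(
    config: SimulationConfig,
    model: _MutationModel,
    rng: np.random.Generator,
    reserved: set[int] = frozenset(),
) -> HaploTree:
    """Balanced marker tree: ROOT → one macro node per group → binary
    subtrees of the configured depth, every edge carrying fresh markers
    not reused along its own root path (infinite sites within lineage).

    ``reserved`` positions (the pathogenic alleles') never become markers,
    so injected carrier frequencies stay exactly as configured.
    """
    nodes: dict[str, tuple[str | None, tuple[str, ...]]] = {"ROOT": (None, ())}
    macro, major = [], []

    def edge_markers(path_positions: set[int]) -> tuple[str, ...]:
        markers = []
        for _ in range(config.markers_per_branch):
            v = model.draw(rng, path_positions | set(reserved))
            path_positions.add(v.position)
            markers.append(v.key)
        return tuple(markers)

    def grow(name: str, parent: str, depth: int, path_positions: set[int]):
        nodes[name] = (parent, edge_markers(path_positions))
        if depth < config.tree_depth:
            for i in range(config.branching):
                grow(f"{name}{i}", name, depth + 1, set(path_positions))

    for group in sorted(config.cohort_sizes):
        macro.append(group)
        grow(group, "ROOT", 0, set())
        for i in range(config.branching):
            major.append(f"{group}{i}")
    return HaploTree(nodes, macro_nodes=macro, major_nodes=major)


def simulate_cohort(
    config: SimulationConfig,
    bundle: ReferenceBundle,
    sequences: bool = True,
) -> CohortBundle:
    """Realize the haplogroup tree and evolve one cohort under it.

    Returns the tree, per-sample FASTA records (when ``sequences``) and
    the truth table. Re-deriving variants from the emitted FASTA
    reproduces ``truth.samples[*].variant_keys`` exactly when the
    ambiguity-injection rate is 0.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    ref = bundle.reference
    model = _MutationModel(ref, config)
    reserved = {
        parse_variant_key(spec.key)[0] for spec in bundle.pathogenic
    }
    tree = _build_tree(config, model, rng, reserved=reserved)

    # leaves of each macro group, with age ranks (rank 0 = oldest)
    leaves_of: dict[str, list[str]] = {}
    for group in sorted(config.cohort_sizes):
        leaves = sorted(
            leaf for leaf in tree.leaves if tree.macro_of(leaf) == group
        )
        leaves_of[group] = leaves

    samples: dict[str, SampleTruth] = {}
    seqs: list[tuple[str, str]] = []
    counts: dict[str, dict[str, int]] = {}
    sid_no = 0
    for group in sorted(config.cohort_sizes):
        n = config.cohort_sizes[group]
        leaves = leaves_of[group]
        n_old = len(leaves) // 2
        for _ in range(n):
            sid_no += 1
            sid = f"S{sid_no:05d}"
            leaf_idx = int(rng.integers(len(leaves)))
            leaf = leaves[leaf_idx]
            old = leaf_idx < n_old
            markers = tree.expected_markers(leaf)
            kept: dict[int, str] = {}
            for mk in markers:
                if config.marker_dropout and rng.random() < config.marker_dropout:
                    continue
                pos, _, alt = parse_variant_key(mk)
                kept[pos] = mk
            occupied = {parse_variant_key(m)[0] for m in markers}

            # pathogenic injection (before privates, so privates avoid them)
            patho_keys: set[str] = set()
            for spec in bundle.pathogenic:
                f = spec.carrier_freq.get(group, 0.0)
                if f and rng.random() < f:
                    pos, _, _ = parse_variant_key(spec.key)
                    if pos in occupied:
                        continue  # infinite-sites collision: skip injection
                    patho_keys.add(spec.key)
                    occupied.add(pos)
            # purifying selection on old clades
            if old and patho_keys and config.selection_s:
                if rng.random() < config.selection_s:
                    for k in patho_keys:
                        occupied.discard(parse_variant_key(k)[0])
                    patho_keys = set()

            lam = config.private_mutation_rate * (
                config.old_age_multiplier if old else 1.0
            )
            # privates avoid pathogenic sites entirely: those positions
            # mutate only by injection, keeping configured carrier
            # frequencies exact (carrier <=> injected)
            n_private = int(rng.poisson(lam))
            private_keys: set[str] = set()
            for _ in range(n_private):
                v = model.draw(rng, occupied | reserved)
                occupied.add(v.position)
                private_keys.add(v.key)

            keys = frozenset(kept.values()) | patho_keys | private_keys
            amb_positions: tuple[int, ...] = ()
            if sequences or config.ambiguity_rate:
                base = list(ref.sequence)
                for key in keys:
                    pos, _, alt = parse_variant_key(key)
                    base[pos - 1] = alt
                if config.ambiguity_rate:
                    k_amb = rng.binomial(ref.length, config.ambiguity_rate)
                    amb_pos = rng.choice(ref.length, size=k_amb, replace=False)
                    amb_positions = tuple(int(p) + 1 for p in sorted(amb_pos))
                    for p0 in amb_positions:
                        cur = base[p0 - 1]
                        other = _BASES[int(rng.integers(4))]
                        while other == cur:
                            other = _BASES[int(rng.integers(4))]
                        base[p0 - 1] = _PAIR_CODE[frozenset((cur, other))]
                if sequences:
                    seqs.append((sid, "".join(base)))

            samples[sid] = SampleTruth(
                sample_id=sid, group=group, leaf=leaf,
                age_rank=leaf_idx, old=old,
                variant_keys=frozenset(keys),
                pathogenic_keys=frozenset(patho_keys),
                ambiguous_positions=amb_positions,
            )
            for key in keys:
                counts.setdefault(key, {}).setdefault(group, 0)
                counts[key][group] += 1

    variants = {}
    for key, gc in counts.items():
        pos, refb, alt = parse_variant_key(key)
        c5 = ref.base(pos - 1 if pos > 1 else ref.length)
        c3 = ref.base(pos + 1 if pos < ref.length else 1)
        variants[key] = VariantTruth(
            key=key,
            group_counts=dict(gc),
            context_class=class_index(refb, alt, c5, c3),
            cpg=is_cpg_position(ref, pos),
        )
    return CohortBundle(
        tree=tree,
        sequences=seqs,
        truth=TruthTable(samples=samples, variants=variants),
        config=config,
    )


# ---------------------------------------------------------------------------
# Synthetic curation-count catalog
# ---------------------------------------------------------------------------

def curation_catalog(
    n_candidates: int = 90, n_accepted: int = 57, seed: int = 0
) -> DiseaseCatalog:
    """Synthetic catalog whose curation counts mirror a published-style
    review: ``n_candidates`` candidate variants of which ``n_accepted``
    satisfy at least one acceptance criterion.

    The variant keys and flag patterns are generated, not real; only the
    counts are meaningful. Accepted entries split between the
    reported-more-than-once and heteroplasmy-segregation criteria.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n_candidates):
        pos = 100 + 7 * i
        refb = _BASES[int(rng.integers(4))]
        alt = _TRANSITION[refb]
        accepted = i < n_accepted
        if accepted:
            r1 = bool(rng.integers(2))
            flags = (True, bool(rng.integers(2))) if r1 else (False, True)
        else:
            flags = (False, False)
        entries.append(
            CatalogEntry(f"m.{pos}{refb}>{alt}", f"G{i % 13 + 1}", *flags)
        )
    return DiseaseCatalog(entries)


def write_truth(path, truth: TruthTable) -> None:
    """Truth tables as TSV (samples section then variants section)."""
    with open(path, "w") as fh:
        fh.write("# section: samples\n")
        fh.write(
            "sample_id\tgroup\tleaf\tage_rank\told\tvariant_keys\t"
            "pathogenic_keys\tambiguous_positions\n"
        )
        for s in truth.samples.values():
            fh.write(
                f"{s.sample_id}\t{s.group}\t{s.leaf}\t{s.age_rank}\t"
                f"{int(s.old)}\t{','.join(sorted(s.variant_keys))}\t"
                f"{','.join(sorted(s.pathogenic_keys))}\t"
                f"{','.join(map(str, s.ambiguous_positions))}\n"
            )
        fh.write("# section: variants\n")
        fh.write("key\tcontext_class\tcpg\tgroup_counts\n")
        for v in truth.variants.values():
            gc = ",".join(f"{g}:{c}" for g, c in sorted(v.group_counts.items()))
            fh.write(f"{v.key}\t{v.context_class}\t{int(v.cpg)}\t{gc}\n")
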