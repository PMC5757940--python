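"""Functional annotation and pathogenicity aggregation.

Substitutions in protein genes are classified synonymous (S) or
non-synonymous (NS) under the **vertebrate mitochondrial genetic code**
(NCBI translation table 2): AGA/AGG are stops, ATA codes Met and TGA
codes Trp — so e.g. TGG→TGA, a nonsense change under the standard code,
is synonymous here. Reverse-strand genes are complemented before
translation, and a variant falling in the overlap of two genes in
different frames gets one independent hit per gene.

Pathogenicity scores are looked up, never computed: NS protein hits from
the amino-acid substitution table, tRNA-gene substitutions from the
per-position tRNA table. When overlapping genes give several scored hits
the maximum is kept (the most damaging interpretation). Protein and tRNA
scores are aggregated in separate streams and never averaged together —
they come from different scoring systems and the analyses treat them
separately.

Disease-causing status is a catalog intersection: a substitution is
flagged iff its key is an *accepted* entry of the disease catalog.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from mitopop.haplo import HaploAssignment
from mitopop.refdata import DiseaseCatalog, GeneAnnotation, ReferenceGenome, ScoreTable
from mitopop.variantcall import Variant

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class AnnotationError(ValueError):
    pass


def translate_codon(codon: str) -> str:
    """One-letter amino acid ('*' for stop) under the vertebrate
    mitochondrial code."""
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    try:
        return _MITO_TABLE.forward_table[codon]
    except KeyError:
        raise AnnotationError(f"untranslatable codon {codon!r}")


@dataclass(frozen=True)
class GeneHit:
    gene: str
    codon_index: int      # 0-based codon within the gene
    ref_aa: str
    alt_aa: str

    @property
    def ns_flag(self) -> bool:
        return self.ref_aa != self.alt_aa

    @property
    def aa_position(self) -> int:
        return self.codon_index + 1


@dataclass
class AnnotatedVariant:
    variant: Variant
    gene_hits: list[GeneHit] = field(default_factory=list)
    trna_genes: list[str] = field(default_factory=list)
    pathogenicity: float | None = None        # protein stream
    trna_pathogenicity: float | None = None   # tRNA stream
    disease_flag: bool = False

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def is_ns(self) -> bool:
        return any(h.ns_flag for h in self.gene_hits)


@dataclass
class SequenceProfile:
    """Per-sequence aggregation of annotated variants."""

    sample_id: str
    variants: list[AnnotatedVariant]
    assignment: HaploAssignment | None = None

    @property
    def macro(self) -> str:
        return self.assignment.macro if self.assignment else ""

    @property
    def substitution_keys(self) -> set[str]:
        return {
            av.key for av in self.variants
            if av.variant.kind == "substitution"
        }

    @property
    def disease_count(self) -> int:
        return sum(1 for av in self.variants if av.disease_flag)

    @property
    def mean_score(self) -> float | None:
        return mean_pathogenicity(self)

    @property
    def mean_trna_score(self) -> float | None:
        return mean_pathogenicity(self, stream="trna")


# ---------------------------------------------------------------------------
# Codon reconstruction
# ---------------------------------------------------------------------------

def _gene_position_index(
    ref: ReferenceGenome,
) -> dict[str, tuple[dict[int, int], list[int]]]:
    """Per-gene (position -> coding index map, coding-order position list).

    Cached on the reference object; rebuilding for every variant would
    dominate runtime on full cohorts.
    """
    cache = ref.__dict__.get("_patho_gene_index")
    if cache is None:
        cache = {}
        for g in ref.genes:
            positions = g.positions(ref.length)
            cache[g.gene] = ({p: i for i, p in enumerate(positions)}, positions)
        ref.__dict__["_patho_gene_index"] = cache
    return cache


def _codon_at(
    ref: ReferenceGenome, gene: GeneAnnotation, idx_coding: int,
    positions: list[int],
) -> tuple[int, str, list[int]]:
    """(codon_index, ref_codon, codon genomic positions) for a coding-strand
    index within a gene."""
    off = gene.reading_frame_offset
    idx_eff = idx_coding - off
    if idx_eff < 0:
        raise AnnotationError(
            f"position upstream of first full codon of {gene.gene!r}"
        )
    codon_index = idx_eff // 3
    start = off + 3 * codon_index
    codon_pos = positions[start:start + 3]
    if len(codon_pos) < 3:
        raise AnnotationError(
            f"codon {codon_index} of {gene.gene!r} runs off the annotation"
        )
    bases = [ref.base(p) for p in codon_pos]
    if gene.strand == "-":
        bases = [_COMP[b] for b in bases]
    return codon_index, "".join(bases), codon_pos


def classify_ns_s(
    variant: Variant, ref: ReferenceGenome
) -> list[GeneHit]:
    """Per-gene synonymous/non-synonymous calls for a substitution.

    Returns one :class:`GeneHit` per overlapping protein gene (empty list
    when the substitution hits no protein gene or is not a substitution).
    """
    if variant.kind != "substitution":
        return []
    hits: list[GeneHit] = []
    index = _gene_position_index(ref)
    for gene in ref.genes_at(variant.position):
        if gene.kind != "protein":
            continue
        pos_to_idx, positions = index[gene.gene]
        idx_coding = pos_to_idx[variant.position]
        try:
            codon_index, ref_codon, codon_pos = _codon_at(
                ref, gene, idx_coding, positions
            )
        except AnnotationError:
            if gene.incomplete_stop:
                continue  # partial terminal codon: no amino acid to call
            raise
        within = codon_pos.index(variant.position)
        alt_base = variant.alt if gene.strand == "+" else _COMP[variant.alt]
        alt_codon = (
            ref_codon[:within] + alt_base + ref_codon[within + 1:]
        )
        hits.append(
            GeneHit(
                gene=gene.gene,
                codon_index=codon_index,
                ref_aa=translate_codon(ref_codon),
                alt_aa=translate_codon(alt_codon),
            )
        )
    return hits


def score_variant(av: AnnotatedVariant, tables: ScoreTable,
                  ref: ReferenceGenome | None = None) -> None:
    """Attach pathogenicity scores to an annotated variant, in place.

    Protein stream: maximum table score over the NS gene hits (synonymous
    hits carry no score). tRNA stream: per-position lookup when the
    substitution lies in a tRNA gene. Missing table entries leave the
    score absent; nothing is imputed.
    """
    protein_scores = [
        s for h in av.gene_hits if h.ns_flag
        if (s := tables.protein(h.gene, h.aa_position, h.ref_aa, h.alt_aa))
        is not None
    ]
    av.pathogenicity = max(protein_scores) if protein_scores else None
    if av.trna_genes and av.variant.kind == "substitution":
        s = tables.trna(av.variant.position, av.variant.alt)
        av.trna_pathogenicity = s


def annotate_profile(
    sample_id: str,
    variants: Sequence[Variant],
    ref: ReferenceGenome,
    tables: ScoreTable | None = None,
    catalog: DiseaseCatalog | None = None,
    assignment: HaploAssignment | None = None,
) -> SequenceProfile:
    """Build a fully annotated per-sequence profile.

    Only substitutions are annotated; ambiguous calls and indels are
    carried through unannotated (and therefore excluded from every
    statistic).
    """
    accepted = catalog.accepted_keys if catalog is not None else set()
    annotated: list[AnnotatedVariant] = []
    for v in variants:
        av = AnnotatedVariant(variant=v)
        if v.kind == "substitution":
            av.gene_hits = classify_ns_s(v, ref)
            av.trna_genes = [
                g.gene for g in ref.genes_at(v.position) if g.kind == "tRNA"
            ]
            if tables is not None:
                score_variant(av, tables, ref)
            av.disease_flag = v.key in accepted
        annotated.append(av)
    return SequenceProfile(
        sample_id=sample_id, variants=annotated, assignment=assignment
    )


def mean_pathogenicity(
    profile: SequenceProfile,
    exclude: str | None = None,
    stream: str = "protein",
) -> float | None:
    """Arithmetic mean of the available scores of one stream.

    ``exclude`` drops one variant key before averaging — the in-silico
    removal used to test whether an age association is driven by the
    pathogenic allele itself. Returns ``None`` when no scored variant
    remains.
    """
    if stream not in ("protein", "trna"):
        raise ValueError(f"unknown stream {stream!r}")
    if exclude is not None and all(av.key != exclude for av in profile.variants):
        raise KeyError(f"exclude key {exclude!r} not in profile")
    scores = []
    for av in profile.variants:
        if exclude is not None and av.key == exclude:
            continue
        s = av.pathogenicity if stream == "protein" else av.trna_pathogenicity
        if s is not None:
            scores.append(s)
    return sum(scores) / len(scores) if scores else None


def flag_disease(
    profile: SequenceProfile, catalog: DiseaseCatalog
) -> int:
    """(Re)flag the profile's variants against the catalog; returns the
    disease count (number of accepted catalog variants present as
    substitutions)."""
    accepted = catalog.accepted_keys
    count = 0
    for av in profile.variants:
        av.disease_flag = (
            av.variant.kind == "substitution" and av.key in accepted
        )
        count += av.disease_flag
    return count


def main_pathogenic_allele(profile: SequenceProfile) -> str | None:
    """Key of the highest-scored disease-flagged variant, if any."""
    best: tuple[float, str] | None = None
    for av in profile.variants:
        if av.disease_flag:
            s = av.pathogenicity if av.pathogenicity is not None else -1.0
            if best is None or s > best[0]:
                best = (s, av.key)
    return best[1] if best else None


# ---------------------------------------------------------------------------
# NS/S ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NsSRatio:
    group: str
    ns: int
    s: int

    @property
    def ratio(self) -> float:
        return self.ns / self.s if self.s else float("inf")

    @property
    def infinite(self) -> bool:
        return self.s == 0


def ns_s_ratio(
    profiles: Iterable[SequenceProfile],
    grouping: Mapping[str, str] | None = None,
) -> dict[str, NsSRatio]:
    """Per-group NS and S counts over *unique* protein-gene variants.

    Each unique variant key counts once per group regardless of carrier
    count — the comparison is between variant inventories, not sequence
    loads. A variant is NS if non-synonymous in at least one overlapping
    gene. Variants hitting no protein gene are excluded.
    """
    per_group: dict[str, dict[str, bool]] = {}
    for p in profiles:
        group = grouping[p.sample_id] if grouping else p.macro
        bucket = per_group.setdefault(group, {})
        for av in p.variants:
            if av.gene_hits:
                bucket[av.key] = bucket.get(av.key, False) or av.is_ns
    out = {}
    for group, inventory in per_group.items():
        ns = sum(1 for is_ns in inventory.values() if is_ns)
        out[group] = NsSRatio(group=group, ns=ns, s=len(inventory) - ns)
    return out


def ns_s_fisher(a: NsSRatio, b: NsSRatio) -> float:
    """Two-sided Fisher p for the 2x2 NS/S count table of two groups."""
    from mitopop.popstats import fisher_2x2

    return fisher_2x2([[a.ns, a.s], [b.ns, b.s]])[1]


def write_profiles(path: str | Path, profiles: Iterable[SequenceProfile]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tmacro\thaplogroup\tn_variants\tn_scored\t"
            "mean_score\tmean_trna_score\tdisease_count\n"
        )
        for p in profiles:
            ms = p.mean_score
            mt = p.mean_trna_score
            fh.write(
                f"{p.sample_id}\t{p.macro}\t"
                f"{p.assignment.best_node if p.assignment else ''}\t"
                f"{len(p.variants)}\t"
                f"{sum(1 for av in p.variants if av.pathogenicity is not None)}\t"
                f"{'' if ms is None else f'{ms:.6f}'}\t"
                f"{'' if mt is None else f'{mt:.6f}'}\t"
                f"{p.disease_count}\n"
            )
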