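"""Reference data: genomes, gene annotations, score tables, disease catalogs.

The mitochondrial genome is circular; every sequence here is stored
linearly but indexed with 1-based inclusive coordinates that wrap around
position ``length`` back to position 1. Gene annotations may cross the
origin (``start > end``), which is flagged rather than rejected.

Two score tables drive pathogenicity analysis:

* protein scores, keyed by ``(gene, aa_position, ref_aa, alt_aa)`` — a
  precomputed probability-like score in ``[0, 1]`` for each possible amino
  acid substitution in the 13 mtDNA protein genes;
* tRNA scores, keyed by ``(position, alt_base)`` — per-position scores for
  substitutions in tRNA genes.

The disease catalog lists candidate pathogenic variants with two curation
flags; a variant is *accepted* as disease-causing iff at least one flag is
set (reported more than once with mtDNA disease, or documented
heteroplasmy segregating with the phenotype).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

VALID_BASES = frozenset("ACGT")

#: IUPAC single-letter ambiguity codes (excluding the four bases).
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse-complement of a (possibly IUPAC-ambiguous) sequence."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene on the circular reference, 1-based inclusive coordinates.

    ``reading_frame_offset`` counts bases skipped at the 5' end of the gene
    (on the coding strand) before the first full codon. ``incomplete_stop``
    marks protein genes whose stop codon is completed by polyadenylation,
    so their length need not be divisible by 3.
    """

    gene: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein"  # protein | tRNA | rRNA | control
    reading_frame_offset: int = 0
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.kind not in ("protein", "tRNA", "rRNA", "control"):
            raise ValueError(f"unknown gene kind {self.kind!r}")

    @property
    def wraps_origin(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> list[int]:
        """All genomic positions of the gene in coding-strand order."""
        if not self.wraps_origin:
            pos = list(range(self.start, self.end + 1))
        else:
            pos = list(range(self.start, genome_length + 1)) + list(
                range(1, self.end + 1)
            )
        return pos if self.strand == "+" else pos[::-1]

    def contains(self, position: int, genome_length: int) -> bool:
        if not self.wraps_origin:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


@dataclass
class ReferenceGenome:
    """A circular reference mitogenome with its gene annotation.

    The sequence must be unambiguous (A/C/G/T only): ambiguity codes are
    legitimate in *sample* sequences but a reference with them would make
    variant naming ill-defined.
    """

    name: str
    sequence: str
    genes: list[GeneAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"reference {self.name!r} contains non-ACGT characters: "
                f"{sorted(bad)}"
            )
        if not self.sequence:
            raise FormatError(f"reference {self.name!r} is empty")
        n = len(self.sequence)
        for g in self.genes:
            if not (1 <= g.start <= n and 1 <= g.end <= n):
                raise FormatError(
                    f"gene {g.gene!r} interval [{g.start},{g.end}] outside "
                    f"[1,{n}]"
                )
            if g.kind == "protein" and not g.incomplete_stop:
                eff = g.length(n) - g.reading_frame_offset
                if eff % 3 != 0:
                    raise FormatError(
                        f"protein gene {g.gene!r} length {eff} (after frame "
                        "offset) not divisible by 3 and no incomplete-stop "
                        "flag"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position, wrapping circularly."""
        return self.sequence[(position - 1) % self.length]

    def genes_at(self, position: int) -> list[GeneAnnotation]:
        return [g for g in self.genes if g.contains(position, self.length)]


def read_fasta(path: str | Path | io.TextIOBase) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into ``[(id, sequence), ...]``.

    Sequences are uppercased; IUPAC ambiguity codes are retained (sample
    consensus sequences legitimately contain them). Record ids must be
    unique and every record non-empty.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    try:
        records = []
        seen: set[str] = set()
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"record {i + 1}: empty FASTA header")
            if not seq:
                raise FormatError(f"record {i + 1} ({rec.id!r}): empty sequence")
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, seq))
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TSV readers.  All tolerate '#' comment lines and blank lines; coordinates
# in files are 1-based inclusive (stated in the writers' headers).
# ---------------------------------------------------------------------------

def _tsv_rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Load a gene annotation TSV.

    Columns: gene, start, end, strand, kind, frame_offset[, incomplete_stop]
    (header optional; 1-based inclusive coordinates).
    """
    genes = []
    for lineno, f in _tsv_rows(path):
        if f[0] == "gene":  # header
            continue
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: expected ≥6 columns, got {len(f)}")
        incomplete = len(f) > 6 and f[6].strip().lower() in ("1", "true", "yes")
        genes.append(
            GeneAnnotation(
                gene=f[0], start=int(f[1]), end=int(f[2]), strand=f[3],
                kind=f[4], reading_frame_offset=int(f[5]),
                incomplete_stop=incomplete,
            )
        )
    return genes


def write_annotation(path: str | Path, genes: Iterable[GeneAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("# gene annotation; 1-based inclusive coordinates\n")
        fh.write("gene\tstart\tend\tstrand\tkind\tframe_offset\tincomplete_stop\n")
        for g in genes:
            fh.write(
                f"{g.gene}\t{g.start}\t{g.end}\t{g.strand}\t{g.kind}\t"
                f"{g.reading_frame_offset}\t{int(g.incomplete_stop)}\n"
            )


class ScoreTable:
    """Pathogenicity scores for protein amino-acid substitutions and tRNA sites."""

    def __init__(
        self,
        protein_scores: Mapping[tuple[str, int, str, str], float] | None = None,
        trna_scores: Mapping[tuple[int, str], float] | None = None,
    ) -> None:
        self.protein_scores = dict(protein_scores or {})
        self.trna_scores = dict(trna_scores or {})
        for key, s in list(self.protein_scores.items()) + list(
            self.trna_scores.items()
        ):
            if not 0.0 <= s <= 1.0:
                raise FormatError(f"score {s} for {key} outside [0,1]")

    def protein(self, gene: str, aa_position: int, ref_aa: str,
                alt_aa: str) -> float | None:
        return self.protein_scores.get((gene, aa_position, ref_aa, alt_aa))

    def trna(self, position: int, alt: str) -> float | None:
        return self.trna_scores.get((position, alt))

    def __len__(self) -> int:
        return len(self.protein_scores) + len(self.trna_scores)


def load_score_table(path: str | Path) -> ScoreTable:
    """Load a score TSV with columns (kind, gene, position, ref, alt, score).

    ``kind`` is ``protein`` (position = amino-acid position, ref/alt =
    amino acids) or ``tRNA`` (position = genomic position, alt = base).
    Scores outside [0,1] and duplicate keys with differing scores are
    rejected with the offending row number.
    """
    protein: dict[tuple[str, int, str, str], float] = {}
    trna: dict[tuple[int, str], float] = {}
    for lineno, f in _tsv_rows(path):
        if f[0] == "kind":
            continue
        if len(f) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 columns, got {len(f)}")
        kind, gene, pos, ref, alt, score_s = f[:6]
        score = float(score_s)
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{path}:{lineno}: score {score} outside [0,1]"
            )
        if kind == "protein":
            key = (gene, int(pos), ref, alt)
            if key in protein and protein[key] != score:
                raise FormatError(
                    f"{path}:{lineno}: duplicate protein key {key} with "
                    f"conflicting scores {protein[key]} vs {score}"
                )
            protein[key] = score
        elif kind.lower() == "trna":
            tkey = (int(pos), alt)
            if tkey in trna and trna[tkey] != score:
                raise FormatError(
                    f"{path}:{lineno}: duplicate tRNA key {tkey} with "
                    f"conflicting scores {trna[tkey]} vs {score}"
                )
            trna[tkey] = score
        else:
            raise FormatError(f"{path}:{lineno}: unknown score kind {kind!r}")
    return ScoreTable(protein, trna)


def write_score_table(path: str | Path, table: ScoreTable) -> None:
    with open(path, "w") as fh:
        fh.write("# pathogenicity scores; positions 1-based\n")
        fh.write("kind\tgene\tposition\tref\talt\tscore\n")
        for (gene, pos, ref, alt), s in sorted(table.protein_scores.items()):
            fh.write(f"protein\t{gene}\t{pos}\t{ref}\t{alt}\t{s:.6g}\n")
        for (pos, alt), s in sorted(table.trna_scores.items()):
            fh.write(f"tRNA\t-\t{pos}\t-\t{alt}\t{s:.6g}\n")


@dataclass(frozen=True)
class CatalogEntry:
    """One candidate disease-causing variant with its curation flags."""

    key: str                     # variant key, e.g. m.3460G>A
    gene: str
    reported_more_than_once: bool
    heteroplasmy_segregation: bool
    usable: bool = True          # False for indel / multi-nucleotide entries

    @property
    def accepted(self) -> bool:
        """Accepted as disease-causing iff either curation criterion holds."""
        return self.usable and (
            self.reported_more_than_once or self.heteroplasmy_segregation
        )


class DiseaseCatalog:
    """Curated catalog of candidate pathogenic mtDNA variants."""

    def __init__(self, entries: Iterable[CatalogEntry]) -> None:
        self.entries = list(entries)
        keys = [e.key for e in self.entries]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise FormatError(f"duplicate catalog keys: {dupes}")

    @property
    def accepted_keys(self) -> set[str]:
        return {e.key for e in self.entries if e.accepted}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_disease_catalog(path: str | Path) -> DiseaseCatalog:
    """Load a catalog TSV.

    Columns: key, gene, reported_more_than_once, heteroplasmy_segregation
    [, accepted [, usable]].  The ``accepted`` column, if present, is
    recomputed from the two criterion flags and must agree with the stored
    value — an entry claiming acceptance with both criteria false is a
    consistency error.
    """
    truthy = ("1", "true", "yes")

    def flag(s: str) -> bool:
        return s.strip().lower() in truthy

    entries = []
    for lineno, f in _tsv_rows(path):
        if f[0] == "key":
            continue
        if len(f) < 4:
            raise FormatError(f"{path}:{lineno}: expected ≥4 columns, got {len(f)}")
        usable = flag(f[5]) if len(f) > 5 else True
        entry = CatalogEntry(
            key=f[0], gene=f[1],
            reported_more_than_once=flag(f[2]),
            heteroplasmy_segregation=flag(f[3]),
            usable=usable,
        )
        if len(f) > 4 and f[4].strip() != "":
            stored = flag(f[4])
            if stored != entry.accepted:
                raise FormatError(
                    f"{path}:{lineno}: stored accepted={stored} inconsistent "
                    f"with criterion flags ({entry.reported_more_than_once}, "
                    f"{entry.heteroplasmy_segregation})"
                )
        entries.append(entry)
    return DiseaseCatalog(entries)


def write_disease_catalog(path: str | Path, catalog: DiseaseCatalog) -> None:
    with open(path, "w") as fh:
        fh.write("# disease-mutation catalog; keys m.<POS><REF>><ALT>\n")
        fh.write(
            "key\tgene\treported_more_than_once\theteroplasmy_segregation"
            "\taccepted\tusable\n"
        )
        for e in catalog:
            fh.write(
                f"{e.key}\t{e.gene}\t{int(e.reported_more_than_once)}\t"
                f"{int(e.heteroplasmy_segregation)}\t{int(e.accepted)}\t"
                f"{int(e.usable)}\n"
            )
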