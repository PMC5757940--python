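"""Alignment of sample mitogenomes to the reference and variant extraction.

Samples are complete mitogenome consensus sequences assumed to be in
reference register (public mitogenomes conventionally start at reference
position 1), so a banded global alignment suffices: the band only needs to
absorb small indels, not rotations. The aligner is an affine-gap
(Gotoh-style) banded Needleman–Wunsch; a length-``k`` gap scores
``gap_open + k * gap_extend``. Traceback ties are broken
diagonal > up > left, so variant calls are deterministic.

Variant calls are *major-allele substitutions*: one substitution per
mismatch column with an unambiguous sample base. Columns where the sample
carries an IUPAC ambiguity code are emitted with ``kind="ambiguous"`` and
excluded from every downstream statistic — the consensus does not support
a single major allele there. Gap runs become single insertion/deletion
records, left-aligned within homopolymers; indels never feed signatures or
scores.

Each substitution carries its immediate 5' and 3' *reference* context,
resolved circularly across the origin, which downstream code bins into the
96-class trinucleotide signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from mitopop.refdata import (
    IUPAC_AMBIGUITY,
    ReferenceGenome,
    VALID_BASES,
)

NEG_INF = -(10 ** 9)

# Default scoring, chosen for near-identical mitogenome pairs: heavy gap
# opening keeps spurious indels out of homopolymer-rich control regions.
DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP_OPEN = -5
DEFAULT_GAP_EXTEND = -1
DEFAULT_BAND = 200

#: Alignments below this identity indicate a rotated / misassembled sample;
#: the pipeline refuses to call variants from them.
MIN_IDENTITY = 0.95


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """A difference between sample and reference at a 1-based position.

    For substitutions ``ref``/``alt`` are single bases and ``context5`` /
    ``context3`` are the flanking *reference* bases (circular). Deletions
    store the deleted reference run in ``ref`` with ``alt == ""``;
    insertions store the inserted sample run in ``alt`` with ``ref == ""``
    and ``position`` the reference base immediately 5' of the insertion.
    """

    position: int
    ref: str
    alt: str
    kind: str  # substitution | insertion | deletion | ambiguous
    context5: str = ""
    context3: str = ""

    @property
    def key(self) -> str:
        return variant_key(self)


def variant_key(v: "Variant") -> str:
    """mtDNA-nomenclature key ``m.<POS><REF>><ALT>`` for a substitution."""
    if v.kind == "deletion":
        return f"m.{v.position}del{v.ref}"
    if v.kind == "insertion":
        return f"m.{v.position}ins{v.alt}"
    return f"m.{v.position}{v.ref}>{v.alt}"


def parse_variant_key(key: str) -> tuple[int, str, str]:
    """Parse ``m.<POS><REF>><ALT>`` into ``(position, ref, alt)``."""
    if not key.startswith("m.") or ">" not in key:
        raise ValueError(f"not a substitution key: {key!r}")
    body = key[2:]
    left, alt = body.split(">", 1)
    pos_s, ref = left[:-1], left[-1]
    return int(pos_s), ref, alt


@dataclass
class Alignment:
    """A banded global alignment of one sample against the reference.

    ``ops`` is the alignment path in forward order: ``("M", ref_pos,
    sample_pos)`` for an aligned column (match or mismatch), ``("D",
    ref_pos, None)`` for a reference base deleted from the sample, ``("I",
    None, sample_pos)`` for a sample base inserted relative to the
    reference. Positions are 1-based.
    """

    sample_id: str
    score: int
    ops: list[tuple[str, int | None, int | None]]
    band_width: int
    ref_name: str
    sample_seq: str
    identity: float


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _banded_kernel(x, y, band, match, mismatch, gap_open, gap_extend):
    """Banded affine-gap global alignment DP over uint8-coded sequences.

    Band coordinate: cell (i, j) is stored at column k = j - i + band, kept
    for |j - i| <= band. States: M (diagonal), X (gap in sample: consumes
    reference), Y (gap in reference: consumes sample). State preference
    everywhere is M > Y > X (diagonal > up > left). Returns (score, ops)
    where ops is an int8 array of 0=M, 1=D(left), 2=I(up) in reverse order.
    """
    n = x.shape[0]
    m = y.shape[0]
    w = 2 * band + 1
    M = np.full((m + 1, w), NEG_INF, dtype=np.int64)
    X = np.full((m + 1, w), NEG_INF, dtype=np.int64)
    Y = np.full((m + 1, w), NEG_INF, dtype=np.int64)
    # pointers: for M, predecessor state at (i-1, j-1); for X at (i, j-1);
    # for Y at (i-1, j). 0=M, 1=X, 2=Y.
    pM = np.zeros((m + 1, w), dtype=np.int8)
    pX = np.zeros((m + 1, w), dtype=np.int8)
    pY = np.zeros((m + 1, w), dtype=np.int8)

    M[0, band] = 0
    # first row: only gaps in sample (consume reference)
    for j in range(1, min(n, band) + 1):
        X[0, j + band] = gap_open + gap_extend * j
        pX[0, j + band] = 0 if j == 1 else 1
    for i in range(1, m + 1):
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > n:
            hi = n
        for j in range(lo, hi + 1):
            k = j - i + band
            if j == 0:
                # first column: only gaps in reference (consume sample)
                Y[i, k] = gap_open + gap_extend * i
                pY[i, k] = 0 if i == 1 else 2
                continue
            # M: diagonal from (i-1, j-1), same k
            if i >= 1:
                s = match if x[j - 1] == y[i - 1] else mismatch
                bm = M[i - 1, k]
                bp = 0
                if Y[i - 1, k] > bm:
                    bm = Y[i - 1, k]
                    bp = 2
                if X[i - 1, k] > bm:
                    bm = X[i - 1, k]
                    bp = 1
                if bm > NEG_INF // 2:
                    M[i, k] = bm + s
                    pM[i, k] = bp
            # X: from (i, j-1), band column k-1
            if k - 1 >= 0:
                opn = M[i, k - 1]
                op_p = 0
                if Y[i, k - 1] > opn:
                    opn = Y[i, k - 1]
                    op_p = 2
                ext = X[i, k - 1]
                if opn > NEG_INF // 2 and opn + gap_open >= ext:
                    X[i, k] = opn + gap_open + gap_extend
                    pX[i, k] = op_p
                elif ext > NEG_INF // 2:
                    X[i, k] = ext + gap_extend
                    pX[i, k] = 1
            # Y: from (i-1, j), band column k+1
            if k + 1 < w:
                opn = M[i - 1, k + 1]
                op_p = 0
                if X[i - 1, k + 1] > opn:
                    opn = X[i - 1, k + 1]
                    op_p = 1
                ext = Y[i - 1, k + 1]
                if opn > NEG_INF // 2 and opn + gap_open >= ext:
                    Y[i, k] = opn + gap_open + gap_extend
                    pY[i, k] = op_p
                elif ext > NEG_INF // 2:
                    Y[i, k] = ext + gap_extend
                    pY[i, k] = 2
    kf = n - m + band
    score = M[m, kf]
    state = 0
    if Y[m, kf] > score:
        score = Y[m, kf]
        state = 2
    if X[m, kf] > score:
        score = X[m, kf]
        state = 1
    # traceback
    ops = np.empty(m + n, dtype=np.int8)
    t = 0
    i = m
    j = n
    while i > 0 or j > 0:
        k = j - i + band
        if state == 0:
            ops[t] = 0
            state = pM[i, k]
            i -= 1
            j -= 1
        elif state == 1:
            ops[t] = 1
            state = pX[i, k]
            j -= 1
        else:
            ops[t] = 2
            state = pY[i, k]
            i -= 1
        t += 1
    return score, ops[:t]


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _banded_kernel_jit = njit(cache=True)(_banded_kernel)
except ImportError:  # pragma: no cover
    _banded_kernel_jit = _banded_kernel


def banded_global_align(
    sample: str,
    ref: ReferenceGenome | str,
    sample_id: str = "sample",
    band: int = DEFAULT_BAND,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Globally align ``sample`` to ``ref`` within a diagonal band.

    The band must cover the length difference (``|len(sample) - len(ref)|
    <= band``); inside the band the returned score is the optimal global
    affine-gap score. Raises :class:`AlignmentError` with advice to raise
    the band when the length difference exceeds it.
    """
    ref_seq = ref.sequence if isinstance(ref, ReferenceGenome) else ref
    ref_name = ref.name if isinstance(ref, ReferenceGenome) else "ref"
    if not sample or not ref_seq:
        raise AlignmentError("empty sequence")
    if abs(len(sample) - len(ref_seq)) > band:
        raise AlignmentError(
            f"length difference {abs(len(sample) - len(ref_seq))} exceeds "
            f"band {band}; rerun with a larger band"
        )
    x = _encode(ref_seq)
    y = _encode(sample.upper())
    score, rev_ops = _banded_kernel_jit(
        x, y, band, match, mismatch, gap_open, gap_extend
    )
    score = int(score)

    ops: list[tuple[str, int | None, int | None]] = []
    i = 0  # sample consumed
    j = 0  # ref consumed
    for code in rev_ops[::-1]:
        if code == 0:
            i += 1
            j += 1
            ops.append(("M", j, i))
        elif code == 1:
            j += 1
            ops.append(("D", j, None))
        else:
            i += 1
            ops.append(("I", None, i))
    ops = _left_align_gaps(ops, ref_seq, sample)
    matches = sum(
        1 for op, rj, si in ops
        if op == "M" and ref_seq[rj - 1] == sample[si - 1]
    )
    identity = matches / len(ops) if ops else 0.0
    return Alignment(
        sample_id=sample_id,
        score=score,
        ops=ops,
        band_width=band,
        ref_name=ref_name,
        sample_seq=sample.upper(),
        identity=identity,
    )


def _left_align_gaps(ops, ref_seq, sample):
    """Shift gap runs left while the flanking base repeats (homopolymers).

    Works on the op list: a deletion (or insertion) run can swap with an
    immediately preceding aligned column whose base equals the last base of
    the run, without changing the aligned sequences.
    """
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        idx = 0
        while idx < len(ops):
            op = ops[idx][0]
            if op not in ("D", "I"):
                idx += 1
                continue
            run_start = idx
            run_end = idx
            while run_end + 1 < len(ops) and ops[run_end + 1][0] == op:
                run_end += 1
            if run_start > 0 and ops[run_start - 1][0] == "M":
                prev = ops[run_start - 1]
                if op == "D":
                    run_base = ref_seq[ops[run_end][1] - 1]
                    prev_base = ref_seq[prev[1] - 1]
                else:
                    run_base = sample[ops[run_end][2] - 1]
                    prev_base = sample[prev[2] - 1]
                if run_base == prev_base:
                    # rotate: M slides right over the run
                    block = ops[run_start:run_end + 1]
                    shifted = _renumber_shift(block, prev, op)
                    ops[run_start - 1:run_end + 1] = shifted
                    changed = True
                    idx = max(run_start - 2, 0)
                    continue
            idx = run_end + 1
    return ops


def _renumber_shift(block, prev_m, op):
    """Move an M column from before a gap run to after it, renumbering."""
    _, prev_rj, prev_si = prev_m
    if op == "D":
        new_block = [("D", rj - 1, None) for _, rj, _ in
                     [(b[0], b[1], b[2]) for b in block]]
        last_rj = block[-1][1]
        new_m = ("M", last_rj, prev_si)
    else:
        new_block = [("I", None, si - 1) for _, _, si in
                     [(b[0], b[1], b[2]) for b in block]]
        last_si = block[-1][2]
        new_m = ("M", prev_rj, last_si)
    return new_block + [new_m]


def triplet_context(ref: ReferenceGenome, position: int) -> tuple[str, str]:
    """5' and 3' reference bases flanking ``position``, wrapping circularly."""
    if not 1 <= position <= ref.length:
        raise ValueError(
            f"position {position} outside [1, {ref.length}]"
        )
    return ref.base(position - 1 if position > 1 else ref.length), ref.base(
        position + 1 if position < ref.length else 1
    )


def call_variants(aln: Alignment, ref: ReferenceGenome) -> list[Variant]:
    """Extract variants from an alignment.

    Mismatch columns with an unambiguous sample base become substitutions
    carrying circular 5'/3' reference context; IUPAC-ambiguous columns are
    emitted as ``kind="ambiguous"``; each gap run collapses to one
    insertion or deletion record. Degenerate alignments yield an empty
    list.
    """
    variants: list[Variant] = []
    idx = 0
    ops = aln.ops
    while idx < len(ops):
        op, rj, si = ops[idx]
        if op == "M":
            rb = ref.sequence[rj - 1]
            sb = aln.sample_seq[si - 1]
            if sb != rb:
                c5, c3 = triplet_context(ref, rj)
                if sb in VALID_BASES:
                    variants.append(
                        Variant(rj, rb, sb, "substitution", c5, c3)
                    )
                elif sb in IUPAC_AMBIGUITY:
                    variants.append(Variant(rj, rb, sb, "ambiguous", c5, c3))
                # other characters (should not occur) are silently skipped
            idx += 1
        elif op == "D":
            start = idx
            while idx + 1 < len(ops) and ops[idx + 1][0] == "D":
                idx += 1
            first = ops[start][1]
            deleted = "".join(
                ref.sequence[o[1] - 1] for o in ops[start:idx + 1]
            )
            variants.append(Variant(first, deleted, "", "deletion"))
            idx += 1
        else:  # I
            start = idx
            while idx + 1 < len(ops) and ops[idx + 1][0] == "I":
                idx += 1
            inserted = "".join(
                aln.sample_seq[o[2] - 1] for o in ops[start:idx + 1]
            )
            # anchor: last consumed reference base before the run
            anchor = 0
            for back in range(start - 1, -1, -1):
                if ops[back][1] is not None:
                    anchor = ops[back][1]
                    break
            variants.append(Variant(anchor, "", inserted, "insertion"))
            idx += 1
    return variants


def substitution_keys(variants: Iterable[Variant]) -> set[str]:
    """Keys of the unambiguous substitutions in a variant list."""
    return {v.key for v in variants if v.kind == "substitution"}


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

VARIANT_TABLE_HEADER = (
    "sample_id\tposition\tref\talt\tkind\tcontext5\tcontext3"
)


def write_variant_table(
    path: str | Path, calls: Iterable[tuple[str, Sequence[Variant]]]
) -> None:
    """Write per-sample variant calls as TSV (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("# variant calls; 1-based inclusive reference coordinates\n")
        fh.write(VARIANT_TABLE_HEADER + "\n")
        for sample_id, variants in calls:
            for v in variants:
                fh.write(
                    f"{sample_id}\t{v.position}\t{v.ref}\t{v.alt}\t{v.kind}"
                    f"\t{v.context5}\t{v.context3}\n"
                )


def read_variant_table(path: str | Path) -> dict[str, list[Variant]]:
    calls: dict[str, list[Variant]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("sample_id"):
                continue
            f = line.split("\t")
            calls.setdefault(f[0], []).append(
                Variant(int(f[1]), f[2], f[3], f[4], f[5], f[6])
            )
    return calls


def write_vcf(
    path: str | Path,
    ref: ReferenceGenome,
    sample_id: str,
    variants: Sequence[Variant],
) -> None:
    """Minimal single-sample VCF 4.2 with the substitution calls only."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={ref.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tFORMAT\t"
            f"{sample_id}\n"
        )
        for v in sorted(variants, key=lambda v: v.position):
            if v.kind != "substitution":
                continue
            fh.write(
                f"{ref.name}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                "GT\t1\n"
            )
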