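"""End-to-end orchestration: ingest → align/call → classify/QC →
annotate/score → population statistics → signatures/dating → report.

Every stage writes its intermediate as TSV under the output directory, and
every number in the plain-text report is re-derivable from those
intermediates. The pipeline is deterministic for a fixed config: rerunning
with the same inputs produces byte-identical outputs.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field, asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from mitopop import haplo, patho, popstats, refdata, sigdate, variantcall
from mitopop.haplo import HaploTree
from mitopop.patho import SequenceProfile
from mitopop.refdata import DiseaseCatalog, ReferenceGenome, ScoreTable


class ValidationError(ValueError):
    pass


def report_percentages(num: int, den: int) -> str:
    """``100*num/den`` rounded half-up to one decimal, e.g. ``"2.2%"``."""
    if den <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * num) / Decimal(den)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


@dataclass
class RunConfig:
    """Validated run configuration (YAML-serializable).

    Thresholds: ``min_identity`` and ``max_ambiguity_frac`` gate samples
    after alignment; ``min_marker_coverage`` is the haplogroup-QC
    coverage floor; ``scan_raw_p`` the association-scan flag threshold.
    """

    samples_fasta: str = ""
    reference_fasta: str = ""
    annotation_tsv: str = ""
    tree_tsv: str = ""
    score_tsv: str = ""
    catalog_tsv: str = ""
    out_dir: str = "out"
    reference_name: str = "rCRS-like"
    band: int = 200
    min_identity: float = 0.95
    max_ambiguity_frac: float = 0.02
    min_marker_coverage: float = 0.90
    scan_raw_p: float = 0.01
    genealogy_mode: str = "star"
    seed: int = 0

    def validate(self) -> None:
        for name in ("samples_fasta", "reference_fasta", "annotation_tsv",
                     "tree_tsv", "score_tsv", "catalog_tsv"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ValidationError(f"{name}: missing input file {p!r}")
        if not 0 < self.min_identity <= 1 or not 0 <= self.max_ambiguity_frac <= 1:
            raise ValidationError("identity/ambiguity thresholds out of range")
        if not 0 <= self.min_marker_coverage <= 1:
            raise ValidationError("min_marker_coverage out of range")
        if not 0 < self.scan_raw_p <= 1:
            raise ValidationError("scan_raw_p out of range")
        if self.genealogy_mode not in ("star", "parsimony-tree"):
            raise ValidationError(f"unknown genealogy_mode {self.genealogy_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class RunResult:
    config: RunConfig
    profiles: list[SequenceProfile]
    kept: dict[str, bool]
    afs: dict
    cooccurrence: dict[str, popstats.CooccurrenceResult]
    scan: list[popstats.AssociationTest]
    spectra: dict[str, sigdate.SignatureSpectrum]
    cpg: dict[str, sigdate.CpGStats]
    rho_estimates: dict[str, sigdate.RhoEstimate]
    age_association: sigdate.AgeAssociation | None
    report_lines: list[str]


def _log(quiet: bool, stage: str, t0: float, msg: str) -> None:
    if not quiet:
        print(f"[{stage}] {time.perf_counter() - t0:6.1f}s {msg}",
              file=sys.stderr)


def run_pipeline(config: RunConfig, quiet: bool = True) -> RunResult:
    """Execute all stages; writes intermediates and a summary report under
    ``config.out_dir``. Raises on validation failure before any compute."""
    config.validate()
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- ingest ------------------------------------------------------------
    genes = refdata.load_annotation(config.annotation_tsv)
    ref_records = refdata.read_fasta(config.reference_fasta)
    ref = ReferenceGenome(ref_records[0][0], ref_records[0][1], genes)
    samples = refdata.read_fasta(config.samples_fasta)
    tree = haplo.load_tree(config.tree_tsv)
    tables = refdata.load_score_table(config.score_tsv)
    catalog = refdata.load_disease_catalog(config.catalog_tsv)
    _log(quiet, "ingest", t0, f"{len(samples)} samples, ref {ref.length} bp")

    # -- align / call ------------------------------------------------------
    calls: dict[str, list[variantcall.Variant]] = {}
    qc_rows = []
    for sid, seq in samples:
        aln = variantcall.banded_global_align(
            seq, ref, sample_id=sid, band=config.band
        )
        variants = variantcall.call_variants(aln, ref)
        n_amb = sum(1 for v in variants if v.kind == "ambiguous")
        ok = (
            aln.identity >= config.min_identity
            and n_amb / ref.length <= config.max_ambiguity_frac
        )
        qc_rows.append((sid, aln.identity, n_amb, ok))
        if ok:
            calls[sid] = variants
    variantcall.write_variant_table(out / "variants.tsv", sorted(calls.items()))
    with open(out / "alignment_qc.tsv", "w") as fh:
        fh.write("sample_id\tidentity\tn_ambiguous\tpass\n")
        for sid, ident, n_amb, ok in qc_rows:
            fh.write(f"{sid}\t{ident:.4f}\t{n_amb}\t{int(ok)}\n")
    _log(quiet, "align", t0, f"{len(calls)} samples passed alignment QC")

    # -- classify / QC -----------------------------------------------------
    key_sets = {
        sid: variantcall.substitution_keys(vs) for sid, vs in calls.items()
    }
    run1 = {
        sid: haplo.classify(ks, tree, sample_id=sid)
        for sid, ks in key_sets.items()
    }
    run2 = {
        sid: haplo.classify(ks, tree, sample_id=sid, tie_break="reverse")
        for sid, ks in key_sets.items()
    }
    kept = haplo.qc_filter(run1, run2, min_coverage=config.min_marker_coverage)
    haplo.write_assignments(
        out / "assignments.tsv",
        [run1[sid] for sid in sorted(run1)],
    )
    _log(quiet, "classify", t0, f"{sum(kept.values())} samples kept after QC")

    # -- annotate / score --------------------------------------------------
    profiles = [
        patho.annotate_profile(
            sid, calls[sid], ref, tables, catalog, assignment=run1[sid]
        )
        for sid in sorted(calls)
        if kept[sid]
    ]
    patho.write_profiles(out / "profiles.tsv", profiles)
    _log(quiet, "annotate", t0, f"{len(profiles)} profiles annotated")

    # -- population statistics --------------------------------------------
    lines: list[str] = ["# mitopop pipeline report", ""]
    by_macro: dict[str, list[SequenceProfile]] = {}
    for p in profiles:
        if p.macro:
            by_macro.setdefault(p.macro, []).append(p)
    macros = sorted(by_macro)

    afs = popstats.allele_frequencies(
        [p for g in macros for p in by_macro[g]]
    )
    popstats.write_af_table(out / "allele_frequencies.tsv", afs)

    lines.append("## Carrier proportions (>=1 disease-causing mutation)")
    for g in macros:
        ps = by_macro[g]
        carriers = sum(1 for p in ps if p.disease_count > 0)
        lines.append(
            f"{g}: {carriers}({report_percentages(carriers, len(ps))}) of "
            f"{len(ps)} sequences"
        )
    lines.append("")

    lines.append("## Mean pathogenicity (per-sequence mean score) by group")
    import numpy as np
    means = {}
    for g in macros:
        vals = [p.mean_score for p in by_macro[g] if p.mean_score is not None]
        means[g] = vals
        lines.append(f"{g}: mean {np.mean(vals):.4f} over {len(vals)} sequences"
                     if vals else f"{g}: no scored sequences")
    for i, g1 in enumerate(macros):
        for g2 in macros[i + 1:]:
            if len(means[g1]) >= 2 and len(means[g2]) >= 2:
                _, _, pt = popstats.welch_t(means[g1], means[g2])
                try:
                    _, pw = popstats.wilcoxon_rank(means[g1], means[g2])
                    pw_s = popstats.format_p(pw)
                except ValueError:
                    pw_s = "NA"
                lines.append(
                    f"{g1} vs {g2}: t-test p {popstats.format_p(pt)}, "
                    f"Wilcoxon p {pw_s}"
                )
    lines.append("")

    lines.append("## Co-occurrence of >=2 disease-causing mutations")
    cooc = {}
    for g in macros:
        r = popstats.cooccurrence(by_macro[g], catalog, group=g)
        cooc[g] = r
        lines.append(
            f"{g}: observed {r.observed_ge2}, expected {r.expected_ge2:.2f}, "
            f"{r.fold:.1f}-fold {r.direction}, Fisher p "
            f"{popstats.format_p(r.p_value)}"
        )
    lines.append("")

    macro_of = {p.sample_id: p.macro for p in profiles if p.macro}
    major_of = {
        p.sample_id: tree.major_of(p.assignment.best_node)
        for p in profiles
        if p.assignment and tree.major_of(p.assignment.best_node)
    }
    lines.append("## Recurrence of disease-causing mutations across haplogroups")
    for level, mapping in (("macro", macro_of), ("major", major_of)):
        s = popstats.recurrence_summary(profiles, catalog, mapping)
        if s["observed_mutations"]:
            lines.append(
                f"{level}: {s['shared']}"
                f"({report_percentages(s['shared'], s['observed_mutations'])})"
                f" of {s['observed_mutations']} observed mutations on >1 "
                f"{level} haplogroup; {s['private']} on one only"
            )
        else:
            lines.append(f"{level}: no accepted mutations observed")
    lines.append("")

    scan = popstats.association_scan(
        profiles, catalog, major_of, raw_threshold=config.scan_raw_p
    )
    popstats.write_scan(out / "association_scan.tsv", scan)
    n_sig_keys = len({t.key for t in scan if t.significant})
    n_keys = len({t.key for t in scan})
    lines.append("## Haplogroup association scan (major level)")
    lines.append(
        f"{n_sig_keys} of {n_keys} recurrent mutations show clustering at "
        f"raw p < {config.scan_raw_p}"
        if n_keys else "no recurrent mutations to scan"
    )
    lines.append("")

    # -- signatures / CpG --------------------------------------------------
    lines.append("## Mutational signatures and CpG%")
    spectra = {}
    cpg = {}
    accepted = catalog.accepted_keys
    for g in macros:
        unique: dict[str, variantcall.Variant] = {}
        for p in by_macro[g]:
            for av in p.variants:
                if av.variant.kind == "substitution":
                    unique.setdefault(av.key, av.variant)
        all_vars = list(unique.values())
        disease_vars = [v for k, v in unique.items() if k in accepted]
        spectra[g] = sigdate.spectrum_96(all_vars, config.reference_name)
        sigdate.write_spectrum(out / f"spectrum_{g}.tsv", spectra[g])
        cpg[f"{g}:all"] = sigdate.cpg_fraction(all_vars, ref)
        cpg[f"{g}:disease"] = sigdate.cpg_fraction(disease_vars, ref)
        for label in ("all", "disease"):
            st = cpg[f"{g}:{label}"]
            lines.append(
                f"{g} {label}: CpG% {st.percent:.2f} "
                f"(C>T-only {st.percent_c_to_t:.2f}) of {st.n_total} variants"
                if st.defined else f"{g} {label}: no variants"
            )
    lines.append("")

    # -- rho dating --------------------------------------------------------
    root_haps = {
        node: haplo.root_haplotype(tree, node) for node in tree.major_nodes
    }
    rho_estimates, rho_of = sigdate.clade_rho_per_sample(
        profiles, major_of, root_haps, mode=config.genealogy_mode
    )
    sigdate.write_rho(
        out / "rho.tsv",
        [rho_estimates[c] for c in sorted(rho_estimates)],
    )
    lines.append("## Age (rho) vs pathogenicity")
    age_assoc = None
    try:
        age_assoc = sigdate.age_pathogenicity_association(profiles, rho_of)
        lines.append(
            f"carriers mean rho {age_assoc.carrier_mean_rho:.3f} "
            f"(n={age_assoc.n_carriers}) vs non-carriers "
            f"{age_assoc.noncarrier_mean_rho:.3f} "
            f"(n={age_assoc.n_noncarriers}); Wilcoxon p "
            f"{popstats.format_p(age_assoc.wilcoxon_p)}; "
            f"score-rho r {age_assoc.score_rho_r:.3f} "
            f"(p {popstats.format_p(age_assoc.score_rho_p)})"
        )
        if age_assoc.score_rho_r_excl is not None:
            lines.append(
                f"after removing main pathogenic allele: r "
                f"{age_assoc.score_rho_r_excl:.3f} "
                f"(p {popstats.format_p(age_assoc.score_rho_p_excl)})"
            )
    except ValueError as exc:
        lines.append(f"not evaluable: {exc}")
    lines.append("")

    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    config.to_yaml(out / "config_used.yaml")
    _log(quiet, "report", t0, f"written to {out / 'report.txt'}")

    return RunResult(
        config=config, profiles=profiles, kept=kept, afs=afs,
        cooccurrence=cooc, scan=scan, spectra=spectra, cpg=cpg,
        rho_estimates=rho_estimates, age_association=age_assoc,
        report_lines=lines,
    )
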