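from __future__ import annotations

import pytest

from mitopop.haplo import HaploAssignment, HaploTree
from mitopop.patho import AnnotatedVariant, SequenceProfile
from mitopop.refdata import GeneAnnotation, ReferenceGenome
from mitopop.synth import SimulationConfig, simulate_cohort, simulate_reference
from mitopop.variantcall import Variant, parse_variant_key


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulated cohort (with sequences) for integration
    tests: 60 sequences per macro group, default study conditions."""
    config = SimulationConfig(
        seed=11, cohort_sizes={"L": 60, "M": 60, "N": 60}
    )
    bundle = simulate_reference(config)
    cohort = simulate_cohort(config, bundle, sequences=True)
    return config, bundle, cohort


@pytest.fixture
def toy_tree():
    """root -> A (marker m1) -> A1 (marker m2)."""
    return HaploTree(
        {
            "root": (None, ()),
            "A": ("root", ("m.5A>G",)),
            "A1": ("A", ("m.9C>T",)),
        }
    )


def make_profile(
    sample_id: str,
    keys: list[str],
    accepted: set[str] = frozenset(),
    scores: dict[str, float] | None = None,
    macro: str = "",
) -> SequenceProfile:
    """Build a SequenceProfile directly from variant keys (bypassing
    alignment/annotation) for statistics-level tests."""
    scores = scores or {}
    variants = []
    for key in keys:
        pos, ref, alt = parse_variant_key(key)
        av = AnnotatedVariant(variant=Variant(pos, ref, alt, "substitution"))
        av.disease_flag = key in accepted
        if key in scores:
            av.pathogenicity = scores[key]
        variants.append(av)
    assignment = None
    if macro:
        assignment = HaploAssignment(
            sample_id=sample_id, best_node=macro, path_markers_expected=1,
            path_markers_found=1, coverage=1.0, tagged=False, macro=macro,
            ambiguous=False,
        )
    return SequenceProfile(
        sample_id=sample_id, variants=variants, assignment=assignment
    )


@pytest.fixture
def coding_ref():
    """Tiny reference with a forward gene, a reverse gene and an
    overlapping out-of-frame pair, for genetic-code tests.

    Layout (1-based):  FWD 11..19 = ATG GCT TGG;  REV 31..39 (minus strand);
    OLP1 51..62, OLP2 53..64 (frames differ by 2).
    """
    seq = list("A" * 80)
    seq[10:19] = "ATGGCTTGG"          # FWD: Met-Ala-Trp
    # REV on minus strand: coding sequence = revcomp(ref[30:39])
    seq[30:39] = "TTACATCAT"          # revcomp -> ATGATGTAA : Met-Met-Stop
    seq[50:64] = "ATGAAACCCGGGTT"
    genes = [
        GeneAnnotation("FWD", 11, 19, "+", "protein", 0),
        GeneAnnotation("REV", 31, 39, "-", "protein", 0),
        GeneAnnotation("OLP1", 51, 62, "+", "protein", 0),
        GeneAnnotation("OLP2", 53, 64, "+", "protein", 0),
        GeneAnnotation("TRNX", 66, 75, "+", "tRNA", 0),
    ]
    return ReferenceGenome("codingtoy", "".join(seq), genes)
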