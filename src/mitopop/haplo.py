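"""Haplogroup classification against a marker-annotated tree.

A haplogroup tree is a rooted tree whose edges carry *defining markers* —
substitution keys (``m.<POS><REF>><ALT>``) accumulated along the path from
the root. Classification scores every node by *marker coverage*: the
fraction of the markers expected on the root→node path that the sample
actually carries. This is a deliberate simplification of production
haplogroup callers' weighted measures, with identical behaviour on
complete marker profiles.

Back mutations follow the ``!`` convention used by the reference human
mtDNA tree: a marker written ``m.152T>C!`` on a branch removes the earlier
``m.152T>C`` expectation from the path set.

The QC split mirrors population-dataset practice: a sample is
*sub-haplogroup tagged* when its best node is a leaf and every expected
path marker was observed; the dual-classifier concordance filter drops
samples whose coverage is below 0.90, whose best node was an ambiguous
tie, or whose two independent classifications disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from mitopop.refdata import FormatError


@dataclass(frozen=True)
class HaploAssignment:
    sample_id: str
    best_node: str
    path_markers_expected: int
    path_markers_found: int
    coverage: float
    tagged: bool
    macro: str  # designated macro-haplogroup ancestor name, or ""
    ambiguous: bool


class HaploTree:
    """Rooted haplogroup tree with per-branch defining markers.

    ``nodes`` maps name → (parent or None, tuple of marker strings).
    Macro-level nodes (the deepest splits, e.g. L/M/N) and major-level
    nodes are designated explicitly rather than inferred, since haplogroup
    nomenclature does not encode levels consistently.
    """

    def __init__(
        self,
        nodes: Mapping[str, tuple[str | None, tuple[str, ...]]],
        macro_nodes: Iterable[str] = (),
        major_nodes: Iterable[str] = (),
    ) -> None:
        self.nodes = {k: (p, tuple(m)) for k, (p, m) in nodes.items()}
        self.macro_nodes = tuple(macro_nodes)
        self.major_nodes = tuple(major_nodes)
        roots = [n for n, (p, _) in self.nodes.items() if p is None]
        if len(roots) != 1:
            raise FormatError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for n, (p, _) in self.nodes.items():
            if p is not None and p not in self.nodes:
                raise FormatError(f"node {n!r} has unknown parent {p!r}")
        # detect cycles / unreachable nodes and precompute paths
        self._path_cache: dict[str, tuple[str, ...]] = {}
        for n in self.nodes:
            self._path_cache[n] = self._walk(n)
        children: dict[str, list[str]] = {n: [] for n in self.nodes}
        for n, (p, _) in self.nodes.items():
            if p is not None:
                children[p].append(n)
        self.children = children
        self.leaves = frozenset(n for n, c in children.items() if not c)
        self._expected_cache: dict[str, frozenset[str]] = {}

    def _walk(self, node: str) -> tuple[str, ...]:
        path = []
        seen = set()
        cur: str | None = node
        while cur is not None:
            if cur in seen:
                raise FormatError(f"cycle in tree at node {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur][0]
        return tuple(reversed(path))  # root ... node

    def path(self, node: str) -> tuple[str, ...]:
        if node not in self.nodes:
            raise KeyError(f"unknown node {node!r}")
        return self._path_cache[node]

    def depth(self, node: str) -> int:
        return len(self.path(node)) - 1

    def expected_markers(self, node: str) -> frozenset[str]:
        """Markers expected in a sample sitting at ``node`` (back mutations
        resolved)."""
        if node not in self._expected_cache:
            self._expected_cache[node] = frozenset(
                _resolve_back_mutations(
                    m for anc in self.path(node) for m in self.nodes[anc][1]
                )
            )
        return self._expected_cache[node]

    def macro_of(self, node: str) -> str:
        """Name of the designated macro-level ancestor of ``node`` (deepest
        one on the path), or '' if none."""
        macro = ""
        for anc in self.path(node):
            if anc in self.macro_nodes:
                macro = anc
        return macro

    def major_of(self, node: str) -> str:
        major = ""
        for anc in self.path(node):
            if anc in self.major_nodes:
                major = anc
        return major


def _resolve_back_mutations(markers: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for m in markers:
        if m.endswith("!"):
            out.discard(m[:-1])
        else:
            out.add(m)
    return out


def root_haplotype(tree: HaploTree, node: str) -> set[str]:
    """Variant keys defining ``node`` relative to the tree root.

    The union of defining markers along the root→node path, with
    ``!``-suffixed back mutations cancelling their earlier expectation.
    """
    if node not in tree.nodes:
        raise KeyError(f"unknown node {node!r}")
    return set(tree.expected_markers(node))


def classify(
    variants: set[str],
    tree: HaploTree,
    sample_id: str = "sample",
    tie_break: str = "lexicographic",
) -> HaploAssignment:
    """Assign a variant profile to the best-covered tree node.

    The best node maximizes coverage = found/expected path markers; ties
    go to the deeper node, then to the higher found-marker count, then to
    node-name order (ascending for ``tie_break="lexicographic"``,
    descending for ``"reverse"``, giving a second independent classifier
    for concordance QC). A tie surviving to the name stage sets
    ``ambiguous``. An empty profile lands on the root with vacuous
    coverage 1.0.
    """
    if tie_break not in ("lexicographic", "reverse"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    best_name = None
    best_rank: tuple[float, int, int] | None = None
    tied = False
    for node in tree.nodes:
        expected = tree.expected_markers(node)
        n_exp = len(expected)
        n_found = len(expected & variants)
        coverage = n_found / n_exp if n_exp else 1.0
        rank = (coverage, tree.depth(node), n_found)
        if best_rank is None or rank > best_rank:
            best_rank = rank
            best_name = node
            tied = False
        elif rank == best_rank:
            tied = True
            better = (node < best_name) if tie_break == "lexicographic" \
                else (node > best_name)
            if better:
                best_name = node
    assert best_name is not None and best_rank is not None
    expected = tree.expected_markers(best_name)
    n_exp = len(expected)
    n_found = len(expected & variants)
    coverage = n_found / n_exp if n_exp else 1.0
    tagged = best_name in tree.leaves and coverage == 1.0 and n_exp > 0
    return HaploAssignment(
        sample_id=sample_id,
        best_node=best_name,
        path_markers_expected=n_exp,
        path_markers_found=n_found,
        coverage=coverage,
        tagged=tagged,
        macro=tree.macro_of(best_name),
        ambiguous=tied,
    )


def qc_filter(
    run1: Mapping[str, HaploAssignment],
    run2: Mapping[str, HaploAssignment],
    min_coverage: float = 0.90,
) -> dict[str, bool]:
    """Keep/drop decision per sample from two independent classifications.

    Drop iff coverage < ``min_coverage``, or either run was ambiguous, or
    the two runs' best nodes differ. Both runs must cover the same ids.
    """
    if set(run1) != set(run2):
        only1 = sorted(set(run1) - set(run2))[:5]
        only2 = sorted(set(run2) - set(run1))[:5]
        raise ValueError(
            f"sample id mismatch between runs (e.g. {only1} vs {only2})"
        )
    keep: dict[str, bool] = {}
    for sid, a1 in run1.items():
        a2 = run2[sid]
        drop = (
            a1.coverage < min_coverage
            or a1.ambiguous
            or a2.ambiguous
            or a1.best_node != a2.best_node
        )
        keep[sid] = not drop
    return keep


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def load_tree(path: str | Path) -> HaploTree:
    """Load a tree TSV: node, parent ('-' for root), comma-joined markers,
    level ('' | macro | major)."""
    nodes: dict[str, tuple[str | None, tuple[str, ...]]] = {}
    macro, major = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("node\t"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 columns")
            name, parent, markers_s = f[0], f[1], f[2]
            level = f[3] if len(f) > 3 else ""
            markers = tuple(m for m in markers_s.split(",") if m)
            nodes[name] = (None if parent in ("-", "") else parent, markers)
            if level == "macro":
                macro.append(name)
            elif level == "major":
                major.append(name)
    return HaploTree(nodes, macro_nodes=macro, major_nodes=major)


def write_tree(path: str | Path, tree: HaploTree) -> None:
    with open(path, "w") as fh:
        fh.write("# haplogroup tree; markers are m.<POS><REF>><ALT> keys\n")
        fh.write("node\tparent\tmarkers\tlevel\n")
        for name, (parent, markers) in tree.nodes.items():
            level = (
                "macro" if name in tree.macro_nodes
                else "major" if name in tree.major_nodes else ""
            )
            fh.write(
                f"{name}\t{parent if parent is not None else '-'}\t"
                f"{','.join(markers)}\t{level}\n"
            )


def write_assignments(
    path: str | Path, assignments: Iterable[HaploAssignment]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tbest_node\tmacro\texpected\tfound\tcoverage\t"
            "tagged\tambiguous\n"
        )
        for a in assignments:
            fh.write(
                f"{a.sample_id}\t{a.best_node}\t{a.macro}\t"
                f"{a.path_markers_expected}\t{a.path_markers_found}\t"
                f"{a.coverage:.4f}\t{int(a.tagged)}\t{int(a.ambiguous)}\n"
            )
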