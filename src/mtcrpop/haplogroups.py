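"""Motif-based haplogroup classification.

A haplogroup tree is a rooted tree of named nodes, each carrying a branch
motif: the variants gained on that branch plus back-mutations (``@NNN``,
meaning an earlier variant at that position is lost).  A haplotype is
assigned to the node whose cumulative motif it matches best within the
sample's analysed range.

The scoring rule is ``matched - missing`` over the expected variants that
fall inside the analysed range, with deterministic tie-breaks (fewer
private variants, then greater depth, then name).  Expected sites outside
the analysed range are never penalised, which is what makes HVS-I-only
profiles classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from ._util import round_half_up
from .codec import Haplotype, HaplotypeError, Variant, normalize, parse_tokens


class TreeError(ValueError):
    """Raised for malformed motif-tree input."""


@dataclass
class HaplogroupNode:
    name: str
    parent: str | None
    gains: tuple[Variant, ...]
    losses: tuple[int, ...]  # positions back-mutated on this branch
    children: list[str] = field(default_factory=list)
    depth: int = 0


class HaplogroupTree:
    """Rooted motif tree with cumulative-state computation."""

    def __init__(self, nodes: dict[str, HaplogroupNode], root: str):
        self.nodes = nodes
        self.root = root
        self._cumulative: dict[str, frozenset[Variant]] = {}
        self._compute_states()

    def _compute_states(self) -> None:
        order = [self.root]
        seen = {self.root}
        for name in order:
            node = self.nodes[name]
            for child in node.children:
                if child in seen:
                    raise TreeError(f"cycle through {child}")
                seen.add(child)
                order.append(child)
        if len(order) != len(self.nodes):
            missing = set(self.nodes) - seen
            raise TreeError(f"unreachable nodes (orphan parents?): {sorted(missing)}")
        for name in order:
            node = self.nodes[name]
            state = dict()
            if node.parent is not None:
                parent_state = self._cumulative[node.parent]
                state = {(v.position, v.insertion_index): v for v in parent_state}
                self.nodes[name].depth = self.nodes[node.parent].depth + 1
            for pos in node.losses:
                key = next((k for k in state if k[0] == pos), None)
                if key is None:
                    raise TreeError(
                        f"{name}: back-mutation @{pos} without an ancestral variant"
                    )
                del state[key]
            for v in node.gains:
                if (v.position, v.insertion_index) in state:
                    raise TreeError(
                        f"{name}: motif variant {v.token()} already in ancestral state"
                    )
                state[(v.position, v.insertion_index)] = v
            self._cumulative[name] = frozenset(state.values())

    def cumulative_state(self, name: str) -> frozenset[Variant]:
        """Union of motifs along the root path, back-mutations removed."""
        return self._cumulative[name]

    def is_internal(self, name: str) -> bool:
        return bool(self.nodes[name].children)

    def root_path(self, name: str) -> list[str]:
        path = [name]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def _parse_motif(text: str) -> tuple[tuple[Variant, ...], tuple[int, ...]]:
    gains: list[Variant] = []
    losses: list[int] = []
    for token in text.split():
        if token.startswith("@"):
            losses.append(int(token[1:]))
        else:
            gains.extend(parse_tokens(token))
    return tuple(gains), tuple(losses)


def load_tree(source) -> HaplogroupTree:
    """Load a motif tree from a TSV of (Name, Parent, Motif) rows.

    The root row has an empty Parent; motif tokens use the difference-codec
    grammar plus ``@NNN`` back-mutations.  ``#`` lines are comments.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    nodes: dict[str, HaplogroupNode] = {}
    root: str | None = None
    header_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if not header_seen and fields[0] == "Name":
            header_seen = True
            continue
        name = fields[0].strip()
        parent = fields[1].strip() if len(fields) > 1 else ""
        motif = fields[2].strip() if len(fields) > 2 else ""
        if not name:
            raise TreeError(f"line {lineno}: empty node name")
        if name in nodes:
            raise TreeError(f"line {lineno}: duplicate node {name}")
        try:
            gains, losses = _parse_motif(motif)
        except HaplotypeError as exc:
            raise TreeError(f"line {lineno}: {exc}") from None
        nodes[name] = HaplogroupNode(name, parent or None, gains, losses)
        if not parent:
            if root is not None:
                raise TreeError(f"two roots: {root} and {name}")
            root = name
    if root is None:
        raise TreeError("no root row (empty Parent) found")
    for node in nodes.values():
        if node.parent is not None:
            if node.parent not in nodes:
                raise TreeError(f"{node.name}: undefined parent {node.parent}")
            nodes[node.parent].children.append(node.name)
    return HaplogroupTree(nodes, root)


def packaged_tree() -> HaplogroupTree:
    """The curated motif tree shipped for tests and simulations.

    A test resource: ~100 nodes covering the haplogroup labels of a
    Southeast Asian control-region survey with plausible
    motifs; not a phylotree redistribution.
    """
    path = resources.files("mtcrpop.data").joinpath("haplogroup_tree.tsv")
    with path.open() as handle:
        return load_tree(handle)


def packaged_counts() -> list[tuple[str, int]]:
    """The packaged haplogroup frequency fixture as (label, count) rows."""
    path = resources.files("mtcrpop.data").joinpath("survey_haplogroup_counts.tsv")
    rows: list[tuple[str, int]] = []
    with path.open() as handle:
        for line in handle:
            if not line.strip() or line.startswith("#") or line.startswith("Haplogroup"):
                continue
            label, n = line.rstrip("\n").split("\t")
            rows.append((label, int(n)))
    return rows


def assignments_from_counts(
    counts: Sequence[tuple[str, int]], tree: HaplogroupTree
) -> list["Assignment"]:
    """Expand a (label, count) table into per-sample assignments.

    Display labels may carry a trailing paragroup ``*``, which is stripped
    to recover the node name; match/miss/private bookkeeping is zeroed as
    the underlying profiles are not part of the table.
    """
    out: list[Assignment] = []
    i = 0
    for label, n in counts:
        name = label.rstrip("*")
        if name not in tree:
            raise TreeError(f"label {label!r} not in tree")
        if label.endswith("*") != tree.is_internal(name):
            raise TreeError(f"paragroup star of {label!r} inconsistent with tree")
        for _ in range(n):
            i += 1
            out.append(Assignment(f"S{i:04d}", name, 0, 0, 0))
    return out


@dataclass(frozen=True)
class Assignment:
    """Best-matching haplogroup for one sample."""

    sample_id: str
    haplogroup: str
    matched: int
    missing: int
    private: int

    def label(self, tree: HaplogroupTree) -> str:
        """Display label; paragroup membership gets a trailing ``*``."""
        return self.haplogroup + ("*" if tree.is_internal(self.haplogroup) else "")


def assign(h: Haplotype, tree: HaplogroupTree) -> Assignment:
    """Assign a haplotype to its most derived matching haplogroup.

    Every node is scored as matched - missing over its expected variants
    inside the analysed range; ties break to fewer private variants, then
    greater depth, then lexicographically smaller name.
    """
    if len(tree) == 0:
        raise TreeError("empty tree")
    observed = {(v.position, v.insertion_index): v for v in normalize(h).variants}
    best: tuple | None = None
    for name in tree.nodes:
        expected = [v for v in tree.cumulative_state(name) if h.covers(v.position)]
        matched = sum(
            1
            for v in expected
            if observed.get((v.position, v.insertion_index)) == v
        )
        missing = len(expected) - matched
        matched_sites = {
            (v.position, v.insertion_index)
            for v in expected
            if observed.get((v.position, v.insertion_index)) == v
        }
        private = len(observed) - len(matched_sites)
        score = matched - missing
        key = (-score, private, -tree.nodes[name].depth, name)
        if best is None or key < best[0]:
            best = (key, name, matched, missing, private)
    _, name, matched, missing, private = best
    return Assignment(h.sample_id, name, matched, missing, private)


def rollup(name: str, tree: HaplogroupTree, targets: Iterable[str]) -> str:
    """Nearest ancestor (or self) whose name is in ``targets``."""
    targets = set(targets)
    unknown = targets - set(tree.nodes)
    if name not in tree:
        raise TreeError(f"unknown haplogroup {name}")
    if unknown:
        raise TreeError(f"unknown rollup targets {sorted(unknown)}")
    for ancestor in tree.root_path(name):
        if ancestor in targets:
            return ancestor
    raise TreeError(f"no rollup target on the root path of {name}")


def tally(
    assignments: Sequence[Assignment],
    tree: HaplogroupTree,
    level: Iterable[str] | str = "as-assigned",
    percent_decimals: int = 1,
) -> list[tuple[str, int, float]]:
    """Frequency table of assignments as (label, count, percent) rows.

    ``level`` is either ``"as-assigned"`` (paragroup-starred display
    labels) or a set of clade names to roll counts up to.  Percentages are
    over the total sample count and rounded half-up.
    """
    counts: dict[str, int] = {}
    for a in assignments:
        if level == "as-assigned":
            label = a.label(tree)
        else:
            label = rollup(a.haplogroup, tree, level)
        counts[label] = counts.get(label, 0) + 1
    total = sum(counts.values())
    return [
        (label, n, round_half_up(100.0 * n / total, percent_decimals))
        for label, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def write_assignments(assignments: Sequence[Assignment], tree: HaplogroupTree, target) -> None:
    if isinstance(target, (str, Path)):
        handle = Path(target).open("w", encoding="utf-8", newline="\n")
        close = True
    else:
        handle, close = target, False
    try:
        handle.write("SampleId\tHaplogroup\tMatched\tMissing\tPrivate\n")
        for a in assignments:
            handle.write(
                f"{a.sample_id}\t{a.label(tree)}\t{a.matched}\t{a.missing}\t{a.private}\n"
            )
    finally:
        if close:
            handle.close()
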