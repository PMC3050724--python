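"""Quasi-median networks for a-posteriori data quality control.

The idea: condense a set of haplotypes to their variable characters,
close the state set under the quasi-median operation, and inspect the
resulting network.  Reticulations and edges carrying rare event classes
(transversions, unfiltered indels) point at possible sequence errors.

For every triple of states the quasi-median takes, per character, the
majority state if two agree, otherwise each of the three states (a
cartesian expansion over the undecided characters).  On binary characters
this reduces to the classical median closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

import networkx as nx

from . import reference as ref
from .codec import Haplotype, Interval, normalize, restrict

#: Filter preset applied before network construction: the hotspot
#: C-insertion anchors plus the hypervariable 16519 and the 573 indel
#: region.  An approximation of database-internal "speedy" filters;
#: fully user-configurable.
CR_SPEEDY = frozenset({16193, 309, 573, 16519})

REF_STATE = "ref"


@dataclass
class Character:
    """One network character: its constituent positions and states.

    ``site_states`` maps, for every constituent position, the character's
    row-state label (taken from the representative column) to that
    position's own state -- needed to classify events on merged
    characters position by position.
    """

    positions: tuple[tuple[int, int], ...]  # (position, insertion_index)
    states: tuple[str, ...]  # distinct state labels, reference included
    site_states: tuple[dict, ...] = ()

    def label(self) -> str:
        return "+".join(
            str(p) if k == 0 else f"{p}.{k}" for p, k in self.positions
        )


@dataclass
class CharacterMatrix:
    """Condensed haplotype states by characters, with node weights."""

    characters: list[Character]
    rows: list[tuple[str, ...]]  # state vector per condensed haplotype
    weights: list[int]
    annotations: list[set]  # e.g. haplogroup labels per condensed row


def condense(
    haplotypes: Sequence[Haplotype],
    window: Sequence[Interval],
    filter_positions: Iterable[int] = CR_SPEEDY,
    labels: Sequence[str] | None = None,
) -> CharacterMatrix:
    """Build the condensed character matrix of a haplotype sample.

    Per-site character columns (indels become binary presence characters)
    are built over the window; filtered and invariant columns are
    dropped, columns inducing identical partitions of the rows are merged
    (position lists concatenated), and identical rows are collapsed with
    their multiplicities summed.
    """
    filtered = frozenset(filter_positions)
    restricted = [normalize(restrict(h, window)) for h in haplotypes]
    sites: set[tuple[int, int]] = set()
    maps = []
    for h in restricted:
        m = {(v.position, v.insertion_index): v.observed for v in h}
        maps.append(m)
        sites.update(k for k in m if k[0] not in filtered)

    columns: list[tuple[tuple[int, int], tuple[str, ...]]] = []
    for site in sorted(sites):
        states = tuple(m.get(site, REF_STATE) for m in maps)
        if len(set(states)) > 1:  # drop invariant columns
            columns.append((site, states))

    # merge columns inducing identical partitions of the rows
    merged: dict[tuple[tuple[int, ...], ...], list] = {}
    order: list = []
    for site, states in columns:
        partition_of: dict[str, list[int]] = {}
        for i, s in enumerate(states):
            partition_of.setdefault(s, []).append(i)
        key = tuple(sorted(tuple(ix) for ix in partition_of.values()))
        if key in merged:
            merged[key][0].append((site, states))
        else:
            merged[key] = [[(site, states)], states]
            order.append(key)

    characters = []
    matrix_cols = []
    for key in order:
        site_cols, rep_states = merged[key]
        site_states = tuple(
            {rep_states[i]: col[i] for i in range(len(rep_states))}
            for _, col in site_cols
        )
        characters.append(
            Character(
                tuple(site for site, _ in site_cols),
                tuple(dict.fromkeys(rep_states)),
                site_states,
            )
        )
        matrix_cols.append(rep_states)

    # collapse identical rows
    row_index: dict[tuple[str, ...], int] = {}
    rows: list[tuple[str, ...]] = []
    weights: list[int] = []
    annotations: list[set] = []
    for i in range(len(restricted)):
        row = tuple(col[i] for col in matrix_cols)
        if row in row_index:
            j = row_index[row]
            weights[j] += 1
            if labels is not None:
                annotations[j].add(labels[i])
        else:
            row_index[row] = len(rows)
            rows.append(row)
            weights.append(1)
            annotations.append({labels[i]} if labels is not None else set())
    return CharacterMatrix(characters, rows, weights, annotations)


class NodeCapExceeded(RuntimeError):
    """Closure growth exceeded the cap -- pathological/unfiltered data."""


def _quasi_medians(a: tuple, b: tuple, c: tuple) -> Iterable[tuple]:
    choices = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            choices.append((x,))
        elif y == z:
            choices.append((y,))
        else:
            choices.append((x, y, z))
    return product(*choices)


@dataclass
class QmNetwork:
    """Closure of a condensed sample under the quasi-median operation."""

    characters: list[Character]
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def observed_nodes(self) -> list[tuple]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("observed")]


def qm_closure(cm: CharacterMatrix, node_cap: int = 10_000) -> QmNetwork:
    """Close the condensed states under quasi-medians and build edges.

    Triples are enumerated in canonical (sorted-state) order so output is
    deterministic; growth past ``node_cap`` raises
    :class:`NodeCapExceeded`, which is the QC signal itself.
    """
    states = set(cm.rows)
    frontier = set(states)
    while frontier:
        current = sorted(states)
        new: set[tuple] = set()
        for triple in combinations(current, 3):
            if not (triple[0] in frontier or triple[1] in frontier or triple[2] in frontier):
                continue
            for qm in _quasi_medians(*triple):
                if qm not in states:
                    new.add(qm)
        if len(states) + len(new) > node_cap:
            raise NodeCapExceeded(
                f"quasi-median closure grew past {node_cap} nodes "
                f"({len(states)} + {len(new)} candidates)"
            )
        states |= new
        frontier = new

    net = QmNetwork(cm.characters)
    observed = {row: (w, ann) for row, w, ann in zip(cm.rows, cm.weights, cm.annotations)}
    for s in sorted(states):
        if s in observed:
            w, ann = observed[s]
            net.graph.add_node(s, observed=True, weight=w, haplogroups=sorted(ann))
        else:
            net.graph.add_node(s, observed=False, weight=0, haplogroups=[])
    for a, b in combinations(sorted(states), 2):
        diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        if len(diffs) == 1:
            i = diffs[0]
            net.graph.add_edge(
                a, b,
                character=i,
                positions=net.characters[i].label(),
                classes=_edge_classes(net.characters[i], a[i], b[i]),
            )
    return net


def _edge_classes(char: Character, state_a: str, state_b: str) -> tuple[str, ...]:
    """Event classes on an edge: substitution class per position, or indel."""
    classes = []
    for (pos, k), mapping in zip(char.positions, char.site_states):
        sa = mapping.get(state_a, state_a)
        sb = mapping.get(state_b, state_b)
        if sa == sb:  # inferred state combination outside this position's split
            continue
        if k >= 1:
            classes.append("indel")
            continue
        a_base = ref.ref_base(pos) if sa == REF_STATE else sa
        b_base = ref.ref_base(pos) if sb == REF_STATE else sb
        if "DEL" in (a_base, b_base):
            classes.append("indel")
        elif a_base in ref.IUPAC_AMBIGUITY or b_base in ref.IUPAC_AMBIGUITY:
            classes.append("heteroplasmy")
        elif ref.is_transition(a_base, b_base):
            classes.append("transition")
        else:
            classes.append("transversion")
    return tuple(classes)


@dataclass
class QcFlag:
    kind: str  # "edge" or "node"
    detail: str


def qc_flags(net: QmNetwork) -> list[QcFlag]:
    """Machine-readable QC report.

    Flags every edge whose label includes a transversion or an unfiltered
    indel, plus weight-1 singleton nodes attached only by flagged edges.
    """
    flags: list[QcFlag] = []
    flagged_edges = set()
    for a, b, data in net.graph.edges(data=True):
        bad = [c for c in data["classes"] if c in ("transversion", "indel")]
        if bad:
            flagged_edges.add(frozenset((a, b)))
            flags.append(
                QcFlag("edge", f"{data['positions']}: {'/'.join(bad)}")
            )
    for node, data in net.graph.nodes(data=True):
        if not data.get("observed") or data.get("weight") != 1:
            continue
        edges = list(net.graph.edges(node))
        if edges and all(frozenset(e) in flagged_edges for e in edges):
            flags.append(QcFlag("node", f"singleton attached only by flagged edges"))
    return flags


def write_dot(net: QmNetwork, target) -> None:
    """GraphViz DOT export (observed nodes boxed, inferred nodes round)."""
    from pathlib import Path

    handle = Path(target).open("w", encoding="utf-8") if isinstance(target, (str, Path)) else target
    names = {node: f"n{i}" for i, node in enumerate(sorted(net.graph.nodes))}
    handle.write("graph qmnetwork {\n")
    for node, data in sorted(net.graph.nodes(data=True)):
        shape = "box" if data.get("observed") else "circle"
        label = "/".join(data.get("haplogroups") or []) or "-"
        weight = data.get("weight", 0)
        handle.write(
            f'  {names[node]} [shape={shape}, label="{label} ({weight})"];\n'
        )
    for a, b, data in sorted(net.graph.edges(data=True)):
        color = "red" if "transversion" in data["classes"] else "green"
        handle.write(
            f'  {names[a]} -- {names[b]} [label="{data["positions"]}", color={color}];\n'
        )
    handle.write("}\n")
    if isinstance(target, (str, Path)):
        handle.close()


def write_edge_list(net: QmNetwork, target) -> None:
    """TSV edge list: from, to, positions, classes."""
    from pathlib import Path

    handle = Path(target).open("w", encoding="utf-8") if isinstance(target, (str, Path)) else target
    names = {node: f"n{i}" for i, node in enumerate(sorted(net.graph.nodes))}
    handle.write("from\tto\tpositions\tclasses\n")
    for a, b, data in sorted(net.graph.edges(data=True)):
        handle.write(f"{names[a]}\t{names[b]}\t{data['positions']}\t{','.join(data['classes'])}\n")
    if isinstance(target, (str, Path)):
        handle.close()
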