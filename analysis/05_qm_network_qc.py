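#!/usr/bin/env python
"""Quasi-median network quality control of the simulated cohort.

Condenses the cohort's HVS-I haplotypes under the CR-speedy filter,
closes them under quasi-medians, exports the network, and lists the QC
flags (transversion/indel edges, suspicious singletons).
"""

from pathlib import Path

from mtcrpop.haplogroups import assign, packaged_tree
from mtcrpop.io import read_population
from mtcrpop.qmnet import CR_SPEEDY, condense, qc_flags, qm_closure, write_dot, write_edge_list

DATA = Path("results/data")
OUT = Path("results")
HVS1 = ((16024, 16365),)


def main() -> None:
    cohort = read_population(DATA / "cohort.tsv")
    tree = packaged_tree()
    # a haplogroup-labelled subsample keeps the torso readable, as QC
    # portraits are usually drawn per segment on condensed data
    subset = cohort.haplotypes[:60]
    labels = [assign(h, tree).label(tree) for h in subset]
    cm = condense(subset, HVS1, CR_SPEEDY, labels=labels)
    net = qm_closure(cm, node_cap=20_000)
    write_dot(net, OUT / "cohort.qmnet.dot")
    write_edge_list(net, OUT / "cohort.qmnet.edges.tsv")

    observed = sum(1 for _, d in net.graph.nodes(data=True) if d["observed"])
    print(f"{len(cm.characters)} condensed characters over {len(subset)} profiles")
    print(f"network: {net.graph.number_of_nodes()} nodes "
          f"({observed} observed), {net.graph.number_of_edges()} edges")

    flags = qc_flags(net)
    with open(OUT / "cohort.qmnet.flags.tsv", "w", encoding="utf-8") as fh:
        fh.write("kind\tdetail\n")
        for f in flags:
            fh.write(f"{f.kind}\t{f.detail}\n")
    edge_flags = sum(1 for f in flags if f.kind == "edge")
    node_flags = len(flags) - edge_flags
    print(f"QC flags: {edge_flags} rare-event edges, {node_flags} suspicious "
          f"singletons (candidates for re-inspection of the raw calls)")


if __name__ == "__main__":
    main()
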