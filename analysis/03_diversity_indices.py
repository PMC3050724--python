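#!/usr/bin/env python
"""Forensic diversity indices of the simulated cohort.

Computes the haplotype spectrum, random match probability, power of
discrimination and mean pairwise differences over the full control
region, plus the heteroplasmy census, and the distance between the two
packaged most-common haplotypes.
"""

from importlib import resources
from pathlib import Path

from mtcrpop._util import round_half_up
from mtcrpop.diversity import heteroplasmy_census, pair_diff, summarize, write_report
from mtcrpop.io import read_population
from mtcrpop.reference import CONTROL_REGION

DATA = Path("results/data")
OUT = Path("results")


def main() -> None:
    cohort = read_population(DATA / "cohort.tsv")
    s = summarize(cohort, CONTROL_REGION)
    write_report([s], OUT / "cohort.diversity.tsv")
    print(f"n = {s.n}, distinct haplotypes = {s.k} "
          f"({round_half_up(100 * s.proportion_haplotypes)}%), "
          f"unique = {s.singletons} ({round_half_up(100 * s.proportion_unique)}%)")
    print(f"MPD = {s.mpd:.2f} +/- {s.mpd_sd:.2f}; "
          f"RMP = {100 * s.rmp:.2f}%; PD = {100 * s.pd:.2f}%")

    counts, prop = heteroplasmy_census(cohort)
    print(f"heteroplasmic profiles: {round_half_up(100 * prop, 1)}% "
          f"({len(counts)} distinct heteroplasmies)")

    with resources.files("mtcrpop.data").joinpath("common_haplotypes.tsv").open() as fh:
        common = read_population(fh, name="common")
    d = pair_diff(common.haplotypes[0], common.haplotypes[1], CONTROL_REGION)
    print(f"distance between the two packaged most-common haplotypes: {d} sites")


if __name__ == "__main__":
    main()
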