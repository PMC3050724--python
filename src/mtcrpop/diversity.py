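"""Per-population forensic diversity statistics.

Haplotype identity follows the forensic matching convention (C-tract
insertions at the hotspot anchors and point heteroplasmies disregarded);
pairwise differences are counted site-wise on normalized, range-restricted
profiles.  The variance attached to the mean number of pairwise
differences is the standard total (stochastic + sampling) variance of
nucleotide diversity,

    Var(pi) = [3n(n+1) pi + 2(n^2+n+3) pi^2] / [11(n^2 - 7n + 6)],

the convention behind the +/- values of the common AMOVA software.
"""

from __future__ import annotations

import math

import numpy as np
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

from . import reference as ref
from ._util import fmt
from .codec import Haplotype, Interval, match_key, normalize, restrict
from .io import PopulationSample


@dataclass(frozen=True)
class DiversitySummary:
    """Table-row summary of one population over one analysis window."""

    population: str
    n: int
    k: int
    singletons: int
    proportion_haplotypes: float
    proportion_unique: float
    mpd: float
    mpd_sd: float
    rmp: float

    @property
    def pd(self) -> float:
        """Power of discrimination, the exact complement of the RMP."""
        return 1.0 - self.rmp


def spectrum(pop: PopulationSample, window: Sequence[Interval]) -> Counter:
    """MatchKey -> count map of a population over a window."""
    return Counter(match_key(h, window) for h in pop)


def rmp(spec: Counter) -> float:
    """Random match probability: sum of squared haplotype frequencies."""
    n = sum(spec.values())
    if n == 0:
        raise ValueError("empty spectrum")
    return sum((c / n) ** 2 for c in spec.values())


def power_of_discrimination(spec: Counter) -> float:
    return 1.0 - rmp(spec)


def pair_diff(h1: Haplotype, h2: Haplotype, window: Sequence[Interval]) -> int:
    """Number of sites at which two haplotypes differ over a window.

    Site-wise symmetric difference of the normalized, restricted variant
    sets: a site where both samples are non-reference but disagree
    (16266A vs 16266G) counts once; an absent variant means reference.
    """
    a = {(v.position, v.insertion_index): v.observed
         for v in normalize(restrict(h1, window))}
    b = {(v.position, v.insertion_index): v.observed
         for v in normalize(restrict(h2, window))}
    return sum(1 for site in set(a) | set(b) if a.get(site) != b.get(site))


def tajima_variance(pi: float, n: int) -> float:
    """Total variance of the mean number of pairwise differences.

    Defined for n >= 7 only: the denominator 11(n-1)(n-6) is non-positive
    below that, where the convention has no meaningful estimate.
    """
    if n < 7:
        raise ValueError("tajima_variance needs n >= 7")
    num = 3 * n * (n + 1) * pi + 2 * (n * n + n + 3) * pi * pi
    den = 11 * (n * n - 7 * n + 6)
    return num / den


def mpd_within(pop: PopulationSample, window: Sequence[Interval]) -> tuple[float, float]:
    """Mean pairwise differences over all unordered pairs, with its SD."""
    n = len(pop)
    if n < 2:
        raise ValueError("mpd_within needs n >= 2")
    haps = [normalize(restrict(h, window)) for h in pop]
    diffs = [pair_diff(a, b, window) for a, b in combinations(haps, 2)]
    mean = sum(diffs) / len(diffs)
    if n >= 7:
        sd = math.sqrt(tajima_variance(mean, n))
    else:  # total variance undefined for tiny n; fall back to descriptive SD
        sd = float(np.std(diffs)) if len(diffs) > 1 else 0.0
    return mean, sd


def mpd_between(
    popA: PopulationSample, popB: PopulationSample, window: Sequence[Interval]
) -> tuple[float, float]:
    """Mean cross-population pairwise differences and the corrected value.

    corrected = d_AB - (pi_A + pi_B)/2; may legitimately fall below zero
    and is reported unclamped.
    """
    if len(popA) == 0 or len(popB) == 0:
        raise ValueError("empty population")
    hapsA = [normalize(restrict(h, window)) for h in popA]
    hapsB = [normalize(restrict(h, window)) for h in popB]
    total = sum(pair_diff(a, b, window) for a in hapsA for b in hapsB)
    between = total / (len(hapsA) * len(hapsB))
    withinA, _ = mpd_within(popA, window)
    withinB, _ = mpd_within(popB, window)
    return between, between - (withinA + withinB) / 2.0


def heteroplasmy_census(pop: PopulationSample) -> tuple[dict[str, int], float]:
    """Census of point heteroplasmies on raw (un-normalized) haplotypes.

    Returns per-variant counts (keyed by token, e.g. ``16261Y``) and the
    proportion of samples carrying at least one heteroplasmic position.
    """
    counts: Counter = Counter()
    flagged = 0
    for h in pop:
        hets = [v for v in h if v.observed in ref.IUPAC_AMBIGUITY]
        if hets:
            flagged += 1
        for v in hets:
            counts[v.token()] += 1
    proportion = flagged / len(pop) if len(pop) else 0.0
    return dict(counts), proportion


def summarize(pop: PopulationSample, window: Sequence[Interval]) -> DiversitySummary:
    spec = spectrum(pop, window)
    n = sum(spec.values())
    k = len(spec)
    singletons = sum(1 for c in spec.values() if c == 1)
    mean, sd = mpd_within(pop, window)
    return DiversitySummary(
        population=pop.name,
        n=n,
        k=k,
        singletons=singletons,
        proportion_haplotypes=k / n,
        proportion_unique=singletons / n,
        mpd=mean,
        mpd_sd=sd,
        rmp=rmp(spec),
    )


def write_report(summaries: Sequence[DiversitySummary], target) -> None:
    """TSV report: population columns, statistic rows, 3-decimal floats."""
    rows = [
        ("Number of samples", lambda s: str(s.n)),
        ("Number of haplotypes", lambda s: str(s.k)),
        ("Proportion of haplotypes", lambda s: fmt(s.proportion_haplotypes, 2)),
        ("Proportion of unique haplotypes", lambda s: fmt(s.proportion_unique, 2)),
        ("Mean pairwise differences", lambda s: f"{fmt(s.mpd)} +/- {fmt(s.mpd_sd)}"),
        ("RMP", lambda s: fmt(s.rmp)),
        ("Power of discrimination", lambda s: fmt(s.pd)),
    ]
    if isinstance(target, (str, Path)):
        handle = Path(target).open("w", encoding="utf-8", newline="\n")
        close = True
    else:
        handle, close = target, False
    try:
        handle.write("Population statistics\t" + "\t".join(s.population for s in summaries) + "\n")
        for label, getter in rows:
            handle.write(label + "\t" + "\t".join(getter(s) for s in summaries) + "\n")
    finally:
        if close:
            handle.close()
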