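"""Synthetic multi-population mtDNA control-region samples.

The generator emulates the structure of a forensic control-region survey
at the granularity the downstream statistics operate on: each sample
draws a haplogroup from population-specific frequencies, inherits the
haplogroup's cumulative control-region motif, and gains Poisson private
mutations, hotspot C-tract insertions and occasional point
heteroplasmies.  Between-population drift follows a Balding-Nichols
style Dirichlet spread of the global haplogroup frequencies:

    f_p ~ Dirichlet(f_global * (1 - F) / F),

which has mean f_global and, per haplogroup, variance
F f (1 - f) -- the classical drift parametrisation; F -> 0 recovers
identical populations.  Truth is fully determined by (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import reference as ref
from .codec import Haplotype, Interval, Variant
from .haplogroups import HaplogroupTree, packaged_counts, packaged_tree
from .io import PopulationSample

#: Per-site probability of a hotspot C-insertion in a simulated profile.
#: 309.1C and 315.1C are the near-ubiquitous HVS-II tract events, the
#: 16193 and 573 tracts are rarer.
DEFAULT_CINS_RATES = {315: 0.70, 309: 0.35, 16193: 0.10, 573: 0.03}


@dataclass
class SimConfig:
    """Study conditions for a simulated multi-population survey.

    Defaults mirror the surveyed population: 214 samples per population,
    the packaged haplogroup frequency table, one extra private mutation
    per profile on average with 95% transitions, and a per-sample
    heteroplasmy rate of 4% (population surveys report 1-9.5%).
    """

    populations: int = 1
    sizes: Sequence[int] | int = 214
    tree: HaplogroupTree | None = None
    base_freqs: dict[str, float] | None = None
    drift: float = 0.0
    private_mut_rate: float = 1.0
    ti_fraction: float = 0.95
    het_rate: float = 0.04
    cins_rates: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_CINS_RATES))
    window: tuple[Interval, ...] = ref.CONTROL_REGION
    seed: int = 0

    def resolved_sizes(self) -> list[int]:
        if isinstance(self.sizes, int):
            return [self.sizes] * self.populations
        sizes = list(self.sizes)
        if len(sizes) != self.populations:
            raise ValueError("sizes must match the number of populations")
        return sizes

    def validate(self) -> None:
        if self.populations < 1:
            raise ValueError("need at least one population")
        if not 0.0 <= self.drift < 1.0:
            raise ValueError("drift F must lie in [0, 1)")
        for rate in (self.ti_fraction, self.het_rate, *self.cins_rates.values()):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.private_mut_rate < 0:
            raise ValueError("private_mut_rate must be >= 0")
        if any(s < 1 for s in self.resolved_sizes()):
            raise ValueError("population sizes must be >= 1")


@dataclass
class SampleTruth:
    sample_id: str
    population: str
    haplogroup: str
    private: tuple[Variant, ...]


@dataclass
class SimTruth:
    samples: list[SampleTruth]
    drift: float
    seed: int
    population_freqs: dict[str, dict[str, float]]


def default_base_freqs(tree: HaplogroupTree) -> dict[str, float]:
    """Haplogroup frequencies of the packaged 64-label count fixture."""
    counts = packaged_counts()
    total = sum(n for _, n in counts)
    freqs = {label.rstrip("*"): n / total for label, n in counts}
    missing = [h for h in freqs if h not in tree]
    if missing:
        raise ValueError(f"frequencies name unknown haplogroups {missing}")
    return freqs


def _window_positions(window: Sequence[Interval]) -> np.ndarray:
    return np.concatenate([np.arange(s, e + 1) for s, e in window])


def simulate(cfg: SimConfig) -> tuple[list[PopulationSample], SimTruth]:
    """Draw the configured populations; deterministic under (config, seed)."""
    cfg.validate()
    tree = cfg.tree or packaged_tree()
    base = cfg.base_freqs or default_base_freqs(tree)
    names = list(base)
    base_vec = np.array([base[h] for h in names], dtype=float)
    if abs(base_vec.sum() - 1.0) > 1e-9:
        raise ValueError("base_freqs must sum to 1")
    rng = np.random.default_rng(cfg.seed)
    positions = _window_positions(cfg.window)
    ref_seq = ref.reference_sequence()

    pops: list[PopulationSample] = []
    truths: list[SampleTruth] = []
    pop_freqs: dict[str, dict[str, float]] = {}
    sample_no = 0
    for p, size in enumerate(cfg.resolved_sizes()):
        pop_name = f"pop{p + 1}"
        if cfg.drift == 0.0:
            freqs = base_vec
        else:
            alpha = base_vec * (1.0 - cfg.drift) / cfg.drift
            freqs = rng.dirichlet(np.maximum(alpha, 1e-9))
        pop_freqs[pop_name] = dict(zip(names, freqs.tolist()))
        pop = PopulationSample(pop_name, metadata={"seed": cfg.seed, "drift": cfg.drift})
        for _ in range(size):
            sample_no += 1
            sid = f"{pop_name}_{sample_no:04d}"
            hg = names[rng.choice(len(names), p=freqs)]
            variants = {
                (v.position, v.insertion_index): v for v in tree.cumulative_state(hg)
            }
            private: list[Variant] = []
            for _ in range(rng.poisson(cfg.private_mut_rate)):
                v = _draw_private(rng, positions, variants, ref_seq, cfg.ti_fraction)
                variants[(v.position, v.insertion_index)] = v
                private.append(v)
            for site, rate in cfg.cins_rates.items():
                if rng.random() < rate and (site, 1) not in variants:
                    variants[(site, 1)] = Variant(site, 1, "C")
            if cfg.het_rate > 0 and rng.random() < cfg.het_rate:
                _heteroplasmize(rng, variants, ref_seq)
            pop.haplotypes.append(
                Haplotype(sid, tuple(cfg.window), tuple(variants.values()))
            )
            truths.append(SampleTruth(sid, pop_name, hg, tuple(private)))
        pops.append(pop)
    return pops, SimTruth(truths, cfg.drift, cfg.seed, pop_freqs)


def _draw_private(
    rng: np.random.Generator,
    positions: np.ndarray,
    existing: dict,
    ref_seq: str,
    ti_fraction: float,
) -> Variant:
    """One private substitution at a fresh in-window position.

    Positions already carrying a variant are redrawn so the generating
    haplogroup stays unambiguous.
    """
    while True:
        pos = int(positions[rng.integers(len(positions))])
        if (pos, 0) in existing:
            continue
        base = ref_seq[pos - 1]
        if base not in "ACGT":
            continue
        if rng.random() < ti_fraction:
            observed = ref.transition_partner(base)
        else:
            observed = ["A", "C", "G", "T"][rng.integers(4)]
            while observed == base or ref.is_transition(base, observed):
                observed = ["A", "C", "G", "T"][rng.integers(4)]
        return Variant(pos, 0, observed)


def _heteroplasmize(rng: np.random.Generator, variants: dict, ref_seq: str) -> None:
    """Convert one substitution variant to an IUPAC ambiguity code."""
    subs = [
        k
        for k, v in variants.items()
        if k[1] == 0 and v.observed in "ACGT"
    ]
    if not subs:
        return
    key = subs[rng.integers(len(subs))]
    v = variants[key]
    pair = frozenset((ref_seq[v.position - 1], v.observed))
    code = ref.AMBIGUITY_OF_PAIR.get(pair)
    if code:
        variants[key] = Variant(v.position, 0, code)


def expected_fst(cfg: SimConfig) -> float:
    """The generating drift F, the target of estimator-recovery tests.

    Haplogroup-frequency drift translates to positive Phi_ST;
    monotonicity in F (not equality) is the tested contract.
    """
    if cfg.populations < 2:
        raise ValueError("expected_fst needs at least two populations")
    return cfg.drift


def write_truth(truth: SimTruth, target) -> None:
    from pathlib import Path

    handle = Path(target).open("w", encoding="utf-8", newline="\n") if isinstance(target, (str, Path)) else target
    handle.write(f"# seed = {truth.seed}, drift F = {truth.drift}\n")
    handle.write("SampleId\tPopulation\tHaplogroup\tPrivateVariants\n")
    for s in truth.samples:
        tokens = " ".join(v.token() for v in s.private)
        handle.write(f"{s.sample_id}\t{s.population}\t{s.haplogroup}\t{tokens}\n")
    if isinstance(target, (str, Path)):
        handle.close()
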