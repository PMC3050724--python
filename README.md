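# mtcrpop

Population analysis of human mitochondrial DNA **control-region (CR)
haplotypes** as practised in forensic genetics: difference-coded profiles
against the revised Cambridge Reference Sequence (rCRS), motif-based
haplogroup classification, forensic diversity indices, AMOVA-based
population comparisons, and quasi-median network quality control — plus a
synthetic multi-population generator with known truth, so the whole
pipeline is testable without any external downloads.

It is written for forensic and population geneticists who work with
EMPOP-style tables: one row per donor, an analysed range (e.g.
`16024-16569 1-576`), and a variant list such as
`73-263-315.1C-523del-524del-16140-16183C-16189-16266A-16519`.

## What it computes

**Haplotype codec.** Profiles are parsed into variants (transitions,
transversions, insertions like `315.1C`, deletions like `523del`, IUPAC
point heteroplasmies like `16093Y`), validated against the packaged
reference, range-restricted to a greatest common range, and normalised for
matching by the forensic identity convention: C-insertions after the
hotspot anchors 16193, 309 and 573 and point heteroplasmies are
disregarded.

**Haplogroup classification.** A motif tree (TSV of `Name, Parent, Motif`
rows, `@NNN` for back-mutations) yields a cumulative variant state per
haplogroup; a profile is assigned to the node maximising
`matched − missing` over the expected variants inside its analysed range,
with deterministic tie-breaks. Paragroup assignments are starred (`M*`).

**Diversity.** For a sample of n profiles with haplotype frequencies f_i:

- random match probability `RMP = Σ f_i²`, power of discrimination
  `PD = 1 − RMP`;
- mean pairwise differences `π` over all n(n−1)/2 pairs (site-wise
  symmetric difference), with the standard total variance
  `Var(π) = [3n(n+1)π + 2(n²+n+3)π²] / [11(n²−7n+6)]`;
- corrected between-population MPD `d_AB − (π_A + π_B)/2`;
- a point-heteroplasmy census on the raw profiles.

**Structure.** One-level molecular AMOVA on pairwise-difference distances
(variance components σ²_a, σ²_b, Φ_ST = σ²_a/(σ²_a+σ²_b), permutation
p-values), pairwise Φ_ST matrices, distinct-haplotype sharing reports, and
classical metric MDS of the Φ_ST matrix with Kruskal stress-1.

**Quasi-median network QC.** Haplotypes are condensed (invariant columns
dropped, co-segregating columns merged, identical rows collapsed),
closed under the quasi-median operation, and exported as DOT/TSV;
transversion and indel edges and suspicious singletons are flagged —
reticulations and rare events are where sequencing errors hide.

**Simulator.** Each sample draws a haplogroup from population-specific
frequencies (Balding–Nichols-style Dirichlet drift `f_p ~
Dirichlet(f·(1−F)/F)`), inherits its cumulative motif, and gains Poisson
private mutations, hotspot C-insertions and occasional heteroplasmies.
Truth (population, haplogroup, private variants) is recorded per sample.

> **Note on the reference:** the packaged `data/synthetic_rcrs.fasta` is a
> clearly-labelled synthetic stand-in for NC_012920.1 — curated,
> well-attested rCRS bases at every position the fixtures touch, seeded
> filler elsewhere. Swap in the GenBank record for production use.

## Worked example

```sh
mtcrpop simulate --populations 4 --size 100 --drift 0.05 --seed 11 --out sim
mtcrpop analyze sim.pop1.tsv sim.pop2.tsv sim.pop3.tsv sim.pop4.tsv \
    --perms 1000 --seed 1 --outdir reports
```

The numbered scripts under `analysis/` run the same flow as a narrative
(simulate → classify → diversity → structure → network QC), writing
tables under `results/`. A run prints, e.g.:

```
55 distinct labels among 214 profiles; top: B5a (25), F1a1a (22), M* (17), C7 (14), B4c2 (10)
macrohaplogroup split: N 57.0%, M 43.0%
recovery of the generating haplogroup: 212/214 (99.1%)
MPD = 11.80 +/- 5.44; RMP = 0.84%; PD = 99.16%
AMOVA: 4.04% of variance among populations, 95.96% within (Phi_ST = 0.0404, p = 0.0010, 1000 permutations)
```

Read: the cohort splits 57/43 between macrohaplogroups N and M; a random
pair of profiles differs at ~12 CR sites and matches with probability
0.84%; at simulated drift F = 0.05 about 4% of molecular variance lies
among populations and the AMOVA permutation test is significant. The
classifier recovers the generating haplogroup for 99% of profiles despite
one private mutation per profile on average.

## Layout

```
src/mtcrpop/      library: codec, haplogroups, diversity, popstruct,
                  qmnet, simulate, io, cli (+ packaged data fixtures)
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance recomputation
docs/methods.md   models, conventions, parameter choices, limitations
```
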