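# Methods

This note documents the statistical and algorithmic conventions the
package implements, the defaults it ships, and what its synthetic data
can and cannot say about real control-region surveys.

## Coordinates and the packaged reference

All variants are 1-based differences to the revised Cambridge Reference
Sequence coordinate system (16,569 bp). The circular genome is always
linearised; the control region is represented as the two closed intervals
[16024, 16569] and [1, 576], never as a wrapped interval. Analysis
windows are interval lists, and window restriction is set intersection
with variants following their anchor position (an insertion `315.1C`
belongs to position 315).

The shipped FASTA is a synthetic stand-in for NC_012920.1: ~110 curated,
well-attested rCRS bases at every position referenced by fixtures, motif
tree and printed example profiles (73 A, 263 A, 16183 A, 16189 T,
16519 T, the C-tracts around 16184–16193, 303–315 and 568–573, the
523–524 AC dinucleotide, position 3107 N, …), with deterministic
seeded filler at human-mtDNA base composition elsewhere. Its MD5 is
computed at runtime (`reference_checksum()`) and recorded in simulation
output headers. Every statistic in the package depends on the reference
only through (a) the bases at curated positions and (b) the
purine/pyrimidine classification rule, so the stand-in is exact for all
packaged analyses; for production work the GenBank record should replace
it.

## Difference codec

Token grammar: bare number = transition to the partner base of the
reference (A↔G, C↔T); `NNNX` = substitution to the stated base;
`NNN.kX` = k-th inserted base after NNN; `NNNdel` = deletion;
`A-Bdel` / `A-B del` = deletion range, expanded to one variant per
position so that difference counting treats each deleted position as one
site; IUPAC ambiguity letters = point heteroplasmies. A stated variant
may never equal the reference base. Hyphen- and whitespace-delimited
lists are both accepted; in hyphen-delimited lists the range-deletion
spelling is unavailable (`523-524del` would be ambiguous with
`523del-524del`) and deletions must be spelled per position.

Haplotype identity ("matching") uses the forensic convention: profiles
are range-restricted to a common window, C-insertions anchored at
{16193, 309, 573} are removed, and point heteroplasmies are removed
entirely — i.e. the sample is treated as reference at a heteroplasmic
position. The alternative, wildcard matching of ambiguity codes, was
rejected because it makes identity non-transitive. The disregard set is
configurable; a second preset {16193, 309, 315} is shipped because both
variants of the rule circulate in practice. `315.1C` is retained by
default: it is nearly universal but appears in printed profiles, so
dropping it silently would distort reported difference counts.

## Haplogroup classification

A motif tree row carries the variants gained on a branch plus `@NNN`
back-mutations; the cumulative state of a node is the union of gains
along the root path with back-mutated positions removed. Validation
rejects duplicate names, multiple roots, orphan parents, cycles, and
back-mutations without an ancestral variant.

Scoring: for every node, `expected` = cumulative state restricted to the
sample's analysed ranges; score = matched − missing. Expected variants
outside the analysed range are never penalised — essential for HVS-I-only
profiles. Ties break to fewer private (unexplained) variants, then
greater depth, then lexicographic name, so assignment is deterministic.
A sample landing on an internal node is reported with a trailing `*`
(paragroup). `pre`-prefixed names are ordinary nodes.

The packaged tree is a curated test resource of 103 nodes covering the
64 labels of the packaged frequency table, with plausible control-region
motifs: hallmark sites are used where well attested (B5a carries
210/16140/16183C/16189/16266A; F1a-lineage profiles carry
249del/16129/16162/16172/16304; the R branch loses 16223 via `@16223`),
and branch positions are otherwise chosen to be unique along each root
path. It is deliberately small and must not be mistaken for a full
phylogeny; classification quality statements below are relative to this
tree.

## Diversity statistics

- Spectrum: match-key → count map over the analysis window; distinct
  haplotype counts therefore legitimately differ between windows.
- RMP = Σ (count_i/n)²; PD = 1 − RMP, an exact complement.
- Pairwise difference: site-wise symmetric difference of the normalised,
  restricted variant maps. Two different non-reference bases at the same
  position count as one difference (MPD is a per-site statistic).
- MPD: mean over all unordered pairs. The attached SD is the square root
  of the standard total (stochastic + sampling) variance
  `[3n(n+1)π + 2(n²+n+3)π²] / [11(n²−7n+6)]`, the convention behind the
  "±" values of the common AMOVA software. That denominator is
  non-positive for n < 7, where the package falls back to the descriptive
  SD of the pair-distance distribution (and 0 for a single pair).
- Corrected between-population MPD = d_AB − (π_A + π_B)/2, reported
  unclamped; slightly negative values are legitimate. For a population
  compared against an exact copy of itself the corrected value is
  −π/n (cross-pair means carry denominator n², within-pair means
  n(n−1)), vanishing only asymptotically.
- Heteroplasmy census runs on raw profiles, before normalisation; a
  sample with several heteroplasmies counts once in the prevalence.

## AMOVA, Φ_ST, MDS

One-level molecular AMOVA with the conventional squared distance for
pairwise-difference data, δ²_ij = d_ij (switchable): SSD_total =
(1/2N)ΣΣδ², SSD_within per group with 1/2n_g, σ²_b = SSD_within/(N−P),
σ²_a = (SSD_among/(P−1) − σ²_b)/n̄ with n̄ = (N − Σn_g²/N)/(P−1), Φ_ST =
σ²_a/(σ²_a+σ²_b). Significance by permutation of individuals across
groups preserving sizes, p = (1 + #{Φ_perm ≥ Φ_obs})/(perms+1); default
10,000 permutations. An all-zero distance matrix is flagged monomorphic
and reported with Φ_ST = 0. Negative Φ_ST estimates are retained; they
are floored at 0 only when a matrix feeds the MDS embedding.

Pairwise Φ_ST(A,B) is the two-population AMOVA on A∪B, guaranteed
consistent with the general routine (tested).

MDS is classical metric scaling (double-centering + eigendecomposition,
top nonnegative eigenpairs), with an optional SMACOF refinement stage
(scikit-learn) initialised from the classical solution. Stress is
Kruskal stress-1, √(Σ(d−d̂)²/Σd²). Sign/reflection indeterminacy is
canonicalised (first nonzero coordinate of each axis made positive) so
repeated runs are comparable. Exactly 2-D-embeddable matrices are
reproduced with stress < 1e-6.

## Quasi-median networks

Condensation builds one character per variable site over the window
(indel sites as presence characters), drops filtered and invariant
columns, merges columns inducing identical row partitions
(concatenating their position lists), and collapses identical rows,
summing multiplicities. The default "CR-speedy" filter is the
normalisation disregard set plus 16519 — an approximation of
database-internal filter lists, fully user-configurable.

Closure: for every triple of states, per character the majority state if
two agree, otherwise all three (cartesian expansion over undecided
characters); new states are added until a fixpoint. On binary characters
this is exactly the median closure (tested against an independent
componentwise-majority oracle). Growth is bounded by a node cap
(default 10,000) whose violation is itself the QC signal — an
exploding closure means homoplasy-rich or unfiltered data. Edges connect
states at condensed Hamming distance 1 and carry positions and event
classes; compatible (perfect-phylogeny) data provably yield trees, and
this is property-tested. QC flags list transversion/indel edges and
weight-1 singletons attached only by flagged edges.

## Synthetic populations

The generator works at haplotype/haplogroup granularity, not sequence
coalescent granularity — it matches what the downstream statistics
consume and keeps closed-form expectations (with λ = 0 and F = 0 the
spectrum is exactly the base frequency law, RMP = Σf²).

Defaults are the package's study conditions: one population of 214
profiles; haplogroup frequencies from the packaged 64-label table;
λ = 1 private mutation per profile (Poisson), 95% transitions; hotspot
C-insertion rates 315: 0.70, 309: 0.35, 16193: 0.10, 573: 0.03 (the
HVS-II tract events are near-ubiquitous in real data, the others rare);
per-sample heteroplasmy rate 4%, inside the 1–9.5% band reported across
population surveys — implemented by converting one substitution to its
IUPAC code. Private mutations redraw on collision with motif sites so
the generating haplogroup stays unambiguous. Drift F spreads haplogroup
frequencies as Dirichlet(f·(1−F)/F), mean f and per-component variance
≈ F·f(1−f); Φ_ST estimated from such populations is monotone in F
(tested over seeded replicates), but not numerically equal to it —
haplotype-level Φ_ST also absorbs within-haplogroup diversity.

What the simulation does **not** emulate: site-specific mutation-rate
heterogeneity of the CR, length-heteroplasmy dynamics of the C-tracts
beyond the hotspot-insertion rates, sequence-level genealogies within a
haplogroup, and real phylotree topology (the packaged tree is a small
curated stand-in). Passing tests therefore demonstrate the correctness
of the statistics and the classifier's behaviour under the stated noise
model — not classification accuracy against the full real phylogeny.

## Problem sizes and numerical choices

Seeded experiment sizes were chosen at the scale of the emulated survey:
cohort analyses use n = 214; estimator-recovery experiments use 2
populations × 100 profiles × 20 replicates per drift value; oracle
equivalence checks use n ≤ 30 where brute-force enumeration is exact.
Percentages in reports round half-up to the printed number of decimals
(`7.45% → 7.5%`); report floats are fixed at 3 decimals (4 for Φ_ST).
Permutation p-values use the +1/+1 correction and never reach zero.
All randomness flows through one seeded generator per run; seeds are
recorded in output headers.

## Known limitations

- The packaged reference is a synthetic stand-in (see above); bare-number
  transition resolution at non-curated positions is internally consistent
  but not guaranteed to match the true rCRS base.
- The motif tree is a 103-node curated resource; real surveys should load
  a full phylotree-derived motif table via `load_tree`.
- AMOVA is one-level only (no regional grouping), matching the analysis
  design it reimplements.
- The quasi-median closure is exponential in the worst case by nature;
  the node cap converts pathological growth into a diagnostic rather than
  a hang.
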