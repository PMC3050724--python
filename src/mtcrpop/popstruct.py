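"""Between-population structure: AMOVA, pairwise PhiST, sharing, MDS.

One-level molecular AMOVA on pairwise-difference distances: with the
conventional squared distance delta^2_ij taken as the difference count
d_ij itself,

    SSD_total  = (1/2N) sum_ij delta^2_ij
    SSD_within = sum_g (1/2n_g) sum_{ij in g} delta^2_ij
    sigma2_b   = SSD_within / (N - P)
    sigma2_a   = (SSD_among/(P-1) - sigma2_b) / nbar,
                 nbar = (N - sum n_g^2 / N) / (P - 1)
    Phi_ST     = sigma2_a / (sigma2_a + sigma2_b)

Significance is by permutation of individuals across groups (sizes
preserved), with the +1/+1 correction so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codec import Interval, normalize, restrict
from .diversity import spectrum
from .io import PopulationSample


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative matrix with zero diagonal, plus labels."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        self.matrix = m


@dataclass
class AmovaResult:
    ssd_total: float
    ssd_among: float
    ssd_within: float
    df_among: int
    df_within: int
    sigma2_a: float
    sigma2_b: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float | None
    permutations: int
    seed: int | None
    monomorphic: bool = False


def _site_map(h) -> dict:
    return {(v.position, v.insertion_index): v.observed for v in h.variants}


def distance_matrix(
    pops: Sequence[PopulationSample], window: Sequence[Interval]
) -> tuple[DistanceMatrix, list[int]]:
    """Per-individual pairwise-difference matrix over a common window.

    Returns the matrix (individuals ordered population by population) and
    the population partition as a list of group sizes.
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    labels: list[str] = []
    maps: list[dict] = []
    sizes: list[int] = []
    for pop in pops:
        sizes.append(len(pop))
        for h in pop:
            labels.append(f"{pop.name}:{h.sample_id}")
            maps.append(_site_map(normalize(restrict(h, window))))
    n = len(maps)
    m = np.zeros((n, n))
    for i in range(n):
        a = maps[i]
        for j in range(i + 1, n):
            b = maps[j]
            d = sum(1 for site in a.keys() | b.keys() if a.get(site) != b.get(site))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m), sizes


def _decompose(sq: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float, float]:
    n_total = sum(len(g) for g in groups)
    ssd_total = sq.sum() / (2 * n_total)
    ssd_within = sum(sq[np.ix_(g, g)].sum() / (2 * len(g)) for g in groups)
    return ssd_total, ssd_total - ssd_within, ssd_within


def _phi_from(sq: np.ndarray, groups: list[np.ndarray]) -> float:
    ssd_total, ssd_among, ssd_within = _decompose(sq, groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_total, p = sizes.sum(), len(groups)
    sigma2_b = ssd_within / (n_total - p)
    nbar = (n_total - (sizes**2).sum() / n_total) / (p - 1)
    sigma2_a = (ssd_among / (p - 1) - sigma2_b) / nbar
    denom = sigma2_a + sigma2_b
    return sigma2_a / denom if denom > 0 else 0.0


def amova(
    dm: DistanceMatrix,
    partition: Sequence[int],
    permutations: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA of a per-individual distance matrix.

    ``partition`` gives the group sizes in matrix order.  A fully
    monomorphic matrix is flagged and reported with Phi_ST = 0.
    """
    sizes = list(partition)
    n_total, p = sum(sizes), len(sizes)
    if n_total != dm.matrix.shape[0]:
        raise ValueError("partition does not cover the matrix")
    if any(s < 1 for s in sizes) or n_total <= p:
        raise ValueError("need every group nonempty and N > P")
    sq = dm.matrix  # delta^2 = pairwise difference count (convention)
    bounds = np.cumsum([0] + sizes)
    groups = [np.arange(bounds[i], bounds[i + 1]) for i in range(p)]

    ssd_total, ssd_among, ssd_within = _decompose(sq, groups)
    df_among, df_within = p - 1, n_total - p
    sigma2_b = ssd_within / df_within
    arr = np.array(sizes, dtype=float)
    nbar = (n_total - (arr**2).sum() / n_total) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_b) / nbar
    denom = sigma2_a + sigma2_b
    monomorphic = bool(np.allclose(sq, 0.0))
    phi = sigma2_a / denom if denom > 0 else 0.0
    total_var = denom if denom > 0 else 1.0
    pct_among = 100.0 * sigma2_a / total_var if denom > 0 else 0.0

    p_value = None
    if permutations > 0 and not monomorphic:
        rng = np.random.default_rng(seed)
        count = 0
        idx = np.arange(n_total)
        for _ in range(permutations):
            rng.shuffle(idx)
            perm_groups = [idx[bounds[i]: bounds[i + 1]] for i in range(p)]
            if _phi_from(sq, perm_groups) >= phi:
                count += 1
        p_value = (1 + count) / (permutations + 1)

    return AmovaResult(
        ssd_total=ssd_total,
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_a=sigma2_a if not monomorphic else 0.0,
        sigma2_b=sigma2_b,
        pct_among=pct_among,
        pct_within=100.0 - pct_among if denom > 0 else 100.0,
        phi_st=phi if not monomorphic else 0.0,
        p_value=p_value,
        permutations=permutations,
        seed=seed,
        monomorphic=monomorphic,
    )


def pairwise_fst(
    pops: Sequence[PopulationSample],
    window: Sequence[Interval],
    permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise Phi_ST matrix with permutation p-values.

    Entry (A, B) is the Phi_ST of the two-population AMOVA on A and B;
    negative estimates are retained (floor them only when feeding MDS).
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    p = len(pops)
    fst = np.zeros((p, p))
    pvals = np.full((p, p), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(p):
        for j in range(i + 1, p):
            dm, sizes = distance_matrix([pops[i], pops[j]], window)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = amova(dm, sizes, permutations=permutations, seed=sub_seed)
            fst[i, j] = fst[j, i] = res.phi_st
            if res.p_value is not None:
                pvals[i, j] = pvals[j, i] = res.p_value
    return DistanceMatrix([pop.name for pop in pops], fst), pvals


@dataclass
class SharingReport:
    focal: str
    focal_distinct: int
    per_population: dict[str, tuple[int, float]]  # name -> (shared count, proportion)
    overall_shared: int
    overall_proportion: float


def shared_haplotypes(
    focal: PopulationSample,
    others: Sequence[PopulationSample],
    window: Sequence[Interval],
) -> SharingReport:
    """Distinct-haplotype sharing between a focal population and others.

    Proportions use the focal population's distinct-key count as the
    denominator; the overall figure counts focal keys present in at least
    one other population.
    """
    focal_keys = set(spectrum(focal, window))
    if not focal_keys:
        raise ValueError("empty focal population")
    per: dict[str, tuple[int, float]] = {}
    union: set[str] = set()
    for other in others:
        keys = set(spectrum(other, window))
        shared = focal_keys & keys
        union |= shared
        per[other.name] = (len(shared), len(shared) / len(focal_keys))
    return SharingReport(
        focal=focal.name,
        focal_distinct=len(focal_keys),
        per_population=per,
        overall_shared=len(union),
        overall_proportion=len(union) / len(focal_keys),
    )


@dataclass
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, dims)
    stress: float  # Kruskal stress-1


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 between a target distance matrix and a configuration."""
    fitted = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(d.shape[0], k=1)
    denom = (d[iu] ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d[iu] - fitted[iu]) ** 2).sum() / denom))


def _canonicalize(coords: np.ndarray) -> np.ndarray:
    """Fix sign/reflection indeterminacy so runs are comparable."""
    coords = coords.copy()
    for dim in range(coords.shape[1]):
        pivot = next((v for v in coords[:, dim] if abs(v) > 1e-12), 1.0)
        if pivot < 0:
            coords[:, dim] *= -1
    return coords


def mds(
    dist: DistanceMatrix,
    dims: int = 2,
    refine: bool = False,
    seed: int | None = None,
) -> MdsResult:
    """Classical metric scaling of a (Phi_ST) distance matrix.

    Negative entries are floored at zero.  Double-centering plus
    eigendecomposition keeps the top nonnegative eigenpairs; ``refine``
    adds an iterative SMACOF stress-minimisation stage initialised from
    the classical solution.
    """
    d = np.maximum(dist.matrix, 0.0)
    n = d.shape[0]
    if dims >= n:
        raise ValueError("dims must be smaller than the matrix size")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    if refine:
        from sklearn.manifold import smacof

        coords, _ = smacof(
            d,
            n_components=dims,
            init=coords,
            n_init=1,
            random_state=seed,
            normalized_stress=False,
        )
    coords = _canonicalize(coords)
    return MdsResult(list(dist.labels), coords, kruskal_stress(d, coords))


def _open(target):
    from pathlib import Path

    if isinstance(target, (str, Path)):
        return Path(target).open("w", encoding="utf-8", newline="\n"), True
    return target, False


def write_amova_report(result: AmovaResult, target) -> None:
    """TSV mirroring the classic AMOVA design table."""
    from ._util import fmt

    handle, close = _open(target)
    try:
        handle.write("Source of variation\td.f.\tSum of squares\tVariance component\tPercentage of variation\n")
        handle.write(
            f"Among populations\t{result.df_among}\t{fmt(result.ssd_among)}\t"
            f"{fmt(result.sigma2_a, 5)}\t{fmt(result.pct_among, 2)}\n"
        )
        handle.write(
            f"Within populations\t{result.df_within}\t{fmt(result.ssd_within)}\t"
            f"{fmt(result.sigma2_b, 5)}\t{fmt(result.pct_within, 2)}\n"
        )
        handle.write(f"Total\t{result.df_among + result.df_within}\t{fmt(result.ssd_total)}\t\t\n")
        phi = fmt(result.phi_st, 4)
        pval = "NA" if result.p_value is None else fmt(result.p_value, 4)
        handle.write(f"# Phi_ST = {phi}\tp = {pval}\tpermutations = {result.permutations}\tseed = {result.seed}\n")
        if result.monomorphic:
            handle.write("# monomorphic input: Phi_ST reported as 0\n")
    finally:
        if close:
            handle.close()


def write_fst_matrix(dist: DistanceMatrix, target, pvals: np.ndarray | None = None) -> None:
    """Labeled TSV of the pairwise Phi_ST matrix (4 decimals)."""
    from ._util import fmt

    handle, close = _open(target)
    try:
        handle.write("Population\t" + "\t".join(dist.labels) + "\n")
        for i, label in enumerate(dist.labels):
            handle.write(label + "\t" + "\t".join(fmt(x, 4) for x in dist.matrix[i]) + "\n")
        if pvals is not None:
            handle.write("# permutation p-values\n")
            for i, label in enumerate(dist.labels):
                row = "\t".join("NA" if np.isnan(x) else fmt(x, 4) for x in pvals[i])
                handle.write(f"# {label}\t{row}\n")
    finally:
        if close:
            handle.close()


def write_mds(result: MdsResult, target) -> None:
    """MDS coordinates as TSV with the stress in a footer comment."""
    from ._util import fmt

    handle, close = _open(target)
    try:
        handle.write("Population\tx\ty\n")
        for label, (x, y) in zip(result.labels, result.coordinates[:, :2]):
            handle.write(f"{label}\t{fmt(float(x), 6)}\t{fmt(float(y), 6)}\n")
        handle.write(f"# stress-1 = {fmt(result.stress, 6)}\n")
    finally:
        if close:
            handle.close()
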