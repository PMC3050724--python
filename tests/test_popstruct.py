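"""AMOVA decomposition, PhiST, sharing and MDS against oracles."""

import numpy as np
import pytest

from mtcrpop.diversity import pair_diff
from mtcrpop.popstruct import (
    DistanceMatrix,
    amova,
    distance_matrix,
    kruskal_stress,
    mds,
    pairwise_fst,
    shared_haplotypes,
)
from mtcrpop.simulate import SimConfig, simulate
from tests.conftest import CR, make_pop

W576 = ((1, 576),)


class TestDistanceMatrix:
    def test_shared_haplotype_everywhere_zero_matrix(self):
        p1 = make_pop("p1", [("a", "73"), ("b", "73")], W576)
        p2 = make_pop("p2", [("c", "73")], W576)
        dm, sizes = distance_matrix([p1, p2], W576)
        assert np.all(dm.matrix == 0) and sizes == [2, 1]

    def test_block_structure_2plus2(self, toy_2plus2):
        dm, _ = distance_matrix(list(toy_2plus2), W576)
        expected = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], float
        )
        assert np.array_equal(dm.matrix, expected)

    def test_matches_pairwise_oracle_on_printed_profiles(self, b5a, f1a1):
        rows = [
            ("s1", "73 263"),
            ("s2", "73 263 16519"),
            ("s3", "73 152 16129"),
        ]
        p1 = make_pop("p1", rows, CR)
        p2 = make_pop("p2", [], CR)
        p2.haplotypes = [b5a, f1a1]
        haps = p1.haplotypes + p2.haplotypes
        dm, _ = distance_matrix([p1, p2], CR)
        for i, a in enumerate(haps):
            for j, b in enumerate(haps):
                expected = 0 if i == j else pair_diff(a, b, CR)
                assert dm.matrix[i, j] == expected

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


class TestAmova:
    def test_two_plus_two_oracle(self, toy_2plus2):
        # hand decomposition: SSD_T = 1, SSD_W = 0, sigma2_b = 0, sigma2_a = 0.5
        dm, sizes = distance_matrix(list(toy_2plus2), W576)
        res = amova(dm, sizes, permutations=0)
        assert res.ssd_total == pytest.approx(1.0)
        assert res.ssd_within == pytest.approx(0.0)
        assert res.sigma2_a == pytest.approx(0.5)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_decomposition_identity(self):
        pops, _ = simulate(SimConfig(populations=3, sizes=15, drift=0.1, seed=5))
        dm, sizes = distance_matrix(pops, CR)
        res = amova(dm, sizes, permutations=0)
        assert res.ssd_among + res.ssd_within == pytest.approx(res.ssd_total, abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_split_panmictic_population_phi_near_zero(self):
        pops, _ = simulate(SimConfig(populations=2, sizes=50, drift=0.0, seed=9))
        dm, sizes = distance_matrix(pops, CR)
        res = amova(dm, sizes, permutations=200, seed=1)
        assert abs(res.phi_st) < 0.05
        assert res.p_value > 0.05

    def test_monomorphic_flagged(self):
        p1 = make_pop("p1", [("a", "73"), ("b", "73")], W576)
        p2 = make_pop("p2", [("c", "73"), ("d", "73")], W576)
        dm, sizes = distance_matrix([p1, p2], W576)
        res = amova(dm, sizes, permutations=50, seed=0)
        assert res.monomorphic and res.phi_st == 0.0

    def test_extreme_phi_has_minimal_p(self, toy_2plus2):
        dm, sizes = distance_matrix(list(toy_2plus2), W576)
        res = amova(dm, sizes, permutations=999, seed=3)
        # observed Phi at the top of its permutation distribution:
        # p <= (1 + #ties)/(perms+1); with 4 individuals ties are common,
        # but p can never undercut the +1/+1 floor
        assert res.p_value >= 1 / 1000
        assert res.p_value <= 0.5

    def test_p_value_invariant_to_population_relabeling(self, toy_2plus2):
        p1, p2 = toy_2plus2
        dm12, s12 = distance_matrix([p1, p2], W576)
        dm21, s21 = distance_matrix([p2, p1], W576)
        r12 = amova(dm12, s12, permutations=300, seed=7)
        r21 = amova(dm21, s21, permutations=300, seed=7)
        assert r12.p_value == r21.p_value
        assert r12.phi_st == pytest.approx(r21.phi_st)


class TestPairwiseFst:
    def test_self_comparison_near_zero(self):
        pops, _ = simulate(SimConfig(populations=2, sizes=40, drift=0.0, seed=21))
        matrix, _ = pairwise_fst(pops, CR, permutations=0)
        assert abs(matrix.matrix[0, 1]) < 0.05

    def test_two_plus_two_oracle(self, toy_2plus2):
        matrix, _ = pairwise_fst(list(toy_2plus2), W576, permutations=0)
        assert matrix.matrix[0, 1] == pytest.approx(1.0)

    def test_consistent_with_two_population_amova(self):
        pops, _ = simulate(SimConfig(populations=3, sizes=20, drift=0.1, seed=13))
        matrix, _ = pairwise_fst(pops, CR, permutations=0)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            dm, sizes = distance_matrix([pops[i], pops[j]], CR)
            res = amova(dm, sizes, permutations=0)
            assert matrix.matrix[i, j] == pytest.approx(res.phi_st)

    def test_phi_monotone_in_simulated_drift(self):
        """Mean estimated PhiST increases with the generating drift F."""
        means = []
        for F in (0.01, 0.2):
            vals = []
            for rep in range(6):
                pops, _ = simulate(
                    SimConfig(populations=2, sizes=60, drift=F, seed=100 + rep)
                )
                matrix, _ = pairwise_fst(pops, CR, permutations=0)
                vals.append(matrix.matrix[0, 1])
            means.append(np.mean(vals))
        assert means[1] > means[0]


class TestSharing:
    def test_focal_equals_other(self):
        rows = [("a", "73"), ("b", "73 263")]
        focal = make_pop("f", rows, W576)
        other = make_pop("o", [(s + "o", t) for s, t in rows], W576)
        rep = shared_haplotypes(focal, [other], W576)
        assert rep.overall_proportion == 1.0

    def test_disjoint_sets(self):
        focal = make_pop("f", [("a", "73")], W576)
        other = make_pop("o", [("b", "263")], W576)
        rep = shared_haplotypes(focal, [other], W576)
        assert rep.overall_proportion == 0.0

    def test_set_intersection_counts(self):
        focal = make_pop("f", [("a", "73"), ("b", "263"), ("c", "152"), ("d", "199")], W576)
        other = make_pop(
            "o", [("x", "263"), ("y", "199"), ("z", "146")], W576
        )
        rep = shared_haplotypes(focal, [other], W576)
        count, prop = rep.per_population["o"]
        assert (count, prop) == (2, 0.5)

    def test_overall_counts_keys_shared_with_any(self):
        focal = make_pop("f", [("a", "73"), ("b", "263"), ("c", "152")], W576)
        o1 = make_pop("o1", [("x", "73")], W576)
        o2 = make_pop("o2", [("y", "263"), ("z", "73")], W576)
        rep = shared_haplotypes(focal, [o1, o2], W576)
        assert rep.overall_shared == 2
        assert rep.overall_proportion == pytest.approx(2 / 3)


class TestMds:
    def test_equilateral_triangle_exact(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        res = mds(d)
        assert res.stress < 1e-6

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = mds(DistanceMatrix(list("abcde"), d))
        assert res.stress < 1e-6
        # distances are reproduced, i.e. recovery up to rigid motion
        got = res.coordinates
        dd = np.sqrt(((got[:, None] - got[None, :]) ** 2).sum(-1))
        assert np.allclose(dd, d, atol=1e-6)

    def test_zero_matrix_degenerate(self):
        res = mds(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3))))
        assert np.allclose(res.coordinates, 0.0)
        assert res.stress == 0.0

    def test_negative_entries_floored_for_embedding(self):
        m = np.array([[0, -0.01, 0.1], [-0.01, 0, 0.1], [0.1, 0.1, 0]])
        res = mds(DistanceMatrix(["a", "b", "c"], m))
        assert np.isfinite(res.stress)

    def test_dims_bound(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            mds(d, dims=2)

    def test_canonical_orientation_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        r1 = mds(DistanceMatrix(list("abcdef"), d))
        r2 = mds(DistanceMatrix(list("abcdef"), d))
        assert np.array_equal(r1.coordinates, r2.coordinates)

    def test_stress_definition(self):
        d = np.array([[0, 2.0], [2.0, 0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.0]])  # fitted distance 1
        assert kruskal_stress(d, coords) == pytest.approx(np.sqrt(1 / 4))
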