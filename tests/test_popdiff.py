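"""Distances, AMOVA, pairwise FST, diversity, PCoA, Mantel."""

import numpy as np
import pandas as pd
import pytest

from msapop import (
    DistanceMatrix,
    amova,
    diversity_indices,
    mantel,
    pairwise_distance,
    pairwise_fst,
    pcoa,
    population_proximity,
)

import oracles


class TestPairwiseDistance:
    def test_simple_binary_rows(self):
        m = pd.DataFrame([[1, 0, 1], [1, 1, 0]], dtype=float)
        d = pairwise_distance(m)
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1]], dtype=float)
        assert pairwise_distance(m).values[0, 1] == 0.0

    def test_missing_rescaling(self):
        m = pd.DataFrame([[1, 0, np.nan], [1, 1, 0]], dtype=float)
        # raw d over 2 shared loci = 1, rescaled by 3/2 -> 1.5
        assert pairwise_distance(m).values[0, 1] == pytest.approx(1.5)

    def test_matches_pair_oracle_with_missing(self):
        rng = np.random.default_rng(0)
        m = (rng.uniform(size=(8, 12)) < 0.5).astype(float)
        m[rng.uniform(size=m.shape) < 0.2] = np.nan
        df = pd.DataFrame(m)
        d = pairwise_distance(df)
        for i in range(8):
            for j in range(i + 1, 8):
                assert d.values[i, j] == pytest.approx(
                    oracles.sq_euclid_oracle(m[i], m[j])
                )

    def test_no_shared_loci_errors(self):
        m = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]])
        with pytest.raises(ValueError, match="share no scored loci"):
            pairwise_distance(m)


class TestAmova:
    def test_no_structure_gives_small_phi(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame((rng.uniform(size=(40, 60)) < 0.5).astype(float))
        pops = ["A"] * 20 + ["B"] * 20
        res = amova(pairwise_distance(m), pops, n_perm=99, seed=0)
        assert abs(res.phi_st) < 0.05
        assert res.p_value > 0.01

    def test_fixed_difference_phi_one(self):
        m = pd.DataFrame([[1, 1, 0]] * 5 + [[1, 0, 0]] * 5, dtype=float)
        res = amova(pairwise_distance(m), ["A"] * 5 + ["B"] * 5, n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_degenerate_identical_distances(self):
        d = DistanceMatrix(np.zeros((6, 6)), pd.Index(range(6)))
        res = amova(d, ["A"] * 3 + ["B"] * 3, n_perm=19, seed=0)
        assert res.phi_st == 0.0
        assert res.p_value == 1.0

    def test_population_of_one_errors(self):
        d = DistanceMatrix(np.zeros((3, 3)), pd.Index(range(3)))
        with pytest.raises(ValueError, match="size < 2"):
            amova(d, ["A", "A", "B"], n_perm=9)

    def test_components_match_bruteforce_oracle(self):
        """Variance components equal the explicit-loop + symbolic-EMS oracle
        on small unbalanced random instances."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            sizes = rng.integers(2, 5, size=3)
            pops = np.repeat(["A", "B", "C"], sizes)
            m = pd.DataFrame((rng.uniform(size=(sizes.sum(), 4)) < 0.5).astype(float))
            d = pairwise_distance(m)
            res = amova(d, pops, n_perm=1, seed=0)
            sa, sw, phi = oracles.amova_oracle(d.values, pops)
            assert res.sigma2["among_populations"] == pytest.approx(sa, abs=1e-10)
            assert res.sigma2["within_populations"] == pytest.approx(sw, abs=1e-10)
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_relabelling_within_populations_invariant(self):
        rng = np.random.default_rng(3)
        m = (rng.uniform(size=(12, 10)) < 0.5).astype(float)
        pops = np.array(["A"] * 6 + ["B"] * 6)
        d = pairwise_distance(pd.DataFrame(m))
        res1 = amova(d, pops, n_perm=1, seed=5)
        # shuffle individuals inside each population
        order = np.r_[rng.permutation(6), 6 + rng.permutation(6)]
        d2 = DistanceMatrix(d.values[np.ix_(order, order)], pd.Index(range(12)))
        res2 = amova(d2, pops[order], n_perm=1, seed=5)
        assert res1.phi_st == pytest.approx(res2.phi_st)
        assert res1.sigma2 == pytest.approx(res2.sigma2)

    def test_phi_equals_percent_over_100(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame((rng.uniform(size=(20, 15)) < 0.4).astype(float))
        res = amova(pairwise_distance(m), ["A"] * 10 + ["B"] * 10, n_perm=1, seed=0)
        assert res.phi_st == pytest.approx(
            res.percent_variation["among_populations"] / 100.0
        )
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)

    def test_two_level_design_partitions_variance(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.2, 0.8, size=20)
        rows, pops = [], []
        for g, shift in (("G1", -0.15), ("G2", 0.15)):
            for p in range(2):
                freq = np.clip(base + shift + rng.normal(0, 0.05, 20), 0.02, 0.98)
                for _ in range(6):
                    rows.append((rng.uniform(size=20) < freq).astype(float))
                    pops.append(f"{g}_p{p}")
        m = pd.DataFrame(rows)
        groups = {p: p.split("_")[0] for p in set(pops)}
        res = amova(pairwise_distance(m), pops, groups=groups, n_perm=99, seed=1)
        assert res.phi_ct is not None
        assert res.phi_ct > 0.0
        assert sum(res.percent_variation.values()) == pytest.approx(100.0)
        assert res.p_ct <= 0.5  # real group separation


class TestPairwiseFst:
    def test_identical_populations_zero(self):
        rng = np.random.default_rng(6)
        block = (rng.uniform(size=(6, 20)) < 0.5).astype(float)
        m = pd.DataFrame(np.vstack([block, block]))
        fst, pv, sig = pairwise_fst(m, ["A"] * 6 + ["B"] * 6, n_perm=49, seed=0)
        assert fst.loc["A", "B"] == 0.0
        assert not sig.loc["A", "B"]

    def test_fixed_difference_significant(self):
        # 5+5: only the 2 of C(10,5)=252 pure relabellings reach phi=1, so
        # the permutation p is well below alpha; 3+3 could never be (p ~ 0.1)
        m = pd.DataFrame([[1, 1, 1]] * 5 + [[0, 0, 0]] * 5, dtype=float)
        fst, pv, sig = pairwise_fst(m, ["A"] * 5 + ["B"] * 5, n_perm=100, seed=0)
        assert fst.loc["A", "B"] == pytest.approx(1.0)
        assert sig.loc["A", "B"]

    def test_three_plus_three_fixed_difference_exact_p(self):
        # permutation enumeration: 2 of the 20 distinct label splits reach
        # phi = 1, so p converges to ~0.107 and cannot be significant
        m = pd.DataFrame([[1, 1, 1]] * 3 + [[0, 0, 0]] * 3, dtype=float)
        d = pairwise_distance(m)
        res = amova(d, ["A"] * 3 + ["B"] * 3, n_perm=2000, seed=3)
        assert res.phi_st == pytest.approx(1.0)
        assert abs(res.p_value - 0.1) < 0.03

    def test_symmetric_zero_diagonal_nonnegative(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame((rng.uniform(size=(18, 12)) < 0.5).astype(float))
        pops = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
        fst, pv, sig = pairwise_fst(m, pops, n_perm=19, seed=0)
        assert np.allclose(fst.values, fst.values.T)
        assert np.allclose(np.diag(fst.values), 0.0)
        assert (fst.values >= 0).all()


class TestDiversity:
    @pytest.mark.parametrize(
        "x,q,ne,h,i",
        [
            (0.25, 0.5, 2.0, 0.5, np.log(2)),
            (1.0, 1.0, 1.0, 0.0, 0.0),
            (0.16, 0.4, None, 0.48, None),
        ],
    )
    def test_closed_forms(self, x, q, ne, h, i):
        n = 200
        col = np.r_[np.zeros(int(x * n)), np.ones(n - int(x * n))]
        m = pd.DataFrame({"locus": col})
        div = diversity_indices(m, ["P"] * n)
        tab = div.per_locus["P"]
        assert tab["q_hat"].iloc[0] == pytest.approx(q, abs=1e-9)
        assert tab["h"].iloc[0] == pytest.approx(h, abs=1e-9)
        if ne is not None:
            assert tab["Ne"].iloc[0] == pytest.approx(ne, abs=1e-9)
        if i is not None:
            assert tab["I"].iloc[0] == pytest.approx(i, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame((rng.uniform(size=(30, 40)) < rng.uniform(size=40)).astype(float))
        div = diversity_indices(m, ["P"] * 30)
        tab = div.per_locus["P"]
        assert ((tab["Ne"] >= 1) & (tab["Ne"] <= 2)).all()
        assert ((tab["h"] >= 0) & (tab["h"] <= 0.5)).all()
        assert ((tab["I"] >= 0) & (tab["I"] <= np.log(2) + 1e-12)).all()

    def test_half_frequency_maximises_h(self):
        n = 40
        m = pd.DataFrame(
            {
                "max": np.r_[np.zeros(n // 2), np.ones(n // 2)],  # x = 0.5? no: x=.5
                "off": np.r_[np.zeros(n // 4), np.ones(3 * n // 4)],
            }
        )
        div = diversity_indices(m, ["P"] * n)
        tab = div.per_locus["P"]
        # h is maximal when the estimated allele frequencies are closest to 1/2,
        # i.e. null-phenotype frequency x = 0.25 (q = 0.5)
        assert tab.loc["off", "h"] == pytest.approx(0.5)
        assert tab.loc["max", "h"] < 0.5


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        d = (pts - pts.T) ** 2
        res = pcoa(DistanceMatrix(d, pd.Index(range(3))))
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.coordinates.shape[1] == 1

    def test_recovers_planted_coordinates(self):
        """PCoA of squared distances from known 2-D points recovers them up
        to rotation/reflection (Procrustes disparity ~ 0)."""
        from scipy.spatial import procrustes

        rng = np.random.default_rng(9)
        for _ in range(10):
            pts = rng.normal(size=(7, 2))
            diff = pts[:, None, :] - pts[None, :, :]
            d = (diff**2).sum(axis=2)
            res = pcoa(DistanceMatrix(d, pd.Index(range(7))))
            rec = res.coordinates.to_numpy()[:, :2]
            _, _, disparity = procrustes(pts, rec)
            assert disparity < 1e-12

    def test_positive_eigenvalue_sum_equals_centred_trace(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 3))
        diff = pts[:, None, :] - pts[None, :, :]
        d = (diff**2).sum(axis=2)
        res = pcoa(DistanceMatrix(d, pd.Index(range(6))))
        n = 6
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ d @ J
        assert res.eigenvalues[res.eigenvalues > 1e-10].sum() == pytest.approx(
            np.trace(B)
        )

    def test_non_euclidean_negative_eigenvalues_reported(self):
        d = np.array(
            [[0, 1, 1, 4], [1, 0, 1, 1], [1, 1, 0, 1], [4, 1, 1, 0]], dtype=float
        )
        res = pcoa(DistanceMatrix(d, pd.Index(range(4))))
        assert res.n_negative >= 1
        assert res.percent_variance.sum() == pytest.approx(100.0)


class TestMantel:
    def _dist(self, rng, n=10):
        pts = rng.normal(size=(n, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        return DistanceMatrix((diff**2).sum(axis=2), pd.Index(range(n)))

    def test_self_correlation_is_one(self):
        d = self._dist(np.random.default_rng(11))
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_affine_invariance(self):
        d1 = self._dist(np.random.default_rng(12))
        d2 = DistanceMatrix(2.5 * d1.values + 0.0, d1.ids)
        # positive affine map of the off-diagonal entries preserves r = 1
        v = 3.0 * d1.values + 1.0
        np.fill_diagonal(v, 0.0)
        d3 = DistanceMatrix(v, d1.ids)
        assert mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(1.0)
        assert mantel(d1, d3, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_constant_matrix_errors(self):
        v = np.ones((4, 4)) - np.eye(4)
        d1 = DistanceMatrix(v, pd.Index(range(4)))
        with pytest.raises(ValueError, match="constant"):
            mantel(d1, d1, n_perm=9)

    def test_agrees_with_skbio(self):
        """Cross-check r and permutation behaviour against scikit-bio."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(13)
        d1, d2 = self._dist(rng), self._dist(rng)
        ours = mantel(d1, d2, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(d1.values),
            skbio_stats.DistanceMatrix(d2.values),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        assert ours.r == pytest.approx(float(r_sk), abs=1e-12)
        assert abs(ours.p_value - float(p_sk)) < 0.08  # both valid permutation p


class TestPopulationProximity:
    def test_identical_means_zero(self):
        t = pd.DataFrame(dict(a=[1.0, 1.0, 1.0, 1.0], b=[2.0, 0.0, 2.0, 0.0]))
        d = population_proximity(t, ["P1", "P1", "P2", "P2"])
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_three_four_five_squared(self):
        t = pd.DataFrame(dict(a=[0.0, 3.0], b=[0.0, 4.0]))
        d = population_proximity(t, ["P1", "P2"])
        assert d.values[0, 1] == pytest.approx(25.0)

    def test_three_population_hand_computation(self):
        t = pd.DataFrame(dict(a=[0.0, 0.0, 1.0, 3.0], b=[0.0, 2.0, 1.0, 3.0]))
        pops = ["P1", "P1", "P2", "P3"]
        d = population_proximity(t, pops).to_frame()
        # means: P1 (0,1), P2 (1,1), P3 (3,3)
        assert d.loc["P1", "P2"] == pytest.approx(1.0)
        assert d.loc["P1", "P3"] == pytest.approx(9 + 4)
        assert d.loc["P2", "P3"] == pytest.approx(4 + 4)
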