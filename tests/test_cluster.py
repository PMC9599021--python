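import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as skbio_mantel

from phenodiv.cluster import (
    DistanceMatrix,
    biochem_distance,
    cut_clusters,
    genetic_distance,
    mantel_test,
    upgma,
)
from phenodiv.ssr import SSRGenotypeTable


def dm(labels, values, name=""):
    return DistanceMatrix(tuple(labels), np.asarray(values, dtype=float), name)


THREE_TAXON = dm("ABC", [[0, 2, 6], [2, 0, 6], [6, 6, 0]])


class TestDistanceMatrix:
    @pytest.mark.parametrize(
        "values",
        [
            [[0, 1], [2, 0]],  # asymmetric
            [[0, -1], [-1, 0]],  # negative
            [[1, 1], [1, 0]],  # nonzero diagonal
            [[0, np.nan], [np.nan, 0]],
        ],
    )
    def test_invalid_matrices_rejected(self, values):
        with pytest.raises(ValueError):
            dm("AB", values)

    def test_reorder_aligns_by_label(self):
        m = dm("ABC", [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        r = m.reorder(["C", "A", "B"])
        assert r.values[0, 1] == 2  # C-A
        assert r.values[0, 2] == 3  # C-B


class TestBiochemDistance:
    def test_identical_rows_distance_zero(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [3.0, 3.0, 5.0]}, index=list("abc"))
        d = biochem_distance(df, standardize=False)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_three_four_five(self):
        df = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=list("ab"))
        assert biochem_distance(df, standardize=False).values[0, 1] == pytest.approx(5.0)

    def test_zscored_matches_hand_calculation(self):
        # three genotypes, two variables; z-scores and distances done by hand
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [10.0, 30.0, 20.0]}, index=list("abc"))
        zx = np.array([-1.0, 0.0, 1.0])
        zy = np.array([-1.0, 1.0, 0.0])
        expected_ab = np.hypot(zx[0] - zx[1], zy[0] - zy[1])
        d = biochem_distance(df)
        assert d.values[0, 1] == pytest.approx(expected_ab)
        assert d.values[1, 2] == pytest.approx(np.hypot(-1.0, 1.0))

    def test_missing_value_names_offender(self):
        df = pd.DataFrame({"x": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b.*x"):
            biochem_distance(df)


class TestGeneticDistance:
    def test_identical_genotypes_zero_under_both_methods(self):
        calls = np.array([[[200, 204]], [[200, 204]]])
        t = SSRGenotypeTable(["a", "b"], ["L"], calls)
        for m in ("allele_size_euclidean", "shared_allele"):
            assert genetic_distance(t, m).values[0, 1] == pytest.approx(0.0)

    def test_shared_allele_half(self):
        calls = np.array([[[200, 204]], [[200, 208]]])
        t = SSRGenotypeTable(["a", "b"], ["L"], calls)
        assert genetic_distance(t, "shared_allele").values[0, 1] == pytest.approx(0.5)

    def test_allele_size_hand_value(self):
        calls = np.array([[[200, 200]], [[204, 204]]])
        t = SSRGenotypeTable(["a", "b"], ["L"], calls)
        d = genetic_distance(t, "allele_size_euclidean")
        assert d.values[0, 1] == pytest.approx(np.sqrt(32))  # 5.657

    def test_heterozygote_order_is_irrelevant(self):
        a = SSRGenotypeTable(["a", "b"], ["L"], np.array([[[204, 200]], [[200, 208]]]))
        b = SSRGenotypeTable(["a", "b"], ["L"], np.array([[[200, 204]], [[208, 200]]]))
        for m in ("allele_size_euclidean", "shared_allele"):
            assert genetic_distance(a, m).values[0, 1] == pytest.approx(
                genetic_distance(b, m).values[0, 1]
            )

    def test_missing_locus_normalization(self):
        # pair typed at 1 of 2 loci gets the same per-locus scale as a full pair
        full = SSRGenotypeTable(
            ["a", "b"], ["L1", "L2"],
            np.array([[[200, 200], [300, 300]], [[204, 204], [304, 304]]]),
        )
        partial = SSRGenotypeTable(
            ["a", "b"], ["L1", "L2"],
            np.array([[[200, 200], [np.nan, np.nan]], [[204, 204], [304, 304]]]),
        )
        d_full = genetic_distance(full).values[0, 1]
        d_part = genetic_distance(partial).values[0, 1]
        assert d_full == pytest.approx(np.sqrt((32 + 32) / 2))
        assert d_part == pytest.approx(np.sqrt(32))

    def test_no_shared_locus_errors(self):
        calls = np.array(
            [[[200, 200], [np.nan, np.nan]], [[np.nan, np.nan], [300, 300]]]
        )
        t = SSRGenotypeTable(["a", "b"], ["L1", "L2"], calls)
        with pytest.raises(ValueError, match="share no typed locus"):
            genetic_distance(t)

    def test_locus_mean_size_variant(self):
        calls = np.array([[[200, 204]], [[200, 208]]])
        t = SSRGenotypeTable(["a", "b"], ["L"], calls)
        d = genetic_distance(t, "allele_size_euclidean", locus_mean_size=True)
        assert d.values[0, 1] == pytest.approx(2.0)  # |202 - 204|


class TestUPGMA:
    def test_two_leaves(self):
        t = upgma(dm("AB", [[0, 2], [2, 0]]))
        assert t.root.height == pytest.approx(1.0)
        assert t.to_newick(precision=1) == "(A:1.0,B:1.0);"

    def test_three_taxon_hand_merges(self):
        t = upgma(THREE_TAXON)
        assert t.root.height == pytest.approx(3.0)
        coph = t.cophenetic()
        assert coph.values[coph.labels.index("A"), coph.labels.index("C")] == pytest.approx(6.0)
        assert coph.values[coph.labels.index("A"), coph.labels.index("B")] == pytest.approx(2.0)

    def test_ultrametric_input_is_fixed_point(self):
        coph = upgma(THREE_TAXON).cophenetic()
        again = upgma(coph).cophenetic()
        assert np.allclose(again.values, coph.values)

    @pytest.mark.parametrize("seed", range(5))
    def test_cophenetic_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        condensed = pdist(pts)
        labels = tuple(f"g{i}" for i in range(8))
        tree = upgma(DistanceMatrix(labels, squareform(condensed)))
        ours = tree.cophenetic().values
        theirs = squareform(cophenet(average(condensed)))
        assert np.allclose(ours, theirs)

    def test_newick_round_trip_via_dendropy(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        labels = tuple("ABCDEF")
        tree = upgma(DistanceMatrix(labels, squareform(pdist(pts))))
        newick = tree.to_newick()
        dt = dendropy.Tree.get(data=newick, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        ours = tree.cophenetic()
        for a, b in itertools.combinations(labels, 2):
            got = pdm.patristic_distance(taxa[a], taxa[b])
            want = ours.values[labels.index(a), labels.index(b)]
            assert got == pytest.approx(want, abs=1e-6)

    def test_tie_break_is_deterministic(self):
        # equilateral: all three merges tie at d=4; smallest indices merge first
        t = upgma(dm("ABC", [[0, 4, 4], [4, 0, 4], [4, 4, 0]]))
        assert t.to_newick(precision=0) == "((A:2,B:2):0,C:2);"


class TestCutClusters:
    def test_extremes(self):
        t = upgma(THREE_TAXON)
        assert set(cut_clusters(t, 1).values()) == {1}
        assert sorted(cut_clusters(t, 3).values()) == [1, 2, 3]

    def test_three_taxon_two_clusters(self):
        t = upgma(THREE_TAXON)
        c = cut_clusters(t, 2)
        assert c["A"] == c["B"] != c["C"]

    def test_invalid_k_rejected(self):
        t = upgma(THREE_TAXON)
        for k in (0, 4):
            with pytest.raises(ValueError):
                cut_clusters(t, k)


class TestMantel:
    def random_dm(self, n, seed, name=""):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 3))
        return DistanceMatrix(
            tuple(f"g{i}" for i in range(n)), squareform(pdist(pts)), name
        )

    def test_self_correlation_is_one(self):
        d = self.random_dm(8, 0)
        res = mantel_test(d, d, 99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_transform_keeps_r_one(self):
        d = self.random_dm(8, 1)
        d2 = DistanceMatrix(d.labels, 0.5 * d.values + squareform([3.0] * 28), "aff")
        assert mantel_test(d, d2, 99, seed=1).r == pytest.approx(1.0)

    def test_alignment_by_label_not_position(self):
        d1 = self.random_dm(7, 2)
        perm = np.random.default_rng(0).permutation(7)
        d2 = DistanceMatrix(
            tuple(d1.labels[i] for i in perm), d1.values[np.ix_(perm, perm)]
        )
        assert mantel_test(d1, d2, 99, seed=3).r == pytest.approx(1.0)

    def test_r_symmetric_in_arguments(self):
        d1, d2 = self.random_dm(9, 4), self.random_dm(9, 5)
        assert mantel_test(d1, d2, 99, seed=1).r == pytest.approx(
            mantel_test(d2, d1, 99, seed=1).r
        )

    def test_seed_reproducibility(self):
        d1, d2 = self.random_dm(9, 6), self.random_dm(9, 7)
        a = mantel_test(d1, d2, 299, seed=42)
        b = mantel_test(d1, d2, 299, seed=42)
        assert a.p_value == b.p_value

    def test_exhaustive_enumeration_oracle_4x4(self):
        """Sampled permutation p agrees with full enumeration over all 4! relabelings."""
        d1, d2 = self.random_dm(4, 8), self.random_dm(4, 9)
        iu = np.triu_indices(4, 1)
        x = d1.values[iu]
        xc = (x - x.mean()) / x.std()

        def r_of(perm):
            y = d2.values[np.ix_(perm, perm)][iu]
            return float(np.mean(xc * (y - y.mean()) / y.std()))

        r_obs = r_of((0, 1, 2, 3))
        perms = list(itertools.permutations(range(4)))
        exact_p = sum(r_of(p) >= r_obs - 1e-12 for p in perms) / len(perms)
        res = mantel_test(d1, d2, 999, seed=0)
        assert res.r == pytest.approx(r_obs)
        # sampled p within Monte-Carlo error (3 binomial SE) of the exact p
        se = np.sqrt(exact_p * (1 - exact_p) / 999)
        assert abs(res.p_value - exact_p) <= 3 * se + 2 / 1000

    def test_matches_skbio_r(self):
        d1, d2 = self.random_dm(10, 10), self.random_dm(10, 11)
        r_ref, p_ref, _ = skbio_mantel(
            SkbioDM(d1.values, d1.labels),
            SkbioDM(d2.values, d2.labels),
            method="pearson",
            permutations=999,
            alternative="greater",
        )
        res = mantel_test(d1, d2, 999, seed=5)
        assert res.r == pytest.approx(float(r_ref), abs=1e-12)
        assert res.p_value == pytest.approx(float(p_ref), abs=0.05)

    def test_zero_variance_rejected(self):
        flat = dm([f"g{i}" for i in range(4)], squareform([1.0] * 6))
        with pytest.raises(ValueError, match="zero variance"):
            mantel_test(flat, self.random_dm(4, 12), 99, seed=1)

    def test_label_mismatch_rejected(self):
        d1 = self.random_dm(5, 13)
        d2 = self.random_dm(5, 14)
        d2 = DistanceMatrix(tuple(f"x{i}" for i in range(5)), d2.values)
        with pytest.raises(ValueError, match="label"):
            mantel_test(d1, d2, 99, seed=1)
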