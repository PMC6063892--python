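"""Alpha diversity, sqrt-JSD, UniFrac (against brute-force and independent
library oracles) and PCoA."""

import io

import numpy as np
import pandas as pd
import pytest
import skbio

import cagscape as cs
from cagscape.core_io import RELATIVE
from cagscape.diversity import pcoa

from conftest import small_table


class TestAlphaDiversity:
    def test_uniform_four_otus(self):
        t = small_table([[0.25, 0.25, 0.25, 0.25]], mode=RELATIVE)
        a = cs.alpha_diversity(t)
        assert a["richness"].iloc[0] == 4
        assert a["shannon"].iloc[0] == pytest.approx(np.log(4), abs=1e-12)
        assert a["pielou"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_single_otu_sample(self):
        t = small_table([[1.0, 0.0]], mode=RELATIVE)
        a = cs.alpha_diversity(t)
        assert a["richness"].iloc[0] == 1
        assert a["shannon"].iloc[0] == 0.0
        assert np.isnan(a["pielou"].iloc[0])

    def test_hand_computed_mixture(self):
        t = small_table([[0.5, 0.25, 0.25]], mode=RELATIVE)
        a = cs.alpha_diversity(t)
        assert a["shannon"].iloc[0] == pytest.approx(1.5 * np.log(2), abs=1e-12)
        assert a["pielou"].iloc[0] == pytest.approx(
            1.5 * np.log(2) / np.log(3), abs=1e-12
        )

    def test_counts_normalized_internally(self):
        counts = small_table([[10, 10, 20]])
        rel = small_table([[0.25, 0.25, 0.5]], mode=RELATIVE)
        pd.testing.assert_frame_equal(
            cs.alpha_diversity(counts), cs.alpha_diversity(rel)
        )


def _jsd_bits(p, q):
    """Brute-force Jensen-Shannon divergence, base-2 logs."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestSqrtJsd:
    def test_identical_rows_give_zero(self):
        t = small_table([[0.3, 0.7], [0.3, 0.7]], mode=RELATIVE)
        assert cs.jsd_sqrt_matrix(t).data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_give_one(self):
        t = small_table([[1.0, 0.0], [0.0, 1.0]], mode=RELATIVE)
        assert cs.jsd_sqrt_matrix(t).data[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_value(self):
        t = small_table([[0.5, 0.5], [1.0, 0.0]], mode=RELATIVE)
        expected = np.sqrt(1.5 - 0.75 * np.log2(3))  # = sqrt(0.31128...)
        d = cs.jsd_sqrt_matrix(t).data[0, 1]
        assert d == pytest.approx(expected, abs=1e-9)
        assert d == pytest.approx(0.557923, abs=1e-5)

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(4)
        comps = rng.dirichlet(np.ones(6), size=8)
        t = small_table(comps, mode=RELATIVE)
        d = cs.jsd_sqrt_matrix(t).data
        for i in range(8):
            for j in range(i):
                assert d[i, j] == pytest.approx(
                    np.sqrt(_jsd_bits(comps[i], comps[j])), abs=1e-9
                )

    def test_triangle_inequality_metric(self):
        """sqrt-JSD is a metric: check 1,000 random composition triples."""
        rng = np.random.default_rng(11)
        triples = rng.dirichlet(np.ones(5), size=(1000, 3))
        for a, b, c in triples:
            dab = np.sqrt(_jsd_bits(a, b))
            dbc = np.sqrt(_jsd_bits(b, c))
            dac = np.sqrt(_jsd_bits(a, c))
            assert dac <= dab + dbc + 1e-12

    def test_requires_relative_mode(self):
        with pytest.raises(ValueError):
            cs.jsd_sqrt_matrix(small_table([[5, 5]]))


def _tree(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(io.StringIO(newick))


def _bruteforce_unifrac(newick, otu_ids, p1, p2, weighted):
    """Independent per-branch enumeration oracle.

    Walks every branch of the tree, computes the descendant abundance (or
    presence) for both samples, excludes branches ancestral to everything
    present in either sample, and sums the UniFrac ratio directly.
    """
    tree = _tree(newick)
    ab1 = dict(zip(otu_ids, p1))
    ab2 = dict(zip(otu_ids, p2))
    tot1, tot2 = sum(ab1.values()), sum(ab2.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        names = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        a = sum(ab1.get(x, 0.0) for x in names)
        b = sum(ab2.get(x, 0.0) for x in names)
        length = node.length or 0.0
        if weighted:
            if a >= tot1 - 1e-12 and b >= tot2 - 1e-12:
                continue  # ancestral to the pair's LCA
            num += length * abs(a - b)
            den += length * (a + b)
        else:
            pres1 = sum(1 for x in names if ab1.get(x, 0.0) > 0)
            pres2 = sum(1 for x in names if ab2.get(x, 0.0) > 0)
            rich1 = sum(1 for v in ab1.values() if v > 0)
            rich2 = sum(1 for v in ab2.values() if v > 0)
            if pres1 == rich1 and pres2 == rich2:
                continue
            if pres1 > 0 or pres2 > 0:
                den += length
                if (pres1 > 0) != (pres2 > 0):
                    num += length
    return num / den if den > 0 else 0.0


CATERPILLAR = "(((A:1,B:2):1,C:3):2,D:1);"


class TestUnifrac:
    def test_identical_samples_zero_both_variants(self):
        t = small_table([[0.5, 0.3, 0.2, 0.0]] * 2, mode=RELATIVE, otu_prefix="X")
        t.data.columns = ["A", "B", "C", "D"]
        tree = _tree(CATERPILLAR)
        for weighted in (True, False):
            d = cs.unifrac_matrix(t, tree, weighted=weighted)
            assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_leaf_disjoint_gives_one(self):
        t = small_table([[1.0, 0.0], [0.0, 1.0]], mode=RELATIVE)
        t.data.columns = ["A", "B"]
        tree = _tree("(A:1,B:1);")
        assert cs.unifrac_matrix(t, tree, True).data[0, 1] == pytest.approx(1.0)
        assert cs.unifrac_matrix(t, tree, False).data[0, 1] == pytest.approx(1.0)

    def test_caterpillar_hand_values(self):
        """Frozen hand computation over all six branches of the caterpillar."""
        t = small_table(
            [[0.5, 0.3, 0.2, 0.0], [0.1, 0.1, 0.3, 0.5], [0.0, 0.0, 0.6, 0.4]],
            mode=RELATIVE,
        )
        t.data.columns = ["A", "B", "C", "D"]
        tree = _tree(CATERPILLAR)
        dw = cs.unifrac_matrix(t, tree, weighted=True).data
        du = cs.unifrac_matrix(t, tree, weighted=False).data
        assert dw[0, 1] == pytest.approx(3.2 / 7.4, abs=1e-9)
        assert dw[0, 2] == pytest.approx(4.3 / 7.9, abs=1e-9)
        assert du[0, 1] == pytest.approx(1.0 / 10.0, abs=1e-9)
        assert du[0, 2] == pytest.approx(5.0 / 10.0, abs=1e-9)

    def test_matches_bruteforce_oracle_random_samples(self):
        newick = "((A:0.5,(B:1.2,C:0.3):0.4):1.0,(D:2.0,(E:0.1,F:0.7):0.9):0.2);"
        otus = list("ABCDEF")
        rng = np.random.default_rng(6)
        comps = rng.dirichlet(np.ones(6), size=5)
        comps[3, :3] = 0  # partial support
        comps[3] /= comps[3].sum()
        t = small_table(comps, mode=RELATIVE)
        t.data.columns = otus
        tree = _tree(newick)
        for weighted in (True, False):
            d = cs.unifrac_matrix(t, tree, weighted=weighted).data
            for i in range(5):
                for j in range(i):
                    expected = _bruteforce_unifrac(
                        newick, otus, comps[i], comps[j], weighted
                    )
                    assert d[i, j] == pytest.approx(expected, abs=1e-9)

    def test_matches_skbio_weighted_normalized(self):
        """Independent library cross-check on a random tree and table."""
        tree = cs.simulate_tree(8, seed=13)
        otus = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(14)
        counts = rng.multinomial(100_000, rng.dirichlet(np.ones(8)), size=6)
        comps = counts / counts.sum(axis=1, keepdims=True)
        t = small_table(comps, mode=RELATIVE)
        t.data.columns = otus
        ours = cs.unifrac_matrix(t, tree, weighted=True).data
        theirs = skbio.diversity.beta_diversity(
            "weighted_unifrac",
            counts,
            ids=t.sample_ids,
            taxa=otus,
            tree=tree,
            normalized=True,
        ).data
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_degree_two_node_invariance(self):
        """Splitting a branch into two summing parts changes nothing."""
        base = "((A:1,B:2):2,(C:3,D:1):1);"
        split = "((A:1,B:2):2,((C:3,D:1):0.4):0.6);"
        rng = np.random.default_rng(15)
        comps = rng.dirichlet(np.ones(4), size=4)
        t = small_table(comps, mode=RELATIVE)
        t.data.columns = list("ABCD")
        for weighted in (True, False):
            d1 = cs.unifrac_matrix(t, _tree(base), weighted=weighted).data
            d2 = cs.unifrac_matrix(t, _tree(split), weighted=weighted).data
            np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_missing_abundant_otu_rejected(self):
        t = small_table([[0.5, 0.5]], mode=RELATIVE)
        t.data.columns = ["A", "Z"]
        with pytest.raises(ValueError, match="missing from tree"):
            cs.unifrac_matrix(t, _tree("(A:1,B:1);"), weighted=True)

    def test_unrooted_tree_rejected(self):
        t = small_table([[0.4, 0.3, 0.3]], mode=RELATIVE)
        t.data.columns = list("ABC")
        with pytest.raises(ValueError, match="unrooted"):
            cs.unifrac_matrix(t, _tree("(A:1,B:1,C:1);"), weighted=True)


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = skbio.DistanceMatrix(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc")
        )
        ord_ = pcoa(dm)
        assert len(ord_.eigenvalues) == 2
        np.testing.assert_allclose(ord_.eigenvalues[0], ord_.eigenvalues[1], atol=1e-12)
        np.testing.assert_allclose(ord_.proportion_explained, [0.5, 0.5], atol=1e-12)

    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        ord_ = pcoa(skbio.DistanceMatrix(d, ids=list("abcd")))
        assert ord_.proportion_explained[0] == pytest.approx(1.0, abs=1e-9)
        axis1 = ord_.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0, 3.0], atol=1e-9)

    def test_identical_samples_collapse(self):
        d = np.array(
            [[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]]
        )
        ord_ = pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
        np.testing.assert_allclose(
            ord_.coordinates.iloc[0], ord_.coordinates.iloc[1], atol=1e-9
        )

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ord_ = pcoa(skbio.DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        coords = ord_.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(d2, d, atol=1e-9)

    def test_matches_skbio_proportions(self, gradient_jsd):
        ours = pcoa(gradient_jsd)
        theirs = skbio.stats.ordination.pcoa(gradient_jsd, method="eigh")
        k = min(3, len(ours.proportion_explained))
        # same leading eigenvalues regardless of negative-eigenvalue policy
        np.testing.assert_allclose(
            ours.eigenvalues[:k],
            theirs.eigvals.to_numpy()[:k],
            rtol=1e-8,
        )
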