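"""Distance phylogenetics: JC distances, NJ, RF, RELL support and
recombination-aware stripping."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

import recsweep as rs
from recsweep.events import RecombinationEvent
from recsweep.phylo import (SaturationError, compatibility_matrix, jc_distance,
                            jc_from_pdiff, nj_tree, rf_distance,
                            sh_like_support, strip_recombination, tree_splits)
from recsweep.alignment import Alignment


def random_additive_tree(n, seed):
    """Random topology with branch lengths bounded away from zero, plus
    its exact leaf-pair path-length matrix."""
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(n)]

    def build(leaves):
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.uniform(0.05, 0.4):.6f}"
        k = int(rng.integers(1, len(leaves)))
        return (f"({build(leaves[:k])},{build(leaves[k:])})"
                f":{rng.uniform(0.05, 0.4):.6f}")

    order = list(rng.permutation(names))
    k = max(1, int(rng.integers(1, len(order))))
    newick = f"({build(order[:k])},{build(order[k:])});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[a], taxa[names[j]])
    return newick, names, D


def test_jc_distance_examples():
    aln = Alignment(["a", "b"], ["ACGT" * 5, "ACGT" * 5])
    assert jc_distance(aln, 0, 1) == 0.0
    assert jc_from_pdiff(0.1) == pytest.approx(0.10732, abs=1e-5)
    ps = np.linspace(0.01, 0.7, 30)
    ds = [jc_from_pdiff(p) for p in ps]
    assert np.all(np.diff(ds) > 0)
    with pytest.raises(SaturationError):
        jc_from_pdiff(0.8)
    sat = Alignment(["x", "y"], ["AAAA", "CCCC"])
    with pytest.raises(SaturationError, match="x"):
        jc_distance(sat, 0, 1)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = nj_tree(D, ["a", "b", "c"])
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_additive_four_taxon_exact():
    # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
    D = np.array([[0, 3, 5, 6],
                  [3, 0, 6, 7],
                  [5, 6, 0, 7],
                  [6, 7, 7, 0]], float)
    tree = nj_tree(D, list("abcd"))
    assert tree_splits(tree) == {
        frozenset((frozenset("ab"), frozenset("cd")))}
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, x in enumerate("abcd"):
        for j, y in enumerate("abcd"):
            if i < j:
                assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(D[i, j])


@pytest.mark.parametrize("n", [5, 6, 8])
def test_nj_recovers_random_additive_trees(n):
    for seed in range(4):
        newick, names, D = random_additive_tree(n, 100 * n + seed)
        est = nj_tree(D, names)
        truth = dendropy.Tree.get(data=newick, schema="newick")
        assert tree_splits(est) == tree_splits(truth)
        pdm = est.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in est.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                assert pdm.distance(taxa[names[i]], taxa[names[j]]) == \
                    pytest.approx(D[i, j], abs=1e-8)


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0, 1], [2, 0]], float), ["a", "b"])
    bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(bad, list("abc"))


def test_rf_examples_and_oracle():
    t1 = nj_tree(np.array([[0, 2, 9, 9], [2, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]], float), list("abcd"))
    t2 = nj_tree(np.array([[0, 9, 2, 9], [9, 0, 9, 2], [2, 9, 0, 9], [9, 2, 9, 0]], float), list("abcd"))
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2
    # random 8-taxon pairs vs the dendropy split-set oracle
    for seed in range(10):
        n1, names, _ = random_additive_tree(8, 500 + seed)
        n2, _, _ = random_additive_tree(8, 900 + seed)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = treecompare.symmetric_difference(d1, d2)
        m1 = dendropy.Tree.get(data=n1, schema="newick")
        m2 = dendropy.Tree.get(data=n2, schema="newick")
        assert rf_distance(m1, m2) == expected
    t3 = nj_tree(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), list("xyz"))
    with pytest.raises(ValueError):
        rf_distance(t1, t3)


def test_rf_is_a_metric_empirically():
    trees = []
    for seed in range(5):
        nwk, _, _ = random_additive_tree(6, 40 + seed)
        trees.append(dendropy.Tree.get(data=nwk, schema="newick"))
    for a in trees:
        assert rf_distance(a, a) == 0
        for b in trees:
            assert rf_distance(a, b) == rf_distance(b, a)
            for c in trees:
                assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)


def test_newick_round_trip():
    nwk, names, D = random_additive_tree(6, 77)
    tree = nj_tree(D, names)
    text = tree.as_string(schema="newick")
    back = dendropy.Tree.get(data=text, schema="newick")
    assert tree_splits(back) == tree_splits(tree)
    lengths = sorted(lf.edge.length for lf in tree.leaf_node_iter())
    lengths2 = sorted(lf.edge.length for lf in back.leaf_node_iter())
    assert np.allclose(lengths, lengths2, atol=1e-9)


def test_sh_like_support_self_and_bounds(bench_quartet):
    aln, _ = bench_quartet
    from recsweep.phylo import jc_matrix
    win = (0, 500)
    own = nj_tree(jc_matrix(aln, win), aln.names)
    assert sh_like_support(aln, win, own, n_rell=100, seed=0) == 1.0
    other_win = (1500, 2000)
    other = nj_tree(jc_matrix(aln, other_win), aln.names)
    s = sh_like_support(aln, win, other, n_rell=100, seed=0)
    assert 0.0 <= s <= 1.0
    with pytest.raises(ValueError):
        sh_like_support(aln, (100, 100), own)


def test_compatibility_matrix_structure():
    aln, _ = rs.simulate_events_dataset(8, 2000, [(600, 1400)], seed=2)
    res = compatibility_matrix(aln, window_len=500, step=250, n_rell=100, seed=0)
    W = len(res["windows"])
    assert res["rf"].shape == (W, W)
    for i in range(W):
        assert res["rf"][i, i] == 0 and res["sh"][i, i] == 1.0
    assert np.allclose(res["rf"], res["rf"].T, equal_nan=True)
    assert np.allclose(res["sh"], res["sh"].T, equal_nan=True)

    null = rs.simulate_tree_alignment(rs.random_tree(8, 7), 2000, 7)
    res0 = compatibility_matrix(null, window_len=500, step=250, n_rell=100, seed=0)
    iu = np.triu_indices(W, 1)
    assert np.nanmedian(res0["rf"][iu]) <= np.nanmedian(res["rf"][iu])
    assert np.nanmedian(res0["sh"][iu]) >= np.nanmedian(res["sh"][iu])
    with pytest.raises(ValueError):
        compatibility_matrix(null, window_len=1900, step=500)


def test_strip_recombination_modes(bench_quartet):
    aln, truth = bench_quartet
    ev = RecombinationEvent(1, [truth.events[0].recombinant], "B", "A",
                            601, (590, 610), 1400, (1390, 1410))
    assert strip_recombination(aln, [], "remove").rows == aln.rows

    removed = strip_recombination(aln, [ev], "remove")
    assert removed.length == aln.length and removed.n_sequences == aln.n_sequences
    idx = removed.index_of("C")
    assert set(removed.rows[idx][600:1400]) == {"-"}
    assert removed.rows[idx][:600] == aln.rows[aln.index_of("C")][:600]

    split = strip_recombination(aln, [ev], "split")
    assert split.n_sequences == aln.n_sequences + 1
    assert "C_minor" in split.names and "C_major" in split.names

    with pytest.raises(KeyError):
        strip_recombination(aln, [RecombinationEvent(
            1, ["nope"], "B", "A", 601, (601, 601), 1400, (1400, 1400))])
    with pytest.raises(ValueError):
        strip_recombination(aln, [ev], "shred")
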