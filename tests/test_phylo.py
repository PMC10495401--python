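"""JC distances, neighbor joining, pruning likelihood, ML search, bootstrap."""

import math

import numpy as np
import pytest

from oracles import exhaustive_loglik, jc_dist
from plastcomp import phylo as P
from plastcomp.synthetic import evolve_alignment


def test_jc_distance_closed_form():
    assert P.jc_distance(0.0) == 0.0
    assert P.jc_distance(0.30) == pytest.approx(jc_dist(0.30), abs=1e-12)
    assert math.isinf(P.jc_distance(0.75))
    assert math.isinf(P.jc_distance(0.9))
    with pytest.raises(ValueError):
        P.jc_distance(1.5)


def test_distance_matrix_identical_zero():
    msa = {"a": "ACGTACGT", "b": "ACGTACGT"}
    dm = P.distance_matrix(msa)
    assert dm.get("a", "b") == 0.0


def test_distance_matrix_no_overlap_errors():
    msa = {"a": "AC--", "b": "--GT"}
    with pytest.raises(ValueError, match="a.*b|b.*a"):
        P.distance_matrix(msa)


def test_distance_recovers_simulated_branch_length():
    t = 0.2
    msa = evolve_alignment(f"(X:{t / 2},Y:{t / 2});", 50_000, seed=3)
    dm = P.distance_matrix(msa)
    d = dm.get("X", "Y")
    p = 0.75 * (1 - math.exp(-4 * t / 3))
    se = math.sqrt(p * (1 - p) / 50_000) / (1 - 4 * p / 3)  # delta method
    assert abs(d - t) < 3 * se


def test_nj_exact_on_additive_four_taxon_matrix():
    # tree: ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
    taxa = ["A", "B", "C", "D"]
    mat = np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 0, 0],
    ], dtype=float)
    mat[2, 3] = mat[3, 2] = 9.0
    dm = P.DistanceMatrix(taxa, mat)
    tree = P.nj_tree(dm)
    assert tree.bipartitions() == {frozenset({"A", "B"})}
    # branch lengths: leaves A and B
    lengths = {l.name: l.length for l in tree.leaves()}
    assert lengths["A"] == pytest.approx(2.0)
    assert lengths["B"] == pytest.approx(3.0)


def test_nj_three_taxa_unique_tree():
    dm = P.DistanceMatrix(["a", "b", "c"],
                          np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
    tree = P.nj_tree(dm)
    assert set(tree.leaf_names()) == {"a", "b", "c"}
    assert len(tree.children) == 3


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(0)
    n = 6
    coords = rng.random((n, 3))
    mat = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    taxa = [f"t{i}" for i in range(n)]
    t1 = P.nj_tree(P.DistanceMatrix(taxa, mat))
    perm = rng.permutation(n)
    t2 = P.nj_tree(P.DistanceMatrix([taxa[i] for i in perm],
                                    mat[np.ix_(perm, perm)]))
    assert t1.bipartitions() == t2.bipartitions()


def test_nj_against_skbio():
    """Cross-check topology with scikit-bio's independent NJ."""
    import skbio

    rng = np.random.default_rng(7)
    true = "((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1,E:0.25);"
    msa = evolve_alignment(true, 5000, seed=8)
    dm = P.distance_matrix(msa)
    ours = P.nj_tree(dm)
    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.taxa)
    sk_tree = skbio.tree.nj(sk_dm)
    sk_splits = set()
    names = set(dm.taxa)
    for node in sk_tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(names) - 2:
            sk_splits.add(min(side, frozenset(names - side),
                              key=lambda s: (len(s), sorted(s))))
    assert ours.bipartitions() == sk_splits


def test_loglik_identical_sequences_zero_branches():
    n = 40
    msa = {"a": "ACGT" * 10, "b": "ACGT" * 10}
    tree = P.parse_newick("(a:0,b:0);")
    assert P.jc_loglik(tree, msa) == pytest.approx(n * math.log(0.25))


def test_loglik_rerooting_invariance():
    msa = evolve_alignment("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07);", 300, seed=4)
    t1 = P.parse_newick("((A:0.1,B:0.2):0.12,C:0.15,D:0.1);")
    t2 = P.parse_newick("((C:0.15,D:0.1):0.12,A:0.1,B:0.2);")
    assert P.jc_loglik(t1, msa) == pytest.approx(P.jc_loglik(t2, msa), abs=1e-9)


@pytest.mark.parametrize("seed", range(4))
def test_loglik_matches_exhaustive_state_sum(seed):
    rng = np.random.default_rng(seed)
    msa = {t: "".join(rng.choice(list("ACGT"), size=6)) for t in "ABCD"}
    tree = P.parse_newick("((A:0.13,B:0.21):0.08,C:0.4,D:0.05);")
    assert P.jc_loglik(tree, msa) == pytest.approx(
        exhaustive_loglik(tree, msa), abs=1e-8)


def test_loglik_gap_marginalization_matches_exhaustive():
    msa = {"A": "AC-GTA", "B": "ACGGTA", "C": "ACN", "D": "ACGGT-"}
    msa = {k: (v + "AAAAAA")[:6] for k, v in msa.items()}
    tree = P.parse_newick("((A:0.1,B:0.2):0.1,C:0.3,D:0.15);")
    assert P.jc_loglik(tree, msa) == pytest.approx(
        exhaustive_loglik(tree, msa), abs=1e-8)


def test_pattern_compression_does_not_change_likelihood():
    msa = evolve_alignment("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.07);", 2000, seed=5)
    tree = P.parse_newick("((A:0.1,B:0.2):0.12,C:0.15,D:0.1);")
    taxa, arr = P.encode_alignment(msa)
    index = {t: i for i, t in enumerate(taxa)}
    uncompressed = P._loglik_compressed(tree, arr, np.ones(arr.shape[1]), index)
    assert P.jc_loglik(tree, msa) == pytest.approx(uncompressed, abs=1e-10)


def test_local_optimality_of_optimized_branch_lengths():
    msa = evolve_alignment("((A:0.1,B:0.2):0.1,C:0.3);", 2000, seed=6)
    tree, ll = P.ml_search(msa)
    rng = np.random.default_rng(0)
    for _ in range(10):
        t2 = tree.copy()
        for e in P._all_edges(t2):
            e.length = max(e.length + rng.normal(0, 0.02), 1e-6)
        assert P.jc_loglik(t2, msa) <= ll + 1e-9


def test_ml_identical_sequences_deterministic_tie():
    msa = {t: "ACGTACGTAC" for t in "ABCD"}
    tree, ll = P.ml_search(msa)
    first = P.enumerate_topologies(["A", "B", "C", "D"])[0]
    assert P.same_topology(tree, first)


def test_ml_recovers_generating_topology():
    true = P.parse_newick("((A:0.05,B:0.08):0.06,(C:0.1,D:0.07):0.09,E:0.15);")
    hits = 0
    for seed in range(3):
        msa = evolve_alignment(true, 10_000, seed=100 + seed)
        tree, _ = P.ml_search(msa)
        hits += P.same_topology(tree, true)
    assert hits == 3


def test_sister_species_clade():
    """The two most similar taxa form a clade (study-system mimic)."""
    nwk = ("(((Llam:0.01,Lcul:0.012):0.05,Lerv:0.06):0.04,"
           "(Cari:0.05,Cech:0.04):0.06,Atha:0.3);")
    msa = evolve_alignment(nwk, 8000, seed=9)
    tree, _ = P.ml_search(msa)
    assert frozenset({"Llam", "Lcul"}) in tree.bipartitions()


def test_ml_fewer_than_three_taxa_errors():
    with pytest.raises(ValueError):
        P.ml_search({"a": "ACGT", "b": "ACGT"})


def test_bootstrap_zero_reps_and_determinism():
    msa = evolve_alignment("((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1,E:0.2);",
                           2000, seed=10)
    t0 = P.bootstrap_support(msa, 0, seed=1, method="nj")
    assert all(n.support is None for n in t0.postorder())
    t1 = P.bootstrap_support(msa, 20, seed=1, method="nj")
    t2 = P.bootstrap_support(msa, 20, seed=1, method="nj")
    s1 = [n.support for n in t1.postorder() if n.support is not None]
    s2 = [n.support for n in t2.postorder() if n.support is not None]
    assert s1 == s2 and s1


def test_bootstrap_strong_signal_full_support():
    msa = evolve_alignment("((A:0.02,B:0.02):0.3,(C:0.02,D:0.02):0.3);",
                           5000, seed=11)
    tree = P.bootstrap_support(msa, 25, seed=2, method="nj")
    supports = [n.support for n in tree.postorder() if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_newick_output_with_supports_parses():
    import dendropy

    msa = evolve_alignment("((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1,E:0.2);",
                           1000, seed=12)
    tree = P.bootstrap_support(msa, 10, seed=3, method="nj")
    nwk = tree.to_newick(with_support=True)
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in dt.leaf_node_iter()} == set("ABCDE")
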