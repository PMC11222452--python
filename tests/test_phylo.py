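import math

import dendropy
import numpy as np
import pytest
from oracles import brute_generalized_rf, brute_log_likelihood, brute_rf

import plastidkit as pk
from plastidkit.phylo import (DistanceMatrix, GTRModel, PhyloTree,
                              SaturationError, bootstrap_consensus,
                              generalized_rf, log_likelihood,
                              majority_consensus, nj_tree, optimize_tree,
                              pairwise_distances, rf_distance)
from plastidkit.simulate import simulate_tree


# ---------------------------------------------------------------------------
# distances between sequences
# ---------------------------------------------------------------------------

def test_pairwise_distance_closed_forms():
    rows = {"a": "A" * 100, "b": "A" * 90 + "C" * 10, "c": "A" * 100}
    d = pairwise_distances(rows, model="p")
    ia, ib = d.taxa.index("a"), d.taxa.index("b")
    assert d.matrix[ia, ib] == pytest.approx(0.1)
    d2 = pairwise_distances(rows, model="JC69")
    assert d2.matrix[ia, ib] == pytest.approx(
        -0.75 * math.log(1 - 0.4 / 3), abs=1e-10)
    assert d2.matrix[ia, ia] == 0.0


def test_k2p_closed_form():
    # 8% transitions (A<->G), 2% transversions (A<->C) over 100 sites
    rows = {"a": "A" * 100, "b": "G" * 8 + "C" * 2 + "A" * 90,
            "c": "A" * 100}
    d = pairwise_distances(rows, model="K2P")
    ia, ib = d.taxa.index("a"), d.taxa.index("b")
    P, Q = 0.08, 0.02
    expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
    assert d.matrix[ia, ib] == pytest.approx(expected, abs=1e-12)


def test_jc_saturation_errors_and_cap():
    rows = {"a": "A" * 100, "b": "C" * 80 + "A" * 20, "c": "A" * 100}
    with pytest.raises(SaturationError):
        pairwise_distances(rows, model="JC69")
    d = pairwise_distances(rows, model="JC69", cap=5.0)
    assert d.matrix.max() == 5.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_nj_three_taxa_solves_three_point_equations():
    m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    t = nj_tree(DistanceMatrix(["A", "B", "C"], m))
    lengths = {n.label: n.length for n in t.root.children}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(2.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_nj_additive_four_taxa():
    m = np.array([[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 4], [4, 4, 4, 0]],
                 float)
    t = nj_tree(DistanceMatrix(list("ABCD"), m))
    assert t.splits() == frozenset({frozenset({"C", "D"})})


def test_nj_recovers_additive_tree_exactly(rng):
    for seed in range(5):
        true = simulate_tree(7, seed=seed)
        taxa = sorted(true.taxa())
        depths = {}

        def paths(tree):
            import itertools
            d = {}
            # path length between tips via common traversal
            anc = {}

            def walk(n, acc):
                acc = acc + [(n, (n.length or 0.0))]
                if n.is_leaf():
                    anc[n.label] = acc
                for c in n.children:
                    walk(c, acc)
            walk(tree.root, [])
            for a, b in itertools.combinations(taxa, 2):
                pa = {id(n): l for n, l in anc[a]}
                shared = [id(n) for n, _ in anc[b] if id(n) in pa]
                lca = shared[-1]
                da = sum(l for n, l in reversed(anc[a])
                         if id(n) != lca) if True else 0
                # sum from tip up to (excluding) the LCA
                def up(path):
                    s = 0.0
                    for n, l in reversed(path):
                        if id(n) == lca:
                            break
                        s += l
                    return s
                d[(a, b)] = up(anc[a]) + up(anc[b])
            return d

        pd_ = paths(true)
        m = np.zeros((len(taxa), len(taxa)))
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    m[i, j] = m[j, i] = pd_[(a, b)]
        rec = nj_tree(DistanceMatrix(taxa, m))
        assert rec.splits() == true.splits()


def test_nj_matches_skbio_on_noisy_matrices(rng):
    import skbio

    for _ in range(5):
        true = simulate_tree(6, seed=int(rng.integers(2 ** 31)))
        taxa = sorted(true.taxa())
        # noisy additive matrix: perturbed path lengths, no exact ties
        rows = {t: "" for t in taxa}
        m = np.zeros((6, 6))
        depths = true.depths()
        anc = {}

        def walk(n, acc):
            acc = acc + [n]
            if n.is_leaf():
                anc[n.label] = acc
            for c in n.children:
                walk(c, acc)
        walk(true.root, [])
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    shared = sum((x.length or 0) for x in anc[a]
                                 if x in anc[b])
                    d = depths[a] + depths[b] - 2 * shared
                    d *= 1 + 0.05 * rng.standard_normal()
                    m[i, j] = m[j, i] = abs(d) + 1e-6
        mine = nj_tree(DistanceMatrix(taxa, m))
        sk = skbio.tree.nj(skbio.DistanceMatrix(m, ids=taxa))
        theirs = PhyloTree.from_newick(str(sk).strip())
        assert mine.splits() == theirs.splits()


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        DistanceMatrix(list("ABC"), np.array([[0, 1, 2], [1.5, 0, 1],
                                              [2, 1, 0]], float))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_two_identical_sequences_zero_branch_length():
    tree = PhyloTree.from_newick("(x:0,y:0);")
    ll = log_likelihood(tree, {"x": "A", "y": "A"}, GTRModel.jc(ncat=1))
    assert ll == pytest.approx(math.log(0.25), abs=1e-9)


def test_long_branch_limit_is_independence():
    tree = PhyloTree.from_newick("(x:200,y:200);")
    ll = log_likelihood(tree, {"x": "A", "y": "C"}, GTRModel.jc(ncat=1))
    assert ll == pytest.approx(math.log(0.25 * 0.25), abs=1e-6)


def test_two_taxon_jc_closed_form():
    t = 0.2
    tree = PhyloTree.from_newick(f"(x:{t / 2},y:{t / 2});")
    rows = {"x": "A" * 100, "y": "A" * 90 + "C" * 10}
    ll = log_likelihood(tree, rows, GTRModel.jc(ncat=1))
    closed = (90 * math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
              + 10 * math.log(0.25 * (0.25 - 0.25 * math.exp(-4 * t / 3))))
    assert ll == pytest.approx(closed, abs=1e-10)


def test_pruning_matches_bruteforce_enumeration(rng):
    model = GTRModel(exch=np.array([1.0, 2.5, 0.8, 1.2, 3.0, 1.0]),
                     freqs=np.array([0.31, 0.19, 0.24, 0.26]),
                     alpha=0.7, ncat=4)
    tree = PhyloTree.from_newick(
        "((A:0.12,B:0.30):0.08,(C:0.25,D:0.05):0.11);")
    rows = {t: "".join("ACGT-"[rng.integers(0, 5)] for _ in range(12))
            for t in "ABCD"}
    ll = log_likelihood(tree, rows, model)
    assert ll == pytest.approx(brute_log_likelihood(tree, rows, model),
                               abs=1e-10)


def test_invalid_model_rejected():
    with pytest.raises(ValueError):
        GTRModel(exch=np.array([1, 1, 1, 1, 1, -1.0]))
    with pytest.raises(ValueError):
        GTRModel(freqs=np.array([0.5, 0.5, 0.2, 0.2]))


# ---------------------------------------------------------------------------
# ML search
# ---------------------------------------------------------------------------

def _simulated_rows(n_taxa, n_sites, seed, subs=0.15, tree=None):
    import dataclasses
    from plastidkit.simulate import SimulationParams, _Evolver
    if tree is None:
        tree = simulate_tree(n_taxa, seed=seed)
    params = SimulationParams(subs_per_site=subs)
    ev = _Evolver(params, np.random.default_rng(seed))
    spec = dataclasses.replace(params.template.lsc[0], name="L",
                               kind="gene", length=n_sites)
    state = ev.root_locus(spec)
    out = {}

    def walk(node, st):
        if node.length:
            st = (ev._substitute(st[0], st[1], node.length * subs), st[1])
        if node.is_leaf():
            out[node.label] = st[0]
        for c in node.children:
            walk(c, st)

    walk(tree.root, state)
    NUC = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {k: NUC[v].tobytes().decode() for k, v in out.items()}, tree


def test_optimize_tree_recovers_topology():
    wins = 0
    for seed in range(6):
        rows, true = _simulated_rows(6, 1200, seed)
        best, ll, _ = optimize_tree(rows)
        wins += rf_distance(best, true).raw == 0
    assert wins >= 5


def test_optimize_tree_improves_on_start():
    rows, true = _simulated_rows(6, 600, seed=11)
    dm = pairwise_distances(rows, cap=5.0)
    start = nj_tree(dm)
    model = pk.GTRModel.jc(ncat=4)
    ll_start = log_likelihood(start, rows, model)
    best, ll, _ = optimize_tree(rows, model=model)
    assert ll >= ll_start


def test_optimize_tree_small_taxa_trivial():
    rows, _ = _simulated_rows(3, 200, seed=2)
    tree, ll, _ = optimize_tree(rows)
    assert tree.taxa() == set(rows)


# ---------------------------------------------------------------------------
# bootstrap + consensus
# ---------------------------------------------------------------------------

def test_bootstrap_single_replicate_is_that_tree():
    rows, _ = _simulated_rows(6, 500, seed=3)
    cons, reps = bootstrap_consensus(rows, B=1, seed=9, method="nj")
    assert cons.splits() == reps[0].splits()
    for n in cons.postorder():
        if not n.is_leaf() and n.support is not None:
            assert n.support == 100.0


def test_bootstrap_clean_signal_high_support():
    # balanced tree with long internal edges: unambiguous signal
    strong = PhyloTree.from_newick(
        "((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1,(E:0.1,F:0.1):0.1);")
    rows, true = _simulated_rows(6, 5000, seed=4, subs=1.0, tree=strong)
    cons, _ = bootstrap_consensus(rows, B=100, seed=5, method="nj")
    assert cons.splits() == true.splits()
    for n in cons.postorder():
        if n.support is not None:
            assert n.support >= 95.0


def test_bootstrap_deterministic_given_seed():
    rows, _ = _simulated_rows(5, 300, seed=6)
    c1, _ = bootstrap_consensus(rows, B=20, seed=42)
    c2, _ = bootstrap_consensus(rows, B=20, seed=42)
    assert c1.to_newick() == c2.to_newick()


def test_majority_consensus_matches_dendropy(rng):
    for trial in range(5):
        trees = [simulate_tree(6, seed=int(rng.integers(2 ** 31)))
                 for _ in range(7)]
        cons = majority_consensus(trees, threshold=0.5)
        tns = dendropy.TaxonNamespace()
        tl = dendropy.TreeList([t.to_dendropy(tns) for t in trees],
                               taxon_namespace=tns)
        dcons = tl.consensus(min_freq=0.5001)
        dsplits = PhyloTree.from_newick(
            dcons.as_string(schema="newick")).splits()
        assert cons.splits() == dsplits


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def test_rf_worked_examples():
    t1 = PhyloTree.from_newick("((A,B),C,(D,E));")
    t2 = PhyloTree.from_newick("((A,C),B,(D,E));")
    star = PhyloTree.from_newick("(A,B,C,D,E);")
    assert rf_distance(t1, t1).raw == 0
    d = rf_distance(t1, t2)
    assert d.raw == 2 and d.normalized == pytest.approx(0.5)
    ds = rf_distance(star, t1)
    assert ds.raw == 2 and ds.normalized == 1.0
    with pytest.raises(ValueError):
        rf_distance(t1, PhyloTree.from_newick("(X,Y,Z);"))


def test_rf_matches_dendropy(rng):
    for _ in range(15):
        t1 = simulate_tree(7, seed=int(rng.integers(2 ** 31)))
        t2 = simulate_tree(7, seed=int(rng.integers(2 ** 31)))
        tns = dendropy.TaxonNamespace()
        d1, d2 = t1.to_dendropy(tns), t2.to_dendropy(tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2).raw == expected
        assert brute_rf(t1, t2) == expected


def test_generalized_rf_axioms(rng):
    for _ in range(25):
        t1 = simulate_tree(8, seed=int(rng.integers(2 ** 31)))
        t2 = simulate_tree(8, seed=int(rng.integers(2 ** 31)))
        d12 = generalized_rf(t1, t2)
        d21 = generalized_rf(t2, t1)
        assert d12.normalized == pytest.approx(d21.normalized, abs=1e-12)
        assert 0.0 <= d12.normalized <= 1.0
        assert generalized_rf(t1, t1).normalized == pytest.approx(0.0,
                                                                  abs=1e-12)
        if t1.splits() != t2.splits():
            assert d12.normalized > 0


def test_generalized_rf_matching_is_optimal(rng):
    # exhaustive matching enumeration for trees with up to 5 splits each
    for _ in range(10):
        t1 = simulate_tree(8, seed=int(rng.integers(2 ** 31)))
        t2 = simulate_tree(8, seed=int(rng.integers(2 ** 31)))
        assert generalized_rf(t1, t2).normalized == pytest.approx(
            brute_generalized_rf(t1, t2), abs=1e-12)


def test_distances_invariant_to_tip_relabeling(rng):
    t1 = simulate_tree(7, seed=1)
    t2 = simulate_tree(7, seed=2)
    perm = dict(zip(sorted(t1.taxa()),
                    rng.permutation(sorted(t1.taxa()))))

    def relabel(t):
        t = t.copy()
        for n in t.postorder():
            if n.is_leaf():
                n.label = perm[n.label]
        return t

    assert rf_distance(t1, t2).raw == rf_distance(relabel(t1),
                                                  relabel(t2)).raw
    assert generalized_rf(t1, t2).normalized == pytest.approx(
        generalized_rf(relabel(t1), relabel(t2)).normalized, abs=1e-12)


def test_distance_on_pruned_common_tips():
    t1 = PhyloTree.from_newick("((A,B),(C,(D,E)));")
    t2 = PhyloTree.from_newick("((A,B),(C,(D,F)));")
    d = rf_distance(t1, t2)
    assert d.n_shared == 4  # E and F pruned away
    assert d.raw == 0
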