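"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code path with the package implementation.
"""

import itertools
import math

import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def brute_pi_windows(rows: dict, window: int, step: int,
                     deletion: str = "complete"):
    """Per-window pi by direct all-pairs counting."""
    names = list(rows)
    ncols = len(rows[names[0]])
    out = []
    start = 0
    while True:
        end = min(start + window, ncols)
        cols = list(range(start, end))
        if deletion == "complete":
            cols = [c for c in cols
                    if all(rows[n][c] not in "-.~" for n in names)]
        total = 0.0
        npairs = 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                npairs += 1
                diff = 0
                comp = 0
                for c in cols:
                    x, y = rows[names[i]][c], rows[names[j]][c]
                    if x in BASES and y in BASES:
                        comp += 1
                        diff += x != y
                if comp:
                    total += diff / comp
        pi = total / npairs if cols else float("nan")
        out.append(pi)
        if end == ncols:
            break
        start += step
        if start >= ncols:
            break
    return out


# ---------------------------------------------------------------------------
# parsimony by exhaustive internal labeling
# ---------------------------------------------------------------------------

def _edges_and_nodes(tree):
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf()]
    edges = []
    for n in nodes:
        for c in n.children:
            edges.append((n, c))
    return internal, edges


def brute_fitch(column: dict, tree) -> int:
    """Minimum changes over all assignments of states to internal nodes."""
    internal, edges = _edges_and_nodes(tree)
    best = None
    for assign in itertools.product(range(4), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assign)}
        ok = True
        cost = 0
        for parent, child in edges:
            if child.is_leaf():
                obs = column[child.label]
                if obs in BASES:
                    cs = BASES.index(obs)
                else:
                    # missing: choose the parent's state for free
                    cs = state[id(parent)]
            else:
                cs = state[id(child)]
            cost += cs != state[id(parent)]
        if ok and (best is None or cost < best):
            best = cost
    return best


# ---------------------------------------------------------------------------
# likelihood by explicit summation over internal states
# ---------------------------------------------------------------------------

def brute_log_likelihood(tree, rows: dict, model) -> float:
    """Sum over all internal-state assignments and rate categories."""
    from scipy.linalg import expm

    q = model.rate_matrix()
    cat_rates = model.category_rates()
    internal, edges = _edges_and_nodes(tree)
    ncols = len(next(iter(rows.values())))
    ll = 0.0
    for site in range(ncols):
        site_l = 0.0
        for r in cat_rates:
            p_edges = {id(c): expm(q * r * (c.length or 0.0))
                       for _, c in edges}
            lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                state = {id(n): s for n, s in zip(internal, assign)}
                term = model.freqs[state[id(tree.root)]]
                for parent, child in edges:
                    ps = state[id(parent)]
                    if child.is_leaf():
                        obs = rows[child.label][site]
                        if obs in BASES:
                            term *= p_edges[id(child)][ps, BASES.index(obs)]
                        # missing: sums to 1, no factor
                    else:
                        term *= p_edges[id(child)][ps, state[id(child)]]
                lik += term
            site_l += lik / len(cat_rates)
        ll += math.log(site_l)
    return ll


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

def splits_of(tree):
    return tree.splits()


def brute_rf(t1, t2) -> int:
    s1, s2 = t1.splits(), t2.splits()
    return len(s1 ^ s2)


def _entropy(p):
    h = 0.0
    for x in (p, 1 - p):
        if x > 0:
            h -= x * math.log2(x)
    return h


def _mci(a, b, taxa):
    n = len(taxa)
    cells = [len(a & b), len(a - b), len(b - a),
             n - len(a | b)]
    pa, pb = len(a) / n, len(b) / n
    margs = [(pa, pb), (pa, 1 - pb), (1 - pa, pb), (1 - pa, 1 - pb)]
    total = 0.0
    for nij, (pi, pj) in zip(cells, margs):
        if nij:
            pij = nij / n
            total += pij * math.log2(pij / (pi * pj))
    return max(total, 0.0)


def brute_generalized_rf(t1, t2) -> float:
    """Exhaustive enumeration over all split matchings."""
    taxa = t1.taxa() & t2.taxa()
    s1, s2 = sorted(t1.splits(), key=sorted), sorted(t2.splits(), key=sorted)
    h1 = sum(_entropy(len(s) / len(taxa)) for s in s1)
    h2 = sum(_entropy(len(s) / len(taxa)) for s in s2)
    if h1 + h2 == 0:
        return 0.0
    best = 0.0
    if s1 and s2:
        small, large = (s1, s2) if len(s1) <= len(s2) else (s2, s1)
        for perm in itertools.permutations(range(len(large)), len(small)):
            score = sum(_mci(small[i], large[j], taxa)
                        for i, j in enumerate(perm))
            best = max(best, score)
    return (h1 + h2 - 2 * best) / (h1 + h2)


def all_binary_topologies(labels):
    """All unrooted binary topologies over the labels, as newick strings."""
    from plastidkit.phylo import Node, PhyloTree

    def grow(trees, label):
        out = []
        for t in trees:
            edges = []

            def collect(n):
                for c in n.children:
                    edges.append((n, c))
                    collect(c)
            collect(t.root)
            for parent, child in edges:
                t2 = t.copy()
                # find matching edge in the copy by traversal order
                e2 = []

                def collect2(n):
                    for c in n.children:
                        e2.append((n, c))
                        collect2(c)
                collect2(t2.root)
                p2, c2 = e2[edges.index((parent, child))]
                mid = Node(children=[c2, Node(label=label)])
                p2.children[p2.children.index(c2)] = mid
                out.append(t2)
        return out

    from plastidkit.phylo import Node as N
    base = PhyloTree(N(children=[N(label=labels[0]), N(label=labels[1]),
                                 N(label=labels[2])]))
    trees = [base]
    for lab in labels[3:]:
        trees = grow(trees, lab)
    return [t.to_newick() for t in trees]
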