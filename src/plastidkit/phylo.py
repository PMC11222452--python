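"""Tree inference and tree comparison.

Covers the phylogenetic layer of the pipeline: pairwise distances
(p/JC69/K2P), neighbor joining, a compact GTR+Γ maximum-likelihood engine
(Felsenstein pruning over discrete-gamma rate categories, branch-length
optimisation and NNI hill climbing), nonparametric bootstrap with
majority-rule consensus, and tree-to-tree distances — the classic
Robinson–Foulds split count and a generalized Robinson–Foulds distance that
pairs splits by maximum-weight matching on their mutual clustering
information.

Trees are stored rooted for convenience but every comparison treats them as
unrooted; newick parsing is delegated to dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .genbank_io import PlastidKitError

NUC = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUC)}


class SaturationError(PlastidKitError):
    pass


# ---------------------------------------------------------------------------
# tree container
# ---------------------------------------------------------------------------

class Node:
    __slots__ = ("label", "children", "length", "support")

    def __init__(self, label=None, children=None, length=None, support=None):
        self.label = label
        self.children = children if children is not None else []
        self.length = length
        self.support = support

    def is_leaf(self):
        return not self.children


class PhyloTree:
    """Rooted storage of an unrooted tree; tip labels are unique strings."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction / io --------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: dendropy.Tree) -> "PhyloTree":
        def conv(dnode):
            n = Node(length=dnode.edge.length)
            if dnode.is_leaf():
                n.label = dnode.taxon.label if dnode.taxon else dnode.label
            else:
                if dnode.label is not None:
                    try:
                        n.support = float(dnode.label)
                    except ValueError:
                        n.label = dnode.label
                n.children = [conv(c) for c in dnode.child_nodes()]
            return n
        return cls(conv(dt.seed_node))

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf():
                s = n.label
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if include_support and n.support is not None:
                    s += format(n.support, "g")
            if n.length is not None:
                s += f":{n.length:.10g}"
            return s
        return fmt(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 taxon_namespace=taxon_namespace)

    # -- traversal ----------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def taxa(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "PhyloTree":
        def cp(n):
            m = Node(label=n.label, length=n.length, support=n.support)
            m.children = [cp(c) for c in n.children]
            return m
        return PhyloTree(cp(self.root))

    # -- topology edits -----------------------------------------------------
    def suppress_unifurcations(self) -> None:
        def walk(n: Node):
            new_children = []
            for c in n.children:
                walk(c)
                if not c.is_leaf() and len(c.children) == 1:
                    g = c.children[0]
                    if g.length is not None or c.length is not None:
                        g.length = (g.length or 0.0) + (c.length or 0.0)
                    new_children.append(g)
                else:
                    new_children.append(c)
            n.children = new_children
        walk(self.root)
        while not self.root.is_leaf() and len(self.root.children) == 1:
            self.root = self.root.children[0]
            self.root.length = None

    def prune_to(self, taxa) -> "PhyloTree":
        """Restriction of the (unrooted) tree to a taxon subset."""
        taxa = set(taxa)

        def keep(n: Node):
            if n.is_leaf():
                return n if n.label in taxa else None
            kids = [k for k in (keep(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                k = kids[0]
                if k.length is not None or n.length is not None:
                    k.length = (k.length or 0.0) + (n.length or 0.0)
                return k
            m = Node(label=n.label, length=n.length, support=n.support)
            m.children = kids
            return m

        pruned = keep(self.copy().root)
        if pruned is None:
            raise ValueError("no taxa left after pruning")
        t = PhyloTree(pruned)
        t.suppress_unifurcations()
        return t

    # -- splits -------------------------------------------------------------
    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the side that does
        not contain the lexicographically smallest taxon."""
        all_taxa = self.taxa()
        if len(all_taxa) < 4:
            return frozenset()
        anchor = min(all_taxa)
        out = set()

        def walk(n: Node) -> frozenset:
            if n.is_leaf():
                return frozenset([n.label])
            below = frozenset().union(*(walk(c) for c in n.children))
            side = all_taxa - below if anchor in below else below
            if 2 <= len(side) <= len(all_taxa) - 2:
                out.add(side)
            return below

        walk(self.root)
        return frozenset(out)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        out = {}

        def walk(n, d):
            d = d + (n.length or 0.0)
            if n.is_leaf():
                out[n.label] = d
            for c in n.children:
                walk(c, d)
        walk(self.root, -(self.root.length or 0.0))
        return out

    def scale(self, factor: float) -> "PhyloTree":
        t = self.copy()
        for n in t.postorder():
            if n.length is not None:
                n.length *= factor
        return t

    def rescale_to_unit_depth(self) -> "PhyloTree":
        depth = max(self.depths().values())
        if depth <= 0:
            raise ValueError("tree has zero depth")
        return self.scale(1.0 / depth)

    def collapse_short_edges(self, min_length: float) -> "PhyloTree":
        """Collapse internal edges shorter than ``min_length`` into
        polytomies: an edge supported by less than one substitution's worth
        of length carries no topological evidence."""
        t = self.copy()

        def walk(n: Node):
            kids = []
            for c in n.children:
                walk(c)
                if not c.is_leaf() and (c.length or 0.0) < min_length:
                    kids.extend(c.children)
                else:
                    kids.append(c)
            n.children = kids
        walk(t.root)
        return t


# ---------------------------------------------------------------------------
# distances between sequences
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray
    model: str = "JC69"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m


def encode_alignment(rows: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """uint8 matrix: A,C,G,T -> 0..3; gap/ambiguity -> 4 (missing)."""
    taxa = list(rows)
    lut = np.full(256, 4, dtype=np.uint8)
    for c, i in _NUC_INDEX.items():
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    mat = np.vstack([lut[np.frombuffer(rows[t].encode(), dtype=np.uint8)]
                     for t in taxa])
    return taxa, mat


def _k2p(p_ts: float, p_tv: float) -> float:
    w1 = 1.0 - 2.0 * p_ts - p_tv
    w2 = 1.0 - 2.0 * p_tv
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("K2P distance undefined (saturated)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def pairwise_distances(rows: dict[str, str], model: str = "JC69",
                       cap: float | None = None) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/ambiguous columns.

    Saturated pairs raise :class:`SaturationError` unless ``cap`` is given,
    in which case they are capped at that value.
    """
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences")
    taxa, mat = encode_alignment(rows)
    n = len(taxa)
    valid = mat < 4
    purine = (mat == 0) | (mat == 2)  # A or G
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nb = int(both.sum())
            if nb == 0:
                raise SaturationError(
                    f"no comparable sites between {taxa[i]} and {taxa[j]}")
            diff = mat[i, both] != mat[j, both]
            p = diff.sum() / nb
            if model == "p":
                dist = p
            elif model == "JC69":
                if p >= 0.75:
                    if cap is None:
                        raise SaturationError(
                            f"JC69 saturated for pair ({taxa[i]}, {taxa[j]}): "
                            f"p = {p:.3f}")
                    dist = cap
                else:
                    dist = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
            elif model == "K2P":
                ts = (diff & (purine[i, both] == purine[j, both])).sum() / nb
                tv = p - ts
                try:
                    dist = _k2p(ts, tv)
                except SaturationError:
                    if cap is None:
                        raise SaturationError(
                            f"K2P saturated for pair ({taxa[i]}, {taxa[j]})")
                    dist = cap
            else:
                raise ValueError(f"unknown model {model!r}")
            if cap is not None:
                dist = min(dist, cap)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=taxa, matrix=d, model=model)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining; deterministic (ties resolved by the
    smallest active index pair); negative branch lengths clamped to zero."""
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(label=t) for t in dm.taxa]
    d = dm.matrix.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        nodes[i].length = max(vi, 0.0)
        nodes[j].length = max(vj, 0.0)
        u = Node(children=[nodes[i], nodes[j]])
        d = np.pad(d, ((0, 1), (0, 1)))
        k_new = d.shape[0] - 1
        for kk in active:
            if kk in (i, j):
                continue
            d[k_new, kk] = d[kk, k_new] = 0.5 * (d[i, kk] + d[j, kk] - d[i, j])
        nodes.append(u)
        active = [x for x in active if x not in (i, j)] + [k_new]
    i, j, k = active
    nodes[i].length = max(0.5 * (d[i, j] + d[i, k] - d[j, k]), 0.0)
    nodes[j].length = max(0.5 * (d[i, j] + d[j, k] - d[i, k]), 0.0)
    nodes[k].length = max(0.5 * (d[i, k] + d[j, k] - d[i, j]), 0.0)
    root = Node(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# GTR + discrete-gamma likelihood
# ---------------------------------------------------------------------------

@dataclass
class GTRModel:
    """GTR exchangeabilities (AC, AG, AT, CG, CT, GT), stationary base
    frequencies, and a discrete-gamma shape; ``ncat=1`` disables rate
    heterogeneity."""

    exch: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    ncat: int = 4

    def __post_init__(self) -> None:
        self.exch = np.asarray(self.exch, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.exch <= 0):
            raise ValueError("exchangeabilities must be positive")
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.freqs <= 0):
            raise ValueError("base frequencies must be positive")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    @classmethod
    def jc(cls, ncat: int = 1, alpha: float = 1.0) -> "GTRModel":
        return cls(exch=np.ones(6), freqs=np.full(4, 0.25), alpha=alpha,
                   ncat=ncat)

    def rate_matrix(self) -> np.ndarray:
        """Q normalised to one expected substitution per unit time."""
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for r, (i, j) in zip(self.exch, idx):
            s[i, j] = s[j, i] = r
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.freqs, np.diag(q))
        return q / mu

    def eigensystem(self):
        q = self.rate_matrix()
        sq = np.sqrt(self.freqs)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        u = (1.0 / sq)[:, None] * v
        uinv = v.T * sq[None, :]
        return w, u, uinv

    def category_rates(self) -> np.ndarray:
        if self.ncat == 1:
            return np.ones(1)
        a = self.alpha
        edges = _gamma_dist.ppf(np.linspace(0, 1, self.ncat + 1), a=a,
                                scale=1.0 / a)
        cdf = gammainc(a + 1.0, a * edges)
        cdf[-1] = 1.0
        return self.ncat * np.diff(cdf)


def _transition_matrices(model: GTRModel, lengths: np.ndarray) -> np.ndarray:
    """P(t·r) for every (edge, category); shape (nedges, ncat, 4, 4)."""
    w, u, uinv = model.eigensystem()
    rates = model.category_rates()
    t = np.maximum(lengths, 0.0)[:, None] * rates[None, :]
    ew = np.exp(t[:, :, None] * w[None, None, :])
    p = np.einsum("ik,eck,kj->ecij", u, ew, uinv)
    return np.clip(p, 0.0, None)


def _index_tree(tree: PhyloTree):
    nodes = list(tree.postorder())
    order = {id(n): i for i, n in enumerate(nodes)}
    return nodes, order


def log_likelihood(tree: PhyloTree, rows: dict[str, str],
                   model: GTRModel) -> float:
    """Felsenstein pruning log-likelihood; gaps and ambiguity codes are
    treated as missing (partial likelihood 1 over all states)."""
    taxa, mat = encode_alignment(rows)
    pos = {t: i for i, t in enumerate(taxa)}
    for leaf in tree.leaves():
        if leaf.label not in pos:
            raise ValueError(f"tip {leaf.label!r} missing from alignment")
    patterns, weights = np.unique(mat, axis=1, return_counts=True)
    return _pruning_ll(tree, patterns, weights, pos, model)


def _pruning_ll(tree, patterns, weights, pos, model) -> float:
    nodes, _ = _index_tree(tree)
    nedge = len(nodes)
    lengths = np.array([n.length or 0.0 for n in nodes])
    P = _transition_matrices(model, lengths)
    ncat = model.ncat
    npat = patterns.shape[1]
    eye = np.vstack([np.eye(4), np.ones(4)])  # row 4 = missing
    partial = {}
    logscale = np.zeros((ncat, npat))
    for i, n in enumerate(nodes):
        if n.is_leaf():
            part = eye[patterns[pos[n.label]]]  # (npat, 4)
            part = np.broadcast_to(part, (ncat, npat, 4))
        else:
            part = np.ones((ncat, npat, 4))
            for c in n.children:
                j = id(c)
                child_part = partial.pop(j)
                ci = nodes.index(c)  # small trees; fine
                lifted = np.einsum("cij,cpj->cpi", P[ci], child_part)
                part = part * lifted
            mx = part.max(axis=2)
            mx = np.where(mx > 0, mx, 1.0)
            logscale += np.log(mx)
            part = part / mx[:, :, None]
        partial[id(n)] = part
    root_part = partial[id(tree.root)]
    site_l = np.einsum("j,cpj->cp", model.freqs, root_part)
    site_l = np.maximum(site_l, 1e-300)
    # average over categories in log space with per-category scaling
    m = logscale.max(axis=0)
    lsum = np.log(np.mean(np.exp(logscale - m[None, :]) * site_l, axis=0)) + m
    return float(np.dot(weights, lsum))


class _LikelihoodWorkspace:
    """Caches pattern compression for repeated evaluations on one alignment."""

    def __init__(self, rows: dict[str, str], model: GTRModel):
        taxa, mat = encode_alignment(rows)
        self.pos = {t: i for i, t in enumerate(taxa)}
        self.patterns, self.weights = np.unique(mat, axis=1,
                                                return_counts=True)
        self.model = model

    def ll(self, tree: PhyloTree) -> float:
        return _pruning_ll(tree, self.patterns, self.weights, self.pos,
                           self.model)


def _optimize_branch_lengths(tree, ws, rounds: int = 1):
    nodes = [n for n in tree.postorder() if n is not tree.root]
    for _ in range(rounds):
        for n in nodes:
            def f(x):
                old = n.length
                n.length = x
                val = -ws.ll(tree)
                n.length = old
                return val
            res = minimize_scalar(f, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": 1e-6})
            n.length = float(res.x)
    return ws.ll(tree)


def _optimize_alpha(tree, ws):
    def f(a):
        ws.model.alpha = float(a)
        return -ws.ll(tree)
    res = minimize_scalar(f, bounds=(0.05, 10.0), method="bounded",
                          options={"xatol": 1e-3})
    ws.model.alpha = float(res.x)
    return ws.ll(tree)


def _internal_edges(tree):
    out = []

    def walk(n):
        for c in n.children:
            if not c.is_leaf():
                out.append((n, c))
            walk(c)
    walk(tree.root)
    return out


def _nni_sweep(tree, ws, best_ll, tol):
    """One NNI pass; accepts improving moves, returns (tree, ll, improved)."""
    improved = False
    for u, v in _internal_edges(tree):
        siblings = [c for c in u.children if c is not v]
        if not siblings or len(v.children) != 2:
            continue
        c = siblings[0]
        a, b = v.children
        for swap_child in (a, b):
            iu, iv = u.children.index(c), v.children.index(swap_child)
            u.children[iu], v.children[iv] = swap_child, c
            cand_ll = ws.ll(tree)
            if cand_ll > best_ll + tol:
                # re-fit the focal edge length, keep the move
                def f(x):
                    old = v.length
                    v.length = x
                    val = -ws.ll(tree)
                    v.length = old
                    return val
                res = minimize_scalar(f, bounds=(1e-9, 10.0), method="bounded",
                                      options={"xatol": 1e-6})
                v.length = float(res.x)
                best_ll = ws.ll(tree)
                # topology changed: restart the sweep with fresh edges
                return best_ll, True
            u.children[iu], v.children[iv] = c, swap_child
    return best_ll, improved


def optimize_tree(rows: dict[str, str], model: GTRModel | None = None,
                  start: PhyloTree | None = None, tol: float = 1e-4,
                  max_rounds: int = 50, optimize_alpha: bool = True
                  ) -> tuple[PhyloTree, float, GTRModel]:
    """ML tree search: NJ start, then alternating branch-length optimisation
    and NNI sweeps until no move improves the log-likelihood by more than
    ``tol``.  Returns (tree, log-likelihood, fitted model)."""
    if model is None:
        model = empirical_model(rows)
    if len(rows) < 4:
        dm = pairwise_distances(rows, model="JC69", cap=5.0)
        t = nj_tree(dm)
        ws = _LikelihoodWorkspace(rows, model)
        ll = _optimize_branch_lengths(t, ws)
        return t, ll, model
    if start is None:
        dm = pairwise_distances(rows, model="JC69", cap=5.0)
        start = nj_tree(dm)
    tree = start.copy()
    ws = _LikelihoodWorkspace(rows, model)
    ll = _optimize_branch_lengths(tree, ws)
    if optimize_alpha and model.ncat > 1:
        ll = _optimize_alpha(tree, ws)
    for _ in range(max_rounds):
        ll, improved = _nni_sweep(tree, ws, ll, tol)
        ll = _optimize_branch_lengths(tree, ws)
        if optimize_alpha and model.ncat > 1:
            ll = _optimize_alpha(tree, ws)
        if not improved:
            break
    return tree, ll, ws.model


def empirical_model(rows: dict[str, str], alpha: float = 1.0,
                    ncat: int = 4) -> GTRModel:
    """GTR with empirical base frequencies and unit exchangeabilities."""
    _, mat = encode_alignment(rows)
    counts = np.array([(mat == i).sum() for i in range(4)], dtype=float)
    counts = np.maximum(counts, 1.0)
    return GTRModel(exch=np.ones(6), freqs=counts / counts.sum(),
                    alpha=alpha, ncat=ncat)


# ---------------------------------------------------------------------------
# bootstrap + consensus
# ---------------------------------------------------------------------------

def _infer(rows: dict[str, str], method: str, model: GTRModel | None):
    if method == "nj":
        return nj_tree(pairwise_distances(rows, model="JC69", cap=5.0))
    if method == "ml":
        tree, _, _ = optimize_tree(rows, model=model)
        return tree
    raise ValueError(f"unknown inference method {method!r}")


def majority_consensus(trees: list[PhyloTree], threshold: float = 0.5
                       ) -> PhyloTree:
    """Majority-rule consensus: keeps splits occurring in > threshold of the
    trees, annotated with percentage support."""
    if not trees:
        raise ValueError("no trees")
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must be in [0.5, 1)")
    taxa = trees[0].taxa()
    anchor = min(taxa)
    counts: dict[frozenset, int] = {}
    for t in trees:
        if t.taxa() != taxa:
            raise ValueError("consensus requires identical taxon sets")
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    b = len(trees)
    kept = [(s, c) for s, c in counts.items() if c / b > threshold]
    # splits kept at > 50% are pairwise compatible, so their anchor-free
    # sides form a laminar family; insert smallest-first into a star tree
    kept.sort(key=lambda sc: (len(sc[0]), sorted(sc[0])))
    root = Node(children=[Node(label=t) for t in sorted(taxa)])
    for side, c in kept:
        host = root
        descending = True
        while descending:
            descending = False
            for ch in host.children:
                if side < _leafset(ch):
                    host = ch
                    descending = True
                    break
        cover = [ch for ch in host.children if _leafset(ch) <= side]
        new = Node(children=cover, support=100.0 * c / b)
        host.children = [ch for ch in host.children
                         if ch not in cover] + [new]
    return PhyloTree(root)


def _leafset(n: Node) -> frozenset:
    return frozenset(x.label for x in PhyloTree(n).leaves())


def bootstrap_consensus(rows: dict[str, str], B: int = 1000,
                        threshold: float = 0.5, seed: int | None = None,
                        method: str = "nj", model: GTRModel | None = None
                        ) -> tuple[PhyloTree, list[PhyloTree]]:
    """Column bootstrap with majority-rule consensus; deterministic given
    ``seed``.  Returns (consensus tree with % supports, replicate trees)."""
    if B < 1:
        raise ValueError("need at least one replicate")
    taxa = list(rows)
    ncols = len(next(iter(rows.values())))
    rng = np.random.default_rng(seed)
    enc = {t: np.frombuffer(rows[t].encode(), dtype=np.uint8) for t in taxa}
    reps = []
    for _ in range(B):
        idx = rng.integers(0, ncols, size=ncols)
        boot = {t: enc[t][idx].tobytes().decode() for t in taxa}
        reps.append(_infer(boot, method, model))
    return majority_consensus(reps, threshold=threshold), reps


# ---------------------------------------------------------------------------
# tree distances
# ---------------------------------------------------------------------------

@dataclass
class TreeDistance:
    method: str
    raw: float
    normalized: float
    n_shared: int


def _common_splits(t1: PhyloTree, t2: PhyloTree):
    shared = t1.taxa() & t2.taxa()
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared tips")
    return t1.prune_to(shared).splits(), t2.prune_to(shared).splits(), shared


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> TreeDistance:
    """Robinson–Foulds: symmetric difference of non-trivial split sets on the
    shared tip set; normalized by |S1| + |S2| (0/0 -> 0)."""
    s1, s2, shared = _common_splits(t1, t2)
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return TreeDistance(method="rf", raw=float(raw),
                        normalized=raw / denom if denom else 0.0,
                        n_shared=len(shared))


def _split_entropy(side: frozenset, n: int) -> float:
    p = len(side) / n
    q = 1.0 - p
    h = 0.0
    for x in (p, q):
        if x > 0:
            h -= x * math.log2(x)
    return h


def _mutual_clustering_information(a: frozenset, b: frozenset,
                                   taxa: frozenset) -> float:
    n = len(taxa)
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = n - n11 - n10 - n01
    pa, pb = len(a) / n, len(b) / n
    total = 0.0
    for nij, pi, pj in ((n11, pa, pb), (n10, pa, 1 - pb),
                        (n01, 1 - pa, pb), (n00, 1 - pa, 1 - pb)):
        if nij > 0 and pi > 0 and pj > 0:
            pij = nij / n
            total += pij * math.log2(pij / (pi * pj))
    return max(total, 0.0)


def generalized_rf(t1: PhyloTree, t2: PhyloTree) -> TreeDistance:
    """Generalized Robinson–Foulds distance: splits paired by maximum-weight
    bipartite matching on mutual clustering information (bits); distance is
    1 − 2·score/(H1 + H2) where Hk sums the clustering entropies of tree k's
    splits.  Zero iff the (pruned) split sets are identical."""
    s1, s2, shared = _common_splits(t1, t2)
    n = len(shared)
    h1 = sum(_split_entropy(s, n) for s in s1)
    h2 = sum(_split_entropy(s, n) for s in s2)
    if h1 + h2 == 0:
        return TreeDistance(method="gen_rf_matching", raw=0.0, normalized=0.0,
                            n_shared=n)
    a_list, b_list = sorted(s1, key=sorted), sorted(s2, key=sorted)
    if a_list and b_list:
        w = np.zeros((len(a_list), len(b_list)))
        for i, a in enumerate(a_list):
            for j, b in enumerate(b_list):
                w[i, j] = _mutual_clustering_information(a, b, shared)
        ri, cj = linear_sum_assignment(-w)
        score = float(w[ri, cj].sum())
    else:
        score = 0.0
    raw = h1 + h2 - 2.0 * score
    if abs(raw) < 1e-12:  # identical split sets up to float residue
        raw = 0.0
    norm = raw / (h1 + h2)
    # numerical guard only; the matching bound keeps this in [0, 1]
    norm = min(max(norm, 0.0), 1.0)
    return TreeDistance(method="gen_rf_matching", raw=raw, normalized=norm,
                        n_shared=n)


def tree_distance(t1: PhyloTree, t2: PhyloTree,
                  method: str = "gen_rf_matching") -> TreeDistance:
    if method == "rf":
        return rf_distance(t1, t2)
    if method == "gen_rf_matching":
        return generalized_rf(t1, t2)
    raise ValueError(f"unknown method {method!r}")
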