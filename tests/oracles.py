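"""Independent reference implementations used only to check the package.

These deliberately avoid the algorithms under test: likelihoods and
posteriors come from explicit enumeration of every internal-node state
assignment (no pruning), the matrix exponential from a Taylor series with
scaling-and-squaring (no eigendecomposition), discrete-gamma category means
from numerical quadrature (no incomplete-gamma identity), and parsimony
minima from exhaustive enumeration of internal labellings (no dynamic
program).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from quatevol.phylo import MISSING, PhyloTree


def series_expm(Q: np.ndarray, t: float, terms: int = 30) -> np.ndarray:
    """exp(Qt) by Taylor series with scaling and squaring."""
    A = np.asarray(Q, float) * t
    s = max(0, int(np.ceil(np.log2(max(np.abs(A).max(), 1e-16)))) + 1)
    A = A / (2 ** s)
    P = np.eye(A.shape[0])
    term = np.eye(A.shape[0])
    for k in range(1, terms + 1):
        term = term @ A / k
        P = P + term
    for _ in range(s):
        P = P @ P
    return P


def gamma_category_means_quadrature(alpha: float, K: int) -> np.ndarray:
    """Mean of gamma(alpha, rate alpha) over each of K quantile bands."""
    edges = gamma_dist.ppf(np.arange(1, K) / K, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    means = []
    for a, b in zip(edges[:-1], edges[1:]):
        hi = b if np.isfinite(b) else gamma_dist.ppf(1 - 1e-12, a=alpha,
                                                     scale=1.0 / alpha)
        num, _ = quad(lambda x: x * gamma_dist.pdf(x, a=alpha, scale=1.0 / alpha),
                      a, hi, limit=200)
        means.append(num * K)
    return np.array(means)


def enumerate_likelihood_posteriors(tree: PhyloTree, leaf_data: np.ndarray,
                                    model, rates, chunk: int = 200_000):
    """Brute-force site likelihoods and internal-node posteriors.

    Sums the joint probability pi(root) * prod_branches P(parent, child)
    over *every* assignment of states to internal nodes, for every column
    and every rate category.  ``leaf_data`` is (n_leaves, n_columns) of
    state indices (MISSING for gap).

    Returns (site_likelihoods, posteriors) with posteriors a dict
    node -> (n_columns, 20) array.
    """
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    leaves = tree.leaf_indices()
    row = {node: r for r, node in enumerate(leaves)}
    pos = {node: r for r, node in enumerate(internal)}
    n_int = len(internal)
    C = leaf_data.shape[1]
    K = rates.K
    root = tree.root

    site_like = np.zeros(C)
    post = {node: np.zeros((C, 20)) for node in internal}

    # missing leaf entries contribute a factor of 1: drop them per column by
    # replacing P[s, MISSING] lookups with 1
    for k in range(K):
        P = {i: model.transition_matrix(float(rates.rates[k] * tree.branch_length[i]))
             for i in range(tree.n_nodes) if tree.parent[i] != -1}
        # augment leaf transition matrices with a "missing" column of ones
        P_leaf = {i: np.hstack([P[i], np.ones((20, 1))]) for i in leaves}

        combos = np.indices((20,) * n_int).reshape(n_int, -1)
        M = combos.shape[1]
        for start in range(0, M, chunk):
            sl = slice(start, min(start + chunk, M))
            states = combos[:, sl]
            w = model.pi[states[pos[root]]].astype(float)
            for node in internal:
                if tree.parent[node] != -1:
                    w = w * P[node][states[pos[tree.parent[node]]],
                                    states[pos[node]]]
            leafprod = np.ones((states.shape[1], C))
            for leaf in leaves:
                par = states[pos[tree.parent[leaf]]]
                leafprod *= P_leaf[leaf][par][:, leaf_data[row[leaf]].astype(int)]
            wlp = leafprod * w[:, None]
            site_like += wlp.sum(axis=0) / K
            for node in internal:
                onehot = np.eye(20)[states[pos[node]]]
                post[node] += (onehot.T @ wlp).T / K
    for node in internal:
        post[node] = post[node] / post[node].sum(axis=1, keepdims=True)
    return site_like, post


def exhaustive_parsimony_min(tree: PhyloTree, leaf_states: dict[int, int],
                             n_states: int) -> int:
    """Minimum change count over all internal-node labellings, by enumeration."""
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    best = None
    for combo in itertools.product(range(n_states), repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign.update(leaf_states)
        changes = sum(1 for i in range(tree.n_nodes)
                      if tree.parent[i] != -1
                      and assign[i] != assign[int(tree.parent[i])])
        if best is None or changes < best:
            best = changes
    return best


def tree_shapes(n_leaves: int, seed: int = 0) -> list[PhyloTree]:
    """All distinct rooted binary tree shapes with the given leaf count,
    with pseudo-random branch lengths."""
    rng = np.random.default_rng(seed)

    def shapes(n):
        if n == 1:
            return ["L"]
        out = []
        for a in range(1, n // 2 + 1):
            for left in shapes(a):
                for right in shapes(n - a):
                    if a == n - a and left > right:
                        continue
                    out.append(f"({left},{right})")
        return out

    trees = []
    for shape in shapes(n_leaves):
        counter = itertools.count(1)
        newick = ""
        for ch in shape:
            if ch == "L":
                newick += f"t{next(counter)}:{rng.uniform(0.05, 0.8):.4f}"
            elif ch in "(),":
                if ch == ")":
                    newick += f"):{rng.uniform(0.05, 0.8):.4f}"
                else:
                    newick += ch
        # strip the branch length on the root
        newick = newick.rsplit(":", 1)[0] + ";"
        trees.append(PhyloTree.from_newick(newick))
    return trees
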