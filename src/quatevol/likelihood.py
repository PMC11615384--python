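"""Felsenstein pruning likelihoods on a fixed tree.

The engine computes, per discrete-gamma rate category, "inside" (conditional)
partial likelihoods in a postorder sweep and "outside" partials in a preorder
sweep.  Per-site scaling factors guard against underflow on large trees.
Site likelihoods average the rate categories with equal prior weight 1/K;
marginal ancestral posteriors (see :mod:`quatevol.asr`) combine the two sweeps,
which implicitly weights categories by their per-site posterior probability
(empirical Bayes).

Gap and unknown ('X') characters are missing data: their leaf partials are
all ones, so an all-gap column contributes log(sum(pi)) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import GammaRates, SubstitutionModel
from .phylo import MISSING, MSA, PhyloTree, check_tree_msa_labels

_TINY = 1e-300


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods and their sum."""

    site: np.ndarray
    total: float


class PruningEngine:
    """Inside/outside partial likelihoods for one (tree, MSA, model) triple.

    Parameters
    ----------
    equal_category_weights :
        If True, ancestral posteriors weight rate categories by the uniform
        prior 1/K instead of their per-site posterior; exposed for
        sensitivity checks only — the joint inside*outside combination below
        already realizes empirical-Bayes weighting when False (default).
    """

    def __init__(self, tree: PhyloTree, msa: MSA, model: SubstitutionModel,
                 rates: GammaRates, equal_category_weights: bool = False):
        check_tree_msa_labels(tree, msa)
        self.tree = tree
        self.msa = msa
        self.model = model
        self.rates = rates
        self.equal_category_weights = equal_category_weights

        leaves = tree.leaf_indices()
        enc = msa.encode(order=[tree.labels[i] for i in leaves])
        self._leaf_row = {node: r for r, node in enumerate(leaves)}
        self._enc = enc
        self.L = msa.length
        self._run()

    # -- sweeps -----------------------------------------------------------

    def _leaf_partial(self, node: int) -> np.ndarray:
        x = self._enc[self._leaf_row[node]]
        F = np.zeros((self.L, 20))
        obs = x != MISSING
        F[np.arange(self.L)[obs], x[obs].astype(int)] = 1.0
        F[~obs, :] = 1.0
        return F

    def _run(self) -> None:
        tree, K, L = self.tree, self.rates.K, self.L
        n = tree.n_nodes
        pi = self.model.pi
        post = tree.postorder()

        # transition matrices per category per node (edge above the node)
        self._P = [[None] * n for _ in range(K)]
        for k, r in enumerate(self.rates.rates):
            for i in range(n):
                if tree.parent[i] != -1:
                    self._P[k][i] = self.model.transition_matrix(
                        float(r * tree.branch_length[i]))

        # inside partials F[k][node] (L, 20), edge messages G[k][node] (L, 20)
        # (message from node to its parent), per-site log scale ls[k][node]
        self._F = [[None] * n for _ in range(K)]
        self._G = [[None] * n for _ in range(K)]
        self._Fls = [[None] * n for _ in range(K)]
        cat_site_ll = np.empty((K, L))
        for k in range(K):
            for node in post:
                if tree.is_leaf(node):
                    F = self._leaf_partial(node)
                    ls = np.zeros(L)
                else:
                    F = np.ones((L, 20))
                    ls = np.zeros(L)
                    for c in tree.children[node]:
                        F = F * self._G[k][c]
                        ls = ls + self._Fls[k][c]
                    smax = np.maximum(F.max(axis=1), _TINY)
                    F = F / smax[:, None]
                    ls = ls + np.log(smax)
                self._F[k][node] = F
                self._Fls[k][node] = ls
                if tree.parent[node] != -1:
                    self._G[k][node] = F @ self._P[k][node].T
            root = tree.root
            site_like = np.maximum(self._F[k][root] @ pi, _TINY)
            cat_site_ll[k] = np.log(site_like) + self._Fls[k][root]

        # total: average categories in probability space per site
        m = cat_site_ll.max(axis=0)
        self._cat_site_ll = cat_site_ll
        self.site_log_likelihoods = m + np.log(
            np.exp(cat_site_ll - m[None, :]).mean(axis=0))
        self.total_log_likelihood = float(self.site_log_likelihoods.sum())

        # outside partials O[k][node]
        self._O = [[None] * n for _ in range(K)]
        self._Ols = [[None] * n for _ in range(K)]
        for k in range(K):
            root = tree.root
            self._O[k][root] = np.broadcast_to(pi, (L, 20)).copy()
            self._Ols[k][root] = np.zeros(L)
            for node in tree.preorder():
                for c in tree.children[node]:
                    M = self._O[k][node].copy()
                    ls = self._Ols[k][node].copy()
                    for sib in tree.children[node]:
                        if sib != c:
                            M = M * self._G[k][sib]
                            ls = ls + self._Fls[k][sib]
                    O = M @ self._P[k][c]
                    smax = np.maximum(O.max(axis=1), _TINY)
                    O = O / smax[:, None]
                    self._O[k][c] = O
                    self._Ols[k][c] = ls + np.log(smax)

    # -- queries ----------------------------------------------------------

    def node_posteriors(self, node: int) -> np.ndarray:
        """Marginal posterior P(state | data) at ``node``, shape (L, 20).

        Rate categories are weighted by their per-site posterior (the joint
        inside*outside terms carry the per-category site likelihoods), or
        uniformly if ``equal_category_weights`` was set.
        """
        K, L = self.rates.K, self.L
        joint = np.empty((K, L, 20))
        ls = np.empty((K, L))
        for k in range(K):
            joint[k] = self._F[k][node] * self._O[k][node]
            ls[k] = self._Fls[k][node] + self._Ols[k][node]
        if self.equal_category_weights:
            # normalize each category's joint to a per-category posterior first
            for k in range(K):
                joint[k] /= np.maximum(joint[k].sum(axis=1, keepdims=True), _TINY)
            post = joint.mean(axis=0)
        else:
            m = ls.max(axis=0)
            post = (joint * np.exp(ls - m[None, :])[:, :, None]).sum(axis=0)
        return post / post.sum(axis=1, keepdims=True)


def pruning_log_likelihood(tree: PhyloTree, msa: MSA, model: SubstitutionModel,
                           rates: GammaRates) -> SiteLikelihoods:
    """Per-site and total log-likelihood of ``msa`` on ``tree``."""
    eng = PruningEngine(tree, msa, model, rates)
    return SiteLikelihoods(site=eng.site_log_likelihoods,
                           total=eng.total_log_likelihood)
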