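"""Marginal ancestral sequence reconstruction and alternative ancestors.

Workflow: compute per-site posterior probabilities over the 20 amino acids at
internal nodes (empirical-Bayes marginal reconstruction), take the maximum
a-posteriori residue per site ("ML ancestor"), and optionally build the
"altAll" robustness ancestor that swaps in the second-most-probable residue
at every site where that alternative is itself plausible (posterior strictly
above a threshold, conventionally 0.2).  Gap structure is handled separately
by parsimony (:mod:`quatevol.parsimony`) and overlaid with
:func:`apply_gap_mask`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import PruningEngine
from .models import GammaRates, SubstitutionModel
from .phylo import AMINO_ACIDS, GAP, MSA, PhyloError, PhyloTree


@dataclass
class PosteriorTable:
    """Per-site amino-acid posterior probabilities at one node."""

    node: int
    probabilities: np.ndarray  # (L, 20), rows sum to 1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 20:
            raise PhyloError(f"posterior table must be (L, 20), got {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise PhyloError("posterior probabilities must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
            raise PhyloError("posterior probabilities must sum to 1 per site")
        self.probabilities = p

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (node, site, state, PP) table."""
        L = self.length
        return pd.DataFrame({
            "node": np.repeat(self.node, L * 20),
            "site": np.repeat(np.arange(L), 20),
            "state": list(AMINO_ACIDS) * L,
            "PP": self.probabilities.ravel(),
        })


@dataclass
class AncestralSequence:
    """A reconstructed sequence with per-site support.

    ``pp[i]`` is the posterior of the chosen residue at site i and is NaN at
    gap positions (no amino-acid posterior applies there).
    """

    node: int
    sequence: str
    pp: np.ndarray
    altered_sites: int | None = None
    gap_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.pp):
            raise PhyloError("sequence and PP vector lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


def marginal_posteriors(tree: PhyloTree, msa: MSA, model: SubstitutionModel,
                        rates: GammaRates, nodes: list[int] | None = None,
                        engine: PruningEngine | None = None,
                        equal_category_weights: bool = False,
                        ) -> dict[int, PosteriorTable]:
    """Marginal amino-acid posteriors at internal nodes.

    ``nodes`` defaults to all internal nodes.  Leaves are observed data, so
    requesting a leaf is an error.  Pass a prebuilt ``engine`` to reuse the
    pruning sweeps across calls.
    """
    if engine is None:
        engine = PruningEngine(tree, msa, model, rates,
                               equal_category_weights=equal_category_weights)
    if nodes is None:
        nodes = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    tables = {}
    for node in nodes:
        if tree.is_leaf(node):
            raise PhyloError(
                f"node {node} is a leaf; its sequence is observed, not inferred")
        tables[node] = PosteriorTable(node=node,
                                      probabilities=engine.node_posteriors(node))
    return tables


def ml_ancestor(post: PosteriorTable) -> AncestralSequence:
    """Maximum-a-posteriori residue per site.

    Exact ties resolve to the earlier state in the fixed alphabet order
    {alphabet} (np.argmax takes the first maximum).
    """
    idx = np.argmax(post.probabilities, axis=1)
    seq = "".join(AMINO_ACIDS[i] for i in idx)
    pp = post.probabilities[np.arange(post.length), idx]
    return AncestralSequence(node=post.node, sequence=seq, pp=pp)


ml_ancestor.__doc__ = ml_ancestor.__doc__.format(alphabet=AMINO_ACIDS)


def altall_ancestor(post: PosteriorTable, threshold: float = 0.2) -> AncestralSequence:
    """Alternative ancestor: second-best residue wherever it is plausible.

    At every site whose second-most-probable residue has posterior strictly
    greater than ``threshold``, that residue replaces the MAP residue; all
    other sites keep the MAP state.  The result is a "worst-case" ancestor
    concentrating all plausible alternative states in one sequence.
    ``threshold`` must lie in (0, 0.5] — above 0.5 no site could ever
    qualify, below/at 0 every site would.
    """
    if not (0.0 < threshold <= 0.5):
        raise PhyloError(f"altAll threshold must be in (0, 0.5], got {threshold}")
    p = post.probabilities
    order = np.argsort(-p, axis=1, kind="stable")
    best, second = order[:, 0], order[:, 1]
    second_pp = p[np.arange(post.length), second]
    use_second = second_pp > threshold
    idx = np.where(use_second, second, best)
    seq = "".join(AMINO_ACIDS[i] for i in idx)
    pp = p[np.arange(post.length), idx]
    return AncestralSequence(node=post.node, sequence=seq, pp=pp,
                             altered_sites=int(use_second.sum()))


def apply_gap_mask(seq: AncestralSequence, gap_states: np.ndarray) -> AncestralSequence:
    """Overlay parsimony gap states: 0 = gap, 1 = keep the residue."""
    gap_states = np.asarray(gap_states)
    if len(gap_states) != len(seq):
        raise PhyloError(
            f"gap mask length {len(gap_states)} != sequence length {len(seq)}")
    chars = [GAP if g == 0 else c for c, g in zip(seq.sequence, gap_states)]
    pp = np.where(gap_states == 0, np.nan, seq.pp)
    return AncestralSequence(node=seq.node, sequence="".join(chars), pp=pp,
                             altered_sites=seq.altered_sites,
                             gap_mask=gap_states.astype(np.int8))


@dataclass
class DivergenceReport:
    residue_differences: int
    gap_mismatches: int
    compared_sites: int


def sequence_divergence(a: AncestralSequence | str,
                        b: AncestralSequence | str) -> DivergenceReport:
    """Residue differences between two equal-length sequences.

    Counts sites where both sequences carry a residue and the residues
    differ; sites where exactly one is gapped are tallied separately as
    ``gap_mismatches`` and excluded from the residue count.
    """
    sa = a.sequence if isinstance(a, AncestralSequence) else a
    sb = b.sequence if isinstance(b, AncestralSequence) else b
    if len(sa) != len(sb):
        raise PhyloError(f"sequence lengths differ: {len(sa)} vs {len(sb)}")
    diff = gapmm = ncomp = 0
    for x, y in zip(sa, sb):
        xg, yg = x == GAP, y == GAP
        if xg != yg:
            gapmm += 1
        elif not xg:
            ncomp += 1
            if x != y:
                diff += 1
    return DivergenceReport(residue_differences=diff, gap_mismatches=gapmm,
                            compared_sites=ncomp)
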