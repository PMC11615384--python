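"""Phylogenetic trees and protein alignments.

Trees are stored in a flat array representation convenient for dynamic
programs (pruning, Fitch, Sankoff): nodes are indexed 0..n-1 in a fixed
postorder, each non-root node records its parent and branch length in
expected substitutions per site.  Newick I/O goes through dendropy, FASTA
I/O through Biopython.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
#: index used for gap / unknown characters in integer-encoded alignments
MISSING = 20


class PhyloError(ValueError):
    """Raised for malformed trees, alignments, or mismatched label sets."""


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths.

    Attributes
    ----------
    parent : array of int, ``parent[i]`` is the parent index of node *i*
        (-1 for the root).
    children : list of lists of child indices.
    branch_length : array of float, length to the parent (0.0 for root).
    labels : list of str or None; leaf labels are unique and non-empty,
        internal labels optional.
    """

    parent: np.ndarray
    children: list[list[int]]
    branch_length: np.ndarray
    labels: list[str | None]

    def __post_init__(self) -> None:
        n = len(self.parent)
        roots = [i for i in range(n) if self.parent[i] == -1]
        if len(roots) != 1:
            raise PhyloError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.branch_length < 0):
            raise PhyloError("branch lengths must be >= 0")
        leaves = self.leaf_indices()
        lab = [self.labels[i] for i in leaves]
        if any(not x for x in lab):
            raise PhyloError("every leaf needs a non-empty label")
        if len(set(lab)) != len(lab):
            raise PhyloError("leaf labels must be unique")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices()]

    def postorder(self) -> list[int]:
        """Children-before-parents node ordering (iterative, no recursion)."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def node_by_label(self, label: str) -> int:
        for i, lab in enumerate(self.labels):
            if lab == label:
                return i
        raise PhyloError(f"no node labelled {label!r}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        """Parse a Newick string.

        Unrooted (trifurcating-root) trees are accepted as-is: the basal
        trifurcation simply becomes a multifurcating root.  Under a
        reversible model the likelihood does not depend on this choice.
        """
        try:
            dt = dendropy.Tree.get(data=newick, schema="newick",
                                   suppress_internal_node_taxa=False)
        except Exception as exc:
            raise PhyloError(f"could not parse Newick: {exc}") from exc
        nodes = list(dt.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        blen = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        labels: list[str | None] = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        return cls(parent=parent, children=children, branch_length=blen, labels=labels)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.is_leaf(i):
                s = self.labels[i]
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    s += self.labels[i]
            if self.parent[i] != -1:
                s += f":{self.branch_length[i]:.10g}"
            return s

        return render(self.root) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def reroot_on_edge(self, node: int, fraction: float = 0.5) -> "PhyloTree":
        """Return a new tree rooted on the edge above ``node``.

        Splits the branch at ``fraction`` of its length (measured from the
        child side); used to verify likelihood invariance to root placement
        under reversible models.
        """
        if self.parent[node] == -1:
            raise PhyloError("cannot reroot on the root's (non-existent) edge")
        n = self.n_nodes
        new_root = n
        parent = np.append(self.parent.copy(), -1)
        blen = np.append(self.branch_length.copy(), 0.0)
        labels = self.labels + [None]
        # sever node from its parent; hang node and the "rest of the tree"
        # from the new root, reversing parent pointers up to the old root
        old_parent = int(self.parent[node])
        b = float(self.branch_length[node])
        parent[node] = new_root
        blen[node] = b * fraction
        # reverse the chain old_parent -> ... -> old root
        prev = new_root
        prev_len = b * (1.0 - fraction)
        cur = old_parent
        while cur != -1:
            nxt = int(self.parent[cur])
            nxt_len = float(self.branch_length[cur])
            parent[cur] = prev
            blen[cur] = prev_len
            prev, prev_len, cur = cur, nxt_len, nxt
        children: list[list[int]] = [[] for _ in range(n + 1)]
        for i in range(n + 1):
            if parent[i] != -1:
                children[parent[i]].append(i)
        tree = PhyloTree(parent=parent, children=children,
                         branch_length=blen, labels=labels)
        return _suppress_unifurcations(tree)


def _suppress_unifurcations(tree: PhyloTree) -> PhyloTree:
    """Remove internal nodes with a single child (merging branch lengths)."""
    keep = [i for i in range(tree.n_nodes)
            if tree.is_leaf(i) or len(tree.children[i]) > 1 or tree.parent[i] == -1]
    # the old root may itself be unifurcating after rerooting; walk children
    # through removed nodes
    parent = tree.parent.copy()
    blen = tree.branch_length.copy()
    removed = set(range(tree.n_nodes)) - set(keep)
    for i in range(tree.n_nodes):
        p = parent[i]
        extra = 0.0
        while p in removed:
            extra += blen[p]
            p = parent[p]
        if p != parent[i]:
            parent[i] = p
            blen[i] = blen[i] + extra
    # drop removed single-child roots too: find nodes reachable and reindex
    remap = {old: new for new, old in enumerate(keep)}
    new_parent = np.array([remap.get(int(parent[i]), -1) for i in keep])
    new_blen = np.array([blen[i] for i in keep])
    new_labels = [tree.labels[i] for i in keep]
    children: list[list[int]] = [[] for _ in keep]
    for i, p in enumerate(new_parent):
        if p != -1:
            children[p].append(i)
    return PhyloTree(parent=new_parent, children=children,
                     branch_length=new_blen, labels=new_labels)


@dataclass
class MSA:
    """Protein multiple sequence alignment over the 20 amino acids plus '-'."""

    labels: list[str]
    sequences: list[str]
    _length: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise PhyloError("alignment is empty")
        lens = {len(s) for s in self.sequences}
        if len(lens) != 1:
            raise PhyloError("sequences differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise PhyloError("alignment labels must be unique")
        self._length = lens.pop()
        valid = set(AMINO_ACIDS + GAP + "X")
        for lab, seq in zip(self.labels, self.sequences):
            bad = set(seq.upper()) - valid
            if bad:
                raise PhyloError(f"sequence {lab!r} has invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return self._length

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    def encode(self, order: list[str] | None = None) -> np.ndarray:
        """Integer-encode: (n_sequences, length); gaps and 'X' map to MISSING."""
        labels = order if order is not None else self.labels
        seqs = dict(zip(self.labels, self.sequences))
        out = np.full((len(labels), self.length), MISSING, dtype=np.int8)
        for r, lab in enumerate(labels):
            for c, ch in enumerate(seqs[lab].upper()):
                out[r, c] = AA_INDEX.get(ch, MISSING)
        return out

    def binary_matrix(self, order: list[str] | None = None) -> np.ndarray:
        """Presence/absence matrix: 1 = residue, 0 = gap (or unknown)."""
        enc = self.encode(order)
        return (enc != MISSING).astype(np.int8)

    def empirical_frequencies(self, pseudocount: float = 0.0) -> np.ndarray:
        enc = self.encode()
        counts = np.bincount(enc[enc != MISSING].astype(int), minlength=20) + pseudocount
        return counts / counts.sum()

    @classmethod
    def from_fasta(cls, source) -> "MSA":
        if isinstance(source, str) and "\n" in source:
            handle = io.StringIO(source)
        else:
            handle = open(source)
        try:
            records = list(SeqIO.parse(handle, "fasta"))
        finally:
            handle.close()
        return cls(labels=[r.id for r in records],
                   sequences=[str(r.seq).upper() for r in records])

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=lab, description="")
                   for lab, s in zip(self.labels, self.sequences)]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


def check_tree_msa_labels(tree: PhyloTree, msa: MSA) -> None:
    """Tree leaf labels and alignment labels must coincide exactly."""
    t, m = set(tree.leaf_labels()), set(msa.labels)
    if t != m:
        missing = sorted(t - m)[:5]
        extra = sorted(m - t)[:5]
        raise PhyloError(
            f"tree/alignment label mismatch (tree-only: {missing}, msa-only: {extra})")
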