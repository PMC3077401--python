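"""Phylogenetic position-mixing signature.

Without domain movement, TRD1 sequences and TRD2 sequences of a locus fall
into two clean clades; with movement they mix. The statistic is the minimum
number of position-state changes on a neighbor-joining tree of the TRD
instances (small parsimony with states = slot indices): a score of 1 means
the positions are perfectly separated, a score >= 2 means mixing.

Distances are 1 - global-alignment identity; trees are neighbor joining
(consistent on additive matrices, deterministic after canonical taxon
ordering). Parsimony uses Hartigan's algorithm, exact for trees of
arbitrary degree — NJ trees come with a trifurcating root.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import Sequence

from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .clustering import pairwise_identity
from .model import TRDInstance


@dataclass
class LabeledTree:
    """An unrooted tree over TRD instances with per-leaf position indices.

    Leaf names follow ``<seq_id>|pos<k>``.
    """

    tree: TreeNode
    positions: dict[str, int]  # leaf name -> position index

    def to_newick(self) -> str:
        out = StringIO()
        self.tree.write(out, format="newick")
        return out.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "LabeledTree":
        tree = TreeNode.read(StringIO(newick), format="newick")
        positions = {}
        for leaf in tree.tips():
            name = leaf.name
            if name is None or "|pos" not in name:
                raise ValueError(f"leaf {name!r} lacks a |pos<k> annotation")
            positions[name] = int(name.rsplit("|pos", 1)[1])
        return cls(tree, positions)


def leaf_name(instance: TRDInstance) -> str:
    return f"{instance.seq_id}|pos{instance.position_index}"


def build_nj_tree(instances: Sequence[TRDInstance]) -> LabeledTree:
    """Neighbor-joining tree on d = 1 - pairwise_identity.

    Requires >= 3 instances; taxa are canonically sorted so the result does
    not depend on input order. Negative NJ branch-length estimates are
    clamped to zero.
    """
    if len(instances) < 3:
        raise ValueError("neighbor joining requires at least 3 instances")
    inst = sorted(instances, key=lambda t: (t.seq_id, t.position_index))
    names = [leaf_name(t) for t in inst]
    if len(set(names)) != len(names):
        raise ValueError("duplicate (seq_id, position) instances")
    n = len(inst)
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(inst[i].sequence, inst[j].sequence)
            dm[i][j] = dm[j][i] = d
    tree = nj(DistanceMatrix(dm, names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return LabeledTree(tree, {leaf_name(t): t.position_index for t in inst})


def collapse_zero_branches(tree: TreeNode, eps: float = 1e-8) -> TreeNode:
    """Collapse internal branches of length <= eps into polytomies.

    Distance data cannot order splits along a zero-length branch, so any
    binary resolution there is an artifact of the NJ agglomeration order;
    the polytomy is the faithful representation. Returns a new tree.
    """
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.traverse()):
            if node.is_tip() or node.parent is None:
                continue
            if node.length is not None and node.length <= eps:
                parent = node.parent
                parent.remove(node)
                parent.extend(node.children)
                changed = True
    return tree


def position_mixing_score(tree: LabeledTree) -> int:
    """Minimum number of position-state changes on the tree (Hartigan).

    1 means TRD1 and TRD2 instances are perfectly separated (the
    no-movement signature); >= 2 means the positions mix. Zero-length
    internal branches are collapsed into polytomies before scoring (their
    binary resolution is arbitrary and carries no signal); Hartigan's
    small-parsimony algorithm is exact for arbitrary node degrees. Raises
    when fewer than two distinct positions are present (the score is
    undefined).
    """
    states = set(tree.positions.values())
    if len(states) < 2:
        raise ValueError("mixing score undefined with a single position present")
    tree = LabeledTree(collapse_zero_branches(tree.tree), tree.positions)

    def hartigan(node) -> tuple[set, int]:
        if node.is_tip():
            return {tree.positions[node.name]}, 0
        votes: dict[int, int] = {}
        changes = 0
        for child in node.children:
            child_set, child_changes = hartigan(child)
            changes += child_changes
            for s in child_set:
                votes[s] = votes.get(s, 0) + 1
        k = max(votes.values())
        top = {s for s, v in votes.items() if v == k}
        return top, changes + (len(node.children) - k)

    _, changes = hartigan(tree.tree)
    return changes
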