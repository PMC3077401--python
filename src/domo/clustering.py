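"""Homology labelling of TRD instances across alleles and loci.

Natural TRD repertoires are highly diverse (well under the clustering
threshold pairwise), while a domain that has *moved* between the TRD1 and
TRD2 slots is a near-verbatim copy. Single-linkage clustering of global
alignment identity at a 0.8 nucleotide threshold therefore separates
"same domain, possibly moved" from "different domain". Labels are the
field's customary lower-case letters a, b, c, ...
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .model import DomainCluster, GeneArchitecture, TRDInstance, domain_label

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -0.5


@lru_cache(maxsize=200_000)
def _identity_cached(a: str, b: str) -> float:
    aln = next(iter(_aligner.align(a, b)))
    counts = aln.counts()
    length = aln.shape[1]
    return counts.identities / length


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -0.5 (a gap of
    length L costs 2 + 0.5(L-1)); identity = matches / alignment length
    including gap columns. Symmetric by construction: the lexicographically
    sorted pair is aligned.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if seq_a == seq_b:
        return 1.0
    a, b = sorted((seq_a, seq_b))
    return _identity_cached(a, b)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_trds(
    instances: Sequence[TRDInstance], threshold: float = 0.8
) -> list[DomainCluster]:
    """Single-linkage clusters over the identity >= ``threshold`` graph.

    Output is canonical: instances are ordered by (seq_id, position_index)
    and clusters labelled 'a', 'b', ... in order of first appearance, so the
    labelling is invariant to input permutation. Identical sequences are
    deduplicated before alignment (single-linkage makes one representative
    per distinct sequence sufficient).
    """
    if not instances:
        raise ValueError("cluster_trds requires at least one instance")
    inst = sorted(instances, key=lambda t: (t.seq_id, t.position_index))
    distinct: dict[str, int] = {}
    seq_of: list[str] = []
    for t in inst:
        if t.sequence not in distinct:
            distinct[t.sequence] = len(seq_of)
            seq_of.append(t.sequence)
    uf = _UnionFind(len(seq_of))
    for i in range(len(seq_of)):
        for j in range(i + 1, len(seq_of)):
            if pairwise_identity(seq_of[i], seq_of[j]) >= threshold:
                uf.union(i, j)
    clusters: dict[int, list[TRDInstance]] = {}
    order: list[int] = []
    for t in inst:
        root = uf.find(distinct[t.sequence])
        if root not in clusters:
            clusters[root] = []
            order.append(root)
        clusters[root].append(t)
    return [
        DomainCluster(
            label=domain_label(i),
            members=clusters[root],
            representative=clusters[root][0].sequence,
        )
        for i, root in enumerate(order)
    ]


def clustering_diagnostic(clusters: Sequence[DomainCluster]) -> dict:
    """Min intra-cluster vs max inter-cluster identity (chaining monitor)."""
    min_intra: Optional[float] = None
    max_inter: Optional[float] = None
    for i, ci in enumerate(clusters):
        seqs_i = {m.sequence for m in ci.members}
        for a in seqs_i:
            for b in seqs_i:
                if a < b:
                    ident = pairwise_identity(a, b)
                    min_intra = ident if min_intra is None else min(min_intra, ident)
        for cj in clusters[i + 1 :]:
            for a in seqs_i:
                for b in {m.sequence for m in cj.members}:
                    ident = pairwise_identity(a, b)
                    max_inter = ident if max_inter is None else max(max_inter, ident)
    return {"min_intra_identity": min_intra, "max_inter_identity": max_inter}


def label_of(clusters: Sequence[DomainCluster]) -> dict[tuple[str, int], str]:
    mapping: dict[tuple[str, int], str] = {}
    for cluster in clusters:
        for member in cluster.members:
            mapping[member.key] = cluster.label
    return mapping


def label_position_matrix(
    clusters: Sequence[DomainCluster],
    architectures: Sequence[GeneArchitecture],
    loci: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Complete (seq_id, locus) x position_index label table; '—' = no slot."""
    mapping = label_of(clusters)
    loci = loci or {}
    max_pos = max((a.n_trds for a in architectures), default=0)
    rows = []
    index = []
    for arch in sorted(architectures, key=lambda a: a.seq_id):
        row = {}
        for pos in range(1, max_pos + 1):
            if pos <= arch.n_trds:
                key = (arch.seq_id, pos)
                if key not in mapping:
                    raise ValueError(f"TRD instance {key} missing from clusters")
                row[pos] = mapping[key]
            else:
                row[pos] = "—"
        rows.append(row)
        index.append((arch.seq_id, loci.get(arch.seq_id, "NA")))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["seq_id", "locus"])
    )
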