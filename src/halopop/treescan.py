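"""Gene-tree survey: alignment filtering, distances, NJ, and consensus.

Discordance among gene genealogies sampled across a genome is a
classical signature of recombination: under strict clonality every
locus shares one genealogy, whereas recombination decouples them.  This
module filters per-gene nucleotide alignments, builds distance-based
neighbor-joining trees, extracts unrooted bipartitions, and computes a
majority-rule consensus whose number of majority splits is the
concordance statistic of interest (few majority splits = discordant
gene trees = recombination).

Tree inference here is deliberately distance-based (raw, JC69 or K2P
distances + neighbor joining with deterministic tie-breaking): the
concordance statistic consumes topologies and is agnostic to the tree
builder, which is pluggable.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import dendropy

from .variants import DistanceMatrix

_NUC = frozenset(b"ACGT")


class SaturatedDistanceError(ValueError):
    """A model-corrected distance is undefined (log argument <= 0)."""


@dataclasses.dataclass
class GeneAlignment:
    """An equal-length nucleotide alignment for one gene.

    Sequences may contain A, C, G, T, N and '-'; only columns where
    both members of a pair have an unambiguous base (A/C/G/T) enter
    pairwise difference counts and distances.
    """

    gene_id: str
    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("one sequence per sample id required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths in {self.gene_id}: {lengths}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def _byte_matrix(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(len(self.sequences), -1)

    @property
    def mean_pairwise_diff(self) -> float:
        """Average number of differing columns over all sequence pairs.

        A column counts for a pair only when both bases are A/C/G/T.
        """
        n = len(self.sequences)
        if n < 2 or self.length == 0:
            return 0.0
        mat = self._byte_matrix()
        ok = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
        total = 0
        for i, j in itertools.combinations(range(n), 2):
            both = ok[i] & ok[j]
            total += int(np.sum(both & (mat[i] != mat[j])))
        return total / (n * (n - 1) / 2)


def filter_alignment(
    aln: GeneAlignment, min_length: int = 200, min_mean_diff: float = 15.0
) -> bool:
    """Keep an alignment for tree building?

    True iff the alignment is strictly longer than `min_length`
    nucleotides AND its average pairwise difference count is strictly
    larger than `min_mean_diff`.  Both inequalities are strict, so an
    alignment of exactly 200 columns or exactly 15.0 mean differences
    is rejected.
    """
    return aln.length > min_length and aln.mean_pairwise_diff > min_mean_diff


def distance_matrix(aln: GeneAlignment, model: str = "K2P") -> DistanceMatrix:
    """Pairwise substitution distances from an alignment.

    model 'raw' = mismatch proportion p; 'JC69' = -(3/4) ln(1 - 4p/3);
    'K2P' corrects separately for transitions (P) and transversions (Q):
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).  Columns with a gap,
    N, or other ambiguity in either sequence are excluded pairwise.
    Saturated pairs (log argument <= 0) raise
    :class:`SaturatedDistanceError` naming the pair.
    """
    model = model.upper()
    if model not in {"RAW", "JC69", "K2P"}:
        raise ValueError(f"unknown model {model!r}")
    n = len(aln.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 sequences")
    mat = aln._byte_matrix()
    ok = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    purine = (mat == ord("A")) | (mat == ord("G"))
    d = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=np.int64)
    for i, j in itertools.combinations(range(n), 2):
        both = ok[i] & ok[j]
        m = int(both.sum())
        nc[i, j] = nc[j, i] = m
        if m == 0:
            raise SaturatedDistanceError(
                f"no comparable columns between {aln.sample_ids[i]} "
                f"and {aln.sample_ids[j]}"
            )
        mism = both & (mat[i] != mat[j])
        p = mism.sum() / m
        if model == "RAW":
            dist = p
        elif model == "JC69":
            arg = 1 - 4 * p / 3
            if arg <= 0:
                raise SaturatedDistanceError(
                    f"JC69 saturated for pair {aln.sample_ids[i]},"
                    f" {aln.sample_ids[j]} (p={p:.3f})"
                )
            dist = -0.75 * math.log(arg)
        else:  # K2P
            transition = mism & (purine[i] == purine[j])
            P = transition.sum() / m
            Q = p - P
            a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
            if a1 <= 0 or a2 <= 0:
                raise SaturatedDistanceError(
                    f"K2P saturated for pair {aln.sample_ids[i]},"
                    f" {aln.sample_ids[j]} (P={P:.3f}, Q={Q:.3f})"
                )
            dist = -0.5 * math.log(a1) - 0.25 * math.log(a2)
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.sample_ids), d, nc)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dist: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree with deterministic tie-breaking.

    Standard Saitou–Nei agglomeration; when several pairs minimize the
    Q criterion the lowest-index pair (row-major scan order over the
    current node list) is joined, so identical input always yields an
    identical tree.  Negative branch lengths are clamped to zero.  The
    result is an unrooted tree represented with a trifurcating seed
    node (for >= 4 taxa).
    """
    labels = list(dist.sample_ids)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.asarray(dist.d, dtype=float).copy()
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(nd)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best  # type: ignore[misc]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        new = dendropy.Node()
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        nd_ = np.zeros((m - 1, m - 1))
        nd_[:-1, :-1] = d[np.ix_(keep, keep)]
        nd_[-1, :-1] = nd_[:-1, -1] = dk[keep]
        d = nd_
        nodes = [nodes[x] for x in keep] + [new]

    root = dendropy.Node()
    if len(nodes) == 3:
        # three-point formulas for the final join
        l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for nd, ln in zip(nodes, (l0, l1, l2)):
            nd.edge.length = max(ln, 0.0)
            root.add_child(nd)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and consensus
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial unrooted bipartitions (splits) of a tree.

    Each internal edge induces a two-set split of the leaf labels; the
    canonical representative is the side NOT containing the
    lexicographically smallest leaf label.  Trivial splits (one leaf on
    a side) are omitted; a star tree yields the empty set.
    """
    labels = _leaf_labels(tree)
    all_set = frozenset(labels)
    ref = labels[0]
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = frozenset([nd.taxon.label])
        else:
            below[id(nd)] = frozenset().union(
                *(below[id(ch)] for ch in nd.child_nodes())
            )
    for nd in tree.postorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        side = below[id(nd)]
        if len(side) < 2 or len(side) > len(all_set) - 2:
            continue
        canon = side if ref not in side else all_set - side
        splits.add(canon)
    return splits


def splits_compatible(s1: frozenset, s2: frozenset, all_taxa: frozenset) -> bool:
    """True iff the two splits can coexist on one tree."""
    c1, c2 = all_taxa - s1, all_taxa - s2
    return (
        not (s1 & s2) or not (s1 & c2) or not (c1 & s2) or not (c1 & c2)
    )


def topology_key(tree: dendropy.Tree) -> frozenset:
    """Hashable unrooted-topology identifier (the set of splits)."""
    return frozenset(bipartitions(tree))


@dataclasses.dataclass
class ConsensusResult:
    """Split frequencies and the majority-rule consensus tree."""

    split_frequencies: dict[frozenset, float]
    majority_splits: set[frozenset]
    consensus_tree: dendropy.Tree
    n_trees: int

    @property
    def n_majority_splits(self) -> int:
        return len(self.majority_splits)


def majority_consensus(
    trees: Sequence[dendropy.Tree], threshold: float = 0.5
) -> ConsensusResult:
    """Majority-rule consensus over a set of trees on one leaf set.

    Tallies each nontrivial bipartition's frequency over trees (each
    tree contributes each of its splits once); majority splits are
    those with frequency strictly greater than `threshold`.  For
    threshold >= 0.5 the majority splits are mutually compatible and
    assemble into a unique consensus tree containing exactly those
    splits.  The number of majority splits is the gene-tree concordance
    count: of the n-3 possible resolved internal edges, how many are
    supported by more than half of the gene trees.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 does not guarantee compatibility")
    leafsets = [_leaf_labels(t) for t in trees]
    for k, ls in enumerate(leafsets[1:], start=1):
        if ls != leafsets[0]:
            raise ValueError(f"tree {k} has a different leaf set than tree 0")
    labels = leafsets[0]
    all_set = frozenset(labels)
    tally: dict[frozenset, int] = {}
    for t in trees:
        for sp in bipartitions(t):
            tally[sp] = tally.get(sp, 0) + 1
    n = len(trees)
    freqs = {sp: c / n for sp, c in tally.items()}
    majority = {sp for sp, f in freqs.items() if f > threshold}

    # assemble the consensus: treat each split as the clade not containing
    # the reference leaf, insert largest-first into a star tree
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = dendropy.Node()
    leaf_nodes = {}
    for lab in labels:
        nd = dendropy.Node(taxon=tns.get_taxon(lab))
        root.add_child(nd)
        leaf_nodes[lab] = nd
    clade_of: dict[int, frozenset] = {id(root): all_set}
    for lab, nd in leaf_nodes.items():
        clade_of[id(nd)] = frozenset([lab])
    for sp in sorted(majority, key=lambda s: (-len(s), sorted(s))):
        # find the smallest existing clade containing sp
        host = root
        changed = True
        while changed:
            changed = False
            for ch in host.child_nodes():
                if sp < clade_of[id(ch)]:
                    host = ch
                    changed = True
                    break
        new = dendropy.Node()
        movers = [ch for ch in host.child_nodes() if clade_of[id(ch)] <= sp]
        for ch in movers:
            host.remove_child(ch)
            new.add_child(ch)
        host.add_child(new)
        clade_of[id(new)] = sp
        new.label = f"{freqs[sp]:.3f}"
    tree.seed_node = root
    tree.is_rooted = False
    return ConsensusResult(
        split_frequencies=freqs,
        majority_splits=majority,
        consensus_tree=tree,
        n_trees=n,
    )


# ---------------------------------------------------------------------------
# FASTA I/O helpers
# ---------------------------------------------------------------------------

def read_alignment(path: str, gene_id: str | None = None) -> GeneAlignment:
    """Read one aligned FASTA file into a GeneAlignment."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no sequences in {path}")
    import os

    return GeneAlignment(
        gene_id=gene_id or os.path.splitext(os.path.basename(str(path)))[0],
        sample_ids=ids,
        sequences=seqs,
    )


def gene_tree_survey(
    alignments: Iterable[GeneAlignment],
    model: str = "K2P",
    min_length: int = 200,
    min_mean_diff: float = 15.0,
    consensus_threshold: float = 0.5,
) -> tuple[list[dendropy.Tree], ConsensusResult | None]:
    """Filter alignments, build one NJ tree per retained gene, and
    compute the majority-rule consensus.

    Returns (trees, consensus); consensus is None when fewer than two
    alignments survive the filter.
    """
    trees = []
    for aln in alignments:
        if not filter_alignment(aln, min_length, min_mean_diff):
            continue
        trees.append(nj_tree(distance_matrix(aln, model=model)))
    if len(trees) < 2:
        return trees, None
    return trees, majority_consensus(trees, threshold=consensus_threshold)
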