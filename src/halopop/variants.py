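"""Haploid genotype data model and variant-based population statistics.

This module houses the substrate of all SNP-based analyses: a samples ×
loci matrix of haploid calls read from VCF, pairwise SNP distances
("bitwise" mismatch counts between haploid genomes), single-linkage
clonal-cluster detection, a minimum spanning network over clonal
lineages, SNP density, and core/soft-core gene counting from a
presence/absence table.

Coordinates are 1-based inclusive throughout (VCF convention). Missing
calls are encoded as -1 in the call matrix.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import networkx as nx
import pysam
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

MISSING = -1


class VCFFormatError(ValueError):
    """Malformed or out-of-contract VCF input (duplicates, bad records)."""


class PloidyError(VCFFormatError):
    """A genotype call was not haploid."""


class Locus(NamedTuple):
    """One SNP locus: contig name, 1-based position, REF and ALT alleles."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]


@dataclasses.dataclass
class GenotypeMatrix:
    """Haploid calls for a set of samples at a set of SNP loci.

    calls[i, j] is the allele index of sample i at locus j: 0 = REF,
    k = k-th ALT, -1 = missing. Loci are sorted by (contig, pos) and
    unique. `contigs` optionally records (name, length) pairs so that
    VCF headers and genome-wide densities can be reconstructed.
    """

    sample_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    contigs: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        n_s, n_l = len(self.sample_ids), len(self.loci)
        if self.calls.shape != (n_s, n_l):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_s} samples x {n_l} loci"
            )
        keys = [(l.contig, l.pos) for l in self.loci]
        if sorted(keys) != keys:
            raise ValueError("loci must be sorted by (contig, pos)")
        if len(set(keys)) != len(keys):
            raise VCFFormatError("duplicate (contig, pos) among loci")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def total_genome_length(self) -> int:
        if not self.contigs:
            raise ValueError("no contig lengths recorded on this matrix")
        return sum(length for _, length in self.contigs)

    def subset_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=[self.loci[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            contigs=list(self.contigs) if self.contigs else None,
        )


@dataclasses.dataclass
class DistanceMatrix:
    """Pairwise distances between samples.

    For SNP data, d[i, j] counts loci where both calls are non-missing
    and differ, and n_compared[i, j] counts loci where both are
    non-missing.  The same container carries substitution-model
    distances (floats) for gene alignments.
    """

    sample_ids: list[str]
    d: np.ndarray
    n_compared: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d)
        self.n_compared = np.asarray(self.n_compared)
        n = len(self.sample_ids)
        if self.d.shape != (n, n) or self.n_compared.shape != (n, n):
            raise ValueError("distance matrices must be n_samples x n_samples")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclasses.dataclass
class ClonalClusters:
    """Single-linkage partition of samples at a SNP-difference cutoff."""

    threshold: int
    partition: list[list[str]]

    @property
    def n_clusters(self) -> int:
        return len(self.partition)

    def lineage_of(self) -> dict[str, int]:
        return {s: i for i, grp in enumerate(self.partition) for s in grp}


@dataclasses.dataclass
class MSNGraph:
    """Minimum spanning network over collapsed clonal lineages.

    Nodes are clonal lineages (lists of sample ids); edges carry the
    minimum inter-lineage SNP distance.  All edges tied at the weight
    at which two components were joined are retained, so the edge set
    contains (at least) one minimum spanning tree.
    """

    node_members: list[list[str]]
    edges: list[tuple[int, int, float]]
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return len(self.node_members)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclasses.dataclass
class CoreGenomeSummary:
    """Counts of core and soft-core gene clusters."""

    n_clusters_total: int
    n_core: int
    n_soft_core: int
    soft_min: int

    def __post_init__(self) -> None:
        if not (self.n_core <= self.n_soft_core <= self.n_clusters_total):
            raise ValueError("expected n_core <= n_soft_core <= total")


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> GenotypeMatrix:
    """Read a haploid multi-sample VCF into a GenotypeMatrix.

    Every GT must be haploid (a single allele per sample); `.` becomes
    missing.  Records are sorted by (contig, pos); duplicate positions
    raise :class:`VCFFormatError`, diploid calls raise
    :class:`PloidyError` naming the offending record.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        contigs = [
            (name, vf.header.contigs[name].length or 0) for name in vf.header.contigs
        ]
        records: list[tuple[Locus, list[int]]] = []
        seen: set[tuple[str, int]] = set()
        for rec in vf:
            key = (rec.contig, rec.pos)
            if key in seen:
                raise VCFFormatError(f"duplicate record at {rec.contig}:{rec.pos}")
            seen.add(key)
            alts = tuple(rec.alts or ())
            row: list[int] = []
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                if len(gt) != 1:
                    raise PloidyError(
                        f"non-haploid GT for sample {s} at {rec.contig}:{rec.pos}"
                    )
                row.append(MISSING if gt[0] is None else int(gt[0]))
            records.append((Locus(rec.contig, rec.pos, rec.ref, alts), row))
    records.sort(key=lambda t: (t[0].contig, t[0].pos))
    loci = [t[0] for t in records]
    if records:
        calls = np.array([t[1] for t in records], dtype=np.int16).T
    else:
        calls = np.zeros((len(samples), 0), dtype=np.int16)
    for loc, row in records:
        for code in row:
            if code > len(loc.alts):
                raise VCFFormatError(
                    f"allele index {code} out of range at {loc.contig}:{loc.pos}"
                )
    return GenotypeMatrix(samples, loci, calls, contigs=contigs or None)


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as an uncompressed haploid VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=halopop\n")
        for name, length in matrix.contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, loc in enumerate(matrix.loci):
            alt = ",".join(loc.alts) if loc.alts else "."
            gts = [
                "." if c == MISSING else str(int(c)) for c in matrix.calls[:, j]
            ]
            fh.write(
                f"{loc.contig}\t{loc.pos}\t.\t{loc.ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# SNP statistics
# ---------------------------------------------------------------------------

def snp_density(matrix: GenotypeMatrix, genome_length: int) -> float:
    """SNP density as a percentage of total genome size.

    Returns 100 x n_loci / genome_length, the 'SNPs per total genome
    size' statistic.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    return 100.0 * matrix.n_loci / genome_length


def pairwise_differences(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Count pairwise SNP differences between all sample pairs.

    d[i, j] counts loci where both samples have a call and the calls
    differ (haploid allele mismatch; for haploid genomes this equals
    the bitwise distance between genomes).  Loci missing in either
    sample are excluded pairwise and n_compared records how many loci
    entered each comparison.
    """
    calls = matrix.calls
    n = matrix.n_samples
    d = np.zeros((n, n), dtype=np.int64)
    nc = np.zeros((n, n), dtype=np.int64)
    present = calls != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            diff = int(np.sum(both & (calls[i] != calls[j])))
            d[i, j] = d[j, i] = diff
            nc[i, j] = nc[j, i] = int(both.sum())
    np.fill_diagonal(nc, present.sum(axis=1))
    return DistanceMatrix(list(matrix.sample_ids), d, nc)


def clonal_clusters(dist: DistanceMatrix, threshold: int = 200) -> ClonalClusters:
    """Partition samples into clonal lineages by single linkage.

    Two samples belong to the same lineage iff they are connected by a
    chain of pairwise distances strictly below `threshold`. The default
    cutoff of 200 SNPs reflects the observed gap between within-lineage
    and between-lineage differences in near-clonal haploid populations.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(dist.sample_ids)
    adj = (dist.d < threshold).astype(np.int8)
    np.fill_diagonal(adj, 1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # order clusters by first member index for determinism
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    partition: list[list[str]] = [[] for _ in range(n_comp)]
    for i in range(n):
        partition[order[labels[i]]].append(dist.sample_ids[i])
    return ClonalClusters(threshold=threshold, partition=partition)


def minimum_spanning_network(
    dist: DistanceMatrix, collapse_threshold: int = 200
) -> MSNGraph:
    """Minimum spanning network over clonal lineages.

    Samples are first collapsed into clonal lineages at
    `collapse_threshold` (each lineage becomes one node, as in
    clone-corrected multilocus-genotype networks); inter-node distance
    is the minimum pairwise distance between members.  Kruskal's
    algorithm is then run by increasing weight; within each weight
    class, every edge that joins two components as they stood at the
    start of the class is retained, so ties produce reticulations
    rather than arbitrary tree edges.
    """
    clusters = clonal_clusters(dist, collapse_threshold)
    members = clusters.partition
    idx = {s: i for i, s in enumerate(dist.sample_ids)}
    m = len(members)
    node_d = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            ia = [idx[s] for s in members[a]]
            ib = [idx[s] for s in members[b]]
            node_d[a, b] = node_d[b, a] = dist.d[np.ix_(ia, ib)].min()
    g = nx.Graph()
    for a in range(m):
        g.add_node(a, members=list(members[a]))
    edges: list[tuple[int, int, float]] = []
    if m > 1:
        parent = list(range(m))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        all_edges = [
            (node_d[a, b], a, b) for a in range(m) for b in range(a + 1, m)
        ]
        all_edges.sort()
        i = 0
        while i < len(all_edges):
            w = all_edges[i][0]
            cls = []
            while i < len(all_edges) and all_edges[i][0] == w:
                cls.append(all_edges[i])
                i += 1
            # evaluate the whole weight class against the pre-class components
            keep = [(a, b) for _, a, b in cls if find(a) != find(b)]
            for a, b in keep:
                edges.append((a, b, float(w)))
                g.add_edge(a, b, weight=float(w))
            for a, b in keep:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    return MSNGraph(node_members=members, edges=edges, graph=g)


def core_genome_counts(presence: pd.DataFrame, soft_min: int) -> CoreGenomeSummary:
    """Count core and soft-core gene clusters from a presence table.

    `presence` has gene clusters as rows and genomes as columns, with
    non-negative copy counts (0 = absent).  Core clusters are present
    (count >= 1) in every genome; soft-core clusters are present in at
    least `soft_min` genomes.
    """
    if presence.shape[0] == 0 or presence.shape[1] == 0:
        raise ValueError("presence table is empty")
    if (presence.to_numpy() < 0).any():
        raise ValueError("presence counts must be non-negative")
    n_genomes = presence.shape[1]
    if soft_min > n_genomes:
        raise ValueError("soft_min exceeds number of genomes")
    present = presence.to_numpy() >= 1
    n_present = present.sum(axis=1)
    n_core = int((n_present == n_genomes).sum())
    n_soft = int((n_present >= soft_min).sum())
    return CoreGenomeSummary(
        n_clusters_total=int(presence.shape[0]),
        n_core=n_core,
        n_soft_core=n_soft,
        soft_min=soft_min,
    )
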