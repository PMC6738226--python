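"""Genotype model, VCF I/O, distances, clustering, MSN and core genome."""

import numpy as np
import pandas as pd
import pytest

from halopop import simpop, variants
from halopop.variants import (
    DistanceMatrix,
    GenotypeMatrix,
    Locus,
    PloidyError,
    VCFFormatError,
)

from conftest import random_genotype_matrix


def _write_vcf_text(path, body: str) -> str:
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=c1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    )
    path.write_text(header + body)
    return str(path)


class TestReadVCF:
    def test_small_file_with_missing_call(self, tmp_path):
        p = _write_vcf_text(
            tmp_path / "a.vcf",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "c1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0\t1\t.\n"
            "c1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1\t1\t0\n",
        )
        gm = variants.read_vcf(p)
        assert gm.sample_ids == ["A", "B", "C"]
        assert gm.n_loci == 2
        assert gm.calls.tolist() == [[0, 1], [1, 1], [-1, 0]]
        assert gm.loci[0] == Locus("c1", 100, "A", ("G",))

    def test_diploid_gt_raises_ploidy_error(self, tmp_path):
        p = _write_vcf_text(
            tmp_path / "b.vcf",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "c1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\n",
        )
        with pytest.raises(PloidyError, match="c1:100"):
            variants.read_vcf(p)

    def test_duplicate_position_raises(self, tmp_path):
        p = _write_vcf_text(
            tmp_path / "c.vcf",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "c1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0\n"
            "c1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t1\n",
        )
        with pytest.raises(VCFFormatError, match="duplicate"):
            variants.read_vcf(p)

    def test_simulated_dataset_round_trips(self, small_dataset, tmp_path):
        paths = simpop.write_dataset(small_dataset, str(tmp_path / "ds"))
        gm = variants.read_vcf(paths["vcf"])
        assert gm.sample_ids == small_dataset.genotypes.sample_ids
        assert gm.loci == small_dataset.genotypes.loci
        assert np.array_equal(gm.calls, small_dataset.genotypes.calls)


class TestSnpDensity:
    @pytest.mark.parametrize(
        "n_loci,length,expected",
        [(0, 9_550_000, 0.0), (32_000, 10_000_000, 0.32), (13_000, 10_000_000, 0.13)],
    )
    def test_density_values(self, n_loci, length, expected):
        rng = np.random.default_rng(0)
        gm = random_genotype_matrix(rng, 3, n_loci) if n_loci else GenotypeMatrix(
            ["a", "b"], [], np.zeros((2, 0))
        )
        assert variants.snp_density(gm, length) == pytest.approx(expected)

    def test_rejects_nonpositive_length(self):
        gm = GenotypeMatrix(["a", "b"], [], np.zeros((2, 0)))
        with pytest.raises(ValueError):
            variants.snp_density(gm, 0)


class TestPairwiseDifferences:
    def test_hand_counted_example(self):
        gm = GenotypeMatrix(
            ["a", "b"],
            [Locus("c1", p, "A", ("G",)) for p in (1, 2, 3, 4, 5)],
            np.array([[0, 0, 1, 1, 0], [1, 0, 1, 0, 0]]),
        )
        d = variants.pairwise_differences(gm)
        assert d.d[0, 1] == 2
        assert d.n_compared[0, 1] == 5

    def test_identical_rows_are_zero(self):
        rng = np.random.default_rng(1)
        gm = random_genotype_matrix(rng, 1, 30)
        gm2 = GenotypeMatrix(
            ["a", "b", "c"], gm.loci, np.vstack([gm.calls[0]] * 3)
        )
        assert variants.pairwise_differences(gm2).d.sum() == 0

    def test_missing_excluded_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        gm = random_genotype_matrix(rng, 6, 40, missing_rate=0.2)
        dm = variants.pairwise_differences(gm)
        for i in range(6):
            for j in range(6):
                diff = sum(
                    1
                    for k in range(40)
                    if gm.calls[i, k] != -1
                    and gm.calls[j, k] != -1
                    and gm.calls[i, k] != gm.calls[j, k]
                )
                assert dm.d[i, j] == diff

    def test_invariant_under_allele_relabeling(self):
        rng = np.random.default_rng(3)
        gm = random_genotype_matrix(rng, 5, 30, missing_rate=0.1)
        flipped = gm.calls.copy()
        cols = rng.choice(30, 10, replace=False)
        for c in cols:
            col = flipped[:, c]
            mask = col != -1
            col[mask] = 1 - col[mask]
        gm2 = GenotypeMatrix(gm.sample_ids, gm.loci, flipped)
        assert np.array_equal(
            variants.pairwise_differences(gm).d, variants.pairwise_differences(gm2).d
        )


def _dist(ids, mat):
    mat = np.asarray(mat, dtype=float)
    return DistanceMatrix(ids, mat, np.full_like(mat, 100))


class TestClonalClusters:
    def test_all_far_apart_gives_singletons(self):
        d = _dist(["a", "b", "c"], [[0, 200, 300], [200, 0, 250], [300, 250, 0]])
        cl = variants.clonal_clusters(d, 200)
        assert cl.partition == [["a"], ["b"], ["c"]]

    def test_chain_linkage_merges_transitively(self):
        d = _dist(["A", "B", "C"], [[0, 150, 300], [150, 0, 150], [300, 150, 0]])
        cl = variants.clonal_clusters(d, 200)
        assert cl.partition == [["A", "B", "C"]]

    def test_matches_bruteforce_union_find(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(3, 12))
            m = rng.integers(0, 400, size=(n, n))
            m = np.triu(m, 1)
            m = m + m.T
            ids = [f"s{i}" for i in range(n)]
            cl = variants.clonal_clusters(_dist(ids, m), 200)
            # brute force: union-find over all thresholded pairs
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for i in range(n):
                for j in range(i + 1, n):
                    if m[i, j] < 200:
                        parent[find(j)] = find(i)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(ids[i])
            expected = sorted(sorted(g) for g in groups.values())
            assert sorted(sorted(g) for g in cl.partition) == expected

    def test_planted_clones_recovered(self, small_dataset):
        dist = variants.pairwise_differences(small_dataset.genotypes)
        cl = variants.clonal_clusters(dist, 200)
        truth: dict[int, list[str]] = {}
        for s, li in small_dataset.truth.lineage.items():
            truth.setdefault(li, []).append(s)
        assert sorted(sorted(g) for g in cl.partition) == sorted(
            sorted(v) for v in truth.values()
        )

    def test_rejects_nonpositive_threshold(self):
        d = _dist(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            variants.clonal_clusters(d, 0)


class TestMinimumSpanningNetwork:
    def test_three_equidistant_nodes_keep_all_tie_edges(self):
        d = _dist(["a", "b", "c"], [[0, 10, 10], [10, 0, 10], [10, 10, 0]])
        msn = variants.minimum_spanning_network(d, collapse_threshold=5)
        assert msn.n_nodes == 3
        assert msn.n_edges == 3

    def test_unique_mst_keeps_only_mst_edges(self):
        d = _dist(["a", "b", "c"], [[0, 1, 10], [1, 0, 1], [10, 1, 0]])
        msn = variants.minimum_spanning_network(d, collapse_threshold=1)
        assert sorted(w for _, _, w in msn.edges) == [1, 1]

    def test_single_node_graph(self):
        d = _dist(["a", "b"], [[0, 3], [3, 0]])
        msn = variants.minimum_spanning_network(d, collapse_threshold=10)
        assert msn.n_nodes == 1 and msn.n_edges == 0

    def test_contains_mst_of_prim_weight(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            m = rng.integers(1, 500, size=(n, n)).astype(float)
            m = np.triu(m, 1)
            m = m + m.T
            d = _dist([f"s{i}" for i in range(n)], m)
            msn = variants.minimum_spanning_network(d, collapse_threshold=1)
            assert msn.n_nodes == n  # collapse threshold 1 keeps all
            # independent Prim over the node distances
            in_tree = {0}
            prim_weight = 0.0
            while len(in_tree) < n:
                best = min(
                    (m[a, b], b)
                    for a in in_tree
                    for b in range(n)
                    if b not in in_tree
                )
                prim_weight += best[0]
                in_tree.add(best[1])
            # a spanning tree of minimal weight must exist inside the MSN
            import networkx as nx

            mst = nx.minimum_spanning_tree(msn.graph, weight="weight")
            assert sum(
                w["weight"] for _, _, w in mst.edges(data=True)
            ) == pytest.approx(prim_weight)

    def test_planted_clones_collapse_to_lineage_nodes(self, small_dataset):
        dist = variants.pairwise_differences(small_dataset.genotypes)
        msn = variants.minimum_spanning_network(dist, 200)
        n_lineages = len(set(small_dataset.truth.lineage.values()))
        assert msn.n_nodes == n_lineages


class TestCoreGenome:
    def test_saturated_table(self):
        t = pd.DataFrame(np.ones((10, 22), dtype=int))
        s = variants.core_genome_counts(t, soft_min=20)
        assert (s.n_core, s.n_soft_core) == (10, 10)

    def test_planted_counts(self):
        rows = [[1] * 22] * 5 + [[1] * 21 + [0]] * 3 + [[1] * 19 + [0] * 3] * 2
        t = pd.DataFrame(rows)
        s = variants.core_genome_counts(t, soft_min=20)
        assert (s.n_core, s.n_soft_core, s.n_clusters_total) == (5, 8, 10)

    def test_soft_min_equal_to_n_genomes_collapses(self):
        rows = [[1] * 5, [1] * 4 + [0]]
        t = pd.DataFrame(rows)
        s = variants.core_genome_counts(t, soft_min=5)
        assert s.n_soft_core == s.n_core == 1

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            variants.core_genome_counts(pd.DataFrame(), soft_min=1)
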