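"""Similarity graph construction and graph partitioning."""

import itertools

import networkx as nx
import numpy as np
import pytest

from polyrep import (
    InheritanceModel,
    ReadGraph,
    ReadSet,
    apply_inheritance,
    build_similarity_graph,
    cluster_reads,
    generate_reads,
    partition_graph,
    planted_genomes,
    pool_readsets,
    tabulate_clusters,
    tag_species,
)
from polyrep.prep import Read

from conftest import batch_edit_distance


def _readset(seqs, prefix="AAAAA"):
    reads = [
        Read(read_id=f"{prefix}_r{i:04d}", sequence=s, qualities=tuple([35] * len(s)))
        for i, s in enumerate(seqs)
    ]
    return ReadSet(reads=reads, read_length=len(seqs[0]), species_code=prefix)


def _random_seq(rng, length=91):
    return "".join(np.random.default_rng(rng).choice(list("ACGT"), length))


class TestSimilarityGraph:
    def test_identical_reads_edge_weight_one(self):
        seq = _random_seq(1)
        g = build_similarity_graph(_readset([seq, seq]))
        assert g.n_edges == 1
        (_, _, w), = g.graph.edges(data="weight")
        assert w == pytest.approx(1.0)

    def test_no_shared_kmer_no_edge(self):
        g = build_similarity_graph(_readset(["A" * 91, "C" * 91]))
        assert g.n_edges == 0

    def test_non_uniform_lengths_rejected(self):
        rs = ReadSet(
            reads=[
                Read("r1", "A" * 91, tuple([35] * 91)),
                Read("r2", "A" * 90, tuple([35] * 90)),
            ]
        )
        with pytest.raises(ValueError, match="non-uniform"):
            build_similarity_graph(rs)

    def test_edge_set_matches_all_pairs_alignment_oracle(self):
        """Planted families + random background vs an exhaustive all-pairs DP.

        Two families at 5% within-family divergence plus random background
        reads: the k-mer-seeded graph must contain exactly the pairs whose
        true edit distance is within the identity threshold, and no
        family-background edges.
        """
        mat, _ = planted_genomes(
            {"famA": 300, "famB": 300},
            80_000,
            seed=11,
            unit_length=91,
            within_family_divergence=0.05,
        )
        rs = generate_reads(mat, proportion=0.28, read_length=91, error_rate=0.0, seed=12)
        rs = tag_species(rs, "AAAAA")
        assert 200 <= len(rs) <= 300
        # guaranteed-recall seeding: k <= 9 pigeonholes >= 1 clean shared
        # k-mer into any pair within 9 edits of each other
        g = build_similarity_graph(rs, k=9, min_shared_kmers=1)

        reads = sorted(rs.reads, key=lambda r: r.read_id)
        ia, ib = np.triu_indices(len(reads), 1)
        dists = batch_edit_distance(
            [reads[i].sequence for i in ia], [reads[j].sequence for j in ib]
        )
        max_dist = int((1 - 0.90) * 91)  # 9 edits
        oracle_edges = {
            frozenset((reads[i].read_id, reads[j].read_id))
            for i, j, d in zip(ia, ib, dists)
            if d <= max_dist
        }
        got_edges = {frozenset((u, v)) for u, v in g.graph.edges}
        assert got_edges == oracle_edges

        fam = rs.provenance
        for e in got_edges:
            u, v = tuple(e)
            assert not (
                (fam[u] is None) ^ (fam[v] is None)
            ), "edge between family and background read"


class TestPartition:
    def _clique_graph(self, groups, bridges=()):
        g = nx.Graph()
        for group in groups:
            for u, v in itertools.combinations(group, 2):
                g.add_edge(u, v, weight=1.0)
        for u, v in bridges:
            g.add_edge(u, v, weight=0.5)
        return ReadGraph(graph=g)

    def test_two_disjoint_cliques_two_clusters(self):
        g = self._clique_graph([[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]])
        parts = partition_graph(g, seed=1)
        assert sorted(len(p) for p in parts) == [5, 5]

    def test_single_clique_single_cluster(self):
        g = self._clique_graph([[f"a{i}" for i in range(6)]])
        assert len(partition_graph(g, seed=1)) == 1

    def test_singletons_excluded(self):
        g = self._clique_graph([[f"a{i}" for i in range(4)]])
        g.graph.add_node("lonely")
        parts = partition_graph(g, seed=1)
        assert all("lonely" not in p for p in parts)

    def test_bridged_communities_split_matches_exhaustive_modularity(self):
        """Greedy split of two bridged 8-cliques vs exhaustive bipartition."""
        a = [f"a{i}" for i in range(8)]
        b = [f"b{i}" for i in range(8)]
        g = self._clique_graph([a, b], bridges=[(a[0], b[0])])
        parts = partition_graph(g, seed=1, split_min_size=10)
        assert len(parts) == 2

        nodes = sorted(g.graph.nodes)
        best, best_q = None, -np.inf
        for size in range(1, len(nodes) // 2 + 1):
            for left in itertools.combinations(nodes, size):
                left = set(left)
                q = nx.community.modularity(
                    g.graph, [left, set(nodes) - left], weight="weight"
                )
                if q > best_q:
                    best, best_q = left, q
        oracle = {frozenset(best), frozenset(set(nodes) - best)}
        assert set(parts) == oracle
        assert oracle == {frozenset(a), frozenset(b)}

    def test_deterministic_partition(self):
        mat, _ = planted_genomes({"famA": 200, "famB": 100}, 120_000, seed=3)
        rs = tag_species(
            generate_reads(mat, proportion=0.1, read_length=91, error_rate=0.01, seed=4),
            "AAAAA",
        )
        g = build_similarity_graph(rs)
        p1 = partition_graph(g, seed=1, split_min_size=20)
        p2 = partition_graph(g, seed=99, split_min_size=20)
        assert p1 == p2


class TestTabulate:
    def test_counts_by_prefix(self):
        part = [frozenset({"AAAAA_1", "AAAAA_2", "BBBBB_1"})]
        table = tabulate_clusters(part, ("AAAAA", "BBBBB"))
        assert table.clusters[0].counts_by_species == {"AAAAA": 2, "BBBBB": 1}

    def test_unknown_prefix_raises(self):
        with pytest.raises(ValueError, match="prefix"):
            tabulate_clusters([frozenset({"XXXXX_1"})], ("AAAAA",))

    def test_total_conservation_and_ranking(self):
        part = [
            frozenset({f"AAAAA_{i}" for i in range(3)}),
            frozenset({f"AAAAA_{i}" for i in range(10, 15)}),
            frozenset({f"BBBBB_{i}" for i in range(3)}),
        ]
        table = tabulate_clusters(part, ("AAAAA", "BBBBB"))
        assert [c.cluster_id for c in table.clusters] == ["CL1", "CL2", "CL3"]
        assert [c.total for c in table.clusters] == [5, 3, 3]
        # tie between the two 3-clusters broken by smallest member id
        assert "AAAAA_0" in table.clusters[1].member_read_ids
        assert sum(c.total for c in table.clusters) == 11


class TestRecovery:
    def test_planted_families_recovered_in_single_clusters(self):
        """Additive trio: >= 90% of each family's reads land in one cluster."""
        copy_numbers = {f"fam{i}": c for i, c in enumerate(
            [500, 400, 300, 250, 200, 150, 120, 100, 80, 60])}
        mat, pat = planted_genomes(
            copy_numbers, 300_000, seed=21, unit_length=91,
            within_family_divergence=0.02, between_parent_divergence=0.02,
        )
        tet = apply_inheritance(mat, pat, InheritanceModel("additive"), "TETRA")
        readsets = []
        for genome, code, seed in ((mat, "AAAAA", 1), (pat, "BBBBB", 2), (tet, "CCCCC", 3)):
            rs = generate_reads(genome, proportion=0.09, read_length=91,
                                error_rate=0.01, seed=seed)
            readsets.append(tag_species(rs, code))
        pooled = pool_readsets(*readsets)
        table = cluster_reads(pooled, ("AAAAA", "BBBBB", "CCCCC"), seed=1)
        membership = table.membership()
        for fam in copy_numbers:
            fam_reads = [rid for rid, f in pooled.provenance.items() if f == fam]
            placed = [membership.get(rid) for rid in fam_reads]
            top = max(placed.count(c) for c in set(placed) if c is not None)
            assert top / len(fam_reads) >= 0.90, fam

    def test_per_species_counts_scale_with_proportion(self):
        """Doubling the genome proportion about doubles per-family counts."""
        copy_numbers = {"famA": 800, "famB": 400, "famC": 200}
        mat, _ = planted_genomes(copy_numbers, 200_000, seed=31, unit_length=91)
        counts = {}
        for prop in (0.05, 0.10):
            rs = tag_species(
                generate_reads(mat, proportion=prop, read_length=91,
                               error_rate=0.01, seed=32),
                "AAAAA",
            )
            table = cluster_reads(_pad(rs), ("AAAAA", "BBBBB"), seed=1)
            membership = table.membership()
            by_fam = {}
            for rid, fam in rs.provenance.items():
                if fam is not None and rid in membership:
                    by_fam[fam] = by_fam.get(fam, 0) + 1
            counts[prop] = by_fam
        for fam, low in counts[0.05].items():
            if low >= 30:
                ratio = counts[0.10][fam] / low
                assert 2 - 4 / np.sqrt(low) <= ratio <= 2 + 4 / np.sqrt(low), fam


def _pad(rs):
    """Add one alien read so the graph has two species prefixes available."""
    alien = Read("BBBBB_pad0", ("ACGT" * 23)[:91], tuple([35] * 91))
    padded = ReadSet(
        reads=rs.reads + [alien],
        read_length=rs.read_length,
        provenance={**rs.provenance, "BBBBB_pad0": None},
    )
    return padded
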