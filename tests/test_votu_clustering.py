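import itertools

import networkx as nx
import numpy as np
import pytest

import oracles
from cutovir.io_formats import GenomeRecord, revcomp
from cutovir.votu_clustering import (
    AaiResult,
    AniResult,
    call_orfs,
    cluster_rank,
    cluster_species,
    compute_aai_shared,
    estimate_ani,
    mcl,
    strain_groups,
)
from conftest import random_seq


def _mutate(seq: str, n_subs: int, rng) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        chars[pos] = rng.choice([b for b in "ACGT" if b != chars[pos]])
    return "".join(chars)


class TestEstimateAni:
    def test_self_identity(self, small_genome):
        res = estimate_ani(small_genome, small_genome)
        assert res.ani == pytest.approx(100.0)
        assert res.af == pytest.approx(100.0)

    def test_reverse_complement_handled(self, small_genome):
        rc = GenomeRecord("rc", revcomp(small_genome.seq))
        res = estimate_ani(small_genome, rc)
        assert res.ani == pytest.approx(100.0)
        assert res.af == pytest.approx(100.0, abs=0.1)

    def test_known_substitution_load(self, rng):
        # 500 substitutions in 10 kb -> true identity 95.0%
        a = GenomeRecord("a", random_seq(rng, 10_000))
        b = GenomeRecord("b", _mutate(a.seq, 500, rng))
        res = estimate_ani(a, b)
        assert res.ani == pytest.approx(95.0, abs=0.5)
        assert res.af >= 99.0

    def test_symmetry(self, rng):
        a = GenomeRecord("a", random_seq(rng, 6000))
        b = GenomeRecord("b", _mutate(a.seq, 200, rng)[:5500])
        r1 = estimate_ani(a, b)
        r2 = estimate_ani(b, a)
        assert r1.ani == pytest.approx(r2.ani, abs=1e-9)
        assert r1.af == pytest.approx(r2.af, abs=1e-9)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            estimate_ani(GenomeRecord("a", "ACGT" * 5), GenomeRecord("b", "ACGT" * 5))


def _pairwise_from_matrix(ani, af):
    def fn(a, b):
        key = (a.id, b.id) if (a.id, b.id) in ani else (b.id, a.id)
        return AniResult(ani[key], af[key])

    return fn


class TestClusterSpecies:
    def test_identical_genomes_one_cluster(self, rng):
        seq = random_seq(rng, 3000)
        gs = [GenomeRecord(f"g{i}", seq) for i in range(3)]
        clusters = cluster_species(gs)
        assert len(clusters) == 1
        # equal lengths: tie broken lexicographically by id
        assert clusters[0].representative_id == "g0"
        assert clusters[0].member_ids == frozenset({"g0", "g1", "g2"})

    def test_below_ani_cutoff_splits(self, rng):
        gs = [GenomeRecord("a", random_seq(rng, 3000)),
              GenomeRecord("b", random_seq(rng, 2900))]
        fn = _pairwise_from_matrix({("a", "b"): 90.0}, {("a", "b"): 99.0})
        clusters = cluster_species(gs, pairwise=fn)
        assert len(clusters) == 2

    def test_af_boundary_strict(self, rng):
        gs = [GenomeRecord("a", random_seq(rng, 3000)),
              GenomeRecord("b", random_seq(rng, 2900))]
        # ani passes, af exactly at the cutoff -> "> 85" fails
        fn = _pairwise_from_matrix({("a", "b"): 96.0}, {("a", "b"): 85.0})
        assert len(cluster_species(gs, pairwise=fn)) == 2
        fn = _pairwise_from_matrix({("a", "b"): 96.0}, {("a", "b"): 85.01})
        assert len(cluster_species(gs, pairwise=fn)) == 1

    def test_matches_brute_force_on_random_matrices(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 9))
            ids = [f"g{i}" for i in range(n)]
            lengths = {g: int(rng.integers(1000, 9000)) for g in ids}
            ani, af = {}, {}
            for x, y in itertools.combinations(ids, 2):
                ani[(x, y)] = float(rng.uniform(80, 100))
                af[(x, y)] = float(rng.uniform(60, 100))
            genomes = [GenomeRecord(g, "A" * lengths[g]) for g in ids]
            got = cluster_species(genomes, pairwise=_pairwise_from_matrix(ani, af))
            want = oracles.greedy_species_clusters(ids, lengths, ani, af)
            assert {(c.representative_id, c.member_ids) for c in got} == set(want)

    def test_members_satisfy_thresholds_vs_representative(self, rng):
        seq = random_seq(rng, 8000)
        gs = [GenomeRecord("a", seq), GenomeRecord("b", _mutate(seq, 200, rng)),
              GenomeRecord("c", random_seq(rng, 7000))]
        clusters = cluster_species(gs)
        by_id = {g.id: g for g in gs}
        for c in clusters:
            rep = by_id[c.representative_id]
            for m in c.member_ids:
                if m == c.representative_id:
                    continue
                res = estimate_ani(rep, by_id[m])
                assert res.ani >= 95.0 and res.af > 85.0

    def test_strain_rule_splits_divergent_members(self, rng):
        seq = random_seq(rng, 8000)
        near = _mutate(seq, 40, rng)   # ~99.5% ANI -> same strain
        far = _mutate(seq, 240, rng)   # ~97% ANI -> distinct strain
        gs = [GenomeRecord("a", seq), GenomeRecord("b", near), GenomeRecord("c", far)]
        clusters = cluster_species(gs)
        assert len(clusters) == 1
        groups = strain_groups(clusters[0], {g.id: g for g in gs})
        assert frozenset({"a", "b"}) in groups
        assert frozenset({"c"}) in groups


class TestCallOrfs:
    def test_constructed_orf_exact_coordinates(self, rng):
        lead = "CCC" * 40  # no ATG, no stops in any frame of this prefix
        orf = "ATG" + "AAA" * 70 + "TAA"
        tail = "CCC" * 40
        g = GenomeRecord("g", lead + orf + tail)
        hits = [o for o in call_orfs(g, min_aa=60) if o.strand == "+"]
        assert any(
            o.start == len(lead) and o.end == len(lead) + len(orf) for o in hits
        )
        hit = next(o for o in hits if o.start == len(lead))
        assert hit.protein == "M" + "K" * 70

    def test_no_start_codon_no_orfs(self):
        g = GenomeRecord("g", "C" * 500)
        assert call_orfs(g, min_aa=10) == []

    def test_matches_six_frame_enumeration(self, rng):
        seq = random_seq(rng, 5000)
        got = {
            (o.start, o.end, o.strand, o.protein)
            for o in call_orfs(GenomeRecord("g", seq), min_aa=30)
        }
        assert got == oracles.orfs_naive(seq, min_aa=30)


def _random_protein(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestAai:
    def test_identical_proteomes(self, rng):
        prots = [_random_protein(rng, 80) for _ in range(5)]
        res = compute_aai_shared(prots, list(prots))
        assert res.aai == pytest.approx(100.0)
        assert res.shared_fraction == pytest.approx(100.0)

    def test_disjoint_random_proteomes_flagged(self, rng):
        a = [_random_protein(rng, 60) for _ in range(4)]
        b = [_random_protein(rng, 60) for _ in range(4)]
        res = compute_aai_shared(a, b)
        assert res.no_hits
        assert res.aai == 0.0 and res.shared_fraction == 0.0

    def test_half_shared_gives_fifty_percent(self, rng):
        shared = [_random_protein(rng, 90) for _ in range(5)]
        a = shared + [_random_protein(rng, 90) for _ in range(5)]
        b = shared + [_random_protein(rng, 90) for _ in range(5)]
        res = compute_aai_shared(a, b)
        assert res.shared_fraction == pytest.approx(50.0)
        assert res.aai == pytest.approx(100.0)
        assert res.n_rbh == 5

    def test_empty_proteome_errors(self):
        with pytest.raises(ValueError):
            compute_aai_shared([], ["MKV"])


def _graph(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestMcl:
    def test_disjoint_cliques_stay_separate(self):
        edges = [(a, b, 1.0) for a, b in itertools.combinations(range(4), 2)]
        edges += [(a, b, 1.0) for a, b in itertools.combinations(range(4, 8), 2)]
        for inflation in (1.2, 2.0, 4.0):
            clusters = mcl(_graph(range(8), edges), inflation)
            assert frozenset(range(4)) in clusters
            assert frozenset(range(4, 8)) in clusters

    def test_single_edge_one_cluster(self):
        assert mcl(_graph([0, 1], [(0, 1, 0.5)]), 2.0) == [frozenset({0, 1})]

    def test_bridged_cliques_split_at_high_inflation(self):
        edges = [(a, b, 1.0) for a, b in itertools.combinations(range(5), 2)]
        edges += [(a, b, 1.0) for a, b in itertools.combinations(range(5, 10), 2)]
        edges.append((4, 5, 0.1))
        clusters = mcl(_graph(range(10), edges), 2.0)
        assert frozenset(range(5)) in clusters
        assert frozenset(range(5, 10)) in clusters

    def test_partition_and_oracle_agreement(self, rng):
        for trial in range(15):
            n = int(rng.integers(4, 10))
            edges = []
            for a, b in itertools.combinations(range(n), 2):
                if rng.random() < 0.4:
                    edges.append((a, b, float(rng.uniform(0.1, 1.0))))
            clusters = mcl(_graph(range(n), edges), 2.0)
            flat = [v for c in clusters for v in c]
            assert sorted(flat) == list(range(n))  # partition
            want = oracles.mcl_naive(list(range(n)), edges, 2.0)
            assert sorted(clusters, key=min) == want

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(ValueError):
            mcl(_graph([0, 1], [(0, 1, float("nan"))]), 2.0)


class TestClusterRank:
    def _pairwise(self, table):
        def fn(x, y):
            key = (x, y) if (x, y) in table else (y, x)
            return table.get(key, AaiResult(0.0, 0.0, no_hits=True))

        return fn

    def test_all_identical_single_cluster(self, rng):
        gs = [GenomeRecord(f"g{i}", random_seq(rng, 2000)) for i in range(4)]
        table = {
            (a.id, b.id): AaiResult(100.0, 100.0, 10)
            for a, b in itertools.combinations(gs, 2)
        }
        for rank in ("genus", "family"):
            clusters = cluster_rank(gs, {}, rank, pairwise=self._pairwise(table))
            assert len(clusters) == 1

    def test_intermediate_pair_family_not_genus(self, rng):
        gs = [GenomeRecord("a", random_seq(rng, 2000)),
              GenomeRecord("b", random_seq(rng, 1900))]
        table = {("a", "b"): AaiResult(30.0, 15.0, 3)}
        fam = cluster_rank(gs, {}, "family", pairwise=self._pairwise(table))
        gen = cluster_rank(gs, {}, "genus", pairwise=self._pairwise(table))
        assert len(fam) == 1  # kept: aai 30 >= 20 and shared 15 >= 10
        assert len(gen) == 2  # dropped: aai 30 < 50

    def test_block_structure_matches_oracle(self, rng):
        n = 12
        gs = [GenomeRecord(f"g{i:02d}", random_seq(rng, 1500 + 10 * i)) for i in range(n)]
        ids = [g.id for g in gs]
        blocks = {g.id: i // 4 for i, g in enumerate(gs)}  # 3 blocks of 4
        table = {}
        edges = []
        for a, b in itertools.combinations(ids, 2):
            if blocks[a] == blocks[b]:
                table[(a, b)] = AaiResult(80.0, 60.0, 8)
                edges.append((a, b, 80.0))
            else:
                table[(a, b)] = AaiResult(10.0, 5.0, 1)
        clusters = cluster_rank(gs, {}, "genus", pairwise=self._pairwise(table))
        want = oracles.mcl_naive(ids, edges, 2.0)
        assert sorted((c.member_ids for c in clusters), key=min) == want
        for c in clusters:
            assert c.representative_id == max(c.member_ids)  # longest member
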