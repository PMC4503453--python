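"""Isoform clustering: similarity predicate, graph vs brute force,
greedy clique cover, consensus accuracy, reassignment and polishing."""

import random

import numpy as np
import pytest

from longform import SimConfig, simulate_all
from longform.classify import FULL_LENGTH, RawRead, classify_reads
from longform.cluster import (
    ClusterParams,
    IsoCluster,
    build_similarity_graph,
    cluster_pipeline,
    dag_consensus,
    filter_by_predicted_errors,
    initial_clusters,
    params_for_error,
    polish,
    predicted_error_count,
    reassign,
    same_isoform,
)
from longform.sim import _corrupt

from conftest import ERR2


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSameIsoform:
    def test_identity(self):
        rng = np.random.default_rng(0)
        a = _rand(rng, 800)
        ok, s = same_isoform(a, a)
        assert ok and s["identity"] == 1.0 and s["offset3"] == 0

    def test_five_prime_degradation_true(self):
        rng = np.random.default_rng(1)
        a = _rand(rng, 1000)
        ok, s = same_isoform(a, a[200:])
        assert ok and s["offset3"] == 0

    def test_internal_deletion_false(self):
        """A 120-nt internal block deletion (an exon skip) must separate
        the pair: the overlap alignment shows an internal gap run far
        above the 20-nt bound."""
        rng = np.random.default_rng(2)
        a = _rand(rng, 1000)
        b = a[:400] + a[520:]
        ok, s = same_isoform(a, b)
        assert not ok
        assert s["max_internal_gap"] >= 100

    def test_three_prime_mismatch_false(self):
        rng = np.random.default_rng(3)
        a = _rand(rng, 900)
        ok, s = same_isoform(a, a[:800])  # truncated at the 3' end
        assert not ok and s["offset3"] >= 100

    def test_containment_beyond_tol5_false(self):
        rng = np.random.default_rng(4)
        a = _rand(rng, 1500)
        ok, s = same_isoform(a, a[600:])
        assert not ok and s["offset5"] == 600

    def test_empty_sequence(self):
        ok, s = same_isoform("", "ACGT")
        assert not ok and s["reason"] == "empty_sequence"


class TestSimilarityGraph:
    def test_identical_reads_complete_graph(self):
        rng = np.random.default_rng(5)
        seq = _rand(rng, 600)
        reads = {f"r{i}": seq for i in range(5)}
        g = build_similarity_graph(reads)
        assert g.number_of_edges() == 10  # K5

    def test_two_isoform_groups_disconnected(self):
        rng = np.random.default_rng(6)
        a = _rand(rng, 900)
        b = a[:300] + a[500:]  # exon-skip-like variant
        reads = {f"a{i}": a for i in range(3)} | {f"b{i}": b for i in range(4)}
        g = build_similarity_graph(reads)
        comps = sorted(len(c) for c in
                       __import__("networkx").connected_components(g))
        assert comps == [3, 4]

    def test_edges_equal_bruteforce_oracle(self, truth_small):
        """Graph construction (with its k-mer prefilter) must equal the
        all-pairs evaluation of the similarity predicate."""
        truth = truth_small
        cfg = truth.config
        raw = [RawRead(r, s, tuple(q)) for r, s, q in truth._read_seqs]
        out = classify_reads(raw, cfg.primer5, cfg.primer3)
        fl = {o.id: o.trimmed_seq for o in out
              if o.classification == FULL_LENGTH}
        ids = sorted(fl)[:150]
        fl = {i: fl[i] for i in ids}
        params = params_for_error(0.02)
        g = build_similarity_graph(fl, params)
        expected = {
            (a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if same_isoform(fl[a], fl[b], params)[0]
        }
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == expected


def _greedy_oracle(adj: dict[str, set[str]]) -> list[list[str]]:
    """Direct simulation of the stated greedy clique-cover rule."""
    deg = {n: len(adj[n]) for n in adj}
    unassigned = set(adj)
    out = []
    for seed in sorted(adj, key=lambda n: (-deg[n], n)):
        if seed not in unassigned:
            continue
        clique = [seed]
        cand = adj[seed] & unassigned
        while cand:
            nxt = sorted(cand, key=lambda n: (-deg[n], n))[0]
            clique.append(nxt)
            cand = cand & adj[nxt] - {nxt}
        unassigned -= set(clique)
        out.append(sorted(clique))
    return out


class TestInitialClusters:
    def _graph(self, edges, nodes):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return g

    def test_k5_single_cluster(self):
        nodes = [f"n{i}" for i in range(5)]
        edges = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        assert initial_clusters(self._graph(edges, nodes)) == [sorted(nodes)]

    def test_disjoint_cliques(self):
        a = ["a0", "a1", "a2"]
        b = ["b0", "b1", "b2", "b3"]
        edges = [(x, y) for i, x in enumerate(a) for y in a[i + 1 :]]
        edges += [(x, y) for i, x in enumerate(b) for y in b[i + 1 :]]
        got = initial_clusters(self._graph(edges, a + b))
        assert sorted(map(tuple, got)) == [tuple(a), tuple(b)]

    def test_bridge_graph_equals_rule_simulation(self):
        """Two triangles joined by one bridge edge, plus random graphs:
        the partition equals an independent simulation of the greedy
        rule."""
        rng = random.Random(7)
        cases = [
            [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")],
        ]
        for _ in range(10):
            nodes = [f"n{i}" for i in range(12)]
            edges = [
                (a, b)
                for i, a in enumerate(nodes)
                for b in nodes[i + 1 :]
                if rng.random() < 0.3
            ]
            cases.append(edges)
        for edges in cases:
            nodes = sorted({n for e in edges for n in e})
            g = self._graph(edges, nodes)
            adj = {n: set(g.neighbors(n)) for n in g.nodes}
            assert initial_clusters(g) == _greedy_oracle(adj)


class TestConsensus:
    def test_single_member_identity(self):
        rng = np.random.default_rng(8)
        seq = _rand(rng, 500)
        assert dag_consensus([(seq, None)]) == seq

    def test_identical_members(self):
        rng = np.random.default_rng(9)
        seq = _rand(rng, 700)
        assert dag_consensus([(seq, [30] * len(seq))] * 5) == seq

    def test_twenty_noisy_reads_recover_truth(self):
        """20 reads of a 1-kb transcript at 10% error: the consensus
        lands within edit distance 2 of the true sequence."""
        import edlib

        rng = np.random.default_rng(10)
        truthseq = _rand(rng, 1000)
        reads = [
            (_corrupt(rng, truthseq, (0.01, 0.05, 0.04)), [10] * 1200)
            for _ in range(20)
        ]
        reads = [(s, q[: len(s)]) for s, q in reads]
        cons = dag_consensus(reads)
        d = edlib.align(cons, truthseq, mode="NW")["editDistance"]
        assert d <= 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        truthseq = _rand(rng, 800)
        members = [
            (_corrupt(rng, truthseq, (0.005, 0.01, 0.01)), None) for _ in range(8)
        ]
        cons1 = dag_consensus(members)
        rng2 = random.Random(3)
        shuffled = members[:]
        rng2.shuffle(shuffled)
        assert dag_consensus(shuffled) == cons1


class TestReassignAndPolish:
    def test_fixed_point_no_moves(self):
        rng = np.random.default_rng(12)
        a, b = _rand(rng, 600), _rand(rng, 600)
        fl = {f"a{i}": a for i in range(3)} | {f"b{i}": b for i in range(3)}
        clusters = [["a0", "a1", "a2"], ["b0", "b1", "b2"]]
        out = reassign(fl, clusters)
        got = sorted(tuple(c.fl_members) for c in out)
        assert got == [("a0", "a1", "a2"), ("b0", "b1", "b2")]

    def test_misassigned_read_moves_home(self):
        rng = np.random.default_rng(13)
        a, b = _rand(rng, 600), _rand(rng, 600)
        fl = {f"a{i}": a for i in range(4)} | {f"b{i}": b for i in range(4)}
        clusters = [["a0", "a1", "a2", "b3"], ["b0", "b1", "b2", "a3"]]
        out = reassign(fl, clusters)
        got = sorted(tuple(sorted(c.fl_members)) for c in out)
        assert got == [("a0", "a1", "a2", "a3"), ("b0", "b1", "b2", "b3")]

    def test_error_threshold_boundary(self):
        """predicted_errors 10.5 is discarded, 9.5 retained ('more than
        10 errors are discarded')."""
        mk = lambda i, pe: IsoCluster(f"c{i}", ["r"], consensus="ACGT",
                                      predicted_errors=pe)
        kept = filter_by_predicted_errors([mk(0, 10.5), mk(1, 9.5), mk(2, 10.0)])
        assert [c.predicted_errors for c in kept] == [9.5, 10.0]

    def test_errorfree_cluster_zero_predicted_errors(self):
        rng = np.random.default_rng(14)
        seq = _rand(rng, 500)
        members = [(seq, [40] * len(seq))] * 6
        assert predicted_error_count(seq, members) < 0.1

    def test_nfl_recruitment(self, truth_small):
        """>=90% of recruited 5'-degraded reads are sequence-consistent
        with their cluster's isoform (a truncated read that lost the
        distinguishing splice site is legitimately ambiguous between
        same-locus isoforms, so consistency — not identity of labels —
        is the recruitment contract)."""
        import edlib

        from longform.align import stats_from_cigar

        truth = truth_small
        cfg = truth.config
        raw = [RawRead(r, s, tuple(q)) for r, s, q in truth._read_seqs]
        out = classify_reads(raw, cfg.primer5, cfg.primer3)
        fl = {o.id: o.trimmed_seq for o in out if o.classification == FULL_LENGTH}
        nfl = {o.id: o.trimmed_seq for o in out
               if o.classification != FULL_LENGTH and len(o.trimmed_seq) >= 50}
        quals = {o.id: list(o.trimmed_qual) for o in out if o.trimmed_qual}
        params = params_for_error(0.02)
        clusters = cluster_pipeline(fl, nfl, params, quals)
        truthmap = {r.id: r.isoform_id for r in truth.reads}
        iso_seq = {i.id: i.seq(truth.genome) for i in truth.isoforms}
        from collections import Counter

        good = total = exact = 0
        for c in clusters:
            maj = Counter(truthmap[r] for r in c.fl_members).most_common(1)[0][0]
            for r in c.nfl_members:
                total += 1
                exact += truthmap[r] == maj
                res = edlib.align(nfl[r][::-1], iso_seq[maj][::-1],
                                  mode="HW", task="path")
                st = stats_from_cigar(res["cigar"])
                off3 = res["locations"][0][0] or 0
                cov = (st.matches + st.mismatches) / len(nfl[r])
                good += off3 <= 30 and cov >= 0.9 and st.identity >= 0.9
        assert total > 0
        assert good / total >= 0.90
        assert exact / total >= 0.5  # labels still mostly recoverable


def test_cluster_pipeline_recovers_junction_chains(truth_small):
    """End of the clustering stage: every abundant true isoform's
    junction chain is represented by some polished consensus."""
    truth = truth_small
    cfg = truth.config
    raw = [RawRead(r, s, tuple(q)) for r, s, q in truth._read_seqs]
    out = classify_reads(raw, cfg.primer5, cfg.primer3)
    fl = {o.id: o.trimmed_seq for o in out if o.classification == FULL_LENGTH}
    quals = {o.id: list(o.trimmed_qual) for o in out if o.trimmed_qual}
    clusters = cluster_pipeline(fl, {}, params_for_error(0.02), quals)
    from longform.splicemap import GenomeIndex, spliced_align

    gidx = GenomeIndex(truth.genome)
    got_chains = set()
    for c in clusters:
        aln = spliced_align(c.consensus, gidx)
        if aln:
            got_chains.add((aln.chain.strand, aln.chain.junctions))
    want = {(i.chain.strand, i.chain.junctions) for i in truth.isoforms}
    recovered = sum(1 for w in want if w in got_chains)
    assert recovered / len(want) >= 0.90
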