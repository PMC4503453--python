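"""ORF finding, polycistronic calls, short-read validation, expression
tiers and the tandem-duplicate enrichment test."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longform import SimConfig, simulate_all, simulate_short_read_support
from longform.orfscan import (
    ORF,
    check_inter_orf_stops,
    call_polycistronic,
    expression_tiers,
    find_orfs,
    scan_transcripts,
    tandem_enrichment,
    validate_shortread,
)
from longform.pipeline import truth_alignments
from longform.sim import STOP_CODONS


def _rand(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _orf_oracle(seq, min_aa):
    """Independent enumeration: regex-free frame scan + the same greedy
    selection applied by hand."""
    cands = []
    for f in range(3):
        open_starts = []
        for p in range(f, len(seq) - 2, 3):
            c = seq[p : p + 3]
            if c == "ATG":
                open_starts.append(p)
            elif c in ("TAA", "TAG", "TGA"):
                for s in open_starts:
                    aa = (p + 3 - s) // 3 - 1
                    if aa >= min_aa:
                        cands.append((s, p + 3, aa))
                open_starts = []
    chosen = []
    for s, e, aa in sorted(cands, key=lambda x: (-x[2], x[0])):
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, aa))
    return sorted(chosen)


class TestFindOrfs:
    def test_no_orfs_in_poly_c(self):
        assert find_orfs("C" * 900) == []

    def test_two_disjoint_orfs_in_order(self):
        rng = np.random.default_rng(0)
        orf1 = "ATG" + "GCT" * 120 + "TAA"
        orf2 = "ATG" + "CAT" * 150 + "TGA"
        gap = "TAATAATAA" + "".join(
            c for c in _rand(rng, 291) if True
        ).replace("ATG", "CCG")
        seq = "CCC" + orf1 + gap + orf2 + "CCC"
        got = find_orfs(seq)
        assert len(got) == 2
        # aa_length counts ATG plus the body codons, not the stop
        assert got[0].aa_length == 121 and got[1].aa_length == 151
        assert got[0].start < got[1].start

    def test_matches_exhaustive_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = _rand(rng, int(rng.integers(300, 2000)))
            got = [(o.start, o.end, o.aa_length) for o in find_orfs(seq, 20)]
            assert got == _orf_oracle(seq, 20)

    def test_greedy_consistency(self):
        """Removing the greedy winner (and everything overlapping it)
        from the candidate pool and re-running the selection yields the
        remainder of the original selection."""
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(30):
            seq = _rand(rng, 1500)
            sel = find_orfs(seq, 20)
            if len(sel) < 2:
                continue
            checked += 1
            winner = max(sel, key=lambda o: (o.aa_length, -o.start))
            cands = _orf_oracle(seq, 20)
            remaining = [
                (s, e, aa)
                for s, e, aa in cands
                if e <= winner.start or s >= winner.end
            ]
            chosen = []
            for s, e, aa in sorted(remaining, key=lambda x: (-x[2], x[0])):
                if all(e <= cs or s >= ce for cs, ce, _ in chosen):
                    chosen.append((s, e, aa))
            assert sorted(chosen) == [
                (o.start, o.end, o.aa_length) for o in sel if o != winner
            ]
        assert checked > 0

    def test_min_aa_boundary(self):
        orf99 = "ATG" + "GCT" * 98 + "TAA"  # aa_length 99
        orf100 = "ATG" + "GCT" * 99 + "TAA"  # aa_length 100
        assert find_orfs("CC" + orf99 + "CC", 100) == []
        got = find_orfs("CC" + orf100 + "CC", 100)
        assert len(got) == 1 and got[0].aa_length == 100

    def test_orf_invariants(self):
        with pytest.raises(ValueError):
            ORF("t", 0, 10, 0)  # not divisible by 3


class TestInterOrfStops:
    def test_constructed_all_frames(self):
        # gap carries TAA at offsets 3, 7 and 11 — one per frame
        gap = "C" + "ATTAATTAATTAA" + "C"
        orf_a = ORF("t", 0, 300, 0)
        orf_b = ORF("t", 300 + len(gap), 300 + len(gap) + 303, 0)
        seq = "A" * 300 + gap + "G" * 303
        flags, allf = check_inter_orf_stops(seq, orf_a, orf_b)
        assert allf and flags == (True, True, True)

    def test_poly_c_gap_no_stops(self):
        orf_a = ORF("t", 0, 300, 0)
        orf_b = ORF("t", 600, 903, 0)
        seq = "A" * 300 + "C" * 300 + "G" * 303
        flags, allf = check_inter_orf_stops(seq, orf_a, orf_b)
        assert flags == (False, False, False) and not allf

    def test_degenerate_tiny_gap(self):
        orf_a = ORF("t", 0, 300, 0)
        orf_b = ORF("t", 302, 605, 0)
        flags, allf = check_inter_orf_stops("A" * 700, orf_a, orf_b)
        assert flags == (False, False, False) and not allf

    def test_random_gaps_match_codon_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            gap = _rand(rng, 300)
            seq = "A" * 300 + gap + "G" * 300
            orf_a, orf_b = ORF("t", 0, 300, 0), ORF("t", 600, 900, 0)
            flags, _ = check_inter_orf_stops(seq, orf_a, orf_b)
            want = tuple(
                any(gap[p : p + 3] in STOP_CODONS
                    for p in range(f, len(gap) - 2, 3))
                for f in range(3)
            )
            assert flags == want


class TestPolycistronicCalls:
    def test_sim_ptu_contained(self, truth_default_errorfree):
        t = truth_default_errorfree
        alns = truth_alignments(t)
        iso = t.ptu_isoforms()[0]
        seq = iso.seq(t.genome)
        orfs = find_orfs(seq, 100, iso.id)
        call = call_polycistronic(iso.id, seq, orfs, alns[iso.id], t.genes)
        assert call is not None
        assert call.category == "contained_2_4"
        assert set(call.contained_genes) == set(iso.gene_ids)
        assert all(call.stops_all_frames)

    def test_monocistronic_not_called(self, truth_default_errorfree):
        t = truth_default_errorfree
        alns = truth_alignments(t)
        iso = next(i for i in t.isoforms if i.kind == "canonical")
        seq = iso.seq(t.genome)
        orfs = find_orfs(seq, 100, iso.id)
        assert call_polycistronic(iso.id, seq, orfs, alns[iso.id], t.genes) is None

    def test_full_sim_calls_equal_manifest(self, truth_default_errorfree):
        """On error-free transcripts, the PTU call set equals the
        manifest readthrough list exactly (precision = recall = 1)."""
        t = truth_default_errorfree
        seqs = {i.id: i.seq(t.genome) for i in t.isoforms}
        _, calls = scan_transcripts(seqs, truth_alignments(t), t.genes)
        got = {c.transcript_id: frozenset(c.contained_genes) for c in calls}
        want = {i.id: frozenset(i.gene_ids) for i in t.ptu_isoforms()}
        assert got == want


class TestValidateShortread:
    @pytest.fixture(scope="class")
    def setup(self, truth_default_errorfree):
        t = truth_default_errorfree
        seqs = {i.id: i.seq(t.genome) for i in t.isoforms}
        alns = truth_alignments(t)
        _, calls = scan_transcripts(seqs, alns, t.genes)
        cov, junc = simulate_short_read_support(
            t.isoforms, t.abundances, t.config
        )
        return t, alns, calls, cov, junc

    def test_uniform_coverage_validates(self, setup):
        t, alns, calls, cov, junc = setup
        c = calls[0]
        chain = alns[c.transcript_id].chain
        assert validate_shortread(c, chain, cov, junc) is True

    def test_single_zero_base_fails(self, setup):
        t, alns, calls, cov, junc = setup
        c = calls[0]
        chain = alns[c.transcript_id].chain
        pos = chain.genomic_positions()
        hole = pos[c.orfs[0].end + 5]
        cov2 = cov[~((cov["chrom"] == chain.chrom) & (cov["pos"] == hole))]
        assert validate_shortread(c, chain, cov2, junc) is False

    def test_min_cov_boundary(self, setup):
        t, alns, calls, cov, junc = setup
        c = calls[0]
        chain = alns[c.transcript_id].chain
        cov10 = cov.copy()
        cov10["coverage"] = 10.0
        assert validate_shortread(c, chain, cov10, junc, min_cov=10) is True
        cov9 = cov.copy()
        cov9["coverage"] = 9.0
        assert validate_shortread(c, chain, cov9, junc, min_cov=10) is False

    def test_flags_equal_direct_rule(self, setup):
        t, alns, calls, cov, junc = setup
        covmap = {(c_, p): v for c_, p, v in
                  zip(cov["chrom"], cov["pos"], cov["coverage"])}
        supmap = {(c_, d, a): s for c_, d, a, s in
                  zip(junc["chrom"], junc["donor"], junc["acceptor"],
                      junc["support"])}
        for call in calls[:5]:
            chain = alns[call.transcript_id].chain
            pos = chain.genomic_positions()
            want = all(
                covmap.get((chain.chrom, pos[p]), 0) >= 10
                for a, b in zip(call.orfs, call.orfs[1:])
                for p in range(a.end, b.start)
            ) and all(
                supmap.get((chain.chrom, d, a), 0) >= 1
                for d, a in chain.junctions
            )
            assert validate_shortread(call, chain, cov, junc) == want


class TestExpressionTiers:
    def test_downstream_lower_every_ptu(self, truth_default_errorfree):
        """downstream_tier_factor 0.5 at depth 20: ORF1's independent
        count exceeds ORF2's for every simulated readthrough unit."""
        t = truth_default_errorfree
        seqs = {i.id: i.seq(t.genome) for i in t.isoforms}
        alns = truth_alignments(t)
        _, calls = scan_transcripts(seqs, alns, t.genes)
        tiers = expression_tiers(calls, alns, t.fl_read_counts(), t.genes)
        assert len(tiers) > 0
        for tx, grp in tiers.groupby("ptu_transcript"):
            g = grp.sort_values("orf_index")
            assert g.independent_fl_count.iloc[0] > g.independent_fl_count.iloc[1]

    def test_no_ptus_empty_table(self, truth_default_errorfree):
        t = truth_default_errorfree
        tiers = expression_tiers([], truth_alignments(t), {}, t.genes)
        assert tiers.empty


class TestTandemEnrichment:
    def test_k_zero_is_one(self):
        assert tandem_enrichment(100, 20, 30, 0) == 1.0

    def test_analytic_single_term(self):
        assert tandem_enrichment(10, 5, 5, 5) == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_exact_rational_oracle(self):
        rng = np.random.default_rng(4)

        def comb(a, b):
            from math import comb as c

            return Fraction(c(a, b))

        for _ in range(60):
            N = int(rng.integers(5, 80))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            kmax = min(K, n)
            k = int(rng.integers(0, kmax + 1))
            if kmax > N:
                continue
            want = sum(
                (comb(K, i) * comb(N - K, n - i)) / comb(N, n)
                for i in range(k, kmax + 1)
                if n - i <= N - K
            )
            got = tandem_enrichment(N, K, n, k)
            assert got == pytest.approx(float(want), rel=1e-12)

    @given(st.integers(10, 60), st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_nonincreasing_in_k(self, N, data):
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ks = range(0, min(K, n) + 1)
        ps = [tandem_enrichment(N, K, n, k) for k in ks]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            tandem_enrichment(10, 12, 5, 1)
        with pytest.raises(ValueError):
            tandem_enrichment(10, 5, 5, 6)
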