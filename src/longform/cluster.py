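"""Isoform-level clustering of full-length reads and consensus polishing.

The stages mirror iterative isoform clustering (ICE-style):

1. a similarity graph over full-length reads, with edges where two reads
   plausibly derive from the same isoform (overlap alignment sharing the
   3' end, no long internal gap, sufficient identity);
2. a deterministic greedy maximal-clique cover seeding one cluster per
   clique;
3. a quality-weighted partial-order (backbone-anchored) consensus per
   cluster;
4. likelihood-based reassignment of reads between clusters until a fixed
   point (or ``max_iter``);
5. recruitment of non-full-length reads, final consensus, and discarding
   of clusters whose expected error count exceeds ``max_errors``.

The expensive primitives ride on edlib; everything above them is pure
Python with explicit deterministic tie-breaks, so a permuted input
yields the same final consensus multiset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import edlib
import networkx as nx
import numpy as np

from .align import cigar_ops, log_likelihood, stats_from_cigar


@dataclass(frozen=True)
class ClusterParams:
    tol3: int = 30  # max 3'-end offset for same-isoform / recruitment
    tol5: int = 200  # max 5'-start offset; absorbs moderate 5' degradation
    min_cov: float = 0.9  # min covered fraction of the shorter read
    max_internal_gap: int = 20  # proxy for a skipped exon
    min_ident: float = 0.70  # suits ~15% per-read error; see params_for_error
    k: int = 15
    kmer_sample_mod: int = 10  # keep k-mers with hash % mod == 0
    min_shared_kmers: int = 2
    max_iter: int = 10
    max_errors: float = 10.0
    consensus_rounds: int = 2
    nfl_min_cov: float = 0.95
    error_rates: tuple[float, float, float] = (0.01, 0.08, 0.06)


def params_for_error(total_error: float, **over) -> ClusterParams:
    """Derive alignment thresholds from the declared per-read error rate:
    identity between two reads of one isoform is ~1 - 2e, with slack."""
    min_ident = max(0.70, 1.0 - 2.5 * total_error)
    e = total_error
    rates = (e / 15.0, 8 * e / 15.0, 6 * e / 15.0) if e > 0 else (0.005, 0.005, 0.005)
    return replace(ClusterParams(), min_ident=min_ident, error_rates=rates, **over)


@dataclass
class IsoCluster:
    id: str
    fl_members: list[str]
    nfl_members: list[str] = field(default_factory=list)
    consensus: str = ""
    predicted_errors: float = 0.0


# ------------------------------------------------------------ same_isoform


def same_isoform(
    a: str, b: str, params: ClusterParams = ClusterParams()
) -> tuple[bool, dict]:
    """Do two transcript-sense sequences look like reads of one isoform?

    True iff an overlap alignment anchored at the 3' ends (gap at the 5'
    end of the later-starting sequence only, bounded by ``tol5``)
    reaches both 3' ends within ``tol3``, covers >= ``min_cov`` of the
    shorter sequence, has no internal gap run longer than
    ``max_internal_gap`` and identity >= ``min_ident``. The 5' bound
    keeps a transcript from being absorbed by a longer readthrough
    transcript that merely contains it.
    """
    if not a or not b:
        return False, {"reason": "empty_sequence"}
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    # reverse both so the 3' ends sit at the alignment start; HW leaves
    # the (reversed) target's tail — the longer read's 5' extension — free
    res = edlib.align(short[::-1], long_[::-1], mode="HW", task="path")
    loc = res["locations"][0]
    off3_target = loc[0] if loc[0] else 0
    ops = cigar_ops(res["cigar"])
    off3_query = ops[0][0] if ops and ops[0][1] == "I" else 0
    off5_query = ops[-1][0] if ops and ops[-1][1] == "I" else 0
    end_t = loc[1] if loc[1] is not None else len(long_) - 1
    off5_target = len(long_) - 1 - end_t
    st = stats_from_cigar(res["cigar"])
    covered = st.matches + st.mismatches
    cov = covered / len(short)
    summary = {
        "identity": st.identity,
        "coverage": cov,
        "max_internal_gap": st.max_internal_gap,
        "offset3": off3_target + off3_query,
        "offset5": off5_target + off5_query,
        "edit_distance": res["editDistance"],
    }
    ok = (
        summary["offset3"] <= params.tol3
        and summary["offset5"] <= params.tol5
        and cov >= params.min_cov
        and st.max_internal_gap <= params.max_internal_gap
        and st.identity >= params.min_ident
    )
    return ok, summary


# -------------------------------------------------------- similarity graph


def _sampled_kmers(seq: str, k: int, mod: int) -> set[str]:
    return {
        seq[i : i + k]
        for i in range(len(seq) - k + 1)
        if hash_kmer(seq[i : i + k]) % mod == 0
    }


def hash_kmer(kmer: str) -> int:
    # order-2 polynomial hash; deterministic across processes (unlike hash())
    h = 0
    for c in kmer:
        h = (h * 131 + ord(c)) & 0x7FFFFFFF
    return h


def candidate_pairs(
    seqs: dict[str, str], params: ClusterParams
) -> set[tuple[str, str]]:
    """Shared-k-mer prefilter: unordered id pairs sharing at least
    ``min_shared_kmers`` sampled k-mers. A superset of the true edge set
    on error-free data (identical reads share every sampled k-mer)."""
    buckets: dict[str, list[str]] = {}
    for rid in sorted(seqs):
        for km in _sampled_kmers(seqs[rid], params.k, params.kmer_sample_mod):
            buckets.setdefault(km, []).append(rid)
    counts: dict[tuple[str, str], int] = {}
    for rids in buckets.values():
        if len(rids) < 2 or len(rids) > 2000:
            continue
        for i in range(len(rids)):
            for j in range(i + 1, len(rids)):
                pair = (rids[i], rids[j])
                counts[pair] = counts.get(pair, 0) + 1
    return {p for p, c in counts.items() if c >= params.min_shared_kmers}


def build_similarity_graph(
    fl_reads: dict[str, str], params: ClusterParams = ClusterParams()
) -> nx.Graph:
    if not fl_reads:
        raise ValueError("need at least one read")
    g = nx.Graph()
    g.add_nodes_from(sorted(fl_reads))
    for i, j in sorted(candidate_pairs(fl_reads, params)):
        ok, summary = same_isoform(fl_reads[i], fl_reads[j], params)
        if ok:
            g.add_edge(i, j, **summary)
    return g


def initial_clusters(graph: nx.Graph) -> list[list[str]]:
    """Deterministic greedy maximal-clique cover.

    Seed with the highest-degree unassigned node (ties: lexicographic
    id); grow by repeatedly adding the unassigned neighbour adjacent to
    all current members with the highest degree (same tie-break)."""
    deg = dict(graph.degree())
    unassigned = set(graph.nodes)
    clusters: list[list[str]] = []
    order = sorted(graph.nodes, key=lambda n: (-deg[n], n))
    for seed in order:
        if seed not in unassigned:
            continue
        clique = [seed]
        cand = set(graph.neighbors(seed)) & unassigned
        while cand:
            nxt = min(cand, key=lambda n: (-deg[n], n))
            clique.append(nxt)
            cand &= set(graph.neighbors(nxt))
            cand.discard(nxt)
        unassigned -= set(clique)
        clusters.append(sorted(clique))
    return clusters


# ------------------------------------------------------------- consensus


_SYMBOLS = "ACGT-"
_SYM_IDX = {c: i for i, c in enumerate(_SYMBOLS)}


def _column_votes(
    backbone: str, members: list[tuple[str, list[float]]]
) -> tuple[list[np.ndarray], list[dict[str, float]]]:
    """Align members to the backbone and accumulate per-column weights
    over {A,C,G,T,-} plus weighted insertion strings after each column."""
    ncol = len(backbone)
    votes = [np.zeros(5) for _ in range(ncol)]
    inserts: list[dict[str, float]] = [dict() for _ in range(ncol + 1)]
    for seq, probs in members:
        res = edlib.align(seq, backbone, mode="HW", task="path")
        tpos = res["locations"][0][0] or 0
        qpos = 0
        mean_p = sum(probs) / len(probs) if probs else 0.9
        for n, op in cigar_ops(res["cigar"]):
            if op in "=X":
                for _ in range(n):
                    votes[tpos][_SYM_IDX.get(seq[qpos], 0)] += probs[qpos]
                    tpos += 1
                    qpos += 1
            elif op == "D":  # gap in query at backbone columns
                for _ in range(n):
                    votes[tpos][4] += mean_p
                    tpos += 1
            else:  # insertion relative to backbone
                ins = seq[qpos : qpos + n]
                w = sum(probs[qpos : qpos + n]) / n
                d = inserts[tpos]
                d[ins] = d.get(ins, 0.0) + w
                qpos += n
    return votes, inserts


def dag_consensus(
    members: list[tuple[str, list[float] | None]],
    rounds: int = 2,
) -> str:
    """Quality-weighted partial-order consensus.

    Members are inserted in decreasing length order (ties by sequence);
    the first fixes the backbone coordinate frame, the rest contribute
    weighted votes to backbone columns and insertion branches. The
    consensus is the heaviest path: per column the symbol with the
    largest summed correctness-probability mass ('-' deletes the
    column), plus any insertion carrying more mass than the gap votes
    around it. A second round re-anchors on the first-round consensus to
    remove backbone-specific errors.
    """
    if not members:
        raise ValueError("need at least one member")
    prepared = []
    for seq, quals in members:
        if quals is None:
            probs = [0.9] * len(seq)
        else:
            probs = [1.0 - 10.0 ** (-q / 10.0) for q in quals]
        prepared.append((seq, probs))
    prepared.sort(key=lambda m: (-len(m[0]), m[0]))
    if len(prepared) == 1:
        return prepared[0][0]
    backbone = prepared[0][0]
    for _ in range(rounds):
        cons = _assemble(backbone, prepared)
        if cons == backbone:
            break
        backbone = cons
    return backbone


def _assemble(backbone: str, prepared: list[tuple[str, list[float]]]) -> str:
    votes, inserts = _column_votes(backbone, prepared)
    total = [v.sum() for v in votes]
    out: list[str] = []
    for i in range(len(backbone)):
        ins = inserts[i]
        if ins:
            best_ins = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            no_ins_w = max(total[i] - sum(ins.values()), 0.0)
            if best_ins[1] > no_ins_w:
                out.append(best_ins[0])
        v = votes[i]
        sym = _SYMBOLS[int(np.argmax(v))] if v.sum() > 0 else backbone[i]
        if sym != "-":
            out.append(sym)
    ins = inserts[len(backbone)]
    if ins:
        best_ins = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
        if best_ins[1] > (total[-1] if total else 0.0) / 2.0:
            out.append(best_ins[0])
    return "".join(out)


def predicted_error_count(
    consensus: str, members: list[tuple[str, list[float] | None]]
) -> float:
    """Expected number of consensus errors: sum over columns of
    (1 - p_column), where p_column is the posterior mass of the plurality
    symbol under independent quality-derived observation errors."""
    if not members:
        return float(len(consensus))
    loglik = np.zeros((len(consensus), 5))
    cover = np.zeros(len(consensus))
    for seq, quals in members:
        probs = (
            [1.0 - 10.0 ** (-q / 10.0) for q in quals]
            if quals is not None
            else [0.9] * len(seq)
        )
        res = edlib.align(seq, consensus, mode="HW", task="path")
        tpos = res["locations"][0][0] or 0
        qpos = 0
        for n, op in cigar_ops(res["cigar"]):
            if op in "=X":
                for _ in range(n):
                    p = min(max(probs[qpos], 0.5), 1.0 - 1e-6)
                    obs = _SYM_IDX.get(seq[qpos], 0)
                    row = np.full(5, math.log((1.0 - p) / 4.0))
                    row[obs] = math.log(p)
                    loglik[tpos] += row
                    cover[tpos] += 1
                    tpos += 1
                    qpos += 1
            elif op == "D":
                for _ in range(n):
                    p = 0.9
                    row = np.full(5, math.log((1.0 - p) / 4.0))
                    row[4] = math.log(p)
                    loglik[tpos] += row
                    cover[tpos] += 1
                    tpos += 1
            else:
                qpos += n
    err = 0.0
    for i in range(len(consensus)):
        if cover[i] == 0:
            err += 1.0
            continue
        row = loglik[i] - loglik[i].max()
        post = np.exp(row)
        err += 1.0 - post.max() / post.sum()
    return float(err)


# ------------------------------------------------------------- reassignment


def anchored_log_likelihood(
    read: str, consensus: str, params: ClusterParams
) -> float:
    """Log-likelihood of a read given a cluster consensus under the
    configured error model, with the 3' ends anchored (within ``tol3``)
    and the 5' offset bounded by ``tol5``; -inf when the ends are
    incompatible, so a read cannot defect to a cluster that merely
    contains it."""
    if not read or not consensus:
        return -math.inf
    res = edlib.align(read[::-1], consensus[::-1], mode="HW", task="path")
    loc = res["locations"][0]
    ops = cigar_ops(res["cigar"])
    off3 = (loc[0] or 0) + (ops[0][0] if ops and ops[0][1] == "I" else 0)
    off5_q = ops[-1][0] if ops and ops[-1][1] == "I" else 0
    end_t = loc[1] if loc[1] is not None else len(consensus) - 1
    off5_t = len(consensus) - 1 - end_t
    if off3 > params.tol3 or max(off5_q, off5_t) > params.tol5:
        return -math.inf
    sub, ins, dele = (max(r, 1e-6) for r in params.error_rates)
    p_match = max(1.0 - sub - ins - dele, 1e-6)
    st = stats_from_cigar(res["cigar"])
    return (
        st.matches * math.log(p_match)
        + st.mismatches * math.log(sub / 3.0)
        + st.t_gap * math.log(ins / 4.0)
        + st.q_gap * math.log(dele)
    )


def _consensus_index(clusters: list[IsoCluster], params: ClusterParams):
    idx: dict[str, list[str]] = {}
    for c in clusters:
        for km in _sampled_kmers(c.consensus, params.k, params.kmer_sample_mod):
            idx.setdefault(km, []).append(c.id)
    return idx


def _candidates_for(
    seq: str, idx, params: ClusterParams, min_shared: int
) -> list[str]:
    counts: dict[str, int] = {}
    for km in _sampled_kmers(seq, params.k, params.kmer_sample_mod):
        for cid in idx.get(km, ()):
            counts[cid] = counts.get(cid, 0) + 1
    return sorted(c for c, n in counts.items() if n >= min_shared)


def reassign(
    fl_reads: dict[str, str],
    clusters: list[list[str]],
    params: ClusterParams = ClusterParams(),
    quals: dict[str, list[float]] | None = None,
) -> list[IsoCluster]:
    """Iteratively move each read to the cluster whose consensus gives it
    the best alignment log-likelihood (ties: current cluster, then
    lexicographic cluster id); consensuses are recomputed after each
    sweep until no read moves or ``max_iter`` sweeps."""
    quals = quals or {}
    out = [
        IsoCluster(id=f"c{i:05d}", fl_members=sorted(m))
        for i, m in enumerate(sorted(clusters, key=lambda m: sorted(m)[0]))
    ]

    def members_of(c: IsoCluster):
        return [(fl_reads[r], quals.get(r)) for r in c.fl_members]

    cons_cache: dict[tuple[str, ...], str] = {}

    def refresh(cl: list[IsoCluster]) -> None:
        for c in cl:
            key = tuple(c.fl_members)
            if key not in cons_cache:
                cons_cache[key] = dag_consensus(members_of(c),
                                                params.consensus_rounds)
            c.consensus = cons_cache[key]

    refresh(out)
    for _ in range(params.max_iter):
        idx = _consensus_index(out, params)
        by_id = {c.id: c for c in out}
        assignment = {r: c.id for c in out for r in c.fl_members}
        moves = 0
        for rid in sorted(fl_reads):
            cur = assignment[rid]
            cand = _candidates_for(fl_reads[rid], idx, params,
                                   params.min_shared_kmers)
            if cur not in cand:
                cand.append(cur)
            scored = [
                (anchored_log_likelihood(fl_reads[rid], by_id[cid].consensus,
                                         params), cid)
                for cid in sorted(cand)
            ]
            top = max(ll for ll, _ in scored)
            if top == -math.inf:
                continue
            tied = [cid for ll, cid in scored if ll >= top - 1e-9]
            best_id = cur if cur in tied else min(tied)
            if best_id != cur:
                assignment[rid] = best_id
                moves += 1
        if moves == 0:
            break
        regroup: dict[str, list[str]] = {}
        for rid, cid in assignment.items():
            regroup.setdefault(cid, []).append(rid)
        out = [
            IsoCluster(id=cid, fl_members=sorted(rids))
            for cid, rids in sorted(regroup.items())
        ]
        refresh(out)
    return out


# ----------------------------------------------------------------- polish


def polish(
    clusters: list[IsoCluster],
    nfl_reads: dict[str, str],
    params: ClusterParams = ClusterParams(),
    fl_reads: dict[str, str] | None = None,
    quals: dict[str, list[float]] | None = None,
) -> list[IsoCluster]:
    """Recruit non-full-length reads, recompute the weighted consensus
    over all members, estimate the expected error count, and drop
    clusters with more than ``max_errors`` predicted errors."""
    quals = quals or {}
    fl_reads = fl_reads or {}
    sub, ins, dele = params.error_rates
    idx = _consensus_index(clusters, params)
    by_id = {c.id: c for c in clusters}
    for c in clusters:
        c.nfl_members = []
    for rid in sorted(nfl_reads):
        seq = nfl_reads[rid]
        best = None
        for cid in _candidates_for(seq, idx, params, params.min_shared_kmers):
            cons = by_id[cid].consensus
            res = edlib.align(seq[::-1], cons[::-1], mode="HW", task="path")
            off3 = res["locations"][0][0] or 0
            st = stats_from_cigar(res["cigar"])
            cov = (st.matches + st.mismatches) / len(seq)
            if off3 > params.tol3 or cov < params.nfl_min_cov:
                continue
            ll = log_likelihood(seq, cons, sub, ins, dele)
            key = (ll, cid)
            if best is None or key > best[0]:
                best = (key, cid)
        if best is not None:
            by_id[best[1]].nfl_members.append(rid)

    kept: list[IsoCluster] = []
    for c in clusters:
        members = [(fl_reads.get(r, ""), quals.get(r)) for r in c.fl_members]
        members = [(s, q) for s, q in members if s] or [(c.consensus, None)]
        members += [(nfl_reads[r], quals.get(r)) for r in c.nfl_members]
        c.consensus = dag_consensus(members, params.consensus_rounds)
        c.predicted_errors = predicted_error_count(c.consensus, members)
        kept.append(c)
    return filter_by_predicted_errors(kept, params.max_errors)


def filter_by_predicted_errors(
    clusters: list[IsoCluster], max_errors: float = 10.0
) -> list[IsoCluster]:
    """Keep clusters with predicted_errors <= max_errors (strictly more
    than the threshold is discarded)."""
    return [c for c in clusters if c.predicted_errors <= max_errors]


def cluster_pipeline(
    fl_reads: dict[str, str],
    nfl_reads: dict[str, str] | None = None,
    params: ClusterParams = ClusterParams(),
    quals: dict[str, list[float]] | None = None,
) -> list[IsoCluster]:
    """similarity graph -> clique cover -> consensus -> reassignment ->
    non-FL recruitment and polishing."""
    graph = build_similarity_graph(fl_reads, params)
    seeds = initial_clusters(graph)
    clusters = reassign(fl_reads, seeds, params, quals)
    return polish(clusters, nfl_reads or {}, params, fl_reads, quals)
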