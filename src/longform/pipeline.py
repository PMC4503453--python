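"""End-to-end driver: reads -> full-length classification -> clustering
and polishing -> spliced mapping -> acceptance filter -> collapse ->
locus assignment. Convenience layer used by the CLI, the examples and
the acceptance analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

from .chains import ExonChain
from .classify import FULL_LENGTH, ClassifyParams, FLRead, RawRead, classify_reads
from .cluster import IsoCluster, cluster_pipeline, params_for_error
from .collapse import CollapseResult, collapse_mapped
from .splicemap import (
    SplicedAlignment,
    SpliceMapParams,
    assign_loci,
    filter_alignments,
    map_transcripts,
)


@dataclass
class PipelineResult:
    classifications: list[FLRead]
    clusters: list[IsoCluster]
    alignments: dict[str, SplicedAlignment]
    accepted: dict[str, SplicedAlignment]
    collapse: CollapseResult
    loci: dict[str, str]

    @property
    def transcripts(self) -> dict[str, str]:
        """Final non-redundant transcript sequences (cluster consensus)."""
        cons = {c.id: c.consensus for c in self.clusters}
        return {t: cons[t] for t in self.collapse.survivors if t in cons}

    @property
    def chains(self) -> dict[str, ExonChain]:
        return {t: self.accepted[t].chain for t in self.collapse.survivors}

    @property
    def fl_counts(self) -> dict[str, int]:
        return {c.id: len(c.fl_members) for c in self.clusters}


def run_pipeline(
    reads: list[tuple[str, str, list[int] | None]],
    primer5: str,
    primer3: str,
    genome: dict[str, str],
    error_rate: float = 0.15,
    classify_params: ClassifyParams = ClassifyParams(),
    splice_params: SpliceMapParams = SpliceMapParams(),
    min_cov: float = 0.99,
    min_ident: float = 0.85,
    tol3p: int = 30,
) -> PipelineResult:
    raw = [RawRead(rid, seq, tuple(q) if q else None) for rid, seq, q in reads]
    cls = classify_reads(raw, primer5, primer3, classify_params)
    fl = {c.id: c.trimmed_seq for c in cls if c.classification == FULL_LENGTH}
    nfl = {
        c.id: c.trimmed_seq
        for c in cls
        if c.classification != FULL_LENGTH and len(c.trimmed_seq) >= 50
    }
    quals = {
        c.id: list(c.trimmed_qual)
        for c in cls
        if c.trimmed_qual is not None and c.trimmed_seq
    }
    cparams = params_for_error(error_rate)
    clusters = cluster_pipeline(fl, nfl, cparams, quals)
    consensi = {c.id: c.consensus for c in clusters if c.consensus}
    alignments = {
        a.query_id: a for a in map_transcripts(consensi, genome, splice_params)
    }
    accepted = {
        a.query_id: a
        for a in filter_alignments(list(alignments.values()), min_cov, min_ident)
    }
    collapse = collapse_mapped(list(accepted.values()), tol3p)
    loci = assign_loci([accepted[t] for t in collapse.survivors])
    return PipelineResult(cls, clusters, alignments, accepted, collapse, loci)


def truth_alignments(truth) -> dict[str, SplicedAlignment]:
    """Perfect alignments for the simulator's ground-truth isoforms
    (used to score pipeline output against the manifest)."""
    return {
        iso.id: SplicedAlignment(iso.id, iso.chain, 1.0, 1.0)
        for iso in truth.isoforms
    }


def score_against_truth(result: PipelineResult, truth):
    """Sensitivity/specificity of the final transcript set against the
    manifest isoforms under exact splice-chain matching."""
    from .evaluate import score_sets

    ref = {iso.id: iso.chain for iso in truth.isoforms}
    query = result.chains
    union = [result.accepted[t] for t in result.collapse.survivors] + [
        SplicedAlignment(i, ch, 1.0, 1.0) for i, ch in ref.items()
    ]
    loci = assign_loci(union)
    return score_sets(query, ref, loci)
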