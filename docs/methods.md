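# Methods

This note documents the models and procedures behind each module, the
parameters that matter, and the choices made where the design was
genuinely open. Coordinates are 0-based half-open internally; GFF3 is
emitted 1-based inclusive and BED12 0-based half-open.

## Read classification

A read-of-insert is *full-length* when three features co-occur: the 5'
primer starting within `end_window` (default 100 nt) of the read 5'
end, the reverse-complemented 3' primer ending within the same window
of the 3' end, and a polyA tract immediately upstream of the 3' primer
hit. Primer hits are best semi-global edlib occurrences accepted up to
`max_edit_fraction` (default 0.3) of the primer length — tolerant
enough for ~15% read error on either strand. The polyA scan walks
3'→5' keeping the running A-fraction of the scanned suffix at or above
0.8 (length ≥ 15 nt); suffixes below the minimum length get a grace
period so a single terminal miscall cannot abort the scan, and the
reported interval is trimmed to its outermost A. Both orientations are
tried; ties break by lower summed primer edit distance, then the +
strand. A primer occurrence in the read interior (outside both end
windows) marks the read as a chimeric artifact and it is discarded,
not split. The interior scan uses a stricter edit fraction (0.2): at
0.3 a scan across a kilobase of random sequence produces spurious hits
often enough to misclassify genuine full-length reads.

## Isoform clustering and consensus

Two transcript-sense sequences are *same-isoform* when an overlap
alignment anchored at the 3' ends satisfies: 3' offset ≤ `tol3`
(30 nt, polyA-trimming jitter), 5' offset ≤ `tol5` (200 nt, moderate
5' degradation), coverage of the shorter ≥ 0.9, identity ≥
`min_ident`, and no internal gap block longer than `max_internal_gap`
(20 nt — the proxy separating sequencing indels from skipped exons).
`min_ident` is derived from the declared per-read error rate e as
max(0.70, 1 − 2.5e): two independent reads of one isoform differ at
~2e of their positions, with slack. The 5' bound exists because an
unbounded free 5' gap would make a monocistronic transcript of a
readthrough unit's last gene indistinguishable from a 5'-degraded
readthrough read, silently merging two real isoforms.

The internal-gap statistic is not the literal longest indel run of the
unit-cost alignment: edit-distance tracebacks fragment a genuine block
deletion with short coincidental match runs. Instead a signed running
sum over alignment columns (+1 per gap base in one direction, −1 in
the other, −0.1 per aligned column, floored at 0; maximum taken over
both directions) scores an unbroken block near its full length while
balanced sequencing indels stay near zero.

Candidate pairs come from a sampled shared-k-mer prefilter (k = 15,
deterministic 1-in-10 hash sampling, ≥ 2 shared k-mers), a strict
superset of true edges on error-free data. Initial clusters are a
deterministic greedy maximal-clique cover: seed at the highest-degree
unassigned node (ties lexicographic), repeatedly add the
highest-degree unassigned common neighbour.

Consensus is a quality-weighted, backbone-anchored partial-order
construction: members enter in decreasing length order, the first
fixes the coordinate frame, and the rest contribute
correctness-probability-weighted votes (p = 1 − 10^(−q/10)) to
backbone columns and insertion branches; the consensus is the heaviest
path (plurality symbol per column, '-' deletes, an insertion is
emitted when its mass exceeds the non-inserting mass). A second round
re-anchors on the first-round consensus to remove backbone-specific
errors. A general partial-order DP was rejected on cost grounds; the
backbone form preserves the same contract (single member ⇒ identity;
20 reads at 10% error land within edit distance 2 of truth, asserted
in the tests).

Reassignment scores each read against candidate cluster consensi with
an alignment log-likelihood under the error model (match/mismatch/
indel log-probabilities from the configured rates), with the same
3'/5'-anchoring gates so a read cannot defect to a cluster that merely
contains it; ties keep the current cluster, then take the
lexicographically smallest id. Sweeps repeat until no read moves (max
10). Polishing recruits non-full-length reads that align over ≥ 95% of
their own length with a compatible 3' end, recomputes the weighted
consensus, and estimates `predicted_errors` = Σ_columns (1 − p_column)
where p_column is the *posterior* mass of the plurality symbol under
independent quality-derived observation errors. Clusters with more
than 10 predicted errors are discarded. Reading "plurality mass" as a
raw vote fraction instead of a posterior would discard every cluster
(a perfect 20-read cluster at 2% error still has ~2% dissent per
column, summing to ≫ 10); the posterior reading preserves the
discard-contract's intent: singletons and junk fail, supported
clusters pass.

## Spliced alignment

A desk-scale seed-and-chain aligner: unique 15-mers of the genome
anchor the transcript, same-diagonal overlapping anchors merge into
segments (so every merged base is covered by an exact match), and the
maximum-weight co-linear chain is selected per orientation, allowing
up to one k-mer of overlap (anchors can coincidentally run past a
junction; the overlap is trimmed). Genomic gaps ≥ 40 nt become
introns. Around each intron the flanking segments are backed off 6 nt,
then donor and acceptor offsets are searched *independently* (an indel
in the query makes the two exonic flank lengths sum away from the
query gap), scoring each candidate by aligning the query gap against
the concatenated genomic flanks with a +4 bonus for canonical
donor/acceptor dinucleotides (GT..AG in transcription direction).
Smaller gaps close by global alignment; query ends extend by end-free
alignment against the adjacent genomic flank. Coverage is the aligned
query fraction and identity the matched fraction of aligned columns;
the acceptance filter keeps coverage ≥ 0.99 AND identity ≥ 0.85,
boundaries inclusive. Loci are connected components of same-strand
exonic overlap (≥ 1 bp, transitive); note a readthrough transcript
therefore fuses its member genes' loci, which is the intended reading
of this convention.

## Collapse

Mapped transcripts group (transitively) when they share the identical
junction chain and their 3' ends agree within `tol3p` = 30 nt;
single-exon transcripts group by same strand, 3' agreement and
containment. Only the longest-spanning member survives; the merge
audit records absorbed ids so transcription-start diversity remains
auditable. Alternative polyadenylation (3' ends differing by more than
the tolerance) and any junction difference are never merged;
alternative transcription starts are, by design. The reference-free
variant merges a shorter transcript into a longer one on a ≥ 0.99
coverage, ≥ 0.99 identity overlap with a free gap only at the 5' end.

## Polycistronic transcription units

ORFs are complete ATG→stop spans in the three forward frames (the
transcripts are oriented), ≥ 100 aa, reduced to a non-overlapping set
greedily by descending length; coding-potential scoring is deliberately
out of scope since downstream logic uses only ORF spans and counts. A
transcript with ≥ 2 qualifying ORFs whose alignment span covers ≥ 2
annotated same-strand genes is a call; 2-4 fully contained genes give
category `contained_2_4`, otherwise `readthrough_partial`. With an
empty annotation the ≥ 2-ORF criterion alone calls (annotation-free
mode). Each inter-ORF gap is checked for a stop codon in all three
frames. Short-read validation requires every genomic base under the
transcript's inter-ORF regions to have coverage ≥ 10 (the "minimum of
10 short-read mapped bases" is interpreted as per-base depth; the
alternative reading — minimum aligned bases per read — is not
implemented) and every junction of the transcript to have support ≥ 1.

Independent expression of member ORF k is the summed full-length read
count of monocistronic transcripts overlapping that gene and no other,
excluding reads of the polycistronic isoform itself. Tandem-duplicate
enrichment is the upper-tail hypergeometric probability computed with
log-gamma terms combined by log-sum-exp; the exact rational-arithmetic
sum serves as the test oracle (agreement to 1e-12 relative).

## Poly(A) sites and termination signals

Terminal sites are the genomic 3'-end positions of aligned
transcripts: polycistronic termini are class pORF2; a monocistronic
transcript of a gene that is a non-final member of some PTU provides
that unit's internal pORF1 site; all other monocistronic termini are
nORF. A cleavage site is a genomic feature, so transcripts sharing an
end position contribute one site — double-counting identical upstream
windows would otherwise inflate small-class fluctuations. Profiles
sample up to 200 sites without replacement (seeded, order-invariant)
and report per-position A/C/G/U frequencies over −W..−1 (W = 100) on
the transcript strand against the 0.25 uniform baseline. Element
detection slides a 6-nt window: NUE present if the maximum mean
A-frequency within −35..−5 reaches baseline + 0.15; FUE likewise for U
within −70..−25. The windows and margin are declared defaults — the
source literature defines the elements qualitatively — and the tests
rely only on class *contrast*, not absolute positions.

## Evaluation and conservation

Exact match compares chromosome, strand, exon count and the ordered
donor-acceptor list; terminal exon outer boundaries are never compared
(5' completeness is not guaranteed by the protocol and polyA trimming
jitters the 3' terminus). Single-exon transcripts match by ≥ 50%
reciprocal overlap (declared rule). Scoring restricts to loci detected
in both sets; bins are keyed by reference isoforms per locus. Swapping
query and reference provably swaps sensitivity and specificity.

Protein best hits use local alignment with BLOSUM62 and affine gap
penalties 11/1 (score threshold 50), one-way by default as a textual
reading of "best hits"; a reciprocal mode is available. A pair is
conserved in a species when both best hits sit at consecutive gene
ranks on one contig with the same strand.

## The generator: what it emulates, and what it does not

Defaults define the study conditions: 60 genes on one chromosome; 2-5
exons per gene with 90-150 nt introns; CDS 150-300 aa flanked by
90-150 / 150-220 nt UTRs; half the genes in readthrough clusters of
2-4 adjacent same-strand genes spaced ~364 ± 60 nt; one readthrough
isoform per cluster at half the base abundance; tandem duplicates (one
pair per ten genes, 8% divergence, splice sites preserved) placed
inside readthrough clusters, reflecting the enrichment of readthrough
units in duplicated genes; 20 full-length reads per isoform (floored
at 5; downstream cluster members scale by 0.5 per tier, so independent
expression forms decreasing tiers); 25% of reads 5'-degraded; errors
i.i.d. per base, (sub, ins, del) = (0.01, 0.08, 0.06) by default.
Poisson-distributed extra isoforms (mean 2.5, ≤ 5 per locus) draw
distinct event kinds — exon skip, 33-nt alternative donor/acceptor,
−80 nt alternative polyadenylation, +60 nt alternative TSS — without
replacement; readthrough-member loci instead carry exactly two
isoforms so locus-level tiers are set by the tier factor alone.

Several constructions keep ground truth recoverable *exactly*, which
real data would not guarantee:

* introns carry C-pads around their GT/AG and T-free alternative-site
  cassettes, making splice placement unambiguous and alternative sites
  stop-free;
* inter-ORF spacers embed a stop block (TAA in all three frames) every
  ~90 nt, so no reading frame crosses a gap and spurious inter-ORF
  ORFs cannot arise;
* the 12 nt upstream of every cleavage site are A-free (and the A-rich
  NUE is implanted at −30..−13 at 60% A), so the polyA-tail boundary
  of an error-free read is exact — an NUE abutting the tail is
  otherwise indistinguishable from it;
* transcript sequence resembling either primer within the
  classification threshold is redrawn at design time, as real primer
  design avoids cross-matching the transcriptome;
* read counts are fixed at the rounded expectation and all randomness
  flows from per-stage substreams of one seed, so every output is
  byte-reproducible.

Consequently, passing tests demonstrate algorithmic correctness under
a clean, fully specified model — not robustness to genomic repeats
beyond tandem duplicates, non-canonical splice sites, heteroduplex or
chimeric artifacts, expression-dependent error biases, or annotation
noise, none of which the generator emulates. Alternative
donor/acceptor shifts default to 33 nt because the clustering
predicate's 20-nt internal-gap bound is, by its own design, the
smallest event size it can separate from sequencing indels. The
short-read support tables are emitted at 10x the isoform abundance
(deep coverage), keyed genomically, with Poisson noise; raw short-read
FASTQ generation is a non-goal.

## Problem sizes and numerical choices

The default study (60 genes, ~150-170 isoforms, ~3,600 reads at 2%
error) runs end to end in roughly three minutes on one core; the
bundled analyses and the acceptance script use this size. Alignment
throughout is edlib (unit-cost, exact); likelihoods floor their rate
parameters at 1e-6; the hypergeometric tail is evaluated in log space;
ties everywhere break deterministically (documented per stage above),
which is what makes shuffled inputs reproduce identical outputs.
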