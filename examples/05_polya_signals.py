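"""Why does readthrough happen? Compare termination signals by class.

Upstream of a poly(A) site, fungi carry an A-rich near upstream element
(NUE, ~-30..-10) and a U-rich far upstream element (FUE, ~-60..-30).
If internal (pORF1) sites of polycistronic units lack both signals,
weak termination explains the readthrough.
"""

from longform import SimConfig, simulate_all
from longform.orfscan import scan_transcripts
from longform.pas import composition_profile, detect_elements, locate_pas
from longform.pipeline import truth_alignments

cfg = SimConfig(seed=42, error_rates=(0, 0, 0))
truth = simulate_all(cfg)
seqs = {i.id: i.seq(truth.genome) for i in truth.isoforms}
alns = truth_alignments(truth)
_, calls = scan_transcripts(seqs, alns, truth.genes)
sites = locate_pas(alns, calls, truth.genes)

for cls in ("nORF", "pORF1", "pORF2"):
    prof = composition_profile(sites, truth.genome, cls, seed=42)
    els = detect_elements(prof)
    a = prof.mean_freq("A", -30, -10)
    u = prof.mean_freq("U", -60, -30)
    print(f"{cls:6s} n={prof.n_sites:3d}  A(-30..-10)={a:.2f} "
          f"U(-60..-30)={u:.2f}  NUE={'yes' if els['nue'] else 'no ':3s} "
          f"FUE={'yes' if els['fue'] else 'no'}")
# expected: nORF and pORF2 show both elements (values far above the
# 0.25 background), the internal pORF1 class shows neither
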