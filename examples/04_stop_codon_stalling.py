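"""40S accumulation at stop codons and its -1 codon signature.

In a recycling knockout, post-termination 40S subunits pile up on stop
codons, strongest where the last sense (-1) codon retains a tightly
bound deacylated tRNA.  This script scores every main-ORF stop for 40S
gain (knockout over wild type), classifies stalled stops, and asks which
-1 codons are over-represented among them — recovering the planted
stalling codon with an exact binomial test over all 61 sense codons.
"""

import numpy as np

from riboreinit import (
    SENSE_CODONS,
    SimulationConfig,
    classify_stalled,
    codon_enrichment_test,
    morf_stop_sites,
    simulate_library,
    simulate_transcriptome,
    stall_scores,
)

config = SimulationConfig(
    seed=13,
    n_transcripts=400,
    depth=1_000_000,
    utr5_length_range=(60, 120),
    cds_length_codons_range=(40, 80),
    utr3_length_range=(10, 30),
    stall_factors={"GCG": 8.0},   # planted: GCG -1 codons stall 8-fold in knockouts
)
tx = simulate_transcriptome(config)
wt = simulate_library(config, tx, "WT", "RIBO40S")
kos = {g: simulate_library(config, tx, g, "RIBO40S") for g in ("KO1", "KO2")}

scores = classify_stalled(stall_scores(wt, kos, morf_stop_sites(tx.models), offset40s=15))
is_gcg = scores["codon_minus1"] == "GCG"
print(f"stop sites scored: {len(scores)}; with GCG -1 codon: {int(is_gcg.sum())}")
print(f"median 40S log2FC at GCG stops:   {scores.loc[is_gcg, 'mean_log2fc'].median():+.2f} "
      f"(planted: {np.log2(8):+.2f})")
print(f"median 40S log2FC at other stops: {scores.loc[~is_gcg, 'mean_log2fc'].median():+.2f}")
print(f"classified stalled: {int(scores['classified'].sum())} "
      f"(GCG among them: {int((scores['classified'] & is_gcg).sum())})\n")

fg = scores[scores["classified"]]
enrich = codon_enrichment_test(fg, scores, position=-1)
hits = enrich[enrich["significant"] & (enrich["log2_enrichment"] > 0)]
print(f"codon enrichment: {len(enrich)} tests (one per sense codon, {len(SENSE_CODONS)} total)")
for row in hits.itertuples():
    print(f"  {row.codon}: {row.count_fg}/{row.n_fg} in stalled vs {row.count_bg}/{row.n_bg} "
          f"overall, log2 enrichment {row.log2_enrichment:+.2f}, adjusted p {row.p_adjusted:.2e}")
print("-> only the planted -1 codon survives Bonferroni correction over the 61 codons.")
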