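"""Translation-efficiency outliers from reinitiation failure.

Transcripts whose uORF traps the recycling machinery lose main-ORF
translation in the knockout.  TE (80S CDS density / RNA density) drops
on exactly those transcripts; the Z-vs-Z scan flags them as heavier-
than-Gaussian outliers without flagging the unaffected background.
"""

import numpy as np

from riboreinit import (
    SimulationConfig,
    UORFDesign,
    compute_te,
    scan_te_table,
    simulate_libraries,
    simulate_transcriptome,
    te_table,
)

config = SimulationConfig(
    seed=5,
    n_transcripts=200,
    depth=800_000,
    uorf_designs=(UORFDesign(2, "GCG", 0.2),),
    stall_factors={"GCG": 8.0},   # GCG-stop uORFs become recycling traps
    reinit_failure=0.25,          # affected mORFs keep 25% of 80S density in knockouts
)
tx = simulate_transcriptome(config)
libs = {g: simulate_libraries(config, tx, g, assays=("RNA", "RIBO80S")) for g in ("WT", "KO1", "KO2")}

wt_te = compute_te(libs["WT"]["RIBO80S"], libs["WT"]["RNA"], tx.models)
ko_te = {
    g: compute_te(libs[g]["RIBO80S"], libs[g]["RNA"], tx.models, enforce_thresholds=False)
    for g in ("KO1", "KO2")
}
table = scan_te_table(te_table(wt_te, ko_te))

affected = set(tx.truth.loc[tx.truth.affected, "transcript_id"])
is_affected = table["transcript_id"].isin(affected)
flagged_down = table["flag"] == "down"

print(f"transcripts in TE table: {len(table)}; planted affected: {len(affected)}")
print(f"median log2FC(TE), affected:   {table.loc[is_affected, 'mean_log2fc_te'].median():+.2f} "
      f"(planted: {np.log2(0.25):+.2f})")
print(f"median log2FC(TE), unaffected: {table.loc[~is_affected, 'mean_log2fc_te'].median():+.2f}")
print(f"down-flagged: {int((flagged_down & is_affected).sum())}/{int(is_affected.sum())} affected, "
      f"{int((flagged_down & ~is_affected).sum())} false")
print("-> TE loss concentrates on transcripts with a stalling uORF, and the "
      "observed-vs-theoretical-Z scan isolates them from the Gaussian bulk.")
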