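# Methods

This note documents the statistical model behind each analysis stage,
the default parameters and their rationale, the scope of the synthetic
data generator, numerical choices, and known limitations. Everything
quantitative stated here is computed by the package (and checked in
`tests/`), not asserted.

## Coordinate conventions

All coordinates are 0-based, half-open, in transcript space. A CDS spans
`[cds_start, cds_end)`; `cds_end - cds_start` is a positive multiple of 3
and includes the stop codon, whose first nucleotide is
`stop_start = cds_end - 3`. Footprints are represented by their 5′-end
coordinate and read length.

## uORF annotation

A uORF is an ATG at position `p < cds_start` together with the first
in-frame stop codon at `q ≥ p`. Classes:

* **contained** — `q + 3 ≤ cds_start`; always reported.
* **overlapping** — the stop lies at or beyond `cds_start`; reported only
  when `include_overlapping=True` **and** the uORF frame differs from the
  main ORF frame. In-frame upstream starts without an intervening stop
  are N-terminal extensions of the main protein, not uORFs, and are never
  reported.

`n_sense_codons` counts the codons from ATG to the last codon before the
stop, inclusive of the initiator; `ATGTGA` is therefore a 1-amino-acid
uORF. Stop-context codons −1/−2/−3 are the sense codons at
`stop_start - 3k` for `k = 1, 2, 3`; positions upstream of the uORF's own
ATG are reported as absent (the ATG itself is a valid −k codon).

The annotator is validated against an independent brute-force enumeration
on ≥1000 random UTRs (acceptance property i).

## Footprint processing

* **5′-end assignment.** An 80S footprint's P-site codon starts 15 nt
  downstream of its 5′ end (`OFFSET_80S = 15`), the standard offset for
  ~30-nt footprints. An initiating ribosome therefore peaks 15 nt
  upstream of the start codon; a terminating one 15 nt upstream of the
  stop; a ribosome queued directly behind a terminating one
  15 + 30 = 45 nt upstream of the stop.
* **Length filters.** 80S: 25–35 nt; 40S: 20–80 nt (small-subunit
  footprints are heterogeneous); RNA: unfiltered.
* **Depth normalization.** Counts per million (CPM) using the library's
  total alignment weight, fixed at load time *before* length filtering so
  normalization does not depend on filter settings.
* **Metagenes** pool per-library CPM at offsets relative to the start
  codon's or stop codon's first nucleotide. Smoothing is a centered
  moving average with truncated edges; even windows widen to the next odd
  width.
* **Peak finding** takes the argmax within a search range; ties break
  toward the offset nearest zero, then the smaller offset, making results
  deterministic.

## Translation efficiency

`TE = (80S CPM on the CDS) / (RNA CPM on the whole transcript)`.
Detection requires ≥10 raw RNA reads and ≥10 raw 80S reads in the
wild-type reference (`min_rna = min_80s = 10`): below that, the TE ratio
is dominated by counting noise. The knockout effect is
`log2(TE_KO / TE_WT)`, averaged over knockout lines. TE is invariant to
joint rescaling of depth and counts to 1e-9 relative (acceptance
property vi).

### Z-vs-Z outlier scan

Per-transcript effects are standardized robustly:
`observed_z = (x − median) / (1.4826 · MAD)` (1.4826 makes MAD consistent
for the standard deviation under normality). Each value's
`theoretical_z` is the standard-normal quantile of its Blom plotting
position `(rank − 0.375) / (n + 0.25)` with average ranks for ties. A
transcript is flagged **down** when
`observed_z − theoretical_z ≤ −delta` and `observed_z ≤ −z_min`
(defaults `delta = 1.0`, `z_min = 1.5`); **up** symmetrically. The first
condition asks whether the value departs from the line expected of a
Gaussian with the data's own robust scale; the second suppresses flags in
the bulk. On 10,000 standard-normal draws the scan flags ≤0.5%, and it
recovers ≥90% of planted −2 log2-unit shifts at ≤1% false flags
(acceptance property ii). Requires n ≥ 50; a zero MAD is an error
(degenerate input).

Gene-level collapse keeps the transcript with the largest
`|mean log2FC(TE)|` per gene, with lexicographic transcript-id
tie-breaking for determinism.

### uORF-length groups

Transcripts are grouped by the lengths of their (optionally translated)
uORFs into non-exclusive bins — except that any transcript bearing a
1-aa uORF belongs only to the 1-aa group, so effects attributed to longer
uORFs cannot be driven by 1-aa uORFs. Groups are compared with a
Kruskal–Wallis omnibus test and pairwise rank-sum tests against the
no-uORF group (Holm-adjusted).

## 40S recycling-defect scores

For every stop site (main ORFs; uORFs restricted to those with 80S
signal on their start codon), 40S CPM is counted in a 10-nt window
`[anchor − 4, anchor + 6)` at `anchor = stop_start − offset40s`. The
offset is calibrated from the pooled stop-anchored 40S metagene
(fallback 15 nt). Per knockout line the score is
`log2((KO + pc) / (WT + pc))` with a CPM pseudocount `pc = 0.05` —
small enough not to bias well-covered sites, large enough to cap the
variance of empty windows — averaged over knockout lines (two or more
required), then standardized into a robust Z separately for mORF and uORF
stop populations. A site is classified stalled when `z ≥ 1.645` (one-sided
5% of a normal) **and** fold change > 4. With stall factors off the null
is centered (|median| < 0.05); planted 8× stalls are recovered at
`log2(8) ± 0.3` at depth 10⁶ (acceptance property iii). Scores are
depth-rescaling invariant to 1e-9 relative (property vi).

If the per-kind MAD is zero (possible in idealized synthetic inputs),
standardization falls back to mean/SD, or to all-zero Z for a point mass.

## Codon enrichment

Foreground (classified) stop sites are compared against the full
background of scored sites — the foreground must be a subset. For each of
the **61 sense codons**, the foreground count of sites with that −1 (or
−2/−3) codon is tested against the background frequency with a two-sided
exact binomial test (minimum-likelihood two-sided definition, verified
against an exhaustive enumeration oracle — acceptance property v).
P-values are Bonferroni-adjusted over the 61 tests by default (Holm and
Benjamini–Hochberg available); α = 0.05. On uniform subsamples the
procedure yields zero significant codons in ≥95/100 repetitions
(measured familywise error ≈1.5%), and it recovers planted stalling
codons {GCG, CTG, ATG} in ≥9/10 seeds (property iv). Note that under a
two-sided test, planting enrichment necessarily de-enriches the remaining
codons; "recovered" therefore means *significantly enriched*
(`p_adjusted < α` and `log2_enrichment > 0`).

## Synthetic data generator

The generator's purpose is verification: every analysis stage must
recover planted truth. Design choices:

* **Sequences.** Background nucleotides are drawn from {C, T, G} — with
  no A, no unintended ATG (hence no unintended uORF) can arise, so the
  annotated catalog equals the planted catalog exactly. Planted ORFs use
  A-free filler codons and the stop TAG, which cannot create an ATG
  across junctions.
* **80S libraries.** Uniform elongation weight per P-site codon, plus
  initiation and termination peaks (10× one elongation position each),
  all shifted −15 nt to 5′-end space. In knockouts, stops whose −1 codon
  has a stall factor > 1 gain a queued-ribosome peak at −45 nt
  (termination weight × `queue_probability`, default 0.8). Transcripts
  whose uORF stalls have their main-ORF density multiplied by
  `reinit_failure` in knockouts.
* **40S libraries.** Uniform scanning weight over the 5′UTR plus a
  recycling peak (20× scanning) on every stop, multiplied by the stall
  factor in knockouts.
* **Noise and depth.** Per-transcript, per-library lognormal abundance
  noise `2^N(0, 0.2)`; reads are one multinomial draw over the
  position grid followed by a per-position multinomial over lengths
  (jointly equivalent to a single draw over the position × length grid by
  the multinomial splitting property), so library depth is conserved
  exactly and identical seeds give byte-identical output (property vii).
* **Seeding.** Streams are derived as
  `default_rng([seed, crc32(label), …])`, so each (genotype, assay)
  library is independent but fully determined by the study seed.

**Scope.** The simulator reproduces the *statistical structure* the
analysis assumes — peak geometry, density ratios, depth effects — not
sequencing realism: no ligation or nuclease sequence bias, no
position-dependent coverage decay, no multimapping ambiguity, no
biological codon-usage correlations. One caveat it *does* share with real
CPM data: boosting density at many sites shifts the normalization
denominator, compressing apparent fold changes; recovery checks therefore
plant stalls at a small fraction of sites (~1/61), matching the
composition of a real transcriptome.

## Numerical choices

* Robust scale uses `1.4826 × MAD` throughout.
* CPM pseudocounts are added after normalization so they are
  depth-independent.
* All argmax/collapse operations have deterministic tie-breaking.
* Exact binomial p-values come from `scipy.stats.binomtest`; adjustments
  from `statsmodels`.

## Limitations

* Transcript-space only: genome alignment, splicing and isoform
  deconvolution are out of scope; multi-mapping reads are counted at
  every reported alignment.
* uORFs must be ATG-initiated; near-cognate starts (CUG, GUG…) are not
  annotated.
* The 40S stop-peak offset calibration assumes a dominant stop-codon peak
  in the pooled metagene; with very sparse 40S data the constant fallback
  (15 nt) is used.
* The Z-vs-Z scan models the null as Gaussian-with-robust-scale;
  heavy-tailed biological nulls will inflate flags, which is why both the
  deviation (`delta`) and absolute (`z_min`) gates are required.
* Statistical power targets in the acceptance suite are verified on
  simulated data; real datasets with shallower depth or stronger biases
  will need threshold re-tuning.
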