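# Methods

## Scope and model

`riboprof-recycle` quantifies what happens to ribosomes at and beyond stop
codons when post-termination 70S complexes (post-TCs) are not recycled.
The observable is ribosome-profiling footprint density represented by the
**3′ end** of each aligned read: on the plus strand the 3′ end of an
interval `[start, end)` is `end − 1`, on the minus strand `start`.  All
coordinates are 0-based half-open; GFF3 input is converted at the
boundary.  A gene's CDS includes its stop codon, and the metagene anchor
(offset 0) is the **final nucleotide of the stop codon**.  Published
bacterial profiling work aligns densities "at stop codons" without fixing
the anchor nucleotide; we fix the last nt — the 3′ end of a terminating
footprint falls at or near this position — and expose the windows so the
anchor can effectively be shifted in configuration.

Region quantification is RPKM: reads per kb of region per million mapped
reads of the library.  For every CDS-based RPKM the terminal
`exclude_last = 15` nt are removed (strand-aware) so that the termination
pileup does not inflate gene-body density; the exclusion is applied
consistently, including to the last-100-nt numerator of the collision
score.  3′-UTR and metagene windows are never trimmed.

Per-gene summary statistics:

* **3′-UTR score** = UTR RPKM / upstream-CDS RPKM.  3′-UTRs are defined by
  transcript units (TUs): only the TU-terminal gene in translation
  direction owns `[cds_end, tu_end)` (plus strand; mirrored on minus).
  Internal operon genes have no 3′-UTR here; this restricts the scored
  gene set relative to analyses that treat intergenic regions as UTRs.
* **collision score** = last-100-nt CDS RPKM / whole-CDS RPKM; genes with
  CDS ≤ 115 nt are skipped (window would cover the gene).
* **ribosome occupancy (RO)** = footprint RPKM / RNA-seq RPKM; genes are
  stratified on the control library into top 20 % ("high") and bottom
  40 % ("low") by quantile threshold, and the labels propagate to the
  depleted libraries.
* **pair ratio** = upstream-CDS RPKM / downstream-CDS RPKM for consecutive
  genes of a multi-gene TU.  Pairs whose RNA abundances differ by more
  than 5-fold are excluded (inclusive boundary: exactly 5-fold is kept);
  pairs whose depleted/control ratio change reaches 2-fold (inclusive) are
  classed `up2x`/`down2x`.  A gene interior to an operon appears in two
  pairs (as downstream and then upstream partner); the pairs are therefore
  not independent, which is acceptable for the correlation and class
  summaries reported here.

Metagene profiles average per-offset density over genes that (a) have no
other CDS within `clearance = 110` nt downstream of the stop, (b) carry at
least `min_cds_reads = 32` CDS 3′-end counts, and (c) fit the whole window
on the chromosome.  The default averaging mode divides each gene's
positional values by that gene's mean CDS density before an unweighted
average ("gene-normalized"), preventing a handful of highly expressed
genes from dominating; a plain rpm mode is retained.  The averaging scheme
of the original figures is not documented; the gene-normalized default is
our choice.

Stacked-ribosome peaks are local maxima (via `scipy.signal.find_peaks`)
within a search window of `[−90, −10]` nt upstream of the anchor, with
prominence at least 3× the median profile value in the window; the modal
spacing is the median distance between successive peaks.

Group comparisons use the one-sided Mann–Whitney rank-sum test (scipy
backend): exact enumeration when the smaller sample has ≤ 8 observations
and no ties, otherwise the normal approximation with tie and continuity
corrections.  Scores enter untransformed — the test is rank-based and
invariant to monotone transforms.

## The synthetic-footprint generator

The generator is first-class, tested code: it provides the explicit null
and alternative models against which every analysis stage is validated.
Per run, gene `g` receives an mRNA abundance `m_g ~ LogNormal(0, 0.8)` and
occupancy `o_g ~ LogNormal(0, 0.5)`, drawn once and shared by all
libraries.  With `λ_g = depth_rpf · m_g · o_g` (default depth 0.5 reads
per nt per unit abundance):

* elongating footprints: Poisson(λ_g) 3′ ends per CDS nt;
* a basal stop peak of Poisson(`w_stop`·λ_g) post-TCs at offset 0
  (`w_stop = 15` nt-equivalents).  The basal peak is modelled as post-TC
  class — i.e. salt-labile — because the control-strain stop peak
  disappears under high-salt lysis, implying recycling is slower than
  peptide release even with the factor present;
* upon depletion, an additional Poisson(`f_post(t)`·λ_g) post-TCs per
  gene; each remains at the stop with probability `p_stay(t)` or is
  displaced by a one-shot Geometric draw (mean `θ(t)` nt) toward the TU
  end, capped there.  Defaults `f_post = {5′: 80, 15′: 160, 60′: 320}`,
  `p_stay = {0.5, 0.35, 0.25}`, `θ = {25, 50, 100}` nt produce the
  qualitative time course of growing, spreading 3′-UTR density.  The
  dwell-vs-diffusion balance is not quantified in the literature; these
  are free model knobs, chosen once.  A one-shot geometric displacement
  (rather than a time-stepped random walk) reproduces the monotone growth
  of UTR density with two parameters per time point;
* behind **each** stop-resident post-TC, a queue of
  `min(Poisson(queue_rate · o_g), ⌊(CDS − 60)/Δ⌋)` elongating ribosomes at
  offsets −Δ, −2Δ, … (`Δ = stack_spacing = 30` nt ≥ footprint length 28;
  queues never reach the 60-nt start-proximal buffer).  Drawing a queue
  per resident post-TC — rather than once per gene — reflects that each
  cellular mRNA copy with a blocked stop codon carries its own queue, and
  makes queue density scale with both post-TC load and occupancy;
* high-salt lysis: the identical realization with each post-TC read kept
  with probability `salt_retention = 0.4`; elongating and queued reads
  always survive.  The default mirrors the observed ~2.5-fold reduction
  of 3′-UTR density;
* RNA-seq: uniform Poisson(depth_rna·m_g) coverage over each CDS and over
  the 3′-UTR of TU-terminal genes.  (Coverage is parameterised per gene,
  not per transcript; operon-internal RNA level steps are therefore
  possible and are exactly what the 5-fold RNA pair filter removes.)

The simulated genome places ~`n_genes/2.5` operons of 1 + Poisson(1.5)
genes on one chromosome, CDS lengths log-normal around 900 nt (multiple of
3, ≥ 150 nt), stop/start overlaps of −4 nt with probability 0.3 (matching
the >30 % of overlapping pairs in enteric genomes), otherwise geometric
intergenic gaps of mean 15 nt, and TU-terminal UTRs uniform in 60–180 nt.
All randomness flows from one integer seed through `SeedSequence` streams
keyed by purpose and condition, so any library can be regenerated
independently and reruns are byte-identical.

An optional coupling knob (`coupling_strength = c > 0`) multiplies the
depleted-condition occupancy of every non-first operon gene by `2^{±c}`
(random sign per gene).  It exists purely to verify detection power: at
`c = 1` the pair-ratio correlation collapses and the 2-fold classes fill.

### What the generator does not emulate

No sequence-level reads (ligation/nuclease bias, mappability), no P-site
offsets or codon-level pausing, no elongation kinetics (TASEP), no
transcription-level co-regulation within operons, and no genuine
re-initiation in UTRs.  Passing tests therefore demonstrate that the
*analysis* recovers the *modelled* phenomena at realistic depths — not
that the model captures every property of real libraries.

## Numerical and design choices

* Zero-denominator genes are excluded from scores, never pseudocounted.
* Quantile stratification uses linear-interpolation quantiles of the
  reference library.
* Boundary conventions are inclusive (5-fold RNA filter, 2-fold classes).
* Pearson correlations of pair ratios are computed on log2 ratios (the
  published scatter axes are logarithmic); raw-scale r is also emitted.
* The high-salt comparison emits both the median of per-gene fold
  reductions and the ratio of median scores — the two are not equivalent
  and the published "2.5-fold" does not say which was used.
* Genes claimed by several TUs are resolved by a priority column in the
  TU table (operon-first rule); the synthetic annotation is always
  unambiguous.
* The `tracks`/`metagene`/`scores`/`coupling` CLI subcommands re-run each
  stage from plain-text intermediates; `all` orchestrates the full run and
  writes a manifest with the configuration hash.

## Problem sizes

Default study conditions simulate 200 genes (~80 operon-terminal UTRs,
~100 RNA-filtered gene pairs) at depth 0.5 reads/nt/unit — a deliberate
scale-down of a transcriptome-wide experiment that keeps every analysis
population large enough for stable medians and rank tests.  The null
calibration of the class-distance test uses 300 genes at depth 0.02 over
50 seeds, where Poisson noise populates the 2-fold classes.  At this
scale a full simulation-plus-analysis run completes in seconds.

## Known limitations

* With a strong depletion load at late time points, displaced post-TCs
  from an upstream gene migrate into downstream CDSs and overlapping
  start codons sit inside the upstream termination pileup.  Both effects
  perturb pair ratios asymmetrically — the simulated 60-min pair-ratio
  correlation settles near 0.92 rather than 1, closely paralleling the
  r = 0.89 observed in the real data.  Null-calibration checks therefore
  use conditions without a depletion-specific post-TC load.
* 3′-UTR scores are restricted to TU-terminal genes; analyses that score
  internal intergenic regions would need a different UTR definition.
* The generator draws the stop-codon dwell probability `p_stay`
  independently of occupancy, so the simulated 3′-UTR-score/occupancy
  comparison is a null: the pipeline computes and reports it, but only
  the collision-score direction is a modelled effect.  (In real data,
  queued ribosomes appear to stabilise post-TCs at stops, lowering UTR
  scores of highly translated genes — a coupling this model omits.)
* Because displaced post-TCs are capped at the TU end, the total UTR read
  count of a gene is independent of its UTR length, which makes the UTR
  *score* anti-correlate with UTR length in simulation.
* The rpm/RPKM denominator is all assigned reads of the library
  (rRNA/tRNA removal is upstream of this package and out of scope).
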