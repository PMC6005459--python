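# Methods

This note documents the models behind each analysis strand, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions.

## Copy-number / LOH segmentation

**Model.** The tumour sample is a mixture of a clonal aberrant population at
purity *p* and diploid heterozygous normal cells. Aberrations are single-copy
changes: loss (1 copy), gain (3 copies), and copy-neutral LOH (2 copies of
one haplotype). At a site heterozygous in the normal, the expected tumour
alt fraction follows the allele-dosage algebra, e.g. cn-LOH gives
`0.5 ± p/2`, loss gives `{(1−p)/(2−p), 1/(2−p)}`, gain
`{1/(2+p)·(1), (1+p)/(2+p)}` depending on which haplotype carries the
alternate allele; total depth scales with the copy ratio `(2(1−p)+c·p)/2`.

**Site filtering.** Sites must be heterozygous in the normal, have genotype
quality ≥ 14, and read depth within the inclusive range [11, 1001] in *both*
samples. The bounds are applied inclusively; the boundary values themselves
pass.

**Track.** BAF = alt/(ref+alt); mirrored BAF folds to [0.5, 1]. The depth
log-ratio `log2(tumour/normal)` is median-centred across the genome, a
standard library-size normalisation that places the neutral state at 0
whenever most of the genome is neutral (true of the data this targets).

**Decoding.** A 4-state Gaussian-emission HMM over (mirrored BAF,
log-ratio) with uniform start probabilities and a sticky transition matrix
(self-transition 0.999) is decoded by Viterbi (via `hmmlearn` with fixed,
non-fitted parameters). Emission means default to the dosage algebra at a
representative purity of 0.8 — neutral (0.54, 0), cn-LOH (0.90, 0), loss
(0.83, −0.74), gain (0.64, 0.49) — with SDs 0.06 (mirrored BAF) and 0.25
(log-ratio). The neutral mirrored-BAF mean is 0.54, not 0.50, because
folding binomial noise at depth ~100 inflates the folded expectation by
`σ·√(2/π) ≈ 0.04`. Purity is deliberately not estimated: the emission means
are fixed and configurable (`HmmParams`), which keeps decoding deterministic
and transparent; events at purities far from the defaults are still
recovered because the sticky prior integrates evidence along the segment.
Chromosomes with fewer than 5 sites are emitted as one neutral segment
rather than decoded.

**Segments and score.** Adjacent same-state sites merge into segments
spanning first to last supporting site (1-based closed); chromosome ends are
not extrapolated. Segment length is `end − start + 1`. The fractional
copy-number aberration score is the summed length of loss+gain segments over
the summed length of all segments; cn-LOH contributes only to the
denominator, since a copy-neutral event is not a copy-number aberration.
Because the score is a ratio, the consistent site-span convention suffices.
LOH runs report maximal stretches of consecutive sites in cn-LOH/loss
states together with the nearest flanking heterozygous (neutral) site on
each side — the most distal retained heterozygosity bounding the run.

## Bisulfite amplicon epiallele analysis

**Conversion model.** Bisulfite converts unmethylated cytosine to uracil
(read T); methylated CpG cytosines resist. Four expected templates are
derived from the amplicon reference: top/bottom strand × methylated/
unmethylated at CpGs, all kept in top-strand orientation (the bottom strand
appears as G→A conversion, its CpG-informative base being the guanine at
CpG offset + 1).

**Calling.** Amplicon reads are position-fixed, so reads are compared to all
four templates by ungapped anchored identity; the best pair fixes the
strand, and reads below an identity floor (default 0.8) are discarded as
off-target. Indel-carrying reads fall below the floor by design; the one
locus where an indel matters (the frameshift mutation) is handled separately
by local-context counting. Methylation calls read the informative base per
CpG; anything else is missing. The per-read conversion failure rate is the
retained fraction at non-CpG cytosine (top) / guanine (bottom) positions; an
optional filter can drop reads above 5% retention but is off by default.

**Epiallele classification.** A read with ≥ `min_called` = 5 informative
calls is dense if its methylated fraction ≥ `dense_min` = 0.9 and
unmethylated if ≤ `unmeth_max` = 0.1. A strict "all CpGs methylated" rule
would be fragile to a single sequencing error or missing call over 23 sites,
so one miss is tolerated; both thresholds are configurable and reported.
The dense fraction carries a Wilson 95% CI (well-behaved at the small counts
that matter here, e.g. 8/661). Mosaic cell fraction = 2 × allele fraction,
valid only for allele fractions ≤ 0.5 (one methylated allele per affected
cell); inputs above 0.5 are rejected rather than clipped. Reported
percentages are rounded to 1 dp, except mutation allele fractions to 2 dp.

## Expression subtyping

**Filtering.** The top 50% of probes by inter-sample variance (sample
variance, ddof 1) are retained, ties broken by probe id order; probes on a
cross-hybridisation blacklist are removed first. Clustering uses Euclidean
distance and average (UPGMA) linkage on samples; dendrograms serialise to
Newick.

**Moderated t.** Implemented in-package: per-probe pooled variances `s²` on
`d` residual df are assumed `s² | σ² ~ σ²χ²_d/d` with a scaled-inverse-χ²
prior `σ² ~ s₀²d₀/χ²_{d₀}`. The prior is fitted by marginal moment matching
on `e = log s² − ψ(d/2) + log(d/2)`: the excess of `var(e)` over `ψ′(d/2)`
identifies `d₀` through the inverse trigamma (Newton iteration); no excess
means effectively infinite `d₀` (complete shrinkage, normal reference
distribution). The moderated t uses the posterior variance and `d + d₀` df.
Setting `prior_df = 0` recovers the ordinary pooled t exactly, which the
tests verify as the no-shrinkage limit; the fit is also cross-checked in the
tests against frozen numbers from an independent reference implementation of
the same estimator on a fixed dataset (agreement to ~1e-6). BH step-up
adjusts p values; selection uses |log2 FC| ≥ log2(fold_min) with adjusted
p < threshold, interpreting "two-fold" on the log2 scale. Signature-overlap
percentages are |query ∩ reference|/|query| rounded half-up to integers.

**Metagenes.** Marker genes are z-scored per gene across samples
(zero-variance genes dropped with a warning; ≥ 2 usable genes required); the
per-sample score is the first right singular vector scaled by the first
singular value. SVD sign is ambiguous, so the score is anchored to correlate
positively with the mean marker z-score — the anchor resolves only the
ambiguity; negating the data negates the scores. Variance explained is
`σ₁²/Σσᵢ²`. Group comparisons use Welch's two-sided t and are deliberately
reported uncorrected (they accompany a small, fixed set of stages); a fully
degenerate comparison (no variability in either group) reports p = 1 when
means are equal.

## Synthetic data: what it does and does not emulate

* **CNV strand** — heterozygous site positions uniform within implanted
  segments (default 12 sites/Mb, depth 100, purity 0.8: the recovery
  condition the segmentation is specified to meet); depths Poisson, alt
  depths binomial at the dosage fraction; 2% of sites get a sub-threshold
  GQ to exercise the filter. Not emulated: mapping bias, GC waves,
  subclonality, germline CNVs. The default three-chromosome genome implants
  one 20 Mb event of each type on a 60 Mb chromosome (truth score 2/9).
* **Bisulfite strand** — two-epiallele mixture with per-CpG methylation
  probabilities 0.99 (dense) and 0.02 (background), conversion 0.995,
  substitution error 1e-3, full-length reads on both strands; defaults
  mirror a MiSeq targeted-amplicon design with dense fraction 0.395 of 1043
  reads. Not emulated: read fragmentation, indels, PCR duplicates or bias
  between epialleles. The bundled amplicon is a synthetic GC-rich stand-in
  (253 bp, 23 CpGs on an even grid), not a genomic sequence.
* **Expression strand** — i.i.d. Gaussian log-scale background (baseline 7,
  SD 0.5) with marker sets shifted by a stated effect (in SD units) in a
  designated subgroup. Not emulated: probe-level correlation, batch
  effects, heavy-tailed noise.

Passing tests therefore demonstrate correctness of the estimators under
their stated models, not robustness to artefacts absent from the models.

## Numerical conventions and problem sizes

Coordinates are 1-based closed everywhere in memory and in TSV outputs; BED
export converts to 0-based half-open in one central function. All
generators take explicit seeds and are bit-reproducible; the pipeline
derives stage seeds from the master seed by fixed offsets. Statistical
suite sizes (e.g. 100-seed mixture-recovery and metagene-power checks, 200
null replicates of 1,000 probes for DE calibration, ~2,000 sites for
segmentation recovery) were chosen to give Monte-Carlo error comfortably
below the tested margins while keeping the default test run fast.

## Known limitations

* The HMM stand-in makes no claim to reproduce any particular exome CNV
  caller's output; it is a transparent, fixed-parameter decoder for the
  states the analysis needs.
* Mutation-methylation phasing is limited to context counting per read;
  co-occurrence across the two assays is not modelled.
* The moderated-t implementation covers the two-group design only.
* Purity is an input to the generators, not an estimate of the
  segmentation; heavily impure samples need adjusted emission means.
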