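# Methods

`dkaryo` screens shallow whole-genome sequencing data (single-end 36 bp
reads, roughly one million filtered reads per sample) for constitutional
copy-number variants and chromosomal mosaicism. This note describes the
statistical model behind each stage, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the known
limitations.

## Genome binning

All depth analysis runs on an ordered partition of the genome into bins
sized by *mappable* bases rather than physical length: a bin closes once it
has accumulated `target_mappable_span` mappable bases (greedy,
left-to-right, per chromosome), and a trailing remainder under half the
target merges into the previous bin. Stretching bins across poorly mappable
territory equalizes expected read counts per bin and suppresses false
deletion calls where short reads cannot map.

The default target is **285 kb** of mappable sequence per bin. With the
downstream three-consecutive-bin calling standard this puts the design
detection floor at 3 × 285 kb = 855 kb, the smallest constitutional event
the screen is expected to recover; the target is a tunable because the
underlying platform does not fix it. On GRCh37 with uniform mappability this
yields 10,863 bins (10,110 autosomal). Mappability is consumed as a weight
track (for example derived from a 36-mer alignability bigWig); the package
never computes it from a reference sequence, and simulations default to
uniform weight 1.

## Read counting

A read contributes to exactly one bin, chosen by its 5'-most aligned base
(leftmost base on the forward strand, rightmost on the reverse strand —
appropriate for single-end data, where fragment midpoints are unknown).
Reads are excluded if unmapped, duplicate-flagged (duplicate *marking* is an
upstream contract), or mapping quality < 20. Excluded-but-mapped reads and
reads falling outside binned territory still count toward the
filtered-mapped total, so the per-sample QC ratio
`100 * filtered_mapped / total_reads` retains its usual meaning (~77% for
unamplified libraries, ~58% after whole-genome amplification).

## Reference-panel normalization and Z-scores

A panel of control samples (default 100; 50 male, 50 female) freezes the
normalization state:

1. each control is depth-normalized to reads per million *autosomal*
   reads (using the autosomal total keeps sex-chromosome aneuploidy from
   biasing autosomal statistics);
2. bins whose normalized control mean falls below `min_mean_depth` (10) are
   masked and never scored;
3. the bin-centered autosomal control matrix is decomposed by SVD and
   high-variance principal components — systematic structure such as
   sample-varying GC response — are projected out;
4. the per-bin standard deviation of the post-removal residuals becomes the
   Z-score denominator.

A test sample is depth-normalized, centered on the bin means, projected
against the removed components, and scaled: `z_b = r_b / s_b`. Leave-one-out
calibration on simulated panels gives per-bin Z with mean ≈ 0 and sd ≈ 1.0
(tested to within [0.9, 1.1] over >5,000 bins).

**Component-removal rule.** A component is removed when its variance exceeds
`median component variance / variance_factor` (default 0.7, i.e. ≈1.43× the
median). The classical "exceeds 0.7 × mean variance" form breaks down for a
100 × ~11,000 matrix: under pure noise the Marchenko–Pastur bulk places
essentially every component variance above 0.7 × mean, so that rule would
remove all 99 components and annihilate the residual. The bulk *median* is a
robust noise-floor estimate; under pure noise the top component sits near
1.2× the median (below the 1.43× cut, so nothing is removed), while genuine
structured components stand far above it. With the default simulator the
panel removes exactly one component — the sample-varying GC response.

**Sex chromosomes.** X bins are centered and scaled against same-sex
controls only (a 50/50 panel is bimodal on X), Y bins against male controls
only; female Y bins are masked. Component projection is restricted to
autosomes: per-sex sub-panels of 50 offer little stable structure to
estimate, and the X/Y denominators absorb what a projection would have
removed.

## CNV calling

Two detectors run over the Z-score vector per chromosome, never crossing a
masked bin (a run cannot jump an unscored bin):

* **3-state HMM.** States deletion / diploid / duplication with unit-variance
  Gaussian emissions centered at −M, 0, +M (default `M = 3`), entry
  probability `p_enter = 1e-8` per bin, exit probability `1/mean_run`
  (default mean run 6 bins), and no direct deletion↔duplication transition.
  Viterbi decoding; maximal non-diploid runs become calls. The exhaustive
  3^n-path maximization is kept in the code base as a test oracle. The
  distance-dependent transition attenuation of the exome formulation is
  deliberately dropped: with near-uniform mappable spans a constant-rate
  chain is equivalent in practice.
* **Consecutive-run standard.** Three or more consecutive bins with
  |Z| ≥ 2.5, same sign throughout, boundary inclusive. The threshold is
  read two-sided because the screen reports both gains and losses under the
  same standard. This floor catches moderate-amplitude events (e.g. an
  855 kb deletion at |Z| ≈ 2.6 per bin) that cannot pay the HMM's ~20-nat
  entry cost.

Calls are unioned; overlapping same-sign calls merge into one spanning
segment with the mean Z recomputed, and each call records which detectors
produced it. Reported size is the bp span of member bins, so sizes are
coarse to bin resolution by construction. HMM quality scores are omitted:
the screen's decision is detection, with `mean_z` and `n_bins` as evidence
summaries.

## Mosaic analysis

Counts are re-aggregated onto a fixed 1 Mb grid (proportional overlap
split). The log2 ratio per grid bin is
`m = log2((sample / sample autosomal median) / panel median profile)`,
GC-corrected by a locally weighted (lowess) fit of `m` against bin GC on the
autosomes and re-centered to autosomal median 0. For a mosaic aneuploidy in
a fraction *f* of cells the expected per-bin copy ratio is `1 ± f/2`, giving
the closed-form inversions

* gain: `f = 2 (2^m − 1)`
* loss: `f = 2 (1 − 2^m)`

applied to the per-chromosome median `m` (or to a segment median for partial
events). The estimator is exact on noiseless input and unbiased within ±5
percentage points for f ≥ 0.2 over 20 simulated replicates at default depth
(per-replicate spread sd ≈ 3 points, dominated by the panel's ~1%
chromosomal-share variability).

The **comparative statistic** addresses low-fraction mosaics the log2
threshold misses: for each chromosome, the sample's share of autosomal reads
is scored against the panel's mean and standard deviation of that share
(sex-matched for X/Y). With a ~1% inter-sample share CV, a 10% trisomy
shifts the share by ~5% ⇒ Z ≈ 4–5, flaggable at the shared 2.5 cutoff where
the log2 median (expected `log2(1.05) ≈ 0.07`) sits below its threshold.

A chromosome is reported when |median m| exceeds the direction threshold
(defaults `log2(1.1)` gain / `|log2(0.9)|` loss — the expected signal of a
20% mosaic, encoding the screen's documented sensitivity floor) and/or
|comparative Z| ≥ 2.5. Contiguous runs of ≥ 5 grid bins beyond threshold on
part of a chromosome are emitted as segmental calls with coordinates; the
5 Mb minimum keeps constitutional CNVs in the CNV caller's territory. A
whole-chromosome log2 flag suppresses segmental re-reporting of the same
chromosome, but a comparative-only flag does not (it cannot localize, so a
localized log2 segment refines it).

Because the default gain threshold *equals* the expected signal at f = 0.20,
flagging at exactly 20% is a coin flip per replicate by construction;
per-replicate flagging becomes near-certain from ~30% under the default
share variability. The comparative arm covers the 10–20% band, and the
screen's union flags whole-chromosome mosaics from ~10% upward.

## Interpretation (flagging)

A CNV call is flagged for reporting when all three hold: size at or above
its direction threshold (duplications ≥ 2.0 Mb, deletions ≥ 1.0 Mb); it
overlaps at least one interval of the user-supplied gene track; and it is
not explained by a population-common CNV, operationalized as reciprocal
overlap ≥ 0.5 with any common-variant interval (the source material states
no overlap criterion; 0.5 reciprocal is this package's choice). Any overlap
with a named pathogenic-region track forces the flag regardless of size.
Five-category clinical classification is out of scope: the report carries
the flag and raw evidence for a human reviewer. All tracks are plain BED;
nothing is fetched from databases.

## Screening orchestration

Per sample: Z-scores → HMM ∪ run-rule → annotation flags, and 1 Mb log2
profile → comparative Z → mosaic calls. CNV calls covering > 80% of a
chromosome flagged as a whole-chromosome mosaic are suppressed from the CNV
section so each genomic territory is reported once. Reports embed full
provenance (bin-set and panel checksums, parameter snapshot, tool version)
and are byte-identical across reruns with identical inputs.

## Synthetic-data generator

The generator emulates the assumed data-generating process so every stage is
testable without external data:

* expected bin count ∝ mappable span × GC factor × ploidy × copy ratio,
  scaled so a diploid autosome totals `mean_filtered_reads`
  (default **1,200,000**, one 24-plex run of a ~25M-read flow cell; the true
  per-sample yield of such experiments is rarely reported, so this is a
  tunable);
* copy ratio per bin: `1 + f · Δcopies · overlap / ploidy` over the truth
  events (heterozygous deletion 0.5; 50% mosaic duplication 1.25; male-X
  single-copy gain 2.0);
* a smooth synthetic GC track and a per-sample GC-response amplitude
  (mean 0.1, sd 30% of mean) — the shared systematic component the panel
  SVD must find and remove;
* per-chromosome representation factors with CV `panel_chrom_cv`
  (default **0.01**), the quantity that calibrates the comparative
  statistic's 10–20% sensitivity claim;
* per-bin gamma overdispersion with CV `dispersion` (default **0.05**,
  i.e. counts are Poisson with a gamma-mixed mean; at ~118 reads/bin total
  residual CV ≈ 0.104, putting a full heterozygous deletion at |Z| ≈ 4.8 —
  consistent with the reported mean gain/loss Z of such screens);
* WGA mode: per-bin gamma amplification factors (shape **150**, extra CV
  ≈ 8%, attenuating |Z| by ~0.79), erratic low retention
  (mean `1 − 0.5`, heavy-tailed) of the last 10 bins of each chromosome,
  and a filtered-mapped target of 57.9% vs 77.35% without WGA. Terminal
  dropout is applied to q-terminal bins only: in the validation experiment
  this mode reproduces, amplified libraries lost a q-terminal 2.2 Mb
  deletion while p-terminal events survived, and a symmetric dropout cannot
  reproduce that column. The gamma shape is the calibration point at which
  the 50%-mosaic duplication miss becomes reliable while the Z attenuation
  stays near the printed with/without-WGA contrast.

All randomness flows from one seed through a counter-based scheme keyed by
sample id, so any sample can be regenerated independently of cohort order.

**What the generator does not emulate:** real mappability structure
(segmental duplications, acrocentric p-arms, PAR regions), GC dependence of
*fragment* recovery as opposed to a smooth per-bin factor, reference biases,
batch effects beyond rank-one GC response, and read-level artifacts
(sequencing error, soft-clipping). Passing simulation tests therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not performance on real libraries — in particular real X/Y and
subtelomeric bins will be noisier than simulated ones.

## Numerical and degenerate-input choices

* Viterbi is computed in log space; ties resolve toward the lower state
  index deterministically via argmax.
* Identical controls give zero residual scale; such bins are masked with a
  warning rather than producing infinite Z.
* Fraction estimates are clipped to [0, 1] with a warning when the log2
  median falls outside the single-event range (m > log2 1.5 or m < −1).
* The run rule treats its 2.5 boundary as inclusive ("2.5 or more").
* Bin files and count matrices are plain TSV with checksums; every
  cross-stage handoff validates the bin-set checksum.
* Opposite-sign truth events overlapping by < 50 kb are tolerated in the
  simulator (printed microarray coordinates carry breakpoint-resolution
  slop) and resolved additively; larger opposite-sign overlaps are rejected.

## Validation experiment sizes

The bundled validation runs use the full-size study: a 100-control panel and
21 cases over 10,863 bins per mode (~20 s per mode on one CPU), 20
replicates per point for the mosaic sweeps, and 20 replicates for estimator
calibration. Three events sit at the screen's stochastic detection floor —
the 855 kb three-bin deletion, the 50%-mosaic duplication (per-bin |Z| ≈
2.4 against the 2.5 standard), and the prospective 555 kb two-bin deletion
(expected Viterbi evidence ~17–19 nats against the ~20.4-nat entry penalty)
— so their recovery varies between replicate runs; everything at or above
~950 kb constitutional size is recovered essentially always without WGA.

## Known limitations

* Breakpoints are bin-quantized; reported sizes exceed microarray sizes by
  up to one bin per side.
* The screen cannot see copy-neutral events (balanced translocations,
  inversions except via breakpoint CNVs, uniparental disomy).
* Mosaic fractions below ~10% are below both statistics' floors at default
  depth; marker chromosomes with little unique sequence yield too few reads
  to score.
* X/Y calling requires known sample sex; unknown sex scores autosomes only.
* The per-bin Z treats bins as exchangeable after panel normalization;
  recurrent artifacts absent from the panel (e.g. a different library prep)
  will produce systematic false calls.
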