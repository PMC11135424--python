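# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices that were genuinely
open, in enough detail to audit or extend the package.

## Coordinates and containers

All intervals are 0-based half-open (BED-native); GTF input is converted
on read (start − 1) and restored on write. Strand `.` is legal for peaks
(binding is undirected) but rejected wherever transcription direction
matters: flank logic, metaplot orientation, flank-sequence extraction.
Signal tracks are step functions — sorted non-overlapping runs per
chromosome, 0 outside runs — backed by a cumulative integral so that the
mean over any interval (and hence metaplot binning) is O(log n) per
query. bedGraph values are taken as already library-size normalized;
a scale factor is the only renormalization offered, because normalization
provenance belongs upstream of this package.

## Differential splicing

PSI uses effective-length normalization,
psi = (I/l_I) / (I/l_I + S/l_S); for a skipped exon counted on junctions
l_I = 2 and l_S = 1. PSI is invariant to scaling both lengths jointly.
Replicates with zero informative reads are dropped per event (never
imputed); counts are then pooled within group.

The two-group test is a binomial likelihood-ratio test on pooled counts:
inclusion reads ~ Binomial(total, f) with group-specific f under the
alternative and shared f under the null, statistic referred to chi-square
with 1 df. Because the inclusion fraction f is a strictly monotone
function of psi given the effective lengths, the LRT is identical in
either parameterization. This replaces a hierarchical event model a
read-level tool would use: it is fully specified, exact to implement, and
validated end to end on simulation. Its known limitation is
overdispersion — pooling replicates assumes binomial sampling, so
biological replicate variability (rho > 0 in the generator) inflates the
type-I error. The null-calibration checks therefore run at rho = 0; with
overdispersed data the p-values should be treated as anticonservative, or
the test swapped for a beta-binomial LRT.

BH correction is applied across all tested events of all types jointly
(no stratification by event type). Calls require FDR < 0.05 AND
|dPSI| > 0.1 AND gene TPM > 1; the TPM filter is skipped for events with
no expression annotation rather than silently failing them. Direction is
`included-in-mutant` for dPSI > 0 (the sign convention makes the
"excluded exon" of the motivating biology — skipped in control, included
after factor loss — a positive dPSI).

## Binding enrichment

"Bound" means ≥ 1 bp overlap between any peak and the exon's symmetric
window; windows clip at the contig start. The headline statistic is the
ratio of bound proportions (relative risk), because "binds X times more
often" arithmetic on percentages matches proportions, not odds; the odds
ratio is reported alongside, and a nearest-peak-distance helper is
provided for distance-based analyses. The Fisher p is two-sided by
hypergeometric tail summation with the same point-probability inclusion
rule as R's `fisher.test` (relative tolerance 1e-7); it is verified
against an exact integer-arithmetic enumeration oracle to 1e-10 over all
tables with margins ≤ 30, and against an independent library
implementation.

Exons are deduplicated by coordinates before counting (an exon shared by
two genes counts once). In directional mode, the downstream flank is
[end, end + w) on `+` and [start − w, start) on `-`; a peak overlapping
the exon body is excluded from both flanks so flank-only binding
partitions cleanly. The directional summary reports both a Fisher test on
the marginal bound counts and a sign test restricted to exons bound on
exactly one flank (the paired design).

Gene-set enrichment is a one-sided upper-tail hypergeometric test per
set, sets intersected with the universe first, BH across sets.

## Metaplots

50-bp bins over ±2.5 kb around the exon midpoint give 101 bins with
centers −2500..2500 (inclusive endpoints, the convention of the common
annotate-and-histogram ChIP tools); start/end anchoring is available via
a flag. Each bin value is the mean track signal over the bin's bases;
windows running off the contig start are clipped, zero-filled and
flagged. Minus-strand rows are reversed so positive offsets always mean
downstream in transcription direction. Per-bin comparisons use the
two-sided Wilcoxon rank-sum test — exact null distribution when
n·m ≤ 400 and the data are tie-free, normal approximation with tie
correction otherwise — then BH across the 101 bins. Profiles are averaged
raw (no per-exon rescaling) by default since the input tracks are already
normalized; per-exon standardization can be layered on by callers.

## Motif enrichment

PWMs are position probability matrices (each row sums to 1, length ≥ 4)
read from MEME-format text. Scanning is sense-strand only — the motifs
model RNA-binding proteins acting on pre-mRNA — with log-odds scores
against a 0-order background recomputed per run from the background
sequence set. A hit requires score ≥ 0.8 × the maximum attainable score,
the common PWM practice, exposed as a parameter. Windows containing
non-ACGT bases are skipped. Flank extraction returns exon + 10-kb flanks
as one concatenated sequence per exon, reverse-complemented for
minus-strand exons so scanning is in pre-mRNA orientation.

Set-level enrichment is a window-level 2×2 Fisher test (windows with
≥ 1 hit vs without, foreground vs background) with BH across motifs; the
hit-density ratio (hits per bp, fg/bg) is reported as the effect size.
"Paused polymerase sites" have no standard computational definition; the
operational one here is the signal maximum within an exon's ±2.5-kb
window when it exceeds a caller-set quantile (default 0.9) of all
exon-window maxima.

## Screen scoring

RQ = 2^−(Ct_target − Ct_reference); the PSI fold change is
(RQ_inclusion/RQ_total) normalized to the negative control's ratio within
the same replicate (each experiment carries its own control, normalizing
between-experiment variance), then averaged across biological
replicates. z-scores per readout are computed with the sample sd (n − 1)
over detected library factors, controls excluded — controls are judged
against the library distribution, so they should not shape it (inclusion
is a flag). A factor is a hit when it is detected, both readout z-scores
exceed the positive control's, and z5 + z21 > 2. Detection requires the
total-transcript amplicon below the Ct detection limit (default 35
cycles) in every replicate. Zero variance in the library fold changes is
a hard error ("degenerate screen") rather than a silent division.

## Methylation

Beta = m/(m+u) for coverage at or above the floor (default 1), otherwise
absent. The default comparison is CpG-paired — the same amplicon CpGs are
measured in both conditions — with a two-sided t-test across per-CpG
differences, mean difference and 95% CI; Wilcoxon signed-rank and an
unpaired t are flags. CpGs covered in only one condition are dropped from
the paired test and counted separately. The unit of analysis is the CpG,
not the read. Degenerate inputs: identical beta vectors return mean
difference 0 with p = 1 (no evidence of change is a valid answer), while
constant *nonzero* differences raise, since a t-test with zero variance
and nonzero mean is undefined; the boundary uses a 1e-12 tolerance to
absorb float rounding in count-derived betas.

## The synthetic-data generator

The generator's defaults define the study conditions the tests exercise:

| parameter | default | rationale |
| --- | --- | --- |
| replicates | 2 control vs 3 mutant | the motivating study's design (three null vs two wild-type animals) |
| null PSI | Beta(2, 2) | broad, bounded away from 0/1 |
| true-event dPSI | 0.3 | comfortably above the 0.1 call threshold |
| fraction included-in-mutant | 0.59 | the direction split reported for the motivating dataset |
| read depth | Poisson(100)/event/replicate | deep-RNA-seq scale for a single junction |
| dispersion rho | 0 | binomial sampling; the LRT's stated regime |
| expression filter | 10% of null genes at TPM < 1 | exercises the filter without entangling it with effect recovery |
| background peaks | 7 per Mbp | ≈ 7% of 5-kb exon windows hit by chance, the background-binding scale of the motivating data |
| planted-peak probability | 0.10 (or solved for a target ratio) | foreground bound proportion ≈ 15% — a bound-proportion ratio ≈ 2.25 |
| peak offset | Uniform(0, 2 kb) downstream | strictly 3′ of the exon in transcription direction |
| stalling bump | Gaussian, amplitude 2, sd 300 bp | unimodal bump inside the ±2.5-kb window; no shape is prescribed by the biology, any unimodal bump exercises the metaplot |
| screen | 71 library factors, 5 spiked hits (effect +0.5), positive control +0.25, Ct noise 0.1/well over 3 technical and 2 biological replicates | the motivating screen's geometry; spiked hits must beat a strong but sub-hit positive control |
| methylation | 200 CpGs, coverage Poisson(50), Beta means 0.6 vs 0.7 | a −0.10 group difference at amplicon-sequencing depth |

Junction counts are beta-binomial around the group PSI (rho = 0 recovers
binomial) with the inclusion-read fraction mapped through the effective
lengths. Effects that would push PSI outside (0.01, 0.99) are clamped and
recorded in the ground truth. Low-TPM genes are drawn only among null
events so the expression-filter truth and the effect-recovery truth stay
separable. Every generator draws from its own seed stream
(SeedSequence([seed, stream_id])), so outputs are byte-identical under a
seed and adding a generator never perturbs another's stream.

`peak_fg_prob_for_ratio` solves the planting probability whose *expected*
bound-proportion ratio equals a target, accounting for background peaks
also hitting foreground windows — used to calibrate the ratio-recovery
simulations.

Screen Ct values model the assay protocol in which each reported value is
the mean of three technical replicates (noise sd ct_noise_sd/sqrt(3) per
reported Ct). Without that averaging, the positive control's z-score —
estimated from just two wells per readout — is noisy enough (sd ≈ 1.25 in
z units) that genuine hits fall below it in a quarter of plates; with it,
exact recovery of the spiked set is the norm.

What the generator does *not* emulate: read-level artifacts (alignment
bias, PCR duplicates, mappability), multi-cassette genes and non-SE event
types (the PSI/LRT machinery accepts them via caller-supplied counts, but
only SE is simulated end to end), correlated peak placement (clustered
binding), signal-track noise (tracks are deterministic given peak
placement), amplification-efficiency differences in qPCR, and
read-level bisulfite conversion errors. Passing tests therefore
demonstrate correctness of the statistics under the stated sampling
models, not robustness to those real-data artifacts.

## Validation design notes

Two null-calibration subtleties are deliberate design choices rather than
workarounds. First, the binding null ensemble compares cassette exons of
*disjoint* gene sets: a same-gene constitutive-exon background shares
window bases with the foreground, positively correlating bound statuses
and making Fisher p-values conservative — a property of that comparison
design worth knowing when interpreting within-gene backgrounds on real
data. Second, exact-test p-values are discrete; at a few hundred exons
per side the discreteness alone visibly distorts a uniformity check, so
the calibration ensemble uses 2000 exons per side where the p-value
distribution is effectively continuous.

Problem sizes in the validation suite (2000 null events, 1000-event
recovery runs, 500 foreground exons, 200-dataset null ensembles,
200 exons/group metaplots, 100 screen plates, 100 motif-power runs) were
chosen so each stage's property is measured with comfortable statistical
margin while the whole suite stays fast enough to run routinely.

## Known limitations

- The LRT is anticonservative under overdispersion (see above).
- One cassette exon per gene keeps the event-exon mapping unambiguous;
  multi-cassette genes are out of scope.
- The Fisher-based directional comparison treats downstream and upstream
  flags as independent margins; the sign test is the paired alternative
  and both are reported.
- PWM scanning is single-strand and 0-order-background only; no de novo
  discovery, no higher-order background models.
- The screen scorer assumes a single plate; multi-plate batch correction
  is out of scope.
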