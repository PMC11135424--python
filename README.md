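# splicechrom

Chromatin-factor-aware alternative-splicing analysis: a reusable pipeline
for asking whether loss of a chromatin protein (the motivating case is the
SMC-family protein SMCHD1, whose loss causes the muscular dystrophy FSHD2
via D4Z4 hypomethylation) changes cassette-exon splicing, whether the
factor's ChIP-seq binding sites cluster near the mis-spliced exons, whether
elongating RNA polymerase II stalls there, which RNA-binding-protein motifs
distinguish the affected exons, which splicing factors reproduce the effect
in a dual-readout knockdown screen, and whether downstream loci change
their CpG methylation.

The package is aimed at computational biologists who have junction-level
read counts, peak calls, normalized signal tracks, qPCR plates and
bisulfite count tables, and want the statistics between those inputs and
the figures — plus a fully seeded synthetic-data generator with ground
truth, so every stage can be validated end to end without touching real
data.

## The statistics at the core

**Differential splicing.** For a cassette exon with inclusion-supporting
reads $I$, skipping-supporting reads $S$ and effective lengths $l_I, l_S$,
the percent-spliced-in is

$$\psi = \frac{I/l_I}{I/l_I + S/l_S},$$

pooled within condition. Group differences are tested with a binomial
likelihood-ratio test (group-specific vs shared inclusion fraction,
$\chi^2_1$), BH-corrected jointly across events; an event is called when
FDR < 0.05, $|\Delta\psi| > 0.1$ and the host gene is expressed
(TPM > 1). $\Delta\psi$ is mutant − control, so exons skipped in control
but included upon factor loss ("excluded exons") have $\Delta\psi > 0$.

**Binding enrichment.** An exon is *bound* when any peak overlaps a
symmetric window (default ±5 kb; ±1 kb offered) by ≥ 1 bp. Enrichment of a
foreground exon set over a background set is the ratio of bound
proportions (relative risk) with a two-sided Fisher exact p computed by
hypergeometric tail summation; strand-aware upstream/downstream flank
flags feed a directional comparison.

**Metaplots.** Signal is averaged in 50-bp bins over ±2.5 kb around exon
centers (101 bins), minus-strand profiles reversed, and two exon groups
are compared per bin by the two-sided Wilcoxon rank-sum test with BH
across bins.

**Motifs.** DNA-encoded RBP position weight matrices (MEME format) are
scanned sense-strand with a log-odds score against the background set's
base composition; hits require ≥ 0.8 of the maximum attainable score.
Set-level enrichment is a window-level Fisher test plus a hit-density
ratio.

**Screen scoring.** qPCR relative quantities $2^{-\Delta C_t}$ give a PSI
fold change (inclusion RQ / total RQ, normalized to the negative
control); z-scores over the detected library factors are computed per
readout, and a factor is a hit when both z-scores exceed the positive
control's and their sum exceeds 2.

**Methylation.** Per-CpG beta values $m/(m+u)$ from bisulfite counts,
compared between conditions with a CpG-paired t-test.

## Worked example

```python
from splicechrom import simulate as sim, splicing as sp, binding as bd

cfg = sim.SimConfig(seed=42, n_genes=500, n_true_events=100, peak_fg_prob=0.3)
ann = sim.simulate_annotation(cfg)
counts, expr, truth = sim.simulate_junction_counts(cfg, ann)

events = sp.call_events(sp.event_table(counts, expr))
summary = sp.summarize_direction(events)
print(f"called {summary['n_called']} events "
      f"({summary['frac_included']:.2f} included / {summary['frac_excluded']:.2f} excluded in mutant)")

peaks, truth = sim.simulate_peaks(ann, truth, cfg)
fg = [ann.cassette_exons()[e] for e in sim.excluded_exon_ids(truth)]
comp = bd.enrichment_vs_background(fg, ann.all_exons(), peaks, window_bp=5000)
print(f"bound: {comp.n_fg_bound}/{comp.n_fg_total} foreground vs "
      f"{comp.n_bg_bound}/{comp.n_bg_total} background exons")
print(f"enrichment ratio {comp.ratio:.2f} (odds ratio {comp.odds_ratio:.2f}), "
      f"Fisher p = {comp.p_value:.2e}")
```

prints

```
called 98 events (0.63 included / 0.37 excluded in mutant)
bound: 19/64 foreground vs 146/1500 background exons
enrichment ratio 3.05 (odds ratio 3.92), Fisher p = 1.29e-05
```

Of 100 planted PSI shifts, 98 are recovered at FDR < 0.05 with the
expected direction split; the exons included upon factor loss carry peaks
within 5 kb 3.05× as often as all exons. Adding the directional test
(`bd.directional_test(bd.directional_occupancy(fg, peaks, 5000))`) shows
the binding sits downstream: 17 downstream-bound vs 2 upstream-bound
exons (Fisher p = 2.8e-04), matching how the peaks were planted.

A command-line interface mirrors the library
(`splicechrom simulate | convert | splice | bind | metaplot | motifs |
screen | meth`); see `splicechrom --help`.

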