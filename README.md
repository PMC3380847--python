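# foxpair

Comparative genome-wide occupancy analysis for a pair of paralogous
transcription factors, built around the forkhead (Fox) family case: two
factors that recognize the same core DNA motif yet occupy partly disjoint
sets of sites with distinct sequence, chromatin and regulatory properties.
The package ships a fully synthetic two-factor ChIP-seq benchmark with known
ground truth, so the entire analysis runs and is testable with no external
data.

It is aimed at computational biologists who want a small, transparent,
deterministic pipeline for differential-occupancy questions: which sites are
bound by both paralogs, which are factor-specific, and how the classes
differ in motif strength, flanking sequence, enhancer-mark context, distance
to transcription start sites, and downstream expression response.

## The analysis

1. **Peak calling with subsample consensus.** Tags are extended to
   fragments; candidate regions are maximal runs of coverage ≥ 2 fragments.
   Each candidate is scored by library-normalized fold change over input,

   FC = ((n_chip + c) / N_chip) / ((n_input + c) / N_input),

   and retained at an empirical FDR: a pseudo-ChIP of N_chip tags drawn from
   the input pool is called identically, and the cutoff is the smallest f
   with #pseudo(FC ≥ f) / #chip(FC ≥ f) ≤ 0.05. The call is repeated on ten
   90% random subsamples; union-merged regions found in ≥ 3 runs survive.
2. **Occupancy classification.** Overlapping A/B peaks (≥ 1 bp) are merged
   into *common* sites. A remaining factor-A peak of length L with n
   cross-factor tags is *A-only* when the density
   d = n · (10⁶/N_B) · (10³/L) stays ≤ 1 tag per million per kilobase
   (otherwise *ambiguous*); symmetrically for B.
3. **Motif analysis.** The degenerate forkhead core T[A/G]TT[G/T]AC (4 exact
   7-mers) is scanned on both strands at 0–2 mismatches; per-class
   perfect-match fractions, flanking-base profiles around perfect matches,
   and Fisher-exact PWM enrichment (relative score ≥ 0.8, sequence-based
   counting) are reported.
4. **Annotation.** Signed distance to the nearest TSS (negative = upstream
   of the gene) with ±100 kb histograms, and the fraction of each class
   overlapping histone-mark (enhancer-like) domains.
5. **Expression integration.** The knockout expression table is filtered at
   |FC| ≥ 1.5 and FDR ≤ 15% (BH); *direct targets* are DE genes with a
   factor-specific peak near their TSS; factor-rooted feed-forward loops
   (factor binds both a regulator and that regulator's target) are
   enumerated from an edge list.

The synthetic generator plants the three site classes with the class
structure the analysis is meant to detect: shared sites carry a perfect
consensus with a preferred C one base upstream and T one base downstream;
B-only sites carry a mostly-perfect core preceded by TGTT; A-only sites
carry a weak core (a minority perfect, the rest 1–2 mismatches). Domains
cover 92% / 29% / 68% of the shared / A-only / B-only classes, and 41% of
DE genes in the factor-B knockout table are direct (bound) targets.

## Worked example

Run the numbered drivers in order (each stage reads only the previous
stage's files under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_call_peaks.py
python analysis/03_classify_occupancy.py
python analysis/04_motif_analysis.py
python analysis/05_annotate_sites.py
python analysis/06_integrate_expression.py
```

With the default configuration (1 Mb genome, 100 shared / 50 A-only /
50 B-only sites, seed 7) this prints:

```
factor A: 144 consensus peaks (108 supported by all 10 runs)
factor B: 148 consensus peaks (99 supported by all 10 runs)
common         93 sites
a_only         49 sites
b_only         50 sites
common   perfect-consensus fraction: 1.000 (93/93)
a_only   perfect-consensus fraction: 0.388 (19/49)
b_only   perfect-consensus fraction: 0.840 (42/50)
flank -1: modal base C at 0.869 (99 matches)
flank +1: modal base T at 0.848 (99 matches)
PWM enrichment (common vs background): OR=42.1, p=1.03e-23
common   domain overlap 0.957  within 10 kb of TSS 1.000
a_only   domain overlap 0.184  within 10 kb of TSS 1.000
b_only   domain overlap 0.720  within 10 kb of TSS 1.000
factor B: 26/63 DE genes are direct targets (41.3%)
feed-forward loops rooted at factor B: 9
```

Reading: nearly every planted site is recovered into its correct occupancy
class; common sites always carry a perfect consensus while B-only sites
carry more perfect cores than A-only sites; the planted C(−1)/T(+1) flank
preference, the per-class domain coverage, and the 41% direct-target rate
all come back within sampling error of the planted configuration.

The same pipeline is available as a CLI (`foxpair simulate | call |
classify | motif | annotate | integrate | run-all | config init`) and as a
single library call, `foxpair.pipeline.run_pipeline`.

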