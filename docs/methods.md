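# Methods

## Overview

This package re-implements a degradome-profiling analysis for human mRNA
decay: 5'-monophosphate tag libraries (PARE) report where decay
intermediates begin, capped-end tag libraries (C-PARE) report where
transcripts actually start, and RNA-seq reports steady-state levels. In
an XRN1-knockdown background, 5'-monophosphate intermediates are
stabilized, so three signatures become measurable per transcript:

1. **Stability** — the ratio of steady-state abundance (FPKM) to decay
   output (DPKM). A transcript producing significantly more decay tags
   than its expression level supports is unstable; the converse, stable.
2. **Endonucleolytic cleavage** — a discrete internal cut leaves a
   dominant tag peak (the *Max-seq*) against the diffuse exonucleolytic
   background.
3. **Decapping** — cap hydrolysis exposes a 5' monophosphate at the
   first nucleotide, so the PARE Max-seq falls exactly at the empirical
   cap position located from C-PARE.

Because the original libraries and annotation snapshot are not
reproducible at desk scale, the package ships a first-class synthetic
generator: every caller is validated by planting known signals and
measuring recovery, and by bounding false positives on a matched null.

## Tag standardization and mapping

Reads are adapter-trimmed, discarded when shorter than 20 nt and
truncated to exactly 20 nt (the protocol's tag length). Note the
length rule: inserts of 19 nt are discarded by default — the stricter
reading consistent with an all-20-nt final state; `min_len=19` restores
the permissive variant.

Three filters follow, in order: (i) simple-sequence repeats — any
12-nt window that is a perfect period-1/2/3 repeat; (ii) genomic
multi-hits — more than 20 loci on either strand of the reference at
≤1 mismatch (the mismatch allowance mirrors the genome-mapping step;
whether the original hit count was exact-match is not stated, so the
two stages share one convention); (iii) exact matches to the
mitochondrial sequence on either strand.

Mapping to cDNAs allows one substitution. The matcher is a
half-and-half seeded k-mer index: a 20-mer within Hamming distance 1 of
a reference window matches one of its 10-nt halves exactly, so
candidates come from a sorted hash table of reference 10-mers and are
verified by full comparison. All stages are vectorized over the
collapsed tag list; a 10^6-read library preprocesses in a few seconds.
The index is checked against an exhaustive per-position Hamming scan in
the tests. `N` never matches anything.

Conventions: a tag hitting k isoforms contributes its full count to
each (dominant peaks shared across isoforms of one gene are reported
per isoform, not split); the RPM denominator counts each distinct
mapped read once, regardless of isoform multiplicity; coordinates are
0-based half-open internally and converted at the GTF boundary.

## Abundance statistics

DPKM = (tag counts on the cDNA) × 10⁹ / (length × total mapped reads);
FPKM is the identical form on RNA-seq counts. Both are computed from
raw counts with explicit normalization (not by re-normalizing RPM), so
log2(FPKM/DPKM) equals the library-normalized count ratio exactly —
length cancels, which is what licenses testing the fold change with a
count test. Isoform deconvolution is replaced by direct per-transcript
counting; synthetic transcripts are unambiguous, and the simplification
is deliberate.

## Stability test

Per transcript, replicate counts are equalized to the geometric-mean
library size and pooled per condition (RNA-seq vs PARE). Under a
negative-binomial model with common dispersion φ, the pooled count per
condition is NB with shape r = 2/φ, and the conditional law of the
RNA share a given the total n is

  P(a | n) ∝ C(a + r − 1, a) · C(n − a + r − 1, n − a),

independent of the mean. The two-sided p-value sums every outcome at
most as probable as the observed one (with a 1e-10 log-scale tolerance
for floating-point ties). As φ → 0 this degenerates to the exact
conditional binomial test at p = 1/2, which is what the implementation
uses at φ = 0 and what the brute-force enumeration oracle checks.
All-zero transcripts get p = 1 by convention.

φ is estimated by method of moments — per-transcript
(s² − m)/m² on equalized counts, averaged over transcripts with mean
≥ 50 in a condition, floored at 0. The mean (not the median) is used:
with two replicates s² has one degree of freedom and a strongly
right-skewed law, so the median is biased low by roughly half; the
per-transcript moment estimator is unbiased and its cross-transcript
mean is stable at n = 500.

Classification applies three filters: abundance (mean FPKM ≥ 1 **or**
mean DPKM ≥ 1 — the original cutoff is unstated; 1 F/DPKM is the
conventional detectability floor and is exposed as `--min-abundance`),
significance (BH-adjusted FDR < 0.01), and fold change
(|log2(FPKM/DPKM)| > 2.5, read on the log2 scale since that is the
scale the quantity is defined on). The fold change uses
replicate-pooled counts with a 0.5 pseudo-count only when exactly one
side is zero.

## Cleavage calling

Per replicate and transcript, the Max-seq is the maximal-RPM position,
ties broken toward the 5'-most coordinate (deterministic, and
consistent with the 5'-biased peaks expected when 5'→3' decay stalls).
Four filters, strict inequalities, applied in order with survivor
counts logged: F1 identical Max-seq position in both replicates;
F2 SOA (sum of abundances on the transcript) > 50 RPM; F3 Max-seq
> 10 RPM; F4 Max-seq/SOA > 0.2. F2–F4 default to the replicate mean;
`per_replicate=True` requires each replicate to pass (the original
replicate semantics are unstated, so both modes exist). F1 across
independent replicates is the dominant specificity guard: under the
uniform null the probability that two independent draws put their
maximum at the same coordinate is small, and the measured null call
rate is ≤ 1%.

Cleavage positions are summarized as a 100-bin histogram of
ceil(100 × (position + 1)/length).

## Cap inference and decap calling

Each transcript gets a 400-nt window: 200 nt of genomic sequence
upstream of the annotated TSS concatenated with the first 200 nt of the
cDNA, reverse-complemented for minus-strand transcripts so offsets
increase 5'→3'; offset 0 is the annotated first nucleotide. Windows
truncate (flagged) near contig edges. Filtered tags are projected into
windows at ≤1 mismatch with RPM re-used from the library normalization,
so window and transcript profiles share a scale.

Cap calls need: F1 identical C-PARE window Max-seq offset across
replicates, F2 mean Max-seq > 10 RPM, F3 mean Max-seq share of
in-window abundance > 0.2. The PARE ratio denominator is in-window
abundance only (the alternative — transcript-wide — is not what the
window construction implies). A decap call requires a cap call and a
PARE window Max-seq, passing the same filters, at the same offset.

## Synthetic data: what it emulates, and what it does not

The generator emulates: two biological replicates per library type;
20-nt 5'-end tags; a uniform decay background with planted peaks;
C-PARE concentrated at the cap with optional integer jitter
(round(Normal(0, σ))); negative-binomial RNA-seq replicate noise; and a
stable/unstable/neither mixture realized as a ±4 log2 RNA:PARE
intensity ratio (comfortably beyond the 2.5 calling threshold, as
planted classes should be). Defaults: 500 transcripts of 800–2000 nt,
20%/20% stable/unstable, 10% cleaved with peak fraction 0.4, 10%
decapped, libraries of 10⁶ reads, dispersion 0.05, per-transcript base
intensity log-normal with σ = 0.75. Library totals are exact
multinomial draws, so tag-count conservation is exact by construction.

Design choices worth noting:

* **Uniform background.** Real degradomes have structured backgrounds;
  uniformity is the analyzable null for the prominence and
  same-position filters. Passing recovery/specificity tests therefore
  demonstrates correctness of the calling logic, not performance on
  structured real backgrounds.
* **Plants avoid stable transcripts and are disjoint** (a transcript is
  cleaved or decapped, not both). This mirrors the biology — a dominant
  decay peak marks active turnover — and makes the
  "no stable transcript carries a cleavage call" cross-tabulation a
  meaningful emergent check rather than an assertion.
* **Cleavage positions are drawn ≥ 50 nt from both ends**, so peaks
  never run off the transcript and cleavage plants stay distinguishable
  from decap plants (which sit at the cap).
* **SSR-free sequences.** Genome and cDNAs are random A/C/G/T scrubbed
  of accidental 12-nt period-≤3 repeats, so no synthetic tag is lost to
  the SSR filter unless a test plants one deliberately.
* **The mitochondrial contig (`chrM`, 2 kb)** carries no transcripts;
  it exists so the mitochondrial filter has a real target.
* Everything derives from `SimConfig.seed` through fixed-index child
  seeds, so outputs are byte-identical across runs.

Not emulated: adapter contamination, sequencing errors, splicing,
structured decay backgrounds, isoform ambiguity, and non-poly(A)
capture biases (e.g. canonical replication-dependent histone mRNAs).

## Problem sizes and numerical choices

The standard fixture (500 transcripts × 10⁶-read libraries) is the
package's benchmark unit: one full pipeline run takes ~12 s, and the
recovery suite runs it for seeds 1–5 plus five matched nulls. The
replicate-correlation numbers on synthetic data (RNA-seq R² ≈ 0.93,
PARE R² ≈ 0.997 at dispersion 0.05) reflect the generator's noise
model, not the original libraries — synthetic PARE replicates are
multinomial (no biological overdispersion), so their correlation is
higher than real degradome replicates, and the RNA-seq correlation is
lower than deeply sequenced real libraries.

Known limitations: the exact test enumerates all n+1 conditional
outcomes (fine up to pooled totals ~10⁵ per transcript; very deep
libraries would want a tail-truncated enumeration); the multi-hit
filter counts loci, not alignments with quality weighting; gapped
alignment is out of scope.
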