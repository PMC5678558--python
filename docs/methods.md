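# Methods

`methgrass` analyses whole-genome bisulfite sequencing (WGBS) and
MeDIP-seq data for a two-genotype plant methylome comparison, and ships a
synthetic-data generator so the entire pipeline is testable without any
external download. This note documents the statistical procedures, the
generative model behind the synthetic data, the defaults and why they were
chosen, and the limits of what the synthetic benchmarks can show.

## Weighted methylation levels

All level summaries use the *weighted* methylation level of a site set S,

    W(S) = sum_{i in S} m_i / sum_{i in S} (m_i + u_i),

where m_i and u_i are methylated and unmethylated read counts at cytosine
i. W is read-count-weighted (not the mean of per-site fractions), robust to
uneven depth, and additive over disjoint site sets because numerators and
denominators pool. A set with no reads has an undefined level, reported as
missing rather than zero. Levels are computed per context (CG, CHG, CHH —
H in {A,C,T}), since plants methylate the three contexts through distinct
pathways with very different typical levels.

Defaults: genome-wide and per-feature levels use `min_depth = 1` (the
statistic's support is kept maximal); the per-site level *distribution*
(low < 0.2, 0.2 <= mid <= 0.6, high > 0.6, with strict outer inequalities)
uses `min_depth = 5`, matching the support required for differential
testing. Both are configurable.

CG sites are treated per strand — each strand's cytosine is an independent
site, exactly as the upstream per-cytosine report provides them. (CG
methylation is normally strand-symmetric in plants; pooling dyads is left
to the caller.)

## Metaprofiles

Gene/TE metaprofiles use fixed 100-bp flank bins over 2 kb on each side
and 20 scaled body bins; a site at offset o in a region of length L falls
in body bin `floor(20*o/L)`. Bin values pool counts across regions
(sum-meth over sum-reads per bin), so region order is irrelevant and the
profile inherits the weighted-level semantics. Minus-strand regions are
reversed so bin 0 is always 5'. TEs are profiled strand-agnostically when
the annotation carries no strand. Flank sites falling inside neighbouring
features are counted (no masking). Gene span (not mRNA span) is the body.

## Differential methylation

1. **Per-cytosine test.** For every cytosine covered by at least 5 reads
   in *both* genotypes, a two-sided Fisher exact test on the 2x2 table
   [[m_A, u_A], [m_B, u_B]]. Conditional on the margins the first cell is
   hypergeometric; the two-sided p sums the probabilities of all tables no
   more probable than the observed one, with a relative tolerance of 1e-7
   on the probability comparison to absorb floating-point rounding. The
   implementation is vectorised over sites (a genome-wide screen tests
   ~1e6 cytosines); sums within 1e-10 of 1 are snapped to 1 because the
   full-support sum is exactly 1 in exact arithmetic. Tests agree with an
   independent exact-enumeration oracle to <1e-10 over every table with
   margins <= 30.
2. **FDR.** Benjamini–Hochberg step-up within each context separately (the
   three contexts have very different site counts and effect sizes);
   pooled correction is available as a flag. DMCs are sites with q < 0.05.
3. **Clustering.** Within one chromosome, context and direction,
   consecutive DMCs with positional gap strictly less than 100 bp chain
   into one cluster (single linkage; strand ignored). Direction-aware
   clustering is a package choice — hyper and hypo counts are reported
   separately downstream and mixed clusters would cancel the region
   difference; a flag disables it.
4. **DMR filter.** Clusters with >= 4 DMCs AND span >= 50 bp are kept
   (conjunctive rule). Each genotype's weighted level is then recomputed
   over *all* same-context sites with depth >= 5 inside the cluster span —
   the conservative reading; a DMC-sites-only mode exists — and the
   cluster is a DMR iff |W_B − W_A| strictly exceeds the context
   threshold: 0.4 (CG), 0.2 (CHG), 0.1 (CHH).
5. **Direction and merging.** *Hyper* means higher in genotype B, *hypo*
   higher in genotype A. Within each direction, overlapping or book-ended
   DMRs from different contexts are unioned for downstream feature
   analysis.

Swapping the genotypes provably flips every direction and negates every
difference while leaving p-values, q-values and boundaries unchanged; the
suite asserts this. No biological-replicate dispersion model is fitted —
the design this package serves pools clonal ramets into one sample per
genotype, so the Fisher test treats reads as the unit of evidence.

## Feature assignment and enrichment

Regions (DMRs, peaks) are assigned one category by precedence
TE > CDS > 5'UTR > 3'UTR > intron > promoter > upstream_2kb >
downstream_2kb > intergenic, where the promoter is the 1 kb immediately 5'
of the TSS, upstream_2kb the 1–2 kb band beyond it, and downstream_2kb the
2 kb past the TES (strand-aware; strandless genes treated as plus). The
1 kb promoter width keeps the promoter and "2 kb upstream" categories
disjoint; both the width and the precedence order are configurable.

Overrepresentation uses a hypergeometric tail on a 100-bp genome tiling:
N = all tiles, K = tiles labelled with the category (same precedence),
n = tiles overlapped by any region, k = overlapped tiles in the category,
p = P(X >= k). The tiling supplies the integer sampling universe the test
needs; tile size is configurable. Because regions cover *adjacent* tiles,
the test is mildly anticonservative for multi-tile regions and
conservative (discrete) for tile-sized ones; BH-adjusted q-values across
the <= 9 categories are reported alongside raw p.

Nearest-TE assignment breaks exact distance ties toward the leftmost TE;
gene extraction near DMRs uses an inclusive 2 kb bound on the gap between
gene span and region.

## MeDIP comparisons

Peak density is peaks per Mb of chromosome, reported raw and rounded to
two decimals (numpy round-half-even). "Common peaks" between genotypes are
the merged >= 1 bp intersections of the two peak sets (no reciprocal
overlap fraction is imposed; configurable). BS-seq levels over peak
regions reuse the weighted level per context; genotype comparisons over a
shared region set use a paired two-sided t-test by default (each region is
measured in both genotypes; an unpaired mode exists). DMR/MeDIP
concordance reports interval-weighted mean bedGraph coverage per DMR and
per genotype, and counts direction-concordant overlaps (hyper DMRs vs
B-upregulated peaks, hypo vs A-upregulated). Differential MeDIP peak
calling itself is out of scope: differential peak sets are inputs.

## The synthetic generator

`simulate` builds, deterministically per seed: a random genome at a
configurable GC fraction (default 0.46), a gene/TE annotation
(non-overlapping genes with exon/intron/UTR structure; TEs intergenic plus
an intronic fraction; classes LTR/Copia, LTR/Gypsy, LINE, DNA), a
two-genotype per-cytosine methylome, and MeDIP-like coverage/peaks.

**Sites.** Cytosine positions and contexts are derived from the simulated
sequence on both strands, so CG/CHG/CHH site ratios emerge from base
composition. Cytosines lacking a full trinucleotide at sequence edges are
skipped.

**True levels.** Each site draws from a context-specific three-component
Beta mixture (near-zero, intermediate, high). Sites inside TEs use an
elevated mixture; sites within 2 kb of a Gypsy TE receive an extra CG/CHG
boost toward 1 (emulating the spread of silencing around Gypsy elements);
a V-shaped dip multiplier (floor 0.15 over ±200 bp) is applied around each
TSS and TTS. The CG mixture is bimodal by construction.

**Observation model.** Depth is negative binomial (mean 20, size 5) per
site and genotype, and methylated reads are Binomial(depth, level).
Critically, the *expected depth shrinks with methylation*:
E[d] = 20·(1 − 0.49·level). This mappability bias emulates a real feature
of plant WGBS: heavily methylated, repeat-derived fragments map uniquely
less often (the motivating datasets kept only uniquely mapped reads at
41–45% mapping rates), so the read-weighted genome mean sits well below
the unweighted per-site mean. It is what lets a genome whose CG sites are
~40% unmethylated and ~48% highly methylated still show a read-weighted
CG mean of 0.38 — without it those two published summaries are mutually
inconsistent. The bias coefficient and the CG mixture weights were
calibrated once against those published summaries and then frozen.

**Normalisation.** Per context and genotype, levels are monotonically
rescaled so the *expected read-weighted* mean under the biased-depth model
equals the configured value exactly (bisection; defaults CG 0.38/0.36,
CHG 0.25/0.24, CHH 0.05/0.04 for genotypes A/B). Genotype B is a
deterministic transform of A — identical when the configured means are
equal, which is the null construction used for FDR studies.

**Planted DMRs.** Non-overlapping windows (default 100 windows of 300 bp
with >= 8 CG sites; placement retries capped) overwrite both genotypes:
the low-side genotype draws near-zero levels ((1−Δ)·Beta(0.5,12), mean
~0.02) and the high side sits exactly Δ = 0.5 above — DMRs flip between
an unmethylated and a methylated state, the typical CG-DMR contrast. The
truth set (intervals, direction, context, Δ) is returned for scoring.

**MeDIP.** Expected window coverage is a Poisson with rate
background + scale·(summed observed site levels in the window), capturing
both methylation level and cytosine density. A window is peak-worthy when
its coverage exceeds 1.5x the genome-wide median and a Poisson tail test
against the median at p < 1e-6; adjacent peak windows merge. A fully
unmethylated genome therefore yields no peaks, and peaks concentrate in
TEs.

**What the generator does not emulate.** Read-level artefacts (bisulfite
conversion failure, M-bias, PCR duplicates), strand-symmetric CG dyad
maintenance (strands draw independently), linkage between neighbouring
sites outside planted DMRs, real repeat taxonomy (SINE/Helitron classes
exist in the type system but are not placed by default), subgenome
structure, and biological replicates. Benchmarks passed on this generator
therefore demonstrate the correctness and calibration of the *pipeline
arithmetic and inference* under a plausible observation model — not
performance on real switchgrass libraries.

## Problem sizes and numerical choices

The test suite and acceptance script run on a 2 Mb two-chromosome default
genome (~9.2e5 cytosines), 50 null replicates of ~10^4 jointly covered
sites for FDR control, and exhaustive Fisher verification over all 245,025
tables with margins <= 30 — sizes chosen so a full run completes in a few
minutes on one core while leaving every statistical check well-powered.
Other numerics: Fisher probability comparisons use a 1e-7 relative
tolerance; p-sums within 1e-10 of 1 snap to 1; BH comes from
statsmodels; the weighted-mean normalisation bisects to 1e-10; per-Mb
densities round half-even to two decimals; paired t-tests with zero
difference variance report a missing p-value with a "no difference" note.

## Known limitations

- The Fisher/BH screen treats sites independently; spatial correlation of
  methylation is only exploited post hoc through clustering, not modelled.
- The enrichment tiling inherits the granularity of `tile_bp`; categories
  thinner than a tile are diluted.
- `bedGraph` coverage is the only supported MeDIP signal format (BIGWIG
  conversion is upstream).
- With a single pooled sample per genotype, between-ramet variance is
  invisible; q-values quantify sampling noise given the pooled counts,
  not biological reproducibility.
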