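# methgrass

Weighted methylation statistics, metaprofiles, differentially methylated
region (DMR) calling, feature enrichment and MeDIP/BS-seq concordance for
two-genotype plant methylome comparisons — with a built-in synthetic
two-genotype methylome generator so every stage runs and is tested without
any external data.

The package is aimed at analysts comparing whole-genome bisulfite
sequencing (WGBS) profiles of two related plant genotypes (the motivating
system is the tetraploid switchgrass pair AP13, a lowland ecotype, and
VS16, an upland ecotype), optionally alongside MeDIP-seq peak calls.

## What it computes

* **Weighted methylation level** of a site set S per context
  c ∈ {CG, CHG, CHH}: `W(S) = Σ m_i / Σ (m_i + u_i)` over cytosines with
  methylated/unmethylated read counts m_i, u_i — read-weighted, additive,
  robust to uneven depth. Global, per-feature (TE, promoter, CDS, UTR,
  intron), per-window (bedGraph tracks), and paired across homeologous
  gene lists between subgenomes (paired t-test).
* **Metaprofiles**: 2 kb flanks in fixed 100-bp bins plus 20 scaled body
  bins over genes or TE classes (Copia/Gypsy/LINE/DNA), count-pooled.
* **DMR calling**: per-cytosine two-sided Fisher exact tests on sites with
  depth ≥ 5 in both genotypes → Benjamini–Hochberg FDR within context
  (DMC: q < 0.05) → chaining of DMCs < 100 bp apart → clusters with ≥ 4
  DMCs spanning ≥ 50 bp → DMR if the region weighted-level difference
  exceeds 0.4 / 0.2 / 0.1 (CG / CHG / CHH) → per-direction cross-context
  merging. *Hyper* = higher in genotype B, *hypo* = higher in genotype A.
* **Annotation**: one feature category per region by precedence
  (TE > CDS > UTR > intron > promoter > upstream 2 kb > downstream 2 kb >
  intergenic), hypergeometric overrepresentation on a 100-bp genome
  tiling, nearest-TE classes/lengths, genes within 2 kb of DMRs.
* **MeDIP**: per-chromosome peak densities (peaks/Mb), common peaks
  between genotypes, BS-seq level matrices over peak regions, paired
  genotype comparisons, and DMR/peak direction concordance.
* **Synthetic data**: seeded genomes, annotations, two-genotype cytosine
  reports with planted DMRs of known effect size, and MeDIP-like
  peaks/coverage. Defaults reproduce the published genome-wide statistics
  of the motivating study (weighted CG means 0.38/0.36, bimodal CG site
  levels with ~40% < 0.2 and ~48% > 0.6, CG > CHG > CHH, TE > genic).

Formats: Bismark-style cytosine/CX reports, GFF3, BED6, narrowPeak,
bedGraph, chromosome-length TSV. See `docs/methods.md` for the full model
description and design decisions.

## Worked example

Simulate a small two-genotype study, summarise it, and call DMRs:

```sh
methgrass simulate --seed 7 --out study --chrom-length 120000 --n-dmrs 5
methgrass stats --cx study/genotypeA.CX_report.txt --out-prefix st
methgrass dmr --a study/genotypeA.CX_report.txt \
              --b study/genotypeB.CX_report.txt --out-prefix d
```

which prints (genotype A summary, then the DMR funnel):

```
context  weighted_level  n_sites  prop_low  prop_mid  prop_high
     CG        0.379522    25088  0.394464  0.128196   0.477340
    CHG        0.249334    19513  0.489980  0.338861   0.171158
    CHH        0.049941    65587  0.916436  0.071987   0.011577

context  sites_tested  sites_p_lt_alpha  dmcs  clusters_kept  dmrs
     CG         22538               605    20              1     1
    CHG         18160               356     0              0     0
    CHH         62805               423     0              0     0
```

Reading this: genotype A's genome-wide weighted CG level is 0.380 with the
bimodal site distribution (39% of CG sites essentially unmethylated, 48%
highly methylated); CHG sits at 0.249 and CHH at 0.050, the canonical
plant ordering. Of 22,538 CG sites deep enough in both genotypes, 605 have
raw p < 0.05 but only 20 survive FDR control; they chain into one cluster
that passes the ≥4-DMC/≥50-bp/Δ>0.4 filters and is reported as one
CG-DMR. (At this toy genome size only the strongest planted DMRs emerge;
at the default 2 Mb scale the caller recovers ≥ 90% of 100 planted DMRs —
see below.) Outputs land in `d.dmcs.tsv`, `d.dmrs.tsv`,
`d.{hyper,hypo}.bed` and `d.funnel.tsv`, ready for
`methgrass annotate --regions d.hyper.bed --gff study/annotation.gff3`.

The same steps are available as library calls (`methgrass.simulate`,
`methgrass.stats`, `methgrass.dmr`, ...), which the test suite exercises
throughout.

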