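# hriquant

**How much adaptive protein evolution does a genome lose to Hill–Robertson
interference?**

Linked selection reduces the efficacy of natural selection wherever
recombination is scarce: beneficial mutations interfere with one another and
with segregating deleterious variation, and some adaptive substitutions that
would fix under free recombination are lost.  `hriquant` implements, as a
tested and reusable pipeline, the population-genomic procedure for
quantifying that loss in a *Drosophila*-style data set — per-gene ortholog
alignments of many ingroup haplotypes plus one outgroup, a fine-scale
crossover map, and gene-level covariates — together with a synthetic-genome
generator that provides ground truth for every estimator.

It is written for population geneticists who want to run (or stress-test)
this analysis on their own data or on simulations, from Python.

## The method

1. **Site classification.** Coding exons are filtered (overlaps resolved to
   the largest exon; exons with gaps, frameshifts or premature stops
   dropped; trimmed to full codons), and sites are classed physically:
   **0-fold** degenerate sites (every change is an amino-acid change),
   **4-fold** degenerate sites in exon-core codons whose amino acid is
   conserved between the two species, and positions 8–30 of **short introns**
   (≤ 65 bp) as an alternative near-neutral class.  Every column is
   downsampled without replacement to a fixed number of chromosomes
   (default 128) and folded site-frequency spectra (SFS) are built per
   class.  Divergence is counted on one randomly drawn ingroup chromosome
   against the outgroup and corrected for multiple hits — Jukes–Cantor at
   0-fold and intron sites, Tamura (1992) at 4-fold sites (allows GC bias
   and a ts/tv bias).

2. **Adaptive rate per gene bin.** Genes are ranked by local crossover rate
   (cM/Mb of the 100-kb window over the gene midpoint) and pooled into
   equal bins (e.g. 45 bins × 136 genes).  Per bin, a two-epoch demography
   is fitted to the neutral folded SFS and a gamma distribution of
   deleterious fitness effects (DFE; mean γ = −N<sub>e</sub>s, shape β) to
   the 0-fold folded SFS, by multinomial maximum likelihood over folded
   bins.  The fitted DFE predicts the nonadaptive nonsynonymous divergence
   d<sub>exp</sub> = K₄ · E<sub>f</sub>[S/(1−e^(−S))], and the excess is
   adaptive:

   α = (K_a − d_exp) / K_a, K_a⁺ = α·K_a, ω_A = K_a⁺ / K₄.

3. **The interference loss.** K_a⁺ rises with recombination and plateaus
   above ~2 cM/Mb.  A LOESS curve (local quadratic, tricube weights,
   span 1) smooths K_a⁺ against bin recombination rate; the mean K_a⁺ of
   bins above the threshold is the no-interference rate K_a⁺₍no HRi₎, and

   Total_noHRi = Σᵢ L_a(i) · K_a⁺₍no HRi₎ (all bins)
   Total_lost  = Σᵢ L_a(i) · (K_a⁺₍no HRi₎ − K_a⁺(i)′) (bins below threshold)
   **f_HRi = Total_lost / Total_noHRi**

   is the fraction of adaptive amino-acid substitutions lost to
   interference.

4. **Inference.** Bootstrap-by-gene percentile CIs (the whole pipeline
   rerun per replicate), paired Z contrasts between gene categories
   (gene-density × mutation-rate halves, with K₄ split into independent
   hypergeometric variates so the classification cannot contaminate the
   estimate), and a label-permutation test for immune/testes gene
   enrichment.

## Worked example

```bash
python examples/simulate_and_recover.py
```

```
simulated 2250 genes; true f_HRi = 0.191 (curve asymptote a = 0.0126)
estimated f_HRi = 0.209  (Ka+ without interference = 0.01279)

per-bin estimates (Ka+ rises with recombination and plateaus):
    mean_rr   alpha  ka_plus  loess_pred
0    0.0697  0.2017   0.0026      0.0047
...
14   7.7020  0.5375   0.0123      0.0124
```

The generator imposed K_a⁺(rr) = 0.0126 − 0.0121·e^(−2·rr): bins below
2 cM/Mb fall short of the 0.0126 plateau, and the site-weighted shortfall
(≈ 0.19 of the total here) is recovered by the estimator within sampling
error.  Other examples: `loss_arithmetic.py` (per-category and global loss
fractions from published substitution totals), `dfe_bin_fit.py` (a full
demography + gamma-DFE fit on one pooled bin), `bootstrap_ci.py`
(bootstrap-by-gene CI), `io_pipeline.py` (the file-based pipeline:
FASTA + GFF3 + recombination map → validated output tables).

A thin CLI covers the shell-worthy operations:
`hriquant simulate|all|validate`.

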