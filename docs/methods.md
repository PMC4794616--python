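# Methods

This note documents the models, numerical choices and known limitations of
`hriquant`, in the spirit of the methods documentation of mature
population-genetics packages.

## Site classification and counting

Per-gene records hold n aligned ingroup haplotypes plus one outgroup
sequence, with exon/intron intervals in alignment coordinates (0-based
half-open internally; GFF3 converted from 1-based inclusive at load).
Minus-strand genes are reverse-complemented once at load so all downstream
logic works on the coding strand in one frame convention.

Filters, in order: overlapping exons resolved by keeping the largest; each
survivor trimmed at its 3' end to full codons; exons containing an alignment
gap in any haplotype or the outgroup dropped; exons with a stop codon in any
sequence dropped, except a stop in the last codon of the gene's final exon
(the terminal stop).  Overlap resolution runs before the per-exon quality
filters; if the larger of two overlapping exons later fails a filter the
smaller is not revisited.

Degeneracy is computed on the ingroup *majority* codon (ties broken
lexicographically): a column is 0-fold iff all three base changes are
nonsynonymous, 4-fold iff all are synonymous.  4-fold columns additionally
require the codon to encode the same amino acid in every ingroup haplotype
and the outgroup; 0-fold columns of amino-acid-segregating codons are kept.
This asymmetry is deliberate: the conservation filter protects the
synonymous-rate (mutation-rate) estimate from hidden amino-acid exchange
paths, while the nonsynonymous inventory must keep the very sites where
amino-acid change happens.  Codons within `core_margin_codons` (default 8,
configurable) of either exon boundary are excluded ("exon core"), as are
codons containing an ambiguous base in any sequence.

Short-intron sites are positions 8–30 (1-based from the 5' end, coding
strand) of introns ≤ 65 bp; the terminal splice AG is excluded explicitly
for introns short enough that the range reaches it; a gene contributes only
if ≥ 2 introns qualify and the gap fraction across their aligned columns is
< 10%.

Every column is downsampled to a fixed chromosome number (default 128) by
drawing called alleles uniformly without replacement; columns with fewer
called alleles, or an uncalled outgroup base, are excluded from all classes.
Divergence is counted on one uniformly drawn ingroup chromosome (pinnable
for reproducibility and round-trip tests).  If that chromosome is uncalled
at a column the column simply cannot contribute a difference; with the
site-class L as denominator this undercounts divergence by the haplotype's
missingness fraction, negligible for fixture-grade data and second-order for
real panels.  Tri-allelic columns are excluded from the folded SFS and
tallied (the minor-allele count is undefined), but remain in L.

Multiple-hit corrections: Jukes–Cantor at 0-fold and intron sites,
K = −(3/4)ln(1 − 4p/3); Tamura (1992) at 4-fold sites,
K = −h·ln(1 − P/h − Q) − ((1−h)/2)·ln(1 − 2Q) with h = 2θ_GC(1−θ_GC),
which reduces to Kimura's two-parameter distance at θ_GC = 0.5.  θ_GC is
the mean GC fraction at 4-fold columns over the divergence haplotype and
the outgroup (the choice of species set here is not standardized in the
literature; using both is symmetric and stable).

Fop (frequency of optimal codons) = optimal codons / codons with synonymous
alternatives (Met, Trp, stops excluded).  The shipped optimal-codon table is
a documented D. melanogaster default (one preferred, C/G-ending codon per
degenerate amino acid) and is configurable — any serious use on another
taxon must supply its own table.  Gene density is the interval-union count
of coding positions of *all* annotated genes within ±50 kb of the gene
midpoint, per 100 kb, rescaled to the surveyed length at chromosome ends.
The recombination rate is read from the 100-kb map window containing the
midpoint, half-open convention, with no smoothing.

## Expected spectra and the DFE fit

Expected folded SFS under selection and a two-epoch history come from a
discretized Wright–Fisher recursion on a haploid grid of size `n_grid`
(default 200; desk-scale studies in the tests use 128, the minimum for
128-chromosome samples).  Per generation, frequencies move
deterministically by genic selection, Δp = σp(1−p) with σ = S/(2·n_grid)
(so S = 4Ns is grid-independent on the diffusion scale), followed by
binomial resampling; mutations enter at frequency 1/n_grid at a rate
proportional to population size (the epoch-2 inflow is scaled by N₂/N₁).
The ancestral epoch is solved to exact equilibrium by a linear solve,
u = (I − Tᵀ)⁻¹e₁; after the size change the state is projected onto the
epoch-2 grid (one reproduction step) and iterated round(t₂·n₂/2)
generations (t₂ in units of N₂ generations, capped at 600 iterations);
finally n chromosomes are sampled binomially and the spectrum folded.  The
model depends on (N₂/N₁, t₂) only through the integer grid size and
generation count, which the engine exploits by memoizing whole folded
spectra — the property that makes per-bin likelihood fits affordable.

Grid coarseness matters at sample sizes near the grid size: rare-variant
classes are compressed relative to the diffusion limit.  Generator and
estimator share the engine, so recovery tests are internally consistent;
absolute spectra at n close to n_grid should not be compared against
closed-form diffusion expectations (at n ≪ n_grid they agree well; the
neutral folded spectrum at n = 4 matches the 1/i law to < 0.005).

Likelihoods are multinomial over folded bins, conditional on segregating.
The demography (log N₂/N₁ ∈ [log 0.1, log 5], log t₂ ∈ [log 10⁻³, log 2])
is fitted on the 4-fold SFS by Nelder–Mead from four fixed starts with the
constant-size model always evaluated as a candidate; the gamma DFE
(γ̄ = −N_e·s ∈ [10⁻³, 10⁶], β ∈ [0.05, 5], log-parametrized) on the 0-fold
SFS from five fixed starts, conditional on the fitted demography (two-step,
neutral first).  Convergence tolerance 10⁻⁸ on the log-likelihood.  The DFE
is discretized on a fixed quadrature of 64 mass points log-spaced in
|S| ∈ [10⁻⁴, 10⁴] plus a neutral point; gamma mass below/above the grid
goes to the neutral/last point.  Deterministic throughout — no stochastic
restarts.

Bit-compatibility with the original DFE-alpha binary is explicitly not a
goal; the contract is the published model (gamma DFE, two-epoch demography,
folded multinomial likelihood) with recovery-on-simulation as the
acceptance surface.

The adaptive rate uses the DFE-averaged relative fixation rate
E_f[r(S)], r(S) = S/(1−e^(−S)) (semidominant diffusion limit, r(0) = 1):
d_exp = K₄·E_f[r], α = (K_a − d_exp)/K_a, K_a⁺ = α·K_a, ω_A = K_a⁺/K₄.
α may be negative (sampling noise or misspecification); bins with K_a = 0
are flagged rather than imputed.

## Splitting, binning, loss equations

When a grouping variable derives from 4-fold divergence, K₄ is split into
independent variates by sequential hypergeometric sampling: block sizes
round(0.33·L₄) twice (three-way) or round(0.5·L₄) (two-way), the last block
taking the remainder, so closure is exact for every seed; per-site rates
divide each block's hits by its *actual* integer block size.  Block-level
ts/tv counts are allocated proportionally to the gene's overall transition
fraction (the split partitions total divergent sites only).  Rank-binning
sorts ascending with gene-id tie-breaks, uses floor(N/n_bins) genes per bin
and discards the highest-keyed remainder (logged) — 6,141 genes → 45 bins
of 136 with 21 discarded.  Nested partitions split every non-final factor
into nearly equal rank groups and rank-bin the final factor, emitting
GenH/GenL × MutH/MutL labels for the 2 × 2 density × mutation design.

LOESS is local quadratic regression with tricube weights, span as the
fraction of points per local fit (default 1.0, i.e. all points weighted by
distance), evaluated at the observed bin positions — matching the R
`loess` defaults with span raised to 1, which stabilizes the curve across
bootstrap replicates.  The no-interference rate is the unweighted mean of
bin K_a⁺ above the recombination threshold (2 cM/Mb; 5 cM/Mb for gene
categories with no visible asymptote).  In the loss equations the
no-interference total runs over all bins and the lost total only over bins
below the threshold (the equation bodies leave the index sets implicit;
this is the reading consistent with "groups of genes with a rate of
recombination less than 2 cM/Mb").  Negative LOESS predictions can be
clamped to zero before the lost total (both variants are reported; they
differ by well under a point in practice).  With clamping f_HRi ≤ 1, and
f_HRi ≥ 0 whenever no below-threshold prediction exceeds the asymptote.

The linear model y = a + bx and the curvilinear model y = a + b·e^(−cx)
are compared by the extra-sum-of-squares F test with (1, n−3) df and by
AIC (Gaussian likelihood, error variance counted as a parameter, matching
R's AIC for lm/nls).  The curvilinear fit multi-starts over
c ∈ {10⁻⁶, 0.25, 0.5, 1, 2, 4} with (a, b) from the conditional linear
solve at each c; the 10⁻⁶ start covers the c → 0 boundary where the family
degenerates to a line, so the nested model is never beaten by more than
float conditioning (~10⁻⁴ of the RSS).  b ≈ 0 leaves c unidentifiable and
is flagged.

## Resampling

Bootstrap-by-gene: resample genes with replacement to the original count,
rerun binning + estimation + LOESS + loss equations per replicate; child
seeds spawn from the master seed (bit-identical replicates for identical
master seeds); replicate failures are logged and redrawn up to three times,
never silently dropped.  CIs are percentile intervals whose endpoints are
order statistics.  Paired category contrasts use Z = f̂_A − f̂_B per
replicate with one-tailed p the fraction of differences on the null side;
ties at zero count toward the null (conservative).  The permutation test
shuffles labels without replacement, recomputes the pooled class difference
per replicate, and divides the count below the observed difference by
exactly B; a flag enables the +1 convention.

## The synthetic genome generator

The generator draws what the analysis consumes — spectra, divergence,
covariates — at the spectrum level (Poisson random field): 4-fold and
short-intron folded spectra are neutral under the chosen demography, 0-fold
spectra follow the gamma DFE, with expected counts calibrated so a neutral
constant-size class has E[segregating sites] = L·θ·a_n (Watterson).
Divergence has a nonadaptive component K₄·E_f[r] and an adaptive component
K_a⁺(rr) = a + b·e^(−c·rr); raw difference counts are drawn at the
*observed* scale by pushing true rates through the inverse Jukes–Cantor /
Tamura maps, so the analysis-side corrections recover the generating rates.
Ground truth (per-gene rates and the implied global f_HRi, with
K_a⁺₍no HRi₎ := a) is returned alongside the data.

Defaults are chosen once to emulate an autosomal *Drosophila*-like coding
genome in 128 lines with a *D. yakuba*-distance outgroup: θ₄ = 0.02 per
site, K₄ = 0.19, gamma DFE (γ̄ = 2000, β = 0.3), mild expansion
(N₂/N₁ = 1.5, t₂ = 0.1), ~1,000 0-fold sites per gene with L₄ ≈ 0.35·L₀,
lognormal mutation-rate heterogeneity (σ = 0.3), transition fraction 0.65,
recombination as a mixture of a near-zero component (25% uniform on
[0, 0.5] cM/Mb) and a broad gamma (shape 2, scale 1.5, truncated at 10), so
both sides of the 2 cM/Mb threshold are populated.  The adaptive curve
default (0.0126, −0.0121, 2.0) keeps the empirically plausible asymptote
while staying non-negative at rr = 0 (a validated constructor invariant;
steeper published amplitudes go negative below ~0.2 cM/Mb and therefore
cannot serve as a generating law).

What the generator does *not* emulate: linkage itself (interference enters
only through the imposed K_a⁺(rr) law — the target is the estimator, not
the mechanism), ancestral polymorphism in divergence, gene conversion,
selection on synonymous sites, alignment error, and spatial
autocorrelation of rates along chromosomes.  Passing recovery tests
therefore validates the estimation chain under the model's own assumptions;
they say nothing about robustness to these real-data features.

`emit_fixtures` additionally materializes genes as FASTA + GFF3 +
recombination-map files built from GGN codons (two 0-fold + one conserved
4-fold site each) and ATG fillers (three 0-fold sites), flanked by
exon-core margins, plus two 60-bp introns.  Each drawn L₀ is snapped to the
nearest composition-realizable value (L₀ = 2L₄ + 3m), and haplotype 0
carries no minor alleles so a pinned divergence line makes the file →
reader → counts round trip exact.

## Calibration results and study sizes

The test suite runs every study at desk scale on one CPU; the sizes are
package choices, stated here so they can be scaled up:

* End-to-end recovery: 10 genomes of 6,120 genes (128 chromosomes, 45
  recombination bins, full per-bin DFE fits on a grid of 128); the mean
  f̂_HRi sits within 0.05 of truth.
* No-adaptation calibration: 24 genomes of 600 genes with a flat zero
  adaptive curve and a *homogeneous* mutation rate; α̂ centres on zero
  (pilot: mean −0.003, SE 0.009).  With per-gene mutation-rate
  heterogeneity on (lognormal σ = 0.3), pooled α̂ acquires a small positive
  offset (~+0.02 at these sizes): pooling genes of different true K₄
  through the concave rate↔proportion maps deflates the pooled synonymous
  rate (a Jensen effect), inflating the apparent adaptive excess.  This is
  a property of pooled MK-style estimation generally, not of this
  implementation; the homogeneous-rate design isolates the estimator.
  Users comparing gene classes with very different rate dispersions should
  keep it in mind.
* Bootstrap coverage: 200 genomes of 900 genes, B = 200, using the
  counts-only fast path with the generating fixation factor supplied (the
  resampling machinery is statistic-agnostic; refitting the DFE inside
  200 × 200 nested replicates — millions of likelihood fits — is not a
  feasible or necessary design).  Coverage of the 95% interval is ~93–95%.
* Null calibration: permutation p values (100 genomes, B = 100) and paired
  Z-test p values (200 genomes, B = 60 per category) are uniform by KS
  test.

## Known limitations

* The WF grid (128–200) is far below real effective population sizes;
  spectra are self-consistent but γ̄ beyond ~2·n_grid saturates the grid
  (such mutations are effectively absent from polymorphism either way, and
  the fixation integral uses the closed form, not the grid).
* γ̄ and β are weakly separately identified from a folded SFS; the
  downstream quantity E_f[r] is what the tests hold to account.
* Demography is a single size change; more elaborate histories are out of
  scope, as are unfolded spectra and non-gamma DFEs.
* The divergence haplotype's missing data slightly undercounts divergence
  (see above).
* f_HRi inherits the identification assumption that the >2 cM/Mb plateau
  is interference-free; nothing in the machinery can test that assumption
  from within.
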