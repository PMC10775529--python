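# Methods

This note documents the models, estimators and numerical choices behind
`er-driftscan`, and what the synthetic studies do and do not show about real
data.

## The drift null and the empirical p-value

The null model for a SNP's frequency change between generation 1 and
generation 9 is pure binomial drift: starting from the observed initial
reference-allele frequency (assigned to the nearest point on a 0.01 grid,
ties toward the lower grid value), 2·Ne gene copies are resampled for 8
generation transitions, 10,000 times per grid point, with every individual
equally fit.  The default Ne = 16 is intentionally much smaller than the
census of 36 plants: effective sizes in selection experiments vary between
generations and treatments, and a small Ne widens the null so that flagged
SNPs are conservative calls.  Ne, the number of transitions, the number of
simulations and the grid step are all configurable, and the simulated bank
is persisted (`.npz`) for reuse.

The empirical p-value counts simulated final frequencies at least as
extreme as the observed final, in the direction of the observed change:
decrease → `#{sims ≤ AF_final}/n_sim`, increase → `#{sims ≥ AF_final}/n_sim`,
no change → 1.  One published formulation prints the opposite inequality
for the decrease case; since that counts the wrong tail (an observed
crash in frequency would receive a p-value near 1), the package defaults to
the direction-consistent tails and provides `literal_tails=True` to
reproduce the printed formula verbatim.  The estimator can return exactly 0
when the observation escapes all 10,000 simulations; an optional
`(r+1)/(n+1)` style correction was considered and rejected to keep the
default faithful to the source procedure — zero p-values are legitimate
outputs of this resampling estimator.

Two calibration facts matter for interpretation:

* Under the null, the **extreme tail** of the p-values is honest:
  P(p ≤ α) ≈ α for small α (verified on simulated drift-only data), which
  is the region that Benjamini–Hochberg FDR control consumes.  The
  **global** distribution of p is *not* uniform: because the tail is chosen
  by the observed direction, the null law of p is a folded uniform with
  essentially no mass above 0.5 except the atom at p = 1 from Δh = 0.
  Tests that compare these p-values to U(0,1) as a whole will reject.
* The conservative Ne = 16 null has substantial mass at near-fixation from
  intermediate initial frequencies (e.g. ≈ 2% of simulations from p₀ = 0.5
  end at ≤ 0.03, and ≈ 10% fix entirely).  Consequently a complete selective
  sweep from a mid-frequency start cannot obtain an empirical p much below
  ~10⁻², and after BH correction across hundreds of SNPs mostly only
  near-complete flips from extreme starting frequencies are flagged.  That
  is the intended behaviour of a conservative null, not a defect; scanning
  the same data against a null matched to the census size (Ne ≈ N) has far
  more power but loses the conservatism, and — when selection is strong and
  polygenic — mis-covers neutral loci, because fitness variance depresses
  the genome-wide realized Ne below the census (we measure Ne ≈ 24.5 under
  ten multiplicative s = 0.5 loci in 36-plant populations, versus ≈ 37
  without selection).  There is no single Ne that simultaneously maximises
  sweep recovery and neutral specificity in that regime.

FDR is controlled within each population pair (four separate corrections),
matching how per-population significant counts are reported; pooling would
change the counts.

## The forward simulator

The simulator emulates the experimental design rather than a generic
coalescent: two replicates are founded independently; a first generation of
36 plants is produced from full-sib founder families; from that shared
generation a control branch (equal fitness) and a selected branch
(fecundity weights multiplied by (1+s) per ALT allele at each selected
locus — both parents of a seed are drawn ∝ fitness, with mother ≠ father
enforced by self-incompatibility) evolve independently for 8 further
transitions; a tenth generation crosses replicates within a treatment with
uniformly random donors and receivers.  Gametes recombine with a fixed
probability per adjacent marker pair within a chromosome and freely between
chromosomes.  "Sequencing" draws 32 of 36 plants without replacement and
emits ALT dosages with per-call GQ (discretised beta) and DP (negative
binomial) and uniform random missingness, written as VCF v4.2 with a
sample-map sidecar.

Defaults mirror the study design: 4,713 SNPs over ten ~28.3 Mb chromosomes
(≈ 283 Mb, ≈ 17 SNPs/Mb), 36 plants, 9 generations, 32 sequenced, 8
populations named A1, B1, C9A, C9B, B9A, B9B, C10, B10.

Founder options:

* **Linkage-equilibrium founders** (default): every founder haplotype is an
  independent Bernoulli draw from per-locus founder frequencies (uniform on
  (0.1, 0.9) by default, consistent with a post-MAF-filter marker set).
* **Segmental standing LD** (`founder_pool_size`, `founder_segment_loci`):
  chromosomes are cut into segments of a few markers and only a small
  number of distinct segment haplotypes circulate, combined freely across
  segments.  This gives the base population short-range LD — short
  haplotype blocks in equilibrium with each other — which is what lets
  drift visibly lengthen and merge blocks within nine generations.
* **Rare selected variants** (`selected_founder_af`): selected loci start
  at a chosen low ALT frequency, so nine generations of moderate selection
  move them to intermediate frequency (soft sweeps).  This is the mechanism
  by which the selected populations *gain* genomic variance along the top
  PCs; hard sweeps to fixation would instead remove variance.

What the simulator does **not** model: read-level sequencing error,
alignment and variant-calling artefacts, genotyping batch effects between
generations (the real study dried one generation's tissue and froze the
other), mutation, hoverfly pollination, or any phenotype.  Passing tests on
simulated data therefore validate the statistical machinery and the
direction of the evolutionary signatures, not robustness to those noise
sources.

## LD, D′ confidence intervals and blocks

r² is the squared Pearson correlation of unphased dosage vectors (the
`--geno-r2` statistic), computed over pairwise-complete samples; the
all-pairs path uses presence-mask cross-products so missing data never
require imputation.  Decay curves report the **median** r² per distance bin
(1 kb bins to 50 kb by default), flagging bins with < 5 pairs.

Two-locus haplotype frequencies come from the standard EM over the
double-heterozygote ambiguity.  Convergence is declared when no frequency
moves by more than 1e-8; boundary solutions (a haplotype frequency tending
to 0) converge sublinearly, so the iteration cap is 3,000 and hitting it
logs a warning and returns the last iterate — for D′ purposes the iterate
is by then accurate to ≪ 1e-3.

The D′ confidence interval follows the Gabriel convention: the likelihood
of the genotype counts is evaluated on a |D′| grid (step 0.001) with allele
frequencies fixed at sample marginals and the sign of D fixed at the EM
estimate; the 90% interval is read off the normalized cumulative likelihood
at the 5th and 95th percentiles.  A pair is *strong LD* when CI-low ≥ 0.70
and CI-high ≥ 0.98, and shows *strong recombination evidence* when CI-high
< 0.90.  Blocks are candidate spans ≤ 200 kb whose outermost pair is strong
and in which ≥ 95% of informative pairs are strong, accepted greedily by
span length without overlap; SNPs below MAF 0.07 within the population are
excluded.  This uses a single informative-fraction rule for all block
sizes, a deliberate simplification of the reference tool's size-dependent
bookkeeping; block sets are invariant to sample order and REF/ALT
relabelling, and exact bit-compatibility with plink is a non-goal.

## PCA polygons and the exact signed-rank test

PCA operates on per-SNP mean-imputed, centred, unit-variance dosages
(binomial-SD scaling is available but not default, since plain "scaled and
centred" is the convention being followed); scores come from SVD, with each
component's sign fixed by making its largest-magnitude loading positive.
Eigenvalue ratios, not raw scores, are the stable quantities across sample
duplication.

For each population the convex-hull area of its scatter in each of the 15
planes spanned by pairs of the first six PCs is the genomic-variance proxy
("polygon linking the outer points").  Degenerate point sets (collinear,
< 3 points) get area 0.  Areas are compared by the exact Wilcoxon
signed-rank test: the null distribution of V is built by the dynamic
programme over rank subsets, p = 2·min(P(V ≤ v), P(V ≥ v)) capped at 1.
The default pairing — target minus baseline area per PC pair per replicate,
30 differences for two replicates — is the unique pairing under which the
published extreme p-values (2/2³⁰ and 10/2³⁰) arise, and it is exposed as a
parameter.  Ties in |differences| fall back to midranks with exact
enumeration up to n = 12 and a tie-corrected normal approximation beyond,
flagged as non-exact.

## Candidate genes

Genes (GFF3 `gene` features) are candidates for a SNP when the SNP lies in
the gene span inflated by ±2 kb, on closed 1-based intervals and ignoring
strand: the source procedure describes a symmetric ~4 kb window, not a
promoter-aware one.  Output is deduplicated by gene with supporting SNPs
retained.

## Pipeline, seeds and problem sizes

`run_pipeline` derives a per-stage seed from the global seed via SHA-256,
so stages are reproducible independently; reports are JSON + text with a
manifest of input hashes.  The test suite and the demonstration configs run
at reduced scale chosen to keep every stage exercised on one CPU in
seconds-to-minutes: simulated studies of 150–2,000 SNPs, drift banks of
10,000 simulations per grid point (the published size — it is cheap), block
detection on 240-marker chromosomes, and 10-seed repetitions for the
recovery properties.  All stochastic behaviour flows from explicit seeds.

## Known limitations

* The empirical p-value's global null law is folded (see above); only its
  tail is uniform-calibrated.  Any downstream use expecting U(0,1)
  p-values throughout (e.g. genomic-control inflation factors) would need
  a two-sided variant.
* The conservative Ne = 16 null trades most power against s ≤ 0.5 sweeps
  from mid frequencies for specificity; quantified above.
* Gabriel-block counts at these sample sizes (32 diploids) are sensitive to
  the CI thresholds; trends (fewer/longer under drift) are robust in the
  simulations, absolute counts are not comparable to other tools.
* The gene windowing is annotation-driven only; no orthology or functional
  enrichment is attempted.
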