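# Methods

## The model

`poda` scores case/control GWAS samples against pathway-defined SNP sets.
Genotypes are coded as the per-individual minor-allele frequency,
y ∈ {0, ½, 1}, so the mean of a column over a pool of samples equals that
pool's minor allele frequency (MAF) and acts as the pool's *centroid*
coordinate at that locus.

For sample *i* and locus *j* the locus distance is

    d_ij = |y_ij − f_j| − |y_ij − g_j|

where f_j and g_j are the MAFs of the control and case pools with sample *i*
removed from its own pool (leave-one-out).  Positive d means the sample sits
closer to the case centroid.  Over the s loci of a SNP set the per-sample
score is the standardized mean

    D_i = d̄_i / ( sd(d_i) / √s_i )

with the sample standard deviation (n−1 denominator) and s_i the number of
loci with a non-missing genotype for sample *i*.  The denominator rewards
samples that are *consistently* closer to one centroid across loci and
penalizes sets where the sample flips sides locus by locus; in data sets of
realistic size D ranges over roughly −3 to 3.

Case and control D distributions are compared with the Wilcoxon rank-sum
statistic W (sum of case midranks of D over all N samples, ascending).  W is
referred to an ensemble of label permutations — each permutation re-runs the
per-gene SNP selection and the full leave-one-out computation under the
permuted labels — giving the distinction score

    DS = (W − mean(W_perm)) / sd(W_perm).

Because the permuted labels also drive the per-gene selection, DS absorbs
the optimism that large genes (many candidate SNPs) enjoy from
most-significant-SNP selection.  Significance of DS is assessed against
random SNP sets of the same size drawn from the global
most-informative-SNP-per-gene pool: p = (b+1)/(B+1) with b the number of
random sets whose DS is at least the pathway's (ties counted — conservative).

## Pipeline

1. Load genotypes (VCF, PLINK-additive `.raw`, or TSV), orient every SNP to
   the pooled minor allele, align phenotypes.
2. QC: drop SNPs with missingness > `max_missing` (default 0.10) or MAF <
   `min_maf` (default 0.01) in either class.  The thresholds follow common
   GWAS practice and are configurable; there is deliberately no
   Hardy-Weinberg filter.
3. Per gene, keep the SNP most associated with status by a two-sided
   Fisher's exact test on the allelic 2×2 table (a genotypic 2×3 exact
   option exists).  Exact p ties break to the lexicographically smaller SNP
   id, making selection deterministic and independent of annotation order.
   Pathways left with fewer than two covered genes are dropped; a SNP
   representing two genes counts once within a pathway's set.
4. Per pathway: D profile, W, DS (default 100 permutations), resampling p
   (default 1000 random sets, sharing one permutation-label ensemble across
   the random sets; per-set re-permutation is available behind a flag).
5. Downstream: logistic regression of status on D (OR per unit D, Wald p,
   Benjamini–Hochberg FDR across pathways), greedy overlap culling, and the
   cross-pathway Pearson correlation of D vectors.
6. Optionally, successive unions of the top pathways (by descending OR) are
   re-scored as single SNP sets ("superpathways"); union sets are held fixed
   across permutations since they are defined at SNP level.

Per-pathway randomness derives from `SeedSequence(seed, spawn_key=(rank,))`
over sorted pathway ids, so results are identical for any worker count and
fully reconstructible from the manifest.

## Numerical choices

* sd floor ε = 1e−12: if sd(d_i) < ε then D_i = 0 when d̄_i ≈ 0, otherwise
  sign(d̄_i)·1e6.  Eq-wise the standardized mean is undefined at zero spread.
* Missing genotypes are excluded locus-wise; √s uses the per-sample count of
  used loci.  Samples missing the whole SNP set raise an error.
* Rank ties get midranks.  W_cases + W_controls = N(N+1)/2 always holds.
* The one-sided orientation is "cases higher": larger W/DS means cases are
  closer to other cases.
* Overlap culling removes a pathway sharing strictly more than 60% of its
  SNPs with an already-retained one, with shared/min(|A|,|B|) as the
  fraction (catches subset pathways; shared/|A| is available).  The greedy
  pass is order-dependent, so it runs over 25 random orders plus the
  score-descending order and returns the modal retained set, ties resolved
  toward the score-descending outcome.
* Perfect separation in the logistic fit is flagged, not penalized away —
  the reported OR keeps plain maximum-likelihood semantics.
* On an exact pooled-frequency tie (0.5) the lexicographically greater
  allele is coded as minor, so re-loading a file is deterministic.

## The pairwise-distance variant

When two classes have *identical* per-locus allele frequencies but different
joint genotype structure (the two-locus XOR configuration: controls carry
{(0,0),(1,1)}, cases {(1,0),(0,1)}), the class centroids coincide and every
centroid-based d is zero — the statistic is blind by construction.
`pairwise_distance_statistics` instead scores each sample by its mean
pairwise distance to the other controls minus the mean to the other cases.
A per-coordinate-separable metric (Manhattan, Hamming) does not help here:
a sample's mean Manhattan distance to a pool depends only on the pool's
per-locus marginals, which the XOR construction matches exactly, so the
Manhattan variant is provably as blind as the centroids.  The default metric
is therefore Euclidean, which couples loci through the square root and
separates the XOR classes cleanly; Manhattan and Hamming remain available
for centroid-visible problems.

## What the generators emulate — and what they do not

`simulate_epistatic_gwas` draws HWE genotypes (Binomial(2, MAF)/2) at 50
loci with MAFs evenly spaced over 0.1–0.4 and assigns disease with baseline
probability 0.2, multiplied by a relative risk of 3 for carriers of
homozygous-minor genotypes at loci (1 and 2) or (1 and 3); individuals are
drawn until 250 cases and 250 controls are collected.  MAFs are assigned in
descending order so the interacting low-index loci sit at the top of the
range — at MAF 0.4 the joint homozygous-minor genotype has frequency
q ≈ 0.047, which is the largest this design allows.  The baseline of 0.2 is
a free choice (any value ≤ 1/3 keeps the 3× risk a probability) made for
feasible case sampling.

This regime is deliberately weak.  A useful closed form: the carrier
fraction among cases is 3q/(1+2q) ≈ 12% *independently of the baseline
prevalence*, while controls carry the risk genotype at between 0% (baseline
1/3) and ≈ 2.4% (baseline 0.2).  With at most ~12% of cases shifted, the
one-sided rank-sum on D for the 12-SNP causal pathway rejects at α = 0.05 in
roughly 15% of replicates at the default baseline (≈ 33% at the 1/3
ceiling) — far above the nominal 5% of a length-matched null pathway, but
not a majority.  Tests therefore assert the contrast between the causal and
null pathways and the aggregate DS ordering across replicates, not
per-replicate significance.

The generators make no attempt at linkage disequilibrium (the per-gene
representative-SNP step exists precisely to side-step within-gene LD),
population structure, genotyping batch effects, or covariates.  Passing
tests show the statistics are computed correctly and calibrated under the
stated sampling model; they say nothing about robustness to stratification
or LD in real cohorts.

## Problem sizes used in the checks

Null calibration uses 200 replicates of 100 cases/100 controls with a
20-gene pathway against an 100-gene pool, 50 permutations and 99 resamples;
the epistatic power sweep uses 50 replicates of the full 250/250 design; the
XOR check uses 200 samples per class.  These sizes give binomial error bars
tight enough to detect miscalibration of a 5% rate while keeping a full run
in the low minutes on one core.

## Known limitations

* Resampling depth bounds the smallest attainable p at 1/(B+1).
* The shared permutation-label ensemble across random sets trades a small
  amount of independence for a large constant-factor speedup; the full
  per-set re-permutation is available where exactness matters.
* Annotation and genotypes are matched on SNP id only; no strand or allele
  reconciliation is attempted.
* Multi-allelic VCF records are skipped, not decomposed.
* No covariate adjustment enters D; confounding must be handled upstream.
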