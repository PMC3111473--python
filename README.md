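# poda — Pathways of Distinction Analysis

`poda` is a multi-SNP analysis tool for case/control GWAS.  Instead of
testing markers one at a time, it asks, for each biological pathway, whether
cases look more like the *other cases* than like the controls across the
pathway's SNPs — a signal that survives even when no individual SNP has a
usable marginal effect, as happens under epistasis.  It is aimed at
statistical geneticists who have genotype data, a case/control phenotype,
gene-set (GMT) annotations and a SNP→gene map, and want pathway-level
association results that complement single-SNP and enrichment analyses.

## The statistic

Genotypes are coded y ∈ {0, ½, 1} (the individual's minor-allele
frequency).  For sample *i* and SNP *j*, with f_j and g_j the control- and
case-pool MAFs computed after removing sample *i* from its own pool,

    d_ij = |y_ij − f_j| − |y_ij − g_j|        (locus distance, > 0 ⇒ closer to cases)

    D_i  = d̄_i / ( sd(d_i) / √s )            (standardized mean over the s loci)

Each gene contributes its single most-associated SNP (Fisher's exact test),
so D reflects correlations *across* genes rather than within-gene LD.  Case
and control D distributions are compared by the Wilcoxon rank sum W; W is
standardized against a permuted-label ensemble (which repeats the per-gene
SNP selection under each permutation) into a distinction score
DS = (W − mean W_perm)/sd W_perm, and DS is referred to random
equally-sized SNP sets from the per-gene representative pool for a
resampling p-value.  Because D_i never uses sample *i*'s own label, it can
feed a logistic regression of status on D, giving an odds ratio per unit D
(BH-FDR adjusted across pathways).  For allele-frequency-matched epistasis
that centroids cannot see (the XOR configuration), a pairwise
sample-sample distance variant is included.  See `docs/methods.md`.

## Worked example

Generate the built-in epistatic demonstration — 250 cases and 250 controls
at 50 HWE loci, where homozygous-minor genotypes at loci (1 and 2) or
(1 and 3) triple disease risk, and four 12-gene pathways of which `PW_001`
contains the interacting loci:

```sh
poda simulate --preset fig1 --seed 4 --out fix
poda run --genotypes fix/genotypes.tsv --pheno fix/phenotypes.tsv \
         --pathways fix/pathways.gmt --snp2gene fix/snp2gene.tsv \
         --perms 100 --resamples 999 --seed 4 --out out
cat out/results.tsv
```

```
Pathway Source    Length  DS        p_DS   OR        FDR_OR
PW_001  synthetic 12      1.54805   0.174  1.17322   0.117505
PW_003  synthetic 12      0.945169  0.31   1.13289   0.148612
PW_002  synthetic 12      0.59594   0.462  1.04943   0.557225
PW_004  synthetic 12      -2.26968  0.993  0.742472  0.00776867
```

The causal pathway `PW_001` ranks first: its distinction score DS = 1.55
says its rank-sum sits 1.55 permutation standard deviations above the
permuted-label mean, and each unit increase in a sample's D multiplies the
odds of being a case by ≈ 1.17.  `p_DS` compares DS against random 12-SNP
sets; with this toy annotation the pool holds only 48 SNPs, so random sets
often include the interacting loci themselves and the resampled p stays
moderate.  Null pathways scatter around DS ≈ 0 (negative DS means the
controls were the more coherent class in that draw; the OR column is
two-sided, so a low FDR can accompany OR < 1).  The run also writes the
per-sample D matrix, an overlap-culling report, the cross-pathway D
correlation matrix and a manifest with every effective parameter and seed.

By design this simulated effect is subtle — the risk genotype appears in
only ~12% of cases (and none of the single loci is marginally significant),
so individual replicates vary; `docs/methods.md` quantifies the regime.

`poda select`, `poda cull` and `poda union` expose the intermediate steps
(per-gene SNP selection, overlap culling, top-k superpathway scoring), and
`--preset null` / `--preset xor` generate calibration and
centroid-blind-epistasis fixtures.

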