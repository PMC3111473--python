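"""The distinction statistics: leave-one-out centroid distances, rank sums,
permutation-normalized distinction scores, and length-matched resampling.

For sample ``i`` and SNP ``j`` the locus distance is

    d_ij = |y_ij - f_j| - |y_ij - g_j|

where ``y_ij`` is the minor-allele-frequency-coded genotype and ``f_j``,
``g_j`` are the MAFs (centroids) of the control and case pools with sample
``i`` removed from its own pool.  Positive ``d`` means closer to the cases.
The per-sample score is the standardized mean across the ``s`` loci,

    D_i = d_bar_i / (sd(d_i) / sqrt(s_i)),

a quantity that rewards samples *consistently* closer to one centroid.  Case
and control D distributions are compared with the Wilcoxon rank-sum statistic
W (sum of case ranks); W is standardized against a permuted-label ensemble
(which re-runs the per-gene SNP selection under each permuted labeling) to
give the Distinction Score DS, and DS is referred to random SNP sets of the
same size drawn from the per-gene representative pool for a resampling p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from poda.errors import ValidationError
from poda.io import GenotypeMatrix, PathwayAnnotation, PhenotypeVector
from poda.selection import SnpSelection, fisher_exact_association

logger = logging.getLogger("poda")

SD_FLOOR = 1e-12
D_CAP = 1e6


@dataclass
class DistanceProfile:
    """Per-sample leave-one-out distance statistics for one SNP set."""

    snp_set: list[str]
    sample_ids: list[str]
    d: np.ndarray  # n_samples x s locus distances (nan where genotype missing)
    d_mean: np.ndarray
    d_sd: np.ndarray
    D: np.ndarray
    used_loci: np.ndarray

    @property
    def s(self) -> int:
        return len(self.snp_set)


@dataclass
class PermutationEnsemble:
    """W statistics under permuted case/control labels (the Eq.-4-style null)."""

    n_perm: int
    seed: int | None
    w_values: np.ndarray
    selected_sets: list[list[str]] = field(default_factory=list)
    label_matrix: np.ndarray | None = None  # n_perm x n_samples boolean

    def mean(self) -> float:
        return float(self.w_values.mean())

    def sd(self) -> float:
        return float(self.w_values.std(ddof=1))


@dataclass
class PathwayResult:
    """Full per-pathway summary (downstream fields filled later)."""

    pathway_id: str
    s: int
    W: float
    DS: float
    p_resample: float | None = None
    OR: float | None = None
    OR_p: float | None = None
    FDR_q: float | None = None
    source: str = ""
    n_genes: int | None = None


# ---------------------------------------------------------------------------
# locus distances


def locus_distance(y, f, g):
    """d = |y - f| - |y - g|: distance-to-controls minus distance-to-cases."""
    y = np.asarray(y, dtype=float)
    return np.abs(y - f) - np.abs(y - g)


def _loo_d_matrix(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Leave-one-out locus distances for all samples and all columns at once.

    Each sample's own genotype is removed from its class centroid before the
    distance is taken; the opposite-class centroid uses the full pool.
    Entries are nan where the genotype is missing or a leave-one-out pool has
    no non-missing genotype left.
    """
    case = np.asarray(is_case, dtype=bool)
    miss = np.isnan(values)
    yf = np.where(miss, 0.0, values)
    nonmiss = (~miss).astype(float)
    in_case = case[:, None] * nonmiss  # 1 where sample is a non-missing case
    in_ctrl = (~case)[:, None] * nonmiss
    n1 = in_case.sum(axis=0)
    n0 = in_ctrl.sum(axis=0)
    s1 = (yf * in_case).sum(axis=0)
    s0 = (yf * in_ctrl).sum(axis=0)
    den_g = n1 - in_case
    den_f = n0 - in_ctrl
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (s1 - yf * in_case) / den_g
        f = (s0 - yf * in_ctrl) / den_f
    d = np.abs(values - f) - np.abs(values - g)
    d[(den_g == 0) | (den_f == 0)] = np.nan
    return d


def _standardized_mean(
    d: np.ndarray, sd_floor: float = SD_FLOOR, cap: float = D_CAP
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-row standardized mean of locus distances: D = mean/(sd/sqrt(s))."""
    used = (~np.isnan(d)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(d, axis=1)
        sd = np.nanstd(d, axis=1, ddof=1)
    sd = np.where(np.isnan(sd), 0.0, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = mean / (sd / np.sqrt(np.maximum(used, 1)))
    degen = sd < sd_floor
    D = np.where(degen, np.where(np.abs(mean) < sd_floor, 0.0, np.sign(mean) * cap), D)
    return mean, sd, D, used


def sample_distance_statistics(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    snp_set,
    sd_floor: float = SD_FLOOR,
) -> DistanceProfile:
    """Leave-one-out relative-distance profile D for every sample over a SNP set."""
    snp_set = list(snp_set)
    if not snp_set:
        raise ValidationError("empty SNP set")
    idx = genotypes.snp_indices(snp_set)
    vals = genotypes.values[:, idx]
    all_missing = np.isnan(vals).all(axis=1)
    if all_missing.any():
        bad = [s for s, m in zip(genotypes.sample_ids, all_missing) if m]
        raise ValidationError(f"samples with no genotypes over the SNP set: {bad[:5]}")
    d = _loo_d_matrix(vals, phenotypes.is_case)
    mean, sd, D, used = _standardized_mean(d, sd_floor=sd_floor)
    return DistanceProfile(snp_set, list(genotypes.sample_ids), d, mean, sd, D, used)


def pooled_locus_distances(
    genotypes: GenotypeMatrix, phenotypes: PhenotypeVector, snp_set
) -> np.ndarray:
    """Locus distances against the *full-pool* class centroids (no leave-one-out).

    Useful as a diagnostic: when case and control centroids coincide (as in a
    marginal-frequency-matched epistatic configuration) every entry is zero.
    """
    idx = genotypes.snp_indices(list(snp_set))
    vals = genotypes.values[:, idx]
    case = phenotypes.is_case
    with np.errstate(invalid="ignore"):
        g = np.nanmean(np.where(case[:, None], vals, np.nan), axis=0)
        f = np.nanmean(np.where(case[:, None], np.nan, vals), axis=0)
    return locus_distance(vals, f, g)


# ---------------------------------------------------------------------------
# rank sum and distinction score


def _rank_sum(D: np.ndarray, is_case: np.ndarray) -> float:
    ranks = stats.rankdata(D)  # ascending, midranks on ties
    return float(ranks[is_case].sum())


def pathway_rank_sum(profile: DistanceProfile, phenotypes: PhenotypeVector) -> float:
    """Wilcoxon rank-sum W: sum of case ranks of D among all samples.

    Larger W means the cases sit higher in the pooled D ordering, i.e. cases
    are closer to other cases than the controls are.
    """
    if len(profile.sample_ids) != len(phenotypes.sample_ids):
        raise ValidationError("profile does not cover the phenotype samples")
    return _rank_sum(profile.D, phenotypes.is_case)


def distinction_score(W: float, ensemble: PermutationEnsemble) -> float:
    """DS = (W - mean(W_perm)) / sd(W_perm), sample sd over the ensemble."""
    sd = ensemble.sd()
    if sd <= 0:
        raise ValidationError(
            "permutation ensemble has zero spread; increase the number of permutations"
        )
    return float((W - ensemble.mean()) / sd)


# ---------------------------------------------------------------------------
# permutation null with per-permutation SNP re-selection


def _reselect_for_pathway(
    genotypes: GenotypeMatrix,
    labels: np.ndarray,
    gene_candidates: dict[str, list[str]],
    table: str = "allelic",
) -> list[str]:
    """Most-associated SNP per gene under a given labeling (lexicographic ties)."""
    pheno = PhenotypeVector(list(genotypes.sample_ids), labels)
    chosen: list[str] = []
    seen: set[str] = set()
    for gene in gene_candidates:
        cands = gene_candidates[gene]
        if len(cands) == 1:
            best = cands[0]
        else:
            best, best_p = None, np.inf
            for snp in cands:
                p = fisher_exact_association(genotypes, pheno, snp, table=table)
                if p < best_p:
                    best, best_p = snp, p
        if best not in seen:
            seen.add(best)
            chosen.append(best)
    return chosen


def _candidate_map(
    annotation: PathwayAnnotation, genotypes: GenotypeMatrix, pathway_id: str, qc
) -> dict[str, list[str]]:
    cand: dict[str, list[str]] = {}
    for gene, snps in annotation.pathway_snps(pathway_id).items():
        ok = sorted(s for s in set(snps) if (qc is None or s in qc) and s in genotypes._snp_index)
        if ok:
            cand[gene] = ok
    if not cand:
        raise ValidationError(f"pathway {pathway_id!r} has no usable SNPs")
    return cand


def _permutation_labels(phenotypes: PhenotypeVector, n_perm: int, rng) -> np.ndarray:
    return np.array([rng.permutation(phenotypes.is_case) for _ in range(n_perm)])


def permutation_null(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    annotation: PathwayAnnotation | None,
    pathway_id: str | None,
    n_perm: int = 100,
    seed: int | None = 0,
    qc: set[str] | None = None,
    snp_set=None,
    table: str = "allelic",
    label_matrix: np.ndarray | None = None,
) -> PermutationEnsemble:
    """W under permuted labels, re-selecting the per-gene SNP in each permutation.

    The permuted labels drive both the per-gene Fisher selection (when an
    annotation is supplied) and the leave-one-out distances, so the ensemble
    absorbs the bias toward large genes.  Passing an explicit ``snp_set``
    (with ``annotation=None``) freezes the SNP set across permutations, which
    is what resampled random sets and pathway unions use.
    """
    if n_perm < 2:
        raise ValidationError("need at least 2 permutations for an ensemble sd")
    if label_matrix is None:
        rng = np.random.default_rng(seed)
        label_matrix = _permutation_labels(phenotypes, n_perm, rng)
    if annotation is not None:
        gene_cands = _candidate_map(annotation, genotypes, pathway_id, qc)
        fixed = all(len(c) == 1 for c in gene_cands.values())
    else:
        if snp_set is None:
            raise ValidationError("either an annotation or an explicit snp_set is required")
        gene_cands = None
        fixed = True
    if gene_cands is not None and fixed:
        snp_set = _reselect_for_pathway(genotypes, phenotypes.is_case, gene_cands, table)
    w_values = np.empty(len(label_matrix))
    selected_sets: list[list[str]] = []
    for k, labels in enumerate(label_matrix):
        if gene_cands is not None and not fixed:
            chosen = _reselect_for_pathway(genotypes, labels, gene_cands, table)
        else:
            chosen = list(snp_set)
        selected_sets.append(chosen)
        vals = genotypes.values[:, genotypes.snp_indices(chosen)]
        d = _loo_d_matrix(vals, labels)
        _, _, D, _ = _standardized_mean(d)
        w_values[k] = _rank_sum(D, labels)
    return PermutationEnsemble(len(label_matrix), seed, w_values, selected_sets, label_matrix)


# ---------------------------------------------------------------------------
# length-matched resampling significance


def resample_pvalue(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    selection: SnpSelection,
    n_resample: int = 1000,
    n_perm: int = 100,
    seed: int | None = 0,
    true_ds: float | None = None,
    annotation: PathwayAnnotation | None = None,
    qc: set[str] | None = None,
    shared_ensemble: bool = True,
    table: str = "allelic",
) -> float:
    """Resampling p for a pathway's DS against random same-size SNP sets.

    Random sets of ``s`` SNPs are drawn (without replacement within a draw)
    from the global most-informative-SNP-per-gene pool and each is given a DS
    against the permutation ensemble.  ``p = (b + 1) / (n_resample + 1)``
    where ``b`` counts random sets with DS at least the pathway's (ties count,
    a conservative convention).  By default one shared set of permuted
    labelings normalizes every random set; ``shared_ensemble=False`` redraws
    the labelings for each set.
    """
    snp_set = selection.snp_ids
    s = len(snp_set)
    pool = [p for p in selection.pool if p in genotypes._snp_index]
    if len(pool) < s:
        raise ValidationError(
            f"representative-SNP pool ({len(pool)}) smaller than pathway size ({s})"
        )
    rng = np.random.default_rng(seed)
    label_matrix = _permutation_labels(phenotypes, n_perm, rng)
    if true_ds is None:
        ens = permutation_null(
            genotypes,
            phenotypes,
            annotation,
            selection.pathway_id if annotation is not None else None,
            n_perm=n_perm,
            qc=qc,
            snp_set=snp_set if annotation is None else None,
            table=table,
            label_matrix=label_matrix,
        )
        profile = sample_distance_statistics(genotypes, phenotypes, snp_set)
        true_ds = distinction_score(pathway_rank_sum(profile, phenotypes), ens)

    pool_idx = genotypes.snp_indices(pool)
    sets = np.array([rng.choice(len(pool), size=s, replace=False) for _ in range(n_resample)])
    case = phenotypes.is_case
    vals = genotypes.values[:, pool_idx]

    def w_for_sets(labels: np.ndarray) -> np.ndarray:
        d = _loo_d_matrix(vals, labels)  # n_samples x pool
        dsub = d[:, sets]  # n_samples x B x s
        n = dsub.shape[0]
        _, _, D, _ = _standardized_mean(dsub.reshape(-1, s))
        D = D.reshape(n, sets.shape[0])
        ranks = stats.rankdata(D, axis=0)
        return ranks[labels].sum(axis=0)

    # W for the random sets under the true labels
    w_true_labels = w_for_sets(case)
    # W for the random sets under each permuted labeling
    if shared_ensemble:
        perm_w = np.array([w_for_sets(lab) for lab in label_matrix])  # n_perm x B
    else:
        perm_w = np.empty((n_perm, n_resample))
        for b in range(n_resample):
            labs = _permutation_labels(phenotypes, n_perm, rng)
            for k, lab in enumerate(labs):
                d = _loo_d_matrix(vals[:, sets[b]], lab)
                _, _, D, _ = _standardized_mean(d)
                perm_w[k, b] = _rank_sum(D, lab)
    mu = perm_w.mean(axis=0)
    sd = perm_w.std(axis=0, ddof=1)
    sd = np.where(sd <= 0, np.nan, sd)
    random_ds = (w_true_labels - mu) / sd
    b_count = int(np.sum(random_ds[~np.isnan(random_ds)] >= true_ds))
    return float((b_count + 1) / (n_resample + 1))


# ---------------------------------------------------------------------------
# pathway unions


def combine_pathways(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    selections: dict[str, SnpSelection],
    pathway_ids,
    n_perm: int = 100,
    n_resample: int = 1000,
    seed: int | None = 0,
) -> tuple[list[str], PathwayResult, DistanceProfile]:
    """Union the selected SNPs of several pathways and re-score the union.

    The merged set is deduplicated; D, W, DS and the resampling p are
    recomputed on the union exactly as for a single pathway (the SNP set is
    held fixed across permutations since the union is defined at SNP level).
    """
    pathway_ids = list(pathway_ids)
    if len(pathway_ids) < 2:
        raise ValidationError("need at least two pathways to combine")
    union: list[str] = []
    seen: set[str] = set()
    for pid in pathway_ids:
        for snp in selections[pid].snp_ids:
            if snp not in seen:
                seen.add(snp)
                union.append(snp)
    profile = sample_distance_statistics(genotypes, phenotypes, union)
    W = pathway_rank_sum(profile, phenotypes)
    ens = permutation_null(
        genotypes, phenotypes, None, None, n_perm=n_perm, seed=seed, snp_set=union
    )
    DS = distinction_score(W, ens)
    merged_id = "+".join(pathway_ids)
    pool = selections[pathway_ids[0]].pool
    result = PathwayResult(merged_id, len(union), W, DS, n_genes=None)
    if len([p for p in pool if p in genotypes._snp_index]) >= len(union):
        merged_sel = SnpSelection(merged_id, [("", s, np.nan) for s in union], pool)
        result.p_resample = resample_pvalue(
            genotypes,
            phenotypes,
            merged_sel,
            n_resample=n_resample,
            n_perm=n_perm,
            seed=seed,
            true_ds=DS,
        )
    else:
        logger.warning("union %s larger than the resampling pool; p_resample omitted", merged_id)
    return union, result, profile


# ---------------------------------------------------------------------------
# pairwise-distance variant (for marginal-frequency-matched epistasis)


def pairwise_distance_statistics(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    snp_set,
    metric: str = "euclidean",
) -> np.ndarray:
    """Per-sample mean pairwise distance to controls minus to cases.

    For each sample the statistic is the mean distance to all controls except
    itself minus the mean distance to all cases except itself (positive means
    closer to cases).  Distances are averaged per used locus, with loci
    missing in either member of a pair skipped.

    The default metric is Euclidean: a per-coordinate-separable metric such
    as Manhattan depends only on the per-locus marginals of the pools, so it
    cannot separate classes whose allele frequencies are matched at every
    locus; the Euclidean metric couples loci and can.
    """
    snp_set = list(snp_set)
    if not snp_set:
        raise ValidationError("empty SNP set")
    vals = genotypes.values[:, genotypes.snp_indices(snp_set)]
    n = vals.shape[0]
    if np.isnan(vals).all(axis=1).any():
        raise ValidationError("a sample has no genotypes over the SNP set")
    case = phenotypes.is_case
    dist = np.zeros((n, n))
    block = max(1, int(2_000_000 // max(1, n * vals.shape[1])))
    for start in range(0, n, block):
        stop = min(n, start + block)
        diff = vals[start:stop, None, :] - vals[None, :, :]
        ok = ~np.isnan(diff)
        used = ok.sum(axis=2)
        if metric == "manhattan":
            num = np.nansum(np.abs(diff), axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist[start:stop] = num / used
        elif metric == "euclidean":
            num = np.nansum(diff**2, axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                dist[start:stop] = np.sqrt(num / used)
        elif metric == "hamming":
            neq = (np.abs(diff) > 0) & ok
            with np.errstate(invalid="ignore", divide="ignore"):
                dist[start:stop] = neq.sum(axis=2) / used
        else:
            raise ValidationError(f"unknown metric {metric!r}")
    stat = np.empty(n)
    for i in range(n):
        others = np.arange(n) != i
        to_ctrl = dist[i, others & ~case]
        to_case = dist[i, others & case]
        stat[i] = np.nanmean(to_ctrl) - np.nanmean(to_case)
    return stat
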