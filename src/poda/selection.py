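"""SNP quality control and per-gene representative-SNP selection.

To keep the pathway statistic sensitive to correlations *across* genes rather
than to linkage disequilibrium within a single heavily-probed gene, each gene
contributes exactly one SNP: the one most associated with case status in a
univariate Fisher's exact test.  The chosen SNP need not itself be
significant — the goal is informativeness, not filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from poda.errors import ValidationError
from poda.io import GenotypeMatrix, PathwayAnnotation, PhenotypeVector

logger = logging.getLogger("poda")


@dataclass
class SnpSelection:
    """Per-pathway representative SNPs plus the global resampling pool."""

    pathway_id: str
    selected: list[tuple[str, str, float]]  # (gene, snp, association p)
    pool: list[str]  # global most-informative-SNP-per-gene pool

    @property
    def snp_ids(self) -> list[str]:
        """Pathway SNP set, deduplicated (a SNP shared by two genes counts once)."""
        seen: set[str] = set()
        out: list[str] = []
        for _, snp, _ in self.selected:
            if snp not in seen:
                seen.add(snp)
                out.append(snp)
        return out

    @property
    def n_genes(self) -> int:
        return len({g for g, _, _ in self.selected})


def compute_maf(
    genotypes: GenotypeMatrix, snp: str, subset: np.ndarray | None = None
) -> float:
    """Minor allele frequency of one SNP over a boolean sample mask.

    Equals the mean of the {0, 0.5, 1} genotype values over non-missing
    samples in the subset.
    """
    col = genotypes.column(snp)
    if subset is not None:
        col = col[np.asarray(subset, dtype=bool)]
    ok = ~np.isnan(col)
    if not ok.any():
        raise ValidationError(f"MAF undefined for SNP {snp!r}: all values missing in subset")
    return float(col[ok].mean())


def qc_filter_snps(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
) -> set[str]:
    """Return the SNP ids passing missingness and class-wise MAF thresholds.

    A SNP is retained iff its missing fraction over all samples is <=
    ``max_missing`` and its MAF is >= ``min_maf`` within cases *and* within
    controls separately (near-monomorphic in either class is excluded).
    """
    if not (0 <= max_missing <= 1 and 0 <= min_maf <= 1):
        raise ValidationError("QC thresholds must lie in [0, 1]")
    case = phenotypes.is_case
    vals = genotypes.values
    miss = np.isnan(vals)
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        maf_case = np.nanmean(np.where(case[:, None], vals, np.nan), axis=0)
        maf_ctrl = np.nanmean(np.where(case[:, None], np.nan, vals), axis=0)
    keep = (
        (miss_frac <= max_missing)
        & ~np.isnan(maf_case)
        & ~np.isnan(maf_ctrl)
        & (maf_case >= min_maf)
        & (maf_ctrl >= min_maf)
    )
    retained = {s for s, k in zip(genotypes.snp_ids, keep) if k}
    if not retained:
        logger.warning("QC retained no SNPs (max_missing=%g, min_maf=%g)", max_missing, min_maf)
    return retained


def _allele_counts(col: np.ndarray, mask: np.ndarray) -> tuple[int, int]:
    """(minor, major) allele counts over non-missing samples in mask."""
    v = col[mask]
    v = v[~np.isnan(v)]
    minor = int(round(2.0 * v.sum()))
    return minor, 2 * len(v) - minor


def fisher_exact_association(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    snp: str,
    table: str = "allelic",
) -> float:
    """Two-sided Fisher's exact p for association of one SNP with case status.

    ``table='allelic'`` tests the 2x2 (minor, major) x (case, control) allele
    count table; ``table='genotypic'`` tests the 2x3 genotype-category table
    by exhaustive conditional enumeration (Freeman–Halton).
    """
    col = genotypes.column(snp)
    case = phenotypes.is_case
    if table == "allelic":
        a = _allele_counts(col, case)
        b = _allele_counts(col, ~case)
        tab = np.array([a, b])
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            logger.warning("degenerate allele table for SNP %s; p set to 1", snp)
            return 1.0
        return float(stats.fisher_exact(tab, alternative="two-sided")[1])
    if table == "genotypic":
        tab = np.array(
            [
                [np.nansum((col == g) & case) for g in (0.0, 0.5, 1.0)],
                [np.nansum((col == g) & ~case) for g in (0.0, 0.5, 1.0)],
            ],
            dtype=int,
        )
        tab = tab[:, tab.sum(axis=0) > 0]
        if tab.shape[1] < 2 or (tab.sum(axis=1) == 0).any():
            logger.warning("degenerate genotype table for SNP %s; p set to 1", snp)
            return 1.0
        return _fisher_2xk(tab)
    raise ValidationError(f"unknown Fisher table form {table!r}")


def _fisher_2xk(tab: np.ndarray) -> float:
    """Exact conditional p for a 2xk table: sum of probabilities of all tables
    with the observed margins whose probability does not exceed the observed."""
    from scipy.special import gammaln

    row0 = int(tab[0].sum())
    cols = tab.sum(axis=0)

    # probability of a table given margins: prod_j C(c_j, t_j) / C(N, row0)

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = int(cols.sum())
    denom = log_comb(total, row0)

    def lp(top) -> float:
        return float(sum(log_comb(c, t) for c, t in zip(cols, top)) - denom)

    obs = lp(tuple(int(x) for x in tab[0]))
    acc = 0.0

    def rec(j: int, remaining: int, top: list[int]):
        nonlocal acc
        if j == len(cols) - 1:
            if 0 <= remaining <= cols[j]:
                val = lp(tuple(top + [remaining]))
                if val <= obs + 1e-9:
                    acc += np.exp(val)
            return
        lo = max(0, remaining - int(cols[j + 1 :].sum()))
        hi = min(int(cols[j]), remaining)
        for t in range(lo, hi + 1):
            rec(j + 1, remaining - t, top + [t])

    rec(0, int(row0), [])
    return float(min(acc, 1.0))


def select_representative_snps(
    annotation: PathwayAnnotation,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    qc: set[str] | None = None,
    table: str = "allelic",
    min_genes: int = 2,
) -> tuple[dict[str, SnpSelection], list[str]]:
    """Choose the most-associated SNP per gene and assemble pathway SNP sets.

    Returns a mapping pathway id -> SnpSelection together with the global
    pool of per-gene representative SNPs used for length-matched resampling.
    Pathways covering fewer than ``min_genes`` genes after QC are dropped.
    """
    if qc is None:
        qc = set(genotypes.snp_ids)
    gene_rep: dict[str, tuple[str, float]] = {}
    for gene, snps in annotation.gene_snps.items():
        candidates = sorted(s for s in set(snps) if s in qc and s in genotypes._snp_index)
        if not candidates:
            continue
        if len(candidates) == 1:
            # association p irrelevant for a single candidate; skip the test
            best, best_p = candidates[0], np.nan
        else:
            best, best_p = None, np.inf
            for s in candidates:  # lexicographic order => deterministic tie-break
                p = fisher_exact_association(genotypes, phenotypes, s, table=table)
                if p < best_p:
                    best, best_p = s, p
        gene_rep[gene] = (best, float(best_p))
    pool = sorted({snp for snp, _ in gene_rep.values()})
    selections: dict[str, SnpSelection] = {}
    for pid, pw in annotation.pathways.items():
        selected = [
            (g, gene_rep[g][0], gene_rep[g][1]) for g in pw.genes if g in gene_rep
        ]
        if len({g for g, _, _ in selected}) < min_genes:
            continue
        selections[pid] = SnpSelection(pid, selected, pool)
    return selections, pool
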