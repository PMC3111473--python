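"""End-to-end orchestration: QC, selection, per-pathway scoring, downstream.

`analyze` is the library entry point working on in-memory objects;
`run_full_analysis` wraps it with file IO, a run manifest and result tables.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from poda import __version__
from poda.core import (
    DistanceProfile,
    PathwayResult,
    combine_pathways,
    distinction_score,
    pathway_rank_sum,
    permutation_null,
    resample_pvalue,
    sample_distance_statistics,
)
from poda.downstream import (
    bh_fdr,
    d_correlation_matrix,
    logistic_odds_ratio,
    pathway_overlap_cull,
)
from poda.errors import ValidationError
from poda.io import (
    GenotypeMatrix,
    PathwayAnnotation,
    PhenotypeVector,
    read_genotypes,
    read_pathways_gmt,
    read_phenotypes,
    read_snp_gene_map,
    write_results,
)
from poda.selection import SnpSelection, qc_filter_snps, select_representative_snps

logger = logging.getLogger("poda")


@dataclass
class RunConfig:
    genotypes: str
    phenotypes: str
    pathways_gmt: str
    snp_gene_map: str
    out_dir: str
    genotype_format: str | None = None
    max_missing: float = 0.10
    min_maf: float = 0.01
    fisher_table: str = "allelic"
    n_perm: int = 100
    n_resample: int = 1000
    seed: int = 0
    cull_threshold: float = 0.60
    cull_orders: int = 25
    union_top: int = 0
    pairwise: bool = False
    n_jobs: int = 1


@dataclass
class AnalysisResult:
    results: list[PathwayResult]
    profiles: dict[str, DistanceProfile]
    selections: dict[str, SnpSelection]
    pool: list[str]
    qc_retained: set[str] = field(default_factory=set)
    culling = None
    d_corr: np.ndarray | None = None


def _pathway_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(base_seed, spawn_key=(index,))


def _analyze_one(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    annotation: PathwayAnnotation,
    selection: SnpSelection,
    qc: set[str],
    n_perm: int,
    n_resample: int,
    seed: np.random.SeedSequence,
    table: str,
) -> tuple[PathwayResult, DistanceProfile]:
    snp_set = selection.snp_ids
    profile = sample_distance_statistics(genotypes, phenotypes, snp_set)
    W = pathway_rank_sum(profile, phenotypes)
    ens = permutation_null(
        genotypes,
        phenotypes,
        annotation,
        selection.pathway_id,
        n_perm=n_perm,
        seed=seed,
        qc=qc,
        table=table,
    )
    DS = distinction_score(W, ens)
    p_res = resample_pvalue(
        genotypes,
        phenotypes,
        selection,
        n_resample=n_resample,
        n_perm=n_perm,
        seed=seed,
        true_ds=DS,
    )
    effect = logistic_odds_ratio(profile.D, phenotypes)
    pw = annotation.pathways.get(selection.pathway_id)
    result = PathwayResult(
        selection.pathway_id,
        len(snp_set),
        W,
        DS,
        p_resample=p_res,
        OR=effect.odds_ratio,
        OR_p=effect.p_value,
        source=pw.source if pw else "",
        n_genes=selection.n_genes,
    )
    return result, profile


def analyze(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    annotation: PathwayAnnotation,
    max_missing: float = 0.10,
    min_maf: float = 0.01,
    n_perm: int = 100,
    n_resample: int = 1000,
    seed: int = 0,
    fisher_table: str = "allelic",
    cull_threshold: float = 0.60,
    cull_orders: int = 25,
    n_jobs: int = 1,
) -> AnalysisResult:
    """Score every covered pathway; returns results, profiles and selections.

    Per-pathway randomness is derived from the base seed and the pathway's
    position in sorted id order, so results do not depend on worker count.
    """
    phenotypes = phenotypes.aligned_to(genotypes)
    qc = qc_filter_snps(genotypes, phenotypes, max_missing, min_maf)
    selections, pool = select_representative_snps(
        annotation, genotypes, phenotypes, qc, table=fisher_table
    )
    if not selections:
        raise ValidationError("no pathway covers at least two genes after QC")
    ordered = sorted(selections)
    seeds = [_pathway_seed(seed, i) for i in range(len(ordered))]
    worker = delayed(_analyze_one)
    out = Parallel(n_jobs=n_jobs)(
        worker(
            genotypes,
            phenotypes,
            annotation,
            selections[pid],
            qc,
            n_perm,
            n_resample,
            s,
            fisher_table,
        )
        for pid, s in zip(ordered, seeds)
    )
    results = [r for r, _ in out]
    profiles = {r.pathway_id: p for r, p in out}
    qvals = bh_fdr([max(r.OR_p, 1e-300) for r in results])
    for r, q in zip(results, qvals):
        r.FDR_q = float(q)
    res = AnalysisResult(results, profiles, selections, pool, qc)
    scores = {r.pathway_id: r.DS for r in results}
    res.culling = pathway_overlap_cull(
        selections, scores, threshold=cull_threshold, n_orders=cull_orders, seed=seed
    )
    if len(profiles) >= 2:
        res.d_corr = d_correlation_matrix([profiles[p] for p in ordered])
    return res


def top_k_unions(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    analysis: AnalysisResult,
    k_max: int,
    n_perm: int = 100,
    n_resample: int = 1000,
    seed: int = 0,
) -> list[PathwayResult]:
    """Re-score the successive unions of the top pathways (by descending OR)."""
    ranked = sorted(
        analysis.results, key=lambda r: (-(r.OR if r.OR is not None else 0), r.pathway_id)
    )
    ids = [r.pathway_id for r in ranked]
    unions: list[PathwayResult] = []
    for k in range(2, min(k_max, len(ids)) + 1):
        _, result, profile = combine_pathways(
            genotypes,
            phenotypes,
            analysis.selections,
            ids[:k],
            n_perm=n_perm,
            n_resample=n_resample,
            seed=seed,
        )
        result.pathway_id = f"Top-{k}"
        effect = logistic_odds_ratio(profile.D, phenotypes)
        result.OR, result.OR_p = effect.odds_ratio, effect.p_value
        unions.append(result)
    if unions:
        qvals = bh_fdr([max(u.OR_p, 1e-300) for u in unions])
        for u, q in zip(unions, qvals):
            u.FDR_q = float(q)
    return unions


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the whole procedure from files to result tables plus manifest."""
    for path in (
        config.genotypes,
        config.phenotypes,
        config.pathways_gmt,
        config.snp_gene_map,
    ):
        if not os.path.exists(path):
            raise ValidationError(f"input file not found: {path}")
    genotypes = read_genotypes(config.genotypes, format=config.genotype_format)
    phenotypes = read_phenotypes(config.phenotypes).aligned_to(genotypes)
    annotation = read_pathways_gmt(config.pathways_gmt)
    annotation = read_snp_gene_map(config.snp_gene_map, annotation)
    analysis = analyze(
        genotypes,
        phenotypes,
        annotation,
        max_missing=config.max_missing,
        min_maf=config.min_maf,
        n_perm=config.n_perm,
        n_resample=config.n_resample,
        seed=config.seed,
        fisher_table=config.fisher_table,
        cull_threshold=config.cull_threshold,
        cull_orders=config.cull_orders,
        n_jobs=config.n_jobs,
    )
    os.makedirs(config.out_dir, exist_ok=True)
    ordered = sorted(analysis.profiles)
    d_matrix = pd.DataFrame(
        {pid: analysis.profiles[pid].D for pid in ordered},
        index=genotypes.sample_ids,
    )
    write_results(
        analysis.results,
        os.path.join(config.out_dir, "results.tsv"),
        d_matrix=d_matrix,
        d_path=os.path.join(config.out_dir, "d_matrix.tsv"),
    )
    cull = analysis.culling
    with open(os.path.join(config.out_dir, "culling.tsv"), "w") as fh:
        fh.write("pathway\tstatus\tpartner\n")
        for pid in cull.retained:
            fh.write(f"{pid}\tretained\t.\n")
        for pid, partner in cull.removed.items():
            fh.write(f"{pid}\tremoved\t{partner}\n")
    if analysis.d_corr is not None:
        pd.DataFrame(analysis.d_corr, index=ordered, columns=ordered).to_csv(
            os.path.join(config.out_dir, "d_correlation.tsv"),
            sep="\t",
            float_format="%.6g",
        )
    outputs = {
        "results": os.path.join(config.out_dir, "results.tsv"),
        "d_matrix": os.path.join(config.out_dir, "d_matrix.tsv"),
        "culling": os.path.join(config.out_dir, "culling.tsv"),
    }
    if config.union_top >= 2:
        unions = top_k_unions(
            genotypes,
            phenotypes,
            analysis,
            config.union_top,
            n_perm=config.n_perm,
            n_resample=config.n_resample,
            seed=config.seed,
        )
        if unions:
            upath = os.path.join(config.out_dir, "unions.tsv")
            write_results(unions, upath)
            outputs["unions"] = upath
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_samples": genotypes.n_samples,
        "n_cases": phenotypes.n_cases,
        "n_controls": phenotypes.n_controls,
        "n_snps": genotypes.n_snps,
        "n_snps_after_qc": len(analysis.qc_retained),
        "n_pathways_scored": len(analysis.results),
        "representative_pool_size": len(analysis.pool),
        "pathway_seed_scheme": "SeedSequence(seed, spawn_key=(rank,)) over sorted pathway ids",
        "culling_modal_frequency": cull.modal_frequency,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["manifest"] = os.path.join(config.out_dir, "manifest.json")
    return outputs
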