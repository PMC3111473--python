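"""Synthetic case/control GWAS generators.

Three regimes are covered:

* an epistatic design in which homozygous-minor genotypes at loci (1 and 2)
  or (1 and 3) multiply the baseline disease risk three-fold, while no single
  locus carries a usable marginal association;
* a pure-null design (labels independent of genotype) for calibration;
* a two-locus XOR configuration whose class centroids coincide exactly at
  every locus, the canonical case the centroid statistic cannot see.

Genotypes are binomial samples under Hardy-Weinberg equilibrium: the
minor-allele-frequency-coded value is Binomial(2, MAF)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from poda.errors import PodaError, ValidationError
from poda.io import GenotypeMatrix, PathwayAnnotation, Pathway, PhenotypeVector

MAX_DRAWS = 10_000_000
_BATCH = 8192

#: default risk rule: homozygous minor at loci (1 and 2) OR (1 and 3), 0-based
FIG_RISK_RULE = (((0, 1), 1.0), ((0, 2), 1.0))


@dataclass
class SimulationConfig:
    """Parameters of the epistatic case/control generator.

    ``risk_rule`` is a list of clauses ``(loci, genotype)`` combined by OR: an
    individual carries the risk genotype when, for at least one clause, all
    listed loci equal the required genotype value.  Carriers' disease
    probability is ``baseline_prevalence * relative_risk`` (capped at 1).
    """

    n_cases: int = 250
    n_controls: int = 250
    n_snps: int = 50
    maf_range: tuple[float, float] = (0.1, 0.4)
    risk_rule: tuple = FIG_RISK_RULE
    relative_risk: float = 3.0
    baseline_prevalence: float = 0.2
    seed: int | None = 0
    maf_mode: str = "spaced"  # "spaced" (deterministic) or "uniform" (random)

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if self.relative_risk < 1:
            raise ValidationError("relative_risk must be >= 1")
        if self.relative_risk * self.baseline_prevalence > 1:
            raise ValidationError("relative_risk * baseline_prevalence must be <= 1")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValidationError("need at least 2 cases and 2 controls")


def _locus_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    low, high = config.maf_range
    if config.maf_mode == "spaced":
        # descending, so the low-index interacting loci sit at the top of the
        # range and the joint homozygous-minor genotype occurs at a usable rate
        return np.linspace(high, low, config.n_snps)
    if config.maf_mode == "uniform":
        return rng.uniform(low, high, config.n_snps)
    raise ValidationError(f"unknown maf_mode {config.maf_mode!r}")


def _risk_indicator(geno: np.ndarray, risk_rule) -> np.ndarray:
    hit = np.zeros(len(geno), dtype=bool)
    for loci, required in risk_rule:
        hit |= np.all(geno[:, list(loci)] == required, axis=1)
    return hit


def _snp_ids(n: int) -> list[str]:
    return [f"SNP_{j + 1:04d}" for j in range(n)]


def simulate_epistatic_gwas(
    config: SimulationConfig | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, dict]:
    """Sample individuals until the case/control quotas are filled.

    Returns the genotype matrix, phenotypes (cases first) and a truth record
    holding the target and realized per-locus MAFs, the risk-rule clauses and
    the per-sample risk-carrier indicator.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    mafs = _locus_mafs(config, rng)
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    case_risk: list[bool] = []
    control_risk: list[bool] = []
    drawn = 0
    while len(cases) < config.n_cases or len(controls) < config.n_controls:
        if drawn >= MAX_DRAWS:
            raise PodaError(
                f"case/control quotas unreachable within {MAX_DRAWS} draws "
                f"(prevalence {config.baseline_prevalence})"
            )
        geno = rng.binomial(2, mafs, size=(_BATCH, config.n_snps)) / 2.0
        risk = _risk_indicator(geno, config.risk_rule)
        p_case = np.minimum(
            config.baseline_prevalence * np.where(risk, config.relative_risk, 1.0), 1.0
        )
        is_case = rng.random(_BATCH) < p_case
        drawn += _BATCH
        for row, r, c in zip(geno, risk, is_case):
            if c and len(cases) < config.n_cases:
                cases.append(row)
                case_risk.append(bool(r))
            elif not c and len(controls) < config.n_controls:
                controls.append(row)
                control_risk.append(bool(r))
    values = np.vstack([np.array(cases), np.array(controls)])
    sample_ids = [f"case_{i + 1:04d}" for i in range(config.n_cases)] + [
        f"control_{i + 1:04d}" for i in range(config.n_controls)
    ]
    labels = np.r_[np.ones(config.n_cases, bool), np.zeros(config.n_controls, bool)]
    gm = GenotypeMatrix(sample_ids, _snp_ids(config.n_snps), values)
    pheno = PhenotypeVector(sample_ids, labels)
    truth = {
        "target_mafs": mafs,
        "realized_mafs": values.mean(axis=0),
        "risk_rule": list(config.risk_rule),
        "risk_carrier": np.array(case_risk + control_risk),
        "n_drawn": drawn,
        "config": config,
    }
    return gm, pheno, truth


def simulate_null_gwas(
    config: SimulationConfig | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Genotypes as in the epistatic design but labels independent of genotype."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    mafs = _locus_mafs(config, rng)
    n = config.n_cases + config.n_controls
    values = rng.binomial(2, mafs, size=(n, config.n_snps)) / 2.0
    sample_ids = [f"case_{i + 1:04d}" for i in range(config.n_cases)] + [
        f"control_{i + 1:04d}" for i in range(config.n_controls)
    ]
    labels = np.r_[np.ones(config.n_cases, bool), np.zeros(config.n_controls, bool)]
    return (
        GenotypeMatrix(sample_ids, _snp_ids(config.n_snps), values),
        PhenotypeVector(sample_ids, labels),
    )


def simulate_xor_gwas(
    n_per_class: int,
    maf: float = 0.3,
    n_filler: int = 8,
    seed: int | None = 0,
) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Two-locus XOR fixture: identical class centroids, epistatic structure.

    Controls carry the concordant genotype pairs {(0,0), (1,1)} and cases the
    discordant pairs {(1,0), (0,1)}, each split exactly 50/50, so both focal
    loci have MAF exactly 0.5 in both classes.  ``n_filler`` label-independent
    binomial loci at the given MAF are appended.
    """
    if n_per_class % 2:
        raise ValidationError("n_per_class must be even for an exact 50/50 split")
    rng = np.random.default_rng(seed)
    half = n_per_class // 2
    ctrl_focal = np.vstack([np.tile([0.0, 0.0], (half, 1)), np.tile([1.0, 1.0], (half, 1))])
    case_focal = np.vstack([np.tile([1.0, 0.0], (half, 1)), np.tile([0.0, 1.0], (half, 1))])
    focal = np.vstack([case_focal, ctrl_focal])
    filler = rng.binomial(2, maf, size=(2 * n_per_class, n_filler)) / 2.0
    values = np.hstack([focal, filler])
    snp_ids = ["XOR_1", "XOR_2"] + [f"NULL_{j + 1:03d}" for j in range(n_filler)]
    sample_ids = [f"case_{i + 1:04d}" for i in range(n_per_class)] + [
        f"control_{i + 1:04d}" for i in range(n_per_class)
    ]
    labels = np.r_[np.ones(n_per_class, bool), np.zeros(n_per_class, bool)]
    return GenotypeMatrix(sample_ids, snp_ids, values), PhenotypeVector(sample_ids, labels)


def make_annotation_fixture(
    n_pathways: int,
    genes_per_pathway: int,
    snps_per_gene: int = 1,
    seed: int | None = 0,
    snp_ids: list[str] | None = None,
    gmt_path=None,
    map_path=None,
) -> PathwayAnnotation:
    """Build a block annotation consistent with a generated genotype matrix.

    Genes are assigned consecutive SNPs, pathways consecutive genes, so the
    first pathway covers the first ``genes_per_pathway * snps_per_gene`` SNPs
    of the matrix — designating it "causal" simply means simulating the risk
    loci among those first SNPs.  Optionally writes GMT and SNP->gene files.
    """
    if min(n_pathways, genes_per_pathway, snps_per_gene) < 1:
        raise ValidationError("all fixture counts must be positive")
    n_genes = n_pathways * genes_per_pathway
    n_snps = n_genes * snps_per_gene
    if snp_ids is None:
        snp_ids = _snp_ids(n_snps)
    if len(snp_ids) < n_snps:
        raise ValidationError(
            f"annotation needs {n_snps} SNP ids but only {len(snp_ids)} supplied"
        )
    gene_ids = [f"GENE_{g + 1:04d}" for g in range(n_genes)]
    gene_snps = {
        gene_ids[g]: [snp_ids[g * snps_per_gene + k] for k in range(snps_per_gene)]
        for g in range(n_genes)
    }
    pathways = {}
    for p in range(n_pathways):
        pid = f"PW_{p + 1:03d}"
        genes = gene_ids[p * genes_per_pathway : (p + 1) * genes_per_pathway]
        pathways[pid] = Pathway(pid, pid, "synthetic", genes)
    annotation = PathwayAnnotation(pathways=pathways, gene_snps=gene_snps)
    if gmt_path is not None or map_path is not None:
        from poda.io import write_gmt, write_snp_gene_map

        if gmt_path is not None:
            write_gmt(annotation, gmt_path)
        if map_path is not None:
            write_snp_gene_map(annotation, map_path)
    return annotation
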