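"""Input/output: genotype matrices, phenotypes, pathway annotations, result tables.

Genotypes are stored as the per-individual minor-allele frequency, i.e. each
entry is 0 (homozygous major), 0.5 (heterozygous) or 1 (homozygous minor);
missing calls are ``numpy.nan``.  With this coding the mean of a column over a
pool of samples is exactly that pool's minor allele frequency, which is the
quantity the centroid-distance statistic is built on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from poda.errors import AlignmentError, FormatError, ValidationError

logger = logging.getLogger("poda")

MISSING = np.nan

_ALLELE_SUFFIX = re.compile(r"_[ACGT]+$")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of minor-allele-frequency-coded genotypes."""

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    snp_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValidationError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP identifiers")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 0.5, 1.0)).all():
            bad = np.unique(finite[~np.isin(finite, (0.0, 0.5, 1.0))])
            raise ValidationError(f"genotype values outside {{0, 0.5, 1}}: {bad[:5]}")
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_indices(self, snp_ids) -> np.ndarray:
        try:
            return np.array([self._snp_index[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]!r} not present in genotype matrix") from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self._snp_index[snp_id]]

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.snp_indices(snp_ids)
        meta = self.snp_meta.iloc[idx] if self.snp_meta is not None else None
        return GenotypeMatrix(self.sample_ids, list(snp_ids), self.values[:, idx], meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.snp_ids)

    def to_tsv(self, path) -> None:
        """Write a samples x SNPs TSV that round-trips exactly."""
        self.to_frame().to_csv(path, sep="\t", index_label="sample", na_rep="NA")


@dataclass
class PhenotypeVector:
    """Case/control status per sample, aligned (or alignable) to a GenotypeMatrix."""

    sample_ids: list[str]
    is_case: np.ndarray

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if self.is_case.shape != (len(self.sample_ids),):
            raise ValidationError("status length does not match sample count")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValidationError(
                "need at least 2 cases and 2 controls (leave-one-out requires a "
                f"non-empty remainder pool); got {self.n_cases} cases, "
                f"{self.n_controls} controls"
            )

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.is_case).sum())

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeVector":
        """Reorder to the genotype sample order; error on any mismatch."""
        order = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in genotypes.sample_ids if s not in order]
        extra = [s for s in self.sample_ids if s not in genotypes._sample_index]
        if missing or extra:
            raise AlignmentError(
                f"phenotype/genotype sample mismatch: missing from phenotypes "
                f"{missing[:5]}, absent from genotypes {extra[:5]}"
            )
        idx = [order[s] for s in genotypes.sample_ids]
        return PhenotypeVector(list(genotypes.sample_ids), self.is_case[idx])


@dataclass
class Pathway:
    pathway_id: str
    name: str
    source: str
    genes: list[str]


@dataclass
class PathwayAnnotation:
    """Pathway -> genes and gene -> SNPs mappings."""

    pathways: dict[str, Pathway] = field(default_factory=dict)
    gene_snps: dict[str, list[str]] = field(default_factory=dict)

    def pathway_snps(self, pathway_id: str) -> dict[str, list[str]]:
        """Candidate SNPs per gene for one pathway (genes with no SNPs omitted)."""
        pw = self.pathways[pathway_id]
        return {g: self.gene_snps[g] for g in pw.genes if self.gene_snps.get(g)}


# ---------------------------------------------------------------------------
# genotype readers


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF, PLINK-additive text (.raw) or plain TSV.

    After loading, every SNP is oriented so the coded allele is the minor
    allele in the pooled sample (cases + controls); additive 0/1/2 counts are
    rescaled to {0, 0.5, 1}.
    """
    path = str(path)
    if format is None:
        if path.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        elif path.endswith(".raw"):
            format = "plink_additive"
        else:
            format = "tsv"
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "plink_additive":
        gm = _read_plink_raw(path)
    elif format == "tsv":
        gm = _read_tsv(path)
    else:
        raise FormatError(f"unknown genotype format {format!r}")
    if gm.n_snps == 0:
        raise FormatError(f"no usable biallelic SNPs in {path}")
    _orient_to_minor(gm)
    return gm


def _read_vcf(path: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise FormatError("cyvcf2 is required for VCF input") from exc
    try:
        vcf = VCF(path)
    except OSError as exc:
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 = hom ref, 1 = het, 2 = unknown, 3 = hom alt
        gt = np.asarray(v.gt_types)
        vals = np.choose(gt, [0.0, 0.5, MISSING, 1.0])
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        snp_ids.append(sid)
        rows.append(vals)
        meta.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
    if n_skipped:
        logger.warning("skipped %d multi-allelic records in %s", n_skipped, path)
    values = np.array(rows).T if rows else np.empty((len(samples), 0))
    meta_df = pd.DataFrame(meta, columns=["chrom", "pos", "major", "minor"], index=snp_ids)
    return GenotypeMatrix(samples, snp_ids, values, meta_df)


def _read_plink_raw(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse PLINK .raw file {path}: {exc}") from exc
    fixed = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE") if c in df.columns]
    if "IID" not in fixed:
        raise FormatError(f"{path}: PLINK .raw header must contain an IID column")
    samples = df["IID"].astype(str).tolist()
    snp_cols = [c for c in df.columns if c not in fixed]
    snp_ids = [_ALLELE_SUFFIX.sub("", c) for c in snp_cols]
    values = df[snp_cols].to_numpy(dtype=float) / 2.0
    return GenotypeMatrix(samples, snp_ids, values)


def _read_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse genotype TSV {path}: {exc}") from exc
    values = df.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size and finite.max() > 1.0:  # additive 0/1/2 counts
        values = values / 2.0
    return GenotypeMatrix(df.index.astype(str).tolist(), [str(c) for c in df.columns], values)


def _orient_to_minor(gm: GenotypeMatrix) -> None:
    """Flip coding where the coded allele is the major one in the pooled sample.

    Exact ties at pooled frequency 0.5 are broken by allele lexicographic
    order when allele metadata is available (so re-loading is deterministic);
    without metadata a tied SNP keeps its loaded orientation.
    """
    with np.errstate(invalid="ignore"):
        pooled = np.nanmean(gm.values, axis=0)
    flip = pooled > 0.5
    if gm.snp_meta is not None and {"major", "minor"} <= set(gm.snp_meta.columns):
        tied = pooled == 0.5
        # on a tie the lexicographically greater allele is coded as minor
        lex = gm.snp_meta["minor"].to_numpy() < gm.snp_meta["major"].to_numpy()
        flip = flip | (tied & lex)
    if flip.any():
        gm.values[:, flip] = 1.0 - gm.values[:, flip]
        if gm.snp_meta is not None and {"major", "minor"} <= set(gm.snp_meta.columns):
            meta = gm.snp_meta.copy()
            maj = meta["major"].copy()
            meta.loc[flip, "major"] = meta.loc[flip, "minor"]
            meta.loc[flip, "minor"] = maj[flip]
            gm.snp_meta = meta


# ---------------------------------------------------------------------------
# phenotype reader

_CASE_LABELS = {"case", "cases", "affected", "1", "2"}
_CONTROL_LABELS = {"control", "controls", "unaffected", "0"}


def read_phenotypes(
    path,
    case_label: str | None = None,
    control_label: str | None = None,
) -> PhenotypeVector:
    """Read a two-column (sample id, status) table.

    Status labels are matched case-insensitively against common conventions
    (case/control, affected/unaffected, 1/0) unless an explicit
    ``case_label``/``control_label`` mapping is declared.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse phenotype table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    first = str(df.iloc[0, 1]).strip().lower()
    if first in {"status", "phenotype", "pheno"}:  # tolerate a header row
        df = df.iloc[1:]
    samples = df.iloc[:, 0].astype(str).tolist()
    raw = df.iloc[:, 1].astype(str).str.strip()
    if case_label is not None and control_label is not None:
        case_set, control_set = {case_label.lower()}, {control_label.lower()}
    else:
        case_set, control_set = _CASE_LABELS, _CONTROL_LABELS
    status = []
    for sample, label in zip(samples, raw.str.lower()):
        if label in case_set:
            status.append(True)
        elif label in control_set:
            status.append(False)
        else:
            raise ValidationError(
                f"unknown status label {label!r} for sample {sample!r}; declare "
                "case_label/control_label explicitly"
            )
    return PhenotypeVector(samples, np.array(status))


# ---------------------------------------------------------------------------
# annotation readers


def read_pathways_gmt(path) -> PathwayAnnotation:
    """Read a GMT gene-set file: name <tab> description/source <tab> gene ..."""
    pathways: dict[str, Pathway] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        logger.warning("empty GMT file %s", path)
        return PathwayAnnotation()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, source = fields[0], fields[1]
        genes: list[str] = []
        seen = set()
        for g in fields[2:]:
            g = g.strip()
            if not g:
                continue
            if g in seen:
                logger.warning("%s:%d: duplicate gene %s in pathway %s", path, lineno, g, name)
                continue
            seen.add(g)
            genes.append(g)
        pathways[name] = Pathway(name, name, source, genes)
    return PathwayAnnotation(pathways=pathways)


def read_snp_gene_map(path, annotation: PathwayAnnotation | None = None) -> PathwayAnnotation:
    """Read a two-column (SNP id, gene id) TSV into the gene -> SNPs mapping.

    SNPs absent from a genotype matrix are retained here and flagged when the
    map is actually used against that matrix.
    """
    gene_snps: dict[str, list[str]] = {}
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"{path}:{lineno}: expected 'snp<TAB>gene'")
            snp, gene = fields[0].strip(), fields[1].strip()
            if (snp, gene) in seen:
                continue
            seen.add((snp, gene))
            gene_snps.setdefault(gene, []).append(snp)
    pathways = annotation.pathways if annotation is not None else {}
    return PathwayAnnotation(pathways=pathways, gene_snps=gene_snps)


# ---------------------------------------------------------------------------
# result writer

RESULT_COLUMNS = ["Pathway", "Source", "Length", "DS", "p_DS", "OR", "FDR_OR"]


def write_results(results, path, d_matrix: pd.DataFrame | None = None, d_path=None) -> None:
    """Write the per-pathway result table (sorted by descending odds ratio).

    ``results`` is a sequence of PathwayResult-like objects.  When a
    samples x pathways matrix of per-sample distance scores is supplied it is
    written alongside as a TSV.
    """
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for r in results:
        rows.append(
            {
                "Pathway": r.pathway_id,
                "Source": getattr(r, "source", ""),
                "Length": r.s,
                "DS": r.DS,
                "p_DS": r.p_resample,
                "OR": r.OR,
                "FDR_OR": r.FDR_q,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values("OR", ascending=False, na_position="last")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    if d_matrix is not None:
        if d_path is None:
            raise ValidationError("d_path required when writing the per-sample D matrix")
        d_matrix.to_csv(d_path, sep="\t", index_label="sample", float_format="%.10g")


def write_gmt(annotation: PathwayAnnotation, path) -> None:
    """Write the pathway -> genes part as a standard GMT file."""
    with open(path, "w") as fh:
        for pw in annotation.pathways.values():
            fh.write("\t".join([pw.pathway_id, pw.source or "na", *pw.genes]) + "\n")


def write_snp_gene_map(annotation: PathwayAnnotation, path) -> None:
    """Write the gene -> SNPs part as a two-column (snp, gene) TSV."""
    with open(path, "w") as fh:
        for gene, snps in annotation.gene_snps.items():
            for snp in snps:
                fh.write(f"{snp}\t{gene}\n")


_GT_CODES = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic VCF (GT only) for a genotype matrix.

    The coded (minor) allele is written as ALT; synthetic matrices without
    allele metadata get placeholder A/C alleles on chromosome 1.
    """
    meta = gm.snp_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j, snp in enumerate(gm.snp_ids):
            if meta is not None and {"chrom", "pos", "major", "minor"} <= set(meta.columns):
                row = meta.iloc[j]
                chrom, pos, ref, alt = row["chrom"], row["pos"], row["major"], row["minor"]
            else:
                chrom, pos, ref, alt = "1", j + 1, "A", "C"
            gts = [
                "./." if np.isnan(v) else _GT_CODES[float(v)] for v in gm.values[:, j]
            ]
            fh.write(f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t")
            fh.write("\t".join(gts) + "\n")


def write_phenotypes(pheno: PhenotypeVector, path) -> None:
    with open(path, "w") as fh:
        for sample, case in zip(pheno.sample_ids, pheno.is_case):
            fh.write(f"{sample}\t{'case' if case else 'control'}\n")
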