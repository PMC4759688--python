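"""Genotype, phenotype and gene-map I/O with minor-allele recoding and QC.

Genotypes are held as a subjects x variants dosage matrix counting copies of
the *minor* allele (0/1/2, NaN for missing).  Recoding to the minor allele is
done per variant from the observed allele frequency, so MAF is always in
[0, 0.5].  Gene membership is a plain variant-id -> gene-name map; the package
never infers genes from coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataFormatError, QCError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "QCReport",
    "compute_maf",
    "recode_to_minor",
    "qc_filter",
    "read_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotypes",
    "read_gene_map",
    "attach_gene_map",
    "align_phenotypes",
]


@dataclass
class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix with variant metadata.

    dosages is float64 so missing calls can be represented as NaN; every
    non-missing entry is 0, 1 or 2 (or a mean-imputed fraction after QC).
    """

    dosages: np.ndarray
    subject_ids: list[str]
    variant_ids: list[str]
    gene_of_variant: dict[str, str] = field(default_factory=dict)
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise DataFormatError("dosages must be a 2-D subjects x variants matrix")
        n, m = self.dosages.shape
        if len(self.subject_ids) != n or len(self.variant_ids) != m:
            raise DataFormatError("subject/variant id lists do not match dosage shape")
        if self.maf is None:
            self.maf = compute_maf(self.dosages)
        else:
            self.maf = np.asarray(self.maf, dtype=np.float64)

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def gene_indices(self) -> dict[str, np.ndarray]:
        """Column indices per gene, in variant input order."""
        out: dict[str, list[int]] = {}
        for j, vid in enumerate(self.variant_ids):
            gene = self.gene_of_variant.get(vid)
            if gene is not None:
                out.setdefault(gene, []).append(j)
        return {g: np.asarray(ix, dtype=np.intp) for g, ix in out.items()}

    def gene_dosages(self) -> dict[str, np.ndarray]:
        """Per-gene dosage sub-matrices (views are copies), keyed by gene."""
        return {g: self.dosages[:, ix] for g, ix in self.gene_indices().items()}

    def subset(self, subjects: np.ndarray | None = None, variants: np.ndarray | None = None) -> "GenotypeMatrix":
        d = self.dosages
        sid, vid = self.subject_ids, self.variant_ids
        if subjects is not None:
            d = d[subjects, :]
            sid = [self.subject_ids[i] for i in np.asarray(subjects).tolist()]
        if variants is not None:
            d = d[:, variants]
            vid = [self.variant_ids[j] for j in np.asarray(variants).tolist()]
        gov = {v: g for v, g in self.gene_of_variant.items() if v in set(vid)}
        return GenotypeMatrix(d.copy(), sid, vid, gov, maf=compute_maf(d))


@dataclass
class PhenotypeTable:
    """Binary phenotype (0 = unaffected, 1 = affected) plus optional covariates."""

    y: np.ndarray
    covariates: np.ndarray
    subject_ids: list[str]
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        bad = ~np.isin(self.y, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise DataFormatError(
                f"phenotype must be binary 0/1; subject {self.subject_ids[i]!r} "
                f"(row {i}) has value {self.y[i]!r}"
            )
        self.y = self.y.astype(np.int8)
        self.covariates = np.asarray(self.covariates, dtype=np.float64).reshape(len(self.y), -1)


@dataclass
class QCReport:
    n_variants_missing_dropped: int = 0
    n_subjects_missing_dropped: int = 0
    n_variants_maf_zero_dropped: int = 0
    n_cells_imputed: int = 0


def compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Per-variant minor allele frequency from non-missing dosages.

    maf = min(p, 1 - p) with p the (possibly major) allele frequency of the
    coded allele; variants with all calls missing get NaN.
    """
    d = np.asarray(dosages, dtype=np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = np.nanmean(d, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def recode_to_minor(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip columns whose coded-allele frequency exceeds 0.5 (dosage -> 2 - dosage).

    Returns the recoded matrix and the boolean per-variant flip mask.
    """
    d = np.array(dosages, dtype=np.float64, copy=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(d, axis=0) / 2.0
    flipped = p > 0.5
    d[:, flipped] = 2.0 - d[:, flipped]
    return d, flipped


def qc_filter(
    g: GenotypeMatrix,
    var_miss_max: float = 0.1,
    subj_miss_max: float = 0.1,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop high-missingness variants, then subjects, then MAF-zero variants.

    MAF is recomputed after the subject drop.  Remaining missing dosages are
    imputed to the per-variant mean so downstream similarity kernels stay
    dense.  Relative subject/variant order is preserved.
    """
    if not (0.0 <= var_miss_max <= 1.0 and 0.0 <= subj_miss_max <= 1.0):
        raise ValueError("missing-rate thresholds must lie in [0, 1]")
    report = QCReport()
    d = g.dosages
    miss = np.isnan(d)

    keep_var = miss.mean(axis=0) <= var_miss_max
    report.n_variants_missing_dropped = int((~keep_var).sum())
    d = d[:, keep_var]

    miss = np.isnan(d)
    keep_subj = (miss.mean(axis=1) <= subj_miss_max) if d.shape[1] else np.ones(d.shape[0], bool)
    report.n_subjects_missing_dropped = int((~keep_subj).sum())
    d = d[keep_subj, :]

    maf = compute_maf(d)
    keep_maf = np.nan_to_num(maf, nan=0.0) > 0.0
    report.n_variants_maf_zero_dropped = int((~keep_maf).sum())
    d = d[:, keep_maf]

    if d.shape[1] == 0:
        raise QCError("QC removed every variant; nothing left to analyze")

    miss = np.isnan(d)
    report.n_cells_imputed = int(miss.sum())
    if report.n_cells_imputed:
        col_mean = np.nanmean(d, axis=0)
        d = np.where(miss, col_mean[None, :], d)

    variant_ids = [v for v, k in zip(g.variant_ids, keep_var) if k]
    variant_ids = [v for v, k in zip(variant_ids, keep_maf) if k]
    subject_ids = [s for s, k in zip(g.subject_ids, keep_subj) if k]
    gov = {v: gn for v, gn in g.gene_of_variant.items() if v in set(variant_ids)}
    out = GenotypeMatrix(d, subject_ids, variant_ids, gov, maf=compute_maf(d))
    logger.info("qc_filter: %s", report)
    return out, report


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a minor-allele dosage matrix.

    Multi-allelic records are rejected (split them upstream).  Dosages are
    recoded per variant so they count the rarer allele; the variant -> gene
    map is left empty until :func:`attach_gene_map` is applied.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise DataFormatError(f"cannot parse VCF {path}: {exc}") from exc
    subjects = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise DataFormatError(
                f"multi-allelic record {rec.ID or f'{rec.CHROM}:{rec.POS}'} not supported"
            )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.choose(gt, [0.0, 1.0, np.nan, 2.0])
        cols.append(col)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
    if not cols:
        raise DataFormatError(f"VCF {path} contains no usable records")
    dosages = np.column_stack(cols)
    dosages, _ = recode_to_minor(dosages)
    return GenotypeMatrix(dosages, subjects, ids, {}, maf=compute_maf(dosages))


def write_dosage_tsv(g: GenotypeMatrix, path: str, header_lines: list[str] | None = None) -> None:
    """Write the dosage TSV dialect: header `subject\\t<variant ids...>`, NA for missing."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write("subject\t" + "\t".join(g.variant_ids) + "\n")
        for i, sid in enumerate(g.subject_ids):
            row = g.dosages[i]
            cells = [
                "NA" if np.isnan(v) else (str(int(v)) if v == int(v) else repr(float(v)))
                for v in row
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    if df.empty:
        raise DataFormatError(f"dosage TSV {path} has no data rows")
    d = df.to_numpy(dtype=np.float64)
    ok = np.isnan(d) | np.isin(d, (0.0, 1.0, 2.0)) | ((d >= 0) & (d <= 2))
    if not ok.all():
        raise DataFormatError(f"dosage TSV {path} has values outside [0, 2]")
    return GenotypeMatrix(
        d, [str(s) for s in df.index], [str(v) for v in df.columns], {}, maf=compute_maf(d)
    )


def read_phenotypes(path: str) -> PhenotypeTable:
    """Read `subject\\tphenotype[\\tcov1...]` TSV; phenotype must be 0/1."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise DataFormatError(f"phenotype TSV {path} needs subject and phenotype columns")
    subj = [str(s) for s in df.iloc[:, 0]]
    y = df.iloc[:, 1].to_numpy()
    cov = df.iloc[:, 2:].to_numpy(dtype=np.float64) if df.shape[1] > 2 else np.empty((len(y), 0))
    return PhenotypeTable(y, cov, subj, covariate_names=[str(c) for c in df.columns[2:]])


def read_gene_map(path: str) -> dict[str, str]:
    """Read `variant_id\\tgene` TSV into a variant -> gene map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise DataFormatError(f"gene map {path} needs variant_id and gene columns")
    return {str(v): str(g) for v, g in zip(df.iloc[:, 0], df.iloc[:, 1])}


def attach_gene_map(g: GenotypeMatrix, mapping: dict[str, str]) -> GenotypeMatrix:
    """Attach a variant -> gene map, dropping unmapped genotype variants.

    Map entries with no matching genotype variant are skipped with a warning;
    genotype variants absent from the map are dropped with a warning.
    """
    have = set(g.variant_ids)
    orphan_map = [v for v in mapping if v not in have]
    if orphan_map:
        warnings.warn(
            f"{len(orphan_map)} gene-map variants absent from genotypes (e.g. {orphan_map[0]!r}); skipped"
        )
    keep = [j for j, v in enumerate(g.variant_ids) if v in mapping]
    dropped = g.n_variants - len(keep)
    if dropped:
        warnings.warn(f"{dropped} genotype variants have no gene assignment; dropped")
    if not keep:
        raise DataFormatError("no genotype variant has a gene assignment")
    sub = g.subset(variants=np.asarray(keep, dtype=np.intp))
    return replace(sub, gene_of_variant={v: mapping[v] for v in sub.variant_ids})


def align_phenotypes(g: GenotypeMatrix, pheno: PhenotypeTable) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Intersect subjects and order the phenotype table to match the genotypes."""
    pos = {s: i for i, s in enumerate(pheno.subject_ids)}
    keep_g = [i for i, s in enumerate(g.subject_ids) if s in pos]
    if len(keep_g) < g.n_subjects:
        warnings.warn(f"{g.n_subjects - len(keep_g)} genotyped subjects lack phenotypes; dropped")
    if not keep_g:
        raise DataFormatError("no subject is shared between genotypes and phenotypes")
    g2 = g.subset(subjects=np.asarray(keep_g, dtype=np.intp))
    order = [pos[s] for s in g2.subject_ids]
    p2 = PhenotypeTable(
        pheno.y[order], pheno.covariates[order], list(g2.subject_ids), pheno.covariate_names
    )
    return g2, p2
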