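"""Containers, readers and preparation filters for SNP-set association data.

Genotypes are additive minor-allele dosages (0/1/2, ``NaN`` for missing)
held in a :class:`GenotypeMatrix`.  Variant annotations and sample metadata
are plain :class:`pandas.DataFrame` objects validated on read; a
:class:`SnpSet` maps a gene to its ordered variant list.

The preparation filters mirror a standard exome-association workflow:
minor-allele frequency (MAF) estimation with folding, the rare/common split
at MAF < 1%, removal of singleton variants (carried by at most one
individual), removal of genes whose rare-variant carrier burden falls below
1% of individuals, and principal-component scores on high-frequency
variants for population-structure adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MAF below which a variant counts as rare (strict inequality).
RARE_MAF_THRESHOLD = 0.01

SAMPLE_REQUIRED_COLUMNS = ("sample_id", "status", "age", "sex", "environment")
SAMPLE_OPTIONAL_COLUMNS = ("subpopulation", "pc1", "pc2")
ANNOTATION_REQUIRED_COLUMNS = ("variant_id", "gene", "functional_class")
FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous")


class ParseError(ValueError):
    """A file could not be parsed under the requested format."""


class ValidationError(ValueError):
    """Input data violate a container invariant or an operation precondition."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """n_samples x n_variants additive minor-allele dosage matrix.

    ``values`` is float so missing genotypes can be carried as ``NaN``;
    every non-missing entry must be 0, 1 or 2.
    """

    values: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D matrix")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.variant_ids) != p:
            raise ValidationError(
                f"axis lengths ({len(self.sample_ids)}, {len(self.variant_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        if len(set(self.variant_ids)) != p:
            raise ValidationError("variant_ids are not unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
            raise ValidationError(
                f"non-missing genotype entries must be 0/1/2; found {bad[:5]}"
            )

    # -- basic geometry ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def variant_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        lookup = {v: j for j, v in enumerate(self.variant_ids)}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown variant id {exc.args[0]!r}") from exc

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.variant_index(variant_ids)
        return GenotypeMatrix(
            self.values[:, idx], list(self.sample_ids), [self.variant_ids[j] for j in idx]
        )

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            ids = [s for s, m in zip(self.sample_ids, mask) if m]
        else:
            ids = [self.sample_ids[i] for i in mask]
        return GenotypeMatrix(self.values[mask], ids, list(self.variant_ids))

    # -- derived quantities ------------------------------------------------

    def dosages(self, variant_ids: Sequence[str] | None = None) -> np.ndarray:
        """Dosage matrix with missing entries imputed to the per-variant mean.

        Mean imputation preserves additive-dosage semantics for downstream
        regression and kernel construction.  A variant that is missing in
        every sample imputes to 0.
        """
        vals = self.values if variant_ids is None else self.values[:, self.variant_index(variant_ids)]
        out = vals.copy()
        if np.isnan(out).any():
            with np.errstate(invalid="ignore"):
                col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nan_r, nan_c = np.nonzero(np.isnan(out))
            out[nan_r, nan_c] = col_mean[nan_c]
        return out

    def carrier_counts(self) -> np.ndarray:
        """Number of samples carrying >= 1 minor allele, per variant."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.values >= 1, axis=0).astype(int)


@dataclass
class SnpSet:
    """Ordered variants mapped to one gene; the unit tested jointly."""

    gene: str
    variant_ids: list[str]

    def __post_init__(self) -> None:
        if not self.variant_ids:
            raise ValidationError(f"SNP set for gene {self.gene!r} is empty")


@dataclass
class Dataset:
    """One analysis-ready replicate: genotypes + annotations + sets + samples."""

    genotypes: GenotypeMatrix
    annotations: pd.DataFrame
    snp_sets: list[SnpSet]
    samples: pd.DataFrame

    def snp_set(self, gene: str) -> SnpSet:
        for s in self.snp_sets:
            if s.gene == gene:
                return s
        raise KeyError(gene)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or the tabular dialect into additive coding.

    For VCF the minor allele is determined per variant from the sample
    allele frequencies, not from REF/ALT orientation: if the ALT frequency
    exceeds 0.5 the column is recoded as ``2 - dosage`` so counts always
    refer to the minor allele.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    ids: list[str] = []
    for rec in vcf:
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ParseError(f"variant {vid} is not biallelic; split multi-allelics first")
        col = np.empty(len(samples))
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last entry is the phased flag
            if len(alleles) != 2:
                raise ParseError(f"non-diploid genotype for variant {vid}, sample {samples[i]}")
            if -1 in alleles:
                col[i] = np.nan
            else:
                col[i] = sum(1 for a in alleles if a != 0)
        with np.errstate(invalid="ignore"):
            alt_freq = np.nanmean(col) / 2.0
        if np.isfinite(alt_freq) and alt_freq > 0.5:
            col = 2.0 - col
        columns.append(col)
        ids.append(vid)
    values = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return GenotypeMatrix(values, samples, ids)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse genotype TSV {path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id', got {df.columns[0]!r}")
    sample_ids = df["sample_id"].tolist()
    variant_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].replace({"NA": np.nan, "": np.nan})
    try:
        values = raw.astype(float).to_numpy()
    except ValueError as exc:
        for line_no, (_, row) in enumerate(raw.iterrows(), start=2):
            for cell in row:
                if isinstance(cell, str):
                    try:
                        float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}:{line_no}: non-numeric genotype entry {cell!r}"
                        ) from exc
        raise ParseError(f"cannot parse genotype TSV {path}: {exc}") from exc
    return GenotypeMatrix(values, sample_ids, variant_ids)


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular genotype dialect (TSV, NA for missing)."""
    out = pd.DataFrame(geno.values, columns=geno.variant_ids)
    out.insert(0, "sample_id", geno.sample_ids)
    for c in geno.variant_ids:
        out[c] = out[c].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample table (TSV): case/control status, covariates, exposure."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sample table missing required column(s): {', '.join(missing)}")
    extras = [c for c in df.columns if c not in SAMPLE_REQUIRED_COLUMNS + SAMPLE_OPTIONAL_COLUMNS]
    if extras:
        logger.warning("sample table has unknown column(s) %s; ignored", extras)
        df = df.drop(columns=extras)
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicated sample_id {dup!r}")
    if not df["status"].isin([0, 1]).all():
        bad = df.loc[~df["status"].isin([0, 1]), "status"].iloc[0]
        raise ValidationError(f"status must be 0/1; found {bad!r}")
    df["status"] = df["status"].astype(int)
    df["age"] = df["age"].astype(float)
    for col in ("sex", "environment"):
        if not df[col].isin([0, 1]).all():
            raise ValidationError(f"column {col!r} must be binary 0/1")
        df[col] = df[col].astype(int)
    return df.reset_index(drop=True)


def read_annotations(path: str | Path) -> tuple[pd.DataFrame, list[SnpSet]]:
    """Read the variant annotation table and derive one SnpSet per gene.

    ``maf`` and ``frequency_class`` are left unset; run :func:`compute_maf`
    and :func:`classify_variant_frequency` after loading genotypes.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        empty = pd.DataFrame(columns=list(ANNOTATION_REQUIRED_COLUMNS))
        return empty, []
    missing = [c for c in ANNOTATION_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation table missing column(s): {', '.join(missing)}")
    if df.empty:
        return df, []
    df["variant_id"] = df["variant_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    bad_class = ~df["functional_class"].isin(FUNCTIONAL_CLASSES)
    if bad_class.any():
        raise ValidationError(
            f"functional_class must be one of {FUNCTIONAL_CLASSES}; "
            f"found {df.loc[bad_class, 'functional_class'].iloc[0]!r}"
        )
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"variant {dup!r} listed more than once (must map to exactly one gene)")
    sets = [
        SnpSet(gene, sub["variant_id"].tolist())
        for gene, sub in df.groupby("gene", sort=False)
    ]
    return df.reset_index(drop=True), sets


# ---------------------------------------------------------------------------
# preparation filters


def compute_maf(geno: GenotypeMatrix, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-variant minor-allele frequency, folded so maf <= 0.5.

    Frequencies use non-missing genotypes only.  Returns the annotation
    table (or a minimal one) with a ``maf`` column filled in.
    """
    vals = geno.values
    n_nonmiss = (~np.isnan(vals)).sum(axis=0)
    all_missing = n_nonmiss == 0
    if all_missing.any():
        vid = geno.variant_ids[int(np.nonzero(all_missing)[0][0])]
        raise ValidationError(f"variant {vid!r} has no non-missing genotypes")
    if geno.n_samples == 0:
        raise ValidationError("genotype matrix has no samples")
    with np.errstate(invalid="ignore"):
        freq = np.nansum(vals, axis=0) / (2.0 * n_nonmiss)
    maf = np.minimum(freq, 1.0 - freq)
    table = pd.DataFrame({"variant_id": geno.variant_ids, "maf": maf})
    if annotations is None:
        return table
    out = annotations.drop(columns=["maf"], errors="ignore").merge(
        table, on="variant_id", how="left"
    )
    return out


def classify_variant_frequency(annotations: pd.DataFrame) -> pd.DataFrame:
    """Fill ``frequency_class``: rare iff maf < 1% (strict), else common."""
    if "maf" not in annotations.columns or annotations["maf"].isna().any():
        raise ValidationError("maf must be computed before frequency classification")
    out = annotations.copy()
    out["frequency_class"] = np.where(out["maf"] < RARE_MAF_THRESHOLD, "rare", "common")
    return out


def filter_singleton_variants(geno: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants carried by at most one individual.

    Monomorphic variants (zero carriers) are removed too: they carry no
    information and break column standardization downstream.
    """
    carriers = geno.carrier_counts()
    keep = carriers >= 2
    removed = [v for v, k in zip(geno.variant_ids, keep) if not k]
    kept_ids = [v for v, k in zip(geno.variant_ids, keep) if k]
    if not kept_ids:
        logger.warning("singleton filter removed every variant")
        return GenotypeMatrix(np.empty((geno.n_samples, 0)), list(geno.sample_ids), []), removed
    return geno.subset_variants(kept_ids), removed


def filter_low_burden_genes(
    geno: GenotypeMatrix,
    snp_sets: Iterable[SnpSet],
    annotations: pd.DataFrame,
) -> tuple[list[SnpSet], list[str]]:
    """Drop genes whose rare variants occur in < 1% of individuals.

    The burden is the fraction of samples carrying >= 1 minor allele at any
    of the gene's rare variants.  Genes without rare variants are retained
    (the rule is vacuous; common-variant tests still apply).
    """
    if "frequency_class" not in annotations.columns:
        raise ValidationError("frequency_class must be set before gene burden filtering")
    rare_ids = set(annotations.loc[annotations["frequency_class"] == "rare", "variant_id"])
    present = set(geno.variant_ids)
    retained: list[SnpSet] = []
    removed: list[str] = []
    n = geno.n_samples
    for s in snp_sets:
        gene_rare = [v for v in s.variant_ids if v in rare_ids and v in present]
        if not gene_rare:
            retained.append(s)
            continue
        sub = geno.values[:, geno.variant_index(gene_rare)]
        with np.errstate(invalid="ignore"):
            carries = np.nansum(sub >= 1, axis=1) > 0
        if carries.sum() / n < RARE_MAF_THRESHOLD:
            removed.append(s.gene)
        else:
            retained.append(s)
    return retained, removed


def compute_population_pcs(
    geno: GenotypeMatrix,
    annotations: pd.DataFrame | None = None,
    maf_min: float = 0.10,
    min_spacing: float | None = None,
    k: int = 2,
) -> np.ndarray:
    """Top-k principal-component scores on high-frequency variants.

    Variants with folded MAF > ``maf_min`` are selected; if ``min_spacing``
    is given, a greedy left-to-right scan per chromosome keeps only variants
    at least that many base pairs apart (requires ``chrom``/``pos`` columns
    in ``annotations``).  Columns are mean-centered (mean-imputed dosages)
    and the top-k left singular scores returned.  Each component's sign is
    fixed so its variant-loading vector has non-negative sum.
    """
    maf_table = compute_maf(geno)
    eligible = [
        v for v, m in zip(maf_table["variant_id"], maf_table["maf"]) if m > maf_min
    ]
    if min_spacing is not None:
        if annotations is None or not {"chrom", "pos"}.issubset(annotations.columns):
            raise ValidationError("min_spacing requires chrom/pos columns in annotations")
        pos = annotations.set_index("variant_id")[["chrom", "pos"]]
        kept = []
        for chrom, sub in pos.loc[pos.index.isin(eligible)].groupby("chrom", sort=False):
            last = -np.inf
            for vid, p in sub.sort_values("pos")["pos"].items():
                if p - last >= min_spacing:
                    kept.append(vid)
                    last = p
        order = {v: i for i, v in enumerate(geno.variant_ids)}
        eligible = sorted(kept, key=order.__getitem__)
    if len(eligible) < k:
        raise ValidationError(
            f"only {len(eligible)} variants eligible for PCA; need at least k={k}"
        )
    X = geno.dosages(eligible)
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :k] * s[:k]
    # deterministic sign: each loading vector sums to >= 0
    for j in range(k):
        if vt[j].sum() < 0:
            scores[:, j] = -scores[:, j]
    return scores


def add_population_pcs(
    samples: pd.DataFrame,
    geno: GenotypeMatrix,
    annotations: pd.DataFrame | None = None,
    maf_min: float = 0.10,
    min_spacing: float | None = None,
) -> pd.DataFrame:
    """Return the sample table with ``pc1``/``pc2`` filled from the genotypes."""
    scores = compute_population_pcs(geno, annotations, maf_min=maf_min, min_spacing=min_spacing, k=2)
    out = samples.copy()
    order = [geno.sample_ids.index(s) for s in out["sample_id"].astype(str)]
    out["pc1"] = scores[order, 0]
    out["pc2"] = scores[order, 1]
    return out


def standardize_columns(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise (mean 0, sd 1) standardization with n-1 denominator.

    Constant columns are mean-centered only; the second return value flags
    them so callers can drop or down-weight degenerate predictors.
    """
    m = np.asarray(m, dtype=float)
    mean = m.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, ddof=1, keepdims=True) if m.shape[0] > 1 else np.zeros((1, m.shape[1]))
    constant = (sd[0] == 0) | ~np.isfinite(sd[0])
    safe_sd = np.where(constant, 1.0, sd[0])
    out = (m - mean) / safe_sd
    return out, constant
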