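"""Genotype matrices: the n x p minor-allele count representation.

Individuals are rows, biallelic variants are columns, and each entry counts
copies (0, 1 or 2) of the *minor* allele at that site.  Matrices can be read
from a VCF (minor allele determined per site from the sample allele
frequency) or from a plain delimited text file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "center_columns",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Minor-allele count matrix with sample and variant identifiers.

    Parameters
    ----------
    values
        Integer array of shape ``(n, p)`` with entries in ``{0, 1, 2}``.
    sample_ids
        ``n`` unique sample identifiers (rows).
    variant_ids
        ``p`` unique variant identifiers (columns).
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(n)]
        if not self.variant_ids:
            self.variant_ids = [f"V{j}" for j in range(p)]
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 variant")
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and match the row count")
        if len(self.variant_ids) != p or len(set(self.variant_ids)) != p:
            raise ValueError("variant_ids must be unique and match the column count")
        if not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("genotype entries must be minor-allele counts in {0, 1, 2}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


def center_columns(Z: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Center every variant column to mean zero.

    Equivalent to the product ``A @ Z`` with the centering matrix
    ``A = I - (1/n) * ones @ ones.T`` but computed by per-column mean
    subtraction.
    """
    values = Z.values if isinstance(Z, GenotypeMatrix) else np.asarray(Z)
    if values.shape[0] < 2:
        raise ValueError("column centering needs at least 2 samples")
    values = values.astype(float)
    return values - values.mean(axis=0, keepdims=True)


def read_genotype_table(path) -> GenotypeMatrix:
    """Read a delimited genotype matrix.

    Expected layout: a header row of variant ids, first column of sample ids,
    whitespace/tab or comma delimited; rows are samples.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    values = df.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite genotype entries")
    return GenotypeMatrix(
        values=values.astype(np.int64),
        sample_ids=[str(s) for s in df.index],
        variant_ids=[str(v) for v in df.columns],
    )


def write_genotype_table(Z: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(Z.values, index=Z.sample_ids, columns=Z.variant_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_vcf(path, max_variants: int | None = None) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into a minor-allele count matrix.

    The minor allele at each site is the one with sample allele frequency
    <= 0.5: if the ALT frequency exceeds 0.5 the dosage is flipped to
    ``2 - alt_count``.  Missing genotypes are imputed with the rounded
    column mean (their count is logged); multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    n_missing = 0
    n_skipped = 0
    for record in vcf:
        if len(record.ALT) != 1:
            n_skipped += 1
            continue
        # gts012=True: 0/1/2 = alt-allele dosage, 3 = missing
        g = np.asarray(record.gt_types, dtype=float)
        miss = g == 3
        if miss.any():
            n_missing += int(miss.sum())
            g[miss] = np.nan
            fill = np.nanmean(g) if not np.isnan(g).all() else 0.0
            g[miss] = round(fill)
        if g.mean() > 1.0:  # ALT frequency > 0.5: ALT is the major allele
            g = 2.0 - g
        columns.append(g.astype(np.int64))
        variant_ids.append(record.ID or f"{record.CHROM}:{record.POS}")
        if max_variants is not None and len(columns) >= max_variants:
            break
    if n_skipped:
        logger.info("skipped %d non-biallelic records", n_skipped)
    if n_missing:
        logger.info("imputed %d missing genotypes with column means", n_missing)
    if not columns:
        raise ValueError(f"{path}: no biallelic variants found")
    values = np.column_stack(columns)
    return GenotypeMatrix(values=values, sample_ids=samples, variant_ids=variant_ids)
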