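"""Core in-memory containers shared across the pipeline.

Genotypes are additive minor-allele counts (0/1/2, NaN for missing) in a
samples × SNPs array; expression is a samples × genes array of (possibly
transformed) intensities; covariates live in a plain pandas DataFrame
indexed by sample id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns required in SNP metadata
SNP_META_COLS = ("snp", "chrom", "pos")
#: columns required in gene metadata (probe interval optional)
GENE_META_COLS = ("symbol", "chrom", "start", "end")


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes with per-SNP metadata.

    ``codes`` is float (n_samples, n_snps) with values in {0, 1, 2} and NaN
    for missing calls; column j is described by ``snp_meta`` row j.
    """

    codes: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x snps)")
        if self.codes.shape != (len(self.sample_ids), len(self.snp_meta)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.snp_meta)} SNPs"
            )
        missing = set(SNP_META_COLS) - set(self.snp_meta.columns)
        if missing:
            raise ValueError(f"snp_meta missing columns: {sorted(missing)}")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = self.snp_meta.index[self.snp_meta["snp"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not on panel")
        return int(idx[0])

    def column(self, snp_id: str) -> np.ndarray:
        return self.codes[:, self.snp_index(snp_id)]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing calls (NaN if none)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
            p = np.nanmean(self.codes, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.codes), axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.codes[:, mask],
            self.snp_meta.loc[mask].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class ExpressionMatrix:
    """Expression values with per-gene genomic (and probe) intervals.

    Intervals in ``gene_meta`` are 1-based inclusive. ``probe_start`` /
    ``probe_end`` describe the hybridization probe, used for
    polymorphic-probe flagging; they may be absent.
    """

    values: np.ndarray
    gene_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        if self.values.shape != (len(self.sample_ids), len(self.gene_meta)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.gene_meta)} genes"
            )
        missing = set(GENE_META_COLS) - set(self.gene_meta.columns)
        if missing:
            raise ValueError(f"gene_meta missing columns: {sorted(missing)}")
        bad = self.gene_meta["start"] > self.gene_meta["end"]
        if bad.any():
            raise ValueError("gene intervals must satisfy start <= end")
        self.gene_meta = self.gene_meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def symbols(self) -> list[str]:
        return list(self.gene_meta["symbol"])

    def gene_index(self, symbol: str) -> int:
        idx = self.gene_meta.index[self.gene_meta["symbol"] == symbol]
        if len(idx) == 0:
            raise KeyError(f"gene {symbol!r} not in matrix")
        return int(idx[0])

    def column(self, symbol: str) -> np.ndarray:
        return self.values[:, self.gene_index(symbol)]

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        return ExpressionMatrix(
            self.values[:, mask],
            self.gene_meta.loc[mask].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class AssociationRecord:
    """One SNP × gene (or gene × risk factor) test result."""

    snp: str
    gene: str
    p: float
    f_stat: float
    r2: float
    n_groups: int
    p_kw: float = np.nan
    beta_additive: float = np.nan
    study_wise: bool = False
    combined_x: bool = False


def check_aligned(sample_ids_a: list[str], sample_ids_b: list[str]) -> None:
    """Raise if two containers do not carry identical sample ids in order."""
    if list(sample_ids_a) != list(sample_ids_b):
        raise ValueError("sample ids are not aligned between inputs")


@dataclass
class QCReport:
    """Per-criterion SNP exclusion counts from genotype QC."""

    n_input: int = 0
    n_kept: int = 0
    n_fail_maf: int = 0
    n_fail_call_rate: int = 0
    n_fail_hwe: int = 0
    n_no_data: int = 0
    reasons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": ["input", "kept", "maf", "call_rate", "hwe", "no_data"],
                "count": [
                    self.n_input,
                    self.n_kept,
                    self.n_fail_maf,
                    self.n_fail_call_rate,
                    self.n_fail_hwe,
                    self.n_no_data,
                ],
            }
        )
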