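"""Plain-text I/O: VCF, dosage/expression/detection/covariate TSV, BED,
ground-truth YAML.

Genotypes round-trip through VCF (GT fields, one contig per chromosome,
read back with cyvcf2) or a dosage TSV. Intervals round-trip through BED
(0-based half-open on disk, 1-based inclusive in memory).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, GenotypeMatrix
from .simdata import DetectionMatrix, GroundTruthLedger

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Sites-plus-GT VCF with one contig line per simulated chromosome."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(G.snp_meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, row in G.snp_meta.iterrows():
            gts = "\t".join(
                "./." if np.isnan(c) else _GT_CODE[c] for c in G.codes[:, j]
            )
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\tA\tG\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF into additive ALT-allele counts (NaN for missing)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    codes_cols, meta_rows = [], []
    for var in vcf:
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.where(gt == 0, 0.0,
                       np.where(gt == 1, 1.0,
                                np.where(gt == 3, 2.0, np.nan)))
        codes_cols.append(col)
        meta_rows.append({"snp": var.ID, "chrom": var.CHROM, "pos": var.POS})
    codes = (np.column_stack(codes_cols) if codes_cols
             else np.empty((len(samples), 0)))
    return GenotypeMatrix(codes, pd.DataFrame(meta_rows, columns=["snp", "chrom", "pos"]),
                          samples)


def write_dosage_tsv(G: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(G.codes.T, index=G.snp_meta["snp"], columns=G.sample_ids)
    df = pd.concat([G.snp_meta.set_index("snp")[["chrom", "pos"]], df], axis=1)
    df.to_csv(path, sep="\t", index_label="snp", float_format="%.6g")


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp")
    meta = df[["chrom", "pos"]].reset_index()
    meta["chrom"] = meta["chrom"].astype(str)
    codes = df.drop(columns=["chrom", "pos"]).to_numpy(dtype=float).T
    return GenotypeMatrix(codes, meta, list(df.columns[2:]))


# ---------------------------------------------------------------------------
# expression / detection / covariates
# ---------------------------------------------------------------------------

def write_expression_tsv(E: ExpressionMatrix, path: str) -> None:
    """Genes × samples TSV with a header row of sample ids."""
    df = pd.DataFrame(E.values.T, index=E.gene_meta["symbol"], columns=E.sample_ids)
    df.to_csv(path, sep="\t", index_label="symbol", float_format="%.8g")


def read_expression_tsv(path: str, gene_bed: str,
                        probe_bed: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="symbol")
    genes = read_bed(gene_bed).set_index("name")
    meta = genes.loc[df.index].reset_index().rename(columns={"name": "symbol"})
    if probe_bed is not None:
        probes = read_bed(probe_bed).set_index("name")
        meta["probe_start"] = probes.loc[meta["symbol"], "start"].to_numpy()
        meta["probe_end"] = probes.loc[meta["symbol"], "end"].to_numpy()
    return ExpressionMatrix(df.to_numpy(dtype=float).T, meta, list(df.columns))


def write_detection_tsv(D: DetectionMatrix, path: str) -> None:
    df = pd.DataFrame(D.pvalues.T, index=D.symbols, columns=D.sample_ids)
    df.to_csv(path, sep="\t", index_label="symbol", float_format="%.6g")


def read_detection_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    """Returns (pvalues samples × genes, sample_ids, symbols)."""
    df = pd.read_csv(path, sep="\t", index_col="symbol")
    return df.to_numpy(dtype=float).T, list(df.columns), list(df.index)


def write_covariates_tsv(C: pd.DataFrame, path: str) -> None:
    C.to_csv(path, sep="\t", index_label="sample", float_format="%.8g")


def read_covariates_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


# ---------------------------------------------------------------------------
# BED (0-based half-open on disk)
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str,
              start_col: str = "start", end_col: str = "end",
              name_col: str = "symbol") -> None:
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            fh.write(f"{row['chrom']}\t{row[start_col] - 1}\t{row[end_col]}"
                     f"\t{row[name_col]}\n")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start0", "end", "name"],
                     dtype={"chrom": str})
    df["start"] = df["start0"] + 1
    return df[["chrom", "start", "end", "name"]]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def write_ledger_yaml(ledger: GroundTruthLedger, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ledger.to_dict(), fh, sort_keys=False)


def read_ledger_yaml(path: str) -> GroundTruthLedger:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return GroundTruthLedger(
        genetic=d.get("genetic", []),
        risk_factor=d.get("risk_factor", []),
        interaction=d.get("interaction", []),
        probe_artifact=d.get("probe_artifact", []),
        plaque_link=d.get("plaque_link", {}) or {},
    )


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
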