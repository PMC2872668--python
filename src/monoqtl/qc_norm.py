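"""Expression pre-processing and genotype quality control.

Expression: arcsinh variance-stabilization (defined for the negative
intensities bead arrays can produce), quantile normalization across arrays,
a negative-control detection filter, and removal of poorly characterized
gene symbols (KIAA/FLJ/HS/MGC/LOC and C<n>orf families).

Genotypes: per-SNP filters on minor allele frequency (>1%), call rate
(>98%) and Hardy-Weinberg equilibrium (1-df chi-square P > 1e-4).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import ExpressionMatrix, GenotypeMatrix, QCReport
from .simdata import DetectionMatrix

_SYMBOL_DROP_RE = re.compile(r"^(KIAA|FLJ|HS|MGC|LOC)|^C\d+orf")


def arcsinh_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise x -> ln(x + sqrt(x²+1)); strictly increasing, odd."""
    return ExpressionMatrix(
        np.arcsinh(expr.values), expr.gene_meta.copy(), list(expr.sample_ids)
    )


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean across-sample sorted distribution.

    Ranks within a sample are preserved; ties receive the mean of the
    reference values at their tied ranks.
    """
    x = expr.values
    if x.shape[0] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if np.isnan(x).any():
        raise ValueError("missing expression values are not supported")
    # reference distribution: mean over samples of within-sample sorted values
    ref = np.sort(x, axis=1).mean(axis=0)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = _map_to_reference(x[i], ref)
    return ExpressionMatrix(out, expr.gene_meta.copy(), list(expr.sample_ids))


def _map_to_reference(row: np.ndarray, ref: np.ndarray) -> np.ndarray:
    order = np.argsort(row, kind="mergesort")
    mapped = np.empty_like(row)
    sorted_vals = row[order]
    # walk runs of tied values; each run gets the mean reference value
    start = 0
    n = len(row)
    while start < n:
        stop = start + 1
        while stop < n and sorted_vals[stop] == sorted_vals[start]:
            stop += 1
        mapped[order[start:stop]] = ref[start:stop].mean()
        start = stop
    return mapped


def detection_filter(
    detect: DetectionMatrix, p_cut: float = 0.05, sample_frac: float = 0.05
) -> np.ndarray:
    """Boolean mask of genes detected above background.

    A gene is kept iff its detection P-value is below ``p_cut`` in strictly
    more than ``sample_frac`` of the samples.
    """
    n_samples = detect.pvalues.shape[0]
    n_below = (detect.pvalues < p_cut).sum(axis=0)
    return n_below > sample_frac * n_samples


def filter_gene_symbols(symbols: list[str]) -> list[str]:
    """Drop putative / poorly characterized symbols (case-sensitive)."""
    return [s for s in symbols if not _SYMBOL_DROP_RE.match(s)]


def hwe_chi2_p(n0: int, n1: int, n2: int) -> float:
    """HWE 1-df chi-square P from genotype counts (no continuity correction).

    The allele frequency is estimated from the counts themselves; expected
    counts are n·(p², 2pq, q²).
    """
    n = n0 + n1 + n2
    if n == 0:
        return np.nan
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    nonzero = expected > 0
    stat = ((observed[nonzero] - expected[nonzero]) ** 2 / expected[nonzero]).sum()
    return float(chi2.sf(stat, 1))


def genotype_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.98,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the three SNP filters; strict inequalities throughout.

    A SNP is kept iff MAF > maf_min AND call rate > call_rate_min AND
    HWE P > hwe_p_min. SNPs with zero non-missing calls are dropped with
    reason "no data". The report counts every criterion a SNP fails.
    """
    codes = G.codes
    n, m = codes.shape
    maf = G.maf()
    call_rate = G.call_rate()

    hwe_p = np.empty(m)
    for j in range(m):
        col = codes[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            hwe_p[j] = np.nan
            continue
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        hwe_p[j] = hwe_chi2_p(n0, n1, n2)

    no_data = np.isnan(hwe_p) | np.isnan(maf)
    fail_maf = ~no_data & ~(maf > maf_min)
    fail_cr = ~(call_rate > call_rate_min)
    fail_hwe = ~no_data & ~(hwe_p > hwe_p_min)
    keep = ~(no_data | fail_maf | fail_cr | fail_hwe)

    reasons = pd.DataFrame(
        {
            "snp": G.snp_meta["snp"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "kept": keep,
            "reason": [
                "no data" if no_data[j] else ";".join(
                    r for r, f in (
                        ("maf", fail_maf[j]),
                        ("call_rate", fail_cr[j]),
                        ("hwe", fail_hwe[j]),
                    ) if f
                )
                for j in range(m)
            ],
        }
    )
    report = QCReport(
        n_input=m,
        n_kept=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
        n_no_data=int(no_data.sum()),
        reasons=reasons,
    )
    kept = G.subset_snps(keep)
    kept.snp_meta = kept.snp_meta.assign(
        maf=maf[keep], call_rate=call_rate[keep], hwe_p=hwe_p[keep]
    )
    return kept, report


# smoking statuses collapsing to "smoker" under the dichotomization
_SMOKER_STATUSES = {"smoker", "occasional smoker", "occasional", "regular smoker"}
_NONSMOKER_STATUSES = {"never smoker", "former smoker", "non-smoker", "never"}


def prepare_covariates(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive analysis covariates: binary smoking and sqrt-CRP.

    Smoking given as text status is dichotomized (never/former -> 0,
    occasional/regular -> 1); numeric smoking is passed through. A
    ``sqrt_crp`` column is added; negative CRP raises.
    """
    out = raw.copy()
    if "smoking" in out.columns and out["smoking"].dtype == object:
        def collapse(status: str) -> float:
            s = status.strip().lower()
            s = re.sub(r",.*$", "", s)  # drop qualifiers like ", <1 cigarette/day"
            if s in _SMOKER_STATUSES:
                return 1.0
            if s in _NONSMOKER_STATUSES:
                return 0.0
            raise ValueError(f"unrecognized smoking status {status!r}")
        out["smoking"] = out["smoking"].map(collapse)
    if "crp" in out.columns:
        crp = out["crp"].to_numpy(dtype=float)
        if (crp < 0).any():
            raise ValueError("negative CRP value")
        out["sqrt_crp"] = np.sqrt(crp)
    return out
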