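"""Genome-wide SNP × expression association scan.

The primary test is a one-way fixed-effects ANOVA of transformed expression
across genotype groups. Rules:

* minor-allele homozygotes are merged with heterozygotes when fewer than 30
  (``min_homozygotes``), giving a 2-group test;
* ANOVA hits are confirmed by a Kruskal-Wallis rank test (robustness filter,
  P < 1e-10 required for study-wise significance);
* chromosome-X SNPs are tested separately in women and men and the per-sex
  P-values combined by Fisher's method (chi-square on 4 df);
* all associations below a storage threshold (1e-5) are persisted; the
  study-wise flag uses the Bonferroni threshold over all SNP × expression
  tests (5.78e-12 at the designed scale).

An additive-coding regression slope is stored alongside each persisted
record: the ANOVA is direction-free, but downstream mediation logic needs
the sign of the effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, check_aligned

STUDY_WISE_P = 5.78e-12
STORE_BELOW_P = 1e-5
KW_CONFIRM_P = 1e-10
MIN_HOMOZYGOTES = 30


class UntestableSNP(ValueError):
    """Raised when a SNP collapses to a single genotype group."""


# ---------------------------------------------------------------------------
# single-test primitives
# ---------------------------------------------------------------------------

def group_genotypes(codes: np.ndarray, min_homozygotes: int = MIN_HOMOZYGOTES
                    ) -> tuple[np.ndarray, int]:
    """Genotype group labels with the small-homozygote merging rule.

    Returns (labels, n_groups); labels are 0..k-1 over non-missing samples,
    -1 where the genotype is missing. Minor-allele homozygotes (the rarer
    homozygote class by allele frequency) are merged into heterozygotes when
    their count is below ``min_homozygotes``. If the heterozygote class of a
    3-group split is itself below the cutoff, the two smallest groups are
    merged. A single remaining group raises :class:`UntestableSNP`.
    """
    codes = np.asarray(codes, dtype=float)
    valid = ~np.isnan(codes)
    present = codes[valid]
    counts = {c: int((present == c).sum()) for c in (0.0, 1.0, 2.0)}
    # allele frequency of the allele counted by the codes
    n_calls = valid.sum()
    if n_calls == 0:
        raise UntestableSNP("no non-missing genotypes")
    freq = present.sum() / (2 * n_calls)
    minor_hom, major_hom = (2.0, 0.0) if freq <= 0.5 else (0.0, 2.0)

    # start from the 0/1/2 partition, then merge per the rules
    groups: list[set[float]] = [{c} for c in (0.0, 1.0, 2.0) if counts[c] > 0]
    if counts[minor_hom] > 0 and counts[minor_hom] < min_homozygotes and counts[1.0] > 0:
        groups = [g for g in groups if g not in ({minor_hom}, {1.0})]
        groups.append({minor_hom, 1.0})
    if len(groups) == 3 and counts[1.0] < min_homozygotes:
        sizes = [sum(counts[c] for c in g) for g in groups]
        order = np.argsort(sizes)
        merged = groups[order[0]] | groups[order[1]]
        groups = [groups[order[2]], merged]
    if len(groups) < 2:
        raise UntestableSNP("fewer than 2 genotype groups")

    # deterministic label order: by the mean code of the group
    groups.sort(key=lambda g: min(g))
    labels = np.full(codes.shape, -1, dtype=int)
    for k, g in enumerate(groups):
        for c in g:
            labels[valid & (codes == c)] = k
    return labels, len(groups)


def anova_assoc(expr: np.ndarray, groups: np.ndarray
                ) -> tuple[float, float, float]:
    """One-way fixed-effects ANOVA: returns (F, P, R²).

    R² = SS_between / SS_total, the fraction of expression variance
    explained by genotype group. Zero total variance yields (0, 1, 0).
    Samples with group label < 0 are excluded.
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(groups)
    keep = g >= 0
    y, g = y[keep], g[keep]
    ids = np.unique(g)
    k, n = len(ids), len(y)
    if k < 2:
        raise UntestableSNP("ANOVA needs at least 2 groups")
    grand = y.mean()
    sst = ((y - grand) ** 2).sum()
    if sst == 0:
        return 0.0, 1.0, 0.0
    ssb = sum(len(y[g == i]) * (y[g == i].mean() - grand) ** 2 for i in ids)
    ssw = sst - ssb
    df1, df2 = k - 1, n - k
    if ssw <= 0:
        return np.inf, 0.0, 1.0
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), p, float(ssb / sst)


def kw_confirm(expr: np.ndarray, groups: np.ndarray) -> float:
    """Kruskal-Wallis P (tie-corrected H on k−1 chi-square df).

    All-tied input gives H = 0, reported as P = 1.
    """
    y = np.asarray(expr, dtype=float)
    g = np.asarray(groups)
    keep = g >= 0
    y, g = y[keep], g[keep]
    ids = np.unique(g)
    k, n = len(ids), len(y)
    if k < 2:
        raise UntestableSNP("KW needs at least 2 groups")
    ranks = stats.rankdata(y)
    h = 12.0 / (n * (n + 1)) * sum(
        len(ranks[g == i]) * ranks[g == i].mean() ** 2 for i in ids
    ) - 3.0 * (n + 1)
    # tie correction
    _, tie_counts = np.unique(y, return_counts=True)
    denom = 1.0 - (tie_counts ** 3 - tie_counts).sum() / (n ** 3 - n)
    if denom <= 0:
        return 1.0  # all values tied
    h /= denom
    if h <= 0:
        return 1.0
    return float(stats.chi2.sf(h, k - 1))


def fisher_combine(pvalues: list[float]) -> float:
    """Fisher's method: −2Σln P ~ chi-square on 2k df."""
    p = np.asarray(pvalues, dtype=float)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * len(p)))


def additive_beta(expr: np.ndarray, codes: np.ndarray) -> float:
    """Slope of expression on additive genotype coding (pairwise complete)."""
    y = np.asarray(expr, dtype=float)
    g = np.asarray(codes, dtype=float)
    keep = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[keep], g[keep]
    vg = g.var()
    if vg == 0:
        return np.nan
    return float(np.cov(g, y, bias=True)[0, 1] / vg)


def chrx_assoc(
    expr: np.ndarray,
    codes: np.ndarray,
    sex_female: np.ndarray,
    min_homozygotes: int = MIN_HOMOZYGOTES,
) -> dict:
    """Sex-stratified test for a chromosome-X SNP.

    ANOVA (and KW) run separately in women and men; the per-sex P-values
    are combined by Fisher's method on 4 df. If only one sex is testable
    its P is returned with ``combined=False``. R² is reported as the
    sample-size-weighted mean of the per-sex R².
    """
    female = np.asarray(sex_female, dtype=float) > 0.5
    per_sex = []
    for mask in (female, ~female):
        y, g = np.asarray(expr)[mask], np.asarray(codes)[mask]
        try:
            labels, k = group_genotypes(g, min_homozygotes)
            f, p, r2 = anova_assoc(y, labels)
            p_kw = kw_confirm(y, labels)
            per_sex.append({"n": int((labels >= 0).sum()), "k": k,
                            "p": p, "p_kw": p_kw, "r2": r2, "f": f})
        except UntestableSNP:
            per_sex.append(None)
    testable = [s for s in per_sex if s is not None]
    if not testable:
        raise UntestableSNP("neither sex testable")
    if len(testable) == 1:
        s = testable[0]
        return {"p": s["p"], "p_kw": s["p_kw"], "r2": s["r2"], "f": s["f"],
                "n": s["n"], "groups": s["k"], "combined": False}
    n_tot = sum(s["n"] for s in testable)
    return {
        "p": fisher_combine([s["p"] for s in testable]),
        "p_kw": fisher_combine([s["p_kw"] for s in testable]),
        "r2": sum(s["r2"] * s["n"] for s in testable) / n_tot,
        "f": np.nan,
        "n": n_tot,
        "groups": max(s["k"] for s in testable),
        "combined": True,
    }


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def _vectorized_anova(Y: np.ndarray, labels: np.ndarray, k: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(F, P, R²) for every gene column of Y under one grouping.

    Y is (n_valid, n_genes) with labels 0..k-1 (no negatives).
    """
    n = Y.shape[0]
    counts = np.bincount(labels, minlength=k).astype(float)
    # group sums via indicator matmul: (k, n) @ (n, genes)
    ind = np.zeros((k, n))
    ind[labels, np.arange(n)] = 1.0
    gsum = ind @ Y
    gmean = gsum / counts[:, None]
    grand = Y.mean(axis=0)
    sst = ((Y - grand) ** 2).sum(axis=0)
    ssb = (counts[:, None] * (gmean - grand) ** 2).sum(axis=0)
    ssw = sst - ssb
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
        r2 = np.where(sst > 0, ssb / sst, 0.0)
    p = np.where(sst > 0, stats.f.sf(f, df1, df2), 1.0)
    f = np.where(sst > 0, f, 0.0)
    return f, p, r2


def genome_scan(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    sex: np.ndarray | None = None,
    store_below: float = STORE_BELOW_P,
    study_wise: float = STUDY_WISE_P,
    kw_threshold: float = KW_CONFIRM_P,
    min_homozygotes: int = MIN_HOMOZYGOTES,
    cis_window: int = 1_000_000,
) -> pd.DataFrame:
    """Test every SNP against every expression trait; persist P < store_below.

    Returns a table with one row per stored association: snp, chrom, pos,
    gene, gene coordinates, n, groups, F, R2, p_anova, p_kw, beta_additive,
    study_wise (0/1), combined_x (0/1), sorted by (gene, p_anova). The
    study-wise flag requires both ANOVA P < ``study_wise`` and KW
    P < ``kw_threshold``. X-linked SNPs are routed through the
    sex-stratified Fisher combination (``sex`` must then be provided,
    female=1).
    """
    check_aligned(E.sample_ids, G.sample_ids)
    records: list[dict] = []
    gene_meta = E.gene_meta
    Y_all = E.values

    for j in range(G.n_snps):
        meta = G.snp_meta.iloc[j]
        codes = G.codes[:, j]
        is_x = str(meta["chrom"]).upper() in ("X", "CHRX", "23")

        if is_x:
            if sex is None:
                raise ValueError("sex vector required to test X-linked SNPs")
            _scan_x_snp(records, Y_all, codes, sex, meta, gene_meta,
                        store_below, min_homozygotes)
            continue

        valid = ~np.isnan(codes)
        try:
            labels, k = group_genotypes(codes, min_homozygotes)
        except UntestableSNP:
            continue
        lab = labels[valid]
        Y = Y_all[valid]
        f, p, r2 = _vectorized_anova(Y, lab, k)
        hits = np.flatnonzero(p < store_below)
        for gi in hits:
            p_kw = kw_confirm(Y[:, gi], lab)
            records.append({
                "snp": meta["snp"], "chrom": meta["chrom"], "pos": meta["pos"],
                "gene": gene_meta.iloc[gi]["symbol"],
                "gene_chrom": gene_meta.iloc[gi]["chrom"],
                "gene_start": gene_meta.iloc[gi]["start"],
                "gene_end": gene_meta.iloc[gi]["end"],
                "n": int(valid.sum()), "groups": k,
                "F": f[gi], "R2": r2[gi],
                "p_anova": p[gi], "p_kw": p_kw,
                "beta_additive": additive_beta(Y_all[:, gi], codes),
                "combined_x": 0,
            })

    out = pd.DataFrame.from_records(
        records,
        columns=["snp", "chrom", "pos", "gene", "gene_chrom", "gene_start",
                 "gene_end", "n", "groups", "F", "R2", "p_anova", "p_kw",
                 "beta_additive", "combined_x"],
    )
    out["study_wise"] = (
        (out["p_anova"] < study_wise) & (out["p_kw"] < kw_threshold)
    ).astype(int)
    out = out.sort_values(["gene", "p_anova"], kind="mergesort").reset_index(drop=True)
    return out


def scan_pvalue_matrix(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    min_homozygotes: int = MIN_HOMOZYGOTES,
) -> np.ndarray:
    """ANOVA P for every (SNP, gene) pair, as an (n_snps, n_genes) matrix.

    Calibration helper: unlike :func:`genome_scan` nothing is filtered or
    persisted and no KW confirmation is run. Untestable SNPs get NaN rows.
    X-linked SNPs are tested unstratified here.
    """
    check_aligned(E.sample_ids, G.sample_ids)
    out = np.full((G.n_snps, E.n_genes), np.nan)
    for j in range(G.n_snps):
        codes = G.codes[:, j]
        valid = ~np.isnan(codes)
        try:
            labels, k = group_genotypes(codes, min_homozygotes)
        except UntestableSNP:
            continue
        _, p, _ = _vectorized_anova(E.values[valid], labels[valid], k)
        out[j] = p
    return out


def _scan_x_snp(records, Y_all, codes, sex, meta, gene_meta,
                store_below, min_homozygotes) -> None:
    """Sex-stratified scan of one X SNP, appending stored hits."""
    female = np.asarray(sex, dtype=float) > 0.5
    per_sex = []
    for mask in (female, ~female):
        g = codes[mask]
        try:
            labels, k = group_genotypes(g, min_homozygotes)
        except UntestableSNP:
            per_sex.append(None)
            continue
        valid = labels >= 0
        f, p, r2 = _vectorized_anova(Y_all[mask][valid], labels[valid], k)
        per_sex.append({"mask": mask, "labels": labels, "k": k,
                        "p": p, "r2": r2, "n": int(valid.sum())})
    testable = [s for s in per_sex if s is not None]
    if not testable:
        return
    if len(testable) == 2:
        a, b = testable
        with np.errstate(divide="ignore"):
            x = -2.0 * (np.log(np.clip(a["p"], 1e-320, 1))
                        + np.log(np.clip(b["p"], 1e-320, 1)))
        p_comb = stats.chi2.sf(x, 4)
        n_tot = a["n"] + b["n"]
        r2_comb = (a["r2"] * a["n"] + b["r2"] * b["n"]) / n_tot
        combined = 1
    else:
        s = testable[0]
        p_comb, r2_comb, n_tot, combined = s["p"], s["r2"], s["n"], 0
    hits = np.flatnonzero(p_comb < store_below)
    for gi in hits:
        kw_parts = []
        for s in testable:
            y = Y_all[s["mask"]][:, gi]
            kw_parts.append(kw_confirm(y[s["labels"] >= 0],
                                       s["labels"][s["labels"] >= 0]))
        p_kw = fisher_combine(kw_parts) if len(kw_parts) == 2 else kw_parts[0]
        records.append({
            "snp": meta["snp"], "chrom": meta["chrom"], "pos": meta["pos"],
            "gene": gene_meta.iloc[gi]["symbol"],
            "gene_chrom": gene_meta.iloc[gi]["chrom"],
            "gene_start": gene_meta.iloc[gi]["start"],
            "gene_end": gene_meta.iloc[gi]["end"],
            "n": n_tot, "groups": max(s["k"] for s in testable),
            "F": np.nan, "R2": float(r2_comb[gi]),
            "p_anova": float(p_comb[gi]), "p_kw": p_kw,
            "beta_additive": additive_beta(Y_all[:, gi], codes),
            "combined_x": combined,
        })
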