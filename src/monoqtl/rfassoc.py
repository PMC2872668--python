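"""Expression × risk-factor association, enrichment and interaction.

Each risk factor is tested against every expression trait by linear
regression with expression as the dependent variable, adjusted per the
declared scheme (age adjusted for sex; BMI, smoking and √CRP for age and
sex; lipids and blood pressure additionally for BMI). Study-wise
significance corrects for 10 risk factors × all expression traits
(3.9e-7 at the designed scale).

The cis-eSNP enrichment odds ratio asks whether risk-factor-associated
traits are more often under cis genetic control; the genotype×risk-factor
interaction scan asks whether the two sources of variability deviate from
additivity; the binomial enrichment is the functional-category test over
user-supplied category counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GenotypeMatrix, check_aligned
from .eqtl import MIN_HOMOZYGOTES, UntestableSNP, group_genotypes
from .regress import design_matrix, is_collinear, ols_scan

RF_STUDY_WISE_P = 3.9e-7

#: default covariate-adjustment scheme per risk factor
DEFAULT_SCHEMES: dict[str, tuple[str, ...]] = {
    "sex": (),
    "age": ("sex",),
    "bmi": ("age", "sex"),
    "smoking": ("age", "sex"),
    "sqrt_crp": ("age", "sex"),
    "crp": ("age", "sex"),
    "hdl": ("age", "sex", "bmi"),
    "ldl": ("age", "sex", "bmi"),
    "tg": ("age", "sex", "bmi"),
    "sbp": ("age", "sex", "bmi"),
    "dbp": ("age", "sex", "bmi"),
}


@dataclass
class EnrichmentResult:
    """2×2 odds ratio with Woolf (log-normal) 95% CI."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float


def rf_assoc_scan(
    E: ExpressionMatrix,
    C: pd.DataFrame,
    risk_factors: list[str] | None = None,
    schemes: dict[str, tuple[str, ...]] | None = None,
    threshold: float = RF_STUDY_WISE_P,
) -> pd.DataFrame:
    """Scan every (gene, risk factor) pair; returns the full result table.

    Columns: gene, risk_factor, n, beta, t, p, significant. Samples with
    missing values in the risk factor or its adjustment covariates are
    dropped per risk factor; a collinear design skips the risk factor with
    reason recorded in the ``skipped`` attribute of the returned frame.
    """
    check_aligned(E.sample_ids, list(C.index))
    schemes = dict(DEFAULT_SCHEMES if schemes is None else schemes)
    if risk_factors is None:
        risk_factors = [rf for rf in schemes if rf in C.columns]
    rows = []
    skipped: list[tuple[str, str]] = []
    for rf in risk_factors:
        covars = schemes.get(rf, ())
        needed = [rf, *covars]
        sub = C[needed].astype(float)
        keep = ~sub.isna().any(axis=1).to_numpy()
        X = design_matrix(sub[rf].to_numpy()[keep],
                          *[sub[c].to_numpy()[keep] for c in covars])
        if is_collinear(X):
            skipped.append((rf, "collinear covariates"))
            continue
        Y = E.values[keep]
        beta, t, p = ols_scan(Y, X, coef_index=1)
        for gi, symbol in enumerate(E.symbols):
            rows.append({"gene": symbol, "risk_factor": rf,
                         "n": int(keep.sum()), "beta": beta[gi],
                         "t": t[gi], "p": p[gi]})
    out = pd.DataFrame(rows, columns=["gene", "risk_factor", "n", "beta", "t", "p"])
    out["significant"] = (out["p"] < threshold).astype(int)
    out.attrs["skipped"] = skipped
    return out


def enrichment_or(
    k_rf_cis: int, k_rf_noncis: int, k_other_cis: int, k_other_noncis: int,
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Odds ratio of cis control given risk-factor association.

    Cells: a = risk-factor-associated and cis-controlled, b = risk-factor-
    associated not cis, c = other traits cis, d = other traits not cis.
    OR = ad/bc with Woolf 95% CI exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).
    With a zero cell the OR/CI are undefined (NaN) unless the Haldane
    +0.5 continuity correction is enabled.
    """
    cells = np.array([k_rf_cis, k_rf_noncis, k_other_cis, k_other_noncis],
                     dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    adj = cells + 0.5 if continuity_correction and (cells == 0).any() else cells
    if (adj == 0).any():
        return EnrichmentResult(*cells.astype(int), np.nan, np.nan, np.nan)
    a, b, c, d = adj
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EnrichmentResult(
        int(cells[0]), int(cells[1]), int(cells[2]), int(cells[3]),
        float(or_), float(or_ * np.exp(-1.96 * se)), float(or_ * np.exp(1.96 * se)),
    )


def enrichment_table(
    rf_assoc: pd.DataFrame,
    cis_genes: set[str],
    all_genes: list[str],
) -> pd.DataFrame:
    """Per-risk-factor cis-eSNP enrichment table (counts, OR, CI).

    ``rf_assoc`` is the scan output; a gene counts as risk-factor-associated
    when flagged significant for that factor, and as cis-controlled when in
    ``cis_genes``.
    """
    total = len(all_genes)
    all_set = set(all_genes)
    cis_total = len(cis_genes & all_set)
    rows = []
    for rf, sub in rf_assoc.groupby("risk_factor", sort=False):
        assoc_genes = set(sub.loc[sub["significant"] == 1, "gene"])
        a = len(assoc_genes & cis_genes)
        b = len(assoc_genes) - a
        c = cis_total - a
        d = total - len(assoc_genes) - c
        res = enrichment_or(a, b, c, d)
        rows.append({"risk_factor": rf, "n_assoc": len(assoc_genes),
                     "n_assoc_cis": a,
                     "pct_cis": 100.0 * a / len(assoc_genes) if assoc_genes else np.nan,
                     "odds_ratio": res.odds_ratio,
                     "ci_low": res.ci_low, "ci_high": res.ci_high})
    return pd.DataFrame(rows)


def interaction_scan(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    C: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    schemes: dict[str, tuple[str, ...]] | None = None,
    min_homozygotes: int = MIN_HOMOZYGOTES,
) -> pd.DataFrame:
    """Genotype × risk-factor interaction test for (gene, snp, rf) triples.

    Model: expression ~ SNP + RF + SNP×RF + adjustment covariates; the
    reported P is the interaction-term t-test, with Benjamini-Hochberg
    q-values across the tested pairs. SNPs whose minor-homozygote class
    falls under the merging rule enter with 2-level (merged) coding.
    """
    check_aligned(E.sample_ids, G.sample_ids)
    check_aligned(E.sample_ids, list(C.index))
    schemes = dict(DEFAULT_SCHEMES if schemes is None else schemes)
    rows = []
    for gene, snp, rf in pairs:
        y = E.column(gene)
        codes = G.column(snp)
        try:
            labels, k = group_genotypes(codes, min_homozygotes)
        except UntestableSNP:
            rows.append({"gene": gene, "snp": snp, "risk_factor": rf,
                         "beta_inter": np.nan, "t": np.nan, "p": np.nan,
                         "n": 0, "coding": "untestable"})
            continue
        g = labels.astype(float)  # 0/1/2 or merged 0/1, additive-in-groups
        covars = schemes.get(rf, ())
        sub = C[[rf, *covars]].astype(float)
        keep = (~sub.isna().any(axis=1).to_numpy()) & (labels >= 0) & ~np.isnan(y)
        x_rf = sub[rf].to_numpy()
        X = design_matrix(
            g[keep], x_rf[keep], g[keep] * x_rf[keep],
            *[sub[c].to_numpy()[keep] for c in covars],
        )
        if is_collinear(X):
            rows.append({"gene": gene, "snp": snp, "risk_factor": rf,
                         "beta_inter": np.nan, "t": np.nan, "p": np.nan,
                         "n": int(keep.sum()), "coding": "collinear"})
            continue
        beta, t, p = ols_scan(y[keep, None], X, coef_index=3)
        rows.append({"gene": gene, "snp": snp, "risk_factor": rf,
                     "beta_inter": float(beta[0]), "t": float(t[0]),
                     "p": float(p[0]), "n": int(keep.sum()),
                     "coding": "2-level" if k == 2 else "additive"})
    out = pd.DataFrame(rows, columns=["gene", "snp", "risk_factor",
                                      "beta_inter", "t", "p", "n", "coding"])
    tested = out["p"].notna()
    out["q_bh"] = np.nan
    if tested.any():
        out.loc[tested, "q_bh"] = multipletests(
            out.loc[tested, "p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def binomial_enrichment(
    observed: int, expected: float, n_genes: int, n_categories: int = 1
) -> float:
    """One-sided binomial category-enrichment P, Bonferroni-corrected.

    Tail P(X ≥ observed) for X ~ Binomial(n_genes, expected/n_genes),
    multiplied by the number of categories tested and capped at 1.
    """
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if not 0 <= observed <= n_genes:
        raise ValueError("observed must lie in [0, n_genes]")
    p0 = expected / n_genes
    tail = float(stats.binom.sf(observed - 1, n_genes, p0))
    return min(1.0, tail * n_categories)
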