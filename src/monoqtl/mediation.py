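"""Mediation-compatibility triangle and outcome attenuation analysis.

A GWAS locus is "compatible with mediation by expression" when three
covariate-adjusted associations hold simultaneously with coherent signs:
SNP→phenotype, SNP→expression, and expression→phenotype, i.e.
sign(SNP→expr) · sign(expr→pheno) = sign(SNP→pheno). This is a
compatibility screen, not a formal mediation effect-size estimate.

The attenuation analysis asks whether a risk factor's association with an
outcome (carotid plaque count) disappears once candidate mediator
expressions are adjusted for; the outcome is modelled by ordinary linear
regression on the count (t-values reported), with Poisson available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .annotate import proxy_search
from .containers import ExpressionMatrix, GenotypeMatrix, check_aligned
from .rfassoc import DEFAULT_SCHEMES

#: default per-leg significance thresholds (all configurable)
TRIANGLE_THRESHOLDS = {
    "snp_pheno": 0.05,
    "snp_expr": 3.9e-6,
    "expr_pheno": 0.05,
}


@dataclass
class TriangleResult:
    locus: str
    lead_snp: str
    tag_snp: str | None
    r2_tag: float
    gene: str | None
    p_snp_pheno: float = np.nan
    sign_snp_pheno: int = 0
    p_snp_expr: float = np.nan
    sign_snp_expr: int = 0
    p_expr_pheno: float = np.nan
    sign_expr_pheno: int = 0
    verdict: str = "untestable"


def _adjusted_fit(y: np.ndarray, x: np.ndarray, covars: list[np.ndarray]
                  ) -> tuple[float, int, float, float]:
    """(P, sign, beta, t) of x in the OLS fit y ~ x + covars."""
    X = sm.add_constant(np.column_stack([x] + covars)) if covars else \
        sm.add_constant(x)
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    res = sm.OLS(y[keep], X[keep]).fit()
    beta = res.params[1]
    return (float(res.pvalues[1]), int(np.sign(beta)), float(beta),
            float(res.tvalues[1]))


def triangle_test(
    G: GenotypeMatrix,
    E: ExpressionMatrix,
    C: pd.DataFrame,
    locus: str,
    lead_snp: str,
    phenotype: str,
    candidate_genes: list[str],
    thresholds: dict[str, float] | None = None,
    schemes: dict[str, tuple[str, ...]] | None = None,
    lead_codes: np.ndarray | None = None,
    lead_chrom: str | None = None,
    lead_pos: int | None = None,
) -> list[TriangleResult]:
    """Run the three-leg compatibility test for one GWAS locus.

    The lead SNP is tagged via :func:`~monoqtl.annotate.proxy_search`
    (r² ≥ 0.8); no tag, or an empty candidate-gene list, yields a single
    "untestable" result. Otherwise each candidate gene gets a verdict:
    "compatible" iff all three legs pass their thresholds with coherent
    signs, else "incompatible". Covariate adjustment follows the
    phenotype's scheme (as in the risk-factor scan).
    """
    check_aligned(E.sample_ids, G.sample_ids)
    check_aligned(E.sample_ids, list(C.index))
    thr = dict(TRIANGLE_THRESHOLDS if thresholds is None else thresholds)
    schemes = dict(DEFAULT_SCHEMES if schemes is None else schemes)
    covar_names = schemes.get(phenotype, ("age", "sex"))

    tag, r2 = proxy_search(G, lead_snp, lead_codes=lead_codes,
                           lead_chrom=lead_chrom, lead_pos=lead_pos)
    if tag is None or not candidate_genes:
        return [TriangleResult(locus, lead_snp, tag, r2, None)]

    g = G.column(tag)
    pheno = C[phenotype].to_numpy(dtype=float)
    covars = [C[c].to_numpy(dtype=float) for c in covar_names]
    p1, s1, _, _ = _adjusted_fit(pheno, g, covars)

    out = []
    for gene in candidate_genes:
        expr = E.column(gene)
        p2, s2, _, _ = _adjusted_fit(expr, g, covars)
        p3, s3, _, _ = _adjusted_fit(pheno, expr, covars)
        ok = (p1 < thr["snp_pheno"] and p2 < thr["snp_expr"]
              and p3 < thr["expr_pheno"] and s2 * s3 == s1 and s1 != 0)
        out.append(TriangleResult(
            locus, lead_snp, tag, r2, gene,
            p_snp_pheno=p1, sign_snp_pheno=s1,
            p_snp_expr=p2, sign_snp_expr=s2,
            p_expr_pheno=p3, sign_expr_pheno=s3,
            verdict="compatible" if ok else "incompatible",
        ))
    return out


@dataclass
class AttenuationReport:
    risk_factor: str
    mediators: list[str]
    dropped_mediators: list[str]
    model_a: pd.DataFrame  # term, beta, t, p — outcome ~ rf + covars
    model_b: pd.DataFrame  # outcome ~ rf + mediators + covars
    p_rf_a: float = np.nan
    p_rf_b: float = np.nan
    attenuated: bool = False
    warnings: list[str] = field(default_factory=list)


def _fit_table(y: np.ndarray, X_df: pd.DataFrame, poisson: bool) -> pd.DataFrame:
    X = sm.add_constant(X_df.to_numpy(dtype=float))
    keep = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if poisson:
        res = sm.GLM(y[keep], X[keep], family=sm.families.Poisson()).fit()
    else:
        res = sm.OLS(y[keep], X[keep]).fit()
    return pd.DataFrame({
        "term": ["intercept", *X_df.columns],
        "beta": res.params,
        "t": res.params / res.bse,
        "p": res.pvalues,
    }).reset_index(drop=True)


def attenuation_test(
    outcome: np.ndarray,
    rf: str,
    mediators: list[str],
    C: pd.DataFrame,
    E: ExpressionMatrix,
    covariates: tuple[str, ...] = ("age", "sex"),
    alpha: float = 0.05,
    poisson: bool = False,
) -> AttenuationReport:
    """Compare outcome ~ rf + covariates with and without the mediators.

    Verdict "attenuated" iff the risk factor is significant (P < alpha)
    without the mediators and no longer significant with them. Mediator
    columns that are collinear with terms already in the model are dropped
    with a warning. With ``mediators=[]`` the two models coincide and the
    verdict is never "attenuated".
    """
    check_aligned(E.sample_ids, list(C.index))
    outcome = np.asarray(outcome, dtype=float)
    if not poisson and (outcome < 0).any():
        raise ValueError("outcome counts must be non-negative")

    base = pd.DataFrame({rf: C[rf].to_numpy(dtype=float)},
                        index=C.index)
    for c in covariates:
        base[c] = C[c].to_numpy(dtype=float)
    model_a = _fit_table(outcome, base, poisson)

    warnings: list[str] = []
    dropped: list[str] = []
    full = base.copy()
    for gene in mediators:
        col = E.column(gene)
        trial = np.column_stack([np.ones(len(col)), full.to_numpy(), col])
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            dropped.append(gene)
            warnings.append(f"mediator {gene} collinear; dropped")
            continue
        full[gene] = col
    model_b = _fit_table(outcome, full, poisson)

    p_a = float(model_a.loc[model_a["term"] == rf, "p"].iloc[0])
    p_b = float(model_b.loc[model_b["term"] == rf, "p"].iloc[0])
    kept = [m for m in mediators if m not in dropped]
    return AttenuationReport(
        risk_factor=rf,
        mediators=kept,
        dropped_mediators=dropped,
        model_a=model_a,
        model_b=model_b,
        p_rf_a=p_a,
        p_rf_b=p_b,
        attenuated=bool(kept) and p_a < alpha and p_b >= alpha,
        warnings=warnings,
    )


def esnp_outcome_test(
    G: GenotypeMatrix,
    outcome: np.ndarray,
    C: pd.DataFrame,
    snps: list[str],
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Additive regression of the outcome on each eSNP, age/sex adjusted.

    Returns one row per SNP with t, P and Bonferroni-corrected P over the
    list length (the multiple-testing family is the tested eSNP set).
    """
    check_aligned(list(C.index), G.sample_ids)
    outcome = np.asarray(outcome, dtype=float)
    covars = [C[c].to_numpy(dtype=float) for c in covariates]
    rows = []
    for snp in snps:
        g = G.column(snp)
        p, _, beta, t = _adjusted_fit(
            outcome, np.where(np.isnan(g), np.nanmean(g), g), covars)
        rows.append({"snp": snp, "beta": beta, "t": t, "p": p,
                     "p_bonf": min(1.0, p * len(snps))})
    out = pd.DataFrame(rows, columns=["snp", "beta", "t", "p", "p_bonf"])
    return out
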