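"""Simulator checks: HWE, LD copula, cohort strata, planted-effect scaling,
detection emulation and plaque link recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import norm

from monoqtl import simdata
from monoqtl.simdata import (ConfigurationError, GeneticEffect,
                             RiskFactorEffect, SimConfig)


def test_hwe_frequencies_at_half():
    """At MAF 0.5 with no LD, genotype frequencies are (1/4, 1/2, 1/4)."""
    cfg = SimConfig(n_samples=100_000, n_snps=5, n_genes=2,
                    maf_range=(0.5, 0.5), ld_rho=0.0, seed=3)
    G = simdata.sim_genotypes(cfg)
    n = cfg.n_samples
    for j in range(G.n_snps):
        col = G.codes[:, j]
        for code, p in ((0.0, 0.25), (1.0, 0.5), (2.0, 0.25)):
            freq = (col == code).mean()
            assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_zero_rho_gives_independent_snps():
    cfg = SimConfig(n_samples=5000, n_snps=20, n_genes=2,
                    ld_block_size=10, ld_rho=0.0, seed=4)
    G = simdata.sim_genotypes(cfg)
    r2s = []
    for a in range(9):
        c = np.corrcoef(G.codes[:, a], G.codes[:, a + 1])[0, 1]
        r2s.append(c * c)
    assert np.mean(r2s) < 2 / cfg.n_samples * 5  # mean r2 ~ 1/n under independence


def test_block_ld_matches_copula_oracle():
    """Sample genotype r² in a 2-SNP block matches a Monte-Carlo oracle.

    The oracle draws 10⁶ latent bivariate-normal pairs at rho=0.95,
    thresholds both at the HWE cutpoints for the fixed MAF, and measures
    the genotype correlation directly — independent of the generator code.
    """
    maf = 0.3
    rho = 0.95
    orng = np.random.default_rng(99)
    u = orng.standard_normal(1_000_000)
    e1 = orng.standard_normal(1_000_000)
    e2 = orng.standard_normal(1_000_000)
    z1 = np.sqrt(rho) * u + np.sqrt(1 - rho) * e1
    z2 = np.sqrt(rho) * u + np.sqrt(1 - rho) * e2
    lo, hi = norm.ppf((1 - maf) ** 2), norm.ppf(1 - maf ** 2)
    g1 = np.where(z1 < lo, 0, np.where(z1 > hi, 2, 1))
    g2 = np.where(z2 < lo, 0, np.where(z2 > hi, 2, 1))
    oracle_r2 = np.corrcoef(g1, g2)[0, 1] ** 2

    cfg = SimConfig(n_samples=5000, n_snps=2, n_genes=2, ld_block_size=2,
                    ld_rho=rho, maf_range=(maf, maf), seed=11,
                    chrom_lengths={"1": 1_000_000})
    G = simdata.sim_genotypes(cfg)
    sample_r2 = np.corrcoef(G.codes[:, 0], G.codes[:, 1])[0, 1] ** 2
    assert sample_r2 == pytest.approx(oracle_r2, abs=0.05)


def test_determinism_bit_identical():
    cfg = dict(n_samples=200, n_snps=50, n_genes=10, seed=42)
    a = simdata.sim_genotypes(SimConfig(**cfg))
    b = simdata.sim_genotypes(SimConfig(**cfg))
    assert np.array_equal(a.codes, b.codes)
    Ca = simdata.sim_risk_factors(SimConfig(**cfg))
    Cb = simdata.sim_risk_factors(SimConfig(**cfg))
    pd.testing.assert_frame_equal(Ca, Cb)


def test_invalid_maf_range_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        SimConfig(maf_range=(0.3, 0.6))


def test_risk_factor_strata_match_cohort_tables():
    """Male BMI 27.6 (3.9); female smoking prevalence 15.5%."""
    cfg = SimConfig(n_samples=100_000, n_snps=1, n_genes=1, seed=5)
    C = simdata.sim_risk_factors(cfg)
    men = C[C["sex"] == 0]
    women = C[C["sex"] == 1]
    n_m = len(men)
    assert men["bmi"].mean() == pytest.approx(27.6, abs=3 * 3.9 / np.sqrt(n_m))
    assert men["bmi"].std() == pytest.approx(3.9, rel=0.05)
    p = 0.155
    assert women["smoking"].mean() == pytest.approx(
        p, abs=3 * np.sqrt(p * (1 - p) / len(women)))
    # sqrt-CRP Gaussian emulation
    assert women["sqrt_crp"].mean() == pytest.approx(1.545, abs=0.03)
    assert np.allclose(C["sqrt_crp"] ** 2, C["crp"])


def test_planted_r2_realized(planted_cohort):
    """A cis effect requested at R²=0.25 lands within ±0.04 in sample."""
    G, E = planted_cohort["G"], planted_cohort["E"]
    rec = [r for r in planted_cohort["ledger"].genetic if r["kind"] == "cis"][0]
    g = G.column(rec["snp"])
    y = E.column(rec["gene"])
    r2 = np.corrcoef(g, y)[0, 1] ** 2
    assert r2 == pytest.approx(0.25, abs=0.04)


def test_noise_free_effect_is_collinear():
    cfg = SimConfig(n_samples=100, n_snps=10, n_genes=3, noise_sd=0.0,
                    ld_rho=0.0, seed=8, chrom_lengths={"1": 2_000_000})
    snp_meta, gene_meta = simdata.layout_maps(cfg)
    row = gene_meta.iloc[0]
    cfg.cis_effects = [GeneticEffect(row["symbol"],
                                     simdata.pick_cis_snp(snp_meta, row),
                                     beta=1.0)]
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    E, _ = simdata.sim_expression(G, C, cfg)
    g = G.column(cfg.cis_effects[0].snp)
    y = E.column(row["symbol"])
    assert np.corrcoef(g, y)[0, 1] ** 2 == pytest.approx(1.0, abs=1e-12)


def test_cis_trans_placement_validated():
    cfg = SimConfig(n_samples=50, n_snps=100, n_genes=10, seed=1)
    snp_meta, gene_meta = simdata.layout_maps(cfg)
    row = gene_meta.iloc[0]
    trans_snp = simdata.pick_trans_snp(snp_meta, row)
    cfg.cis_effects = [GeneticEffect(row["symbol"], trans_snp, beta=1.0)]
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    with pytest.raises(ConfigurationError):
        simdata.sim_expression(G, C, cfg)


def test_detection_design_fraction():
    """With 20% genes undetected, the filter keeps ~80% (binomial oracle)."""
    from monoqtl.qc_norm import detection_filter

    cfg = SimConfig(n_samples=200, n_snps=1, n_genes=1000, seed=6)
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    E, _ = simdata.sim_expression(G, C, cfg)
    D = simdata.sim_detection_pvalues(E, 0.2, seed=6)
    kept = detection_filter(D)
    sd = np.sqrt(1000 * 0.2 * 0.8)
    assert abs(kept.sum() - 800) <= 3 * sd
    # filter outcome tracks the design mask almost everywhere
    assert (kept == ~D.undetected).mean() > 0.99
    # boundary fractions
    assert detection_filter(simdata.sim_detection_pvalues(E, 0.0, seed=1)).all()
    assert not detection_filter(simdata.sim_detection_pvalues(E, 1.0, seed=1)).any()


def test_plaque_smoking_link_recovered():
    """Poisson GLM recovers the planted smoking coefficient within 3 SE."""
    cfg = SimConfig(n_samples=100_000, n_snps=1, n_genes=1, seed=9)
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    E, _ = simdata.sim_expression(G, C, cfg)
    truth = 0.5
    smoke = C["smoking"].to_numpy()
    smoke_std = (smoke - smoke.mean()) / smoke.std()
    counts = simdata.sim_plaques(C, E, {"intercept": 0.0, "smoking": truth},
                                 seed=9)
    X = sm.add_constant(smoke_std)
    res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    assert abs(res.params[1] - truth) < 3 * res.bse[1]


def test_null_plaques_independent_of_smoking():
    cfg = SimConfig(n_samples=5000, n_snps=1, n_genes=1, seed=10)
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    E, _ = simdata.sim_expression(G, C, cfg)
    counts = simdata.sim_plaques(C, E, {"intercept": 0.0}, seed=10)
    X = sm.add_constant(C["smoking"].to_numpy())
    res = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    assert res.pvalues[1] > 0.001
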