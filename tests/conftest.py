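import numpy as np
import pandas as pd
import pytest

from monoqtl import simdata
from monoqtl.simdata import GeneticEffect, RiskFactorEffect, SimConfig


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one cis, one trans and one smoking effect.

    Used across modules for recovery-style checks; the planted genes are
    distinct so each effect owns its variance fraction.
    """
    cfg = SimConfig(n_samples=400, n_snps=600, n_genes=60, seed=7,
                    maf_range=(0.15, 0.5), ld_rho=0.4)
    snp_meta, gene_meta = simdata.layout_maps(cfg)
    cis_gene = gene_meta.iloc[5]
    trans_gene = gene_meta.iloc[20]
    cfg.cis_effects = [GeneticEffect(
        cis_gene["symbol"], simdata.pick_cis_snp(snp_meta, cis_gene), r2=0.25)]
    cfg.trans_effects = [GeneticEffect(
        trans_gene["symbol"], simdata.pick_trans_snp(snp_meta, trans_gene),
        r2=0.20)]
    cfg.rf_effects = [RiskFactorEffect(gene_meta.iloc[40]["symbol"],
                                       "smoking", 1.0)]
    G = simdata.sim_genotypes(cfg)
    C = simdata.sim_risk_factors(cfg)
    E, ledger = simdata.sim_expression(G, C, cfg)
    return {"config": cfg, "G": G, "C": C, "E": E, "ledger": ledger}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_expression():
    """3-sample, 4-gene expression matrix with trivial metadata."""
    from monoqtl.containers import ExpressionMatrix

    meta = pd.DataFrame({
        "symbol": [f"G{i}" for i in range(4)],
        "chrom": ["1"] * 4,
        "start": [100, 200, 300, 400],
        "end": [150, 250, 350, 450],
    })
    values = np.arange(12, dtype=float).reshape(3, 4)
    return ExpressionMatrix(values, meta, ["s1", "s2", "s3"])
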