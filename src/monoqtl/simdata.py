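"""Synthetic-cohort simulator.

Generates genotype, expression, covariate, detection and plaque-count data
with the statistical structure the downstream analysis assumes:

* HWE genotypes at per-SNP minor allele frequencies, with within-block LD
  induced by a latent equicorrelated Gaussian copula thresholded at the HWE
  quantiles;
* cohort risk factors drawn per sex to match the study population the
  pipeline was designed around (n≈1,490; e.g. male BMI 27.6 (3.9) kg/m²,
  female HDL 69.2 (17.8) mg/dL, smoking prevalence 16.8%/15.5%, CRP such
  that √CRP is Gaussian);
* expression built additively from planted cis/trans genotype effects,
  risk-factor effects, optional genotype×risk-factor interactions, probe
  artifacts and Gaussian noise;
* array-style detection P-values and a Poisson plaque count with a
  configurable smoking/expression link.

Every planted effect is recorded in a :class:`GroundTruthLedger` so that
parameter-recovery tests can check the analysis end to end. All draws are
deterministic given ``SimConfig.seed``: each sub-generator derives its own
stream from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import ExpressionMatrix, GenotypeMatrix

CIS_WINDOW = 1_000_000


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneticEffect:
    """Planted additive genotype effect on one gene.

    Either ``beta`` (per minor allele, on the expression scale) or
    ``r2`` (expected fraction of expression variance relative to the
    non-genetic background) must be given; ``r2`` takes precedence.
    """

    gene: str
    snp: str
    beta: float | None = None
    r2: float | None = None


@dataclass
class RiskFactorEffect:
    gene: str
    risk_factor: str
    beta: float


@dataclass
class InteractionEffect:
    gene: str
    snp: str
    risk_factor: str
    beta: float


@dataclass
class ProbeArtifact:
    """Multiplicative probe-binding attenuation per alternate allele."""

    gene: str
    snp: str
    attenuation: float


#: default chromosome lengths (bp) — a compact genome with an X
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 200_000_000,
    "2": 180_000_000,
    "3": 160_000_000,
    "X": 150_000_000,
}

# Cohort composition: per-sex means (SD) of the emulated study population.
N_MEN, N_WOMEN = 760, 730
SEX_STRATA = {
    # sex coded female=1, male=0 (so "associated with female sex" is positive)
    "male": {
        "age": (56.4, 10.6),
        "bmi": (27.6, 3.9),
        "hdl": (54.4, 14.9),
        "ldl": (133.7, 36.1),
        "tg": (143.2, 97.5),
        "sbp": (135.8, 16.7),
        "dbp": (85.2, 9.6),
        "sqrt_crp": (1.509, 0.818),
        "glucose": (97.8, 18.5),
        "smoking_rate": 0.168,
    },
    "female": {
        "age": (53.9, 11.2),
        "bmi": (26.2, 5.1),
        "hdl": (69.2, 17.8),
        "ldl": (133.0, 36.8),
        "tg": (114.4, 56.8),
        "sbp": (128.5, 18.2),
        "dbp": (81.2, 9.5),
        "sqrt_crp": (1.545, 0.743),
        "glucose": (91.8, 15.4),
        "smoking_rate": 0.155,
    },
}


@dataclass
class SimConfig:
    n_samples: int = 1490
    n_snps: int = 1000
    n_genes: int = 100
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.7
    cis_effects: Sequence[GeneticEffect] = field(default_factory=list)
    trans_effects: Sequence[GeneticEffect] = field(default_factory=list)
    rf_effects: Sequence[RiskFactorEffect] = field(default_factory=list)
    interaction_effects: Sequence[InteractionEffect] = field(default_factory=list)
    probe_artifacts: Sequence[ProbeArtifact] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline: float = 8.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi < 0.5 + 1e-12):
            raise ConfigurationError(
                f"maf_range {self.maf_range} must lie within (0.01, 0.5]"
            )
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class GroundTruthLedger:
    """Record of every planted effect, for parameter-recovery tests."""

    genetic: list[dict] = field(default_factory=list)
    risk_factor: list[dict] = field(default_factory=list)
    interaction: list[dict] = field(default_factory=list)
    probe_artifact: list[dict] = field(default_factory=list)
    plaque_link: dict = field(default_factory=dict)

    def genes_with_genetic_effect(self) -> set[str]:
        return {rec["gene"] for rec in self.genetic}

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# deterministic streams and layout
# ---------------------------------------------------------------------------

_STREAMS = {
    "genotypes": 0,
    "risk_factors": 1,
    "expression": 2,
    "detection": 3,
    "plaques": 4,
    "missing": 5,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Derive a named, independent random stream from the master seed."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


def layout_maps(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic SNP and gene placement along the simulated genome.

    SNPs and genes are spread evenly over the concatenated chromosomes, so
    the cis/trans geometry of a configuration is reproducible without any
    random draw.
    """
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    total = bounds[-1]

    def place(n: int, prefix: str) -> pd.DataFrame:
        pos_linear = (np.arange(n) + 0.5) * total / n
        chrom_idx = np.searchsorted(bounds, pos_linear, side="right") - 1
        pos = (pos_linear - bounds[chrom_idx]).astype(int) + 1
        return pd.DataFrame(
            {
                "name": [f"{prefix}{i + 1}" for i in range(n)],
                "chrom": [chroms[i] for i in chrom_idx],
                "pos": pos,
            }
        )

    snps = place(config.n_snps, "rs").rename(columns={"name": "snp"})
    genes = place(config.n_genes, "GENE").rename(columns={"name": "symbol"})
    # genes get a 20 kb interval and a 50 bp probe at their 3' end
    genes["start"] = genes.pop("pos")
    genes["end"] = genes["start"] + 20_000
    genes["probe_start"] = genes["end"] - 50
    genes["probe_end"] = genes["end"]
    return snps, genes[
        ["symbol", "chrom", "start", "end", "probe_start", "probe_end"]
    ]


def pick_cis_snp(snp_meta: pd.DataFrame, gene_row: pd.Series,
                 window: int = CIS_WINDOW) -> str:
    """Id of a SNP within ``window`` of the gene (for planting cis effects)."""
    same = snp_meta[snp_meta["chrom"] == gene_row["chrom"]]
    near = same[(same["pos"] >= gene_row["start"] - window)
                & (same["pos"] <= gene_row["end"] + window)]
    if near.empty:
        raise ConfigurationError(f"no SNP within {window} bp of {gene_row['symbol']}")
    return str(near.iloc[0]["snp"])


def pick_trans_snp(snp_meta: pd.DataFrame, gene_row: pd.Series) -> str:
    other = snp_meta[snp_meta["chrom"] != gene_row["chrom"]]
    if other.empty:
        raise ConfigurationError("no SNP on another chromosome available")
    return str(other.iloc[0]["snp"])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def hwe_thresholds(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent-Gaussian cutpoints reproducing HWE genotype frequencies.

    With minor allele frequency q, genotype probabilities are
    ((1-q)², 2q(1-q), q²); a standard-normal draw below the first cutpoint
    codes 0, above the second codes 2 (minor-allele homozygote).
    """
    p = 1.0 - maf
    lo = norm.ppf(p ** 2)
    hi = norm.ppf(1.0 - maf ** 2)
    return lo, hi


def sim_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw HWE genotypes with block LD from the latent Gaussian copula."""
    rng = stream_rng(config.seed, "genotypes")
    snp_meta, _ = layout_maps(config)
    n, m = config.n_samples, config.n_snps
    if n < 2 or m < 1:
        raise ConfigurationError("need n_samples >= 2 and n_snps >= 1")

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    snp_meta = snp_meta.assign(maf=maf)

    # latent equicorrelated Gaussian per LD block; blocks never span chroms
    z = rng.standard_normal((n, m))
    if config.ld_rho > 0 and config.ld_block_size > 1:
        block_of = _block_ids(snp_meta, config.ld_block_size)
        n_blocks = block_of.max() + 1
        shared = rng.standard_normal((n, n_blocks))
        rho = config.ld_rho
        z = np.sqrt(rho) * shared[:, block_of] + np.sqrt(1.0 - rho) * z

    lo, hi = hwe_thresholds(maf)
    codes = np.where(z < lo, 0.0, np.where(z > hi, 2.0, 1.0))

    if config.missing_rate > 0:
        miss = stream_rng(config.seed, "missing").random((n, m)) < config.missing_rate
        codes = np.where(miss, np.nan, codes)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(codes, snp_meta, sample_ids)


def _block_ids(snp_meta: pd.DataFrame, block_size: int) -> np.ndarray:
    """Consecutive-SNP block labels, restarting at chromosome boundaries."""
    block = np.zeros(len(snp_meta), dtype=int)
    current, within, prev_chrom = -1, block_size, None
    for j, chrom in enumerate(snp_meta["chrom"]):
        if chrom != prev_chrom or within >= block_size:
            current += 1
            within = 0
            prev_chrom = chrom
        block[j] = current
        within += 1
    return block


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def sim_risk_factors(config: SimConfig) -> pd.DataFrame:
    """Per-sample risk factors drawn per sex from the cohort strata.

    Returns a DataFrame indexed by sample id with columns age, sex
    (female=1), bmi, hdl, ldl, tg, sbp, dbp, smoking (0/1), crp, sqrt_crp,
    glucose. CRP is generated on the square-root scale (truncated at zero)
    so that sqrt(CRP) is Gaussian to the stratum mean/SD.
    """
    rng = stream_rng(config.seed, "risk_factors")
    n = config.n_samples
    p_male = N_MEN / (N_MEN + N_WOMEN)
    male = rng.random(n) < p_male
    out = {"sex": (~male).astype(float)}  # female=1

    for col in ("age", "bmi", "hdl", "ldl", "tg", "sbp", "dbp", "sqrt_crp", "glucose"):
        mu_m, sd_m = SEX_STRATA["male"][col]
        mu_f, sd_f = SEX_STRATA["female"][col]
        draw = rng.standard_normal(n)
        out[col] = np.where(male, mu_m + sd_m * draw, mu_f + sd_f * draw)

    out["sqrt_crp"] = np.maximum(out["sqrt_crp"], 0.0)
    out["crp"] = out["sqrt_crp"] ** 2
    rate = np.where(male, SEX_STRATA["male"]["smoking_rate"],
                    SEX_STRATA["female"]["smoking_rate"])
    out["smoking"] = (rng.random(n) < rate).astype(float)

    df = pd.DataFrame(out, index=[f"S{i + 1:05d}" for i in range(n)])
    df.index.name = "sample"
    cols = ["age", "sex", "bmi", "hdl", "ldl", "tg", "sbp", "dbp",
            "smoking", "crp", "sqrt_crp", "glucose"]
    return df[cols]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _impute_mean(g: np.ndarray) -> np.ndarray:
    if np.isnan(g).any():
        g = np.where(np.isnan(g), np.nanmean(g), g)
    return g


def sim_expression(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimConfig,
) -> tuple[ExpressionMatrix, GroundTruthLedger]:
    """Build expression additively from the planted effects plus noise.

    expression = baseline + Σ genotype terms + Σ risk-factor terms
               + Σ interaction terms + N(0, noise_sd²),
    with probe artifacts applied multiplicatively afterwards. Genetic
    effects declared by expected R² get their beta from
    beta² = R²·Var(rest) / ((1−R²)·Var(genotype)), so the realized variance
    fraction matches the request in expectation.
    """
    rng = stream_rng(config.seed, "expression")
    _, gene_meta = layout_maps(config)
    n = genotypes.n_samples
    if list(covariates.index) != list(genotypes.sample_ids):
        raise ValueError("covariate rows not aligned with genotype samples")

    values = config.baseline + config.noise_sd * rng.standard_normal(
        (n, config.n_genes)
    )
    gidx = {s: i for i, s in enumerate(gene_meta["symbol"])}
    ledger = GroundTruthLedger()

    for eff in config.rf_effects:
        if eff.risk_factor not in covariates.columns:
            raise ConfigurationError(f"unknown risk factor {eff.risk_factor!r}")
        x = covariates[eff.risk_factor].to_numpy(dtype=float)
        values[:, _gene_col(gidx, eff.gene)] += eff.beta * (x - x.mean())
        ledger.risk_factor.append(
            {"gene": eff.gene, "risk_factor": eff.risk_factor, "beta": eff.beta}
        )

    for eff in config.interaction_effects:
        g = _impute_mean(genotypes.column(eff.snp))
        x = covariates[eff.risk_factor].to_numpy(dtype=float)
        term = (g - g.mean()) * (x - x.mean())
        values[:, _gene_col(gidx, eff.gene)] += eff.beta * term
        ledger.interaction.append(
            {"gene": eff.gene, "snp": eff.snp,
             "risk_factor": eff.risk_factor, "beta": eff.beta}
        )

    for kind, effects in (("cis", config.cis_effects), ("trans", config.trans_effects)):
        for eff in effects:
            j = _gene_col(gidx, eff.gene)
            _check_cis_trans(kind, genotypes.snp_meta, gene_meta, eff)
            g = _impute_mean(genotypes.column(eff.snp))
            gc = g - g.mean()
            var_g = gc.var()
            if var_g == 0:
                raise ConfigurationError(f"SNP {eff.snp} is monomorphic")
            if eff.r2 is not None:
                if not (0 <= eff.r2 < 1):
                    raise ConfigurationError(
                        f"requested variance fraction {eff.r2} outside [0, 1)"
                    )
                var_rest = values[:, j].var()
                beta = float(np.sqrt(eff.r2 * var_rest / ((1 - eff.r2) * var_g)))
            elif eff.beta is not None:
                beta = float(eff.beta)
            else:
                raise ConfigurationError(f"effect on {eff.gene} needs beta or r2")
            values[:, j] += beta * gc
            ledger.genetic.append(
                {"gene": eff.gene, "snp": eff.snp, "kind": kind,
                 "beta": beta, "expected_r2": eff.r2}
            )

    for art in config.probe_artifacts:
        g = _impute_mean(genotypes.column(art.snp))
        j = _gene_col(gidx, art.gene)
        values[:, j] *= (1.0 - art.attenuation) ** g
        ledger.probe_artifact.append(
            {"gene": art.gene, "snp": art.snp, "attenuation": art.attenuation}
        )

    expr = ExpressionMatrix(values, gene_meta, list(genotypes.sample_ids))
    return expr, ledger


def _gene_col(gidx: dict[str, int], gene: str) -> int:
    if gene not in gidx:
        raise ConfigurationError(f"planted gene {gene!r} does not exist")
    return gidx[gene]


def _check_cis_trans(
    kind: str, snp_meta: pd.DataFrame, gene_meta: pd.DataFrame, eff: GeneticEffect
) -> None:
    srow = snp_meta[snp_meta["snp"] == eff.snp]
    grow = gene_meta[gene_meta["symbol"] == eff.gene]
    if srow.empty:
        raise ConfigurationError(f"planted SNP {eff.snp!r} does not exist")
    if grow.empty:
        raise ConfigurationError(f"planted gene {eff.gene!r} does not exist")
    s, g = srow.iloc[0], grow.iloc[0]
    is_cis = (s["chrom"] == g["chrom"]
              and g["start"] - CIS_WINDOW <= s["pos"] <= g["end"] + CIS_WINDOW)
    if kind == "cis" and not is_cis:
        raise ConfigurationError(f"{eff.snp} is not within 1 Mb of {eff.gene}")
    if kind == "trans" and is_cis:
        raise ConfigurationError(f"{eff.snp} is within 1 Mb of {eff.gene}")


# ---------------------------------------------------------------------------
# detection P-values and plaques
# ---------------------------------------------------------------------------

@dataclass
class DetectionMatrix:
    """Per-sample, per-gene array detection P-values plus the design mask."""

    pvalues: np.ndarray  # samples x genes
    undetected: np.ndarray  # bool per gene (generator design)
    sample_ids: list[str]
    symbols: list[str]


def sim_detection_pvalues(
    expr: ExpressionMatrix, frac_undetected_genes: float, seed: int = 0
) -> DetectionMatrix:
    """Emulate negative-control detection P-values.

    Detected genes get P ~ U(0, 0.01) in every sample; genes drawn as
    undetected get P ~ U(0.05, 1) in ~99% of samples (U(0, 0.05) in the
    rest), so the detection filter keeps essentially none of them.
    """
    if not 0.0 <= frac_undetected_genes <= 1.0:
        raise ValueError("frac_undetected_genes must be in [0, 1]")
    rng = stream_rng(seed, "detection")
    n, m = expr.n_samples, expr.n_genes
    undetected = rng.random(m) < frac_undetected_genes
    p = rng.uniform(0.0, 0.01, size=(n, m))
    if undetected.any():
        k = int(undetected.sum())
        high = rng.uniform(0.05, 1.0, size=(n, k))
        low = rng.uniform(0.0, 0.05, size=(n, k))
        pick_low = rng.random((n, k)) < 0.01
        p[:, undetected] = np.where(pick_low, low, high)
    return DetectionMatrix(p, undetected, list(expr.sample_ids), expr.symbols)


def sim_plaques(
    covariates: pd.DataFrame,
    expr: ExpressionMatrix,
    link: Mapping[str, float],
    seed: int = 0,
    ledger: GroundTruthLedger | None = None,
) -> np.ndarray:
    """Poisson carotid-plaque counts with a log-linear smoking/expression link.

    ``link`` maps term names to coefficients: "intercept", "smoking", and/or
    gene symbols (expression standardized before entering the linear
    predictor). A fully mediated design sets the direct smoking coefficient
    to 0 and routes the effect through gene terms.
    """
    rng = stream_rng(seed, "plaques")
    eta = np.full(len(covariates), float(link.get("intercept", 0.0)))
    for name, coef in link.items():
        if name == "intercept":
            continue
        if name in covariates.columns:
            x = covariates[name].to_numpy(dtype=float)
        else:
            x = expr.column(name)
        sd = x.std()
        eta += coef * ((x - x.mean()) / sd if sd > 0 else 0.0)
    counts = rng.poisson(np.exp(eta)).astype(float)
    if ledger is not None:
        ledger.plaque_link = dict(link)
    return counts


def plaque_scenario(
    seed: int,
    mediated: bool = True,
    n_samples: int = 1490,
    rf_beta: float = 2.0,
    link: float = 0.12,
    intercept: float = 0.7,
) -> tuple[ExpressionMatrix, pd.DataFrame, np.ndarray, GroundTruthLedger]:
    """Canonical smoking → expression → plaque study condition.

    ``mediated=True`` routes the whole smoking effect through one gene
    (direct smoking coefficient 0); ``mediated=False`` plants a direct
    smoking effect with no mediator path. The defaults give a mean of
    roughly two plaques per subject and a smoking effect detectable with
    near-full power at the default cohort size, while keeping the
    log-linear outcome mild enough that a linear attenuation model is
    well specified. Returns (expression, covariates, counts, ledger);
    the mediator gene is "GENE1".
    """
    cfg = SimConfig(n_samples=n_samples, n_snps=4, n_genes=3, seed=seed,
                    chrom_lengths={"1": 1_000_000})
    G = sim_genotypes(cfg)
    C = sim_risk_factors(cfg)
    cfg.rf_effects = [RiskFactorEffect("GENE1", "smoking", rf_beta)]
    E, ledger = sim_expression(G, C, cfg)
    link_map = ({"intercept": intercept, "GENE1": link} if mediated
                else {"intercept": intercept, "smoking": link})
    counts = sim_plaques(C, E, link_map, seed=seed, ledger=ledger)
    return E, C, counts, ledger
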