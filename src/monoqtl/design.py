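"""Study-design calculators: Bonferroni thresholds, minimum detectable R²,
analytic power for a single-SNP expression association.

Power uses the noncentral-F tail with noncentrality λ = n·R²/(1−R²); at the
designed scale (n = 1,490, α = 5.78e-12, R² = 0.04, df1 = 1) this gives
0.824, consistent with the ≥80% design claim.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bonferroni_threshold(alpha: float, n_tests_a: int, n_tests_b: int = 1
                         ) -> float:
    """Per-test threshold alpha / (n_tests_a · n_tests_b), 3 significant digits."""
    if n_tests_a <= 0 or n_tests_b <= 0:
        raise ValueError("test counts must be positive")
    raw = alpha / (n_tests_a * n_tests_b)
    return float(f"{raw:.3g}")


def min_detectable_r2(alpha: float, n: int, df1: int = 1) -> float:
    """Smallest variance fraction reaching significance at level alpha.

    Inverts the central F distribution at (df1, n−df1−1):
    R² = df1·F* / (df1·F* + n − df1 − 1).
    """
    if n <= df1 + 1:
        raise ValueError("need n > df1 + 1")
    df2 = n - df1 - 1
    f_star = stats.f.isf(alpha, df1, df2)
    return float(df1 * f_star / (df1 * f_star + df2))


def power_single_snp(n: int, alpha: float, r2: float, df1: int = 1) -> float:
    """Analytic power to detect a SNP explaining a fraction r2 of variance.

    P(F'(df1, n−df1−1, λ) > F*) with λ = n·r2/(1−r2) and F* the central
    critical value at level alpha. r2 = 0 returns alpha exactly.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError("r2 must be in [0, 1)")
    df2 = n - df1 - 1
    if df2 <= 0:
        raise ValueError("need n > df1 + 1")
    f_star = stats.f.isf(alpha, df1, df2)
    if r2 == 0.0:
        return float(alpha)
    lam = n * r2 / (1.0 - r2)
    return float(stats.ncf.sf(f_star, df1, df2, lam))


def simulate_power(
    n: int, alpha: float, r2: float, n_reps: int = 20_000,
    seed: int = 0, chunk: int = 2_000,
) -> float:
    """Monte-Carlo power of the 1-df additive test, as an analytic cross-check.

    Simulates y = β·g + ε with a biallelic HWE genotype (MAF 0.3) and β set
    so the population variance fraction is r2, then counts replicates whose
    regression F exceeds the central critical value.
    """
    rng = np.random.default_rng(seed)
    df2 = n - 2
    f_star = stats.f.isf(alpha, 1, df2)
    maf = 0.3
    var_g = 2 * maf * (1 - maf)
    beta = np.sqrt(r2 / ((1 - r2) * var_g))
    hits = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        g = rng.binomial(2, maf, size=(n, b)).astype(float)
        y = beta * g + rng.standard_normal((n, b))
        gc = g - g.mean(axis=0)
        yc = y - y.mean(axis=0)
        r = (gc * yc).sum(axis=0) / np.sqrt(
            (gc ** 2).sum(axis=0) * (yc ** 2).sum(axis=0)
        )
        f = df2 * r ** 2 / (1.0 - r ** 2)
        hits += int((f > f_star).sum())
        done += b
    return hits / n_reps
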