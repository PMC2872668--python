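"""eQTL scan checks: genotype grouping, ANOVA/KW/Fisher primitives against
independent oracles, X-chromosome combination, and genome-scan behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from monoqtl import eqtl, simdata
from monoqtl.containers import ExpressionMatrix, GenotypeMatrix
from monoqtl.simdata import GeneticEffect, SimConfig


def _codes(n0, n1, n2):
    return np.array([0.0] * n0 + [1.0] * n1 + [2.0] * n2)


class TestGrouping:
    def test_thirty_homozygotes_keep_three_groups(self):
        labels, k = eqtl.group_genotypes(_codes(1000, 400, 30))
        assert k == 3

    def test_29_homozygotes_merge(self):
        labels, k = eqtl.group_genotypes(_codes(1000, 400, 29))
        assert k == 2
        sizes = np.bincount(labels[labels >= 0])
        assert sorted(sizes) == [429, 1000]

    def test_absent_homozygotes_two_groups(self):
        _, k = eqtl.group_genotypes(_codes(1000, 490, 0))
        assert k == 2

    def test_minor_allele_detected_when_codes_flipped(self):
        # here code 0 is the rare homozygote: it must merge into hets
        labels, k = eqtl.group_genotypes(_codes(10, 400, 1000))
        assert k == 2
        sizes = np.bincount(labels[labels >= 0])
        assert sorted(sizes) == [410, 1000]

    def test_single_group_untestable(self):
        with pytest.raises(eqtl.UntestableSNP):
            eqtl.group_genotypes(_codes(50, 0, 0))


class TestAnova:
    def test_hand_example(self):
        y = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
        g = np.repeat([0, 1, 2], 3)
        f, p, r2 = eqtl.anova_assoc(y, g)
        assert f == pytest.approx(3.0, rel=1e-12)
        assert r2 == pytest.approx(0.5, rel=1e-12)
        assert p == pytest.approx(0.125, rel=1e-12)

    def test_matches_scipy_oracle_on_random_fixtures(self, rng):
        for _ in range(100):
            k = rng.integers(2, 4)
            sizes = rng.integers(3, 12, size=k)
            y = [rng.normal(size=s) for s in sizes]
            g = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
            f, p, _ = eqtl.anova_assoc(np.concatenate(y), g)
            f_ref, p_ref = stats.f_oneway(*y)
            assert f == pytest.approx(f_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_two_groups_equal_squared_t(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=15), rng.normal(size=12)
            f, p, _ = eqtl.anova_assoc(np.concatenate([a, b]),
                                       np.repeat([0, 1], [15, 12]))
            t, p_t = stats.ttest_ind(a, b)
            assert f == pytest.approx(t * t, rel=1e-10)
            assert p == pytest.approx(p_t, rel=1e-10)

    def test_zero_variance(self):
        f, p, r2 = eqtl.anova_assoc(np.ones(10), np.repeat([0, 1], 5))
        assert (f, p, r2) == (0.0, 1.0, 0.0)

    def test_r2_affine_invariant(self, rng):
        y = rng.normal(size=30)
        g = rng.integers(0, 2, size=30)
        _, _, r2 = eqtl.anova_assoc(y, g)
        _, _, r2b = eqtl.anova_assoc(3.5 * y - 11.0, g)
        assert r2 == pytest.approx(r2b, rel=1e-12)


class TestKruskalWallis:
    def test_hand_example(self):
        p = eqtl.kw_confirm(np.array([1.0, 2.0, 3.0, 4.0]),
                            np.array([0, 0, 1, 1]))
        # H = 2.4 on 1 df
        assert p == pytest.approx(stats.chi2.sf(2.4, 1), rel=1e-10)
        assert p == pytest.approx(0.1213, abs=5e-5)

    def test_all_tied_is_one(self):
        assert eqtl.kw_confirm(np.ones(8), np.repeat([0, 1], 4)) == 1.0

    def test_matches_scipy_oracle_with_ties(self, rng):
        for _ in range(100):
            k = rng.integers(2, 4)
            sizes = rng.integers(4, 10, size=k)
            # integer values force ties
            groups = [rng.integers(0, 5, size=s).astype(float) for s in sizes]
            y = np.concatenate(groups)
            g = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
            if all(np.ptp(y) == 0 for y in [y]):
                continue
            p = eqtl.kw_confirm(y, g)
            _, p_ref = stats.kruskal(*groups)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_outlier_fixture_rejected_by_kw_only(self):
        """A single huge outlier drives ANOVA but not the rank test."""
        rng = np.random.default_rng(0)
        n = 600
        g = rng.integers(0, 2, size=n)
        y = rng.normal(size=n) * 0.01
        y[g == 1] += 0.001
        y[np.argmax(g == 1)] = 1e6  # one extreme carrier
        labels = g
        _, p_anova, _ = eqtl.anova_assoc(y, labels)
        p_kw = eqtl.kw_confirm(y, labels)
        assert p_anova < 1e-12 or p_kw > 1e-10  # KW guards the call
        assert p_kw > 1e-10


class TestFisherCombination:
    @pytest.mark.parametrize("p_pair, expected", [
        ((0.5, 0.5), 0.5966),       # e^{-X/2}(1 + X/2) at X = -4 ln 0.5
        ((1.0, 1.0), 1.0),
        ((1e-8, 1.0), 1.9421e-07),  # closed form
    ])
    def test_closed_form(self, p_pair, expected):
        x = -2.0 * np.sum(np.log(p_pair))
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert eqtl.fisher_combine(list(p_pair)) == pytest.approx(closed, rel=1e-10)
        assert eqtl.fisher_combine(list(p_pair)) == pytest.approx(expected, rel=1e-3)


class TestChrX:
    def test_combined_equals_fisher_of_per_sex(self, rng):
        n = 400
        sex = rng.integers(0, 2, size=n).astype(float)
        codes = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(size=n)
        res = eqtl.chrx_assoc(y, codes, sex, min_homozygotes=5)
        parts = []
        for val in (1.0, 0.0):
            mask = sex == val
            labels, _ = eqtl.group_genotypes(codes[mask], 5)
            _, p, _ = eqtl.anova_assoc(y[mask], labels)
            parts.append(p)
        assert res["combined"]
        assert res["p"] == pytest.approx(eqtl.fisher_combine(parts), rel=1e-12)

    def test_one_sex_untestable_falls_back(self, rng):
        n = 200
        sex = np.zeros(n)
        sex[:100] = 1.0
        codes = np.ones(n)
        codes[sex == 1] = np.repeat([0.0, 1.0, 2.0], [40, 30, 30])
        y = rng.normal(size=n)
        res = eqtl.chrx_assoc(y, codes, sex, min_homozygotes=5)
        assert not res["combined"]


class TestGenomeScan:
    def test_empty_genotypes_empty_output(self, planted_cohort):
        E = planted_cohort["E"]
        G_empty = GenotypeMatrix(
            np.empty((E.n_samples, 0)),
            pd.DataFrame(columns=["snp", "chrom", "pos"]),
            list(E.sample_ids))
        out = eqtl.genome_scan(E, G_empty)
        assert len(out) == 0

    def test_misaligned_samples_raise(self, planted_cohort):
        E, G = planted_cohort["E"], planted_cohort["G"]
        E_bad = ExpressionMatrix(E.values, E.gene_meta,
                                 list(reversed(E.sample_ids)))
        with pytest.raises(ValueError):
            eqtl.genome_scan(E_bad, G)

    def test_planted_effects_recovered_and_stored_p_reproducible(self, planted_cohort):
        E, G, C = planted_cohort["E"], planted_cohort["G"], planted_cohort["C"]
        n_tests = G.n_snps * E.n_genes
        thr = 0.05 / n_tests
        out = eqtl.genome_scan(E, G, sex=C["sex"].to_numpy(), study_wise=thr,
                               kw_threshold=thr * 20)
        sw = out[out["study_wise"] == 1]
        planted = {(r["snp"], r["gene"])
                   for r in planted_cohort["ledger"].genetic}
        found = set(zip(sw["snp"], sw["gene"]))
        assert planted <= found
        # each stored record's P recomputes from scratch
        for _, row in out.head(20).iterrows():
            codes = G.column(row["snp"])
            y = E.column(row["gene"])
            if row["combined_x"]:
                continue
            labels, k = eqtl.group_genotypes(codes)
            _, p, _ = eqtl.anova_assoc(y, labels)
            assert p == pytest.approx(row["p_anova"], rel=1e-12)

    def test_null_pvalues_calibrated(self):
        """Under the global null the P distribution is uniform."""
        cfg = SimConfig(n_samples=250, n_snps=120, n_genes=40, ld_rho=0.0,
                        seed=21, chrom_lengths={"1": 10_000_000, "2": 10_000_000})
        G = simdata.sim_genotypes(cfg)
        C = simdata.sim_risk_factors(cfg)
        E, _ = simdata.sim_expression(G, C, cfg)
        P = eqtl.scan_pvalue_matrix(E, G)
        p = P[~np.isnan(P)]
        for alpha in (1e-1, 1e-2):
            frac = (p < alpha).mean()
            sd = np.sqrt(alpha * (1 - alpha) / p.size)
            assert abs(frac - alpha) < 4 * sd
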