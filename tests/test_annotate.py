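"""Annotation checks: cis/trans boundaries, tier summaries vs an
independent tally, LD r², proxy search, probe flags, replication overlap."""

import numpy as np
import pandas as pd
import pytest

from monoqtl import annotate, simdata
from monoqtl.containers import GenotypeMatrix
from monoqtl.simdata import SimConfig


class TestCisTrans:
    @pytest.mark.parametrize("pos, expected", [
        (5_000_000 - 1_000_000, "cis"),      # inclusive boundary at 5' end
        (5_000_000 - 1_000_000 - 1, "trans"),
        (5_020_000 + 1_000_000, "cis"),      # inclusive boundary at 3' end
        (5_020_000 + 1_000_000 + 1, "trans"),
    ])
    def test_window_boundaries(self, pos, expected):
        assert annotate.classify_cis_trans("1", pos, "1", 5_000_000,
                                           5_020_000) == expected

    def test_other_chromosome_is_trans(self):
        assert annotate.classify_cis_trans("2", 5_000_000, "1", 5_000_000,
                                           5_020_000) == "trans"

    def test_labels_exhaustive_and_exclusive(self, rng):
        n = 200
        assoc = pd.DataFrame({
            "chrom": rng.choice(["1", "2"], n),
            "pos": rng.integers(1, 10**8, n),
            "gene_chrom": rng.choice(["1", "2"], n),
            "gene_start": rng.integers(1, 10**8, n),
        })
        assoc["gene_end"] = assoc["gene_start"] + 20_000
        out = annotate.add_cis_trans(assoc)
        assert set(out["cis_trans"]) <= {"cis", "trans"}
        for _, r in out.head(50).iterrows():
            assert r["cis_trans"] == annotate.classify_cis_trans(
                r["chrom"], r["pos"], r["gene_chrom"],
                r["gene_start"], r["gene_end"])


def _assoc_table(rng, n=300):
    genes = [f"G{i}" for i in range(20)]
    snps = [f"rs{i}" for i in range(80)]
    df = pd.DataFrame({
        "snp": rng.choice(snps, n),
        "gene": rng.choice(genes, n),
        "p_anova": 10.0 ** rng.uniform(-15, -4, n),
        "R2": rng.uniform(0.01, 0.6, n),
        "cis_trans": rng.choice(["cis", "trans"], n, p=[0.8, 0.2]),
    })
    return df.drop_duplicates(subset=["snp", "gene"])


class TestSummarize:
    def test_single_association(self):
        df = pd.DataFrame({"snp": ["rs1"], "gene": ["G1"],
                           "p_anova": [1e-13], "R2": [0.3],
                           "cis_trans": ["cis"]})
        out = annotate.summarize_eqtls(df, [1e-12])
        row = out.iloc[0]
        assert row["n_assoc"] == row["n_eqtls"] == row["n_esnps"] == 1
        assert row["esnps_per_eqtl_median"] == 1

    def test_counts_match_independent_tally(self, rng):
        df = _assoc_table(rng)
        tiers = [1e-5, 1e-8, 1e-12]
        out = annotate.summarize_eqtls(df, tiers)
        for tier, row in zip(tiers, out.itertuples()):
            sub = df[df["p_anova"] < tier]
            assert row.n_assoc == len(sub)
            assert row.n_eqtls == sub["gene"].nunique()
            assert row.n_esnps == sub["snp"].nunique()
            assert row.min_r2 == pytest.approx(sub["R2"].min())
            cis_g = sub.loc[sub.cis_trans == "cis", "gene"].nunique()
            trans_g = sub.loc[sub.cis_trans == "trans", "gene"].nunique()
            if trans_g:
                assert row.eqtl_cis_trans == pytest.approx(cis_g / trans_g)

    def test_monotone_under_tightening(self, rng):
        df = _assoc_table(rng)
        out = annotate.summarize_eqtls(df, [1e-4, 1e-6, 1e-8, 1e-10, 1e-14])
        for col in ("n_assoc", "n_eqtls", "n_esnps"):
            assert (np.diff(out[col]) <= 0).all()

    def test_planted_ratio(self):
        rows = []
        for i in range(10):
            rows.append({"snp": f"rs{i}", "gene": f"CG{i}", "p_anova": 1e-14,
                         "R2": 0.2, "cis_trans": "cis"})
        for i in range(2):
            rows.append({"snp": f"rt{i}", "gene": f"TG{i}", "p_anova": 1e-14,
                         "R2": 0.2, "cis_trans": "trans"})
        out = annotate.summarize_eqtls(pd.DataFrame(rows), [1e-12])
        assert out.iloc[0]["eqtl_cis_trans"] == pytest.approx(5.0)

    def test_empty_table(self):
        df = pd.DataFrame(columns=["snp", "gene", "p_anova", "R2", "cis_trans"])
        out = annotate.summarize_eqtls(df, [1e-12])
        assert out.iloc[0]["n_assoc"] == 0


class TestLD:
    def _matrix(self, cols):
        codes = np.array(cols, dtype=float).T
        m = codes.shape[1]
        meta = pd.DataFrame({"snp": [f"rs{j}" for j in range(m)],
                             "chrom": ["1"] * m,
                             "pos": np.arange(1, m + 1) * 1000})
        return GenotypeMatrix(codes, meta,
                              [f"s{i}" for i in range(codes.shape[0])])

    def test_identical_columns(self, rng):
        col = rng.integers(0, 3, 100).astype(float)
        G = self._matrix([col, col])
        assert annotate.ld_r2(G, "rs0", "rs1") == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        cfg = SimConfig(n_samples=10_000, n_snps=2, n_genes=1, ld_rho=0.0,
                        seed=2, chrom_lengths={"1": 10_000})
        G = simdata.sim_genotypes(cfg)
        assert annotate.ld_r2(G, "rs1", "rs2") < 0.01

    def test_zero_variance_is_missing(self, rng):
        G = self._matrix([np.ones(50), rng.integers(0, 3, 50).astype(float)])
        assert np.isnan(annotate.ld_r2(G, "rs0", "rs1"))

    def test_block_r2_matches_copula_scale(self):
        cfg = SimConfig(n_samples=5000, n_snps=2, n_genes=1, ld_block_size=2,
                        ld_rho=0.9, maf_range=(0.3, 0.3), seed=3,
                        chrom_lengths={"1": 10_000})
        G = simdata.sim_genotypes(cfg)
        direct = np.corrcoef(G.codes[:, 0], G.codes[:, 1])[0, 1] ** 2
        assert annotate.ld_r2(G, "rs1", "rs2") == pytest.approx(direct, rel=1e-12)


class TestProxySearch:
    def _panel(self, rng, extra_cols=()):
        lead = rng.integers(0, 3, 500).astype(float)
        cols = [lead] + [np.asarray(c, dtype=float) for c in extra_cols]
        codes = np.column_stack(cols)
        m = codes.shape[1]
        meta = pd.DataFrame({"snp": [f"rs{j}" for j in range(m)],
                             "chrom": ["1"] * m,
                             "pos": np.arange(1, m + 1) * 1000})
        return lead, GenotypeMatrix(codes, meta,
                                    [f"s{i}" for i in range(500)])

    def test_lead_on_panel(self, rng):
        _, G = self._panel(rng)
        tag, r2 = annotate.proxy_search(G, "rs0")
        assert tag == "rs0" and r2 == 1.0

    def test_best_of_two_proxies(self, rng):
        lead = rng.integers(0, 3, 2000).astype(float)
        flip_many = lead.copy()
        flip_few = lead.copy()
        idx = rng.permutation(2000)
        flip_many[idx[:300]] = rng.integers(0, 3, 300)
        flip_few[idx[300:400]] = rng.integers(0, 3, 100)
        codes = np.column_stack([flip_many, flip_few])
        meta = pd.DataFrame({"snp": ["rsA", "rsB"], "chrom": ["1", "1"],
                             "pos": [1000, 2000]})
        G = GenotypeMatrix(codes, meta, [f"s{i}" for i in range(2000)])
        tag, r2 = annotate.proxy_search(G, "rsLEAD", lead_codes=lead,
                                        lead_chrom="1", lead_pos=1500)
        assert tag == "rsB" and r2 > 0.8

    def test_weak_proxies_give_none(self, rng):
        lead = rng.integers(0, 3, 500).astype(float)
        weak = lead.copy()
        weak[rng.permutation(500)[:300]] = rng.integers(0, 3, 300)
        codes = weak[:, None]
        meta = pd.DataFrame({"snp": ["rsA"], "chrom": ["1"], "pos": [1000]})
        G = GenotypeMatrix(codes, meta, [f"s{i}" for i in range(500)])
        tag, r2 = annotate.proxy_search(G, "rsLEAD", lead_codes=lead,
                                        lead_chrom="1", lead_pos=1000)
        assert tag is None and np.isnan(r2)


class TestProbeFlags:
    def test_direct_proxy_and_unflagged(self):
        probes = pd.DataFrame({
            "symbol": ["Gdirect", "Gproxy", "Gclean"],
            "chrom": ["1", "1", "1"],
            "probe_start": [100, 500, 900],
            "probe_end": [150, 550, 950],
        })
        ref_snps = pd.DataFrame({
            "snp": ["rsIn1", "rsIn2", "rsFar"],
            "chrom": ["1", "1", "1"],
            "pos": [120, 520, 5000],
        })
        panel = {"rsIn1", "rsTag"}
        ld = lambda a, b: 1.0 if {a, b} == {"rsIn2", "rsTag"} else 0.2
        flags = annotate.flag_polymorphic_probes(probes, ref_snps, panel, ld)
        by_gene = flags.set_index("symbol")["flag"]
        assert by_gene["Gdirect"] == "direct"
        assert by_gene["Gproxy"] == "proxy"
        assert by_gene["Gclean"] == ""


class TestReplication:
    def _internal(self):
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(60)],
            "p_anova": [1e-8] * 40 + [1e-3] * 20,
            "cis_trans": ["cis"] * 60,
        })

    def test_fraction_arithmetic(self):
        external = pd.DataFrame({"gene": [f"G{i}" for i in range(60)],
                                 "tier": ["all"] * 60})
        out = annotate.replication_overlap(external, self._internal())
        row = out[out["tier"] == "all"].iloc[0]
        assert row["n"] == 60
        assert row["pct_replicated"] == pytest.approx(66.7, abs=0.05)

    def test_unmatched_genes_excluded(self):
        external = pd.DataFrame({"gene": ["G0", "ABSENT1", "ABSENT2"],
                                 "tier": ["t"] * 3})
        out = annotate.replication_overlap(external, self._internal())
        assert out[out["tier"] == "all"].iloc[0]["n"] == 1

    def test_identical_lists_full_replication(self):
        internal = self._internal().iloc[:40]
        external = pd.DataFrame({"gene": internal["gene"], "tier": "t"})
        out = annotate.replication_overlap(external, internal)
        assert out[out["tier"] == "all"].iloc[0]["pct_replicated"] == 100.0
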