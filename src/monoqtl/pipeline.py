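"""End-to-end pipeline driver: simulate → QC → scan → annotate → risk
factors → interaction → stability → mediation → design report.

Every stage writes TSV artifacts plus a JSON run manifest (inputs,
parameters, seed, version) sufficient to reproduce any output exactly.
The default configuration is a desk-scale demonstration cohort (300
samples × 200 genes × 3,000 SNPs) with a handful of planted effects.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd

from . import __version__, annotate, design, io, mediation, qc_norm, rfassoc, simdata, stability
from . import eqtl as eqtl_mod
from .simdata import (GeneticEffect, InteractionEffect, ProbeArtifact,
                      RiskFactorEffect, SimConfig)

DEFAULT_THRESHOLDS = {
    "study_wise": eqtl_mod.STUDY_WISE_P,
    "store_below": eqtl_mod.STORE_BELOW_P,
    "kw": eqtl_mod.KW_CONFIRM_P,
    "rf_study_wise": rfassoc.RF_STUDY_WISE_P,
    "screen": stability.SCREEN_P,
    "enter": stability.P_ENTER,
    "valid": stability.P_VALID,
    "freq_min": stability.FREQ_MIN,
    "cis_window": annotate.CIS_WINDOW,
    "min_homozygotes": eqtl_mod.MIN_HOMOZYGOTES,
}


def default_config(seed: int = 0) -> dict[str, Any]:
    """Demo-scale pipeline configuration with planted effects."""
    return {
        "seed": seed,
        "sim": {
            "n_samples": 300,
            "n_snps": 3000,
            "n_genes": 200,
            "ld_block_size": 10,
            "ld_rho": 0.7,
            "maf_range": [0.1, 0.5],
            "noise_sd": 1.0,
            "cis_effects": [
                {"gene_index": 10, "r2": 0.25},
                {"gene_index": 40, "r2": 0.15},
            ],
            "trans_effects": [{"gene_index": 70, "r2": 0.15}],
            "rf_effects": [
                {"gene_index": 10, "risk_factor": "smoking", "beta": 0.8},
                {"gene_index": 120, "risk_factor": "smoking", "beta": 0.9},
                {"gene_index": 150, "risk_factor": "bmi", "beta": 0.05},
            ],
            "frac_undetected": 0.1,
            "plaque_link": {"intercept": -0.3, "smoking": 0.0, "genes": {120: 0.4}},
        },
        "thresholds": {**DEFAULT_THRESHOLDS,
                       # demo scale: Bonferroni over the simulated test count
                       "study_wise": 0.05 / (3000 * 200),
                       "rf_study_wise": 0.05 / (10 * 200),
                       "screen": 0.05 / 200},
        "stability": {"risk_factor": "smoking", "n_reps": 25,
                      "covariates": ["age", "sex"]},
        "preprocess_expression": True,
    }


def _resolve_sim_config(sim: dict[str, Any], seed: int
                        ) -> tuple[SimConfig, dict[str, float]]:
    """Build a SimConfig, resolving gene_index/snp placement to real ids."""
    base = SimConfig(
        n_samples=sim.get("n_samples", 300),
        n_snps=sim.get("n_snps", 3000),
        n_genes=sim.get("n_genes", 200),
        ld_block_size=sim.get("ld_block_size", 10),
        ld_rho=sim.get("ld_rho", 0.7),
        maf_range=tuple(sim.get("maf_range", (0.1, 0.5))),
        noise_sd=sim.get("noise_sd", 1.0),
        missing_rate=sim.get("missing_rate", 0.0),
        seed=seed,
    )
    snp_meta, gene_meta = simdata.layout_maps(base)

    def gene_id(spec: dict) -> str:
        if "gene" in spec:
            return spec["gene"]
        return str(gene_meta.iloc[spec["gene_index"]]["symbol"])

    def cis_snp(spec: dict) -> str:
        if "snp" in spec:
            return spec["snp"]
        row = gene_meta[gene_meta["symbol"] == gene_id(spec)].iloc[0]
        return simdata.pick_cis_snp(snp_meta, row)

    def trans_snp(spec: dict) -> str:
        if "snp" in spec:
            return spec["snp"]
        row = gene_meta[gene_meta["symbol"] == gene_id(spec)].iloc[0]
        return simdata.pick_trans_snp(snp_meta, row)

    base.cis_effects = [
        GeneticEffect(gene_id(s), cis_snp(s), beta=s.get("beta"), r2=s.get("r2"))
        for s in sim.get("cis_effects", [])
    ]
    base.trans_effects = [
        GeneticEffect(gene_id(s), trans_snp(s), beta=s.get("beta"), r2=s.get("r2"))
        for s in sim.get("trans_effects", [])
    ]
    base.rf_effects = [
        RiskFactorEffect(gene_id(s), s["risk_factor"], s["beta"])
        for s in sim.get("rf_effects", [])
    ]
    base.interaction_effects = [
        InteractionEffect(gene_id(s), cis_snp(s), s["risk_factor"], s["beta"])
        for s in sim.get("interaction_effects", [])
    ]
    base.probe_artifacts = [
        ProbeArtifact(gene_id(s), cis_snp(s), s["attenuation"])
        for s in sim.get("probe_artifacts", [])
    ]

    link_spec = sim.get("plaque_link", {"intercept": -0.3, "smoking": 0.3})
    link = {k: v for k, v in link_spec.items() if k != "genes"}
    for gi, coef in link_spec.get("genes", {}).items():
        sym = (gi if isinstance(gi, str)
               else str(gene_meta.iloc[int(gi)]["symbol"]))
        link[sym] = coef
    return base, link


def run_pipeline(config: dict[str, Any], outdir: str) -> dict[str, Any]:
    """Execute every stage, writing artifacts and a manifest into outdir.

    Returns the manifest; raises on stage failure after writing a manifest
    marking the failed stage.
    """
    io.ensure_dir(outdir)
    seed = int(config.get("seed", 0))
    thr = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    manifest: dict[str, Any] = {
        "version": __version__, "seed": seed, "thresholds": thr,
        "stages": [], "outputs": {},
    }

    def done(stage: str, **outputs: str) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].update(outputs)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        # --- simulate -----------------------------------------------------
        sim_cfg, plaque_link = _resolve_sim_config(config.get("sim", {}), seed)
        G = simdata.sim_genotypes(sim_cfg)
        C = simdata.sim_risk_factors(sim_cfg)
        E, ledger = simdata.sim_expression(G, C, sim_cfg)
        D = simdata.sim_detection_pvalues(
            E, config.get("sim", {}).get("frac_undetected", 0.1), seed=seed)
        C = C.copy()
        C["plaques"] = simdata.sim_plaques(C, E, plaque_link, seed=seed,
                                           ledger=ledger)
        paths = {k: os.path.join(outdir, v) for k, v in {
            "vcf": "genotypes.vcf", "dosage": "genotypes_dosage.tsv",
            "expression": "expression.tsv", "detection": "detection.tsv",
            "genes_bed": "genes.bed", "probes_bed": "probes.bed",
            "covariates": "covariates.tsv", "ledger": "ground_truth.yaml",
        }.items()}
        io.write_vcf(G, paths["vcf"])
        io.write_dosage_tsv(G, paths["dosage"])
        io.write_expression_tsv(E, paths["expression"])
        io.write_detection_tsv(D, paths["detection"])
        io.write_bed(E.gene_meta, paths["genes_bed"])
        io.write_bed(E.gene_meta, paths["probes_bed"],
                     start_col="probe_start", end_col="probe_end")
        io.write_covariates_tsv(C, paths["covariates"])
        io.write_ledger_yaml(ledger, paths["ledger"])
        done("simulate", **paths)

        # --- qc -----------------------------------------------------------
        G_qc, qc_report = qc_norm.genotype_qc(G)
        kept_genes = qc_norm.detection_filter(D)
        kept_symbols = set(qc_norm.filter_gene_symbols(
            [s for s, k in zip(E.symbols, kept_genes) if k]))
        gene_mask = np.array([s in kept_symbols for s in E.symbols])
        E_qc = E.subset_genes(gene_mask)
        if config.get("preprocess_expression", True):
            E_qc = qc_norm.quantile_normalize(qc_norm.arcsinh_transform(E_qc))
        qc_path = os.path.join(outdir, "genotype_qc.tsv")
        qc_report.to_frame().to_csv(qc_path, sep="\t", index=False)
        done("qc", genotype_qc=qc_path)

        # --- scan ---------------------------------------------------------
        assoc = eqtl_mod.genome_scan(
            E_qc, G_qc, sex=C["sex"].to_numpy(),
            store_below=thr["store_below"], study_wise=thr["study_wise"],
            kw_threshold=thr["kw"], min_homozygotes=thr["min_homozygotes"],
        )
        assoc = annotate.add_cis_trans(assoc, window=thr["cis_window"])
        assoc_path = os.path.join(outdir, "associations.tsv")
        assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.6g")
        done("scan", associations=assoc_path)

        # --- annotate -----------------------------------------------------
        tiers = sorted({thr["store_below"], 1e-6, 1e-8, thr["study_wise"]},
                       reverse=True)
        summary = annotate.summarize_eqtls(assoc, tiers)
        summary_path = os.path.join(outdir, "eqtl_summary.tsv")
        summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")
        done("annotate", eqtl_summary=summary_path)

        # --- risk factors -------------------------------------------------
        rf_table = rfassoc.rf_assoc_scan(E_qc, C, threshold=thr["rf_study_wise"])
        sw = assoc[(assoc["study_wise"] == 1) & (assoc["cis_trans"] == "cis")]
        cis_genes = set(sw["gene"])
        enrich = rfassoc.enrichment_table(rf_table, cis_genes, E_qc.symbols)
        rf_path = os.path.join(outdir, "rf_associations.tsv")
        enr_path = os.path.join(outdir, "rf_cis_enrichment.tsv")
        rf_table.to_csv(rf_path, sep="\t", index=False, float_format="%.6g")
        enrich.to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
        done("rf-assoc", rf_associations=rf_path, rf_cis_enrichment=enr_path)

        # --- interaction --------------------------------------------------
        best_cis = (sw.sort_values("p_anova").groupby("gene").first()["snp"]
                    if len(sw) else pd.Series(dtype=object))
        sig_rf = rf_table[rf_table["significant"] == 1]
        pairs = [(g, best_cis[g], rf)
                 for g, rf in zip(sig_rf["gene"], sig_rf["risk_factor"])
                 if g in best_cis.index]
        inter = rfassoc.interaction_scan(E_qc, G_qc, C, pairs)
        inter_path = os.path.join(outdir, "interactions.tsv")
        inter.to_csv(inter_path, sep="\t", index=False, float_format="%.6g")
        done("interact", interactions=inter_path)

        # --- stability ----------------------------------------------------
        stab_cfg = config.get("stability", {})
        rf_name = stab_cfg.get("risk_factor", "smoking")
        stab = stability.stability_select(
            E_qc, C, rf_name,
            covariates=tuple(stab_cfg.get("covariates", ("age", "sex"))),
            n_reps=int(stab_cfg.get("n_reps", 25)),
            freq_min=thr["freq_min"], screen_p=thr["screen"],
            p_enter=thr["enter"], p_valid=thr["valid"], master_seed=seed,
        )
        stab_path = os.path.join(outdir, "stability.tsv")
        stab.selected.assign(risk_factor=rf_name).to_csv(
            stab_path, sep="\t", index=False, float_format="%.6g")
        done("stability", stability=stab_path)

        # --- mediation ----------------------------------------------------
        mediators = list(stab.selected["gene"]) or list(
            sig_rf.loc[sig_rf["risk_factor"] == rf_name, "gene"])
        att = mediation.attenuation_test(
            C["plaques"].to_numpy(), rf_name, mediators[:5], C, E_qc)
        att_path = os.path.join(outdir, "attenuation.tsv")
        att.model_b.assign(model="full").pipe(
            lambda b: pd.concat([att.model_a.assign(model="base"), b])
        ).to_csv(att_path, sep="\t", index=False, float_format="%.6g")
        esnp_snps = [best_cis[g] for g in mediators if g in best_cis.index]
        esnp = mediation.esnp_outcome_test(G_qc, C["plaques"].to_numpy(), C,
                                           esnp_snps)
        esnp_path = os.path.join(outdir, "esnp_outcome.tsv")
        esnp.to_csv(esnp_path, sep="\t", index=False, float_format="%.6g")
        manifest["attenuated"] = att.attenuated
        done("mediate", attenuation=att_path, esnp_outcome=esnp_path)

        # --- design -------------------------------------------------------
        n = sim_cfg.n_samples
        report = pd.DataFrame([
            {"quantity": "study_wise_threshold", "value": thr["study_wise"]},
            {"quantity": "min_detectable_r2",
             "value": design.min_detectable_r2(thr["study_wise"], n)},
            {"quantity": "power_r2_0.04",
             "value": design.power_single_snp(n, thr["study_wise"], 0.04)},
        ])
        design_path = os.path.join(outdir, "design_report.tsv")
        report.to_csv(design_path, sep="\t", index=False, float_format="%.6g")
        done("design", design_report=design_path)
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    return manifest
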