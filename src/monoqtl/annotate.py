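"""Post-scan annotation: cis/trans labels, tier summaries, LD utilities,
polymorphic-probe flags, and replication overlap with external eQTL lists.

"cis" means the SNP lies on the gene's chromosome within 1 Mb of either
gene end (inclusive, 1-based coordinates); everything else is trans. An
eQTL (gene) counts as cis at a significance tier if it has at least one cis
eSNP there, trans if at least one trans eSNP — a gene can be both.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

CIS_WINDOW = 1_000_000


def classify_cis_trans(
    snp_chrom: str, snp_pos: int,
    gene_chrom: str, gene_start: int, gene_end: int,
    window: int = CIS_WINDOW,
) -> str:
    """"cis" iff same chromosome and pos in [start−window, end+window]."""
    if snp_chrom is None or gene_chrom is None:
        raise ValueError("unknown chromosome")
    if str(snp_chrom) != str(gene_chrom):
        return "trans"
    return "cis" if gene_start - window <= snp_pos <= gene_end + window else "trans"


def add_cis_trans(assoc: pd.DataFrame, window: int = CIS_WINDOW) -> pd.DataFrame:
    """Vectorized cis/trans labeling of a scan output table."""
    same = assoc["chrom"].astype(str).to_numpy() == assoc["gene_chrom"].astype(str).to_numpy()
    pos = assoc["pos"].to_numpy()
    lo = assoc["gene_start"].to_numpy() - window
    hi = assoc["gene_end"].to_numpy() + window
    cis = same & (pos >= lo) & (pos <= hi)
    out = assoc.copy()
    out["cis_trans"] = np.where(cis, "cis", "trans")
    return out


def summarize_eqtls(assoc: pd.DataFrame, tiers: list[float]) -> pd.DataFrame:
    """Tiered catalogue summary (association / eQTL / eSNP counts).

    For each P-value tier: number of associations, distinct genes (eQTLs)
    and distinct SNPs (eSNPs), cis/trans ratios for each, the minimum R²
    among tier associations, and the median and IQR of eSNPs per eQTL.
    A gene (or SNP) counts cis if any of its tier associations is cis and
    trans if any is trans, so the two classes can overlap.
    """
    rows = []
    for tier in tiers:
        sub = assoc[assoc["p_anova"] < tier] if len(assoc) else assoc
        if len(sub) == 0:
            rows.append({"tier": tier, "n_assoc": 0, "assoc_cis_trans": np.nan,
                         "n_eqtls": 0, "eqtl_cis_trans": np.nan,
                         "n_esnps": 0, "esnp_cis_trans": np.nan,
                         "min_r2": np.nan, "esnps_per_eqtl_median": np.nan,
                         "esnps_per_eqtl_q1": np.nan, "esnps_per_eqtl_q3": np.nan})
            continue
        is_cis = sub["cis_trans"] == "cis"
        n_assoc = len(sub)
        cis_genes = set(sub.loc[is_cis, "gene"])
        trans_genes = set(sub.loc[~is_cis, "gene"])
        cis_snps = set(sub.loc[is_cis, "snp"])
        trans_snps = set(sub.loc[~is_cis, "snp"])
        per_gene = sub.groupby("gene")["snp"].nunique()
        rows.append({
            "tier": tier,
            "n_assoc": n_assoc,
            "assoc_cis_trans": _ratio(int(is_cis.sum()), int((~is_cis).sum())),
            "n_eqtls": sub["gene"].nunique(),
            "eqtl_cis_trans": _ratio(len(cis_genes), len(trans_genes)),
            "n_esnps": sub["snp"].nunique(),
            "esnp_cis_trans": _ratio(len(cis_snps), len(trans_snps)),
            "min_r2": float(sub["R2"].min()),
            "esnps_per_eqtl_median": float(per_gene.median()),
            "esnps_per_eqtl_q1": float(per_gene.quantile(0.25)),
            "esnps_per_eqtl_q3": float(per_gene.quantile(0.75)),
        })
    return pd.DataFrame(rows)


def _ratio(n_cis: int, n_trans: int) -> float:
    return np.nan if n_trans == 0 else n_cis / n_trans


def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of additive codes (pairwise complete).

    Returns NaN when either SNP has zero variance over the shared samples
    or fewer than 2 shared calls.
    """
    a = G.column(snp_a)
    b = G.column(snp_b)
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if len(a) < 2 or a.var() == 0 or b.var() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def proxy_search(
    G: GenotypeMatrix,
    lead_snp: str,
    lead_codes: np.ndarray | None = None,
    lead_chrom: str | None = None,
    lead_pos: int | None = None,
    r2_min: float = 0.8,
    window: int = CIS_WINDOW,
) -> tuple[str | None, float]:
    """Tag SNP for a GWAS lead SNP.

    Returns the lead itself (r²=1) when it is on the genotyping panel.
    Otherwise, if reference additive codes for the lead are supplied
    (``lead_codes``, aligned to the panel samples, e.g. from a denser
    reference panel), the highest-r² panel SNP within ``window`` of
    ``lead_pos`` on ``lead_chrom`` is returned provided r² ≥ ``r2_min``;
    else (None, nan) — the locus is untaggable.
    """
    try:
        G.snp_index(lead_snp)
        return lead_snp, 1.0
    except KeyError:
        pass
    if lead_codes is None or lead_chrom is None or lead_pos is None:
        return None, np.nan
    meta = G.snp_meta
    cand = meta[(meta["chrom"].astype(str) == str(lead_chrom))
                & (meta["pos"] >= lead_pos - window)
                & (meta["pos"] <= lead_pos + window)]
    best, best_r2 = None, -1.0
    lead = np.asarray(lead_codes, dtype=float)
    for _, row in cand.iterrows():
        g = G.column(row["snp"])
        keep = ~np.isnan(g) & ~np.isnan(lead)
        if keep.sum() < 2 or g[keep].var() == 0 or lead[keep].var() == 0:
            continue
        r2 = float(np.corrcoef(g[keep], lead[keep])[0, 1] ** 2)
        if r2 > best_r2:
            best, best_r2 = str(row["snp"]), r2
    if best is not None and best_r2 >= r2_min:
        return best, best_r2
    return None, np.nan


def flag_polymorphic_probes(
    probe_intervals: pd.DataFrame,
    snp_positions: pd.DataFrame,
    panel_snps: set[str],
    ld: "callable[[str, str], float] | None" = None,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """Flag genes whose probe sequence contains a known SNP.

    ``probe_intervals``: columns (symbol, chrom, probe_start, probe_end);
    ``snp_positions``: the reference SNP map (snp, chrom, pos), which may be
    a superset of the genotyping panel. A gene is flagged "direct" when an
    in-probe SNP is itself on the panel, "proxy" when a panel SNP has
    r² = 1 with an in-probe SNP (``ld`` provides r² between SNP ids), else
    it is left unflagged (flag "").
    """
    rows = []
    for _, gene in probe_intervals.iterrows():
        in_probe = snp_positions[
            (snp_positions["chrom"].astype(str) == str(gene["chrom"]))
            & (snp_positions["pos"] >= gene["probe_start"])
            & (snp_positions["pos"] <= gene["probe_end"])
        ]
        flag, flag_snp, flag_r2 = "", "", np.nan
        for _, srow in in_probe.iterrows():
            sid = str(srow["snp"])
            if sid in panel_snps:
                flag, flag_snp, flag_r2 = "direct", sid, 1.0
                break
        if not flag and ld is not None:
            for _, srow in in_probe.iterrows():
                sid = str(srow["snp"])
                for panel_sid in panel_snps:
                    r2 = ld(sid, panel_sid)
                    if r2 is not None and not np.isnan(r2) and r2 >= 1.0:
                        flag, flag_snp, flag_r2 = "proxy", panel_sid, float(r2)
                        break
                if flag:
                    break
        rows.append({"symbol": gene["symbol"], "flag": flag,
                     "snp": flag_snp, "r2": flag_r2})
    return pd.DataFrame(rows)


def replication_overlap(
    external: pd.DataFrame,
    internal: pd.DataFrame,
    threshold: float = 3.9e-6,
) -> pd.DataFrame:
    """Percent of external cis eQTLs replicating internally, per tier.

    ``external`` needs columns (gene, tier); ``internal`` is a scan table
    with cis/trans labels. External genes absent from the internal
    expression panel are excluded from the denominator. An external eQTL
    replicates iff the internal best cis P for that gene is below
    ``threshold``. Returns per-tier rows plus an "all" row.
    """
    if len(internal):
        cis = internal[internal["cis_trans"] == "cis"]
        best_cis = cis.groupby("gene")["p_anova"].min()
        panel_genes = set(internal["gene"])
    else:
        best_cis = pd.Series(dtype=float)
        panel_genes = set()
    matched = external[external["gene"].isin(panel_genes)].copy()
    matched["replicated"] = matched["gene"].map(
        lambda g: bool(best_cis.get(g, 1.0) < threshold)
    )
    rows = []
    for tier, sub in matched.groupby("tier"):
        rows.append({"tier": str(tier), "n": len(sub),
                     "pct_replicated": 100.0 * sub["replicated"].mean()})
    rows.append({
        "tier": "all", "n": len(matched),
        "pct_replicated": (100.0 * matched["replicated"].mean()
                           if len(matched) else np.nan),
    })
    return pd.DataFrame(rows)
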