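"""Split-half stability selection of independent expression correlates.

For one risk factor, each replicate randomly halves the cohort into a
screening and a validation sample. Screening: genes passing a univariate
covariate-adjusted filter enter a forward stepwise regression (risk factor
as the dependent variable, P-to-enter 0.01). Validation: the selected
genes are jointly refit in the held-out half; a gene counts in the
replicate iff its validation t-test P < 0.01, and a global P compares the
full model against the covariates-only model. Genes appearing in more than
``freq_min`` (default 25%) of 250 replicates are reported, with their
selection frequency and the sign of association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, check_aligned
from .regress import design_matrix, nested_f_test, ols_scan, partial_f_p

SCREEN_P = 3.9e-6
P_ENTER = 0.01
P_VALID = 0.01
N_REPS = 250
FREQ_MIN = 0.25
MAX_CANDIDATES = 100  # guards the stepwise in pathological screens


@dataclass
class StabilityResult:
    risk_factor: str
    n_reps: int
    selected: pd.DataFrame  # gene, frequency, sign
    global_p_median: float
    global_p_min: float
    global_p_max: float
    replicate_log: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)


def split_half(sample_ids: list[str], seed: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic random halving; returns (screen, validation) index arrays.

    Disjoint and exhaustive; sizes differ by at most one (the screening
    half gets the extra sample when n is odd).
    """
    n = len(sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    perm = np.random.default_rng(seed).permutation(n)
    half = (n + 1) // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def screen_stepwise(
    Y: np.ndarray,
    symbols: list[str],
    rf: np.ndarray,
    covars: np.ndarray | None,
    screen_p: float = SCREEN_P,
    p_enter: float = P_ENTER,
    max_candidates: int = MAX_CANDIDATES,
) -> list[str]:
    """Univariate screen then pure-forward stepwise selection.

    ``Y`` is (n, genes) expression on the screening half; ``covars`` is an
    (n, k) matrix (no intercept) or None. The univariate filter keeps genes
    whose covariate-adjusted partial P is below ``screen_p`` (capped at the
    ``max_candidates`` smallest). Stepwise then adds, at each step, the
    candidate with the smallest partial-F P to the model
    rf ~ covariates + selected, while that P is below ``p_enter``.
    """
    rf = np.asarray(rf, dtype=float)
    base_cols = [] if covars is None else [covars]
    X_base = design_matrix(*base_cols) if base_cols else np.ones((len(rf), 1))
    # univariate covariate-adjusted screen (partial P of each gene alone)
    p_uni = partial_f_p(rf, X_base, Y)
    cand_idx = np.flatnonzero(p_uni < screen_p)
    if len(cand_idx) == 0:
        return []
    if len(cand_idx) > max_candidates:
        cand_idx = cand_idx[np.argsort(p_uni[cand_idx], kind="mergesort")][:max_candidates]

    selected: list[int] = []
    remaining = list(cand_idx)
    X_current = X_base
    while remaining:
        cand = Y[:, remaining]
        p_add = partial_f_p(rf, X_current, cand)
        best = int(np.argmin(p_add))
        if p_add[best] >= p_enter:
            break
        gi = remaining.pop(best)
        selected.append(gi)
        X_current = np.column_stack([X_current, Y[:, gi]])
        if X_current.shape[1] >= len(rf) - 1:
            break
    return [symbols[i] for i in selected]


def validate_joint(
    Y: np.ndarray,
    symbols: list[str],
    selected: list[str],
    rf: np.ndarray,
    covars: np.ndarray | None,
) -> tuple[pd.DataFrame, float]:
    """Joint refit of the selected genes in the validation half.

    Returns (per-gene table with beta/t/p, global nested-model F-test P of
    the full model vs covariates only). An empty selection returns an empty
    table and global P = 1 by convention.
    """
    if not selected:
        return pd.DataFrame(columns=["gene", "beta", "t", "p"]), 1.0
    rf = np.asarray(rf, dtype=float)
    idx = {s: i for i, s in enumerate(symbols)}
    cols = [Y[:, idx[s]] for s in selected]
    base_cols = [] if covars is None else [covars]
    X_reduced = design_matrix(*base_cols) if base_cols else np.ones((len(rf), 1))
    X_full = np.column_stack([X_reduced] + cols)
    if X_full.shape[1] >= len(rf):
        raise ValueError("more predictors than validation samples")
    rows = []
    n_base = X_reduced.shape[1]
    for j, gene in enumerate(selected):
        beta, t, p = ols_scan(rf[:, None], X_full, coef_index=n_base + j)
        rows.append({"gene": gene, "beta": float(beta[0]),
                     "t": float(t[0]), "p": float(p[0])})
    _, global_p = nested_f_test(rf, X_full, X_reduced)
    return pd.DataFrame(rows), global_p


def stability_select(
    E: ExpressionMatrix,
    C: pd.DataFrame,
    rf: str,
    covariates: tuple[str, ...] = (),
    n_reps: int = N_REPS,
    freq_min: float = FREQ_MIN,
    screen_p: float = SCREEN_P,
    p_enter: float = P_ENTER,
    p_valid: float = P_VALID,
    master_seed: int = 0,
    max_candidates: int = MAX_CANDIDATES,
) -> StabilityResult:
    """Repeated split-half screening/validation for one risk factor.

    A gene counts in a replicate iff it was selected at screening AND its
    validation per-gene P < ``p_valid``. Reported genes have frequency
    strictly above ``freq_min``, sorted by frequency descending; the sign
    is the majority sign of the validation coefficient. Per-replicate seeds
    derive as master_seed + replicate index, so the whole result is
    reproducible bit for bit.
    """
    check_aligned(E.sample_ids, list(C.index))
    needed = [rf, *covariates]
    sub = C[needed].astype(float)
    keep = ~sub.isna().any(axis=1).to_numpy()
    Y = E.values[keep]
    rf_vec = sub[rf].to_numpy()[keep]
    covar_mat = (np.column_stack([sub[c].to_numpy()[keep] for c in covariates])
                 if covariates else None)
    ids = [s for s, k in zip(E.sample_ids, keep) if k]
    symbols = E.symbols

    counts: dict[str, int] = {}
    sign_sum: dict[str, float] = {}
    log_rows = []
    for rep in range(n_reps):
        screen_idx, valid_idx = split_half(ids, master_seed + rep)
        sel = screen_stepwise(
            Y[screen_idx], symbols, rf_vec[screen_idx],
            None if covar_mat is None else covar_mat[screen_idx],
            screen_p=screen_p, p_enter=p_enter, max_candidates=max_candidates,
        )
        per_gene, global_p = validate_joint(
            Y[valid_idx], symbols, sel, rf_vec[valid_idx],
            None if covar_mat is None else covar_mat[valid_idx],
        )
        confirmed = per_gene[per_gene["p"] < p_valid]
        for _, row in confirmed.iterrows():
            counts[row["gene"]] = counts.get(row["gene"], 0) + 1
            sign_sum[row["gene"]] = sign_sum.get(row["gene"], 0.0) + np.sign(row["beta"])
        log_rows.append({"replicate": rep, "n_screened": len(sel),
                         "n_confirmed": len(confirmed), "global_p": global_p,
                         "selected": ";".join(sel)})

    freq = pd.DataFrame(
        [{"gene": g, "frequency": c / n_reps,
          "sign": int(np.sign(sign_sum[g])) if sign_sum[g] != 0 else 0}
         for g, c in counts.items()]
    )
    if len(freq):
        freq = freq[freq["frequency"] > freq_min]
        freq = freq.sort_values(["frequency", "gene"],
                                ascending=[False, True]).reset_index(drop=True)
    else:
        freq = pd.DataFrame(columns=["gene", "frequency", "sign"])
    log = pd.DataFrame(log_rows)
    global_ps = log["global_p"].to_numpy() if len(log) else np.array([1.0])
    return StabilityResult(
        risk_factor=rf,
        n_reps=n_reps,
        selected=freq,
        global_p_median=float(np.median(global_ps)),
        global_p_min=float(global_ps.min()),
        global_p_max=float(global_ps.max()),
        replicate_log=log,
    )
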