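"""Instrument selection, harmonization and quality control.

Turns the colocalized causal SNPs of one cell type into a harmonized
instrument table for a single exposure-outcome pair.  The stage order
is fixed:

    select -> confounder filter -> LD clumping -> proxy substitution
           -> harmonization -> radial outlier removal -> F-statistic

Each stage logs how many candidates enter, how many leave, and why the
rest were dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import InputError, LDMatrix

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: columns of a harmonized instrument table
INSTRUMENT_COLUMNS = [
    "snp", "ea", "oa", "eaf_exp", "beta_exp", "se_exp", "p_exp",
    "eaf_out", "beta_out", "se_out", "context", "provenance",
]


@dataclass
class StageLog:
    stage: str
    n_in: int
    n_out: int
    dropped: dict[str, int] = field(default_factory=dict)


@dataclass
class FStats:
    """Instrument-strength summary.

    Per-SNP variance explained is ``R2_i = beta_i^2 / (beta_i^2 +
    se_i^2 * N)``; the joint F-statistic is ``F = R2 (N - k - 1) /
    (k (1 - R2))`` with ``R2`` the sum over instruments.  F below 10
    flags a weak instrument set.
    """

    r2_per_snp: np.ndarray
    r2_total: float
    k: int
    n: float
    f: float

    @property
    def weak(self) -> bool:
        return self.f < 10.0


def select_candidates(
    coloc_snps: list[str],
    exposure: pd.DataFrame,
    p_thresh: float = 5e-8,
) -> pd.DataFrame:
    """Exposure rows for the pooled colocalized SNPs that pass the
    genome-wide relevance filter ``p < p_thresh``, deduplicated."""
    pool = pd.unique(pd.Series(coloc_snps))
    cand = exposure[exposure["snp"].isin(pool)]
    cand = cand[cand["p"] < p_thresh].drop_duplicates("snp")
    if cand.empty:
        logger.info("no candidate instruments pass p < %g", p_thresh)
    return cand.reset_index(drop=True)


def confounder_filter(
    candidates: pd.DataFrame,
    table: pd.DataFrame | None,
    ld: LDMatrix | None,
    r2_proxy: float = 0.8,
    p_conf: float = 5e-8,
) -> tuple[pd.DataFrame, StageLog]:
    """Drop candidates associated with a confounder, directly or through
    a proxy in LD at r^2 > ``r2_proxy``.

    ``table`` has columns ``snp, confounder, p`` (e.g. a PhenoScanner
    export).  Candidates without LD coverage are treated as having no
    proxies and logged.
    """
    log = StageLog("confounder_filter", len(candidates), 0)
    if table is None or table.empty:
        log.n_out = len(candidates)
        return candidates, log
    hits = set(table.loc[table["p"] < p_conf, "snp"])

    def is_confounded(snp: str) -> bool:
        if snp in hits:
            return True
        if ld is None or snp not in ld.snp_ids:
            return False
        for other in ld.snp_ids:
            if other != snp and other in hits and ld.r2(snp, other) > r2_proxy:
                return True
        return False

    keep = ~candidates["snp"].map(is_confounded)
    n_drop = int((~keep).sum())
    if n_drop:
        log.dropped["confounder_associated"] = n_drop
    out = candidates[keep].reset_index(drop=True)
    log.n_out = len(out)
    return out, log


def ld_clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    r2: float = 0.001,
    window_kb: int = 10_000,
    p_thresh: float = 5e-8,
) -> tuple[pd.DataFrame, StageLog]:
    """Greedy LD clumping to near-independent index SNPs.

    Candidates are visited by ascending p (ties by position then id);
    a SNP is kept iff no already-kept SNP on the same chromosome lies
    within ``window_kb`` and has r^2 above ``r2`` with it.  SNP pairs
    absent from the LD matrix count as unlinked.
    """
    log = StageLog("ld_clump", len(candidates), 0)
    cand = candidates[candidates["p"] < p_thresh]
    below = len(candidates) - len(cand)
    if below:
        log.dropped["above_p_threshold"] = below
    cand = cand.sort_values(["p", "pos", "snp"], kind="mergesort")

    kept: list[pd.Series] = []
    window = window_kb * 1000
    have_ld = set(ld.snp_ids) if ld is not None else set()
    for _, row in cand.iterrows():
        clumped = False
        for k in kept:
            if str(k["chr"]) != str(row["chr"]) or abs(int(k["pos"]) - int(row["pos"])) > window:
                continue
            if row["snp"] in have_ld and k["snp"] in have_ld:
                if ld.r2(row["snp"], k["snp"]) > r2:
                    clumped = True
                    break
        if clumped:
            log.dropped["clumped"] = log.dropped.get("clumped", 0) + 1
        else:
            kept.append(row)
    out = pd.DataFrame(kept, columns=candidates.columns).reset_index(drop=True)
    log.n_out = len(out)
    return out, log


def proxy_substitute(
    index_snps: pd.DataFrame,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None,
    r2: float = 0.8,
) -> tuple[pd.DataFrame, StageLog]:
    """Replace index SNPs missing from the outcome by their best proxy.

    A proxy must have r^2 > ``r2`` with the index SNP and be present in
    both exposure and outcome tables; the highest-r^2 proxy wins.
    Unresolvable SNPs are dropped.  Adds a ``provenance`` column:
    ``original`` or ``proxy(<index snp>,r2=<value>)``.
    """
    log = StageLog("proxy_substitute", len(index_snps), 0)
    out_snps = set(outcome["snp"])
    exp_snps = set(exposure["snp"])
    rows = []
    for _, row in index_snps.iterrows():
        snp = row["snp"]
        if snp in out_snps:
            r = row.copy()
            r["provenance"] = "original"
            rows.append(r)
            continue
        best, best_r2 = None, r2
        if ld is not None and snp in ld.snp_ids:
            for other in ld.snp_ids:
                if other == snp or other not in out_snps or other not in exp_snps:
                    continue
                rr = ld.r2(snp, other)
                if rr > best_r2:
                    best, best_r2 = other, rr
        if best is None:
            log.dropped["no_proxy"] = log.dropped.get("no_proxy", 0) + 1
            continue
        r = exposure.loc[exposure["snp"] == best].iloc[0].copy()
        r["provenance"] = f"proxy({snp},r2={best_r2:.3f})"
        rows.append(r)
    out = pd.DataFrame(rows).reset_index(drop=True) if rows else index_snps.iloc[0:0].copy()
    if "provenance" not in out.columns:
        out["provenance"] = pd.Series(dtype=str)
    log.n_out = len(out)
    return out, log


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def harmonize_pair(
    exp_row: pd.Series,
    out_row: pd.Series,
    palindrome_af: float = 0.42,
) -> tuple[pd.Series | None, str]:
    """Align one outcome record to the exposure's allele orientation.

    Returns ``(instrument_row, reason)``; the row is None when the pair
    is dropped, with ``reason`` saying why.  Swapped alleles negate the
    outcome beta and flip its frequency; complementary-strand records
    are flipped to the forward strand first.  Palindromic (A/T, C/G)
    variants whose minor-allele frequency exceeds ``palindrome_af`` in
    either dataset — or whose frequency is missing — are ambiguous and
    dropped; the rest are resolved by frequency matching.
    """
    ea_e, oa_e = exp_row["ea"], exp_row["oa"]
    ea_o, oa_o = out_row["ea"], out_row["oa"]
    beta_out, eaf_out = float(out_row["beta"]), out_row["eaf"]

    if _is_palindromic(ea_e, oa_e):
        eaf_e = exp_row["eaf"]
        if pd.isna(eaf_e) or pd.isna(eaf_out):
            return None, "palindromic_missing_eaf"
        maf_e = min(eaf_e, 1 - eaf_e)
        maf_o = min(eaf_out, 1 - eaf_out)
        if maf_e > palindrome_af or maf_o > palindrome_af:
            return None, "palindromic_intermediate_af"
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return None, "irreconcilable_alleles"
        # on a palindrome, allele labels cannot distinguish strands;
        # orient by whether the frequencies fall on the same side of 0.5
        same_label = ea_o == ea_e
        same_side = (eaf_out < 0.5) == (eaf_e < 0.5)
        if same_label != same_side:
            beta_out = -beta_out
            eaf_out = 1 - eaf_out
    else:
        if {ea_o, oa_o} == {ea_e, oa_e}:
            pass
        elif {COMPLEMENT.get(ea_o), COMPLEMENT.get(oa_o)} == {ea_e, oa_e}:
            ea_o, oa_o = COMPLEMENT[ea_o], COMPLEMENT[oa_o]
        else:
            return None, "irreconcilable_alleles"
        if ea_o != ea_e:  # swapped orientation
            beta_out = -beta_out
            eaf_out = 1 - eaf_out if pd.notna(eaf_out) else eaf_out

    inst = pd.Series(
        {
            "snp": exp_row["snp"],
            "ea": ea_e,
            "oa": oa_e,
            "eaf_exp": exp_row["eaf"],
            "beta_exp": float(exp_row["beta"]),
            "se_exp": float(exp_row["se"]),
            "p_exp": float(exp_row["p"]),
            "eaf_out": eaf_out,
            "beta_out": beta_out,
            "se_out": float(out_row["se"]),
            "context": exp_row.get("context", ""),
            "provenance": exp_row.get("provenance", "original"),
        }
    )
    return inst, "ok"


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_af: float = 0.42,
) -> tuple[pd.DataFrame, StageLog]:
    """Harmonize all shared SNPs into an instrument table."""
    log = StageLog("harmonize", len(exposure), 0)
    out_by_snp = outcome.set_index("snp")
    rows = []
    for _, exp_row in exposure.iterrows():
        snp = exp_row["snp"]
        if snp not in out_by_snp.index:
            log.dropped["absent_from_outcome"] = log.dropped.get("absent_from_outcome", 0) + 1
            continue
        inst, reason = harmonize_pair(exp_row, out_by_snp.loc[snp], palindrome_af)
        if inst is None:
            log.dropped[reason] = log.dropped.get(reason, 0) + 1
        else:
            rows.append(inst)
    out = pd.DataFrame(rows, columns=INSTRUMENT_COLUMNS).reset_index(drop=True)
    log.n_out = len(out)
    return out, log


def _radial_fits(instruments: pd.DataFrame, tol: float = 1e-4, max_iter: int = 100):
    """Radial IVW and radial Egger fits with first-order weights.

    On the radial scale the response is ``sqrt(w_j) * ratio_j`` and the
    regressor ``sqrt(w_j)``, with ``w_j = beta_exp_j^2 / se_out_j^2``.
    First-order weights do not depend on the slope, so the iteratively
    reweighted loop converges immediately; it is kept for interface
    parity with modified-weight variants.
    """
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    so = instruments["se_out"].to_numpy(dtype=float)
    w = bx**2 / so**2
    ratio = by / bx
    sw = np.sqrt(w)
    y = sw * ratio

    beta_ivw = np.sum(w * ratio) / np.sum(w)
    for _ in range(max_iter):
        new = np.sum(w * ratio) / np.sum(w)
        if abs(new - beta_ivw) < tol:
            break
        beta_ivw = new
    q_ivw = w * (ratio - beta_ivw) ** 2

    X = np.column_stack([np.ones_like(sw), sw])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    q_egger = (y - X @ coef) ** 2
    return beta_ivw, q_ivw, coef, q_egger


def radial_outlier_filter(
    instruments: pd.DataFrame,
    alpha: float = 0.05,
    tol: float = 1e-4,
    iterate: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove pleiotropic outliers flagged by radial IVW or radial Egger.

    Each instrument's heterogeneity contribution ``Q_j = w_j (ratio_j -
    fit)^2`` is referred to chi-square(1); SNPs with ``p < alpha`` under
    either fit are removed (the union).  A single pass by default;
    ``iterate=True`` repeats until no outlier remains.  Fewer than 3
    instruments pass through unchanged.  Instruments with a zero
    exposure effect cannot form a ratio and are dropped up front.

    Returns ``(retained, removed)`` where ``removed`` carries a
    ``flagged_by`` column (``ivw``, ``egger`` or ``ivw+egger``).
    """
    removed_rows = []
    zero = instruments["beta_exp"] == 0
    if zero.any():
        for _, r in instruments[zero].iterrows():
            r = r.copy()
            r["flagged_by"] = "zero_exposure_beta"
            removed_rows.append(r)
        instruments = instruments[~zero]

    current = instruments.reset_index(drop=True)
    while True:
        if len(current) < 3:
            logger.info("fewer than 3 instruments; radial filter passes through")
            break
        beta_ivw, q_ivw, _, q_egger = _radial_fits(current, tol=tol)
        p_ivw = stats.chi2.sf(q_ivw, df=1)
        p_egger = stats.chi2.sf(q_egger, df=1)
        out_mask = (p_ivw < alpha) | (p_egger < alpha)
        if not out_mask.any():
            break
        for i in np.flatnonzero(out_mask):
            r = current.iloc[i].copy()
            flags = []
            if p_ivw[i] < alpha:
                flags.append("ivw")
            if p_egger[i] < alpha:
                flags.append("egger")
            r["flagged_by"] = "+".join(flags)
            removed_rows.append(r)
        current = current[~out_mask].reset_index(drop=True)
        if not iterate:
            break

    removed = pd.DataFrame(removed_rows).reset_index(drop=True)
    return current, removed


def instrument_strength(instruments: pd.DataFrame, n_exposure: float) -> FStats:
    """Joint instrument strength via the F-statistic.

    Uses the exposure sample size ``N``; raises when ``N <= k + 1``
    since the F formula's numerator degrees of freedom would vanish.
    """
    k = len(instruments)
    if k < 1:
        raise InputError("need at least one instrument")
    if n_exposure <= k + 1:
        raise InputError(f"exposure sample size {n_exposure} <= k + 1 = {k + 1}")
    beta = instruments["beta_exp"].to_numpy(dtype=float)
    se = instruments["se_exp"].to_numpy(dtype=float)
    r2 = beta**2 / (beta**2 + se**2 * n_exposure)
    r2_total = float(np.sum(r2))
    f = r2_total * (n_exposure - k - 1) / (k * (1 - r2_total))
    return FStats(r2_per_snp=r2, r2_total=r2_total, k=k, n=n_exposure, f=f)
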