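"""End-to-end driver: colocalize per context, build instruments, run MR.

For each cell-type context the pipeline (i) colocalizes every gene's
cis region between the exposure GWAS and that context's eQTL signal
(fine-mapping mode with single-variant fallback), (ii) pools the top
shared causal variants of colocalized genes as candidate instruments,
(iii) runs the selection/QC cascade per outcome, (iv) applies the MR
estimator suite with pleiotropy diagnostics and nominates the main
method, and (v) Bonferroni-corrects across the outcomes x contexts
family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coloc as _coloc
from . import instruments as _iv
from . import mr as _mr
from .finemap import credible_sets, susie_rss
from .sumstats import InputError, LDMatrix, exclude_mhc

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "exposure", "outcome", "context", "status", "n_iv", "chosen_method",
    "beta", "se", "ci_low", "ci_high", "p",
    "q", "q_p", "q_prime", "q_prime_p", "egger_intercept", "egger_intercept_p",
    "presso_p", "f_stat", "weak_instruments",
    "p_bonferroni_threshold", "significant", "rationale",
]


@dataclass
class PipelineParams:
    """All stage thresholds, at their published or conventional defaults."""

    pph4: float = 0.8
    coverage: float = 0.9
    min_purity: float = 0.5
    susie_L: int = 10
    flank: int = 100_000
    p_exposure: float = 5e-8
    p_confounder: float = 5e-8
    r2_proxy: float = 0.8
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    palindrome_af: float = 0.42
    radial_alpha: float = 0.05
    f_min: float = 10.0
    alpha: float = 0.05
    n_boot: int = 1000
    presso_nsim: int = 1000


@dataclass
class PipelineConfig:
    """In-memory inputs of one pipeline run.

    ``ld_by_region`` maps each gene to the LD matrix of its cis region;
    ``outcomes`` maps outcome names to canonical GWAS tables.
    """

    exposure: pd.DataFrame
    eqtl: pd.DataFrame
    outcomes: dict[str, pd.DataFrame]
    ld_by_region: dict[str, LDMatrix]
    confounders: pd.DataFrame | None = None
    contexts: list[str] | None = None
    exposure_name: str = "exposure"
    params: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0


def bonferroni_adjust(n_outcomes: int, n_contexts: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / (n_outcomes * n_contexts)``."""
    if n_outcomes < 1 or n_contexts < 1:
        raise InputError("counts must be >= 1")
    return alpha / (n_outcomes * n_contexts)


def colocalize_context(
    exposure: pd.DataFrame,
    eqtl_ctx: pd.DataFrame,
    ld_by_region: dict[str, LDMatrix],
    params: PipelineParams,
) -> tuple[list[str], pd.DataFrame]:
    """Colocalize every gene of one context against the exposure GWAS.

    Returns the pooled (union) top causal SNPs of colocalized genes and
    a per-gene summary table.  Fine-mapping mode runs when both traits
    yield credible sets; otherwise the enumeration falls back to
    marginal Bayes factors, which is recorded in the summary.
    """
    causal: list[str] = []
    rows = []
    for gene, etab in eqtl_ctx.groupby("gene"):
        if gene not in ld_by_region:
            logger.warning("no LD for gene %s; skipped", gene)
            continue
        etab = exclude_mhc(etab)
        gtab = exclude_mhc(exposure)
        shared = [s for s in etab["snp"] if s in set(gtab["snp"])]
        if not shared:
            continue
        gtab = gtab.set_index("snp").loc[shared].reset_index()
        etab = etab.set_index("snp").loc[shared].reset_index()
        ld = ld_by_region[gene].subset(shared)

        z1 = (gtab["beta"] / gtab["se"]).to_numpy()
        z2 = (etab["beta"] / etab["se"]).to_numpy()
        fit1 = susie_rss(z1, ld, L=params.susie_L)
        fit2 = susie_rss(z2, ld, L=params.susie_L)
        sets1 = credible_sets(fit1, ld, params.coverage, params.min_purity)
        sets2 = credible_sets(fit2, ld, params.coverage, params.min_purity)

        trait1_p = gtab.set_index("snp")["p"]
        results = _coloc.coloc_susie(fit1, sets1, fit2, sets2, trait1_p=trait1_p)
        mode = "susie"
        if not results:
            logger.info("gene %s: no credible sets; falling back to ABF mode", gene)
            results = [_coloc.coloc_abf(gtab, etab)]
            mode = "abf"
        for res in results:
            hit = _coloc.classify_coloc(res, params.pph4)
            top = _coloc.top_causal_snp(res) if hit else None
            if top is not None:
                causal.append(top)
            rows.append(
                {
                    "gene": gene, "mode": mode, "n_snps": res.n_snps,
                    **res.pph, "colocalized": hit, "top_snp": top,
                    "signal_pair": res.signal_pair,
                }
            )
    summary = pd.DataFrame(rows)
    return list(dict.fromkeys(causal)), summary


def combined_ld(ld_by_region: dict[str, LDMatrix], snps: list[str]) -> LDMatrix:
    """Block-diagonal LD over SNPs pooled from independent regions."""
    want = [s for s in snps]
    blocks, order = [], []
    remaining = set(want)
    for ld in ld_by_region.values():
        members = [s for s in ld.snp_ids if s in remaining]
        if members:
            blocks.append(ld.subset(members).r)
            order.extend(members)
            remaining -= set(members)
    if remaining:
        blocks.append(np.eye(len(remaining)))
        order.extend(sorted(remaining))
    n = len(order)
    r = np.zeros((n, n))
    i = 0
    for b in blocks:
        k = b.shape[0]
        r[i : i + k, i : i + k] = b
        i += k
    return LDMatrix(order, r)


def build_instruments(
    causal_snps: list[str],
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix | None,
    confounders: pd.DataFrame | None,
    params: PipelineParams,
    context: str,
) -> tuple[pd.DataFrame, list[_iv.StageLog]]:
    """The fixed selection/QC cascade for one context and outcome."""
    logs: list[_iv.StageLog] = []
    cand = _iv.select_candidates(causal_snps, exposure, params.p_exposure)
    logs.append(_iv.StageLog("select_candidates", len(causal_snps), len(cand)))
    if cand.empty:
        return cand, logs

    cand, log = _iv.confounder_filter(
        cand, confounders, ld, params.r2_proxy, params.p_confounder
    )
    logs.append(log)
    cand, log = _iv.ld_clump(cand, ld, params.clump_r2, params.clump_kb, params.p_exposure)
    logs.append(log)
    cand, log = _iv.proxy_substitute(cand, exposure, outcome, ld, params.r2_proxy)
    logs.append(log)
    cand["context"] = context
    inst, log = _iv.harmonize(cand, outcome, params.palindrome_af)
    logs.append(log)
    inst, removed = _iv.radial_outlier_filter(inst, alpha=params.radial_alpha)
    logs.append(
        _iv.StageLog(
            "radial_outlier_filter", len(inst) + len(removed), len(inst),
            {"radial_outlier": len(removed)} if len(removed) else {},
        )
    )
    return inst, logs


def analyze_instruments(
    inst: pd.DataFrame, params: PipelineParams, seed: int
) -> dict:
    """Estimator suite + diagnostics + main-method choice for one table."""
    k = len(inst)
    estimates = _mr.run_all_estimators(inst, n_boot=params.n_boot, seed=seed)
    het = _mr.heterogeneity(inst) if k >= 2 else _mr.HeterogeneityStats()
    intercept = intercept_p = None
    if k >= 3:
        intercept, _, intercept_p = _mr.egger_intercept_test(inst)
    presso_p = None
    presso = None
    if k >= 4:
        presso = _mr.presso_global(inst, n_sim=params.presso_nsim, seed=seed)
        presso_p = presso.p_global
    choice = _mr.select_main_method(
        n_iv=k,
        q_p=het.q_p if k >= 2 else None,
        egger_intercept_p=intercept_p,
        presso_p=presso_p,
        q_prime_p=het.q_prime_p if k >= 3 else None,
        alpha=params.alpha,
    )
    loo = _mr.leave_one_out(inst) if k >= 3 else None
    return {
        "estimates": estimates,
        "heterogeneity": het,
        "egger_intercept": intercept,
        "egger_intercept_p": intercept_p,
        "presso": presso,
        "choice": choice,
        "leave_one_out": loo,
    }


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the full cell-stratified MR analysis; one row per
    (outcome, context), deterministic under the configured seed."""
    params = config.params
    contexts = config.contexts or sorted(config.eqtl["context"].unique())
    n_tests = len(config.outcomes) * len(contexts)
    threshold = bonferroni_adjust(len(config.outcomes), len(contexts), params.alpha)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        len(contexts) * len(config.outcomes)
    ) % (2**31)

    rows = []
    task = 0
    for context in contexts:
        eqtl_ctx = config.eqtl[config.eqtl["context"] == context]
        if eqtl_ctx.empty:
            logger.info("context %s has no eQTL records; skipped", context)
            task += len(config.outcomes)
            continue
        causal, coloc_summary = colocalize_context(
            config.exposure, eqtl_ctx, config.ld_by_region, params
        )
        logger.info("context %s: %d colocalized causal SNPs", context, len(causal))
        for outcome_name, outcome in config.outcomes.items():
            seed = int(seeds[task])
            task += 1
            row = {
                "exposure": config.exposure_name,
                "outcome": outcome_name,
                "context": context,
                "p_bonferroni_threshold": threshold,
            }
            ld = combined_ld(config.ld_by_region, causal) if causal else None
            inst, logs = build_instruments(
                causal, config.exposure, outcome, ld,
                config.confounders, params, context,
            )
            row["n_iv"] = len(inst)
            if inst.empty:
                row.update(status="no-instruments", significant=False)
                rows.append(row)
                continue
            res = analyze_instruments(inst, params, seed)
            choice = res["choice"]
            est = res["estimates"].get(choice.chosen) or next(iter(res["estimates"].values()))
            het = res["heterogeneity"]
            fstat = _iv.instrument_strength(inst, float(config.exposure["n"].iloc[0]))
            row.update(
                status="ok",
                chosen_method=choice.chosen,
                rationale=choice.rationale,
                beta=est.beta, se=est.se, ci_low=est.ci_low, ci_high=est.ci_high,
                p=est.pvalue,
                q=het.q, q_p=het.q_p, q_prime=het.q_prime, q_prime_p=het.q_prime_p,
                egger_intercept=res["egger_intercept"],
                egger_intercept_p=res["egger_intercept_p"],
                presso_p=res["presso"].p_global if res["presso"] else None,
                f_stat=fstat.f, weak_instruments=fstat.weak,
                significant=est.pvalue < threshold,
            )
            rows.append(row)

    table = pd.DataFrame(rows)
    for col in RESULT_COLUMNS:
        if col not in table.columns:
            table[col] = None
    table.attrs["n_tests"] = n_tests
    return table[RESULT_COLUMNS]


def write_report(table: pd.DataFrame, outdir) -> list[str]:
    """Write the main results TSV, a diagnostics TSV with the per-method
    recommendation, and a run log; returns the paths written."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if table.empty:
        raise InputError("result table is empty")
    main = outdir / "mr_results.tsv"
    table.to_csv(main, sep="\t", index=False)
    diag_cols = [
        "exposure", "outcome", "context", "n_iv", "q", "q_p", "q_prime",
        "q_prime_p", "egger_intercept", "egger_intercept_p", "presso_p",
        "chosen_method", "rationale",
    ]
    diag = table[[c for c in diag_cols if c in table.columns]].copy()
    diag = diag.rename(columns={"chosen_method": "recommendation"})
    diag_path = outdir / "mr_diagnostics.tsv"
    diag.to_csv(diag_path, sep="\t", index=False)
    log_path = outdir / "run_log.txt"
    with open(log_path, "w") as fh:
        fh.write(f"rows: {len(table)}\n")
        fh.write(f"tests in family: {table.attrs.get('n_tests', len(table))}\n")
        fh.write(
            f"significant: {int(table['significant'].fillna(False).sum())}\n"
        )
    return [str(main), str(diag_path), str(log_path)]
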