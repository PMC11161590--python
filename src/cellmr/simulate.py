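"""Seedable synthetic data with known ground truth for every stage.

Regional summary statistics are simulated directly at the z-score
level: for an LD matrix ``R`` and true (standardized, sparse) effect
z-scores ``z_true``, the observed marginal z-scores follow

    z ~ MVN(R @ z_true, R)

which is exactly the model the fine-mapping and colocalization math
assumes.  Betas and SEs are back-computed from z, minor-allele
frequency and sample size on the standardized-trait scale, so the
generated tables satisfy all reader invariants and round-trip through
the I/O layer.

The MR generator plants a causal effect ``true_beta`` and one of four
pleiotropy regimes (none, balanced, directional, outlier) into an
exposure/outcome instrument pair.

Defaults emulate the scale disparity of the studies this pipeline
targets: large-biobank GWAS (n ~ 1e5) against a few hundred donors of
single-cell eQTL data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import LDMatrix

NON_PALINDROMIC_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


@dataclass
class SimRegionConfig:
    """One genomic region with planted causal variants.

    ``causal_gwas``/``causal_eqtl`` give the planted SNP index per
    trait; ``shared_causal`` maps each context to whether its eQTL
    causal variant coincides with the GWAS one.
    """

    n_snps: int = 100
    block_size: int = 20
    rho: float = 0.9
    causal_index: int | None = None
    causal_z: float = 8.0
    contexts: dict[str, bool] = field(default_factory=lambda: {"cellA": True})
    eqtl_causal_z: float = 8.0
    n_gwas: float = 100_000
    n_eqtl: float = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.1
    chrom: str = "1"
    start_pos: int = 1_000_000
    gene: str = "GENE1"
    seed: int = 0


@dataclass
class SimMRConfig:
    """Exposure/outcome instrument tables with a planted causal effect."""

    k_iv: int = 20
    true_beta: float = 0.3
    gamma_sd: float = 0.1  # spread of true exposure effects
    gamma_min: float = 0.05  # keeps instruments strong (relevance)
    se_exp: float = 0.005
    se_out: float = 0.01
    pleiotropy: str = "none"  # none | balanced | directional | outlier
    tau: float = 0.05  # balanced pleiotropy SD
    delta: float = 0.1  # directional pleiotropy mean
    n_outliers: int = 1
    outlier_size: float = 10.0  # in units of se_out
    seed: int = 0


def simulate_ld(
    n_snps: int,
    block_size: int = 20,
    rho: float = 0.9,
    snp_ids: list[str] | None = None,
) -> LDMatrix:
    """Block-diagonal AR(1) correlation matrix: within a block,
    ``r(i, j) = rho ** |i - j|``; blocks are independent."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    r = np.zeros((n_snps, n_snps))
    for start in range(0, n_snps, block_size):
        end = min(start + block_size, n_snps)
        idx = np.arange(start, end)
        r[np.ix_(idx, idx)] = rho ** np.abs(np.subtract.outer(idx, idx))
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return LDMatrix(snp_ids, r)


def genotype_panel(
    ld: LDMatrix, n_samples: int, maf: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a diploid dosage panel realizing the target AR-block LD.

    Haplotype alleles follow a two-state Markov chain whose adjacent
    correlation equals the target neighbor LD; for binary chains the
    correlation then decays exactly geometrically with distance,
    matching the AR(1) block structure.  With strongly heterogeneous
    allele frequencies the conditional probabilities are clipped to
    [0, 1], which slightly attenuates the realized correlation.
    """
    maf = np.broadcast_to(np.asarray(maf, float), (len(ld.snp_ids),))
    p = len(ld.snp_ids)
    dosage = np.zeros((n_samples, p))
    adj = np.array([ld.r[j, j + 1] for j in range(p - 1)])
    for _ in range(2):  # two haplotypes
        hap = np.zeros((n_samples, p))
        hap[:, 0] = rng.random(n_samples) < maf[0]
        for j in range(p - 1):
            pj, pk, rho = maf[j], maf[j + 1], adj[j]
            scale = rho * np.sqrt(pk * (1 - pk) / (pj * (1 - pj)))
            cond = np.clip(pk + scale * (hap[:, j] - pj), 0.0, 1.0)
            hap[:, j + 1] = rng.random(n_samples) < cond
        dosage += hap
    return dosage


def write_vcf(
    path: str | Path,
    ld: LDMatrix,
    dosage: np.ndarray,
    chrom: str = "1",
    positions: np.ndarray | None = None,
) -> None:
    """Write a dosage panel as an uncompressed VCF v4.2 with GT fields."""
    n_samples, p = dosage.shape
    if positions is None:
        positions = np.arange(1, p + 1) * 1000
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i + 1}" for i in range(n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, snp in enumerate(ld.snp_ids):
            gts = "\t".join(gt_codes[int(d)] for d in dosage[:, j])
            fh.write(f"{chrom}\t{int(positions[j])}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def _alleles(n_snps: int, palindromic_fraction: float, rng: np.random.Generator):
    ea = np.empty(n_snps, dtype=object)
    oa = np.empty(n_snps, dtype=object)
    for i in range(n_snps):
        if rng.random() < palindromic_fraction:
            pair = PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))]
        else:
            pair = NON_PALINDROMIC_PAIRS[rng.integers(len(NON_PALINDROMIC_PAIRS))]
        if rng.random() < 0.5:
            pair = pair[::-1]
        ea[i], oa[i] = pair
    return ea, oa


def _z_to_table(
    z: np.ndarray,
    maf: np.ndarray,
    n: float,
    snp_ids: list[str],
    chrom: str,
    positions: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
) -> pd.DataFrame:
    # standardized-trait marginal regression: se = 1/sqrt(2 maf (1-maf) n)
    se = 1.0 / np.sqrt(2 * maf * (1 - maf) * n)
    beta = z * se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "snp": snp_ids,
            "chr": chrom,
            "pos": positions.astype(int),
            "ea": ea,
            "oa": oa,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "p": p,
            "n": float(n),
        }
    )


def simulate_region_sumstats(
    config: SimRegionConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict]:
    """Simulate one region's GWAS table, per-context eQTL tables, and a
    truth record holding everything planted.

    The GWAS causal variant is ``causal_index`` (block-center by
    default); each context's eQTL causal variant either coincides with
    it (``shared_causal``) or sits in a different LD block.
    """
    rng = np.random.default_rng(config.seed)
    p = config.n_snps
    ld = simulate_ld(p, config.block_size, config.rho,
                     snp_ids=[f"rs{config.seed}_{i + 1}" for i in range(p)])
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(p))
    maf = rng.uniform(*config.maf_range, size=p)
    positions = config.start_pos + np.arange(p) * 1000
    ea, oa = _alleles(p, config.palindromic_fraction, rng)

    causal = config.causal_index
    if causal is None:
        causal = config.block_size // 2

    def draw(z_true: np.ndarray) -> np.ndarray:
        return ld.r @ z_true + chol @ rng.standard_normal(p)

    z_true_gwas = np.zeros(p)
    z_true_gwas[causal] = config.causal_z
    z_gwas = draw(z_true_gwas)
    gwas = _z_to_table(z_gwas, maf, config.n_gwas, ld.snp_ids,
                       config.chrom, positions, ea, oa)

    eqtl: dict[str, pd.DataFrame] = {}
    truth = {
        "seed": config.seed,
        "gwas_causal": ld.snp_ids[causal],
        "z_true_gwas": z_true_gwas,
        "eqtl_causal": {},
        "ld": ld,
    }
    n_blocks = max(1, p // config.block_size)
    for context, shared in config.contexts.items():
        if shared:
            c_idx = causal
        else:
            # a different block, same within-block offset
            blk = (causal // config.block_size + 1 + hash(context) % max(1, n_blocks - 1)) % n_blocks
            c_idx = blk * config.block_size + causal % config.block_size
            if c_idx == causal:
                c_idx = (c_idx + config.block_size) % p
        z_true = np.zeros(p)
        z_true[c_idx] = config.eqtl_causal_z
        tab = _z_to_table(draw(z_true), maf, config.n_eqtl, ld.snp_ids,
                          config.chrom, positions, ea, oa)
        tab["gene"] = config.gene
        tab["context"] = context
        eqtl[context] = tab
        truth["eqtl_causal"][context] = ld.snp_ids[c_idx]
    return gwas, eqtl, truth


def simulate_mr_dataset(
    config: SimMRConfig,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a harmonized instrument table with planted causal effect.

    True exposure effects gamma_j are drawn with magnitude at least
    ``gamma_min`` (random sign); outcome effects are ``true_beta *
    gamma_j`` plus the configured pleiotropy term; observed effects add
    normal noise at the configured SEs.  Returns the table (columns of
    ``instruments.INSTRUMENT_COLUMNS``) and the truth record.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k_iv
    sign = rng.choice([-1.0, 1.0], size=k)
    gamma = sign * (config.gamma_min + np.abs(rng.normal(0, config.gamma_sd, size=k)))

    pleio = np.zeros(k)
    outlier_idx: list[int] = []
    if config.pleiotropy == "balanced":
        pleio = rng.normal(0, config.tau, size=k)
    elif config.pleiotropy == "directional":
        # directional in the exposure-increasing allele orientation: the
        # direct effect flips with the reported allele, like the betas do
        pleio = sign * rng.normal(config.delta, config.tau, size=k)
    elif config.pleiotropy == "outlier":
        outlier_idx = list(rng.choice(k, size=config.n_outliers, replace=False))
        pleio[outlier_idx] = config.outlier_size * config.se_out
    elif config.pleiotropy != "none":
        raise ValueError(f"unknown pleiotropy model {config.pleiotropy!r}")

    gamma_hat = gamma + rng.normal(0, config.se_exp, size=k)
    Gamma = config.true_beta * gamma + pleio
    Gamma_hat = Gamma + rng.normal(0, config.se_out, size=k)

    z_exp = gamma_hat / config.se_exp
    table = pd.DataFrame(
        {
            "snp": [f"rs{i + 1}" for i in range(k)],
            "ea": "A",
            "oa": "G",
            "eaf_exp": 0.3,
            "beta_exp": gamma_hat,
            "se_exp": config.se_exp,
            "p_exp": np.clip(2 * stats.norm.sf(np.abs(z_exp)), 1e-300, 1.0),
            "eaf_out": 0.3,
            "beta_out": Gamma_hat,
            "se_out": config.se_out,
            "context": "sim",
            "provenance": "original",
        }
    )
    truth = {
        "true_beta": config.true_beta,
        "gamma": gamma,
        "pleiotropy": pleio,
        "outlier_snps": [table["snp"].iloc[i] for i in outlier_idx],
        "seed": config.seed,
    }
    return table, truth


@dataclass
class SimPipelineConfig:
    """A full multi-region, multi-context dataset for end-to-end runs.

    Contexts listed in ``effect_contexts`` have their genes' eQTL
    signals share the GWAS causal variant, and the outcome GWAS carries
    a causal effect of the exposure routed through those variants; all
    other contexts get distinct causal variants and no effect.
    """

    contexts: tuple[str, ...] = ("cellA", "cellB")
    effect_contexts: tuple[str, ...] = ("cellA",)
    genes_per_context: int = 12
    true_beta: float = 0.5
    n_snps_per_region: int = 60
    block_size: int = 20
    rho: float = 0.9
    causal_z: float = 10.0
    eqtl_causal_z: float = 8.0
    n_gwas: float = 100_000
    n_eqtl: float = 200
    n_outcome: float = 100_000
    seed: int = 0


def simulate_pipeline_dataset(config: SimPipelineConfig):
    """Compose regional simulations into full pipeline inputs.

    Returns ``(exposure_gwas, eqtl_table, outcome_gwas, ld_by_region,
    truth)``.  Every gene occupies its own far-apart region (so index
    SNPs never clump with each other), with one causal variant shared
    between exposure GWAS and the eQTL of the gene's context.  The
    outcome effect at each exposure-causal variant is ``true_beta``
    times the exposure effect, with sampling noise at outcome-GWAS
    scale; elsewhere the outcome is null.
    """
    rng = np.random.default_rng(config.seed)
    gwas_parts, eqtl_parts, outcome_parts = [], [], []
    ld_by_region: dict[str, LDMatrix] = {}
    truth = {"causal_by_context": {}, "true_beta": config.true_beta,
             "effect_contexts": list(config.effect_contexts)}

    gene_no = 0
    for context in config.contexts:
        shared = context in config.effect_contexts
        truth["causal_by_context"][context] = []
        for _ in range(config.genes_per_context):
            gene_no += 1
            gene = f"GENE{gene_no}"
            region_seed = int(rng.integers(0, 2**31 - 1))
            rc = SimRegionConfig(
                n_snps=config.n_snps_per_region,
                block_size=config.block_size,
                rho=config.rho,
                causal_z=config.causal_z,
                eqtl_causal_z=config.eqtl_causal_z,
                contexts={context: shared},
                n_gwas=config.n_gwas,
                n_eqtl=config.n_eqtl,
                chrom=str((gene_no - 1) % 5 + 1),
                start_pos=1_000_000 + ((gene_no - 1) // 5) * 50_000_000,
                gene=gene,
                palindromic_fraction=0.0,
                seed=region_seed,
            )
            gwas, eqtl, rtruth = simulate_region_sumstats(rc)
            ld_by_region[gene] = rtruth["ld"]

            # outcome at the same SNPs: causal effect routed through the
            # exposure signal only where the context carries the effect
            p = len(gwas)
            se_out = 1.0 / np.sqrt(
                2 * gwas["eaf"].values * (1 - gwas["eaf"].values) * config.n_outcome
            )
            mean = np.zeros(p)
            if shared:
                # route the effect through the TRUE marginal exposure
                # effects so exposure and outcome noise stay independent
                se_exp = gwas["se"].values
                beta_marg_true = (rtruth["ld"].r @ rtruth["z_true_gwas"]) * se_exp
                mean = config.true_beta * beta_marg_true
            beta_out = mean + rng.normal(0, se_out)
            z_out = beta_out / se_out
            outcome = gwas.copy()
            outcome["beta"] = beta_out
            outcome["se"] = se_out
            outcome["p"] = np.clip(2 * stats.norm.sf(np.abs(z_out)), 1e-300, 1.0)
            outcome["n"] = config.n_outcome

            gwas_parts.append(gwas)
            outcome_parts.append(outcome)
            eqtl_parts.append(eqtl[context])
            truth["causal_by_context"][context].append(rtruth["gwas_causal"])

    exposure = pd.concat(gwas_parts, ignore_index=True)
    outcome = pd.concat(outcome_parts, ignore_index=True)
    eqtl_all = pd.concat(eqtl_parts, ignore_index=True)
    return exposure, eqtl_all, outcome, ld_by_region, truth
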