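"""Bayesian colocalization of a GWAS signal with an eQTL signal.

Per-SNP evidence is an asymptotic (Wakefield) Bayes factor computed
from each variant's effect estimate and standard error under a normal
effect prior.  The five-hypothesis enumeration then weighs, for each
region,

    H0  no association with either trait
    H1  association with trait 1 (GWAS) only
    H2  association with trait 2 (eQTL) only
    H3  both traits associated, distinct causal variants
    H4  both traits associated, a shared causal variant

All Bayes-factor accumulation happens in log space, so the posteriors
are stable for |z| well beyond 30.  When fine-mapping yields credible
sets on both sides, every credible-set pair is colocalized separately
using that effect's per-SNP single-effect Bayes factors, which is the
multiple-causal-variant mode; otherwise the single-causal-variant
enumeration on marginal Bayes factors applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import CredibleSet, SusieFit
from .sumstats import InputError

HYPOTHESES = ("pph0", "pph1", "pph2", "pph3", "pph4")


@dataclass
class ABFParams:
    """Priors of the colocalization model.

    ``prior_sd_quant``/``prior_sd_cc`` are the prior standard deviations
    of true effect sizes for quantitative and binary (log-odds scale)
    traits; ``p1``, ``p2``, ``p12`` are the per-SNP prior probabilities
    of association with trait 1 only, trait 2 only, or both.
    """

    prior_sd_quant: float = 0.15
    prior_sd_cc: float = 0.2
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if min(self.prior_sd_quant, self.prior_sd_cc, self.p1, self.p2, self.p12) <= 0:
            raise InputError("ABF priors must be positive")
        if self.p1 + self.p2 + self.p12 > 1:
            raise InputError("p1 + p2 + p12 must not exceed 1")

    def prior_sd(self, trait_type: str) -> float:
        return self.prior_sd_cc if trait_type == "cc" else self.prior_sd_quant


@dataclass
class ColocResult:
    pph: dict[str, float]
    per_snp_h4: pd.Series  # indexed by snp id, sums to 1
    n_snps: int
    mode: str = "abf"  # "abf" | "susie"
    signal_pair: tuple[int, int] | None = None
    trait1_p: pd.Series | None = None  # trait-1 p-values for tie-breaking

    @property
    def pph4(self) -> float:
        return self.pph["pph4"]


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Natural-log asymptotic Bayes factor for association of one variant.

    With sampling variance ``V = se**2``, prior variance ``W =
    prior_sd**2`` and shrinkage ``r = W/(V+W)``, the log Bayes factor in
    favor of association is ``0.5*log(1-r) + r*z**2/2``.
    """
    if np.any(np.asarray(se) <= 0):
        raise InputError("se must be positive")
    v = np.square(se)
    w = prior_sd**2
    r = w / (v + w)
    z2 = np.square(np.asarray(beta) / se)
    return 0.5 * np.log1p(-r) + 0.5 * r * z2


def _enumerate_hypotheses(
    lbf1: np.ndarray, lbf2: np.ndarray, params: ABFParams
) -> tuple[dict[str, float], np.ndarray]:
    """Posterior over H0..H4 from per-SNP log Bayes factors of each trait."""
    ls1 = logsumexp(lbf1)
    ls2 = logsumexp(lbf2)
    lboth = logsumexp(lbf1 + lbf2)

    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(params.p1) + ls1
    lh[2] = np.log(params.p2) + ls2
    # sum over ordered distinct pairs: S1*S2 - sum_i BF1_i*BF2_i
    ratio = np.exp(lboth - ls1 - ls2)
    if ratio < 1.0:
        lh[3] = np.log(params.p1) + np.log(params.p2) + ls1 + ls2 + np.log1p(-ratio)
    else:  # single-SNP region: no distinct-variant pairing exists
        lh[3] = -np.inf
    lh[4] = np.log(params.p12) + lboth

    norm = logsumexp(lh[np.isfinite(lh)])
    pph = {h: float(np.exp(v - norm)) if np.isfinite(v) else 0.0 for h, v in zip(HYPOTHESES, lh)}
    joint = lbf1 + lbf2
    per_snp = np.exp(joint - logsumexp(joint))
    return pph, per_snp


def _intersect(trait1: pd.DataFrame, trait2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    shared = trait1.merge(trait2[["snp"]], on="snp")["snp"]
    if shared.empty:
        raise InputError("no shared SNPs between the two traits")
    t1 = trait1.set_index("snp").loc[shared]
    t2 = trait2.set_index("snp").loc[shared]
    return t1, t2


def coloc_abf(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    params: ABFParams | None = None,
    trait1_type: str = "quant",
    trait2_type: str = "quant",
) -> ColocResult:
    """Single-causal-variant colocalization on marginal Bayes factors.

    ``trait1`` is the GWAS, ``trait2`` the eQTL table, both in canonical
    form; they are intersected on shared SNP ids (allele orientation is
    assumed consistent — harmonize upstream).
    """
    params = params or ABFParams()
    t1, t2 = _intersect(trait1, trait2)
    lbf1 = np.asarray(log_abf(t1["beta"].values, t1["se"].values, params.prior_sd(trait1_type)))
    lbf2 = np.asarray(log_abf(t2["beta"].values, t2["se"].values, params.prior_sd(trait2_type)))
    pph, per_snp = _enumerate_hypotheses(lbf1, lbf2, params)
    return ColocResult(
        pph=pph,
        per_snp_h4=pd.Series(per_snp, index=t1.index),
        n_snps=len(t1),
        mode="abf",
        trait1_p=t1["p"],
    )


def coloc_susie(
    fit1: SusieFit,
    sets1: list[CredibleSet],
    fit2: SusieFit,
    sets2: list[CredibleSet],
    params: ABFParams | None = None,
    trait1_p: pd.Series | None = None,
) -> list[ColocResult]:
    """Credible-set-pairwise colocalization for multiple causal variants.

    For every pair of surviving credible sets (one per trait), the
    five-hypothesis enumeration runs on the per-SNP single-effect log
    Bayes factors of the corresponding effects.  Returns one result per
    pair; empty when either trait has no credible set (callers fall back
    to :func:`coloc_abf`).
    """
    params = params or ABFParams()
    if not sets1 or not sets2:
        return []
    if fit1.snp_ids != fit2.snp_ids:
        shared = [s for s in fit1.snp_ids if s in set(fit2.snp_ids)]
        if not shared:
            raise InputError("fits share no SNPs")
        i1 = [fit1.snp_ids.index(s) for s in shared]
        i2 = [fit2.snp_ids.index(s) for s in shared]
    else:
        shared = fit1.snp_ids
        i1 = i2 = list(range(len(shared)))

    results = []
    for cs1 in sets1:
        for cs2 in sets2:
            lbf1 = fit1.lbf[cs1.effect_index][i1]
            lbf2 = fit2.lbf[cs2.effect_index][i2]
            pph, per_snp = _enumerate_hypotheses(lbf1, lbf2, params)
            results.append(
                ColocResult(
                    pph=pph,
                    per_snp_h4=pd.Series(per_snp, index=shared),
                    n_snps=len(shared),
                    mode="susie",
                    signal_pair=(cs1.effect_index, cs2.effect_index),
                    trait1_p=trait1_p.reindex(shared) if trait1_p is not None else None,
                )
            )
    return results


def classify_coloc(result: ColocResult, threshold: float = 0.8) -> bool:
    """Strong colocalization evidence: PPH4 strictly above the threshold."""
    return result.pph4 > threshold


def top_causal_snp(result: ColocResult) -> str:
    """The SNP most likely to be the shared causal variant under H4.

    Ties on the per-SNP posterior break by smaller trait-1 p-value,
    then lexicographic SNP id.  Only meaningful for colocalized results.
    """
    if not classify_coloc(result):
        raise ValueError("top_causal_snp requires a colocalized result")
    h4 = result.per_snp_h4
    best = h4.max()
    tied = h4.index[np.isclose(h4.values, best, rtol=0, atol=0)]
    if len(tied) > 1 and result.trait1_p is not None:
        p = result.trait1_p.reindex(tied)
        tied = p.index[p == p.min()]
    return sorted(tied)[0]
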