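"""Sum-of-single-effects (SuSiE) fine-mapping from z-scores and LD.

Fits the regression-with-summary-statistics model in which the observed
regional z-scores satisfy ``z ~ N(R b, R)`` for LD matrix ``R`` and a
sparse effect vector ``b`` written as a sum of ``L`` single effects.
Each single effect places all its mass on one SNP, with a normal prior
``N(0, sigma0_sq)`` on the effect size; the per-effect prior variance is
estimated by maximizing the single-effect marginal likelihood and
floored at zero so that null effects collapse to a uniform inclusion
vector and report no credible set.

The iterative Bayesian stepwise selection (IBSS) updates each effect
against the residualized z-scores, and the variational objective (ELBO)
is tracked to guarantee monotone convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .sumstats import InputError, LDMatrix


class FitError(RuntimeError):
    """Fine-mapping failed (e.g. badly conditioned LD matrix)."""


@dataclass
class SusieFit:
    """Result of a SuSiE fit.

    Attributes
    ----------
    alpha
        ``L x p`` matrix; row ``l`` is the posterior probability that
        each SNP carries single effect ``l`` (rows sum to 1).
    post_mean
        ``L x p`` posterior mean effect sizes (already weighted by alpha).
    lbf
        ``L x p`` per-SNP log Bayes factors of each single effect, the
        quantities consumed by credible-set-pairwise colocalization.
    pip
        Per-SNP posterior inclusion probability
        ``1 - prod_l (1 - alpha[l, i])``.
    sigma0_sq
        Estimated prior variance per effect; 0 marks a null effect.
    """

    snp_ids: list[str]
    alpha: np.ndarray
    post_mean: np.ndarray
    lbf: np.ndarray
    pip: np.ndarray
    sigma0_sq: np.ndarray
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False


@dataclass
class CredibleSet:
    effect_index: int
    snp_ids: list[str]
    coverage_attained: float
    purity: float


def _lse(x: np.ndarray) -> float:
    m = x.max()
    return float(m + np.log(np.sum(np.exp(x - m))))


def _single_effect_update(
    resid_z: np.ndarray, prior_var_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Bayesian single-effect regression against residual z-scores.

    With standardized sufficient statistics each SNP's marginal estimate
    is the residual z itself with unit sampling variance, so the log
    Bayes factor under prior variance V is
    ``0.5 * log(1/(1+V)) + 0.5 * z^2 * V/(1+V)``.
    Returns (alpha, mu, mu2, sigma0_sq, loglik_total).
    """
    p = resid_z.size
    log_prior = -np.log(p)  # uniform

    z2 = resid_z**2

    def neg_marginal(log_v: float) -> float:
        v = np.exp(log_v)
        lbf = 0.5 * np.log1p(-v / (1 + v)) + 0.5 * z2 * v / (1 + v)
        return -_lse(log_prior + lbf)

    res = minimize_scalar(
        neg_marginal, bounds=(-10.0, np.log(max(prior_var_max, 1e-3))),
        method="bounded", options={"xatol": 1e-6},
    )
    v = float(np.exp(res.x))
    # floor the prior variance at 0: if the optimum does not beat the
    # point-null (all BFs = 1), declare the effect null
    if -res.fun <= 0.0:
        v = 0.0
        lbf = np.zeros(p)
        alpha = np.full(p, 1.0 / p)
        mu = np.zeros(p)
        mu2 = np.zeros(p)
        return alpha, mu, mu2, 0.0, 0.0

    lbf = 0.5 * np.log(1.0 / (1 + v)) + 0.5 * resid_z**2 * v / (1 + v)
    w = log_prior + lbf
    total = _lse(w)
    alpha = np.exp(w - total)
    shrink = v / (1 + v)
    mu = shrink * resid_z  # conditional posterior mean given inclusion
    mu2 = shrink + mu**2
    return alpha, mu, mu2, v, float(total)


def susie_rss(
    z: np.ndarray,
    ld: LDMatrix,
    L: int = 10,
    max_iter: int = 100,
    tol: float = 1e-3,
    ridge: float = 1e-6,
) -> SusieFit:
    """Fit the sum-of-single-effects model to regional z-scores.

    Parameters
    ----------
    z
        Per-SNP z-scores, same order as ``ld.snp_ids``.
    L
        Maximum number of single effects.
    tol
        Convergence threshold on the change in the variational objective.
    ridge
        Added to the LD diagonal when the matrix is not numerically PSD.
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise InputError("z-scores contain NaN")
    p = z.size
    if len(ld.snp_ids) != p:
        raise InputError(f"{p} z-scores but {len(ld.snp_ids)} SNPs in LD")
    if L < 1:
        raise InputError("L must be >= 1")
    L = min(L, p)

    R = np.asarray(ld.r, dtype=float)
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -1e-8:
        if min_eig < -0.05:
            raise FitError(
                f"LD matrix strongly non-PSD (min eigenvalue {min_eig:.3g}); "
                "supply a valid correlation matrix or increase ridge regularization"
            )
        R = R + (ridge - min_eig) * np.eye(p)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)

    prior_var_max = max(float(np.max(z**2)), 1.0)

    alpha = np.full((L, p), 1.0 / p)
    mu = np.zeros((L, p))
    mu2 = np.zeros((L, p))
    lbf = np.zeros((L, p))
    sigma0 = np.zeros(L)
    b_bar = np.zeros(p)  # sum over effects of alpha * mu

    elbo_trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        for l in range(L):
            b_l = alpha[l] * mu[l]
            b_bar -= b_l
            resid = z - R @ b_bar
            a, m, m2, v, _ = _single_effect_update(resid, prior_var_max)
            alpha[l], mu[l], mu2[l] = a, m, m2
            sigma0[l] = v
            if v > 0:
                lbf[l] = 0.5 * np.log(1.0 / (1 + v)) + 0.5 * resid**2 * v / (1 + v)
            else:
                lbf[l] = 0.0
            b_bar += alpha[l] * mu[l]

        elbo = _elbo(z, R, alpha, mu, mu2, sigma0, b_bar)
        elbo_trace.append(elbo)
        if len(elbo_trace) > 1 and abs(elbo_trace[-1] - elbo_trace[-2]) < tol:
            converged = True
            break

    pip = 1.0 - np.prod(1.0 - alpha, axis=0)
    return SusieFit(
        snp_ids=list(ld.snp_ids),
        alpha=alpha,
        post_mean=alpha * mu,
        lbf=lbf,
        pip=pip,
        sigma0_sq=sigma0,
        elbo_trace=elbo_trace,
        converged=converged,
    )


def _elbo(
    z: np.ndarray,
    R: np.ndarray,
    alpha: np.ndarray,
    mu: np.ndarray,
    mu2: np.ndarray,
    sigma0: np.ndarray,
    b_bar: np.ndarray,
) -> float:
    """Variational objective ``E[log p(z|b)] - sum_l KL_l`` up to a
    constant in z.

    The KL of single effect ``l`` against its prior (uniform SNP choice,
    ``N(0, sigma0_sq)`` effect) decomposes into a categorical term and a
    per-SNP normal-vs-normal term; a null effect (prior variance 0) has
    KL exactly zero by construction.
    """
    b_eff = alpha * mu  # L x p
    # E[b' R b] for the sum of independent single effects
    quad_cross = b_bar @ R @ b_bar - np.einsum("lp,pq,lq->", b_eff, R, b_eff)
    quad_self = np.sum(alpha * mu2)  # diag(R) = 1
    e_loglik = -0.5 * (z @ z) + b_bar @ z - 0.5 * (quad_cross + quad_self)

    p = z.size
    kl = 0.0
    for l in range(alpha.shape[0]):
        v = sigma0[l]
        if v <= 0:
            continue  # q equals the prior for a null effect
        a = alpha[l]
        nz = a > 0
        kl_cat = float(np.sum(a[nz] * (np.log(a[nz]) + np.log(p))))
        # conditional posterior is N(mu_j, v/(1+v)); prior N(0, v)
        kl_norm = 0.5 * (np.log1p(v) + mu2[l] / v - 1.0)
        kl += kl_cat + float(np.sum(a * kl_norm))
    return float(e_loglik - kl)


def credible_sets(
    fit: SusieFit,
    ld: LDMatrix,
    coverage: float = 0.9,
    min_purity: float = 0.5,
) -> list[CredibleSet]:
    """Extract level-``coverage`` credible sets from a SuSiE fit.

    For each non-null effect, SNPs are ranked by inclusion probability
    and the smallest prefix whose cumulative mass reaches ``coverage``
    forms the set.  Sets whose minimum absolute pairwise LD (purity)
    falls below ``min_purity`` are discarded, as are duplicates.
    """
    index = {s: i for i, s in enumerate(ld.snp_ids)}
    sets: list[CredibleSet] = []
    seen: set[frozenset[str]] = set()
    for l in range(fit.alpha.shape[0]):
        if fit.sigma0_sq[l] <= 0:
            continue  # null effect: uniform alpha, no set
        order = np.argsort(-fit.alpha[l], kind="stable")
        cum = np.cumsum(fit.alpha[l][order])
        k = int(np.searchsorted(cum, coverage) + 1)
        k = min(k, len(order))
        members = [fit.snp_ids[i] for i in order[:k]]
        attained = float(cum[k - 1])
        if attained < coverage:
            continue
        idx = np.array([index[s] for s in members])
        sub = np.abs(ld.r[np.ix_(idx, idx)])
        purity = float(sub.min()) if len(idx) > 1 else 1.0
        if purity < min_purity:
            continue
        key = frozenset(members)
        if key in seen:
            continue
        seen.add(key)
        sets.append(
            CredibleSet(
                effect_index=l,
                snp_ids=members,
                coverage_attained=attained,
                purity=purity,
            )
        )
    return sets
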