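"""Two-sample Mendelian randomization estimators and diagnostics.

Six complementary estimators — Wald ratio, inverse-variance weighted
(IVW) with a multiplicative random-effects model, MR-Egger, weighted
median, weighted mode, and the robust adjusted profile score (RAPS) —
plus the pleiotropy and heterogeneity diagnostics (Cochran's Q,
Rucker's Q', Egger intercept, the MR-PRESSO global test, leave-one-out)
and the decision tree that nominates the main method.

All estimators take a harmonized instrument table with columns
``beta_exp, se_exp, beta_out, se_out`` (see ``instruments``); effects
must already refer to the same effect alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import InputError

Z95 = stats.norm.ppf(0.975)

HUBER_K = 1.345
#: E[psi(Z) * Z] for standard-normal Z under the Huber score — the
#: centering constant of the overdispersion moment equation
HUBER_C1 = 2 * stats.norm.cdf(HUBER_K) - 1


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_iv: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    @classmethod
    def from_normal(cls, method: str, beta: float, se: float, n_iv: int, **kw) -> "MREstimate":
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        p = 2 * stats.norm.sf(abs(z)) if se > 0 else 0.0
        return cls(
            method=method, beta=beta, se=se,
            ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
            pvalue=float(p), n_iv=n_iv, **kw,
        )


@dataclass
class HeterogeneityStats:
    q: float = np.nan
    q_df: int = 0
    q_p: float = np.nan
    q_prime: float = np.nan
    q_prime_df: int = 0
    q_prime_p: float = np.nan


@dataclass
class PressoResult:
    rss_obs: float
    p_global: float
    n_sim: int
    seed: int


@dataclass
class MethodChoice:
    chosen: str
    rationale: str
    diagnostics: dict[str, float] = field(default_factory=dict)
    incomplete: bool = False


def _arrays(instruments: pd.DataFrame):
    bx = instruments["beta_exp"].to_numpy(dtype=float)
    by = instruments["beta_out"].to_numpy(dtype=float)
    sx = instruments["se_exp"].to_numpy(dtype=float)
    sy = instruments["se_out"].to_numpy(dtype=float)
    return bx, by, sx, sy


def wald_ratio(instruments: pd.DataFrame) -> MREstimate:
    """Single-instrument causal estimate ``beta_out / beta_exp`` with the
    first-order delta-method standard error ``se_out / |beta_exp|``."""
    if len(instruments) != 1:
        raise InputError("wald_ratio expects exactly one instrument")
    bx, by, _, sy = _arrays(instruments)
    if bx[0] == 0:
        raise InputError("exposure effect is zero; ratio undefined")
    return MREstimate.from_normal("wald", float(by[0] / bx[0]), float(sy[0] / abs(bx[0])), 1)


def ivw(instruments: pd.DataFrame) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance weighted estimate under a multiplicative
    random-effects model.

    Origin-constrained weighted regression of outcome on exposure
    effects with weights ``1/se_out^2``; residual heterogeneity
    (Cochran's Q on the radial scale) inflates the fixed-effect SE by
    ``max(1, sqrt(Q/(k-1)))``.
    """
    k = len(instruments)
    if k == 1:
        est = wald_ratio(instruments)
        return est, HeterogeneityStats(q=0.0, q_df=0, q_p=np.nan)
    if k < 1:
        raise InputError("ivw needs at least one instrument")
    bx, by, _, sy = _arrays(instruments)
    w = 1.0 / sy**2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w * bx**2)))
    q = float(np.sum(w * (by - beta * bx) ** 2))  # == radial Q
    q_df = k - 1
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    est = MREstimate.from_normal("ivw", beta, se_fixed * scale, k)
    het = HeterogeneityStats(q=q, q_df=q_df, q_p=float(stats.chi2.sf(q, q_df)) if q_df > 0 else np.nan)
    return est, het


def mr_egger(instruments: pd.DataFrame) -> tuple[MREstimate, HeterogeneityStats]:
    """MR-Egger regression: weighted regression with intercept, oriented
    so all exposure effects are positive.

    The slope is the causal estimate under the InSIDE assumption; the
    intercept estimates the average directional pleiotropy.  Residual
    heterogeneity (Rucker's Q') scales the SEs multiplicatively as in
    :func:`ivw`.
    """
    k = len(instruments)
    if k < 3:
        raise InputError("mr_egger needs at least 3 instruments")
    bx, by, _, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    q_prime = float(np.sum(w * resid**2))
    q_df = k - 2
    scale = max(1.0, np.sqrt(q_prime / q_df)) if q_df > 0 else 1.0
    cov = np.linalg.inv(xtx) * scale**2
    se_slope = float(np.sqrt(cov[1, 1]))
    se_int = float(np.sqrt(cov[0, 0]))
    est = MREstimate.from_normal(
        "egger", float(coef[1]), se_slope, k,
        intercept=float(coef[0]), intercept_se=se_int,
        intercept_p=float(2 * stats.norm.sf(abs(coef[0] / se_int))) if se_int > 0 else 0.0,
    )
    het = HeterogeneityStats(
        q_prime=q_prime, q_prime_df=q_df,
        q_prime_p=float(stats.chi2.sf(q_prime, q_df)) if q_df > 0 else np.nan,
    )
    return est, het


def _weighted_percentile(ratios: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Weighted quantile with linear interpolation between bracketing
    order statistics (midpoint convention on the cumulative weights)."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    if q <= cum[0]:
        return float(r[0])
    if q >= cum[-1]:
        return float(r[-1])
    return float(np.interp(q, cum, r))


def weighted_median(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator: consistent when at least half the
    total instrument weight comes from valid instruments.

    The point estimate is the inverse-variance-weighted 50th percentile
    of the per-SNP ratio estimates; the SE comes from a seeded
    parametric bootstrap over the summary statistics.
    """
    k = len(instruments)
    if k < 3:
        raise InputError("weighted_median needs at least 3 instruments")
    bx, by, sx, sy = _arrays(instruments)
    ratios = by / bx
    weights = bx**2 / sy**2  # inverse of first-order ratio variance
    beta = _weighted_percentile(ratios, weights)
    boots = _bootstrap_ratio_statistic(
        bx, by, sx, sy, lambda r, w: _weighted_percentile(r, w), n_boot, seed
    )
    se = float(np.std(boots, ddof=1))
    ci = np.percentile(boots, [2.5, 97.5])
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return MREstimate(
        "wmedian", beta, se, float(ci[0]), float(ci[1]), float(p), k
    )


def _weighted_mad_scale(ratios: np.ndarray, weights: np.ndarray) -> float:
    med = _weighted_percentile(ratios, weights)
    return 1.4826 * _weighted_percentile(np.abs(ratios - med), weights)


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    scale = _weighted_mad_scale(ratios, weights)
    if scale == 0:
        return float(ratios[0])
    h = bandwidth_factor * 0.9 * scale * len(ratios) ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    # argmax; exact density ties resolve toward the smaller ratio
    return float(grid[np.argmax(dens)])


def weighted_mode(
    instruments: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimator: consistent when the largest group of
    instruments sharing a ratio is valid.

    A Gaussian kernel density over the ratio estimates, weighted by
    inverse ratio variance with bandwidth proportional to a weighted
    MAD scale, is maximized on a fine grid; SE by seeded parametric
    bootstrap.
    """
    k = len(instruments)
    if k < 3:
        raise InputError("weighted_mode needs at least 3 instruments")
    bx, by, sx, sy = _arrays(instruments)
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _mode_estimate(ratios, weights, bandwidth_factor)
    boots = _bootstrap_ratio_statistic(
        bx, by, sx, sy, lambda r, w: _mode_estimate(r, w, bandwidth_factor), n_boot, seed
    )
    se = float(np.std(boots, ddof=1))
    ci = np.percentile(boots, [2.5, 97.5])
    p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else 0.0
    return MREstimate("wmode", beta, se, float(ci[0]), float(ci[1]), float(p), k)


def _bootstrap_ratio_statistic(bx, by, sx, sy, statistic, n_boot: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(by, sy)
        bx_s = np.where(bx_s == 0, np.finfo(float).tiny, bx_s)
        out[b] = statistic(by_s / bx_s, bx_s**2 / sy**2)
    return out


def _huber_psi(t: np.ndarray) -> np.ndarray:
    return np.clip(t, -HUBER_K, HUBER_K)


def mr_raps(
    instruments: pd.DataFrame,
    overdispersion: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score estimating equations in the causal effect
    beta and (optionally) an overdispersion variance tau^2 >= 0, with
    standardized residuals ``t_j = (beta_out_j - beta*beta_exp_j) /
    sqrt(se_out_j^2 + beta^2 se_exp_j^2 + tau^2)`` robustified by the
    Huber score (tuning constant 1.345).  The SE is the sandwich
    variance of the profile score.
    """
    k = len(instruments)
    if k < 3:
        raise InputError("mr_raps needs at least 3 instruments")
    bx, by, sx, sy = _arrays(instruments)

    def tstat(beta: float, tau2: float) -> tuple[np.ndarray, np.ndarray]:
        v = sy**2 + beta**2 * sx**2 + tau2
        return (by - beta * bx) / np.sqrt(v), v

    def score_beta(beta: float, tau2: float) -> float:
        t, v = tstat(beta, tau2)
        return float(np.sum(_huber_psi(t) * bx / np.sqrt(v)))

    def score_tau(tau2: float, beta: float) -> float:
        t, v = tstat(beta, tau2)
        return float(np.sum((_huber_psi(t) * t - HUBER_C1) / v))

    # blockwise iteration: beta given tau2 by bracketed root, tau2 by moment eq
    beta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    tau2 = 0.0
    span = max(10.0, 10 * abs(beta) + 10)
    for _ in range(max_iter):
        beta_old, tau2_old = beta, tau2
        lo, hi = beta - span, beta + span
        if score_beta(lo, tau2) * score_beta(hi, tau2) > 0:
            raise InputError("mr_raps profile score has no root in bracket")
        beta = optimize.brentq(lambda b: score_beta(b, tau2), lo, hi, xtol=1e-12)
        if overdispersion:
            if score_tau(0.0, beta) <= 0:
                tau2 = 0.0  # moment equation satisfied at the boundary
            else:
                hi_t = 1.0
                while score_tau(hi_t, beta) > 0 and hi_t < 1e6:
                    hi_t *= 10
                tau2 = optimize.brentq(lambda t2: score_tau(t2, beta), 0.0, hi_t, xtol=1e-12)
        if abs(beta - beta_old) < tol and abs(tau2 - tau2_old) < tol:
            break
    else:
        raise InputError("mr_raps failed to converge")

    # sandwich variance of the beta profile score
    t, v = tstat(beta, tau2)
    psi = _huber_psi(t)
    bread = _numeric_derivative(lambda b: score_beta(b, tau2), beta)
    meat = float(np.sum((psi * bx / np.sqrt(v)) ** 2))
    se = float(np.sqrt(meat) / abs(bread)) if bread != 0 else np.nan
    return MREstimate.from_normal("raps", beta, se, k)


def _numeric_derivative(f, x: float, eps: float = 1e-6) -> float:
    h = eps * max(1.0, abs(x))
    return (f(x + h) - f(x - h)) / (2 * h)


def cochran_q(instruments: pd.DataFrame) -> HeterogeneityStats:
    """Cochran's Q of the fixed-effect IVW fit, chi-square(k-1)."""
    _, het = ivw(instruments)
    return het


def rucker_q(instruments: pd.DataFrame) -> HeterogeneityStats:
    """Rucker's Q' of the MR-Egger fit, chi-square(k-2)."""
    _, het = mr_egger(instruments)
    return het


def heterogeneity(instruments: pd.DataFrame) -> HeterogeneityStats:
    """Both heterogeneity statistics in one record (Q' requires >= 3 IVs)."""
    het = cochran_q(instruments)
    if len(instruments) >= 3:
        hp = rucker_q(instruments)
        het.q_prime, het.q_prime_df, het.q_prime_p = hp.q_prime, hp.q_prime_df, hp.q_prime_p
    return het


def egger_intercept_test(instruments: pd.DataFrame) -> tuple[float, float, float]:
    """Directional-pleiotropy test: the MR-Egger intercept, its SE and p."""
    est, _ = mr_egger(instruments)
    return est.intercept, est.intercept_se, est.intercept_p


def presso_global(
    instruments: pd.DataFrame, n_sim: int = 1000, seed: int = 0
) -> PressoResult:
    """MR-PRESSO global test for horizontal pleiotropy.

    The observed statistic is the weighted residual sum of squares with
    each instrument's expectation from the IVW fit that leaves it out;
    the null distribution is simulated parametrically by redrawing the
    summary statistics around their leave-one-out expectations.  The
    Monte-Carlo p carries the +1 correction, so its resolution is
    ``1/(n_sim + 1)`` and it is never exactly zero.
    """
    k = len(instruments)
    if k < 4:
        raise InputError("presso_global needs at least 4 instruments")
    bx, by, sx, sy = _arrays(instruments)
    w = 1.0 / sy**2

    def loo_betas(bxa: np.ndarray, bya: np.ndarray) -> np.ndarray:
        num = np.sum(w * bxa * bya)
        den = np.sum(w * bxa**2)
        return (num - w * bxa * bya) / (den - w * bxa**2)

    def rss(bxa: np.ndarray, bya: np.ndarray) -> float:
        b_loo = loo_betas(bxa, bya)
        return float(np.sum(w * (bya - b_loo * bxa) ** 2))

    rss_obs = rss(bx, by)
    b_loo = loo_betas(bx, by)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_sim):
        bx_s = rng.normal(bx, sx)
        by_s = rng.normal(b_loo * bx, sy)
        if rss(bx_s, by_s) >= rss_obs:
            exceed += 1
    p = (1 + exceed) / (n_sim + 1)
    return PressoResult(rss_obs=rss_obs, p_global=p, n_sim=n_sim, seed=seed)


def leave_one_out(
    instruments: pd.DataFrame, sig_threshold: float = 0.05
) -> pd.DataFrame:
    """Leave-one-out sensitivity table: the IVW estimate without each SNP.

    Flags exclusions that flip the sign of the estimate or move its p
    across ``sig_threshold`` relative to the full-set fit.
    """
    k = len(instruments)
    if k < 3:
        raise InputError("leave_one_out needs at least 3 instruments")
    full, _ = ivw(instruments)
    rows = []
    for i in range(k):
        sub = instruments.drop(instruments.index[i])
        est, _ = ivw(sub)
        rows.append(
            {
                "excluded_snp": instruments.iloc[i]["snp"],
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "flag": (np.sign(est.beta) != np.sign(full.beta))
                or ((est.pvalue < sig_threshold) != (full.pvalue < sig_threshold)),
            }
        )
    return pd.DataFrame(rows)


def select_main_method(
    n_iv: int,
    q_p: float | None,
    egger_intercept_p: float | None,
    presso_p: float | None,
    q_prime_p: float | None,
    alpha: float = 0.05,
) -> MethodChoice:
    """Nominate the main MR method from the pleiotropy diagnostics.

    Branches, in order:

    1. a single instrument -> Wald ratio;
    2. no pleiotropy signal (Cochran Q, Egger intercept and PRESSO all
       p > alpha) -> IVW;
    3. pleiotropy detected but the Egger fit is adequate (Rucker Q'
       p > alpha) -> MR-Egger;
    4. pleiotropy detected and Q' p < alpha -> weighted median
       (preferred over weighted mode for power).

    A diagnostic that could not be computed (e.g. PRESSO below 4 IVs)
    counts as non-significant but marks the choice diagnostic-incomplete.
    """
    diagnostics = {
        "q_p": q_p, "egger_intercept_p": egger_intercept_p,
        "presso_p": presso_p, "q_prime_p": q_prime_p,
    }
    if n_iv == 1:
        return MethodChoice("wald", "single instrument", diagnostics)

    incomplete = any(
        v is None or (isinstance(v, float) and np.isnan(v))
        for v in (q_p, egger_intercept_p, presso_p)
    )

    def sig(p):
        return p is not None and not np.isnan(p) and p < alpha

    if not (sig(q_p) or sig(egger_intercept_p) or sig(presso_p)):
        return MethodChoice(
            "ivw", "no directional pleiotropy detected", diagnostics, incomplete
        )
    if q_prime_p is None or np.isnan(q_prime_p):
        raise InputError(
            "pleiotropy detected but Rucker Q' unavailable; cannot resolve the decision tree"
        )
    if q_prime_p > alpha:
        return MethodChoice(
            "egger", "pleiotropy detected, Egger residual heterogeneity acceptable",
            diagnostics, incomplete,
        )
    return MethodChoice(
        "wmedian", "pleiotropy detected and Egger heterogeneity significant",
        diagnostics, incomplete,
    )


def run_all_estimators(
    instruments: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> dict[str, MREstimate]:
    """All applicable estimators for an instrument table, keyed by method."""
    k = len(instruments)
    out: dict[str, MREstimate] = {}
    if k == 0:
        return out
    if k == 1:
        out["wald"] = wald_ratio(instruments)
        return out
    est_ivw, _ = ivw(instruments)
    out["ivw"] = est_ivw
    if k >= 3:
        out["egger"] = mr_egger(instruments)[0]
        out["wmedian"] = weighted_median(instruments, n_boot=n_boot, seed=seed)
        out["wmode"] = weighted_mode(instruments, n_boot=n_boot, seed=seed + 1)
        try:
            out["raps"] = mr_raps(instruments)
        except InputError:
            pass  # non-convergence: estimator reported unavailable
    return out
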