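"""Univariable two-sample Mendelian randomization estimators.

All estimators consume a :class:`~tsmr.gwas_io.HarmonizedSet` and return
:class:`MrResult` objects carrying the causal estimate on the outcome's
scale (log-odds for binary outcomes), its standard error, a p-value, the
Wald-type 95% CI (beta ± 1.96·se) and the exponentiated odds-ratio view.

The inverse-variance-weighted (IVW) estimate is the weighted regression of
outcome effects on exposure effects through the origin with weights
1/se_outcome², i.e. the precision-weighted consolidation of the per-SNP
Wald ratios.  Both the fixed-effect SE and the multiplicative
random-effects (MRE) SE — the fixed SE inflated by max(1, sqrt(Q/(k−1)))
— are always produced; the headline pick between them is auditable via
:func:`ivw_headline`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .gwas_io import HarmonizedSet

__all__ = [
    "MrResult",
    "wald_ratio",
    "ivw",
    "ivw_headline",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "effect_to_or",
    "Z95",
]

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile used for all reported 95% intervals

_P_FLOOR = 5e-324  # smallest subnormal; keeps p in (0, 1]


@dataclass(frozen=True)
class MrResult:
    """One estimator's output."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    or_: float = field(default=math.nan)
    or_low: float = field(default=math.nan)
    or_high: float = field(default=math.nan)
    extra: Mapping[str, float | str] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


def _two_sided_normal_p(z: float) -> float:
    return float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)))


def _two_sided_t_p(t: float, df: int) -> float:
    return float(min(1.0, max(2.0 * stats.t.sf(abs(t), df), _P_FLOOR)))


def _make_result(
    method: str,
    beta: float,
    se: float,
    n_snp: int,
    pval: float | None = None,
    df: int | None = None,
    extra: Mapping[str, float | str] | None = None,
) -> MrResult:
    if pval is None:
        z = beta / se
        pval = _two_sided_t_p(z, df) if df is not None else _two_sided_normal_p(z)
    lo, hi = beta - Z95 * se, beta + Z95 * se
    return MrResult(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=float(pval),
        n_snp=n_snp,
        ci_low=lo,
        ci_high=hi,
        or_=math.exp(beta),
        or_low=math.exp(lo),
        or_high=math.exp(hi),
        extra=dict(extra or {}),
    )


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sex: float, by: float, sey: float) -> MrResult:
    """Single-SNP causal estimate: by/bx with first-order SE sey/|bx|.

    The exposure SE ``sex`` is accepted for interface symmetry but does
    not enter the first-order SE.
    """
    if bx == 0:
        raise ValueError("degenerate instrument: exposure beta is zero")
    beta = by / bx
    se = sey / abs(bx)
    return _make_result("wald", beta, se, n_snp=1)


def _ivw_core(hset: HarmonizedSet) -> tuple[float, float, float]:
    """Return (beta, fixed se, Q)."""
    w = hset.se_outcome**-2
    bx, by = hset.beta_exposure, hset.beta_outcome
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se_fixed = s_xx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(hset: HarmonizedSet) -> tuple[MrResult, MrResult]:
    """Inverse-variance-weighted estimate, fixed and MRE variants.

    Both share the point estimate; the MRE SE is the fixed SE times
    max(1, sqrt(Q/(k−1))) with Q the IVW Cochran statistic.  With a single
    SNP this falls back to the Wald ratio (logged).
    """
    if hset.n_snp < 2:
        logger.info("ivw: single SNP, falling back to Wald ratio")
        res = wald_ratio(
            float(hset.beta_exposure[0]),
            float(hset.se_exposure[0]),
            float(hset.beta_outcome[0]),
            float(hset.se_outcome[0]),
        )
        note = {"note": "single-SNP fallback to Wald ratio"}
        fixed = _make_result("ivw_fixed", res.beta, res.se, 1, extra=note)
        return fixed, _make_result("ivw_mre", res.beta, res.se, 1, extra=note)
    beta, se_fixed, q = _ivw_core(hset)
    k = hset.n_snp
    scale = max(1.0, math.sqrt(q / (k - 1)))
    extra = {"q": q, "q_df": k - 1, "mre_scale": scale}
    fixed = _make_result("ivw_fixed", beta, se_fixed, k, extra=extra)
    mre = _make_result("ivw_mre", beta, se_fixed * scale, k, extra=extra)
    return fixed, mre


def ivw_headline(hset: HarmonizedSet) -> MrResult:
    """The reported IVW result: MRE when Q/(k−1) > 1, fixed otherwise.

    Both variants share the beta, so the choice only affects the SE and
    p-value; the discarded variant remains available via :func:`ivw`.
    """
    fixed, mre = ivw(hset)
    chosen = mre if mre.se > fixed.se else fixed
    return chosen


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def _egger_fit(hset: HarmonizedSet) -> dict[str, float]:
    bx = hset.beta_exposure.copy()
    by = hset.beta_outcome.copy()
    # Orient so every exposure effect is non-negative (InSIDE convention);
    # flipping both signs leaves the Wald ratio unchanged.
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    w = hset.se_outcome**-2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    k = hset.n_snp
    rss_w = float(np.sum(w * resid**2))
    sigma = max(1.0, math.sqrt(rss_w / (k - 2))) if k > 2 else 1.0
    cov_unit = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov_unit)) * sigma
    return {
        "intercept": float(coef[0]),
        "intercept_se": float(se[0]),
        "slope": float(coef[1]),
        "slope_se": float(se[1]),
        "rss_w": rss_w,
        "sigma": sigma,
        "df": k - 2,
    }


def mr_egger(hset: HarmonizedSet) -> MrResult:
    """MR-Egger regression: WLS of by on bx with a free intercept.

    The intercept estimates the average directional pleiotropic effect;
    the slope is the pleiotropy-adjusted causal estimate.  SEs carry the
    residual-scale inflation max(1, sqrt(RSS_w/(k−2))); p-values use
    t(k−2).  The intercept block lands in ``extra``.
    """
    if hset.n_snp < 3:
        raise ValueError("MR-Egger requires at least 3 SNPs")
    fit = _egger_fit(hset)
    df = int(fit["df"])
    intercept_p = _two_sided_t_p(fit["intercept"] / fit["intercept_se"], df)
    return _make_result(
        "egger",
        fit["slope"],
        fit["slope_se"],
        hset.n_snp,
        pval=_two_sided_t_p(fit["slope"] / fit["slope_se"], df),
        extra={
            "intercept": fit["intercept"],
            "intercept_se": fit["intercept_se"],
            "intercept_pval": intercept_p,
            "rss_w": fit["rss_w"],
            "sigma": fit["sigma"],
            "df": df,
        },
    )


# ---------------------------------------------------------------------------
# Weighted median / mode
# ---------------------------------------------------------------------------

def _ratio_inputs(hset: HarmonizedSet) -> tuple[np.ndarray, ...]:
    """Per-SNP ratio estimates and weights, excluding bx == 0 SNPs."""
    keep = hset.beta_exposure != 0
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("excluded %d SNP(s) with zero exposure beta", n_excluded)
    bx = hset.beta_exposure[keep]
    by = hset.beta_outcome[keep]
    sex = hset.se_exposure[keep]
    sey = hset.se_outcome[keep]
    theta = by / bx
    w = bx**2 / sey**2
    return theta, w, bx, by, sex, sey


def _weighted_median_1d(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    cw = np.cumsum(w[order]) - 0.5 * w[order]
    cw = cw / np.sum(w)
    if cw[0] >= 0.5:
        return float(t[0])
    if cw[-1] < 0.5:
        return float(t[-1])
    below = int(np.searchsorted(cw, 0.5, side="left")) - 1
    frac = (0.5 - cw[below]) / (cw[below + 1] - cw[below])
    return float(t[below] + (t[below + 1] - t[below]) * frac)


def _weighted_median_rows(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Row-wise weighted median of (B, k) arrays."""
    order = np.argsort(theta, axis=1, kind="stable")
    t = np.take_along_axis(theta, order, axis=1)
    ws = np.take_along_axis(w, order, axis=1)
    cw = np.cumsum(ws, axis=1) - 0.5 * ws
    cw = cw / np.sum(ws, axis=1, keepdims=True)
    below = np.clip(np.sum(cw < 0.5, axis=1) - 1, 0, theta.shape[1] - 2)
    rows = np.arange(theta.shape[0])
    c0, c1 = cw[rows, below], cw[rows, below + 1]
    t0, t1 = t[rows, below], t[rows, below + 1]
    frac = np.where(c1 > c0, (0.5 - c0) / np.where(c1 > c0, c1 - c0, 1.0), 0.0)
    est = t0 + (t1 - t0) * np.clip(frac, 0.0, 1.0)
    est = np.where(cw[:, 0] >= 0.5, t[:, 0], est)
    est = np.where(cw[:, -1] < 0.5, t[:, -1], est)
    return est


def _bootstrap_draws(
    bx: np.ndarray,
    by: np.ndarray,
    sex: np.ndarray,
    sey: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Parametric draws of (theta*, w*) with bx*==0 rows nudged off zero."""
    bx_star = rng.normal(bx, sex, size=(n_boot, bx.size))
    by_star = rng.normal(by, sey, size=(n_boot, bx.size))
    bx_star = np.where(bx_star == 0, np.finfo(float).tiny, bx_star)
    theta = by_star / bx_star
    w = bx_star**2 / sey**2
    return theta, w


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 5000, seed: int | None = None
) -> MrResult:
    """Weighted-median estimator: consistent if ≥50% of weight is valid.

    The estimate is where the weighted empirical CDF of the sorted per-SNP
    ratios crosses 0.5 (linearly interpolated); the SE comes from a
    seeded parametric bootstrap of the summary statistics.
    """
    theta, w, bx, by, sex, sey = _ratio_inputs(hset)
    if theta.size < 3:
        raise ValueError("weighted median requires at least 3 usable SNPs")
    estimate = _weighted_median_1d(theta, w / np.sum(w))
    rng = np.random.default_rng(seed)
    boot_theta, boot_w = _bootstrap_draws(bx, by, sex, sey, n_boot, rng)
    boots = _weighted_median_rows(boot_theta, boot_w)
    se = float(np.std(boots, ddof=1))
    return _make_result(
        "weighted_median", estimate, se, int(theta.size), extra={"n_boot": n_boot}
    )


def _silverman_bandwidth(theta: np.ndarray) -> float:
    sd = float(np.std(theta, ddof=1)) if theta.size > 1 else 0.0
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    s = min(sd, mad) if mad > 0 else sd
    return 0.9 * s * theta.size ** (-1 / 5)


def _weighted_mode_1d(theta: np.ndarray, w: np.ndarray, h: float, n_grid: int = 2048) -> float:
    if h <= 0 or np.ptp(theta) == 0:
        # Degenerate spread: the mode is the (weighted) point mass.
        return float(theta[int(np.argmax(w))])
    grid = np.linspace(float(np.min(theta)), float(np.max(theta)), n_grid)
    dens = np.zeros_like(grid)
    wn = w / np.sum(w)
    for tj, wj in zip(theta, wn):
        dens += wj * np.exp(-0.5 * ((grid - tj) / h) ** 2)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int | None = None,
) -> MrResult:
    """Weighted-mode estimator (ZEMPA: the largest valid-instrument group).

    The estimate is the mode of the weighted normal-kernel density of the
    per-SNP ratios, with bandwidth = ``bandwidth_factor`` times the
    modified Silverman rule 0.9·min(sd, normalized MAD)·k^(−1/5); the SE
    is a seeded parametric bootstrap as in :func:`weighted_median`.
    """
    theta, w, bx, by, sex, sey = _ratio_inputs(hset)
    if theta.size < 3:
        raise ValueError("weighted mode requires at least 3 usable SNPs")
    h = bandwidth_factor * _silverman_bandwidth(theta)
    estimate = _weighted_mode_1d(theta, w, h)
    rng = np.random.default_rng(seed)
    boot_theta, boot_w = _bootstrap_draws(bx, by, sex, sey, n_boot, rng)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        hb = bandwidth_factor * _silverman_bandwidth(boot_theta[b])
        boots[b] = _weighted_mode_1d(boot_theta[b], boot_w[b], hb, n_grid=512)
    se = float(np.std(boots, ddof=1))
    return _make_result(
        "weighted_mode",
        estimate,
        se,
        int(theta.size),
        extra={"n_boot": n_boot, "bandwidth": h},
    )


# ---------------------------------------------------------------------------
# Odds-ratio view
# ---------------------------------------------------------------------------

def effect_to_or(
    beta: float,
    se: float | None = None,
    ci: tuple[float, float] | None = None,
) -> tuple[float, float, float]:
    """Exponentiate a log-odds effect (and its 95% CI) to an odds ratio.

    Either ``se`` (CI taken as beta ± 1.96·se) or an explicit ``ci`` pair
    may be given; with neither, the CI slots are NaN.
    """
    if se is not None and ci is not None:
        raise ValueError("give either se or ci, not both")
    if se is not None:
        if se <= 0:
            raise ValueError("se must be positive")
        ci = (beta - Z95 * se, beta + Z95 * se)
    if ci is None:
        return math.exp(beta), math.nan, math.nan
    lo, hi = ci
    return math.exp(beta), math.exp(lo), math.exp(hi)
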