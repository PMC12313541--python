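"""Sensitivity diagnostics for a fitted univariable MR.

Covers Cochran heterogeneity (IVW and Egger flavours), the Egger-intercept
pleiotropy test, leave-one-out stability, the MR-PRESSO global/outlier
simulation test, and funnel-plot coordinates.  Heterogeneity at p < 0.05
is the conventional flag.  All simulation-based outputs are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import Z95, ivw, _egger_fit, _ivw_core
from .gwas_io import HarmonizedSet

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "pleiotropy_test",
    "leave_one_out",
    "mr_presso",
    "funnel_coordinates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str  # "ivw" or "egger"
    q: float
    df: int
    pval: float

    @property
    def heterogeneous(self) -> bool:
        return self.pval < 0.05


@dataclass(frozen=True)
class PressoResult:
    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: list[str]
    n_sim: int
    seed: int | None
    beta_raw: float
    beta_corrected: float
    extra: dict = field(default_factory=dict)


def cochran_q(hset: HarmonizedSet, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q across per-SNP estimates.

    IVW flavour: Q = Σ w_j (θ_j − θ_IVW)² with θ_j the Wald ratios and
    w_j = bx_j²/sey_j² (df = k−1).  Egger flavour: the weighted residual
    sum of squares of the Egger fit (df = k−2).
    """
    k = hset.n_snp
    if method == "ivw":
        if k < 2:
            raise ValueError("IVW heterogeneity requires at least 2 SNPs")
        _, _, q = _ivw_core(hset)
        df = k - 1
    elif method == "egger":
        if k < 3:
            raise ValueError("Egger heterogeneity requires at least 3 SNPs")
        q = _egger_fit(hset)["rss_w"]
        df = k - 2
    else:
        raise ValueError(f"unknown heterogeneity method {method!r}")
    pval = float(max(stats.chi2.sf(q, df), 5e-324))
    return HeterogeneityResult(method=method, q=float(q), df=df, pval=pval)


def pleiotropy_test(hset: HarmonizedSet) -> dict[str, float]:
    """Egger-intercept test for directional pleiotropy.

    Returns ``{"intercept", "se", "pval"}``; a two-sided t(k−2) p-value
    below 0.05 indicates a nonzero average pleiotropic effect.
    """
    if hset.n_snp < 3:
        raise ValueError("pleiotropy test requires at least 3 SNPs")
    fit = _egger_fit(hset)
    df = int(fit["df"])
    t = fit["intercept"] / fit["intercept_se"]
    return {
        "intercept": fit["intercept"],
        "se": fit["intercept_se"],
        "pval": float(min(1.0, max(2.0 * stats.t.sf(abs(t), df), 5e-324))),
    }


def leave_one_out(hset: HarmonizedSet) -> pd.DataFrame:
    """IVW-MRE refits excluding each SNP in turn, plus an "all" row.

    The ``flagged`` column marks exclusions whose 95% CI no longer covers
    the full-set estimate — a crude influence indicator.
    """
    if hset.n_snp < 3:
        raise ValueError("leave-one-out requires at least 3 SNPs")
    _, full = ivw(hset)
    rows = []
    for i in range(hset.n_snp):
        idx = [j for j in range(hset.n_snp) if j != i]
        _, res = ivw(hset.subset(idx))
        rows.append(
            {
                "excluded_snp": hset.snp_ids[i],
                "n_snp": res.n_snp,
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "flagged": not (res.ci_low <= full.beta <= res.ci_high),
            }
        )
    rows.append(
        {
            "excluded_snp": "all",
            "n_snp": full.n_snp,
            "beta": full.beta,
            "se": full.se,
            "pval": full.pval,
            "ci_low": full.ci_low,
            "ci_high": full.ci_high,
            "flagged": False,
        }
    )
    return pd.DataFrame(rows)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized: θ_(−j) for each j."""
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(
    hset: HarmonizedSet,
    n_sim: int = 1000,
    sig: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO global heterogeneity and per-SNP outlier test.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = Σ w_j (by_j − θ_(−j)·bx_j)², w_j = 1/sey_j².  Its null
    distribution comes from ``n_sim`` parametric draws
    by*_j ~ N(θ_(−j)·bx_j, sey_j), bx*_j ~ N(bx_j, sex_j), each draw
    re-deriving its own leave-one-out slopes.  Per-SNP outlier p-values
    are the empirical tails of each SNP's observed weighted residual in
    its simulated distribution, Bonferroni-adjusted by k; flagged SNPs
    are removed for ``beta_corrected`` (IVW on the remainder).
    """
    k = hset.n_snp
    if k < 4:
        raise ValueError("MR-PRESSO requires at least 4 SNPs")
    if n_sim < 100:
        logger.warning("mr_presso: n_sim=%d is small; p-values will be coarse", n_sim)
    bx, by = hset.beta_exposure, hset.beta_outcome
    sex, sey = hset.se_exposure, hset.se_outcome
    w = sey**-2

    theta_loo = _loo_slopes(bx, by, w)
    obs_resid2 = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_resid2))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sex, size=(n_sim, k))
    by_star = rng.normal(theta_loo * bx, sey, size=(n_sim, k))
    theta_star = _loo_slopes(bx_star, by_star, w)
    sim_resid2 = w * (by_star - theta_star * bx_star) ** 2
    rss_star = np.sum(sim_resid2, axis=1)

    global_pval = (1 + int(np.sum(rss_star >= rss_obs))) / (n_sim + 1)
    raw_p = (1 + np.sum(sim_resid2 >= obs_resid2, axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * k)
    outlier_mask = adj_p < sig
    outliers = [hset.snp_ids[i] for i in np.flatnonzero(outlier_mask)]

    beta_raw = ivw(hset)[0].beta
    if outlier_mask.any() and int(np.sum(~outlier_mask)) >= 1:
        beta_corrected = ivw(hset.subset(np.flatnonzero(~outlier_mask)))[0].beta
    else:
        beta_corrected = beta_raw
    return PressoResult(
        global_rss=rss_obs,
        global_pval=float(global_pval),
        outlier_pvals=dict(zip(hset.snp_ids, adj_p.astype(float))),
        outliers=outliers,
        n_sim=n_sim,
        seed=seed,
        beta_raw=float(beta_raw),
        beta_corrected=float(beta_corrected),
        extra={"raw_outlier_pvals": dict(zip(hset.snp_ids, raw_p.astype(float)))},
    )


def funnel_coordinates(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio and its precision 1/se(θ_j) for funnel plotting.

    SNPs with bx = 0 are excluded (logged).  Symmetry of θ_j around the
    IVW estimate at increasing precision is the visual check; no
    rendering is done here.
    """
    keep = hset.beta_exposure != 0
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("funnel_coordinates: excluded %d zero-bx SNP(s)", n_excluded)
    bx = hset.beta_exposure[keep]
    by = hset.beta_outcome[keep]
    sey = hset.se_outcome[keep]
    return pd.DataFrame(
        {
            "snp_id": [s for s, k_ in zip(hset.snp_ids, keep) if k_],
            "theta": by / bx,
            "precision": np.abs(bx) / sey,
        }
    )
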