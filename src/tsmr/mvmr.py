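"""Multivariable MR: joint direct effects of several exposures on one outcome.

The design matrix stacks each exposure's harmonized per-SNP effects; the
fit is weighted least squares of the outcome effects on that matrix with
no intercept and weights 1/se_outcome².  Standard errors carry the usual
heterogeneity inflation max(1, sqrt(Q/df)).  With a single exposure the
fit reduces exactly to univariable IVW.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import EmptyOverlapError, HarmonizedSet, SummaryStatRecord, harmonize
from .instruments import filter_by_pvalue, ld_clump

__all__ = [
    "MultiHarmonizedSet",
    "MvmrResult",
    "CollinearityError",
    "mvmr_harmonize",
    "mvmr_fit",
]


class CollinearityError(ValueError):
    """The exposure design matrix is rank deficient."""


@dataclass
class MultiHarmonizedSet:
    """Per-SNP effects for several exposures and one outcome, one allele
    convention (the first exposure's)."""

    exposure_names: list[str]
    snp_ids: list[str]
    beta_exposures: np.ndarray  # (k, p)
    se_exposures: np.ndarray  # (k, p)
    beta_outcome: np.ndarray  # (k,)
    se_outcome: np.ndarray  # (k,)
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k, p = len(self.snp_ids), len(self.exposure_names)
        self.beta_exposures = np.asarray(self.beta_exposures, dtype=float)
        self.se_exposures = np.asarray(self.se_exposures, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        if self.beta_exposures.shape != (k, p) or self.se_exposures.shape != (k, p):
            raise ValueError("exposure matrices must be (n_snp, n_exposures)")
        if self.beta_outcome.shape != (k,) or self.se_outcome.shape != (k,):
            raise ValueError("outcome arrays must have length n_snp")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_names)


@dataclass(frozen=True)
class MvmrResult:
    exposures: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    q: float
    df: int
    n_snp: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "beta": self.betas,
                "se": self.ses,
                "pval": self.pvals,
                "ci_low": self.betas - 1.96 * self.ses,
                "ci_high": self.betas + 1.96 * self.ses,
            }
        )

    def block(self, exposure: str) -> dict[str, float]:
        i = self.exposures.index(exposure)
        return {
            "beta": float(self.betas[i]),
            "se": float(self.ses[i]),
            "pval": float(self.pvals[i]),
            "ci_low": float(self.betas[i] - 1.96 * self.ses[i]),
            "ci_high": float(self.betas[i] + 1.96 * self.ses[i]),
        }


def mvmr_harmonize(
    exposure_sets: Sequence[Sequence[SummaryStatRecord]],
    outcome: Sequence[SummaryStatRecord],
    exposure_names: Sequence[str] | None = None,
    pval_threshold: float = 5e-6,
    ld: pd.DataFrame | None = None,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    palindrome_eaf_window: float = 0.08,
) -> MultiHarmonizedSet:
    """Build the joint instrument set for multivariable MR.

    The SNP set is the union of each exposure's clumped instruments,
    restricted to SNPs present in every exposure GWAS and the outcome
    GWAS, then re-clumped jointly (ranking by the best p-value any
    exposure assigns the SNP).  Allele alignment follows the first
    exposure's convention, applied pairwise via
    :func:`~tsmr.gwas_io.harmonize`; a SNP dropped by any pairwise
    alignment is dropped from the joint set.
    """
    if len(exposure_sets) < 2:
        raise ValueError("mvmr_harmonize needs at least 2 exposures")
    names = list(exposure_names or [f"exposure_{i + 1}" for i in range(len(exposure_sets))])
    if len(names) != len(exposure_sets):
        raise ValueError("exposure_names length mismatch")

    by_id = [{r.snp_id: r for r in recs} for recs in exposure_sets]
    out_by_id = {r.snp_id: r for r in outcome}

    union_ids: list[str] = []
    seen: set[str] = set()
    counts = []
    for recs in exposure_sets:
        inst = ld_clump(
            filter_by_pvalue(recs, pval_threshold), ld=ld, r2_threshold=clump_r2, kb_window=clump_kb
        )
        counts.append(len(inst))
        for r in inst:
            if r.snp_id not in seen:
                seen.add(r.snp_id)
                union_ids.append(r.snp_id)

    shared = [
        s for s in union_ids if all(s in m for m in by_id) and s in out_by_id
    ]
    if not shared:
        per_source = ", ".join(
            f"{n}: {c} instruments" for n, c in zip(names, counts)
        )
        raise EmptyOverlapError(
            f"no joint SNPs across all sources ({per_source}, outcome: {len(outcome)} SNPs)"
        )

    # Joint re-clump: rank each SNP by the best p-value across exposures.
    from dataclasses import replace

    joint_records = [
        replace(by_id[0][s], pval=min(m[s].pval for m in by_id)) for s in shared
    ]
    joint = ld_clump(joint_records, ld=ld, r2_threshold=clump_r2, kb_window=clump_kb)
    joint_ids = [r.snp_id for r in joint]

    # Pairwise allele alignment against exposure 1's convention.
    anchor = [by_id[0][s] for s in joint_ids]
    prov: list[tuple[str, str, str]] = []
    aligned: list[dict[str, SummaryStatRecord]] = []
    kept_ids = list(joint_ids)
    for name, mapping in list(zip(names[1:], by_id[1:])) + [("outcome", out_by_id)]:
        hset = harmonize(
            anchor, [mapping[s] for s in kept_ids], palindrome_eaf_window=palindrome_eaf_window
        )
        kept = set(hset.snp_ids)
        for s, action, reason in hset.provenance:
            prov.append((s, action, f"{name}:{reason}"))
        kept_ids = [s for s in kept_ids if s in kept]
        anchor = [r for r in anchor if r.snp_id in kept]
        aligned.append(
            {
                s: SummaryStatRecord(
                    snp_id=s,
                    effect_allele="",
                    other_allele="",
                    beta=float(b),
                    se=float(e),
                    pval=1.0,
                )
                for s, b, e in zip(hset.snp_ids, hset.beta_outcome, hset.se_outcome)
            }
        )

    if not kept_ids:
        raise EmptyOverlapError("all joint SNPs dropped during allele alignment")

    anchor_by_id = {r.snp_id: r for r in anchor}
    beta_cols = [np.array([anchor_by_id[s].beta for s in kept_ids])]
    se_cols = [np.array([anchor_by_id[s].se for s in kept_ids])]
    for col in aligned[:-1]:
        beta_cols.append(np.array([col[s].beta for s in kept_ids]))
        se_cols.append(np.array([col[s].se for s in kept_ids]))
    out_col = aligned[-1]
    return MultiHarmonizedSet(
        exposure_names=names,
        snp_ids=kept_ids,
        beta_exposures=np.column_stack(beta_cols),
        se_exposures=np.column_stack(se_cols),
        beta_outcome=np.array([out_col[s].beta for s in kept_ids]),
        se_outcome=np.array([out_col[s].se for s in kept_ids]),
        provenance=prov,
    )


def mvmr_fit(mh: MultiHarmonizedSet) -> MvmrResult:
    """Weighted least squares of outcome effects on the exposure matrix.

    No intercept; weights 1/se_outcome².  SEs from the weighted normal
    equations, inflated by max(1, sqrt(Q/df)) with Q the weighted residual
    sum of squares and df = n_snp − n_exposures; p-values are two-sided
    normal.  Raises :class:`CollinearityError` for rank-deficient designs.
    """
    X = mh.beta_exposures
    y = mh.beta_outcome
    k, p = X.shape
    if k <= p + 1:
        raise ValueError(f"need more SNPs ({k}) than exposures+1 ({p + 1})")
    # An exposure contributing no instrument signal (all-zero column) is
    # inert — it gets beta 0 / infinite SE rather than a failure; genuine
    # linear dependence among informative columns is an error.
    nonzero = np.any(X != 0, axis=0)
    if np.linalg.matrix_rank(X[:, nonzero]) < int(np.sum(nonzero)):
        corr = np.corrcoef(X, rowvar=False)
        pairs = [
            f"{mh.exposure_names[i]}~{mh.exposure_names[j]}"
            for i in range(p)
            for j in range(i + 1, p)
            if nonzero[i] and nonzero[j] and abs(corr[i, j]) > 0.999
        ]
        raise CollinearityError(
            "rank-deficient exposure design"
            + (f" (collinear: {', '.join(pairs)})" if pairs else "")
        )
    w = mh.se_outcome**-2
    Xn = X[:, nonzero]
    xtwx = Xn.T @ (w[:, None] * Xn)
    betas_n = np.linalg.solve(xtwx, Xn.T @ (w * y))
    betas = np.zeros(p)
    betas[nonzero] = betas_n
    resid = y - X @ betas
    q = float(np.sum(w * resid**2))
    df = k - int(np.sum(nonzero))
    scale = max(1.0, math.sqrt(q / df))
    ses = np.full(p, np.inf)
    ses[nonzero] = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale
    z = betas / ses
    pvals = np.minimum(1.0, np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324))
    return MvmrResult(
        exposures=list(mh.exposure_names),
        betas=betas,
        ses=ses,
        pvals=pvals,
        q=q,
        df=df,
        n_snp=k,
    )
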