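"""Instrument selection and strength scoring.

Instruments are SNPs passing a genome-wide p-value threshold, pruned to
approximate linkage equilibrium by greedy clumping (r² < 0.001 within a
10,000-kb window by default).  Strength is scored by the variance
explained R² = 2·MAF·(1−MAF)·β² and the F statistic
F = R²·(n−k−1) / (k·(1−R²)); instruments with F < 10 are flagged weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import SummaryStatRecord

__all__ = [
    "InstrumentStrength",
    "filter_by_pvalue",
    "ld_clump",
    "instrument_strength",
    "read_ld_matrix",
    "WEAK_F_THRESHOLD",
]

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class InstrumentStrength:
    """Variance explained and F statistic for one SNP or an aggregate set.

    For an aggregate, ``snp_id`` is ``"<aggregate>"``, ``maf`` is None and
    ``r2`` is the sum of per-SNP variances explained.
    """

    snp_id: str
    maf: float | None
    r2: float
    f_stat: float
    n: int
    k: int

    @property
    def weak(self) -> bool:
        return self.f_stat < WEAK_F_THRESHOLD


def filter_by_pvalue(
    records: Sequence[SummaryStatRecord], threshold: float
) -> list[SummaryStatRecord]:
    """Records with ``pval`` strictly below ``threshold``, order preserved."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    return [r for r in records if r.pval < threshold]


def read_ld_matrix(path: str | Path) -> pd.DataFrame:
    """Read a square tab-delimited r² matrix (first row/column = SNP ids)."""
    ld = pd.read_csv(path, sep="\t", index_col=0)
    ld.index = ld.index.astype(str)
    ld.columns = ld.columns.astype(str)
    return ld


def _validate_ld(ld: pd.DataFrame, snp_ids: Sequence[str]) -> None:
    missing = [s for s in snp_ids if s not in ld.index or s not in ld.columns]
    if missing:
        raise KeyError(f"LD matrix missing SNP(s): {', '.join(missing[:5])}")
    sub = ld.loc[list(snp_ids), list(snp_ids)].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-8):
        raise ValueError("LD matrix is not symmetric")


def _within_window(
    a: SummaryStatRecord, b: SummaryStatRecord, kb_window: int
) -> bool:
    # Unknown coordinates cannot prove independence; treat as within-window
    # so the r² condition alone decides (conservative pruning).
    if a.chrom is None or b.chrom is None or a.pos is None or b.pos is None:
        return True
    if a.chrom != b.chrom:
        return False
    return abs(a.pos - b.pos) <= kb_window * 1000


def ld_clump(
    records: Sequence[SummaryStatRecord],
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
    kb_window: int = 10_000,
) -> list[SummaryStatRecord]:
    """Greedy LD clumping to an independent instrument set.

    SNPs are visited by ascending p-value (ties broken by SNP id); each
    accepted SNP discards every remaining SNP that is jointly (a) within
    ``kb_window`` kilobases on the same chromosome and (b) correlated at
    r² ≥ ``r2_threshold``.  Without an LD matrix the pruning is purely
    positional (chrom/pos required); with a matrix but without positions
    the r² condition alone decides.  Output keeps the input ordering.
    """
    if not records:
        return []
    if ld is None:
        missing = [r.snp_id for r in records if r.chrom is None or r.pos is None]
        if missing:
            raise ValueError(
                "distance-only clumping requires chrom/pos on every record; "
                f"missing for: {', '.join(missing[:5])}"
            )
    else:
        _validate_ld(ld, [r.snp_id for r in records])

    order = sorted(range(len(records)), key=lambda i: (records[i].pval, records[i].snp_id))
    discarded = [False] * len(records)
    accepted: set[int] = set()
    for i in order:
        if discarded[i]:
            continue
        accepted.add(i)
        for j in order:
            if j == i or discarded[j] or j in accepted:
                continue
            if not _within_window(records[i], records[j], kb_window):
                continue
            if ld is not None:
                r2 = float(ld.at[records[i].snp_id, records[j].snp_id])
                if r2 < r2_threshold:
                    continue
            discarded[j] = True
    return [r for i, r in enumerate(records) if i in accepted]


def instrument_strength(
    records: Sequence[SummaryStatRecord],
    n: int,
    aggregate: bool = False,
) -> list[InstrumentStrength] | InstrumentStrength:
    """Score instrument strength via R² = 2·MAF·(1−MAF)·β² and the F statistic.

    Per-SNP mode (default) evaluates each SNP with k = 1; aggregate mode
    sums the per-SNP R² and uses k = number of SNPs.  ``beta`` is assumed
    to be on a standardized trait scale — R² is only interpretable as a
    variance fraction under that convention.  The weak-instrument flag
    fires at F < 10.
    """
    if not records:
        raise ValueError("no records supplied")
    missing = [r.snp_id for r in records if r.eaf is None]
    if missing:
        raise ValueError(f"eaf required for strength scoring; missing: {', '.join(missing)}")
    k = len(records) if aggregate else 1
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed k+1={k + 1}")

    def per_snp_r2(rec: SummaryStatRecord) -> tuple[float, float]:
        maf = min(rec.eaf, 1.0 - rec.eaf)
        return maf, 2.0 * maf * (1.0 - maf) * rec.beta**2

    def f_of(r2: float, k_: int) -> float:
        return r2 * (n - k_ - 1) / (k_ * (1.0 - r2))

    if aggregate:
        r2_total = sum(per_snp_r2(r)[1] for r in records)
        return InstrumentStrength(
            snp_id="<aggregate>",
            maf=None,
            r2=r2_total,
            f_stat=f_of(r2_total, k),
            n=n,
            k=k,
        )
    out = []
    for rec in records:
        maf, r2 = per_snp_r2(rec)
        out.append(
            InstrumentStrength(snp_id=rec.snp_id, maf=maf, r2=r2, f_stat=f_of(r2, 1), n=n, k=1)
        )
    return out
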