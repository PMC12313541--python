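"""Seeded synthetic GWAS summary statistics with known causal structure.

Stands in for consortium-scale GWAS sources: per-SNP effect/SE pairs whose
SEs follow the 1/sqrt(2·MAF·(1−MAF)·n) scaling of a standardized-trait
regression, a true causal effect θ, a configurable fraction of invalid
(pleiotropic) instruments, and an exposure → mediator → outcome chain for
mediation studies.  Everything is deterministic given the seed.

Default condition: ~80 instruments from biobank-scale samples
(n ≈ 4.6–4.9 × 10⁵) with a true log-odds effect of 0.162 — the scale of
the alcohol-frequency → IBS analysis this generator emulates — and no
pleiotropy unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import SummaryStatRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_instrument_set",
    "simulate_mediation_study",
    "inject_ld_structure",
    "replicate_seed",
]

_NON_PALINDROMIC_PAIRS = (
    ("A", "G"),
    ("A", "C"),
    ("T", "G"),
    ("T", "C"),
    ("G", "A"),
    ("C", "A"),
    ("G", "T"),
    ("C", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the synthetic GWAS world."""

    k: int = 80  # exposure instruments
    theta: float = 0.162  # true causal effect of exposure on outcome
    n_exp: int = 460_000
    n_out: int = 486_601
    n_med: int = 500_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.05  # true instrument-effect scale (strong-instrument regime)
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.01
    mediation: tuple[float, float, float] | None = None  # (a, b, c_prime)
    k_med: int | None = None  # mediator-specific instruments (defaults to k)
    outlier: tuple[int, float] | None = None  # (snp index, shift in sey units)
    palindrome_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low < high <= 0.5")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise ValueError("pleiotropy_frac must lie in [0, 1]")
        if not (0 <= self.palindrome_frac <= 1):
            raise ValueError("palindrome_frac must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        for name in ("n_exp", "n_out", "n_med"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        if self.outlier is not None and not (0 <= self.outlier[0] < self.k):
            raise ValueError("outlier index out of range")


@dataclass
class SimulationTruth:
    """Latent values behind one simulated dataset."""

    theta: float
    per_snp: pd.DataFrame  # snp_id, maf, gamma, alpha[, gamma_med, group]
    mediation: tuple[float, float, float] | None = None

    @property
    def true_proportion(self) -> float | None:
        """Closed-form mediated proportion a·b/(c′ + a·b) of the chain."""
        if self.mediation is None:
            return None
        a, b, c_prime = self.mediation
        return a * b / (c_prime + a * b)

    def to_frame(self) -> pd.DataFrame:
        df = self.per_snp.copy()
        df["theta"] = self.theta
        if self.mediation is not None:
            df["a"], df["b"], df["c_prime"] = self.mediation
        return df


def replicate_seed(seed: int, replicate: int) -> int:
    """Per-replicate seed: base seed plus replicate index."""
    return int(seed) + int(replicate)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 5e-324, 1.0)


def _coordinates(j: int) -> tuple[str, int]:
    # Spread SNPs over 22 chromosomes, >20 Mb apart within a chromosome,
    # so the default 10,000-kb clumping window treats them as independent.
    chrom = str(j % 22 + 1)
    pos = 1_000_000 + (j // 22) * 20_000_001
    return chrom, pos


def _alleles(rng: np.random.Generator, k: int, palindrome_frac: float):
    pal = rng.random(k) < palindrome_frac
    idx_np = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=k)
    idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    return [
        _PALINDROMIC_PAIRS[idx_p[j]] if pal[j] else _NON_PALINDROMIC_PAIRS[idx_np[j]]
        for j in range(k)
    ]


def _records(
    snp_ids: Sequence[str],
    alleles,
    mafs: np.ndarray,
    betas: np.ndarray,
    ses: np.ndarray,
    n: int,
    coords: Sequence[tuple[str, int]],
) -> list[SummaryStatRecord]:
    pvals = _pvals(betas, ses)
    return [
        SummaryStatRecord(
            snp_id=snp_ids[j],
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            beta=float(betas[j]),
            se=float(ses[j]),
            pval=float(pvals[j]),
            chrom=coords[j][0],
            pos=coords[j][1],
            eaf=float(mafs[j]),
            n=n,
        )
        for j in range(len(snp_ids))
    ]


def _latents(cfg: SimulationConfig, rng: np.random.Generator, k: int):
    mafs = rng.uniform(*cfg.maf_range, size=k)
    gamma = rng.normal(0.0, cfg.gamma_sd, size=k)
    alpha = np.where(
        rng.random(k) < cfg.pleiotropy_frac,
        rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=k),
        0.0,
    )
    return mafs, gamma, alpha


def _se_for(mafs: np.ndarray, n: int) -> np.ndarray:
    return (2.0 * mafs * (1.0 - mafs) * n) ** -0.5


def simulate_instrument_set(
    cfg: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], SimulationTruth]:
    """Simulate exposure and outcome summary statistics for one trait pair.

    Per SNP j: MAF ~ U(maf_range); true instrument effect γ_j ~ N(0,
    gamma_sd²); SEs from the allele-frequency/sample-size formula;
    pleiotropic effect α_j (zero with probability 1 − pleiotropy_frac);
    observed bx_j ~ N(γ_j, se_x²), by_j ~ N(θ·γ_j + α_j, se_y²).  The
    optional outlier shift is applied to the outcome beta last.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    mafs, gamma, alpha = _latents(cfg, rng, k)
    se_x = _se_for(mafs, cfg.n_exp)
    se_y = _se_for(mafs, cfg.n_out)
    bx = rng.normal(gamma, se_x)
    # Pleiotropic effects act on the exposure-increasing allele: under the
    # arbitrary allele coding of real GWAS, that is the only orientation in
    # which "directional" pleiotropy is well defined.
    by = rng.normal(cfg.theta * gamma + np.sign(gamma) * alpha, se_y)
    if cfg.outlier is not None:
        j, shift = cfg.outlier
        by[j] += shift * se_y[j]
    snp_ids = [f"rs{j + 1:06d}" for j in range(k)]
    alleles = _alleles(rng, k, cfg.palindrome_frac)
    coords = [_coordinates(j) for j in range(k)]
    exposure = _records(snp_ids, alleles, mafs, bx, se_x, cfg.n_exp, coords)
    outcome = _records(snp_ids, alleles, mafs, by, se_y, cfg.n_out, coords)
    truth = SimulationTruth(
        theta=cfg.theta,
        per_snp=pd.DataFrame(
            {"snp_id": snp_ids, "maf": mafs, "gamma": gamma, "alpha": alpha}
        ),
    )
    return exposure, outcome, truth


def simulate_mediation_study(
    cfg: SimulationConfig,
) -> tuple[
    list[SummaryStatRecord],
    list[SummaryStatRecord],
    list[SummaryStatRecord],
    SimulationTruth,
]:
    """Simulate an exposure → mediator → outcome chain.

    Exposure instruments follow :func:`simulate_instrument_set` with the
    chain-implied marginal effects: mediator betas ~ N(a·γ, se_m²) and
    outcome betas ~ N((c′ + a·b)·γ + α, se_y²).  A second block of
    ``k_med`` mediator-specific instruments (effects γm on the mediator,
    b·γm on the outcome, null on the exposure) makes the mediator
    independently instrumentable, which the MVMR adjustment step
    requires.  The true mediated proportion is a·b/(c′ + a·b).
    """
    cfg.validate()
    if cfg.mediation is None:
        raise ValueError("cfg.mediation=(a, b, c_prime) is required")
    a, b, c_prime = cfg.mediation
    rng = np.random.default_rng(cfg.seed)
    k, k_med = cfg.k, cfg.k_med if cfg.k_med is not None else cfg.k
    total = k + k_med

    mafs, gamma, alpha = _latents(cfg, rng, k)
    mafs_m = rng.uniform(*cfg.maf_range, size=k_med)
    gamma_med = rng.normal(0.0, cfg.gamma_sd, size=k_med)

    all_mafs = np.concatenate([mafs, mafs_m])
    se_x = _se_for(all_mafs, cfg.n_exp)
    se_m = _se_for(all_mafs, cfg.n_med)
    se_y = _se_for(all_mafs, cfg.n_out)

    mean_x = np.concatenate([gamma, np.zeros(k_med)])
    mean_m = np.concatenate([a * gamma, gamma_med])
    mean_y = np.concatenate(
        [(c_prime + a * b) * gamma + np.sign(gamma) * alpha, b * gamma_med]
    )

    bx = rng.normal(mean_x, se_x)
    bm = rng.normal(mean_m, se_m)
    by = rng.normal(mean_y, se_y)
    if cfg.outlier is not None:
        j, shift = cfg.outlier
        by[j] += shift * se_y[j]

    snp_ids = [f"rs{j + 1:06d}" for j in range(total)]
    alleles = _alleles(rng, total, cfg.palindrome_frac)
    coords = [_coordinates(j) for j in range(total)]
    exposure = _records(snp_ids, alleles, all_mafs, bx, se_x, cfg.n_exp, coords)
    mediator = _records(snp_ids, alleles, all_mafs, bm, se_m, cfg.n_med, coords)
    outcome = _records(snp_ids, alleles, all_mafs, by, se_y, cfg.n_out, coords)
    truth = SimulationTruth(
        theta=c_prime + a * b,
        per_snp=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "maf": all_mafs,
                "gamma": mean_x,
                "alpha": np.concatenate([alpha, np.zeros(k_med)]),
                "gamma_med": np.concatenate([np.zeros(k), gamma_med]),
                "group": ["exposure"] * k + ["mediator"] * k_med,
            }
        ),
        mediation=(a, b, c_prime),
    )
    return exposure, mediator, outcome, truth


def inject_ld_structure(
    records: Sequence[SummaryStatRecord],
    block_size: int,
    r2_within: float,
) -> tuple[list[SummaryStatRecord], pd.DataFrame]:
    """Overlay a block-diagonal LD structure onto existing records.

    Consecutive runs of ``block_size`` SNPs form blocks with pairwise r² =
    ``r2_within`` inside and 0 between.  Coordinates are reassigned so
    block members sit within one clumping window (1-kb spacing) and
    distinct blocks are independent by distance/chromosome.  Returns the
    re-coordinated records and the aligned symmetric r² matrix.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not (0 <= r2_within <= 1):
        raise ValueError("r2_within must lie in [0, 1]")
    out: list[SummaryStatRecord] = []
    for j, rec in enumerate(records):
        block = j // block_size
        chrom, base = _coordinates(block)
        out.append(replace(rec, chrom=chrom, pos=base + (j % block_size) * 1000))
    n = len(records)
    ld = np.zeros((n, n))
    for j in range(n):
        for i in range(j, min((j // block_size + 1) * block_size, n)):
            ld[j, i] = ld[i, j] = r2_within
    np.fill_diagonal(ld, 1.0)
    ids = [r.snp_id for r in out]
    return out, pd.DataFrame(ld, index=ids, columns=ids)
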