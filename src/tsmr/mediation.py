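"""Two-step MR mediation decomposition.

The chain exposure → mediator → outcome is decomposed into

* βa — effect of the exposure on the mediator (IVW, exposure instruments),
* βb — total effect of the mediator on the outcome (IVW, mediator
  instruments),
* βc — total effect of the exposure on the outcome,
* βb′, βc′ — mediator and exposure effects on the outcome after joint
  multivariable-MR adjustment.

The indirect effect is the product of coefficients.  When the adjusted
mediator effect βb′ is itself significant (95% CI excluding zero) the
Propagation-of-Error route is used: indirect = βa·βb′ with the first-order
SE sqrt(a²·se_b² + b²·se_a²).  Otherwise a Sobel z-test on the unadjusted
product βa·βb decides: p < α selects the Sobel route, else no mediated
proportion is reported.  The mediated proportion is indirect/βc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .estimators import Z95, MrResult, ivw_headline
from .gwas_io import SummaryStatRecord, harmonize
from .instruments import filter_by_pvalue, ld_clump
from .mvmr import mvmr_fit, mvmr_harmonize

__all__ = [
    "EffectBlock",
    "MediationResult",
    "StageError",
    "indirect_effect_poe",
    "sobel_test",
    "mediated_proportion",
    "decompose_mediation",
    "run_two_step_mediation",
]

POE = "propagation_of_error"
SOBEL = "sobel"
NOT_AVAILABLE = "not_available"


class StageError(RuntimeError):
    """A mediation stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class EffectBlock:
    """A point estimate with its SE, 95% CI and p-value."""

    beta: float
    se: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    pval: float = math.nan

    @classmethod
    def from_beta_se(cls, beta: float, se: float) -> "EffectBlock":
        z = beta / se if se > 0 else math.inf
        p = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))
        return cls(beta, se, beta - Z95 * se, beta + Z95 * se, p)

    @classmethod
    def from_ci(cls, beta: float, ci_low: float, ci_high: float) -> "EffectBlock":
        """Build from a printed 95% CI; SE back-derived as width/(2·1.96)."""
        se = (ci_high - ci_low) / (2 * Z95)
        z = beta / se if se > 0 else math.inf
        p = float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))
        return cls(beta, se, ci_low, ci_high, p)

    @classmethod
    def from_result(cls, res: MrResult) -> "EffectBlock":
        return cls(res.beta, res.se, res.ci_low, res.ci_high, res.pval)

    @property
    def significant(self) -> bool:
        """95% CI excludes zero (equivalently p < 0.05)."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass(frozen=True)
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    beta_a: EffectBlock
    beta_b: EffectBlock
    beta_c: EffectBlock
    beta_b_adj: EffectBlock | None
    beta_c_adj: EffectBlock | None
    indirect: float
    indirect_se: float
    sobel_z: float | None
    sobel_p: float | None
    proportion: float | None  # fraction, not percent
    proportion_se: float | None
    method_flag: str  # POE | SOBEL | NOT_AVAILABLE
    extra: dict = field(default_factory=dict)

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion


def indirect_effect_poe(
    a: float, se_a: float, b: float, se_b: float
) -> tuple[float, float]:
    """Product-of-coefficients indirect effect with first-order SE.

    indirect = a·b; se = sqrt(a²·se_b² + b²·se_a²) — the Propagation-of-
    Error (delta-method) formula, symmetric in (a, se_a) ↔ (b, se_b).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    return a * b, math.sqrt(a**2 * se_b**2 + b**2 * se_a**2)


def sobel_test(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """Sobel z-test of the indirect effect a·b.

    z = a·b / sqrt(a²·se_b² + b²·se_a²) — the denominator is exactly the
    Propagation-of-Error SE; p is two-sided normal.
    """
    indirect, se = indirect_effect_poe(a, se_a, b, se_b)
    if se == 0:
        raise ValueError("degenerate Sobel denominator: a = b = 0")
    z = indirect / se
    return z, float(min(1.0, max(2.0 * stats.norm.sf(abs(z)), 5e-324)))


def mediated_proportion(
    indirect: float, beta_c: float, se_indirect: float, se_c: float
) -> tuple[float, float | None]:
    """Fraction of the total effect carried by the mediator.

    proportion = indirect/βc (multiply by 100 for percent); its SE uses
    first-order ratio propagation and is None when indirect = 0.
    """
    if beta_c == 0:
        raise ValueError("undefined proportion: total effect beta_c is zero")
    prop = indirect / beta_c
    if indirect == 0:
        return prop, None
    rel = math.sqrt((se_indirect / indirect) ** 2 + (se_c / beta_c) ** 2)
    return prop, abs(prop) * rel


def decompose_mediation(
    beta_a: EffectBlock,
    beta_b: EffectBlock,
    beta_c: EffectBlock,
    beta_b_adj: EffectBlock | None = None,
    beta_c_adj: EffectBlock | None = None,
    alpha: float = 0.05,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Apply the mediation decision rule to precomputed stage estimates.

    Route selection: Propagation of Error on βa·βb′ when the adjusted
    mediator effect βb′ is significant; otherwise the Sobel test on the
    unadjusted βa·βb decides (p < alpha → Sobel route); otherwise no
    proportion is reported.  The proportion is always taken against the
    total effect βc.
    """
    sobel_z, sobel_p = None, None
    if not (beta_a.beta == 0 and beta_b.beta == 0):
        sobel_z, sobel_p = sobel_test(beta_a.beta, beta_a.se, beta_b.beta, beta_b.se)

    if beta_b_adj is not None and beta_b_adj.significant:
        method = POE
        indirect, ind_se = indirect_effect_poe(
            beta_a.beta, beta_a.se, beta_b_adj.beta, beta_b_adj.se
        )
    elif sobel_p is not None and sobel_p < alpha:
        method = SOBEL
        indirect, ind_se = indirect_effect_poe(
            beta_a.beta, beta_a.se, beta_b.beta, beta_b.se
        )
    else:
        method = NOT_AVAILABLE
        indirect, ind_se = indirect_effect_poe(
            beta_a.beta, beta_a.se, beta_b.beta, beta_b.se
        )

    if method == NOT_AVAILABLE:
        prop, prop_se = None, None
    else:
        prop, prop_se = mediated_proportion(indirect, beta_c.beta, ind_se, beta_c.se)

    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        beta_a=beta_a,
        beta_b=beta_b,
        beta_c=beta_c,
        beta_b_adj=beta_b_adj,
        beta_c_adj=beta_c_adj,
        indirect=indirect,
        indirect_se=ind_se,
        sobel_z=sobel_z,
        sobel_p=sobel_p,
        proportion=prop,
        proportion_se=prop_se,
        method_flag=method,
    )


def _select_instruments(
    records: Sequence[SummaryStatRecord],
    pval_threshold: float,
    ld,
    clump_r2: float,
    clump_kb: int,
) -> list[SummaryStatRecord]:
    return ld_clump(
        filter_by_pvalue(records, pval_threshold),
        ld=ld,
        r2_threshold=clump_r2,
        kb_window=clump_kb,
    )


def run_two_step_mediation(
    exposure: Sequence[SummaryStatRecord],
    mediator: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
    pval_threshold_exposure: float = 5e-6,
    pval_threshold_mediator: float = 5e-6,
    ld=None,
    clump_r2: float = 0.001,
    clump_kb: int = 10_000,
    alpha: float = 0.05,
) -> MediationResult:
    """Full two-step mediation analysis from three summary-stat tables.

    Stages: (1) βa = IVW of exposure instruments on the mediator;
    (2) βb = IVW of mediator instruments on the outcome; (3) βc = IVW of
    exposure instruments on the outcome; (4) MVMR of outcome on
    (exposure, mediator) gives βc′ and βb′; (5) the decision rule of
    :func:`decompose_mediation`.  Stage failures raise
    :class:`StageError` naming the stage.
    """

    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise StageError(name, str(exc)) from exc

    inst_x = stage(
        "instrument-selection:exposure",
        lambda: _select_instruments(exposure, pval_threshold_exposure, ld, clump_r2, clump_kb),
    )
    inst_m = stage(
        "instrument-selection:mediator",
        lambda: _select_instruments(mediator, pval_threshold_mediator, ld, clump_r2, clump_kb),
    )
    if not inst_x:
        raise StageError("instrument-selection:exposure", "no instruments pass threshold")

    beta_a = stage(
        "beta_a", lambda: EffectBlock.from_result(ivw_headline(harmonize(inst_x, mediator)))
    )
    beta_c = stage(
        "beta_c", lambda: EffectBlock.from_result(ivw_headline(harmonize(inst_x, outcome)))
    )
    if not inst_m:
        # An uninstrumentable mediator: the two-step decomposition cannot
        # be carried out, which is a not-available verdict, not a failure.
        nan_block = EffectBlock(math.nan, math.nan)
        return MediationResult(
            exposure=exposure_name,
            mediator=mediator_name,
            outcome=outcome_name,
            beta_a=beta_a,
            beta_b=nan_block,
            beta_c=beta_c,
            beta_b_adj=None,
            beta_c_adj=None,
            indirect=math.nan,
            indirect_se=math.nan,
            sobel_z=None,
            sobel_p=None,
            proportion=None,
            proportion_se=None,
            method_flag=NOT_AVAILABLE,
            extra={"note": "mediator has no instruments at the configured threshold"},
        )
    beta_b = stage(
        "beta_b", lambda: EffectBlock.from_result(ivw_headline(harmonize(inst_m, outcome)))
    )

    def fit_mvmr():
        mh = mvmr_harmonize(
            [exposure, mediator],
            outcome,
            exposure_names=[exposure_name, mediator_name],
            pval_threshold=max(pval_threshold_exposure, pval_threshold_mediator),
            ld=ld,
            clump_r2=clump_r2,
            clump_kb=clump_kb,
        )
        return mvmr_fit(mh)

    mv = stage("mvmr", fit_mvmr)
    c_adj = mv.block(exposure_name)
    b_adj = mv.block(mediator_name)

    return decompose_mediation(
        beta_a=beta_a,
        beta_b=beta_b,
        beta_c=beta_c,
        beta_b_adj=EffectBlock(
            b_adj["beta"], b_adj["se"], b_adj["ci_low"], b_adj["ci_high"], b_adj["pval"]
        ),
        beta_c_adj=EffectBlock(
            c_adj["beta"], c_adj["se"], c_adj["ci_low"], c_adj["ci_high"], c_adj["pval"]
        ),
        alpha=alpha,
        exposure=exposure_name,
        mediator=mediator_name,
        outcome=outcome_name,
    )
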