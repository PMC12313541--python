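"""Bundled worked-example summary results.

These constants are the printed summary results of a published two-sample
MR study of beverage intake and irritable bowel syndrome (IBS) with
psychiatric-disorder mediation.  They are inputs for worked examples and
end-to-end arithmetic checks: a ten-exposure beverage panel with raw and
FDR-adjusted p-values, and a five-mediator decomposition table with the
coefficient blocks βc, βa, βb, βc′, βb′ (each with its printed 95% CI),
the published method route and the published mediated proportion.

Standard errors are not printed in the source tables; wherever one is
needed it is back-derived from the 95% CI as width/(2·1.96).
"""

from __future__ import annotations

from .mediation import NOT_AVAILABLE, POE, SOBEL, EffectBlock

__all__ = [
    "BEVERAGE_PANEL",
    "BEVERAGE_PANEL_ADJUSTED",
    "MEDIATION_TABLE",
    "TOTAL_EFFECT_BETA",
    "TOTAL_EFFECT_CI",
    "TOTAL_EFFECT_OR",
    "TOTAL_EFFECT_OR_CI",
]

# Beverage-panel IVW p-values against IBS: exposure -> (n_snp, raw p,
# published BH-adjusted p, published OR, published OR 95% CI).
BEVERAGE_PANEL: dict[str, tuple[int, float, float, float, tuple[float, float]]] = {
    "drinks_per_week": (91, 1.14e-4, 5.70e-4, 1.26, (1.12, 1.42)),
    "alcohol_intake_frequency": (79, 1.10e-5, 1.10e-4, 1.18, (1.09, 1.26)),
    "water_intake": (140, 0.03, 0.10, 1.16, (1.01, 1.34)),
    "milk_intake": (9, 0.23, 0.38, 0.21, (0.02, 2.65)),
    "honey_intake": (39, 0.79, 0.79, 0.98, (0.82, 1.17)),
    "coffee_intake": (39, 0.31, 0.39, 0.87, (0.67, 1.13)),
    "orange_juice_intake": (12, 0.44, 0.49, 0.92, (0.74, 1.14)),
    "pure_fruit_vegetable_juice_intake": (8, 0.14, 0.28, 1.34, (0.91, 1.97)),
    "grapefruit_juice_intake": (19, 0.28, 0.39, 0.80, (0.53, 1.21)),
    "yogurt_intake": (9, 0.06, 0.15, 0.80, (0.63, 1.01)),
}

#: exposure -> published BH-adjusted p (display precision of the source).
BEVERAGE_PANEL_ADJUSTED = {name: row[2] for name, row in BEVERAGE_PANEL.items()}

# Total effect of alcohol intake frequency on IBS (log-odds and 95% CI)
# and its published odds-ratio view.
TOTAL_EFFECT_BETA = 0.162
TOTAL_EFFECT_CI = (0.090, 0.234)
TOTAL_EFFECT_OR = 1.18
TOTAL_EFFECT_OR_CI = (1.09, 1.26)

def _block(beta: float, lo: float, hi: float) -> EffectBlock:
    return EffectBlock.from_ci(beta, lo, hi)


# Mediation decomposition rows (exposure = alcohol intake frequency,
# outcome = IBS).  Published proportion is in percent; None = not
# available in the source.
MEDIATION_TABLE: list[dict] = [
    {
        "mediator": "depression_broad",
        "beta_c": _block(0.162, 0.090, 0.234),
        "beta_a": _block(0.033, 0.015, 0.050),
        "beta_b": _block(0.42, 0.321, 0.519),
        "beta_c_adj": _block(0.082, 0.019, 0.144),
        "beta_b_adj": _block(1.238, 0.911, 1.565),
        "published_method": POE,
        "published_proportion_pct": 25.22,
    },
    {
        "mediator": "major_depressive_disorder",
        "beta_c": _block(0.162, 0.090, 0.234),
        "beta_a": _block(0.111, 0.057, 0.165),
        "beta_b": _block(0.293, 0.243, 0.343),
        "beta_c_adj": _block(-0.009, -0.105, 0.087),
        "beta_b_adj": _block(0.668, 0.403, 0.933),
        "published_method": POE,
        "published_proportion_pct": 45.77,
    },
    {
        "mediator": "adhd",
        "beta_c": _block(0.162, 0.090, 0.234),
        "beta_a": _block(0.318, 0.212, 0.424),
        "beta_b": _block(0.062, 0.034, 0.089),
        "beta_c_adj": _block(0.141, 0.033, 0.249),
        "beta_b_adj": _block(0.084, -0.039, 0.207),
        "published_method": SOBEL,
        "published_proportion_pct": 12.10,
    },
    {
        "mediator": "ptsd",
        "beta_c": _block(0.162, 0.090, 0.234),
        "beta_a": _block(0.385, 0.226, 0.544),
        "beta_b": _block(0.002, -0.041, 0.045),
        "beta_c_adj": _block(0.114, 0.021, 0.207),
        "beta_b_adj": _block(-0.017, -0.124, 0.091),
        "published_method": NOT_AVAILABLE,
        "published_proportion_pct": None,
    },
    {
        "mediator": "postpartum_depression",
        "beta_c": _block(0.162, 0.090, 0.234),
        "beta_a": _block(0.198, 0.054, 0.342),
        "beta_b": _block(-0.008, -0.028, 0.014),
        "beta_c_adj": _block(0.113, 0.020, 0.206),
        "beta_b_adj": _block(-0.01, -0.132, 0.111),
        "published_method": NOT_AVAILABLE,
        "published_proportion_pct": None,
    },
]
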