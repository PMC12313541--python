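"""Benjamini–Hochberg FDR across an exposure panel and results assembly."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .estimators import MrResult

__all__ = ["bh_adjust", "bonferroni_adjust", "assemble_panel", "PanelRow"]


def _validate_pvals(pvals: Sequence[float]) -> np.ndarray:
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value list")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return arr


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min over j ≥ i of min(1, m·p_(j)/j) on the ascending sort,
    mapped back to the original order; ties share the smaller value.
    """
    arr = _validate_pvals(pvals)
    return multipletests(arr, method="fdr_bh")[1]


def bonferroni_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment (utility only; BH is the reporting default)."""
    arr = _validate_pvals(pvals)
    return np.minimum(1.0, arr * arr.size)


class PanelRow(dict):
    """A Table-1-style row; plain mapping with attribute sugar."""

    def __getattr__(self, item):
        try:
            return self[item]
        except KeyError as exc:
            raise AttributeError(item) from exc


def _fmt_p(p: float) -> str:
    return f"{p:.2e}" if p < 0.01 else f"{p:.2f}"


def assemble_panel(
    results: Mapping[str, MrResult] | Iterable[tuple[str, MrResult]],
    alpha: float = 0.05,
    gwas_ids: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH-adjust a panel of primary (IVW) results and build report tables.

    Returns ``(panel, forest)``: the panel is sorted by adjusted p-value
    and keeps full-precision columns alongside display-rounded ones
    (OR to 2 dp, p at 3 significant digits); the forest table carries
    (label, or, or_low, or_high) plotting coordinates.  Duplicate
    exposure labels raise; an empty panel raises.
    """
    pairs = list(results.items()) if isinstance(results, Mapping) else list(results)
    if not pairs:
        raise ValueError("empty results panel")
    labels = [lab for lab, _ in pairs]
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"duplicate exposure labels: {', '.join(dupes)}")

    padj = bh_adjust([res.pval for _, res in pairs])
    rows = []
    for (label, res), adj in zip(pairs, padj):
        rows.append(
            PanelRow(
                exposure=label,
                gwas_id=(gwas_ids or {}).get(label, ""),
                n_snp=res.n_snp,
                pval=res.pval,
                pval_adj=float(adj),
                significant=bool(adj < alpha),
                or_=res.or_,
                or_low=res.or_low,
                or_high=res.or_high,
                beta=res.beta,
                se=res.se,
                method=res.method,
            )
        )
    panel = pd.DataFrame(rows).sort_values("pval_adj", kind="stable").reset_index(drop=True)
    panel["or_display"] = panel["or_"].map(lambda v: f"{v:.2f}")
    panel["ci_display"] = [
        f"{lo:.2f}-{hi:.2f}" for lo, hi in zip(panel["or_low"], panel["or_high"])
    ]
    panel["p_display"] = panel["pval"].map(lambda p: f"{p:.3g}")
    panel["padj_display"] = panel["pval_adj"].map(lambda p: f"{p:.3g}")
    forest = panel[["exposure", "or_", "or_low", "or_high"]].rename(
        columns={"exposure": "label"}
    )
    return panel, forest
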