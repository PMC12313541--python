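"""Config-driven orchestration: panel MR → sensitivity → mediation → report.

One YAML config describes exposures (each with its own instrument p-value
threshold), the outcome, optional mediators, thresholds and the seed.
``run_pipeline`` executes instrument selection, harmonization, all
estimators, the sensitivity suite, mediation decompositions and the
FDR-adjusted panel, writing tab-delimited tables plus a provenance
manifest.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .estimators import MrResult, ivw, ivw_headline, mr_egger, weighted_median, weighted_mode
from .gwas_io import HarmonizedSet, harmonize, read_summary_stats
from .instruments import filter_by_pvalue, ld_clump, read_ld_matrix
from .mediation import run_two_step_mediation
from .multiplicity import assemble_panel
from .sensitivity import cochran_q, funnel_coordinates, leave_one_out, mr_presso, pleiotropy_test

__all__ = ["RunConfig", "TraitSource", "run_pipeline", "load_config", "run_methods",
           "write_harmonized", "read_harmonized"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class TraitSource:
    name: str
    path: str
    pval_threshold: float = 5e-6
    gwas_id: str = ""


@dataclass
class RunConfig:
    exposures: list[TraitSource]
    outcome: TraitSource
    mediators: list[TraitSource] = field(default_factory=list)
    mediation_exposure: str | None = None  # defaults to the first exposure
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    alpha: float = 0.05
    methods: tuple[str, ...] = ("ivw", "egger")
    n_boot: int = 1000
    presso_nsim: int = 1000
    ld_matrix: str | None = None
    seed: int = 0
    output_dir: str = "tsmr_run"

    def validate(self) -> None:
        if not self.exposures:
            raise ValueError("at least one exposure is required")
        for thr in [s.pval_threshold for s in self.exposures + self.mediators]:
            if not (0 < thr <= 1):
                raise ValueError("pval thresholds must lie in (0, 1]")
        if self.clump_r2 <= 0 or self.clump_kb <= 0 or self.alpha <= 0:
            raise ValueError("thresholds must be positive")

    def canonical_json(self) -> str:
        def enc(obj: Any):
            if isinstance(obj, TraitSource):
                return vars(obj)
            raise TypeError(type(obj))

        return json.dumps(vars(self), default=enc, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())

    def source(d: dict) -> TraitSource:
        return TraitSource(
            name=d["name"],
            path=d["path"],
            pval_threshold=float(d.get("pval_threshold", 5e-6)),
            gwas_id=d.get("gwas_id", ""),
        )

    thresholds = raw.get("thresholds", {})
    return RunConfig(
        exposures=[source(d) for d in raw["exposures"]],
        outcome=source(raw["outcome"]),
        mediators=[source(d) for d in raw.get("mediators", [])],
        mediation_exposure=raw.get("mediation_exposure"),
        clump_r2=float(thresholds.get("clump_r2", 0.001)),
        clump_kb=int(thresholds.get("clump_kb", 10_000)),
        alpha=float(thresholds.get("alpha", 0.05)),
        methods=tuple(raw.get("methods", ["ivw", "egger"])),
        n_boot=int(raw.get("n_boot", 1000)),
        presso_nsim=int(raw.get("presso_nsim", 1000)),
        ld_matrix=raw.get("ld_matrix"),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "tsmr_run"),
    )


# ---------------------------------------------------------------------------
# Harmonized-set TSV round trip (CLI interchange format)
# ---------------------------------------------------------------------------

def write_harmonized(hset: HarmonizedSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp": hset.snp_ids,
            "beta_exposure": hset.beta_exposure,
            "se_exposure": hset.se_exposure,
            "beta_outcome": hset.beta_outcome,
            "se_outcome": hset.se_outcome,
            "eaf": hset.eaf,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def read_harmonized(path: str | Path) -> HarmonizedSet:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    return HarmonizedSet(
        snp_ids=df["snp"].astype(str).tolist(),
        beta_exposure=df["beta_exposure"].to_numpy(),
        se_exposure=df["se_exposure"].to_numpy(),
        beta_outcome=df["beta_outcome"].to_numpy(),
        se_outcome=df["se_outcome"].to_numpy(),
        eaf=df["eaf"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def run_methods(
    hset: HarmonizedSet,
    methods: Sequence[str] = ("ivw", "egger", "wmedian", "wmode"),
    n_boot: int = 5000,
    seed: int | None = None,
) -> list[MrResult]:
    """Run the requested estimators on one harmonized set."""
    out: list[MrResult] = []
    for method in methods:
        if method == "ivw":
            out.extend(ivw(hset))
        elif method == "egger":
            out.append(mr_egger(hset))
        elif method == "wmedian":
            out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
        elif method == "wmode":
            out.append(weighted_mode(hset, n_boot=n_boot, seed=seed))
        else:
            raise ValueError(f"unknown method {method!r}")
    return out


def results_frame(rows: list[tuple[str, str, MrResult]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "exposure": exp,
                "outcome": out,
                "method": r.method,
                "nsnp": r.n_snp,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "or": r.or_,
                "or_lci": r.or_low,
                "or_uci": r.or_high,
            }
            for exp, out, r in rows
        ]
    )


def sensitivity_suite(
    hset: HarmonizedSet,
    out_dir: Path,
    presso_nsim: int = 1000,
    seed: int | None = None,
) -> dict[str, int]:
    """Write het/pleio/loo/presso/funnel tables; returns row counts."""
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    het_rows = [vars(cochran_q(hset, "ivw"))]
    if hset.n_snp >= 3:
        het_rows.append(vars(cochran_q(hset, "egger")))
    het = pd.DataFrame(het_rows)
    het.to_csv(out_dir / "het.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    counts["het"] = len(het)
    if hset.n_snp >= 3:
        pleio = pd.DataFrame([pleiotropy_test(hset)])
        pleio.to_csv(out_dir / "pleio.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        counts["pleio"] = len(pleio)
        loo = leave_one_out(hset)
        loo.to_csv(out_dir / "loo.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        counts["loo"] = len(loo)
    if hset.n_snp >= 4:
        presso = mr_presso(hset, n_sim=presso_nsim, seed=seed)
        pd.DataFrame(
            {
                "snp": list(presso.outlier_pvals),
                "outlier_pval_adj": list(presso.outlier_pvals.values()),
                "is_outlier": [s in presso.outliers for s in presso.outlier_pvals],
                "global_rss": presso.global_rss,
                "global_pval": presso.global_pval,
                "beta_raw": presso.beta_raw,
                "beta_corrected": presso.beta_corrected,
            }
        ).to_csv(out_dir / "presso.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        counts["presso_outliers"] = len(presso.outliers)
    funnel = funnel_coordinates(hset)
    funnel.to_csv(out_dir / "funnel.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    counts["funnel"] = len(funnel)
    return counts


def mediation_frame(results) -> pd.DataFrame:
    def fmt(block):
        if block is None:
            return "NA"
        return f"{block.beta:.3f} ({block.ci_low:.3f}-{block.ci_high:.3f})"

    return pd.DataFrame(
        [
            {
                "exposure": m.exposure,
                "outcome": m.outcome,
                "mediator": m.mediator,
                "beta_c": fmt(m.beta_c),
                "beta_a": fmt(m.beta_a),
                "beta_b": fmt(m.beta_b),
                "beta_c_adj": fmt(m.beta_c_adj),
                "beta_b_adj": fmt(m.beta_b_adj),
                "sobel_p": "NA" if m.sobel_p is None else f"{m.sobel_p:.3g}",
                "proportion_pct": (
                    "NA" if m.proportion_pct is None else f"{m.proportion_pct:.2f}"
                ),
                "method_flag": m.method_flag,
                "indirect": m.indirect,
                "indirect_se": m.indirect_se,
            }
            for m in results
        ]
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow and write the run directory.

    Aborts on the first stage error, naming the stage and input; partial
    outputs are flagged in the manifest.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ld = read_ld_matrix(config.ld_matrix) if config.ld_matrix else None

    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "complete": False,
    }

    def fail(stage: str, path: str, exc: Exception):
        manifest["error"] = {"stage": stage, "input": path, "message": str(exc)}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed on {path}: {exc}") from exc

    try:
        outcome_records, _ = read_summary_stats(config.outcome.path)
    except Exception as exc:  # noqa: BLE001
        fail("read:outcome", config.outcome.path, exc)

    headline: list[tuple[str, MrResult]] = []
    all_rows: list[tuple[str, str, MrResult]] = []
    for i, src in enumerate(config.exposures):
        stage_counts: dict[str, int] = {}
        try:
            records, read_log = read_summary_stats(src.path)
            stage_counts["rows_read"] = read_log.n_kept
            inst = ld_clump(
                filter_by_pvalue(records, src.pval_threshold),
                ld=ld,
                r2_threshold=config.clump_r2,
                kb_window=config.clump_kb,
            )
            stage_counts["instruments_selected"] = len(inst)
            hset = harmonize(inst, outcome_records)
            stage_counts["instruments_harmonized"] = hset.n_snp
            hset.write_provenance(out_dir / f"harmonization_{src.name}.tsv")
            write_harmonized(hset, out_dir / f"harmonized_{src.name}.tsv")
            seed_i = config.seed + 1000 * (i + 1)
            for res in run_methods(hset, config.methods, n_boot=config.n_boot, seed=seed_i):
                all_rows.append((src.name, config.outcome.name, res))
            head = ivw_headline(hset)
            stage_counts["instruments_used"] = head.n_snp
            headline.append((src.name, head))
            stage_counts.update(
                sensitivity_suite(
                    hset,
                    out_dir / "sens" / src.name,
                    presso_nsim=config.presso_nsim,
                    seed=seed_i + 1,
                )
            )
        except Exception as exc:  # noqa: BLE001
            fail(f"exposure:{src.name}", src.path, exc)
        manifest["stages"][src.name] = stage_counts

    results_frame(all_rows).to_csv(
        out_dir / "results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    try:
        panel, forest = assemble_panel(
            headline,
            alpha=config.alpha,
            gwas_ids={s.name: s.gwas_id for s in config.exposures},
        )
        panel.to_csv(out_dir / "panel.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    except Exception as exc:  # noqa: BLE001
        fail("report", "panel", exc)

    if config.mediators:
        med_exp_name = config.mediation_exposure or config.exposures[0].name
        med_exp = next(s for s in config.exposures if s.name == med_exp_name)
        exp_records, _ = read_summary_stats(med_exp.path)
        med_results = []
        for med in config.mediators:
            try:
                med_records, _ = read_summary_stats(med.path)
                med_results.append(
                    run_two_step_mediation(
                        exp_records,
                        med_records,
                        outcome_records,
                        exposure_name=med_exp.name,
                        mediator_name=med.name,
                        outcome_name=config.outcome.name,
                        pval_threshold_exposure=med_exp.pval_threshold,
                        pval_threshold_mediator=med.pval_threshold,
                        ld=ld,
                        clump_r2=config.clump_r2,
                        clump_kb=config.clump_kb,
                        alpha=config.alpha,
                    )
                )
            except Exception as exc:  # noqa: BLE001
                fail(f"mediation:{med.name}", med.path, exc)
        mediation_frame(med_results).to_csv(
            out_dir / "mediation.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        manifest["stages"]["mediation"] = {"rows": len(med_results)}

    manifest["complete"] = True
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
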