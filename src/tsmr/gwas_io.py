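"""Reading, writing and harmonizing GWAS summary statistics.

Summary statistics are tab- (or comma-) delimited tables with one row per
SNP.  Canonical column names are ``snp, chr, pos, effect_allele,
other_allele, eaf, beta, se, pval, n``; ``"NA"`` marks a missing value.
Non-canonical headers can be remapped through a ``column_map``.

Harmonization aligns an exposure and an outcome table onto a single
effect-allele convention so that every retained SNP contributes a
(beta_exposure, beta_outcome) pair measured with respect to the same
allele.  Palindromic variants (A/T, C/G) are oriented by allele frequency
or dropped when the frequency is uninformative; every per-SNP decision is
recorded in a provenance log.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SummaryStatRecord",
    "ReadLog",
    "HarmonizedSet",
    "ConfigError",
    "EmptyInputError",
    "EmptyOverlapError",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "CANONICAL_COLUMNS",
]

CANONICAL_COLUMNS = (
    "snp",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class ConfigError(ValueError):
    """A configuration problem, e.g. an unresolvable mandatory column."""


class EmptyInputError(ValueError):
    """An input file contained no data rows."""


class EmptyOverlapError(ValueError):
    """Exposure and outcome share no SNP identifiers."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait); ``eaf`` is the effect-allele frequency and may be
    missing (``None``), as may the sample size ``n``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    def validate(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: identical alleles")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")

    @property
    def is_snp(self) -> bool:
        """True for single-base A/C/G/T biallelic records."""
        return (
            self.effect_allele in _VALID_ALLELES
            and self.other_allele in _VALID_ALLELES
            and self.effect_allele != self.other_allele
        )

    @property
    def is_palindromic(self) -> bool:
        return self.is_snp and _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class ReadLog:
    """Row accounting for one parsed summary-statistics file."""

    n_rows: int = 0
    n_kept: int = 0
    drops: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.drops)


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effects sharing one allele convention.

    This is the unit every univariable estimator consumes.  Arrays are
    parallel; ``eaf`` holds NaN where the frequency is unknown.  The
    ``provenance`` log accounts for every SNP in the exposure/outcome
    overlap: ``(snp_id, action, reason)`` with action in
    {kept, sign-flipped, strand-flipped, dropped}.
    """

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    eaf: np.ndarray
    n_exposure: int | None = None
    n_outcome: int | None = None
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.snp_ids)
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome", "eaf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (k,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({k},)")
            setattr(self, name, arr)
        if k == 0:
            raise ValueError("HarmonizedSet must contain at least one SNP")
        if len(set(self.snp_ids)) != k:
            raise ValueError("duplicate SNP identifiers in HarmonizedSet")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def subset(self, index: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        idx = np.asarray(index, dtype=int)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            eaf=self.eaf[idx],
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
            provenance=list(self.provenance),
        )

    def write_provenance(self, path: str | Path) -> None:
        """Write the per-SNP harmonization decisions as a sidecar TSV."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["snp", "action", "reason"])
            writer.writerows(self.provenance)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_float(token: str) -> float | None:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "NAN", "."}:
        return None
    try:
        value = float(token)
    except ValueError:
        return None
    if math.isnan(value):
        return None
    return value


def _parse_int(token: str) -> int | None:
    value = _parse_float(token)
    if value is None:
        return None
    return int(round(value))


def read_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], ReadLog]:
    """Parse a summary-statistics table into records.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"snp": "MarkerName", "pval": "P"}``.  Rows whose beta/se/pval do not
    parse (or violate basic domain constraints) are dropped and counted in
    the returned :class:`ReadLog`; input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if first == "":
            raise EmptyInputError(f"{path}: empty file")
        delimiter = "\t" if first.count("\t") >= first.count(",") else ","
        header = [h.strip() for h in first.rstrip("\n").split(delimiter)]
        colmap = dict(column_map or {})
        index: dict[str, int] = {}
        for canonical in CANONICAL_COLUMNS:
            name = colmap.get(canonical, canonical)
            if name in header:
                index[canonical] = header.index(name)
        for canonical in MANDATORY_COLUMNS:
            if canonical not in index:
                raise ConfigError(
                    f"{path}: mandatory column {canonical!r} not found "
                    f"(looked for {colmap.get(canonical, canonical)!r})"
                )

        records: list[SummaryStatRecord] = []
        log = ReadLog()
        reader = csv.reader(fh, delimiter=delimiter)
        for row_number, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            log.n_rows += 1

            def cell(name: str) -> str:
                i = index.get(name)
                return row[i].strip() if i is not None and i < len(row) else ""

            beta = _parse_float(cell("beta"))
            se = _parse_float(cell("se"))
            pval = _parse_float(cell("pval"))
            if beta is None or se is None or pval is None:
                log.drops.append((row_number, "unparseable beta/se/pval"))
                continue
            if se <= 0:
                log.drops.append((row_number, "non-positive se"))
                continue
            if not (0 < pval <= 1):
                log.drops.append((row_number, "pval outside (0, 1]"))
                continue
            eaf = _parse_float(cell("eaf"))
            if eaf is not None and not (0 <= eaf <= 1):
                log.drops.append((row_number, "eaf outside [0, 1]"))
                continue
            chrom_token = cell("chr")
            record = SummaryStatRecord(
                snp_id=cell("snp"),
                effect_allele=cell("effect_allele").upper(),
                other_allele=cell("other_allele").upper(),
                beta=beta,
                se=se,
                pval=pval,
                chrom=None if chrom_token.upper() in {"", "NA"} else chrom_token,
                pos=_parse_int(cell("pos")),
                eaf=eaf,
                n=_parse_int(cell("n")),
            )
            if record.effect_allele == record.other_allele:
                log.drops.append((row_number, "identical alleles"))
                continue
            records.append(record)
            log.n_kept += 1
        if log.n_rows == 0:
            raise EmptyInputError(f"{path}: no data rows")
    return records, log


def write_summary_stats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical tab-delimited table (``NA`` = missing).

    Round-trips: ``read_summary_stats(write_summary_stats(x)) == x``
    field-for-field.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CANONICAL_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.snp_id,
                    rec.chrom if rec.chrom is not None else "NA",
                    rec.pos if rec.pos is not None else "NA",
                    rec.effect_allele,
                    rec.other_allele,
                    repr(rec.eaf) if rec.eaf is not None else "NA",
                    repr(rec.beta),
                    repr(rec.se),
                    repr(rec.pval),
                    rec.n if rec.n is not None else "NA",
                ]
            )


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _flip_outcome(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Swap the outcome record's allele roles: negate beta, mirror eaf."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def _complement(rec: SummaryStatRecord) -> SummaryStatRecord:
    return replace(
        rec,
        effect_allele=_COMPLEMENT[rec.effect_allele],
        other_allele=_COMPLEMENT[rec.other_allele],
    )


def _median_n(records: Sequence[SummaryStatRecord]) -> int | None:
    ns = [r.n for r in records if r.n is not None]
    if not ns:
        return None
    return int(np.median(ns))


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele convention.

    Matching is by SNP identifier.  Per overlapping SNP:

    * identical alleles — kept as-is;
    * swapped alleles — outcome beta sign-flipped, eaf mirrored;
    * strand complements — outcome alleles complemented, then as above;
    * palindromic (A/T or C/G) — oriented by allele frequency: kept only
      when both frequencies are known, both lie outside
      ``0.5 ± palindrome_eaf_window``, and (after nominal allele alignment)
      they fall on the same side of 0.5; otherwise dropped;
    * anything else (incompatible or non-SNP alleles) — dropped.

    Every overlap SNP is accounted for in the provenance log.  Raises
    :class:`EmptyOverlapError` if no SNP identifier is shared.
    """
    if not exposure or not outcome:
        raise ValueError("exposure and outcome record lists must be nonempty")
    outcome_by_id: dict[str, SummaryStatRecord] = {}
    for rec in outcome:
        outcome_by_id.setdefault(rec.snp_id, rec)

    overlap = [r for r in exposure if r.snp_id in outcome_by_id]
    if not overlap:
        raise EmptyOverlapError("no overlapping SNPs between exposure and outcome")

    prov: list[tuple[str, str, str]] = []
    kept_exp: list[SummaryStatRecord] = []
    kept_out: list[SummaryStatRecord] = []
    seen: set[str] = set()

    for exp in overlap:
        out = outcome_by_id[exp.snp_id]
        if exp.snp_id in seen:
            prov.append((exp.snp_id, "dropped", "duplicate-snp-id"))
            continue
        seen.add(exp.snp_id)
        if not exp.is_snp or not out.is_snp:
            prov.append((exp.snp_id, "dropped", "non-snp-allele"))
            continue

        if exp.is_palindromic:
            if not out.is_palindromic or {out.effect_allele, out.other_allele} != {
                exp.effect_allele,
                exp.other_allele,
            }:
                prov.append((exp.snp_id, "dropped", "incompatible-alleles"))
                continue
            # Nominal alignment by allele label first.
            aligned = out if out.effect_allele == exp.effect_allele else _flip_outcome(out)
            if exp.eaf is None or aligned.eaf is None:
                prov.append((exp.snp_id, "dropped", "palindromic-missing-eaf"))
                continue
            if (
                abs(exp.eaf - 0.5) <= palindrome_eaf_window
                or abs(aligned.eaf - 0.5) <= palindrome_eaf_window
            ):
                prov.append((exp.snp_id, "dropped", "palindromic-ambiguous"))
                continue
            if (exp.eaf - 0.5) * (aligned.eaf - 0.5) < 0:
                # Frequencies disagree on orientation: a strand flip would be
                # required, but for a palindrome that is indistinguishable
                # from a genuine effect-allele mismatch.
                prov.append((exp.snp_id, "dropped", "palindromic-strand-inconsistent"))
                continue
            action = "kept" if aligned is out else "sign-flipped"
            prov.append((exp.snp_id, action, "palindromic-oriented-by-frequency"))
            kept_exp.append(exp)
            kept_out.append(aligned)
            continue

        exp_alleles = (exp.effect_allele, exp.other_allele)
        if (out.effect_allele, out.other_allele) == exp_alleles:
            prov.append((exp.snp_id, "kept", "identical-alleles"))
            kept_exp.append(exp)
            kept_out.append(out)
        elif (out.other_allele, out.effect_allele) == exp_alleles:
            prov.append((exp.snp_id, "sign-flipped", "swapped-alleles"))
            kept_exp.append(exp)
            kept_out.append(_flip_outcome(out))
        else:
            comp = _complement(out)
            if (comp.effect_allele, comp.other_allele) == exp_alleles:
                prov.append((exp.snp_id, "strand-flipped", "strand-complement"))
                kept_exp.append(exp)
                kept_out.append(comp)
            elif (comp.other_allele, comp.effect_allele) == exp_alleles:
                prov.append((exp.snp_id, "strand-flipped", "strand-complement-swapped"))
                kept_exp.append(exp)
                kept_out.append(_flip_outcome(comp))
            else:
                prov.append((exp.snp_id, "dropped", "incompatible-alleles"))

    if not kept_exp:
        raise EmptyOverlapError(
            "no SNPs survived harmonization "
            f"({len(overlap)} overlapping, all dropped)"
        )

    return HarmonizedSet(
        snp_ids=[r.snp_id for r in kept_exp],
        beta_exposure=np.array([r.beta for r in kept_exp]),
        se_exposure=np.array([r.se for r in kept_exp]),
        beta_outcome=np.array([r.beta for r in kept_out]),
        se_outcome=np.array([r.se for r in kept_out]),
        eaf=np.array([np.nan if r.eaf is None else r.eaf for r in kept_exp]),
        n_exposure=_median_n(kept_exp),
        n_outcome=_median_n(kept_out),
        provenance=prov,
    )
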