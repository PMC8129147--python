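"""GWAS summary-statistics tables and LD matrices.

The canonical interchange dialect is a tab-separated table with header

    snp chrom pos effect_allele other_allele eaf beta se pval n

Missing optional values are written as ``NA``; floats are written at full
(round-trippable) precision.  A sidecar JSON file ``<path>.meta.json``
carries the trait name and type (continuous vs. binary on the log-odds
scale) so a written dataset re-reads identically.

LD matrices are square TSVs of r-squared values with the variant IDs as
both the header row and the first column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SUMSTATS_COLUMNS",
    "VALID_BASES",
    "SummaryDataset",
    "LDMatrix",
    "LoadReport",
    "SumstatsFormatError",
    "EmptyDatasetError",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
]

SUMSTATS_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: required by every record; the rest may be NA
REQUIRED_COLUMNS = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]

VALID_BASES = frozenset("ACGT")

TRAIT_CONTINUOUS = "continuous"
TRAIT_BINARY = "binary-logOR"


class SumstatsFormatError(ValueError):
    """Malformed summary-statistics or LD file."""


class EmptyDatasetError(ValueError):
    """A file yielded zero valid association records."""


@dataclass
class LoadReport:
    """Per-load audit: how many rows survived validation and why rows fell."""

    n_input: int = 0
    n_accepted: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (snp, reason)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.rejections:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


@dataclass
class SummaryDataset:
    """One trait's GWAS summary statistics, one row per variant.

    ``table`` holds the canonical columns (see :data:`SUMSTATS_COLUMNS`);
    ``snp`` keys are unique.  ``trait_type`` is metadata only — betas for a
    binary trait are log odds ratios but the container is agnostic.
    """

    trait_name: str
    trait_type: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in (TRAIT_CONTINUOUS, TRAIT_BINARY):
            raise ValueError(f"unknown trait_type: {self.trait_type!r}")
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset table missing columns: {missing}")
        if self.table["snp"].duplicated().any():
            raise ValueError("duplicate snp keys in dataset")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def subset(self, snps) -> "SummaryDataset":
        keep = self.table[self.table["snp"].isin(set(snps))]
        return SummaryDataset(self.trait_name, self.trait_type, keep.copy())


@dataclass
class LDMatrix:
    """Symmetric r-squared matrix over an ordered variant list."""

    snps: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snps)
        if self.r2.shape != (n, n):
            raise SumstatsFormatError(
                f"LD matrix shape {self.r2.shape} does not match {n} variant IDs"
            )
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0):
            raise SumstatsFormatError("LD matrix is not symmetric (tolerance 1e-12)")
        if not np.all(np.diag(self.r2) == 1.0):
            raise SumstatsFormatError("LD matrix diagonal must be exactly 1")
        if self.r2.min() < 0.0 or self.r2.max() > 1.0:
            raise SumstatsFormatError("LD r2 values must lie in [0, 1]")

    def lookup(self, snp_a: str, snp_b: str) -> float | None:
        """r2 between two variants, or None if either is absent."""
        try:
            i = self.snps.index(snp_a)
            j = self.snps.index(snp_b)
        except ValueError:
            return None
        return float(self.r2[i, j])


def _validate_row(row: pd.Series) -> str | None:
    """Return a rejection reason, or None if the record is valid."""
    snp = row["snp"]
    if not isinstance(snp, str) or not snp:
        return "missing snp ID"
    ea, oa = row["effect_allele"], row["other_allele"]
    for allele in (ea, oa):
        if not isinstance(allele, str) or not allele:
            return "missing allele"
        if allele != allele.upper() or not set(allele) <= VALID_BASES:
            return "non-ACGT allele"
        if len(allele) != 1:
            return "indel or multi-base allele"
    if ea == oa:
        return "identical alleles"
    if pd.isna(row["beta"]) or not np.isfinite(row["beta"]):
        return "missing beta"
    if pd.isna(row["se"]) or not np.isfinite(row["se"]) or row["se"] <= 0:
        return "nonpositive SE"
    p = row["pval"]
    if pd.isna(p) or not (0 < p <= 1):
        return "p-value outside (0,1]"
    eaf = row["eaf"]
    if not pd.isna(eaf) and not (0 < eaf < 1):
        return "EAF outside (0,1)"
    return None


def validate_table(raw: pd.DataFrame) -> tuple[pd.DataFrame, LoadReport]:
    """Validate rows, dropping invalid ones and duplicate snp keys (keep first)."""
    report = LoadReport(n_input=len(raw))
    reasons = raw.apply(_validate_row, axis=1) if len(raw) else pd.Series(dtype=object)
    keep_mask = reasons.isna() if len(raw) else pd.Series(dtype=bool)
    for _, row in raw[~keep_mask].iterrows() if len(raw) else []:
        report.rejections.append((str(row["snp"]), reasons.loc[row.name]))
    kept = raw[keep_mask].copy() if len(raw) else raw.copy()
    dup_mask = kept["snp"].duplicated() if len(kept) else pd.Series(dtype=bool)
    for snp in kept.loc[dup_mask, "snp"] if len(kept) else []:
        report.rejections.append((snp, "duplicate snp ID"))
    kept = kept[~dup_mask] if len(kept) else kept
    report.n_accepted = len(kept)
    return kept.reset_index(drop=True), report


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str | None = None,
) -> tuple[SummaryDataset, LoadReport]:
    """Read a summary-statistics table.

    ``column_map`` maps canonical column names to the file's header names
    for foreign dialects; the canonical header needs no map.  Rows that
    violate record invariants are dropped with a reason in the
    :class:`LoadReport`; a file with zero valid rows raises
    :class:`EmptyDatasetError`.
    """
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", dtype={"snp": str}, na_values=["NA"],
        float_precision="round_trip",
    )
    rename = {}
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required columns {missing}")
    for col in SUMSTATS_COLUMNS:
        if col not in raw.columns:
            raw[col] = np.nan
    raw = raw[SUMSTATS_COLUMNS]
    raw["snp"] = raw["snp"].astype(str)
    table, report = validate_table(raw)
    if len(table) == 0:
        raise EmptyDatasetError(f"{path}: no valid association records")

    meta_path = path.with_name(path.name + ".meta.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    dataset = SummaryDataset(
        trait_name=trait_name or meta.get("trait_name", path.stem),
        trait_type=trait_type or meta.get("trait_type", TRAIT_CONTINUOUS),
        table=table,
    )
    return dataset, report


def _format_value(x) -> str:
    if pd.isna(x):
        return "NA"
    if isinstance(x, str):
        return x
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_sumstats(dataset: SummaryDataset, path) -> None:
    """Write the canonical dialect plus the trait-metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SUMSTATS_COLUMNS) + "\n")
        for _, row in dataset.table.iterrows():
            fh.write("\t".join(_format_value(row[c]) for c in SUMSTATS_COLUMNS) + "\n")
    meta_path = path.with_name(path.name + ".meta.json")
    meta_path.write_text(
        json.dumps(
            {"trait_name": dataset.trait_name, "trait_type": dataset.trait_type},
            indent=1,
        )
    )


def read_ld(path) -> LDMatrix:
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    snps = [str(s) for s in raw.columns]
    if list(map(str, raw.index)) != snps:
        raise SumstatsFormatError(f"{path}: LD row IDs do not match column IDs")
    return LDMatrix(snps=snps, r2=raw.to_numpy(dtype=float))


def write_ld(matrix: LDMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("snp\t" + "\t".join(matrix.snps) + "\n")
        for snp, row in zip(matrix.snps, matrix.r2):
            fh.write(snp + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
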