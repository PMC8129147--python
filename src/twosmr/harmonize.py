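"""Instrument selection (P threshold + greedy LD pruning) and allele harmonization.

Selection keeps variants below a genome-wide significance threshold
(default P < 5e-8) and prunes them greedily: repeatedly retain the
remaining variant with the lowest P value and discard every remaining
variant correlated with it at r2 >= threshold (default 0.01).  Ties in P
are broken by lexicographic variant ID so selection is order-invariant.

Harmonization aligns the outcome dataset to the exposure's effect-allele
orientation, resolving transposed alleles (negate beta, reflect EAF),
strand flips (complement both alleles), and palindromic A/T-C/G variants
(orient by allele frequency when both EAFs are safely away from 0.5,
otherwise drop).  Every candidate variant gets exactly one audit-log entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import COMPLEMENT
from .sumstats import LDMatrix, SummaryDataset

__all__ = [
    "HarmonizedSet",
    "select_instruments",
    "harmonize",
    "DEFAULT_P_THRESHOLD",
    "DEFAULT_R2_THRESHOLD",
    "DEFAULT_PALINDROME_WINDOW",
]

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.01
DEFAULT_PALINDROME_WINDOW = 0.08

# audit-log actions
KEPT = "kept"
BETA_FLIPPED = "beta-flipped"
STRAND_FLIPPED = "strand-flipped"
STRAND_AND_BETA_FLIPPED = "strand-and-beta-flipped"
PALINDROME_FREQ_FLIPPED = "palindrome-freq-flipped"
DROPPED = "dropped"


@dataclass
class HarmonizedSet:
    """Aligned per-variant (beta_X, se_X, beta_Y, se_Y) for one exposure-outcome pair.

    ``table`` columns: snp, beta_x, se_x, beta_y, se_y, eaf.  ``audit`` has
    one row per candidate variant with the action taken and, for drops, the
    reason.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    audit: pd.DataFrame
    outcome_trait_type: str = "continuous"
    meta: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def action_counts(self) -> dict[str, int]:
        return self.audit["action"].value_counts().to_dict()


def select_instruments(
    exposure: SummaryDataset,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    ld: LDMatrix | None = None,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> SummaryDataset:
    """Significance filtering followed by greedy lowest-P LD pruning.

    Variants absent from ``ld`` are treated as independent of everything.
    An empty result is returned (not raised): single- and zero-instrument
    exposures are legitimate and handled downstream.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")

    sig = exposure.table[exposure.table["pval"] < p_threshold]
    # deterministic greedy order: lowest P first, ties by snp ID
    order = sig.sort_values(["pval", "snp"], kind="mergesort")

    if ld is not None:
        idx = {snp: i for i, snp in enumerate(ld.snps)}
    kept: list[str] = []
    remaining = list(order["snp"])
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        if ld is None or best not in idx:
            continue
        i = idx[best]
        remaining = [
            snp
            for snp in remaining
            if snp not in idx or ld.r2[i, idx[snp]] < r2_threshold
        ]

    kept_set = set(kept)
    table = exposure.table[exposure.table["snp"].isin(kept_set)].copy()
    return SummaryDataset(exposure.trait_name, exposure.trait_type, table)


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT.get(ea) == oa


def _freq_side(eaf: float) -> bool:
    """True when the effect allele is the minor one."""
    return eaf < 0.5


def harmonize(
    instruments: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedSet:
    """Align outcome effect alleles to the exposure orientation.

    Per shared variant: identical alleles are kept; transposed alleles
    negate beta_Y and reflect eaf_Y; a strand-complement match is
    complemented first and then resolved the same way.  Palindromic
    variants cannot be resolved by letters: when both EAFs are available
    and both lie outside [0.5 - w, 0.5 + w] they are oriented by frequency
    concordance, otherwise dropped as ambiguous.
    """
    out_by_snp = {row.snp: row for row in outcome.table.itertuples()}
    w = palindrome_eaf_window

    records = []
    audit = []
    for row in instruments.table.itertuples():
        snp = row.snp
        if snp not in out_by_snp:
            audit.append((snp, DROPPED, "missing in outcome"))
            continue
        o = out_by_snp[snp]
        ea_x, oa_x = row.effect_allele, row.other_allele
        ea_y, oa_y = o.effect_allele, o.other_allele
        beta_y, eaf_y = o.beta, o.eaf

        if _is_palindromic(ea_x, oa_x):
            same_pair = {ea_y, oa_y} == {ea_x, oa_x}
            if not same_pair:
                audit.append((snp, DROPPED, "allele mismatch"))
                continue
            eaf_x = row.eaf
            usable = (
                not pd.isna(eaf_x)
                and not pd.isna(eaf_y)
                and abs(eaf_x - 0.5) > w
                and abs(eaf_y - 0.5) > w
            )
            if not usable:
                audit.append((snp, DROPPED, "ambiguous palindrome"))
                continue
            # letters first (a transposed palindrome still swaps), then
            # frequency concordance decides the strand
            action = KEPT
            if ea_y != ea_x:
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = BETA_FLIPPED
            if _freq_side(eaf_x) != _freq_side(eaf_y):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                action = PALINDROME_FREQ_FLIPPED
        elif (ea_y, oa_y) == (ea_x, oa_x):
            action = KEPT
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, (1.0 - eaf_y if not pd.isna(eaf_y) else eaf_y)
            action = BETA_FLIPPED
        elif (COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)) == (ea_x, oa_x):
            action = STRAND_FLIPPED
        elif (COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y)) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, (1.0 - eaf_y if not pd.isna(eaf_y) else eaf_y)
            action = STRAND_AND_BETA_FLIPPED
        else:
            audit.append((snp, DROPPED, "allele mismatch"))
            continue

        audit.append((snp, action, ""))
        records.append(
            {
                "snp": snp,
                "beta_x": row.beta,
                "se_x": row.se,
                "beta_y": beta_y,
                "se_y": o.se,
                "eaf": row.eaf,
            }
        )

    table = pd.DataFrame(
        records, columns=["snp", "beta_x", "se_x", "beta_y", "se_y", "eaf"]
    )
    audit_df = pd.DataFrame(audit, columns=["snp", "action", "reason"])
    return HarmonizedSet(
        exposure_name=instruments.trait_name,
        outcome_name=outcome.trait_name,
        table=table,
        audit=audit_df,
        outcome_trait_type=outcome.trait_type,
        meta={"palindrome_eaf_window": palindrome_eaf_window},
    )


def harmonized_to_tsv(h: HarmonizedSet, path) -> None:
    """Serialize a harmonized set (with per-variant action) as TSV."""
    merged = h.table.merge(h.audit[["snp", "action"]], on="snp", how="left")
    merged.to_csv(path, sep="\t", index=False)


def harmonized_from_tsv(
    path, exposure_name: str = "exposure", outcome_name: str = "outcome"
) -> HarmonizedSet:
    """Load a harmonized set written by :func:`harmonized_to_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str})
    required = ["snp", "beta_x", "se_x", "beta_y", "se_y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: harmonized table missing columns {missing}")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    audit = pd.DataFrame(
        {
            "snp": df["snp"],
            "action": df["action"] if "action" in df.columns else KEPT,
            "reason": "",
        }
    )
    return HarmonizedSet(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        table=df[["snp", "beta_x", "se_x", "beta_y", "se_y", "eaf"]].copy(),
        audit=audit,
    )
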