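"""End-to-end study orchestration: many exposures x outcomes from one config.

For every exposure-outcome pair the pipeline selects (or accepts
pre-selected) instruments, harmonizes alleles, computes the primary IVW
estimate with the automatic fixed/random switch, and — when the pair has
more than two instruments and shows a nominally significant effect or
significant heterogeneity — runs the sensitivity battery (weighted
median, weighted mode, MR-Egger, contamination mixture, MR-PRESSO).
Exposures flagged for cluster exploration get a mechanism-clustering fit.
Primary IVW rows are then FDR-corrected within families (by default one
family per exposure tier x outcome) and classified as
significant / suggestive / null.

Degenerate pairs (zero or one instrument, all-zero effects) never abort
the study: they yield an NA row and the run continues.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_scatter_table, fit_clusters
from .estimators import (
    DegenerateInputError,
    InsufficientInstrumentsError,
    MRResult,
    contamination_mixture,
    ivw,
    mr_egger,
    mr_presso,
    wald_ratios,
    weighted_median,
    weighted_mode,
)
from .harmonize import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_PALINDROME_WINDOW,
    DEFAULT_R2_THRESHOLD,
    harmonize,
    select_instruments,
)
from .inference import classify
from .sumstats import read_ld, read_sumstats

__all__ = [
    "RunConfig",
    "StudyResults",
    "run_study",
    "sensitivity_triggered",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "tier",
    "method",
    "n_snps",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "effects_model",
    "Q",
    "Q_pval",
    "intercept",
    "intercept_pval",
    "seed",
]

SENSITIVITY_METHODS = (
    "weighted_median",
    "weighted_mode",
    "mr_egger",
    "contamination_mixture",
    "mr_presso",
)


@dataclass
class ExposureSpec:
    name: str
    path: str
    tier: str = "primary"  # primary | secondary
    preselected: bool = False
    cluster: bool = False


@dataclass
class OutcomeSpec:
    name: str
    path: str
    trait_type: str = "binary-logOR"


@dataclass
class RunConfig:
    exposures: list[ExposureSpec]
    outcomes: list[OutcomeSpec]
    ld_path: str | None = None
    p_threshold: float = DEFAULT_P_THRESHOLD
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    palindrome_eaf_window: float = DEFAULT_PALINDROME_WINDOW
    n_boot: int = 1000
    n_sim: int = 1000
    k_max: int = 5
    n_restarts: int = 20
    fdr_family: str = "tier"  # tier (pool outcomes within a tier) | tier_outcome
    alpha: float = 0.05
    q_threshold: float = 0.05
    seed: int = 0
    out_dir: str = "mr_results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        exposures = [ExposureSpec(**e) for e in raw.pop("exposures")]
        outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
        return cls(exposures=exposures, outcomes=outcomes, **raw)

    def validate(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ValueError("config needs at least one exposure and one outcome")
        for spec in [*self.exposures, *self.outcomes]:
            if not Path(spec.path).exists():
                raise FileNotFoundError(f"input file not found: {spec.path}")
        if self.ld_path is not None and not Path(self.ld_path).exists():
            raise FileNotFoundError(f"LD matrix not found: {self.ld_path}")
        for name, lo, hi in [
            ("p_threshold", 0, 1),
            ("r2_threshold", 0, 1),
            ("alpha", 0, 1),
            ("q_threshold", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi})")
        if self.fdr_family not in ("tier_outcome", "tier"):
            raise ValueError("fdr_family must be 'tier_outcome' or 'tier'")


@dataclass
class StudyResults:
    results: pd.DataFrame  # one row per (pair, method)
    families: pd.DataFrame  # primary IVW rows with qval + classification
    cluster_tables: dict[str, pd.DataFrame]
    manifest: dict


def sensitivity_triggered(primary: MRResult) -> bool:
    """Battery gate: >2 instruments and (nominal P < 0.05 or Q-derived P < 0.05)."""
    if primary.n_snps <= 2:
        return False
    sig = np.isfinite(primary.pval) and primary.pval < 0.05
    het = np.isfinite(primary.Q_pval) and primary.Q_pval < 0.05
    return bool(sig or het)


def _na_row(exposure, outcome, tier, method, n_snps, seed, reason="") -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "tier": tier,
        "method": method,
        "n_snps": n_snps,
        "estimate": np.nan,
        "se": np.nan,
        "ci_low": np.nan,
        "ci_high": np.nan,
        "pval": np.nan,
        "effects_model": "n/a",
        "Q": np.nan,
        "Q_pval": np.nan,
        "intercept": np.nan,
        "intercept_pval": np.nan,
        "seed": seed,
    }


def _result_row(exposure, outcome, tier, res: MRResult, seed) -> dict:
    row = _na_row(exposure, outcome, tier, res.method, res.n_snps, seed)
    row.update(res.as_row())
    return row


def run_study(config: RunConfig, write: bool = True) -> StudyResults:
    """Execute the full study; optionally write the results bundle to disk."""
    config.validate()
    t_start = time.time()
    rng = np.random.default_rng(config.seed)
    ld = read_ld(config.ld_path) if config.ld_path else None

    outcomes = {}
    for ospec in config.outcomes:
        ds, _ = read_sumstats(ospec.path, trait_name=ospec.name, trait_type=ospec.trait_type)
        outcomes[ospec.name] = ds

    rows: list[dict] = []
    cluster_tables: dict[str, pd.DataFrame] = {}
    stage_log: list[dict] = []

    for espec in config.exposures:
        exposure, load_report = read_sumstats(espec.path, trait_name=espec.name)
        t0 = time.time()
        if espec.preselected:
            instruments = exposure
        else:
            instruments = select_instruments(
                exposure, config.p_threshold, ld, config.r2_threshold
            )
        for ospec in config.outcomes:
            pair_seed = int(rng.integers(0, 2**31 - 1))
            outcome = outcomes[ospec.name]
            h = harmonize(instruments, outcome, config.palindrome_eaf_window)
            pair_log = {
                "exposure": espec.name,
                "outcome": ospec.name,
                "n_candidates": instruments.n_variants,
                "n_harmonized": h.n_snps,
                "n_dropped_load": load_report.n_rejected,
                "drop_actions": h.action_counts(),
                "seed": pair_seed,
            }
            if h.n_snps == 0:
                rows.append(
                    _na_row(espec.name, ospec.name, espec.tier, "ivw", 0, pair_seed)
                )
                stage_log.append(pair_log)
                continue
            try:
                r = wald_ratios(h)
                primary = ivw(r, model="auto")
            except DegenerateInputError:
                rows.append(
                    _na_row(espec.name, ospec.name, espec.tier, "ivw", h.n_snps, pair_seed)
                )
                stage_log.append(pair_log)
                continue
            rows.append(_result_row(espec.name, ospec.name, espec.tier, primary, pair_seed))

            if sensitivity_triggered(primary):
                battery = {
                    "weighted_median": lambda: weighted_median(
                        r, n_boot=config.n_boot, seed=pair_seed
                    ),
                    "weighted_mode": lambda: weighted_mode(
                        r, n_boot=config.n_boot, seed=pair_seed + 1
                    ),
                    "mr_egger": lambda: mr_egger(h),
                    "contamination_mixture": lambda: contamination_mixture(r),
                }
                for name, call in battery.items():
                    try:
                        rows.append(
                            _result_row(espec.name, ospec.name, espec.tier, call(), pair_seed)
                        )
                    except (InsufficientInstrumentsError, DegenerateInputError):
                        rows.append(
                            _na_row(espec.name, ospec.name, espec.tier, name, r.n_snps, pair_seed)
                        )
                try:
                    presso = mr_presso(h, n_sim=config.n_sim, seed=pair_seed + 2)
                    row = _na_row(
                        espec.name, ospec.name, espec.tier, "mr_presso", r.n_snps, pair_seed + 2
                    )
                    row["pval"] = presso.global_pval
                    rows.append(row)
                except (InsufficientInstrumentsError, DegenerateInputError):
                    rows.append(
                        _na_row(espec.name, ospec.name, espec.tier, "mr_presso", r.n_snps, pair_seed)
                    )

            if espec.cluster and r.n_snps >= 2:
                model = fit_clusters(
                    r,
                    k_max=config.k_max,
                    n_restarts=config.n_restarts,
                    seed=pair_seed + 3,
                )
                cluster_tables[f"{espec.name}__{ospec.name}"] = cluster_scatter_table(
                    model, h
                )
            pair_log["wall_clock_s"] = round(time.time() - t0, 3)
            stage_log.append(pair_log)

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)

    # FDR within families over the primary IVW rows
    primary_rows = results[results["method"] == "ivw"].copy()
    fam_cols = ["tier", "outcome"] if config.fdr_family == "tier_outcome" else ["tier"]
    fams = []
    for _, fam in primary_rows.groupby(fam_cols, sort=True):
        fams.append(classify(fam, alpha=config.alpha, q_threshold=config.q_threshold))
    families = (
        pd.concat(fams).sort_index() if fams else primary_rows.assign(qval=np.nan)
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            "exposures": [vars(e) for e in config.exposures],
            "outcomes": [vars(o) for o in config.outcomes],
            "ld_path": config.ld_path,
            "p_threshold": config.p_threshold,
            "r2_threshold": config.r2_threshold,
            "palindrome_eaf_window": config.palindrome_eaf_window,
            "n_boot": config.n_boot,
            "n_sim": config.n_sim,
            "k_max": config.k_max,
            "n_restarts": config.n_restarts,
            "fdr_family": config.fdr_family,
            "alpha": config.alpha,
            "q_threshold": config.q_threshold,
        },
        "stages": stage_log,
        "wall_clock_s": round(time.time() - t_start, 3),
    }

    bundle = StudyResults(
        results=results,
        families=families,
        cluster_tables=cluster_tables,
        manifest=manifest,
    )
    if write:
        _write_bundle(bundle, config)
    return bundle


def _write_tsv_with_header(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# twosmr {__version__} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_bundle(bundle: StudyResults, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv_with_header(bundle.results, out / "results.tsv", config.seed)
    _write_tsv_with_header(bundle.families, out / "classification.tsv", config.seed)
    for key, table in bundle.cluster_tables.items():
        _write_tsv_with_header(table, out / f"clusters_{key}.tsv", config.seed)
    # manifest wall-clocks vary run to run; results TSVs are the determinism surface
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=1, default=str))
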