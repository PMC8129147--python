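#!/usr/bin/env python
"""Generate the synthetic two-sample MR study inputs.

Emulates a study of circulating immunity/inflammation biomarkers against
two outcomes — a binary late-onset dementia phenotype (log-OR scale,
IGAP-like sample size) and a continuous hippocampal-volume endophenotype —
with every true causal effect set to zero.  Some exposures carry balanced
pleiotropy (heterogeneity without directional bias), one exposure has a
single instrument, and allele pathologies (swapped alleles, strand flips,
palindromic variants) are injected into the outcome records so the
harmonization stage is genuinely exercised.

Writes per-exposure instrument files, two pooled outcome files, and a
ready-to-run YAML study config under scratch/study/.
"""

from pathlib import Path

import pandas as pd
import yaml

from twosmr.simulate import SimConfig, resample_outcome, simulate_pair
from twosmr.sumstats import SummaryDataset, write_sumstats

SEED = 20_260_924
OUT = Path("scratch/study")

PRIMARY = [
    # (name, n_instruments, balanced-pleiotropy sd) — zero sd means no pleiotropy
    ("platelet_count", 40, 0.02),
    ("eosinophil_count", 35, 0.0),
    ("neutrophil_count", 30, 0.02),
    ("basophil_count", 12, 0.0),
    ("monocyte_count", 30, 0.0),
    ("lymphocyte_count", 30, 0.02),
    ("platelet_lymphocyte_ratio", 8, 0.0),
    ("monocyte_lymphocyte_ratio", 8, 0.0),
    ("cd4_count", 1, 0.0),  # single instrument, as for adaptive-immunity traits
    ("cd8_count", 3, 0.0),
    ("cd4_cd8_ratio", 3, 0.0),
    ("cd56_count", 4, 0.0),
    ("il6", 3, 0.0),
    ("fibrinogen", 20, 0.02),
    ("crp", 24, 0.03),
    ("lp_pla2_activity", 6, 0.0),
    ("lp_pla2_mass", 5, 0.0),
]
SECONDARY = [
    ("il1", 3, 0.0),
    ("icam1", 6, 0.0),
    ("p_selectin", 4, 0.0),
    ("mip1b", 10, 0.02),
    ("stem_cell_factor", 8, 0.0),
]


def simulate_exposure(name, n_inst, pleio_sd, idx):
    common = dict(
        n_variants=n_inst,
        theta_true=0.0,  # the emulated study is truly null throughout
        pleiotropy_mode="balanced" if pleio_sd > 0 else "none",
        alpha_sd=pleio_sd,
        frac_invalid=0.5 if pleio_sd > 0 else 0.0,
        frac_swapped=0.15,
        frac_flipped=0.10,
        frac_palindromic=0.05,
        seed=SEED + idx,
        exposure_name=name,
    )
    ad = simulate_pair(SimConfig(outcome_name="alzheimers_disease", **common))
    # same instrument panel against the second outcome: independent noise,
    # shared alleles/pathologies/ground truth
    hv = resample_outcome(
        ad, seed=SEED + idx + 100_000, outcome_name="hippocampal_volume",
        binary=False, n_sample=33_536,
    )
    for ds in (ad.exposure, ad.outcome, hv):
        ds.table["snp"] = [f"x{idx:02d}_{s}" for s in ds.table["snp"]]
    return ad.exposure, ad.outcome.table, hv.table


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exposures_cfg = []
    ad_parts, hv_parts = [], []
    idx = 0
    for tier, traits in (("primary", PRIMARY), ("secondary", SECONDARY)):
        for name, n_inst, pleio_sd in traits:
            exposure, ad_table, hv_table = simulate_exposure(name, n_inst, pleio_sd, idx)
            path = OUT / f"{name}.tsv"
            write_sumstats(exposure, path)
            exposures_cfg.append(
                dict(name=name, path=str(path), tier=tier, preselected=True,
                     cluster=name in ("crp", "cd4_count", "lp_pla2_activity"))
            )
            ad_parts.append(ad_table)
            hv_parts.append(hv_table)
            idx += 1

    ad = SummaryDataset("alzheimers_disease", "binary-logOR",
                        pd.concat(ad_parts, ignore_index=True))
    hv = SummaryDataset("hippocampal_volume", "continuous",
                        pd.concat(hv_parts, ignore_index=True))
    write_sumstats(ad, OUT / "outcome_alzheimers_disease.tsv")
    write_sumstats(hv, OUT / "outcome_hippocampal_volume.tsv")

    config = dict(
        exposures=exposures_cfg,
        outcomes=[
            dict(name="alzheimers_disease",
                 path=str(OUT / "outcome_alzheimers_disease.tsv"),
                 trait_type="binary-logOR"),
            dict(name="hippocampal_volume",
                 path=str(OUT / "outcome_hippocampal_volume.tsv"),
                 trait_type="continuous"),
        ],
        n_boot=500, n_sim=500, k_max=3, n_restarts=10,
        fdr_family="tier", seed=SEED, out_dir="results/study",
    )
    (OUT / "study.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    n_inst = sum(n for _, n, _ in PRIMARY + SECONDARY)
    print(f"wrote {len(exposures_cfg)} exposures ({n_inst} instruments total), "
          f"2 outcomes and study.yaml under {OUT}")


if __name__ == "__main__":
    main()
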