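"""Instrument selection (greedy LD pruning) and allele harmonization."""

import numpy as np
import pandas as pd
import pytest

from twosmr.harmonize import harmonize, select_instruments
from twosmr.simulate import SimConfig, simulate_pair
from twosmr.sumstats import LDMatrix, SUMSTATS_COLUMNS, SummaryDataset


def make_dataset(rows, name="exposure", trait_type="continuous"):
    """rows: list of dicts with at least snp/effect_allele/other_allele/beta/se/pval."""
    table = pd.DataFrame(rows)
    for col in SUMSTATS_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    return SummaryDataset(name, trait_type, table[SUMSTATS_COLUMNS])


def variant(snp, ea="A", og="G", beta=0.1, se=0.01, pval=1e-9, eaf=0.3):
    return dict(snp=snp, effect_allele=ea, other_allele=og, beta=beta, se=se,
                pval=pval, eaf=eaf)


class TestSelectInstruments:
    def test_independent_significant_variants_all_retained(self):
        ds = make_dataset([variant(f"rs{i}") for i in range(3)])
        ld = LDMatrix([f"rs{i}" for i in range(3)], np.eye(3))
        assert select_instruments(ds, ld=ld).n_variants == 3

    def test_correlated_pair_keeps_lowest_p(self):
        ds = make_dataset(
            [variant("rs1", pval=1e-10), variant("rs2", pval=1e-9)]
        )
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        kept = select_instruments(ds, ld=ld)
        assert list(kept.table["snp"]) == ["rs1"]

    def test_nonsignificant_variants_excluded_and_empty_ok(self):
        ds = make_dataset([variant("rs1", pval=1e-6)])
        assert select_instruments(ds).n_variants == 0

    def test_variants_missing_from_ld_treated_independent(self):
        ds = make_dataset([variant("rs1", pval=1e-10), variant("rsX", pval=1e-9)])
        ld = LDMatrix(["rs1"], np.eye(1))
        assert select_instruments(ds, ld=ld).n_variants == 2

    def test_matches_explicit_greedy_trace_oracle(self, rng):
        # random 50-variant set with block LD; oracle replays the greedy
        # rule by explicit elimination over the sorted candidate list
        n = 50
        sim = simulate_pair(
            SimConfig(n_variants=n, ld_blocks=[(10, 0.3), (10, 0.8), (5, 0.02)], seed=21)
        )
        ds = sim.exposure
        ld = sim.ld
        kept = set(select_instruments(ds, 5e-8, ld, 0.01).table["snp"])

        sig = ds.table[ds.table["pval"] < 5e-8]
        order = sig.sort_values(["pval", "snp"]).reset_index(drop=True)
        idx = {s: i for i, s in enumerate(ld.snps)}
        alive = {s: True for s in order["snp"]}
        expected = []
        for s in order["snp"]:
            if not alive[s]:
                continue
            expected.append(s)
            for other in order["snp"]:
                if alive[other] and other != s and ld.r2[idx[s], idx[other]] >= 0.01:
                    alive[other] = False
        assert kept == set(expected)

    def test_selection_invariant_to_input_row_order(self, rng):
        sim = simulate_pair(SimConfig(n_variants=30, ld_blocks=[(15, 0.5)], seed=4))
        ds = sim.exposure
        shuffled = SummaryDataset(
            ds.trait_name,
            ds.trait_type,
            ds.table.sample(frac=1.0, random_state=0).reset_index(drop=True),
        )
        a = set(select_instruments(ds, ld=sim.ld).table["snp"])
        b = set(select_instruments(shuffled, ld=sim.ld).table["snp"])
        assert a == b

    def test_p_value_tie_broken_by_snp_id(self):
        ds = make_dataset([variant("rsB", pval=1e-10), variant("rsA", pval=1e-10)])
        ld = LDMatrix(["rsA", "rsB"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = select_instruments(ds, ld=ld)
        assert list(kept.table["snp"]) == ["rsA"]

    def test_threshold_validation(self):
        ds = make_dataset([variant("rs1")])
        with pytest.raises(ValueError):
            select_instruments(ds, p_threshold=0.0)


class TestHarmonize:
    def test_transposed_alleles_negate_beta(self):
        exp = make_dataset([variant("rs1", "A", "G", beta=0.2)])
        out = make_dataset([variant("rs1", "G", "A", beta=-0.1, eaf=0.7)], name="outcome")
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_y"] == pytest.approx(0.1)
        assert h.table.loc[0, "eaf"] == 0.3
        assert h.audit.loc[0, "action"] == "beta-flipped"

    def test_strand_flip_resolved(self):
        exp = make_dataset([variant("rs1", "A", "G", beta=0.2)])
        out = make_dataset([variant("rs1", "T", "C", beta=0.1)], name="outcome")
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_y"] == pytest.approx(0.1)
        assert h.audit.loc[0, "action"] == "strand-flipped"

    def test_strand_flip_plus_swap(self):
        exp = make_dataset([variant("rs1", "A", "G", beta=0.2)])
        out = make_dataset([variant("rs1", "C", "T", beta=0.1)], name="outcome")
        h = harmonize(exp, out)
        assert h.table.loc[0, "beta_y"] == pytest.approx(-0.1)
        assert h.audit.loc[0, "action"] == "strand-and-beta-flipped"

    def test_palindrome_near_half_dropped(self):
        exp = make_dataset([variant("rs1", "A", "T", eaf=0.51)])
        out = make_dataset([variant("rs1", "A", "T", beta=0.1, eaf=0.2)], name="outcome")
        h = harmonize(exp, out)
        assert h.n_snps == 0
        assert h.audit.loc[0, "reason"] == "ambiguous palindrome"

    def test_palindrome_resolved_by_frequency(self):
        exp = make_dataset([variant("rs1", "A", "T", eaf=0.2)])
        # outcome reports the same pair but the frequency says the effect
        # allele is on the opposite strand orientation
        out = make_dataset([variant("rs1", "A", "T", beta=0.1, eaf=0.8)], name="outcome")
        h = harmonize(exp, out)
        assert h.n_snps == 1
        assert h.table.loc[0, "beta_y"] == pytest.approx(-0.1)
        assert h.audit.loc[0, "action"] == "palindrome-freq-flipped"

    def test_missing_in_outcome_and_mismatch_dropped(self):
        exp = make_dataset([variant("rs1"), variant("rs2", "A", "G")])
        out = make_dataset([variant("rs2", "A", "C", beta=0.1)], name="outcome")
        h = harmonize(exp, out)
        assert h.n_snps == 0
        reasons = dict(zip(h.audit["snp"], h.audit["reason"]))
        assert reasons == {"rs1": "missing in outcome", "rs2": "allele mismatch"}

    def test_audit_covers_every_candidate_exactly_once(self):
        sim = simulate_pair(
            SimConfig(n_variants=40, frac_swapped=0.3, frac_flipped=0.3,
                      frac_palindromic=0.2, seed=17)
        )
        h = harmonize(sim.exposure, sim.outcome)
        assert sorted(h.audit["snp"]) == sorted(sim.exposure.table["snp"])

    def test_pathology_counts_match_generator_truth(self):
        sim = simulate_pair(
            SimConfig(n_variants=200, theta_true=0.1, frac_swapped=0.3,
                      frac_flipped=0.3, seed=23)
        )
        h = harmonize(sim.exposure, sim.outcome)
        truth = sim.truth
        counts = h.action_counts()
        swapped = truth["swapped"].to_numpy()
        flipped = truth["flipped"].to_numpy()
        assert counts.get("beta-flipped", 0) == int((swapped & ~flipped).sum())
        assert counts.get("strand-flipped", 0) == int((flipped & ~swapped).sum())
        assert counts.get("strand-and-beta-flipped", 0) == int((flipped & swapped).sum())
        assert counts.get("kept", 0) == int((~flipped & ~swapped).sum())

    def test_harmonization_restores_prepathology_betas(self):
        cfg = dict(n_variants=80, theta_true=0.2, seed=29)
        clean = simulate_pair(SimConfig(**cfg))
        pathological = simulate_pair(
            SimConfig(frac_swapped=0.4, frac_flipped=0.4, **cfg)
        )
        h = harmonize(pathological.exposure, pathological.outcome)
        np.testing.assert_allclose(
            h.table["beta_y"].to_numpy(), clean.outcome.table["beta"].to_numpy()
        )

    def test_self_harmonization_is_identity(self):
        sim = simulate_pair(SimConfig(n_variants=30, seed=2))
        h = harmonize(sim.exposure, sim.exposure)
        np.testing.assert_array_equal(h.table["beta_x"], h.table["beta_y"])
        assert set(h.audit["action"]) == {"kept"}

    def test_harmonization_is_idempotent(self):
        sim = simulate_pair(
            SimConfig(n_variants=50, frac_swapped=0.5, frac_flipped=0.3, seed=31)
        )
        h1 = harmonize(sim.exposure, sim.outcome)
        # express the harmonized outcome as a dataset in exposure orientation
        exp_t = sim.exposure.table.set_index("snp")
        rows = []
        for _, r in h1.table.iterrows():
            e = exp_t.loc[r["snp"]]
            rows.append(variant(r["snp"], e["effect_allele"], e["other_allele"],
                                beta=r["beta_y"], se=r["se_y"], eaf=e["eaf"]))
        realigned = make_dataset(rows, name="outcome")
        h2 = harmonize(sim.exposure.subset(h1.table["snp"]), realigned)
        np.testing.assert_array_equal(
            h1.table["beta_y"].to_numpy(), h2.table["beta_y"].to_numpy()
        )
        assert all(a in ("kept", "beta-flipped") for a in h2.audit["action"])
        assert not (h2.audit["action"] == "beta-flipped").any()
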