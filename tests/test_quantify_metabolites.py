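import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import specshell as sp
from specshell.quantify_metabolites import (
    BELOW_LOQ,
    NOT_DETECTED,
    QUANTIFIED,
    UNQUANTIFIABLE,
    PanelError,
    AnalyteEntry,
)

# frozen via exact rational arithmetic: F = 315/34 for this 3-group design
ANOVA_GROUPS = [
    np.array([6.0, 8, 4, 5, 3, 4]),
    np.array([8.0, 12, 9, 11, 6, 8]),
    np.array([13.0, 9, 11, 8, 7, 12]),
]
ANOVA_F_EXACT = 315.0 / 34.0


class TestQuantify:
    def test_worked_arithmetic(self):
        conc, status = sp.quantify(1000.0, 500.0, 10.0, 25.0)
        assert conc == pytest.approx(500.0)
        assert status == QUANTIFIED

    def test_zero_area_not_detected(self):
        conc, status = sp.quantify(0.0, 500.0, 10.0, 25.0)
        assert conc is None and status == NOT_DETECTED

    def test_zero_standard_is_unquantifiable_not_zero(self):
        conc, status = sp.quantify(1000.0, 0.0, 10.0, 25.0)
        assert conc is None and status == UNQUANTIFIABLE

    def test_below_loq_flagged(self):
        conc, status = sp.quantify(1.0, 1000.0, 10.0, 25.0, loq=1.0)
        assert conc is None and status == BELOW_LOQ

    @settings(deadline=None, max_examples=40)
    @given(
        area=st.floats(min_value=1e-3, max_value=1e7),
        is_area=st.floats(min_value=1e-3, max_value=1e7),
        is_conc=st.floats(min_value=1e-3, max_value=1e3),
        dilution=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_linearity_in_area(self, area, is_area, is_conc, dilution):
        c1, _ = sp.quantify(area, is_area, is_conc, dilution)
        c2, _ = sp.quantify(2 * area, is_area, is_conc, dilution)
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_batch_matches_independent_formula(self, rng):
        """200 random records equal an independently coded evaluation."""
        panel = sp.chain_elongation_panel()
        analytes = rng.choice(panel.analytes, size=200)
        areas = rng.uniform(1.0, 1e6, size=200)
        is_areas = rng.uniform(1.0, 1e6, size=200)
        table = pd.DataFrame(
            {"strain": "S", "bio_rep": "B1", "tech_rep": "T1",
             "analyte": analytes, "area": areas, "is_area": is_areas}
        )
        out = sp.quantify_table(table, panel, 10.0, 25.0)
        expected = areas / is_areas * 10.0 * 25.0
        assert np.allclose(out["concentration"].astype(float), expected)

    def test_unknown_analyte_rejected(self):
        table = pd.DataFrame(
            {"strain": ["S"], "bio_rep": ["B1"], "tech_rep": ["T1"],
             "analyte": ["mystery"], "area": [1.0], "is_area": [1.0]}
        )
        with pytest.raises(PanelError):
            sp.quantify_table(table, sp.chain_elongation_panel(), 10.0, 25.0)


class TestPanels:
    def test_elongation_rounds_encoded_in_names(self):
        panel = sp.chain_elongation_panel()
        rounds = {e.analyte: e.elongation_rounds for e in panel.entries}
        assert rounds["HM"] == 1 and rounds["HexaHM"] == 6 and rounds["HeptaHM"] == 7
        assert rounds["HL"] == 1 and rounds["DHL"] == 2 and rounds["TriHL"] == 3
        assert rounds["HPhe"] == 1

    def test_name_rounds_mismatch_rejected(self):
        with pytest.raises(PanelError):
            AnalyteEntry("HM", "methionine", 2, "Met-13C15N")

    def test_glucosinolate_class_sizes(self):
        panel = sp.glucosinolate_panel()
        assert len(panel.by_class("aliphatic")) == 9
        assert len(panel.by_class("indolic")) == 3
        assert len(panel.by_class("aromatic")) == 1

    def test_glucosinolate_chain_length_groups(self):
        panel = sp.glucosinolate_panel()
        short = [e.analyte for e in panel.by_class("aliphatic")
                 if 1 <= e.elongation_rounds <= 3]
        long = [e.analyte for e in panel.by_class("aliphatic")
                if e.elongation_rounds >= 4]
        assert len(short) == 5 and len(long) == 4


class TestProfile:
    def _table(self, concentrations, noise_cv=0.0, seed=0, **kw):
        spec = sp.MrmSpec(concentrations=concentrations, noise_cv=noise_cv, **kw)
        table, _ = sp.gen_mrm_table(spec, seed)
        return sp.quantify_table(
            table, sp.chain_elongation_panel(), spec.is_concentration,
            spec.dilution_factor,
        )

    def test_percentages_match_planted_shares(self):
        q = self._table({"S": {"DHM": 50.0, "HPhe": 30.0, "HL": 20.0}})
        summary = sp.profile(q, sp.chain_elongation_panel())
        row = summary.group_percentages.loc["S"]
        assert row["methionine"] == pytest.approx(50.0)
        assert row["phenylalanine"] == pytest.approx(30.0)
        assert row["leucine"] == pytest.approx(20.0)

    def test_zero_total_strain_flagged(self):
        q = self._table({"S": {"HM": 0.0}})
        summary = sp.profile(q, sp.chain_elongation_panel())
        assert summary.zero_total_strains == ("S",)
        assert summary.group_percentages.loc["S"].isna().all()

    def test_percentages_sum_to_100(self):
        q = self._table(
            {"A": {"HM": 3.0, "DHL": 2.0, "HPhe": 9.0},
             "B": {"TriHM": 1.0, "HL": 4.0}},
            noise_cv=0.1, seed=4,
        )
        summary = sp.profile(q, sp.chain_elongation_panel())
        sums = summary.group_percentages.sum(axis=1)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_round_distribution_bins(self):
        q = self._table({"S": {"HM": 10.0, "DHM": 30.0, "TriHM": 40.0,
                               "TetraHM": 20.0}})
        summary = sp.profile(q, sp.chain_elongation_panel())
        row = summary.round_distribution.loc["S"]
        assert row["1"] == pytest.approx(10.0)
        assert row["2"] == pytest.approx(30.0)
        assert row[">=3"] == pytest.approx(60.0)

    def test_noisy_shares_recovered_within_tolerance(self):
        q = self._table({"S": {"DHM": 50.0, "HPhe": 30.0, "HL": 20.0}},
                        noise_cv=0.1, seed=9)
        summary = sp.profile(q, sp.chain_elongation_panel())
        row = summary.group_percentages.loc["S"]
        assert row["methionine"] == pytest.approx(50.0, abs=5.0)
        assert row["phenylalanine"] == pytest.approx(30.0, abs=5.0)
        assert row["leucine"] == pytest.approx(20.0, abs=5.0)


class TestFoldChange:
    def _quantified(self, conc, noise_cv=0.0, seed=0):
        table, _ = sp.gen_mrm_table(
            sp.MrmSpec(concentrations=conc, noise_cv=noise_cv), seed
        )
        return sp.quantify_table(table, sp.chain_elongation_panel(), 10.0, 25.0)

    def test_planted_five_fold(self):
        q = self._quantified({"A": {"HM": 100.0}, "B": {"HM": 20.0}})
        assert sp.fold_change(q, "A", "B") == pytest.approx(5.0)

    def test_identical_strains_unity(self):
        q = self._quantified({"A": {"HM": 33.0}, "B": {"HM": 33.0}})
        assert sp.fold_change(q, "A", "B") == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        q = self._quantified({"A": {"HM": 10.0}, "B": {"HM": 0.0}})
        with pytest.warns(RuntimeWarning):
            assert np.isnan(sp.fold_change(q, "A", "B"))

    def test_single_analyte_scope(self):
        q = self._quantified(
            {"A": {"HM": 10.0, "HPhe": 20.0}, "B": {"HM": 10.0, "HPhe": 1.0}}
        )
        assert sp.fold_change(q, "A", "B", analyte="HPhe") == pytest.approx(20.0)


class TestAnova:
    def test_frozen_three_group_fixture(self):
        F, p, df_b, df_w = sp.one_way_anova(ANOVA_GROUPS)
        assert F == pytest.approx(ANOVA_F_EXACT, abs=1e-12)
        assert (df_b, df_w) == (2, 15)

    def test_matches_scipy_on_random_data(self, rng):
        from scipy.stats import f_oneway

        groups = [rng.normal(i, 1.0, size=6) for i in range(4)]
        F, p, _, _ = sp.one_way_anova(groups)
        ref = f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_identical_values_degenerate(self):
        F, p, _, _ = sp.one_way_anova([np.ones(3), np.ones(3)])
        assert np.isnan(F) and np.isnan(p)


class TestTukey:
    def test_matches_statsmodels(self, rng):
        groups = {g: rng.normal(i * 0.5, 1.0, size=5) for i, g in enumerate("ABCD")}
        ours = sp.tukey_hsd(groups)
        values = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), [len(v) for v in groups.values()])
        ref = pairwise_tukeyhsd(values, labels, alpha=0.05)
        ref_p = np.asarray(ref.pvalues)
        assert np.allclose(np.sort(ours["p_adj"]), np.sort(ref_p), atol=1e-6)

    def test_grand_mean_contrast_effects_sum_to_zero_balanced(self, rng):
        groups = {g: rng.normal(0, 1, size=4) for g in "ABC"}
        contrasts = sp.grand_mean_contrasts(groups)
        assert contrasts["effect"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_fwer_calibrated_quick(self):
        fwer = sp.simulate_tukey_fwer(3000, 4, 3, alpha=0.05, seed=12)
        assert 0.035 <= fwer <= 0.065


class TestCompareStrains:
    def test_integration_on_planted_difference(self):
        table, _ = sp.gen_mrm_table(
            sp.MrmSpec(
                concentrations={"A": {"HM": 100.0}, "B": {"HM": 100.0},
                                "C": {"HM": 300.0}},
                noise_cv=0.05, n_bio_reps=4,
            ),
            seed=2,
        )
        q = sp.quantify_table(table, sp.chain_elongation_panel(), 10.0, 25.0)
        cmp = sp.compare_strains(q, "HM")
        assert cmp.anova["p"].iloc[0] < 0.01
        pair_ac = cmp.tukey_pairs.query(
            "(group_a == 'A' and group_b == 'C') or "
            "(group_a == 'C' and group_b == 'A')"
        )
        assert bool(pair_ac["reject"].iloc[0])
        assert not cmp.degenerate
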