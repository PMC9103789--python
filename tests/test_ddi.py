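"""DDI mechanics: inhibition terms, enzyme turnover, calibration and AUCR."""

import numpy as np
import pytest

from szddi import (
    ConstantExposure,
    DDIResult,
    DoseRegimen,
    GenotypeScenario,
    InteractionSpec,
    calibrate_baseline,
    default_scenarios,
    enzyme_turnover_rhs,
    inhibition_terms,
    pk_metrics,
    run_ddi,
    scenario_table,
    simulate,
    static_aucr_oracle,
)
from szddi.ddi import EnzymeInhibition
from szddi.exceptions import CalibrationError, ConfigurationError, DomainError


def _spec(mode="RI_and_TDI", ki=2.0, KI=0.5, kinact=0.04, enzyme="CYP3A4"):
    return InteractionSpec(
        perpetrator="inhib", mode=mode,
        enzymes={enzyme: EnzymeInhibition(ki=ki, KI=KI, kinact=kinact)},
    )


class TestInhibitionTerms:
    def test_zero_exposure_is_neutral(self):
        assert inhibition_terms(0.0, _spec(), "CYP3A4") == (1.0, 0.0)

    def test_half_inhibition_at_ki(self):
        ri, _ = inhibition_terms(2.0, _spec(ki=2.0), "CYP3A4")
        assert ri == pytest.approx(0.5)

    def test_half_saturation_kobs_at_KI(self):
        _, kobs = inhibition_terms(0.5, _spec(KI=0.5, kinact=0.04), "CYP3A4")
        assert kobs == pytest.approx(30.0 * 0.04)  # 60·kinact/2, in h⁻¹

    def test_unlisted_enzyme_untouched(self):
        assert inhibition_terms(10.0, _spec(), "CYP3A5") == (1.0, 0.0)

    def test_mode_requires_constants(self):
        with pytest.raises(ConfigurationError):
            InteractionSpec(
                perpetrator="x", mode="RI_only",
                enzymes={"CYP3A4": EnzymeInhibition(KI=0.5, kinact=0.04)},
            )
        tdi_only = _spec("TDI_only", ki=None)
        with pytest.raises(ConfigurationError):
            tdi_only.with_mode("RI_and_TDI")


class TestEnzymeTurnover:
    def test_steady_state_closed_form(self):
        kdeg, kobs = 0.0193, 0.5
        fss = kdeg / (kdeg + kobs)
        assert enzyme_turnover_rhs(fss, kdeg, kobs) == pytest.approx(0.0, abs=1e-15)

    def test_relaxes_to_one_without_inactivation(self):
        assert enzyme_turnover_rhs(0.5, 0.0193, 0.0) > 0
        assert enzyme_turnover_rhs(1.0, 0.0193, 0.0) == 0.0

    def test_trajectory_matches_analytic_exponential(self, victim, phys):
        # constant exposure: f(t) = fss + (1-fss)·exp(-(kdeg+kobs)t)
        spec = _spec("TDI_only", ki=None)
        iu = 0.5
        ce = ConstantExposure(spec, iu)
        _, kobs = inhibition_terms(iu, spec, "CYP3A4")
        reg = DoseRegimen(compound=victim.name, dose_mg=2.0, times=[0.0])
        res = simulate([victim], [reg], phys, interaction=ce, duration=48.0)
        kdeg = phys.kdeg["CYP3A4"]
        fss = kdeg / (kdeg + kobs)
        expected = fss + (1 - fss) * np.exp(-(kdeg + kobs) * res.time)
        np.testing.assert_allclose(res.enzyme_fractions["CYP3A4"], expected, atol=1e-6)


class TestStaticOracle:
    def test_neutral_cases(self, scenario_ne):
        spec = _spec()
        assert static_aucr_oracle(0.0, spec, scenario_ne) == pytest.approx(1.0)
        all_other = GenotypeScenario(
            label="non_expresser", cyp3a5_abundance_scalar=0.0,
            fm_cyp3a4=0.0, fm_cyp3a5=0.0, fm_other=1.0,
        )
        assert static_aucr_oracle(50.0, spec, all_other) == pytest.approx(1.0)

    def test_dynamic_constant_infusion_matches_oracle(self, victim, phys, scenario_ne, szb_interaction):
        iu = 0.03
        ce = ConstantExposure(szb_interaction, iu)
        f0 = {
            e: phys.kdeg[e] / (phys.kdeg[e] + inhibition_terms(iu, szb_interaction, e)[1])
            for e in ("CYP3A4", "CYP3A5")
        }
        phys_ne = phys.model_copy(
            update={"cyp_abundance": {**phys.cyp_abundance, "CYP3A5": 0.0}}
        )
        reg = [DoseRegimen(compound=victim.name, dose_mg=2.0, times=[0.0])]
        duration = 600.0  # long enough that window truncation is negligible
        ctrl = simulate([victim], reg, phys_ne, duration=duration)
        inh = simulate(
            [victim], reg, phys_ne, interaction=ce, duration=duration,
            initial_enzyme_fractions=f0,
        )
        aucr = (
            pk_metrics(inh, victim.name, matrix="blood").auc
            / pk_metrics(ctrl, victim.name, matrix="blood").auc
        )
        oracle = static_aucr_oracle(iu, szb_interaction, scenario_ne, phys.kdeg)
        assert aucr == pytest.approx(oracle, rel=0.02)


class TestCalibration:
    def test_control_aucs_hit_targets(self, calibrated):
        _, _, diag = calibrated
        assert diag["achieved_auc"]["non_expresser"] == pytest.approx(118.07, rel=0.01)
        assert diag["achieved_auc"]["expresser"] == pytest.approx(62.50, rel=0.01)

    def test_fm_splits_are_consistent(self, scenario_ne, scenario_ex):
        assert scenario_ne.fm_cyp3a5 == 0.0
        assert scenario_ex.fm_cyp3a5 > 0.2
        for s in (scenario_ne, scenario_ex):
            assert s.fm_cyp3a4 + s.fm_cyp3a5 + s.fm_other == pytest.approx(1.0)

    def test_indistinguishable_genotypes_rejected(self, victim_raw, phys):
        ne, ex = default_scenarios()
        ex0 = ex.model_copy(update={"cyp3a5_abundance_scalar": 0.0})
        with pytest.raises(CalibrationError, match="indistinguishable"):
            calibrate_baseline(victim_raw, phys, [ne, ex0])


class TestRunDDI:
    def test_zero_perpetrator_dose_gives_unity(self, victim, szb, szb_interaction, scenario_ne, phys):
        r = run_ddi(
            victim, szb, szb_interaction, "single_dose", scenario_ne,
            "RI_and_TDI", phys, perp_single=0.0,
        )
        assert r.aucr == pytest.approx(1.0, abs=1e-6)

    def test_aucr_monotone_in_dose(self, victim, szb, szb_interaction, scenario_ne, phys):
        aucrs = []
        control = None
        for dose in (1.0, 5.0, 10.8, 30.0):
            r = run_ddi(
                victim, szb, szb_interaction, "single_dose", scenario_ne,
                "RI_and_TDI", phys, perp_single=dose, control_auc=control,
            )
            control = r.auc_control
            aucrs.append(r.aucr)
        assert all(b >= a for a, b in zip(aucrs, aucrs[1:]))
        assert aucrs[0] > 1.0

    def test_combined_mechanism_dominates_each_alone(self, victim, szb, szb_interaction, scenario_ex, phys):
        results = {}
        control = None
        for mode in ("RI_only", "TDI_only", "RI_and_TDI"):
            r = run_ddi(
                victim, szb, szb_interaction, "single_dose", scenario_ex,
                mode, phys, control_auc=control,
            )
            control = r.auc_control
            results[mode] = r.aucr
        assert results["RI_and_TDI"] >= max(results["RI_only"], results["TDI_only"]) - 1e-9

    def test_fast_enzyme_turnover_abolishes_tdi(self, victim, szb, szb_interaction, scenario_ne, phys):
        fast = phys.model_copy(update={"kdeg": {"CYP3A4": 100.0, "CYP3A5": 100.0}})
        r = run_ddi(
            victim, szb, szb_interaction, "single_dose", scenario_ne,
            "TDI_only", fast,
        )
        assert r.aucr == pytest.approx(1.0, abs=0.01)

    def test_invalid_regimen_label(self, victim, szb, szb_interaction, scenario_ne, phys):
        with pytest.raises(DomainError):
            run_ddi(victim, szb, szb_interaction, "weekly", scenario_ne, "RI_only", phys)


class TestScenarioGrid:
    def test_full_grid_has_24_cells_with_gaps_for_missing_mechanisms(
        self, victim, calibrated, sza, szb, sza_interaction, szb_interaction, phys
    ):
        from szddi.ddi import run_scenario_grid

        grid = run_scenario_grid(
            victim,
            {"SZA": (sza, sza_interaction), "SZB": (szb, szb_interaction)},
            calibrated[1],
            phys,
        )
        assert len(grid) == 24  # 2 genotypes × 2 inhibitors × 2 regimens × 3 cases
        # SZA has no reversible constants: its RI-containing cells are gaps
        gaps = grid[grid["aucr"].isna()]
        assert len(gaps) == 8
        assert set(gaps["inhibitor"]) == {"SZA"}
        filled = grid.dropna(subset=["aucr"])
        assert (filled["aucr"] >= 1.0 - 1e-9).all()


class TestScenarioTable:
    def _result(self, scenario, aucr=1.5):
        return DDIResult.from_aucs(100.0, 100.0 * aucr, scenario)

    def test_tabulates_and_computes_percent(self):
        r = self._result(("SZB", "multiple_dose", "non_expresser", "RI_and_TDI"), 1.5721)
        df = scenario_table([r])
        assert len(df) == 1
        assert df.loc[0, "percent_increase"] == pytest.approx(57.21)

    def test_duplicate_scenarios_rejected(self):
        s = ("SZB", "single_dose", "expresser", "RI_only")
        with pytest.raises(DomainError, match="duplicate"):
            scenario_table([self._result(s), self._result(s)])

    def test_empty_list_gives_header_only(self):
        df = scenario_table([])
        assert df.empty and "aucr" in df.columns
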