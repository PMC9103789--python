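"""IC50, Dixon-Ki and inactivation-kinetics estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from szddi import (
    GeneratorSpec,
    efficiency,
    fit_dixon,
    fit_ic50,
    fit_inactivation,
    fit_kobs,
    fit_tdi,
    generate_dixon_dataset,
    generate_ic50_dataset,
    generate_ic50_pair,
    generate_tdi_dataset,
    ic50_shift,
)
from szddi.kinetics import DixonKiEstimator, IC50Regressor
from szddi.exceptions import DomainError, FitError, NoInhibitionError

SZA_IC50_GRID = (0, 20, 30, 40, 50, 60, 70, 80, 90, 100)


class TestIC50:
    def test_noiseless_curve_recovers_truth(self):
        ds = generate_ic50_dataset(GeneratorSpec(ic50=0.56, cv=0.0))
        fit = fit_ic50(ds)
        assert fit.ic50 == pytest.approx(0.56, rel=1e-6)
        assert fit.converged

    def test_flat_responses_raise_no_inhibition(self):
        est = IC50Regressor()
        conc = np.array([0, 0.1, 1, 10, 100.0]).reshape(-1, 1)
        with pytest.raises(NoInhibitionError):
            est.fit(conc, np.ones(5))

    def test_ic50_far_above_grid_reads_as_flat(self):
        ds = generate_ic50_dataset(GeneratorSpec(ic50=5e4, cv=0.0))
        with pytest.raises(NoInhibitionError):
            fit_ic50(ds)

    def test_noisy_recovery_within_ten_percent(self):
        ds = generate_ic50_dataset(GeneratorSpec(ic50=0.56, cv=0.05, seed=3))
        assert fit_ic50(ds).ic50 == pytest.approx(0.56, rel=0.10)

    def test_estimator_predict_matches_model(self):
        ds = generate_ic50_dataset(GeneratorSpec(ic50=2.0, hill=1.0, cv=0.0))
        df = ds.to_frame()
        est = IC50Regressor().fit(
            df[["inhibitor_conc_uM"]].to_numpy(), df["response"].to_numpy()
        )
        pred = est.predict(np.array([[2.0], [0.0]]))
        assert pred[0] == pytest.approx(0.5, rel=1e-6)
        assert pred[1] == 1.0

    def test_sklearn_param_round_trip(self):
        est = IC50Regressor(free_bottom=True)
        params = est.get_params()
        assert params["free_bottom"] is True
        est.set_params(flat_tolerance=0.1)
        assert est.flat_tolerance == 0.1


class TestShift:
    def test_reference_shift_values(self):
        szb = ic50_shift(11.98, 0.56)
        sza = ic50_shift(63.46, 40.45)
        assert round(szb.shift, 2) == 21.39 and szb.tdi_flag
        assert round(sza.shift, 2) == 1.57 and sza.tdi_flag

    def test_identity_is_not_flagged(self):
        res = ic50_shift(5.0, 5.0)
        assert res.shift == 1.0 and not res.tdi_flag

    def test_nonpositive_raises(self):
        with pytest.raises(DomainError):
            ic50_shift(0.0, 1.0)

    @given(
        a=st.floats(1e-3, 1e3, allow_nan=False),
        b=st.floats(1e-3, 1e3, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_shift_reciprocity(self, a, b):
        assert ic50_shift(a, b).shift * ic50_shift(b, a).shift == pytest.approx(1.0)

    def test_pipeline_shift_from_generated_pair(self):
        no_pre, pre = generate_ic50_pair(GeneratorSpec(cv=0.0), 11.98, 0.56)
        res = ic50_shift(fit_ic50(no_pre), fit_ic50(pre))
        assert res.shift == pytest.approx(21.39, abs=0.005)
        assert res.tdi_flag


class TestDixon:
    @pytest.mark.parametrize("ki", [5.82, 2.18, 2.03])
    def test_noiseless_competitive_recovery(self, ki):
        ds = generate_dixon_dataset(GeneratorSpec(ki=ki, cv=0.0))
        fit = fit_dixon(ds)
        assert fit.mechanism_label == "competitive"
        assert fit.ki == pytest.approx(ki, rel=1e-6)
        assert fit.intersection_x == pytest.approx(-ki, rel=1e-6)

    @given(ki=st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exactness_over_ki_range(self, ki):
        ds = generate_dixon_dataset(GeneratorSpec(ki=ki, cv=0.0))
        fit = fit_dixon(ds)
        assert fit.mechanism_label == "competitive"
        assert fit.ki == pytest.approx(ki, rel=1e-6)

    def test_no_inhibition_labelled_none_detected(self):
        # effectively infinite Ki: zero-slope Dixon lines
        ds = generate_dixon_dataset(GeneratorSpec(ki=1e12, cv=0.0))
        fit = fit_dixon(ds)
        assert fit.mechanism_label == "none_detected"
        assert fit.ki is None

    def test_single_substrate_level_rejected(self):
        est = DixonKiEstimator()
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(Exception, match="substrate"):
            est.fit(X, np.array([1.0, 0.5, 0.33]))

    def test_nonpositive_velocity_rejected(self):
        est = DixonKiEstimator()
        X = np.array([[s, i] for s in (0.5, 1.0) for i in (0.0, 1.0, 2.0)])
        y = np.array([1.0, 0.5, 0.0, 1.0, 0.6, 0.4])
        with pytest.raises(DomainError):
            est.fit(X, y)


class TestKobs:
    def _dataset(self, KI=0.43, kinact=0.044):
        return generate_tdi_dataset(
            GeneratorSpec(KI=KI, kinact=kinact, cv=0.0, inhibitor_grid=(0, 0.43, 1, 2, 4))
        )

    def test_closed_form_decay(self):
        ds = generate_tdi_dataset(
            GeneratorSpec(KI=1.0, kinact=0.06, cv=0.0, inhibitor_grid=(0.0, 1.0))
        )
        # at [I] = KI, kobs = kinact/2 = 0.03
        assert fit_kobs(ds, 1.0) == pytest.approx(0.03, abs=1e-9)

    def test_half_saturation_point(self):
        assert fit_kobs(self._dataset(), 0.43) == pytest.approx(0.022, abs=1e-6)

    def test_constant_activity_gives_zero(self):
        ds = self._dataset()
        assert fit_kobs(ds, 0.0, control_correct=False) == 0.0

    def test_control_correction_removes_shared_decay(self):
        # inject a common NADPH-independent loss on top of the TDI signal
        from szddi.assay import AssayDataset, VelocityRecord

        base = self._dataset()
        k0 = 0.005
        records = [
            VelocityRecord(
                r.substrate_conc, r.inhibitor_conc, r.preincubation_min,
                r.replicate, r.response * np.exp(-k0 * r.preincubation_min),
            )
            for r in base.records
        ]
        ds = AssayDataset(records=records, assay_kind="tdi", normalized=True)
        assert fit_kobs(ds, 0.43) == pytest.approx(0.022, abs=1e-9)
        assert fit_kobs(ds, 0.43, control_correct=False) == pytest.approx(
            0.022 + k0, abs=1e-9
        )

    def test_zero_activity_rejected(self):
        from szddi.assay import AssayDataset, VelocityRecord

        records = [
            VelocityRecord(200, 0.0, t, 1, 1.0) for t in (0, 5, 10, 20, 30)
        ] + [VelocityRecord(200, 1.0, t, 1, max(1.0 - 0.04 * t, 0.0)) for t in (0, 5, 10, 20, 30)]
        ds = AssayDataset(records=records, assay_kind="tdi", normalized=True)
        with pytest.raises(DomainError, match="log"):
            fit_kobs(ds, 1.0)


class TestInactivation:
    @pytest.mark.parametrize(
        "kinact, KI, eff",
        [(0.37, 0.69, 536.23), (0.044, 0.43, 102.33), (0.009, 0.5, 18.0)],
    )
    def test_noiseless_recovery_and_efficiency(self, kinact, KI, eff):
        I = (KI * 0.25, KI * 0.5, KI, 2 * KI, 4 * KI)
        kobs = {i: kinact * i / (KI + i) for i in I}
        fit = fit_inactivation(kobs)
        assert fit.kinact == pytest.approx(kinact, rel=1e-6)
        assert fit.KI == pytest.approx(KI, rel=1e-6)
        assert fit.efficiency == pytest.approx(eff, abs=0.005)

    def test_kitz_wilson_diagnostic_agrees_noiseless(self):
        kobs = {i: 0.044 * i / (0.43 + i) for i in (0.1, 0.2, 0.5, 1.0, 2.0)}
        fit = fit_inactivation(kobs)
        assert fit.kitz_wilson["kinact"] == pytest.approx(0.044, rel=1e-6)
        assert fit.kitz_wilson["KI"] == pytest.approx(0.43, rel=1e-6)

    def test_all_zero_kobs_raises(self):
        with pytest.raises(FitError, match="no inactivation"):
            fit_inactivation({0.1: 0.0, 0.5: 0.0, 1.0: 0.0, 2.0: 0.0})

    def test_full_pipeline_on_generated_activity(self):
        ds = generate_tdi_dataset(GeneratorSpec(KI=0.43, kinact=0.044, cv=0.0))
        fit = fit_tdi(ds)
        assert fit.efficiency == pytest.approx(102.33, abs=0.005)

    def test_kobs_monotone_and_bounded_by_kinact(self):
        ds = generate_tdi_dataset(GeneratorSpec(KI=0.69, kinact=0.37, cv=0.0))
        fit = fit_tdi(ds)
        ordered = [fit.kobs_by_conc[c] for c in sorted(fit.kobs_by_conc)]
        assert all(b >= a - 1e-12 for a, b in zip(ordered, ordered[1:]))
        assert max(ordered) <= fit.kinact * (1 + 1e-9)


class TestEfficiency:
    @pytest.mark.parametrize(
        "kinact, KI, expected",
        [
            (0.044, 0.43, 102.33),
            (0.029, 15.625, 1.856),
            (0.024, 15.38, 1.56),
            (0.37, 0.69, 536.23),
            (0.009, 0.5, 18.0),
        ],
    )
    def test_reference_values(self, kinact, KI, expected):
        assert efficiency(kinact, KI) == pytest.approx(expected, abs=0.005)

    def test_domain(self):
        with pytest.raises(DomainError):
            efficiency(0.0, 1.0)
        with pytest.raises(DomainError):
            efficiency(0.1, -1.0)
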