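"""End-to-end calibration comparison and solubility determination."""

import numpy as np
import pytest

from thermocal.exceptions import AlignmentError, CoverageError, ParameterError
from thermocal.pls import CVConfig
from thermocal.synthetic_data import (
    SolubilityModel,
    default_uv_config,
    generate_calibration_set,
    generate_slurry_experiment,
    generate_validation_set,
    solubility_at,
    table1_design,
)
from thermocal.workflows import (
    SolubilityCurve,
    _prepare_variant,
    bias_metrics,
    default_uv_variants,
    extract_hold_endpoints,
    fit_vant_hoff,
    predict_solubility_curve,
    reference_curve,
    run_calibration_comparison,
)


@pytest.fixture(scope="module")
def lin_chain_report():
    """Comparison run on linearized noise-free data (2 replicates so CV
    folds stay populated)."""
    cfg = default_uv_config(mode="linearized", noise_sd=0.0, n_replicates=2)
    cal = generate_calibration_set(table1_design(), cfg, seed=0)
    val = generate_validation_set(cfg, seed=1)
    report = run_calibration_comparison(cal, val, default_uv_variants(), CVConfig(seed=0))
    return cfg, report


class TestCalibrationComparison:
    def test_local_variant_trains_only_on_the_isothermal_slice(self):
        cfg = default_uv_config(n_replicates=2)
        cal = generate_calibration_set(table1_design(), cfg, seed=0)
        val = generate_validation_set(cfg, seed=1)
        local = [v for v in default_uv_variants() if v.label == "local_isothermal"][0]
        ds, _, _ = _prepare_variant(cal, val, local)
        assert np.all(ds.temperatures == 50.0)
        assert {m.concentration for m in ds.meta} == {4.0, 8.0, 12.0, 16.0, 20.0}

    def test_lss_variant_fits_on_three_lower_concentrations_only(self, realistic_report):
        lss_model = realistic_report.chains["global_lss"].lss_model
        # 3 compositions x 5 replicates anchored at the reference temperature
        assert lss_model.ref_scores.shape == (15, 2)
        assert lss_model.temps_used.size == 10

    def test_qualitative_ordering_of_variants(self, realistic_report):
        """Temperature correction recovers near-local complexity and
        accuracy; the uncorrected global model needs more components."""
        r = {v.label: v for v in realistic_report.variants}
        assert r["global_raw"].chosen_lv >= r["global_lss"].chosen_lv
        assert r["global_lss"].chosen_lv == r["local_isothermal"].chosen_lv
        assert (
            r["local_isothermal"].rmsecv
            <= r["global_lss"].rmsecv
            <= r["global_raw"].rmsecv
        )

    def test_validation_precision_improves_with_correction(self, realistic_report):
        r = {v.label: v for v in realistic_report.variants}
        for sample in r["global_raw"].validation:
            assert (
                r["global_lss"].validation[sample].rsd
                < r["global_raw"].validation[sample].rsd
            )

    def test_report_is_bit_reproducible(self):
        cfg = default_uv_config(n_replicates=2)
        cal = generate_calibration_set(table1_design(), cfg, seed=3)
        val = generate_validation_set(cfg, seed=4)
        a = run_calibration_comparison(cal, val, default_uv_variants(), CVConfig(seed=5))
        b = run_calibration_comparison(cal, val, default_uv_variants(), CVConfig(seed=5))
        assert a.to_dict() == b.to_dict()

    def test_ir_variants_chain_derivative_and_correction(self):
        """The IR strategy set corrects the first-derivative spectra; the
        preprocessing tags must chain consistently through the pipeline."""
        from thermocal.synthetic_data import default_ir_config
        from thermocal.workflows import default_ir_variants

        cfg = default_ir_config(n_replicates=2)
        cal = generate_calibration_set(table1_design(), cfg, seed=0)
        val = generate_validation_set(cfg, seed=1)
        report = run_calibration_comparison(
            cal, val, default_ir_variants(), CVConfig(seed=0)
        )
        assert report.chains["global_lss"].pls.preprocessing_tag == "absorbance:sg7d1:lss50"
        assert report.chains["global_lss"].lss_model.preprocessing_tag == "absorbance:sg7d1"
        r = {v.label: v for v in report.variants}
        assert r["global_lss"].chosen_lv <= r["global_raw"].chosen_lv

    def test_report_dataframe_has_one_row_per_variant(self, realistic_report):
        df = realistic_report.to_dataframe()
        assert list(df["label"]) == [v.label for v in realistic_report.variants]
        assert {"LVs", "RMSEC", "RMSECV"} <= set(df.columns)


@pytest.fixture(scope="module")
def slurry():
    cfg = default_uv_config(noise_sd=0.0, n_replicates=1)
    return generate_slurry_experiment(
        cfg, SolubilityModel(), spectra_per_hold=4, seed=0
    )


class TestHoldEndpoints:

    def test_one_endpoint_per_hold(self, slurry):
        ds, profile = slurry
        endpoints = extract_hold_endpoints(ds, profile)
        assert endpoints.n_spectra == 8

    def test_endpoint_is_latest_spectrum_of_each_hold(self, slurry):
        ds, profile = slurry
        endpoints = extract_hold_endpoints(ds, profile)
        times = ds.times
        for meta, hold in zip(endpoints.meta, profile.holds):
            in_hold = (times >= hold.start) & (times <= hold.end)
            assert meta.time == times[in_hold].max()
            assert meta.temperature == hold.setpoint

    def test_ramp_spectra_are_excluded(self, slurry):
        ds, profile = slurry
        endpoints = extract_hold_endpoints(ds, profile)
        assert all(not m.sample_id.startswith("slurry_ramp") for m in endpoints.meta)

    def test_empty_hold_raises(self, slurry):
        ds, profile = slurry
        ramp_only = ds.subset(
            [i for i, m in enumerate(ds.meta) if m.sample_id.startswith("slurry_ramp")]
        )
        with pytest.raises(CoverageError):
            extract_hold_endpoints(ramp_only, profile)


class TestSolubilityCurve:
    def test_linearized_lss_chain_recovers_ground_truth_within_one_percent(
        self, lin_chain_report
    ):
        cfg, report = lin_chain_report
        sol = SolubilityModel()
        ds, profile = generate_slurry_experiment(
            cfg, sol, spectra_per_hold=3, kinetics_tau=0.0, seed=0
        )
        endpoints = extract_hold_endpoints(ds, profile)
        curve = predict_solubility_curve(report.chains["global_lss"], endpoints)
        truth = solubility_at(sol, curve.temperatures)
        assert np.max(np.abs(curve.concentrations - truth) / truth) < 0.01

    def test_correction_does_not_worsen_bias(self, realistic_report):
        cfg = default_uv_config()
        sol = SolubilityModel()
        ds, profile = generate_slurry_experiment(cfg, sol, seed=0)
        endpoints = extract_hold_endpoints(ds, profile)
        summaries = {}
        for label in ("global_raw", "global_lss"):
            curve = predict_solubility_curve(realistic_report.chains[label], endpoints)
            summaries[label] = bias_metrics(
                curve, reference_curve(sol, curve.temperatures)
            )
        assert abs(summaries["global_lss"].mean_bias) <= abs(
            summaries["global_raw"].mean_bias
        )
        assert summaries["global_lss"].bias_range <= summaries["global_raw"].bias_range

    def test_empty_endpoints_give_empty_curve(self, lin_chain_report):
        cfg, report = lin_chain_report
        from thermocal.spectra_core import SpectralDataset

        empty = SpectralDataset(
            axis=cfg.axis, intensities=np.empty((0, len(cfg.axis))), meta=[]
        )
        curve = predict_solubility_curve(report.chains["global_lss"], empty)
        assert curve.temperatures.size == 0

    def test_curve_temperatures_must_increase(self):
        with pytest.raises(ParameterError):
            SolubilityCurve(np.array([10.0, 5.0]), np.array([1.0, 2.0]))


class TestBias:
    def _curve(self, biases):
        t = np.array([0.0, 10.0, 20.0])[: len(biases)]
        base = np.array([5.0, 6.0, 7.0])[: len(biases)]
        return (
            SolubilityCurve(t, base + np.asarray(biases), "pred"),
            SolubilityCurve(t, base, "ref"),
        )

    def test_identical_curves(self):
        pred, ref = self._curve([0.0, 0.0, 0.0])
        b = bias_metrics(pred, ref)
        assert b.mean_bias == 0.0 and b.bias_range == 0.0

    def test_constant_offset(self):
        pred, ref = self._curve([0.5, 0.5, 0.5])
        b = bias_metrics(pred, ref)
        assert b.mean_bias == pytest.approx(0.5) and b.bias_range == 0.0

    def test_mixed_biases(self):
        pred, ref = self._curve([0.2, -0.1, 0.3])
        b = bias_metrics(pred, ref)
        assert b.mean_bias == pytest.approx(0.4 / 3)
        assert b.bias_range == pytest.approx(0.4)

    def test_grid_mismatch_rejected(self):
        pred, _ = self._curve([0.0, 0.0, 0.0])
        other = SolubilityCurve(np.array([0.0, 15.0, 20.0]), np.array([5.0, 6.0, 7.0]))
        with pytest.raises(AlignmentError):
            bias_metrics(pred, other)


class TestVantHoffFit:
    def test_exact_points_recover_parameters(self):
        sol = SolubilityModel(A=8.1, B=1600.0)
        temps = np.arange(0.0, 80.0, 10.0)
        fit = fit_vant_hoff(reference_curve(sol, temps))
        assert fit.A == pytest.approx(8.1, abs=1e-9)
        assert fit.B == pytest.approx(1600.0, abs=1e-6)

    def test_two_points_interpolate_exactly(self):
        sol = SolubilityModel(A=7.0, B=1200.0)
        temps = np.array([10.0, 60.0])
        fit = fit_vant_hoff(reference_curve(sol, temps))
        np.testing.assert_allclose(
            solubility_at(fit, temps), solubility_at(sol, temps), rtol=1e-12
        )

    def test_noisy_points_recover_slope_within_ten_percent(self):
        sol = SolubilityModel(A=8.1, B=1600.0)
        temps = np.arange(0.0, 80.0, 10.0)
        noisy = reference_curve(sol, temps, noise_sd=0.1, seed=0)
        fit = fit_vant_hoff(noisy)
        assert abs(fit.B - 1600.0) / 1600.0 < 0.10

    def test_non_positive_concentration_rejected(self):
        with pytest.raises(ParameterError):
            fit_vant_hoff(SolubilityCurve(np.array([0.0, 10.0]), np.array([0.0, 1.0])))
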