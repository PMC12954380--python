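"""Unit tests for the spectro-titration processing and Nernstian fitting."""

import numpy as np
import pandas as pd
import pytest

from redoxpath import (
    FitConvergenceError,
    ProcessingConfig,
    SpectrumRecord,
    TitrationError,
    TitrationSeries,
    band_average,
    baseline_correct,
    bootstrap_em_sd,
    drift_correct,
    fit_nernst,
    nernst_response,
    normalize_trace,
    read_titration,
    to_she,
    write_titration,
)


def grid_search_em(E, y, config, step=0.1, margin=60.0):
    """Independent brute-force oracle: exhaustive Em grid with closed-form
    linear least squares for (a, c) at each candidate."""
    E = np.asarray(E, float)
    y = np.asarray(y, float)
    vt = 1000.0 * config.gas_constant * config.temperature / (config.electrons_z * config.faraday)
    best_rss, best_em = np.inf, None
    for em in np.arange(E.min() - margin, E.max() + margin + step / 2, step):
        f = 1.0 / (np.exp(np.clip((E - em) / vt, -500, 500)) + 1.0)
        design = np.column_stack([f, np.ones_like(f)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((design @ coef - y) ** 2).sum())
        if rss < best_rss:
            best_rss, best_em = rss, em
    return best_em


def make_trace(values, potentials=None):
    n = len(values)
    return pd.DataFrame(
        {
            "acquisition_index": np.arange(n),
            "applied_potential": potentials if potentials is not None else np.linspace(-300, 300, n),
            "value": np.asarray(values, float),
        }
    )


class TestDataModel:
    def test_nonmonotone_wavelengths_rejected(self):
        with pytest.raises(TitrationError, match="strictly increasing"):
            SpectrumRecord(wavelengths=[500, 490, 510], absorbances=[1, 1, 1],
                           applied_potential=0.0, acquisition_index=0)

    def test_nonfinite_absorbance_rejected(self):
        with pytest.raises(TitrationError, match="non-finite"):
            SpectrumRecord(wavelengths=[490, 500], absorbances=[1.0, np.nan],
                           applied_potential=0.0, acquisition_index=0)

    def test_noncontiguous_indices_rejected(self):
        wl = np.array([650.0, 660.0, 700.0])
        spectra = [
            SpectrumRecord(wavelengths=wl, absorbances=np.zeros(3),
                           applied_potential=float(i), acquisition_index=i)
            for i in (0, 2)
        ]
        with pytest.raises(TitrationError, match="contiguous"):
            TitrationSeries(spectra=spectra)


class TestCsvIO:
    def test_roundtrip(self, flat_series, tmp_path):
        path = write_titration(flat_series, tmp_path / "series.csv")
        back = read_titration(path)
        assert len(back) == 3
        assert [s.acquisition_index for s in back.spectra] == [0, 1, 2]
        assert back.reference_offset == flat_series.reference_offset
        for orig, rt in zip(flat_series.spectra, back.spectra):
            np.testing.assert_allclose(rt.absorbances, orig.absorbances)
            assert rt.applied_potential == orig.applied_potential

    def test_duplicate_acquisition_index_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "acquisition_index,applied_potential_mV,wavelength_nm,absorbance\n"
            "0,-330,470,0.1\n0,-330,480,0.1\n"
            "1,-310,470,0.2\n1,-310,480,0.2\n"
            "1,-290,470,0.3\n1,-290,480,0.3\n"
        )
        with pytest.raises(TitrationError, match="duplicated acquisition_index 1"):
            read_titration(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text(
            "acquisition_index,applied_potential_mV,wavelength_nm,absorbance\n"
            "0,-330,470,0.1\n0,-330,480\n"
        )
        with pytest.raises(TitrationError, match="row"):
            read_titration(path)

    def test_header_offset_parsed(self, tmp_path):
        path = tmp_path / "offset.csv"
        path.write_text(
            "# reference_offset_mV=197.0\n"
            "acquisition_index,applied_potential_mV,wavelength_nm,absorbance\n"
            "0,-330,470,0.1\n0,-330,480,0.1\n"
        )
        assert read_titration(path).reference_offset == 197.0


class TestBaselineCorrect:
    def test_constant_spectrum_goes_to_zero(self, flat_series, config):
        out = baseline_correct(flat_series, config)
        for s in out.spectra:
            np.testing.assert_allclose(s.absorbances, 0.0, atol=1e-12)

    def test_step_spectrum(self, config):
        wl = np.arange(400.0, 720.0, 2.0)
        absorb = np.where(wl < 650.0, 0.2, 0.4)
        series = TitrationSeries(spectra=[SpectrumRecord(wl, absorb, 0.0, 0)])
        out = baseline_correct(series, config).spectra[0]
        np.testing.assert_allclose(out.absorbances[wl < 650], -0.2, atol=1e-12)
        np.testing.assert_allclose(out.absorbances[(wl >= 650) & (wl <= 700)], 0.0, atol=1e-12)

    def test_idempotent(self, flat_series, config):
        once = baseline_correct(flat_series, config)
        twice = baseline_correct(once, config)
        for a, b in zip(once.spectra, twice.spectra):
            np.testing.assert_allclose(a.absorbances, b.absorbances, atol=1e-14)

    def test_no_samples_in_window_errors(self, config):
        wl = np.arange(400.0, 600.0, 2.0)  # misses the 650-700 nm window
        series = TitrationSeries(spectra=[SpectrumRecord(wl, np.zeros_like(wl), 0.0, 0)])
        with pytest.raises(TitrationError, match="baseline window"):
            baseline_correct(series, config)


class TestBandAverage:
    def test_arithmetic_mean_of_band(self, config):
        wl = np.concatenate([[465.0, 475.0, 485.0], np.arange(650.0, 702.0, 2.0)])
        absorb = np.concatenate([[0.1, 0.2, 0.3], np.zeros(26)])
        series = TitrationSeries(spectra=[SpectrumRecord(wl, absorb, 10.0, 0)])
        trace = band_average(series, config)
        assert trace.loc[0, "value"] == pytest.approx(0.2)
        assert trace.loc[0, "applied_potential"] == 10.0

    def test_single_sample_in_band(self, config):
        wl = np.concatenate([[475.0], np.arange(650.0, 702.0, 2.0)])
        absorb = np.concatenate([[0.42], np.zeros(26)])
        series = TitrationSeries(spectra=[SpectrumRecord(wl, absorb, 0.0, 0)])
        assert band_average(series, config).loc[0, "value"] == pytest.approx(0.42)

    def test_empty_band_errors(self, config):
        wl = np.arange(600.0, 720.0, 2.0)
        series = TitrationSeries(spectra=[SpectrumRecord(wl, np.zeros_like(wl), 0.0, 0)])
        with pytest.raises(TitrationError, match="analysis band"):
            band_average(series, config)


class TestDriftCorrect:
    def test_zero_difference_leaves_trace_unchanged(self):
        trace = make_trace([0.5, 0.7, 0.9, 0.5], potentials=[-330, -250, -170, -330])
        out = drift_correct(trace, repeated_potential=-330)
        np.testing.assert_allclose(out["value"], trace["value"], atol=1e-14)

    def test_constructed_ramp_removed_exactly(self):
        rng = np.random.default_rng(11)
        clean = rng.normal(size=8)
        clean[7] = clean[0]  # drift-free repeat re-measures the same value
        potentials = [-330, -250, -170, -90, -10, 70, 150, -330]
        n = len(clean)
        d = 0.37
        ramp = d * np.arange(n) / (n - 1)
        trace = make_trace(clean + ramp, potentials=potentials)
        out = drift_correct(trace, repeated_potential=-330)
        np.testing.assert_allclose(out["value"], clean, rtol=1e-12, atol=1e-12)

    def test_first_and_last_repeat_become_equal(self):
        trace = make_trace([0.1, 0.4, 0.8, 0.35], potentials=[-330, -250, -170, -330])
        out = drift_correct(trace, repeated_potential=-330)
        assert out.loc[0, "value"] == pytest.approx(out.loc[3, "value"], abs=1e-12)

    def test_missing_repeat_advises_skip(self):
        trace = make_trace([0.1, 0.4, 0.8], potentials=[-330, -250, -170])
        with pytest.raises(TitrationError, match="skip drift correction"):
            drift_correct(trace, repeated_potential=-999)


class TestNormalizeTrace:
    def test_min_max_scaling(self):
        out = normalize_trace(make_trace([2.0, 3.0, 4.0], potentials=[-300, 0, 300]))
        np.testing.assert_allclose(out["value"], [0.0, 0.5, 1.0])

    def test_idempotent(self):
        once = normalize_trace(make_trace([2.0, 2.5, 4.0], potentials=[-300, 0, 300]))
        twice = normalize_trace(once)
        np.testing.assert_allclose(twice["value"], once["value"], atol=1e-14)

    def test_decreasing_trace_rezeroed_at_lowest_potential(self):
        out = normalize_trace(make_trace([4.0, 3.0, 2.0], potentials=[-300, 0, 300]))
        np.testing.assert_allclose(out["value"], [0.0, -0.5, -1.0])

    def test_order_preserved_on_monotone_sigmoid(self, config):
        E = np.linspace(-50, 550, 31)
        y = nernst_response(E, 250.0, -1.0, 1.0, config)
        out = normalize_trace(make_trace(y, potentials=E))
        assert np.all(np.diff(out["value"]) * np.diff(y) >= 0)

    def test_constant_trace_errors(self):
        with pytest.raises(TitrationError, match="constant trace"):
            normalize_trace(make_trace([1.0, 1.0, 1.0]))


class TestScaleAndModel:
    def test_reference_offset_conversion(self, config):
        assert to_she(0.0, config) == pytest.approx(280.0)
        assert to_she(-280.0, config) == pytest.approx(0.0)
        assert to_she(55.0, config) == pytest.approx(335.0)

    def test_nernst_midpoint_and_limits(self, config):
        assert nernst_response(300.0, 300.0, 1.0, 0.25, config) == pytest.approx(0.75)
        assert nernst_response(1e5, 300.0, 1.0, 0.25, config) == pytest.approx(0.25)
        assert nernst_response(-1e5, 300.0, 1.0, 0.25, config) == pytest.approx(1.25)

    def test_ln9_spacing(self, config):
        # RT/F at 293 K puts the 10 % point ~55.5 mV above Em
        vt = 1000.0 * 8.3145 * 293.0 / 96485.34
        assert nernst_response(vt * np.log(9.0), 0.0, 1.0, 0.0, config) == pytest.approx(0.100, abs=1e-3)
        assert nernst_response(55.5, 0.0, 1.0, 0.0, config) == pytest.approx(0.100, abs=1e-3)

    def test_transition_width_closed_form(self, config):
        """The 10%->90% span of a fitted curve is 2 ln9 RT/F (~111 mV)."""
        from scipy.optimize import brentq
        E = np.arange(-50.0, 551.0, 20.0)
        y = nernst_response(E, 303.0, -1.0, 1.0, config)
        fit = fit_nernst(E, y, config)

        def level(frac):
            target = fit.offset_c + frac * fit.amplitude_a
            return brentq(
                lambda e: nernst_response(e, fit.Em, fit.amplitude_a, fit.offset_c, config) - target,
                -500.0, 1000.0,
            )

        span = abs(level(0.1) - level(0.9))
        expected = 2.0 * np.log(9.0) * config.thermal_voltage_mV
        assert span == pytest.approx(expected, abs=1.0)
        assert expected == pytest.approx(110.9, abs=0.5)


class TestFitNernst:
    @pytest.mark.parametrize("em_true", [303.0, 335.0])
    def test_noiseless_recovery(self, config, em_true):
        E = np.arange(-50.0, 551.0, 20.0)
        y = nernst_response(E, em_true, -1.0, 1.0, config)
        fit = fit_nernst(E, y, config)
        assert fit.Em == pytest.approx(em_true, abs=0.1)
        assert fit.amplitude_a == pytest.approx(-1.0, abs=1e-6)
        assert fit.offset_c == pytest.approx(1.0, abs=1e-6)
        assert fit.em_in_range

    @pytest.mark.parametrize("em_true,a,c", [(303.0, -1.0, 1.0), (335.0, -1.0, 1.0),
                                             (150.0, 0.8, 0.1), (420.0, 1.3, -0.2)])
    def test_agrees_with_grid_search_oracle(self, config, em_true, a, c):
        E = np.arange(-50.0, 551.0, 20.0)
        y = nernst_response(E, em_true, a, c, config)
        fit = fit_nernst(E, y, config)
        oracle = grid_search_em(E, y, config)
        assert abs(fit.Em - oracle) < 1.0

    def test_translation_equivariance(self, config):
        E = np.arange(-50.0, 551.0, 20.0)
        rng = np.random.default_rng(3)
        y = nernst_response(E, 250.0, -1.0, 1.0, config) + rng.normal(0, 0.01, E.size)
        fit0 = fit_nernst(E, y, config)
        fit1 = fit_nernst(E + 10.0, y, config)
        assert fit1.Em - fit0.Em == pytest.approx(10.0, abs=1e-4)

    def test_too_few_distinct_potentials(self, config):
        with pytest.raises(TitrationError, match="4 distinct"):
            fit_nernst([0.0, 0.0, 100.0, 200.0], [1, 1, 0.5, 0.0], config)

    def test_narrow_span_rejected(self, config):
        E = np.array([0.0, 10.0, 20.0, 30.0])
        with pytest.raises(TitrationError, match="span"):
            fit_nernst(E, [0.9, 0.6, 0.4, 0.1], config)


class TestBootstrap:
    @pytest.fixture
    def noiseless(self, config):
        E = np.arange(-50.0, 551.0, 20.0)
        return E, nernst_response(E, 300.0, -1.0, 1.0, config)

    def test_zero_sds_give_zero_spread(self, config, noiseless):
        E, y = noiseless
        est = bootstrap_em_sd(E, y, np.zeros_like(y), config, n_replicates=50, seed=1)
        assert est.Em_sd == pytest.approx(0.0, abs=1e-9)
        assert est.Em_mean == pytest.approx(300.0, abs=0.1)

    def test_sd_scale_monotonicity(self, config, noiseless):
        E, y = noiseless
        sds = np.full_like(y, 0.02)
        lo = bootstrap_em_sd(E, y, sds, config, n_replicates=300, sd_scale=1.0, seed=5)
        hi = bootstrap_em_sd(E, y, sds, config, n_replicates=300, sd_scale=3.0, seed=5)
        assert hi.Em_sd > lo.Em_sd

    def test_seed_determinism(self, config, noiseless):
        E, y = noiseless
        sds = np.full_like(y, 0.02)
        a = bootstrap_em_sd(E, y, sds, config, n_replicates=100, seed=42)
        b = bootstrap_em_sd(E, y, sds, config, n_replicates=100, seed=42)
        assert a.Em_sd == b.Em_sd
        assert a.Em_mean == b.Em_mean

    def test_negative_sds_rejected(self, config, noiseless):
        E, y = noiseless
        with pytest.raises(TitrationError, match="non-negative"):
            bootstrap_em_sd(E, y, np.full_like(y, -0.1), config, n_replicates=10, seed=0)
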