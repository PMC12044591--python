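import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroplast.core_model import Spectrum, TgaFtirRun, ValidationError, WavenumberGrid
from pyroplast.preprocess import (
    PreprocessConfig,
    align_tg_to_spectra,
    apply_temperature_offset,
    baseline_correct,
    gram_schmidt_trace,
    preprocess_run,
    snv,
    snv_vector,
)

from conftest import toy_run


@pytest.fixture(scope="module")
def wide_grid():
    return WavenumberGrid(np.arange(800.0, 4000.0, 4.0))


class TestBaseline:
    def test_flat_spectrum_goes_to_zero(self, wide_grid):
        s = Spectrum(np.full(len(wide_grid), 0.3), 300.0)
        out = baseline_correct(s, wide_grid)
        assert np.abs(out.absorbance).max() < 1e-6

    def test_all_zero_stays_zero(self, wide_grid):
        s = Spectrum(np.zeros(len(wide_grid)), 300.0)
        out = baseline_correct(s, wide_grid)
        assert np.abs(out.absorbance).max() < 1e-12

    def test_gaussian_peak_on_ramp_preserved(self, wide_grid):
        x = wide_grid.values
        ramp = 0.1 + 1e-4 * (x - 800.0)
        peak = 0.8 * np.exp(-((x - 1600.0) ** 2) / (2 * 40.0**2))
        out = baseline_correct(Spectrum(ramp + peak, 300.0), wide_grid)
        height = out.absorbance[np.argmin(np.abs(x - 1600.0))]
        assert height == pytest.approx(0.8, rel=0.02)

    def test_too_few_unmasked_points(self, wide_grid):
        mask = np.zeros(len(wide_grid), dtype=bool)
        mask[:5] = True
        s = Spectrum(np.ones(len(wide_grid)), 300.0, mask)
        with pytest.raises(ValidationError):
            baseline_correct(s, wide_grid)


class TestSnv:
    def test_known_values(self):
        out = snv_vector(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    def test_idempotent(self):
        s = Spectrum(np.array([1.0, 2.0, 3.0, 7.0]), 300.0)
        once = snv(s)
        twice = snv(once)
        np.testing.assert_allclose(once.absorbance, twice.absorbance, atol=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValidationError, match="zero variance"):
            snv_vector(np.array([5.0, 5.0, 5.0]))

    def test_stats_use_unmasked_only(self):
        x = np.array([1.0, 2.0, 3.0, 999.0])
        mask = np.array([True, True, True, False])
        out = snv_vector(x, mask)
        np.testing.assert_allclose(out[:3], [-1.22474487, 0.0, 1.22474487], atol=1e-8)

    @settings(max_examples=25, deadline=None)
    @given(
        values=st.lists(st.floats(-10, 10), min_size=4, max_size=16),
        scale=st.floats(0.1, 50),
        shift=st.floats(-5, 5),
    )
    def test_affine_invariance(self, values, scale, shift):
        x = np.asarray(values)
        if x.std() < 1e-6:
            return
        np.testing.assert_allclose(
            snv_vector(x), snv_vector(scale * x + shift), atol=1e-6
        )


class TestTemperatureOffset:
    def _run(self, small_grid, temps):
        return toy_run(small_grid, temps, [np.zeros(5)] * len(temps))

    def test_default_offset(self, small_grid):
        run = self._run(small_grid, [200.0, 300.0])
        out = apply_temperature_offset(run)  # 2.5 s at 10 degC/min
        np.testing.assert_allclose(out.temperatures, [200.0 - 0.41666667, 300.0 - 0.41666667])
        assert out.spectra[0].temperature == pytest.approx(200.0 - 2.5 * 10 / 60)

    def test_zero_dwell_is_identity(self, small_grid):
        run = self._run(small_grid, [200.0])
        out = apply_temperature_offset(run, PreprocessConfig(dwell_time_s=0.0))
        assert out.temperatures[0] == 200.0

    def test_unit_sanity_60s_at_60(self, small_grid):
        run = self._run(small_grid, [200.0])
        cfg = PreprocessConfig(dwell_time_s=60.0, heating_rate=60.0)
        out = apply_temperature_offset(run, cfg)
        assert out.temperatures[0] == pytest.approx(140.0)

    def test_applied_only_once(self, small_grid):
        run = self._run(small_grid, [200.0])
        out = apply_temperature_offset(apply_temperature_offset(run))
        assert out.temperatures[0] == pytest.approx(200.0 - 2.5 * 10 / 60)


class TestAlignTg:
    def test_linear_interpolation(self, small_grid):
        run = toy_run(small_grid, [250.0], [np.zeros(5)])
        run.metadata["tg_table"] = {"temperature": [200.0, 300.0], "tg": [100.0, 90.0]}
        out = align_tg_to_spectra(run)
        assert out.tg[0] == pytest.approx(95.0)

    def test_linear_dtg_value(self, small_grid):
        temps = np.linspace(200.0, 300.0, 21)
        run = toy_run(small_grid, temps, [np.zeros(5)] * 21)
        run.metadata["tg_table"] = {"temperature": [150.0, 350.0], "tg": [105.0, 85.0]}
        out = align_tg_to_spectra(run)
        np.testing.assert_allclose(out.dtg, 0.1, atol=1e-9)  # -d(tg)/dT of -0.1 %/degC

    def test_constant_tg_gives_zero_dtg(self, small_grid):
        temps = np.linspace(200.0, 300.0, 15)
        run = toy_run(small_grid, temps, [np.zeros(5)] * 15)
        run.metadata["tg_table"] = {"temperature": [100.0, 400.0], "tg": [90.0, 90.0]}
        out = align_tg_to_spectra(run)
        np.testing.assert_allclose(out.dtg, 0.0, atol=1e-12)

    def test_quadratic_tg_matches_analytic_derivative(self, small_grid):
        temps = np.linspace(200.0, 400.0, 101)
        run = toy_run(small_grid, temps, [np.zeros(5)] * 101)
        t_table = np.linspace(150.0, 450.0, 601)
        tg_table = 100.0 - 1e-4 * (t_table - 150.0) ** 2
        run.metadata["tg_table"] = {"temperature": t_table.tolist(), "tg": tg_table.tolist()}
        out = align_tg_to_spectra(run)
        analytic = 2e-4 * (temps - 150.0)  # positive loss rate
        np.testing.assert_allclose(out.dtg[3:-3], analytic[3:-3], atol=2e-3)

    def test_coverage_gap_names_interval(self, small_grid):
        run = toy_run(small_grid, [250.0, 500.0], [np.zeros(5)] * 2)
        run.metadata["tg_table"] = {"temperature": [200.0, 300.0], "tg": [100.0, 90.0]}
        with pytest.raises(ValidationError, match="500"):
            align_tg_to_spectra(run)


class TestGramSchmidt:
    def test_zero_spectrum(self, small_grid):
        run = toy_run(small_grid, [200.0], [np.zeros(5)])
        assert gram_schmidt_trace(run)[0] == 0.0

    def test_homogeneity(self, small_grid):
        v = np.array([0.1, 0.4, 0.2, 0.3, 0.5])
        run = toy_run(small_grid, [200.0, 300.0], [v, 2 * v])
        trace = gram_schmidt_trace(run)
        assert trace[1] == pytest.approx(2 * trace[0])

    def test_matches_brute_force(self, small_grid):
        v = np.array([0.0, 1.0, 1.0, 0.0, 0.0])
        run = toy_run(small_grid, [200.0], [v])
        assert gram_schmidt_trace(run)[0] == pytest.approx(np.sqrt(2.0))

    def test_masked_points_excluded(self, small_grid):
        s = Spectrum(np.array([1.0, 1.0, 1.0, 1.0, 5.0]), 200.0,
                     mask=np.array([True, True, True, True, False]))
        run = TgaFtirRun(grid=small_grid, temperatures=np.array([200.0]), spectra=[s])
        assert gram_schmidt_trace(run)[0] == pytest.approx(2.0)


def _raw_fixture_run(n_spectra=400, t_lo=40.0, t_hi=1000.0, seed=0, noise_sd=0.002):
    """Raw-looking run over the full heating programme (about 2.4 degC/spectrum)."""
    grid = WavenumberGrid(np.arange(600.0, 4400.0, 8.0))
    rng = np.random.default_rng(seed)
    temps = np.linspace(t_lo, t_hi, n_spectra)
    x = grid.values
    band = np.exp(-((x - 1600.0) ** 2) / (2 * 40.0**2))
    env = np.exp(-((temps - 450.0) ** 2) / (2 * 50.0**2))
    spectra = [
        Spectrum(0.05 + e * band + rng.normal(0, noise_sd, len(grid)), t)
        for e, t in zip(env, temps)
    ]
    run = TgaFtirRun(grid=grid, temperatures=temps, spectra=spectra)
    run.metadata["tg_table"] = {
        "temperature": [0.0, 1100.0],
        "tg": [100.0, 80.0],
    }
    return run


class TestPreprocessRun:
    def test_spectrum_count_in_window(self):
        run = _raw_fixture_run()
        out = preprocess_run(run)
        assert 240 <= out.n_spectra <= 260  # ~250 spectra per run in 150-750 degC
        assert out.temperatures[0] >= 150.0 and out.temperatures[-1] <= 750.0
        assert out.gram_schmidt is not None and out.dtg is not None

    def test_no_spectra_in_window_errors(self, small_grid):
        run = toy_run(small_grid, [50.0, 60.0], [np.zeros(5)] * 2)
        with pytest.raises(ValidationError):
            preprocess_run(run)

    def test_idempotence(self):
        # noise-free so the second baseline fit is a true no-op; with noise the
        # re-fit is bounded by the noise floor instead
        run = _raw_fixture_run(n_spectra=60, noise_sd=0.0)
        once = preprocess_run(run)
        twice = preprocess_run(once)
        np.testing.assert_allclose(twice.temperatures, once.temperatures, atol=1e-9)
        np.testing.assert_allclose(twice.tg, once.tg, atol=1e-9)
        assert twice.n_spectra == once.n_spectra
        # only the baseline re-fit may touch the spectra, and it is a near no-op
        assert np.abs(twice.spectra_matrix() - once.spectra_matrix()).max() < 1e-3

    def test_masked_windows_inert(self):
        """Perturbing data only inside the excluded windows changes nothing."""
        run = _raw_fixture_run(n_spectra=60)
        out1 = preprocess_run(run)

        tampered = run.copy()
        poke = (tampered.grid.values >= 2200) & (tampered.grid.values <= 2400)
        poke |= (tampered.grid.values >= 3150) & (tampered.grid.values <= 3500)
        for s in tampered.spectra:
            s.absorbance[poke] += 123.0
        out2 = preprocess_run(tampered)

        usable = out1.spectra[0].mask
        m1, m2 = out1.spectra_matrix(), out2.spectra_matrix()
        np.testing.assert_array_equal(m1[:, usable], m2[:, usable])
        np.testing.assert_array_equal(out1.gram_schmidt, out2.gram_schmidt)


class TestConfig:
    def test_sg_window_validation(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(sg_window=3, sg_order=5)

    def test_interval_validation(self):
        with pytest.raises(ValidationError):
            PreprocessConfig(analysis_range=(4000.0, 800.0))
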