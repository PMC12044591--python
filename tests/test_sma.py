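import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyroplast.core_model import (
    LibraryEntry,
    SpectralLibrary,
    Spectrum,
    ValidationError,
    WavenumberGrid,
)
from pyroplast.preprocess import snv, snv_vector
from pyroplast.sma import (
    LibraryMatcher,
    TemperaturePenalty,
    hit_quality,
    match_run,
    match_spectrum,
    pearson,
)


class TestPearson:
    def test_identity(self):
        a = np.array([1.0, 2.0, 4.0, 3.0])
        assert pearson(a, a) == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = np.array([1.0, 2.0, 4.0])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0, 9.0]
        # brute-force product-moment formula
        a_, b_ = np.asarray(a), np.asarray(b)
        da, db = a_ - a_.mean(), b_ - b_.mean()
        expected = (da @ db) / math.sqrt((da @ da) * (db @ db))
        assert pearson(a, b) == pytest.approx(expected, abs=1e-12)
        assert pearson(a, b) == pytest.approx(0.9799, abs=1e-4)

    def test_constant_errors(self):
        with pytest.raises(ValidationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_mask_respected(self):
        a = np.array([1.0, 2.0, 3.0, 100.0])
        b = np.array([1.0, 2.0, 3.0, -50.0])
        mask = np.array([True, True, True, False])
        assert pearson(a, b, mask) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100), shift=st.floats(-10, 10))
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(5)
        a, b = rng.random(12), rng.random(12)
        assert pearson(scale * a + shift, b) == pytest.approx(pearson(a, b), abs=1e-9)


@pytest.fixture(scope="module")
def band_grid():
    return WavenumberGrid(np.arange(800.0, 4000.0, 8.0))


def _band_spectrum(grid, centers, widths, heights, temperature, snv_norm=True):
    x = grid.values
    y = np.zeros(len(grid))
    for c, w, h in zip(centers, widths, heights):
        y += h * np.exp(-((x - c) ** 2) / (2 * w**2))
    s = Spectrum(y, temperature)
    return snv(s) if snv_norm else s


class TestHitQuality:
    def test_identical_equal_temperature(self, band_grid):
        s = _band_spectrum(band_grid, [1600], [40], [1.0], 400.0)
        score = hit_quality(s, s, band_grid)
        assert score.r_final == pytest.approx(1.0)
        assert score.r_comb == pytest.approx(1.0)

    def test_identical_at_one_sigma(self, band_grid):
        s = _band_spectrum(band_grid, [1600], [40], [1.0], 400.0)
        ref = Spectrum(s.absorbance.copy(), 450.0)
        score = hit_quality(s, ref, band_grid, TemperaturePenalty("gaussian", 50.0))
        assert score.r_final == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_shared_band_pair_derivative_sharper(self, band_grid):
        # two materials sharing a strong CH-like band but differing elsewhere
        a = _band_spectrum(band_grid, [2915, 1460], [55, 28], [1.0, 0.25], 400.0)
        b = _band_spectrum(band_grid, [2940, 1376], [55, 26], [1.0, 0.25], 400.0)
        score = hit_quality(a, b, band_grid)
        assert score.r0 > 0.6
        assert score.r1 < score.r0

    def test_linear_penalty_form(self, band_grid):
        s = _band_spectrum(band_grid, [1600], [40], [1.0], 400.0)
        ref = Spectrum(s.absorbance.copy(), 420.0)
        score = hit_quality(s, ref, band_grid, TemperaturePenalty("linear", 0.01))
        assert score.r_final == pytest.approx(1.0 - 0.01 * 20.0, abs=1e-9)

    def test_penalty_monotone_in_dt(self, band_grid):
        s = _band_spectrum(band_grid, [1600], [40], [1.0], 400.0)
        last = 2.0
        for dt in (0.0, 10.0, 25.0, 60.0, 120.0):
            ref = Spectrum(s.absorbance.copy(), 400.0 + dt)
            r = hit_quality(s, ref, band_grid).r_final
            assert r < last or dt == 0.0
            last = r

    def test_r_final_never_exceeds_r_comb(self, band_grid):
        s = _band_spectrum(band_grid, [1600], [40], [1.0], 400.0)
        ref = Spectrum(s.absorbance.copy(), 500.0)
        score = hit_quality(s, ref, band_grid)
        assert score.r_final <= score.r_comb


def _two_class_library(band_grid):
    """Two near-orthogonal band classes A=PE-like, B=PS-like."""
    entries = []
    for cls, centers in (("PE", [2915, 1460]), ("PS", [1601, 842])):
        rows = []
        for k, t in enumerate((395.0, 400.0, 405.0)):
            rows.append(
                _band_spectrum(band_grid, centers, [40, 25], [1.0, 0.4], t, snv_norm=False)
            )
        entries.append(
            LibraryEntry(cls, f"{cls.lower()}-1", ((380.0, 420.0),), rows)
        )
    return SpectralLibrary(entries=entries, grid=band_grid)


class TestMatchSpectrum:
    def test_exact_library_spectrum(self, band_grid):
        lib = _two_class_library(band_grid)
        target = lib.entries[0].spectra[1]
        result = match_spectrum(snv(target), lib)
        assert result.label_set == {"PE"}
        assert result.labels[0][1].r_final == pytest.approx(1.0, abs=1e-9)
        assert result.iterations[0]["residual_norm"] < 1e-6

    def test_two_component_mixture_recovered(self, band_grid):
        lib = _two_class_library(band_grid)
        a = lib.entries[0].spectra[1].absorbance
        b = lib.entries[1].spectra[1].absorbance
        mixed = Spectrum(0.6 * a + 0.4 * b, 400.0)
        result = match_spectrum(snv(mixed), lib, max_components=4)
        assert result.label_set == {"PE", "PS"}
        assert len(result.iterations) == 2

    def test_white_noise_matches_nothing(self, band_grid):
        lib = _two_class_library(band_grid)
        matcher = LibraryMatcher(lib)
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(100):
            noise = Spectrum(rng.normal(0, 1, len(band_grid)), 400.0)
            hits += bool(match_spectrum(snv(noise), matcher).label_set)
        assert hits == 0

    def test_empty_library_errors(self, band_grid):
        lib = SpectralLibrary(entries=[], grid=band_grid)
        with pytest.raises(ValidationError):
            match_spectrum(
                _band_spectrum(band_grid, [1600], [40], [1.0], 400.0), lib
            )

    def test_scale_invariance(self, band_grid):
        lib = _two_class_library(band_grid)
        a = lib.entries[0].spectra[1].absorbance
        b = lib.entries[1].spectra[1].absorbance
        for factor in (0.2, 1.0, 37.5):
            mixed = Spectrum(factor * (0.6 * a + 0.4 * b), 400.0)
            result = match_spectrum(snv(mixed), lib)
            assert result.label_set == {"PE", "PS"}

    def test_residual_norm_strictly_decreases(self, band_grid):
        lib = _two_class_library(band_grid)
        a = lib.entries[0].spectra[1].absorbance
        b = lib.entries[1].spectra[1].absorbance
        mixed = snv(Spectrum(0.6 * a + 0.4 * b, 400.0))
        result = match_spectrum(mixed, lib)
        start = float(np.linalg.norm(snv_vector(mixed.absorbance, mixed.mask)))
        norms = [start] + [it["residual_norm"] for it in result.iterations]
        assert all(n2 < n1 for n1, n2 in zip(norms, norms[1:]))

    def test_terminates_within_max_components(self, band_grid):
        lib = _two_class_library(band_grid)
        a = lib.entries[0].spectra[1].absorbance
        mixed = Spectrum(a + 0.1, 400.0)
        result = match_spectrum(snv(mixed), lib, threshold=0.0, max_components=4)
        assert len(result.iterations) <= 4


class TestMatchRun:
    def test_single_polymer_run(self, lib, runs_by_class):
        result = match_run(runs_by_class["PET"][0], lib)
        assert result.run_labels == {"PET"}

    def test_blank_run_empty_labels(self, lib, runs_by_class):
        result = match_run(runs_by_class["BLANK"][0], lib)
        assert result.run_labels == set()

    def test_three_component_mixture(self, lib, runs_by_class):
        from pyroplast.synthetic_data import MixtureSpec, make_mixture

        spec = MixtureSpec(
            components=(("PMMA", "PMMA-0"), ("PET", "PET-0"), ("PTFE", "PTFE-0")),
            fractions=(0.4, 0.35, 0.25),
            rng_seed=3,
        )
        mix = make_mixture(
            spec,
            {c: runs_by_class[c][0] for c in ("PMMA", "PET", "PTFE")},
        )
        result = match_run(mix, lib)
        assert result.run_labels == {"PMMA", "PET", "PTFE"}

    def test_library_self_match_rank_one(self, lib):
        """Every library spectrum matches its own class with r_final = 1 at rank 1."""
        matcher = LibraryMatcher(lib)
        checked = 0
        for entry in lib.entries:
            if entry.polymer_class == "BLANK":
                continue
            for s in entry.spectra[:3]:  # subsample per entry for speed
                try:
                    z = snv(s)
                except ValidationError:
                    continue
                scores = matcher.score(z.absorbance, z.mask, z.temperature)
                best = matcher.best_index(scores[:, 2], z.temperature)
                assert matcher.ref_classes[best] == entry.polymer_class
                assert scores[best, 2] == pytest.approx(1.0, abs=1e-9)
                checked += 1
        assert checked > 20

    def test_class_trace_shape(self, lib, runs_by_class):
        run = runs_by_class["PS"][0]
        result = match_run(run, lib)
        trace = result.class_trace()
        assert trace.shape == (run.n_spectra, len(result.classes))
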