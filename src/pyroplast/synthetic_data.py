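"""Synthetic data: parametric pseudo-polymer fixtures and mixture thermograms.

Two generators live here.  :func:`make_fixture_library` builds a fully
self-contained library of parametric pseudo-polymers — each defined by a set
of infrared bands and sigmoidal decomposition steps — so that every part of
the toolchain can be exercised without any measured data.  The default twelve
archetypes loosely mirror the band/decomposition structure of the common
polymer classes (e.g. the PE- and PP-like archetypes share strong CH-stretch
bands and are deliberately confusable on raw spectra).

:func:`make_mixture` / :func:`make_mixture_dataset` compose evaluation
thermograms by fraction-weighted summation of single-material runs: spectra
and TG curves add linearly, the overall absorbance scale is randomised per
mixture, and the generating components are recorded in the manifest as ground
truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_model import (
    ANALYSIS_RANGE,
    TEMP_WINDOW,
    LibraryEntry,
    SpectralLibrary,
    Spectrum,
    TgaFtirRun,
    ValidationError,
    WavenumberGrid,
)
from .preprocess import PreprocessConfig, gram_schmidt_trace, _smooth_dtg

__all__ = [
    "PolymerArchetype",
    "MixtureSpec",
    "default_archetypes",
    "make_fixture_run",
    "make_fixture_library",
    "make_mixture",
    "make_mixture_dataset",
    "write_manifest",
]


@dataclass(frozen=True)
class PolymerArchetype:
    """Parametric pseudo-polymer used to generate fixture runs.

    ``bands``: (center cm^-1, width cm^-1, relative intensity) Gaussians.
    ``dtg_peaks``: (T_max degC, width degC, mass-loss share) decomposition
    steps; shares plus ``residual_mass`` must sum to 1.
    """

    label: str
    bands: tuple[tuple[float, float, float], ...]
    dtg_peaks: tuple[tuple[float, float, float], ...]
    residual_mass: float = 0.0

    def __post_init__(self) -> None:
        total = sum(share for *_ignored, share in self.dtg_peaks) + self.residual_mass
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.label}: mass-loss shares + residual must sum to 1, got {total}"
            )
        lo, hi = ANALYSIS_RANGE
        for center, _w, _i in self.bands:
            if not (lo <= center <= hi):
                raise ValidationError(f"{self.label}: band center {center} outside analysis range")
            for mlo, mhi in ((2200.0, 2400.0), (3150.0, 3500.0)):
                if mlo <= center <= mhi:
                    raise ValidationError(
                        f"{self.label}: band center {center} inside masked window"
                    )
        tlo, thi = TEMP_WINDOW
        for tmax, _w, _s in self.dtg_peaks:
            if not (tlo <= tmax <= thi):
                raise ValidationError(f"{self.label}: DTG peak {tmax} outside temperature window")


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for one synthetic mixture thermogram."""

    components: tuple[tuple[str, str], ...]  # (class label, source run id)
    fractions: tuple[float, ...]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        classes = [c for c, _ in self.components]
        if len(set(classes)) != len(classes):
            raise ValidationError("mixture component classes must be distinct")
        if len(self.fractions) != len(self.components):
            raise ValidationError("one fraction per component required")
        if any(f < 0 for f in self.fractions):
            raise ValidationError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


def default_archetypes() -> tuple[PolymerArchetype, ...]:
    """Twelve archetypes mimicking the class structure of common polymers.

    Decomposition temperatures are spread through the analysis window, the
    PE/PP pair shares dominant CH-stretch bands (confusable raw spectra), and
    the PMMA- and PVC-like archetypes decompose in two steps (multi-ROI).
    """
    return (
        PolymerArchetype("PE", bands=((2915, 55, 1.0), (2850, 40, 0.75), (1462, 28, 0.22), (908, 22, 0.12)),
                         dtg_peaks=((468, 26, 0.97),), residual_mass=0.03),
        PolymerArchetype("PP", bands=((2948, 52, 1.0), (2918, 45, 0.85), (2852, 40, 0.50), (1455, 28, 0.26), (1376, 24, 0.22), (886, 20, 0.16)),
                         dtg_peaks=((444, 25, 0.96),), residual_mass=0.04),
        PolymerArchetype("PS", bands=((3028, 38, 0.65), (2922, 48, 0.70), (1601, 24, 0.55), (1494, 24, 0.45), (842, 24, 1.0)),
                         dtg_peaks=((418, 24, 0.95),), residual_mass=0.05),
        PolymerArchetype("PET", bands=((1762, 28, 1.0), (1263, 32, 0.55), (1098, 36, 0.45), (871, 24, 0.35)),
                         dtg_peaks=((432, 24, 0.80),), residual_mass=0.20),
        PolymerArchetype("PA", bands=((3082, 38, 0.40), (2932, 40, 0.50), (1642, 28, 1.0), (1552, 28, 0.60)),
                         dtg_peaks=((456, 28, 0.92),), residual_mass=0.08),
        PolymerArchetype("PVC", bands=((2898, 55, 0.80), (1259, 28, 0.45), (962, 28, 0.90)),
                         dtg_peaks=((328, 24, 0.60), (472, 30, 0.30)), residual_mass=0.10),
        PolymerArchetype("PUR", bands=((2122, 38, 0.55), (1731, 28, 0.85), (1521, 28, 0.50), (1222, 28, 0.40)),
                         dtg_peaks=((392, 27, 0.85),), residual_mass=0.15),
        PolymerArchetype("PMMA", bands=((1742, 28, 1.0), (1152, 32, 0.70), (2953, 42, 0.50), (988, 24, 0.30)),
                         dtg_peaks=((290, 22, 0.25), (382, 24, 0.72)), residual_mass=0.03),
        PolymerArchetype("PTFE", bands=((1204, 36, 1.0), (1148, 32, 0.85), (982, 28, 0.40)),
                         dtg_peaks=((590, 24, 0.99),), residual_mass=0.01),
        PolymerArchetype("PC", bands=((1772, 28, 0.90), (1232, 32, 0.70), (2968, 38, 0.40), (1012, 24, 0.50), (829, 24, 0.55)),
                         dtg_peaks=((521, 28, 0.75),), residual_mass=0.25),
        PolymerArchetype("CEL", bands=((1059, 42, 1.0), (2901, 48, 0.40), (1728, 28, 0.45), (1161, 28, 0.55)),
                         dtg_peaks=((345, 26, 0.80),), residual_mass=0.20),
        PolymerArchetype("BLANK", bands=(), dtg_peaks=(), residual_mass=1.0),
    )


def _logistic_step(t: np.ndarray, center: float, width: float) -> np.ndarray:
    # 0 -> 1 transition; `width` is roughly the half-width of the DTG bump
    return 1.0 / (1.0 + np.exp(-(t - center) / (width / 2.5)))


def _band_profile(grid: WavenumberGrid, bands) -> np.ndarray:
    profile = np.zeros(len(grid))
    x = grid.values
    for center, width, intensity in bands:
        profile += intensity * np.exp(-((x - center) ** 2) / (2.0 * width**2))
    return profile


def make_fixture_run(
    archetype: PolymerArchetype,
    grid: WavenumberGrid,
    n_spectra: int = 120,
    noise_sd: float = 0.004,
    seed: int = 0,
    sample_id: str | None = None,
    peak_shift: float = 0.0,
) -> TgaFtirRun:
    """Generate one single-material run inside the analysis temperature window.

    The TG curve is a sum of sigmoidal loss steps; each spectrum is the
    archetype's band profile amplitude-modulated by the DTG envelope, plus
    white noise.  ``peak_shift`` rigidly shifts all decomposition peaks
    (used to emulate sample-to-sample variability).
    """
    rng = np.random.default_rng(seed)
    tlo, thi = TEMP_WINDOW
    temps = np.linspace(tlo + 2.0, thi - 2.0, n_spectra)
    tg = np.full(n_spectra, 100.0)
    envelope = np.zeros(n_spectra)
    for tmax, width, share in archetype.dtg_peaks:
        step = _logistic_step(temps, tmax + peak_shift, width)
        tg -= 100.0 * share * step
        envelope += share * np.gradient(step, temps)
    profile = _band_profile(grid, archetype.bands)
    env_max = envelope.max() if envelope.max() > 0 else 1.0
    spectra = []
    for i in range(n_spectra):
        amplitude = envelope[i] / env_max
        absorbance = amplitude * profile + rng.normal(0.0, noise_sd, len(grid))
        spectra.append(Spectrum(absorbance, temps[i]))
    run = TgaFtirRun(
        grid=grid,
        temperatures=temps,
        spectra=spectra,
        tg=tg,
        metadata={
            "sample_id": sample_id or f"{archetype.label}-s{seed}",
            "classes": [] if archetype.label == "BLANK" else [archetype.label],
            "heating_rate": 10.0,
            "dwell_time_s": 2.5,
            "preprocessed": True,
            "temperature_offset_applied": 0.0,
        },
    )
    cfg = PreprocessConfig()
    run.dtg = _smooth_dtg(tg, temps, cfg)
    run.gram_schmidt = gram_schmidt_trace(run)
    return run


def _roi_intervals(archetype: PolymerArchetype, peak_shift: float = 0.0) -> tuple[tuple[float, float], ...]:
    tlo, thi = TEMP_WINDOW
    if not archetype.dtg_peaks:
        return ((tlo, thi),)
    return tuple(
        (max(tlo, tmax + peak_shift - 1.5 * width), min(thi, tmax + peak_shift + 1.5 * width))
        for tmax, width, _share in archetype.dtg_peaks
    )


def make_fixture_library(
    archetypes=None,
    grid_step: float = 8.0,
    n_spectra: int = 120,
    runs_per_archetype: int = 2,
    noise_sd: float = 0.004,
    seed: int = 0,
    include_background_entries: bool = True,
) -> tuple[SpectralLibrary, dict[str, list[TgaFtirRun]]]:
    """Build a library plus the single-material runs it was cut from.

    Returns ``(library, runs_by_class)``.  Each archetype contributes
    ``runs_per_archetype`` runs (with slight decomposition-temperature
    jitter between runs); library entries hold the ROI spectra of each run.
    With ``include_background_entries`` the quiet out-of-ROI spectra of every
    run are added as BLANK-labelled entries so classifiers see true negatives.
    """
    archetypes = tuple(archetypes) if archetypes is not None else default_archetypes()
    if len(archetypes) < 2:
        raise ValidationError("need at least 2 archetypes")
    seen: set[str] = set()
    for a in archetypes:
        if a.label in seen:
            warnings.warn(f"duplicate archetype label {a.label!r}")
        seen.add(a.label)
    lo, hi = ANALYSIS_RANGE
    grid = WavenumberGrid(np.arange(lo, hi + grid_step / 2, grid_step))
    rng = np.random.default_rng(seed)

    entries: list[LibraryEntry] = []
    runs_by_class: dict[str, list[TgaFtirRun]] = {}
    for a in archetypes:
        runs_by_class[a.label] = []
        for rep in range(runs_per_archetype):
            shift = float(rng.uniform(-4.0, 4.0)) if rep > 0 else 0.0
            sample_id = f"{a.label}-{rep}"
            run = make_fixture_run(
                a, grid, n_spectra=n_spectra, noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31)), sample_id=sample_id,
                peak_shift=shift,
            )
            runs_by_class[a.label].append(run)
            roi = _roi_intervals(a, shift)
            in_roi = [
                s.copy() for s in run.spectra
                if any(rlo <= s.temperature <= rhi for rlo, rhi in roi)
            ]
            entries.append(
                LibraryEntry(polymer_class=a.label, sample_id=sample_id,
                             roi=roi, spectra=in_roi)
            )
            if include_background_entries and a.label != "BLANK":
                quiet = _quiet_intervals(run, roi)
                bg = [
                    s.copy() for s in run.spectra
                    if any(qlo <= s.temperature <= qhi for qlo, qhi in quiet)
                ]
                if bg:
                    entries.append(
                        LibraryEntry(polymer_class="BLANK", sample_id=f"{sample_id}-bg",
                                     roi=quiet, spectra=bg)
                    )
    lib = SpectralLibrary(
        entries=entries, grid=grid,
        provenance=f"fixture library: {len(archetypes)} archetypes, seed {seed}",
    )
    return lib, runs_by_class


def _quiet_intervals(run: TgaFtirRun, roi, margin: float = 30.0):
    """Temperature intervals well clear of every ROI (background spectra)."""
    tlo, thi = float(run.temperatures[0]), float(run.temperatures[-1])
    edges = sorted((max(tlo, rlo - margin), min(thi, rhi + margin)) for rlo, rhi in roi)
    quiet, cursor = [], tlo
    for lo, hi in edges:
        if lo - cursor > 1.0:
            quiet.append((cursor, lo))
        cursor = max(cursor, hi)
    if thi - cursor > 1.0:
        quiet.append((cursor, thi))
    return tuple(quiet)


def make_mixture(
    spec: MixtureSpec,
    runs: dict[str, TgaFtirRun] | list[TgaFtirRun],
    randomize_scale: bool = True,
    temperature_shift: float = 0.0,
) -> TgaFtirRun:
    """Compose one mixture thermogram by fraction-weighted summation.

    Spectra and TG add linearly at each aligned temperature; DTG and the
    Gram-Schmidt trace are recomputed.  ``randomize_scale`` multiplies the
    spectra (only) by a global scalar drawn log-uniform in [0.5, 2] so that
    the overall infrared absorbance varies between mixtures; the TG curve is
    untouched, preserving mass conservation.  ``temperature_shift`` > 0
    enables a per-component uniform shift in [-shift, +shift] degC, emulating
    decomposition-temperature shifts seen in experimental mixtures.
    """
    if isinstance(runs, dict):
        source = [runs[cls] for cls, _rid in spec.components]
    else:
        source = list(runs)
    if len(source) != len(spec.components):
        raise ValidationError("one source run per component required")
    base = source[0]
    rng = np.random.default_rng(spec.rng_seed)
    shifts = (
        rng.uniform(-temperature_shift, temperature_shift, len(source))
        if temperature_shift > 0 else np.zeros(len(source))
    )
    for r in source[1:]:
        if not r.grid.matches(base.grid):
            raise ValidationError("component runs are not on a shared wavenumber grid")
        if r.temperatures.size != base.temperatures.size or not np.allclose(
            r.temperatures, base.temperatures, atol=1e-9
        ):
            raise ValidationError("component run temperatures are not aligned")

    n = base.n_spectra
    spectra_sum = np.zeros((n, len(base.grid)))
    tg_sum = np.zeros(n)
    mask = np.ones(len(base.grid), dtype=bool)
    for frac, run, shift in zip(spec.fractions, source, shifts):
        spectra_mat = run.spectra_matrix()
        tg = run.tg if run.tg is not None else np.full(n, 100.0)
        if shift != 0.0:
            t = base.temperatures
            spectra_mat = np.vstack(
                [np.interp(t, t + shift, spectra_mat[:, j], left=0, right=0)
                 for j in range(spectra_mat.shape[1])]
            ).T
            tg = np.interp(t, t + shift, tg)
        spectra_sum += frac * spectra_mat
        tg_sum += frac * tg
        mask &= run.spectra[0].mask

    scale = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) if randomize_scale else 1.0
    spectra = [
        Spectrum(scale * spectra_sum[i], base.temperatures[i], mask.copy())
        for i in range(n)
    ]
    run = TgaFtirRun(
        grid=base.grid,
        temperatures=base.temperatures.copy(),
        spectra=spectra,
        tg=tg_sum,
        metadata={
            "sample_id": "mix-" + "+".join(cls for cls, _ in spec.components),
            "classes": [cls for cls, _ in spec.components],
            "fractions": list(spec.fractions),
            "source_runs": [rid for _, rid in spec.components],
            "absorbance_scale": scale,
            "rng_seed": spec.rng_seed,
            "preprocessed": True,
            "temperature_offset_applied": 0.0,
        },
    )
    cfg = PreprocessConfig()
    run.dtg = _smooth_dtg(tg_sum, base.temperatures, cfg)
    run.gram_schmidt = gram_schmidt_trace(run)
    return run


def make_mixture_dataset(
    runs_by_class: dict[str, list[TgaFtirRun]],
    n: int = 1028,
    k_range: tuple[int, int] = (2, 4),
    seed: int = 0,
    randomize_scale: bool = True,
    temperature_shift: float = 0.0,
) -> tuple[list[TgaFtirRun], list[dict]]:
    """Generate ``n`` mixture thermograms with 2-4 distinct components each.

    Component classes are sampled uniformly without replacement (BLANK is
    never a component), a source run of each class is chosen at random, and
    fractions are drawn from a flat Dirichlet.  Returns ``(runs, manifest)``;
    each manifest record stores the generating classes, fractions and seed —
    the ground truth for evaluation.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    classes = [c for c, rs in runs_by_class.items() if c != "BLANK" and rs]
    if len(classes) < max(2, k_range[0]):
        raise ValidationError("need at least 2 non-blank source classes")
    if len({c: len(rs) for c, rs in runs_by_class.items() if rs}) < 1 or len(classes) < 5:
        warnings.warn("fewer than 5 distinct source classes; combination diversity is low")
    rng = np.random.default_rng(seed)
    runs_out: list[TgaFtirRun] = []
    manifest: list[dict] = []
    for i in range(n):
        k = int(rng.integers(k_range[0], min(k_range[1], len(classes)) + 1))
        chosen = list(rng.choice(classes, size=k, replace=False))
        fractions = rng.dirichlet(np.ones(k))
        sources = {}
        components = []
        for cls in chosen:
            pool = runs_by_class[cls]
            run = pool[int(rng.integers(0, len(pool)))]
            sources[cls] = run
            components.append((cls, str(run.metadata.get("sample_id", cls))))
        spec = MixtureSpec(
            components=tuple(components),
            fractions=tuple(fractions / fractions.sum()),
            rng_seed=int(rng.integers(0, 2**31)),
        )
        mixture = make_mixture(
            spec, sources, randomize_scale=randomize_scale,
            temperature_shift=temperature_shift,
        )
        mixture.metadata["sample_id"] = f"mix-{i:05d}"
        runs_out.append(mixture)
        manifest.append(
            {
                "sample_id": f"mix-{i:05d}",
                "components": [cls for cls, _ in spec.components],
                "fractions": list(spec.fractions),
                "source_runs": [rid for _, rid in spec.components],
                "seed": spec.rng_seed,
            }
        )
    return runs_out, manifest


def write_manifest(manifest: list[dict], path) -> Path:
    """Write a mixture manifest as JSON lines (one record per thermogram)."""
    path = Path(path)
    with open(path, "w") as fh:
        for record in manifest:
            fh.write(json.dumps(record) + "\n")
    return path
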