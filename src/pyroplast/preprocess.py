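"""Raw-run preprocessing: masking, cropping, baseline, SNV, TG alignment.

The fixed pipeline order in :func:`preprocess_run` is

    mask -> crop to analysis wavenumber range -> temperature offset ->
    crop to temperature window -> baseline correction -> TG alignment ->
    Gram-Schmidt trace.

SNV normalisation is deliberately *not* part of the pipeline; matching and
training stages apply it themselves so that raw absorbance magnitudes remain
available for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._baselines import aspls
from .core_model import (
    ANALYSIS_RANGE,
    DEFAULT_MASK_WINDOWS,
    TEMP_WINDOW,
    Spectrum,
    TgaFtirRun,
    ValidationError,
    WavenumberGrid,
    fill_masked,
)

__all__ = [
    "PreprocessConfig",
    "baseline_correct",
    "snv",
    "snv_vector",
    "apply_temperature_offset",
    "align_tg_to_spectra",
    "gram_schmidt_trace",
    "preprocess_run",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage parameters; defaults follow a 10 degC/min heating programme with
    a ~2.5 s transfer-line dwell."""

    baseline_lambda: float = 1e6
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-3
    sg_window: int = 11
    sg_order: int = 2
    mask_windows: tuple[tuple[float, float], ...] = DEFAULT_MASK_WINDOWS
    analysis_range: tuple[float, float] = ANALYSIS_RANGE
    temp_window: tuple[float, float] = TEMP_WINDOW
    dwell_time_s: float = 2.5
    heating_rate: float = 10.0

    def __post_init__(self) -> None:
        if self.sg_window <= self.sg_order:
            raise ValidationError("sg_window must exceed sg_order")
        if self.sg_window % 2 == 0:
            raise ValidationError("sg_window must be odd")
        for lo, hi in (*self.mask_windows, self.analysis_range, self.temp_window):
            if hi <= lo:
                raise ValidationError(f"interval ({lo}, {hi}) is not well-ordered")

    @property
    def temperature_offset(self) -> float:
        """Transfer-line lag in degC: dwell time x heating rate."""
        return self.dwell_time_s * self.heating_rate / 60.0


def baseline_correct(
    s: Spectrum, grid: WavenumberGrid, cfg: PreprocessConfig | None = None
) -> Spectrum:
    """Subtract an asPLS baseline fitted without using masked-out data."""
    cfg = cfg or PreprocessConfig()
    if int(s.mask.sum()) < 10:
        raise ValidationError("baseline correction needs >= 10 unmasked points")
    filled = fill_masked(s.absorbance, s.mask, grid)
    baseline = aspls(
        filled,
        lam=cfg.baseline_lambda,
        max_iter=cfg.baseline_max_iter,
        tol=cfg.baseline_tol,
    )
    return Spectrum(s.absorbance - baseline, s.temperature, s.mask.copy())


def snv_vector(x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Standard normal variate using mean/population-SD of unmasked points."""
    x = np.asarray(x, dtype=float)
    sel = x if mask is None else x[np.asarray(mask, dtype=bool)]
    sd = sel.std()  # population (ddof=0)
    if sd <= 0 or not np.isfinite(sd):
        raise ValidationError("SNV undefined: zero variance spectrum")
    return (x - sel.mean()) / sd


def snv(s: Spectrum) -> Spectrum:
    """SNV-normalise a spectrum; statistics are taken over unmasked points only."""
    return Spectrum(snv_vector(s.absorbance, s.mask), s.temperature, s.mask.copy())


def apply_temperature_offset(run: TgaFtirRun, cfg: PreprocessConfig | None = None) -> TgaFtirRun:
    """Shift FTIR spectrum temperatures back by the transfer-line lag.

    TG temperatures are untouched: the mass reading is instantaneous while the
    evolved gas reaches the spectrometer ``dwell_time_s`` later.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.heating_rate <= 0:
        raise ValidationError("heating_rate must be positive")
    out = run.copy()
    if out.metadata.get("temperature_offset_applied"):
        return out
    offset = cfg.temperature_offset
    out.temperatures = out.temperatures - offset
    for s in out.spectra:
        s.temperature -= offset
    out.metadata["temperature_offset_applied"] = offset
    return out


def _smooth_dtg(tg: np.ndarray, temps: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    # positive mass-loss rate, -dTG/dT, central differences then SG smoothing
    if tg.size < 2:
        return np.zeros_like(tg)
    raw = -np.gradient(tg, temps)
    window = min(cfg.sg_window, raw.size if raw.size % 2 else raw.size - 1)
    if window <= cfg.sg_order:
        return raw
    return savgol_filter(raw, window, cfg.sg_order)


def align_tg_to_spectra(run: TgaFtirRun, cfg: PreprocessConfig | None = None) -> TgaFtirRun:
    """Interpolate TG onto spectrum temperatures and recompute smoothed DTG."""
    cfg = cfg or PreprocessConfig()
    out = run.copy()
    table = out.metadata.get("tg_table")
    if table is not None:
        t_raw = np.asarray(table["temperature"], dtype=float)
        v_raw = np.asarray(table["tg"], dtype=float)
    elif out.tg is not None:
        t_raw, v_raw = out.temperatures, out.tg
    else:
        raise ValidationError("run has no TG data to align")
    lo, hi = out.temperatures[0], out.temperatures[-1]
    if t_raw[0] > lo or t_raw[-1] < hi:
        raise ValidationError(
            f"TG table covers [{t_raw[0]:g}, {t_raw[-1]:g}] degC but spectra "
            f"need [{lo:g}, {hi:g}] degC"
        )
    out.tg = np.interp(out.temperatures, t_raw, v_raw)
    out.dtg = _smooth_dtg(out.tg, out.temperatures, cfg)
    return out


def gram_schmidt_trace(run: TgaFtirRun) -> np.ndarray:
    """Integrated-absorbance surrogate: root-sum-square of unmasked points.

    With blank-corrected spectra this tracks the classical Gram-Schmidt
    reconstruction (orthogonalisation against pre-run background vectors)
    because the background component is already removed.
    """
    return np.array(
        [float(np.sqrt(np.sum(s.absorbance[s.mask] ** 2))) for s in run.spectra]
    )


def _crop_wavenumbers(run: TgaFtirRun, lo: float, hi: float) -> TgaFtirRun:
    idx = run.grid.range_indices(lo, hi)
    if idx.size < 2:
        raise ValidationError(f"no grid points inside [{lo}, {hi}] cm^-1")
    grid = WavenumberGrid(run.grid.values[idx])
    spectra = [
        Spectrum(s.absorbance[idx], s.temperature, s.mask[idx]) for s in run.spectra
    ]
    return TgaFtirRun(
        grid=grid,
        temperatures=run.temperatures.copy(),
        spectra=spectra,
        tg=None if run.tg is None else run.tg.copy(),
        dtg=None if run.dtg is None else run.dtg.copy(),
        gram_schmidt=None,
        metadata=dict(run.metadata),
    )


def _crop_temperatures(run: TgaFtirRun, lo: float, hi: float) -> TgaFtirRun:
    keep = (run.temperatures >= lo) & (run.temperatures <= hi)
    if not keep.any():
        raise ValidationError(f"no spectra inside temperature window [{lo}, {hi}] degC")
    idx = np.nonzero(keep)[0]
    return TgaFtirRun(
        grid=run.grid,
        temperatures=run.temperatures[idx],
        spectra=[run.spectra[i].copy() for i in idx],
        tg=None if run.tg is None else run.tg[idx],
        dtg=None if run.dtg is None else run.dtg[idx],
        gram_schmidt=None,
        metadata=dict(run.metadata),
    )


def preprocess_run(run: TgaFtirRun, cfg: PreprocessConfig | None = None) -> TgaFtirRun:
    """Full preprocessing pipeline; returns a new analysis-ready run.

    Idempotent up to the baseline re-fit: the temperature offset is recorded
    in metadata and never applied twice, and cropping an already-cropped run
    is a no-op.
    """
    cfg = cfg or PreprocessConfig()
    out = run.copy()
    window_mask = out.grid.window_mask(cfg.mask_windows)
    for s in out.spectra:
        s.mask &= window_mask
    out = _crop_wavenumbers(out, *cfg.analysis_range)
    out = apply_temperature_offset(out, cfg)
    out = _crop_temperatures(out, *cfg.temp_window)
    out.spectra = [baseline_correct(s, out.grid, cfg) for s in out.spectra]
    if out.tg is not None or out.metadata.get("tg_table") is not None:
        out = align_tg_to_spectra(out, cfg)
    out.gram_schmidt = gram_schmidt_trace(out)
    out.metadata["preprocessed"] = True
    return out
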