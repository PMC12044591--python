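"""Temperature-penalized spectral matching with iterative residual re-matching.

Hit quality against a reference spectrum combines the Pearson correlation of
the SNV spectra (r0) with that of their first derivatives (r1) — the
derivative term sharpens discrimination between materials whose raw spectra
are nearly collinear — and is then reduced by a single-point penalty on the
temperature difference between the data spectrum and the reference spectrum:

    r_comb  = (r0 + r1) / 2
    r_final = r_comb * exp(-(T_data - T_lib)^2 / (2 sigma^2))      (gaussian)
    r_final = max(0, r_comb - k * |T_data - T_lib|)                (linear)

Matches above the acceptance threshold trigger a least-squares-scaled
subtraction of the matched reference and re-matching of the residual, so a
single mixed spectrum can yield several labels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core_model import (
    Spectrum,
    SpectralLibrary,
    TgaFtirRun,
    ValidationError,
    fill_masked,
)
from .preprocess import snv_vector

__all__ = [
    "TemperaturePenalty",
    "MatchScore",
    "SpectrumMatch",
    "SmaResult",
    "pearson",
    "hit_quality",
    "LibraryMatcher",
    "match_spectrum",
    "match_run",
]

DEFAULT_THRESHOLD = 0.7
DEFAULT_MAX_COMPONENTS = 4


@dataclass(frozen=True)
class TemperaturePenalty:
    """Penalty on |T_data - T_lib|; ``kind`` is 'gaussian' or 'linear'.

    ``scale`` is sigma (degC) for the gaussian form and the slope k
    (r units per degC) for the linear form.
    """

    kind: str = "gaussian"
    scale: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "linear"):
            raise ValidationError(f"unknown penalty kind {self.kind!r}")
        if self.scale <= 0:
            raise ValidationError("penalty scale must be positive")

    def apply(self, r_comb: float, dt: float) -> float:
        # Negative combined scores are already non-matches; penalising them
        # further (i.e. making them *less* negative) would be a boost, so
        # they pass through untouched.
        if r_comb <= 0:
            return r_comb
        if self.kind == "gaussian":
            return r_comb * math.exp(-(dt * dt) / (2.0 * self.scale * self.scale))
        return max(0.0, r_comb - self.scale * abs(dt))

    @classmethod
    def parse(cls, text: str) -> "TemperaturePenalty":
        """Parse 'gaussian:50' / 'linear:0.005' CLI notation."""
        kind, _, scale = text.partition(":")
        return cls(kind=kind, scale=float(scale) if scale else 50.0)


@dataclass(frozen=True)
class MatchScore:
    """Hit-quality bundle for one data spectrum vs. one reference spectrum."""

    r0: float
    r1: float
    t_data: float
    t_lib: float
    r_final: float

    @property
    def r_comb(self) -> float:
        return 0.5 * (self.r0 + self.r1)


@dataclass
class SpectrumMatch:
    """Match result for a single spectrum: accepted labels plus diagnostics."""

    temperature: float
    class_scores: dict[str, MatchScore]  # best first-pass score per class
    labels: list[tuple[str, MatchScore]] = field(default_factory=list)
    iterations: list[dict] = field(default_factory=list)

    @property
    def label_set(self) -> set[str]:
        return {cls for cls, _ in self.labels}


@dataclass
class SmaResult:
    classes: tuple[str, ...]
    temperatures: np.ndarray
    spectrum_matches: list[SpectrumMatch]
    threshold: float

    @property
    def run_labels(self) -> set[str]:
        out: set[str] = set()
        for m in self.spectrum_matches:
            out |= m.label_set
        return out

    def class_trace(self) -> np.ndarray:
        """Per-spectrum, per-class best first-pass r_final (n_spectra x n_classes)."""
        trace = np.full((len(self.spectrum_matches), len(self.classes)), np.nan)
        for i, m in enumerate(self.spectrum_matches):
            for j, cls in enumerate(self.classes):
                score = m.class_scores.get(cls)
                if score is not None:
                    trace[i, j] = score.r_final
        return trace

    def to_json(self) -> str:
        payload = {
            "threshold": self.threshold,
            "classes": list(self.classes),
            "run_labels": sorted(self.run_labels),
            "spectra": [
                {
                    "temperature": m.temperature,
                    "labels": [
                        {"class": cls, "r_final": s.r_final, "r0": s.r0, "r1": s.r1,
                         "t_lib": s.t_lib}
                        for cls, s in m.labels
                    ],
                    "scores": {cls: s.r_final for cls, s in m.class_scores.items()},
                }
                for m in self.spectrum_matches
            ],
        }
        return json.dumps(payload, indent=1)


def pearson(a, b, mask=None) -> float:
    """Product-moment correlation over unmasked points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("sequences must have equal length")
    if mask is not None:
        sel = np.asarray(mask, dtype=bool)
        a, b = a[sel], b[sel]
    if a.size < 3:
        raise ValidationError("pearson needs >= 3 unmasked points")
    da = a - a.mean()
    db = b - b.mean()
    na = np.linalg.norm(da)
    nb = np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ValidationError("pearson undefined for constant input")
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


def _sg_derivative(values: np.ndarray, mask: np.ndarray, grid, window: int = 11, order: int = 2) -> np.ndarray:
    filled = fill_masked(values, mask, grid)
    w = min(window, filled.size if filled.size % 2 else filled.size - 1)
    if w <= order:
        return np.gradient(filled)
    return savgol_filter(filled, w, order, deriv=1)


def hit_quality(
    data: Spectrum,
    ref: Spectrum,
    grid,
    penalty: TemperaturePenalty | None = None,
) -> MatchScore:
    """Score one SNV-normalised data spectrum against one reference spectrum."""
    penalty = penalty or TemperaturePenalty()
    mask = data.mask & ref.mask
    r0 = pearson(data.absorbance, ref.absorbance, mask)
    d_data = _sg_derivative(data.absorbance, data.mask, grid)
    d_ref = _sg_derivative(ref.absorbance, ref.mask, grid)
    r1 = pearson(d_data, d_ref, mask)
    r_comb = 0.5 * (r0 + r1)
    dt = data.temperature - ref.temperature
    return MatchScore(r0=r0, r1=r1, t_data=data.temperature,
                      t_lib=ref.temperature, r_final=penalty.apply(r_comb, dt))


class LibraryMatcher:
    """Vectorised scorer of data spectra against every reference spectrum.

    Reference spectra are SNV-normalised once; Pearson correlations against
    all of them reduce to one matrix product per query.  BLANK entries are
    excluded by default — the blank is represented by an empty label set, not
    by a positive match.
    """

    def __init__(
        self,
        lib: SpectralLibrary,
        penalty: TemperaturePenalty | None = None,
        include_blank: bool = False,
        sg_window: int = 11,
        sg_order: int = 2,
    ):
        self.penalty = penalty or TemperaturePenalty()
        self.grid = lib.grid
        self.sg_window = sg_window
        self.sg_order = sg_order
        mask = lib.common_mask()
        self.cols = np.nonzero(mask)[0]
        if self.cols.size < 3:
            raise ValidationError("library has fewer than 3 usable wavenumber points")

        raw_rows, deriv_rows, temps, classes = [], [], [], []
        for e in lib.entries:
            if e.polymer_class == "BLANK" and not include_blank:
                continue
            for s in e.spectra:
                try:
                    z = snv_vector(s.absorbance, s.mask)
                except ValidationError:
                    continue  # constant reference carries no information
                raw_rows.append(z[self.cols])
                deriv_rows.append(
                    _sg_derivative(z, s.mask, self.grid, sg_window, sg_order)[self.cols]
                )
                temps.append(s.temperature)
                classes.append(e.polymer_class)
        if not raw_rows:
            raise ValidationError("library has no usable (non-blank) spectra")
        self.ref_temps = np.asarray(temps)
        self.ref_classes = np.asarray(classes)
        self.classes: tuple[str, ...] = tuple(dict.fromkeys(classes))
        self._ref_raw = self._standardize(np.vstack(raw_rows))
        self._ref_deriv = self._standardize(np.vstack(deriv_rows))
        self._snv_refs = np.vstack(raw_rows)  # SNV reference rows on self.cols

    @staticmethod
    def _standardize(X: np.ndarray) -> np.ndarray:
        X = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return X / norms

    def score(self, values: np.ndarray, mask: np.ndarray, temperature: float) -> np.ndarray:
        """r_final against every reference spectrum; NaN-free."""
        v = values[self.cols]
        dv = _sg_derivative(values, mask, self.grid, self.sg_window, self.sg_order)[self.cols]
        v = v - v.mean()
        dv = dv - dv.mean()
        nv, ndv = np.linalg.norm(v), np.linalg.norm(dv)
        if nv == 0:
            raise ValidationError("pearson undefined for constant input")
        r0 = np.clip(self._ref_raw @ (v / nv), -1.0, 1.0)
        r1 = np.clip(self._ref_deriv @ (dv / ndv), -1.0, 1.0) if ndv > 0 else np.zeros_like(r0)
        r_comb = 0.5 * (r0 + r1)
        dt = temperature - self.ref_temps
        if self.penalty.kind == "gaussian":
            g = np.exp(-(dt * dt) / (2.0 * self.penalty.scale**2))
            r_final = np.where(r_comb > 0, r_comb * g, r_comb)
        else:
            r_final = np.where(
                r_comb > 0,
                np.maximum(0.0, r_comb - self.penalty.scale * np.abs(dt)),
                r_comb,
            )
        return np.column_stack([r0, r1, r_final])

    def best_index(self, r_final: np.ndarray, temperature: float) -> int:
        """Arg-max with deterministic tie-breaking: lower |dT| wins, then order."""
        best = r_final.max()
        ties = np.nonzero(r_final >= best - 1e-12)[0]
        if ties.size == 1:
            return int(ties[0])
        dt = np.abs(temperature - self.ref_temps[ties])
        return int(ties[np.argmin(dt)])  # argmin is first-of-ties -> library order


def match_spectrum(
    data: Spectrum,
    lib: SpectralLibrary | LibraryMatcher,
    threshold: float = DEFAULT_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    penalty: TemperaturePenalty | None = None,
) -> SpectrumMatch:
    """Match one spectrum, iteratively re-matching the residual.

    ``data`` must be preprocessed; it is SNV-normalised internally (Pearson is
    affine-invariant, so re-normalising the residual between iterations does
    not change any score — the residual is therefore kept on the working scale
    so that its norm strictly decreases with every accepted subtraction).
    Classes already accepted are excluded from later iterations.
    """
    matcher = lib if isinstance(lib, LibraryMatcher) else LibraryMatcher(lib, penalty)
    cols = matcher.cols
    v = snv_vector(data.absorbance, data.mask)
    result = SpectrumMatch(temperature=data.temperature, class_scores={})

    accepted: set[str] = set()
    for iteration in range(max_components):
        if np.std(v[cols]) < 1e-12:
            break
        scores = matcher.score(v, data.mask, data.temperature)
        r_final = scores[:, 2]
        if iteration == 0:
            for cls in matcher.classes:
                rows = np.nonzero(matcher.ref_classes == cls)[0]
                k = rows[int(np.argmax(r_final[rows]))]
                result.class_scores[cls] = MatchScore(
                    r0=float(scores[k, 0]), r1=float(scores[k, 1]),
                    t_data=data.temperature, t_lib=float(matcher.ref_temps[k]),
                    r_final=float(r_final[k]),
                )
        available = ~np.isin(matcher.ref_classes, list(accepted))
        if not available.any():
            break
        masked_scores = np.where(available, r_final, -np.inf)
        best = matcher.best_index(masked_scores, data.temperature)
        best_score = MatchScore(
            r0=float(scores[best, 0]), r1=float(scores[best, 1]),
            t_data=data.temperature, t_lib=float(matcher.ref_temps[best]),
            r_final=float(r_final[best]),
        )
        if best_score.r_final <= threshold:
            break
        cls = str(matcher.ref_classes[best])
        accepted.add(cls)
        result.labels.append((cls, best_score))
        # non-negative least-squares scale of the reference, then subtract
        ref = matcher._snv_refs[best]
        vc = v[cols]
        scale = max(0.0, float(vc @ ref) / float(ref @ ref))
        v = v.copy()
        v[cols] = vc - scale * ref
        result.iterations.append(
            {"class": cls, "t_lib": best_score.t_lib, "r_final": best_score.r_final,
             "scale": scale, "residual_norm": float(np.linalg.norm(v[cols]))}
        )
        if scale == 0.0:
            break
    return result


def match_run(
    run: TgaFtirRun,
    lib: SpectralLibrary | LibraryMatcher,
    threshold: float = DEFAULT_THRESHOLD,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    penalty: TemperaturePenalty | None = None,
) -> SmaResult:
    """Match every spectrum in a preprocessed run against the library."""
    matcher = lib if isinstance(lib, LibraryMatcher) else LibraryMatcher(lib, penalty)
    matches = []
    for s in run.spectra:
        try:
            matches.append(
                match_spectrum(s, matcher, threshold=threshold,
                               max_components=max_components)
            )
        except ValidationError:
            # constant spectrum (e.g. dead detector segment): no labels
            matches.append(SpectrumMatch(temperature=s.temperature, class_scores={}))
    return SmaResult(
        classes=matcher.classes,
        temperatures=run.temperatures.copy(),
        spectrum_matches=matches,
        threshold=threshold,
    )
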