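"""Semi-quantitative composition estimation from DTG mass loss.

Contiguous temperature spans with an identical positive label set become
*segments*; the DTG integral of each segment is apportioned among its
assigned classes — by multivariate curve resolution when more than one class
shares a segment — and summed per class.  Relative compositions are the
per-class losses normalised over all assigned mass loss.

The residual (char) mass of each material is deliberately NOT corrected for,
and within mixed segments the spectral contribution fraction is used directly
as a mass-fraction proxy; both simplifications are inherent to screening-level
quantification and are surfaced in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._mcr import McrConvergenceWarning, mcr_als
from .core_model import SpectralLibrary, TgaFtirRun, ValidationError, fill_masked
from .ml_pipeline import PredictionMap

__all__ = [
    "SegmentAssignment",
    "QuantReport",
    "assign_segments",
    "mcr_apportion",
    "quantify",
    "quantify_run",
    "sma_prediction_map",
]


@dataclass
class SegmentAssignment:
    """One contiguous temperature span with a constant positive-label set."""

    t_start: float
    t_stop: float
    index_start: int  # inclusive spectrum index
    index_stop: int  # inclusive
    classes: tuple[str, ...]

    @property
    def unassigned(self) -> bool:
        return len(self.classes) == 0


@dataclass
class QuantReport:
    mass_loss_by_class: dict[str, float]  # % of initial mass
    relative_composition: dict[str, float]  # % of total assigned loss
    unassigned_loss: float
    total_loss: float
    segments: list[SegmentAssignment] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mass_loss_by_class": self.mass_loss_by_class,
                "relative_composition": self.relative_composition,
                "unassigned_loss": self.unassigned_loss,
                "total_loss": self.total_loss,
                "segments": [
                    {
                        "t_start": s.t_start,
                        "t_stop": s.t_stop,
                        "classes": list(s.classes),
                    }
                    for s in self.segments
                ],
                "warnings": self.warnings,
            },
            indent=1,
        )


def assign_segments(pred: PredictionMap, run: TgaFtirRun) -> list[SegmentAssignment]:
    """Group spectra into contiguous segments of identical positive-label sets."""
    if pred.temperatures.size != run.n_spectra:
        raise ValidationError("prediction map is not aligned to the run")
    label_sets = pred.label_sets()
    segments: list[SegmentAssignment] = []
    start = 0
    for i in range(1, len(label_sets) + 1):
        if i == len(label_sets) or label_sets[i] != label_sets[start]:
            segments.append(
                SegmentAssignment(
                    t_start=float(run.temperatures[start]),
                    t_stop=float(run.temperatures[i - 1]),
                    index_start=start,
                    index_stop=i - 1,
                    classes=tuple(sorted(label_sets[start])),
                )
            )
            start = i
    return segments


def mcr_apportion(
    segment_spectra: np.ndarray,
    candidate_classes,
    lib: SpectralLibrary,
    max_iter: int = 50,
    refine_spectra: bool = False,
) -> np.ndarray:
    """Per-spectrum class contribution fractions within a mixed segment.

    ``segment_spectra`` is (n_spectra x n_grid) on the library grid.  MCR with
    non-negativity constraints is initialised from the library mean spectrum
    of each candidate class; because the candidate spectra are known, they are
    held fixed by default (equality-constrained MCR-ALS) so only the
    concentration profiles are resolved — a free spectral update can collapse
    a constant-composition segment onto a single component.
    ``refine_spectra`` enables the full alternating update.  The returned
    (n_spectra x n_classes) rows are normalised to sum to 1.  On
    non-convergence a warning is raised and an equal split returned.
    """
    candidate_classes = list(candidate_classes)
    D = np.atleast_2d(np.asarray(segment_spectra, dtype=float))
    k = len(candidate_classes)
    if k == 1:
        return np.ones((D.shape[0], 1))
    if D.shape[0] < 3:
        raise ValidationError("MCR apportionment needs >= 3 spectra in the segment")
    cols = np.nonzero(lib.common_mask())[0]
    S_init = []
    for cls in candidate_classes:
        entries = lib.entries_of(cls)
        if not entries:
            raise ValidationError(f"library has no entries for class {cls!r}")
        rows = [
            fill_masked(s.absorbance, s.mask, lib.grid)
            for e in entries
            for s in e.spectra
        ]
        S_init.append(np.maximum(np.mean(rows, axis=0), 0.0))
    S_init = np.vstack(S_init)[:, cols]
    Dm = np.maximum(D[:, cols], 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", McrConvergenceWarning)
            C, _S, _converged = mcr_als(
                Dm, S_init, max_iter=max_iter, fix_spectra=not refine_spectra
            )
    except McrConvergenceWarning:
        warnings.warn(
            "MCR-ALS failed to converge; falling back to an equal split",
            McrConvergenceWarning,
        )
        return np.full((D.shape[0], k), 1.0 / k)
    totals = C.sum(axis=1, keepdims=True)
    fractions = np.where(totals > 0, C / np.where(totals > 0, totals, 1.0), 1.0 / k)
    return fractions


def _segment_trapezoid_weights(temps: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Trapezoid quadrature weights for integrating over spectra i0..i1."""
    t = temps[i0 : i1 + 1]
    if t.size == 1:
        return np.zeros(1)
    w = np.zeros(t.size)
    dt = np.diff(t)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return w


def quantify(
    run: TgaFtirRun,
    assignments: list[SegmentAssignment],
    apportionments: dict[int, np.ndarray] | None = None,
) -> QuantReport:
    """Integrate DTG mass loss per class over assigned segments.

    ``apportionments`` maps segment index -> (n_spectra x n_classes)
    per-spectrum contribution fractions (column order = segment class order);
    segments without an entry are split entirely to their single class (or
    equally if multi-class).  Per-temperature fractions are weighted by the
    local DTG value through the trapezoid quadrature.
    """
    if run.dtg is None:
        raise ValidationError("run has no DTG curve; preprocess it first")
    apportionments = apportionments or {}
    loss_by_class: dict[str, float] = {}
    unassigned = 0.0
    total = 0.0
    notes: list[str] = []
    for seg_idx, seg in enumerate(assignments):
        w = _segment_trapezoid_weights(run.temperatures, seg.index_start, seg.index_stop)
        dtg = run.dtg[seg.index_start : seg.index_stop + 1]
        seg_loss = float(np.sum(w * dtg))
        total += seg_loss
        if seg.unassigned:
            unassigned += seg_loss
            continue
        k = len(seg.classes)
        fractions = apportionments.get(seg_idx)
        if fractions is None:
            fractions = np.full((dtg.size, k), 1.0 / k)
        else:
            fractions = np.atleast_2d(np.asarray(fractions, dtype=float))
            if fractions.shape != (dtg.size, k):
                raise ValidationError(
                    f"segment {seg_idx}: apportionment shape {fractions.shape} "
                    f"!= ({dtg.size}, {k})"
                )
        for j, cls in enumerate(seg.classes):
            loss_by_class[cls] = loss_by_class.get(cls, 0.0) + float(
                np.sum(w * dtg * fractions[:, j])
            )
    assigned_total = sum(loss_by_class.values())
    if assigned_total > 0:
        composition = {
            cls: 100.0 * v / assigned_total for cls, v in loss_by_class.items()
        }
    else:
        composition = {cls: 0.0 for cls in loss_by_class}
        notes.append("zero total assigned mass loss; compositions are all zero")
        warnings.warn(notes[-1])
    return QuantReport(
        mass_loss_by_class=loss_by_class,
        relative_composition=composition,
        unassigned_loss=unassigned,
        total_loss=total,
        segments=assignments,
        warnings=notes,
    )


def quantify_run(
    run: TgaFtirRun,
    pred: PredictionMap,
    lib: SpectralLibrary | None = None,
) -> QuantReport:
    """Convenience chain: segment -> MCR-apportion mixed segments -> integrate.

    Works with any per-spectrum label map (ML probabilities or SMA scores
    wrapped in a :class:`~pyroplast.ml_pipeline.PredictionMap`).
    """
    assignments = assign_segments(pred, run)
    apportionments: dict[int, np.ndarray] = {}
    if lib is not None:
        spectra_mat = run.spectra_matrix()
        for i, seg in enumerate(assignments):
            if len(seg.classes) < 2:
                continue
            D = spectra_mat[seg.index_start : seg.index_stop + 1]
            if D.shape[0] < 3:
                continue  # too short for MCR; falls back to equal split
            apportionments[i] = mcr_apportion(D, seg.classes, lib)
    return quantify(run, assignments, apportionments)


def sma_prediction_map(result, run: TgaFtirRun) -> PredictionMap:
    """Adapt an :class:`~pyroplast.sma.SmaResult` to the PredictionMap interface.

    Scores are clipped to [0, 1] so thresholding semantics carry over; the
    map's threshold is the SMA acceptance threshold.
    """
    trace = np.nan_to_num(result.class_trace(), nan=0.0)
    # labels accepted on a residual iteration may score below threshold on the
    # first pass; lift them to their accepted score so thresholding keeps them
    col = {cls: j for j, cls in enumerate(result.classes)}
    for i, match in enumerate(result.spectrum_matches):
        for cls, score in match.labels:
            j = col.get(cls)
            if j is not None:
                trace[i, j] = max(trace[i, j], score.r_final)
    return PredictionMap(
        temperatures=run.temperatures.copy(),
        classes=result.classes,
        probabilities=np.clip(trace, 0.0, 1.0),
        threshold=result.threshold,
    )
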