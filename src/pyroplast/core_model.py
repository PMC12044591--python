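"""Domain types and file I/O for temperature-resolved evolved-gas FTIR runs.

A *run* couples a thermogravimetric (TG) mass-loss curve with the sequence of
gas-phase FTIR spectra recorded while the sample is heated.  A *library* is a
collection of reference spectra taken from the decomposition region(s) of
known materials, used for spectral matching and classifier training.

Canonical interchange formats are plain text: a CSV matrix dialect for runs
(wavenumber column + one column per spectrum, header row of temperatures,
sidecar ``<stem>.tg.csv`` table of TG vs. temperature) and JCAMP-DX for single
spectra.  Libraries and preprocessed runs round-trip through a single HDF5
bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "GRID_BOUNDS",
    "ANALYSIS_RANGE",
    "TEMP_WINDOW",
    "DEFAULT_MASK_WINDOWS",
    "ValidationError",
    "ParseError",
    "SchemaError",
    "WavenumberGrid",
    "Spectrum",
    "TgaFtirRun",
    "LibraryEntry",
    "SpectralLibrary",
    "fill_masked",
    "read_run",
    "write_run",
    "read_jcamp",
    "read_library",
    "write_library",
    "correlation_matrix",
]

#: Material classes recognised by default: ten common polymers, cellulose
#: (a ubiquitous environmental matrix component) and the blank / background
#: class.  Extensible via :func:`register_class`.
CLASS_LABELS: tuple[str, ...] = (
    "PE", "PP", "PS", "PET", "PA", "PVC",
    "PUR", "PMMA", "PTFE", "PC", "CEL", "BLANK",
)

GRID_BOUNDS = (400.0, 4500.0)
ANALYSIS_RANGE = (800.0, 4000.0)
TEMP_WINDOW = (150.0, 750.0)
#: Wavenumber windows excluded from all analysis: CO2 and OH regions that are
#: dominated by atmospheric leakage / sample matrix.
DEFAULT_MASK_WINDOWS = ((2200.0, 2400.0), (3150.0, 3500.0))

_extra_classes: list[str] = []


def register_class(label: str) -> None:
    """Add a material class label to the allowed vocabulary."""
    if label not in allowed_classes():
        _extra_classes.append(label)


def allowed_classes() -> tuple[str, ...]:
    return CLASS_LABELS + tuple(_extra_classes)


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


class SchemaError(ValueError):
    """A bundle is missing required keys or carries unknown labels."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class WavenumberGrid:
    """Strictly ascending wavenumber axis (cm^-1) shared by a set of spectra."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValidationError("grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(values) > 0):
            raise ValidationError("wavenumber grid must be strictly increasing")
        lo, hi = GRID_BOUNDS
        if values[0] < lo or values[-1] > hi:
            raise ValidationError(
                f"grid values must lie within [{lo}, {hi}] cm^-1, "
                f"got [{values[0]}, {values[-1]}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def matches(self, other: "WavenumberGrid", tol: float = 1e-9) -> bool:
        return len(self) == len(other) and bool(
            np.allclose(self.values, other.values, atol=tol, rtol=0.0)
        )

    def window_mask(self, windows: Iterable[tuple[float, float]]) -> np.ndarray:
        """Boolean mask, True where a point lies OUTSIDE every window."""
        usable = np.ones(len(self), dtype=bool)
        for lo, hi in windows:
            usable &= ~((self.values >= lo) & (self.values <= hi))
        return usable

    def range_indices(self, lo: float, hi: float) -> np.ndarray:
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


@dataclass
class Spectrum:
    """One gas-phase absorbance spectrum with its effective sample temperature.

    ``mask`` is True for usable points; masked-out points are carried along but
    never contribute to correlation, feature selection or training.
    """

    absorbance: np.ndarray
    temperature: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 1:
            raise ValidationError("spectrum absorbance must be 1-D")
        if self.mask is None:
            self.mask = np.ones(self.absorbance.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.absorbance.shape:
                raise ValidationError("mask length must equal absorbance length")
        self.temperature = float(self.temperature)

    def copy(self) -> "Spectrum":
        return Spectrum(self.absorbance.copy(), self.temperature, self.mask.copy())


def fill_masked(absorbance: np.ndarray, mask: np.ndarray, grid: WavenumberGrid) -> np.ndarray:
    """Replace masked-out points by linear interpolation between usable ones.

    The result depends only on unmasked values, so downstream operations that
    need a gap-free vector (derivatives, baseline fits) remain bit-identical
    under arbitrary perturbation of masked-out data.
    """
    if mask.all():
        return np.asarray(absorbance, dtype=float).copy()
    if not mask.any():
        raise ValidationError("cannot fill a fully masked spectrum")
    x = grid.values
    return np.interp(x, x[mask], np.asarray(absorbance, dtype=float)[mask])


@dataclass
class TgaFtirRun:
    """One TGA-FTIR run: aligned TG, DTG, Gram-Schmidt trace and spectra.

    ``temperatures[i]`` is the effective temperature of ``spectra[i]``; after
    alignment ``tg``/``dtg``/``gram_schmidt`` are sampled at those same
    temperatures.  DTG is stored as a positive mass-loss rate (-dTG/dT, %/degC).
    """

    grid: WavenumberGrid
    temperatures: np.ndarray
    spectra: list[Spectrum]
    tg: np.ndarray | None = None
    dtg: np.ndarray | None = None
    gram_schmidt: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        n = self.temperatures.size
        if len(self.spectra) != n:
            raise ValidationError(
                f"{len(self.spectra)} spectra but {n} temperatures"
            )
        if n > 1 and not np.all(np.diff(self.temperatures) > 0):
            raise ValidationError("spectrum temperatures must be ascending")
        for s in self.spectra:
            if s.absorbance.size != len(self.grid):
                raise ValidationError("spectrum length does not match grid")
        for name in ("tg", "dtg", "gram_schmidt"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.size != n:
                    raise ValidationError(f"{name} length must equal spectrum count")
                setattr(self, name, arr)

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)

    def spectra_matrix(self) -> np.ndarray:
        return np.vstack([s.absorbance for s in self.spectra])

    def mask_matrix(self) -> np.ndarray:
        return np.vstack([s.mask for s in self.spectra])

    def validate_tg(self, tol: float = 1e-6) -> None:
        """Check TG is non-increasing within tolerance (post blank correction)."""
        if self.tg is None or np.isnan(self.tg).any():
            return
        if np.any(np.diff(self.tg) > tol):
            raise ValidationError("TG curve is not non-increasing within tolerance")

    def copy(self) -> "TgaFtirRun":
        return TgaFtirRun(
            grid=self.grid,
            temperatures=self.temperatures.copy(),
            spectra=[s.copy() for s in self.spectra],
            tg=None if self.tg is None else self.tg.copy(),
            dtg=None if self.dtg is None else self.dtg.copy(),
            gram_schmidt=None if self.gram_schmidt is None else self.gram_schmidt.copy(),
            metadata=json.loads(json.dumps(self.metadata)),
        )


@dataclass
class LibraryEntry:
    """Reference spectra of one sample, restricted to its region(s) of interest.

    ``roi`` holds one or more temperature intervals around the sample's
    decomposition peak(s); materials with multiple DTG peaks carry one
    interval per peak.
    """

    polymer_class: str
    sample_id: str
    roi: tuple[tuple[float, float], ...]
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if self.polymer_class not in allowed_classes():
            raise SchemaError(
                f"unknown class label {self.polymer_class!r}; "
                f"allowed: {', '.join(allowed_classes())}"
            )
        self.roi = tuple((float(lo), float(hi)) for lo, hi in self.roi)
        for lo, hi in self.roi:
            if hi <= lo:
                raise ValidationError(f"empty ROI interval ({lo}, {hi})")
        for s in self.spectra:
            if not any(lo <= s.temperature <= hi for lo, hi in self.roi):
                raise ValidationError(
                    f"spectrum at {s.temperature} degC lies outside every ROI "
                    f"of entry {self.sample_id!r}"
                )


@dataclass
class SpectralLibrary:
    entries: list[LibraryEntry]
    grid: WavenumberGrid
    provenance: str = ""

    def __post_init__(self) -> None:
        for e in self.entries:
            for s in e.spectra:
                if s.absorbance.size != len(self.grid):
                    raise ValidationError(
                        f"entry {e.sample_id!r} spectra do not match library grid"
                    )

    @property
    def classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.polymer_class, None)
        return tuple(seen)

    def entries_of(self, polymer_class: str) -> list[LibraryEntry]:
        return [e for e in self.entries if e.polymer_class == polymer_class]

    def common_mask(self) -> np.ndarray:
        """AND of every entry spectrum mask (all-true for an empty library)."""
        mask = np.ones(len(self.grid), dtype=bool)
        for e in self.entries:
            for s in e.spectra:
                mask &= s.mask
        return mask


# ---------------------------------------------------------------------------
# Run I/O — CSV matrix dialect, JCAMP-DX, HDF5
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def _tg_sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".tg.csv")


def read_run(path, dialect: str | None = None) -> TgaFtirRun:
    """Read one run from disk.

    Dialects: ``csv_matrix`` (first column wavenumber, one column per
    spectrum, header row of temperatures, sidecar ``<stem>.tg.csv``),
    ``jcamp_dx`` (single spectrum) and ``hdf5``.  Inferred from the file
    extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {
            ".csv": "csv_matrix",
            ".jdx": "jcamp_dx",
            ".dx": "jcamp_dx",
            ".h5": "hdf5",
            ".hdf5": "hdf5",
        }.get(suffix)
        if dialect is None:
            raise ParseError(f"cannot infer dialect from extension {suffix!r}")
    if dialect == "csv_matrix":
        return _read_run_csv(path)
    if dialect == "jcamp_dx":
        return _read_run_jcamp(path)
    if dialect == "hdf5":
        return _read_run_h5(path)
    raise ParseError(f"unknown dialect {dialect!r}")


def _read_run_csv(path: Path) -> TgaFtirRun:
    with open(path) as fh:
        header = fh.readline().strip()
    cells = header.split(",")
    if not cells or cells[0].strip().lower() not in ("wavenumber", "wavenumber_cm-1"):
        raise ParseError(
            f"column 1 header must be 'wavenumber', got {cells[0]!r}" if cells
            else "empty header row"
        )
    temps = []
    for i, cell in enumerate(cells[1:], start=2):
        try:
            temps.append(float(cell))
        except ValueError:
            raise ParseError(
                f"column {i} header {cell!r} is not a temperature"
            ) from None
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != len(cells):
        raise ParseError("data row width does not match header width")
    wavenumbers = data[:, 0]
    if np.any(np.diff(wavenumbers) <= 0):
        raise ValidationError("wavenumber column is not strictly increasing")
    grid = WavenumberGrid(wavenumbers)
    order = np.argsort(temps, kind="stable")
    temps_sorted = np.asarray(temps, dtype=float)[order]
    spectra = [Spectrum(data[:, 1 + j], temps_sorted[i]) for i, j in enumerate(order)]

    metadata: dict = {"source": str(path)}
    tg = None
    sidecar = _tg_sidecar(path)
    if sidecar.exists():
        table = pd.read_csv(sidecar)
        required = {"temperature", "tg"}
        if not required.issubset(table.columns):
            raise ParseError(
                f"TG sidecar {sidecar.name} must have columns {sorted(required)}"
            )
        t_raw = table["temperature"].to_numpy(dtype=float)
        v_raw = table["tg"].to_numpy(dtype=float)
        metadata["tg_table"] = {"temperature": t_raw.tolist(), "tg": v_raw.tolist()}
        tg = np.interp(temps_sorted, t_raw, v_raw)
    meta_json = path.with_name(path.stem + ".meta.json")
    if meta_json.exists():
        metadata.update(json.loads(meta_json.read_text()))
    return TgaFtirRun(grid=grid, temperatures=temps_sorted, spectra=spectra,
                      tg=tg, metadata=metadata)


def _read_run_jcamp(path: Path) -> TgaFtirRun:
    spectrum, grid = read_jcamp(path)
    return TgaFtirRun(
        grid=grid,
        temperatures=np.array([spectrum.temperature]),
        spectra=[spectrum],
        metadata={"source": str(path)},
    )


def read_jcamp(path) -> tuple[Spectrum, WavenumberGrid]:
    """Minimal JCAMP-DX reader for a single AFFN-encoded spectrum.

    Supports ``##XYDATA=(X++(Y..Y))`` blocks with plain numeric values plus
    the FIRSTX/LASTX/NPOINTS/XFACTOR/YFACTOR records.  Compressed (SQZ/DIF)
    encodings are out of scope.
    """
    path = Path(path)
    records: dict[str, str] = {}
    y_values: list[float] = []
    in_xydata = False
    for line in path.read_text().splitlines():
        line = line.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                in_xydata = True
                continue
            if key == "END":
                in_xydata = False
                continue
            records[key] = value
            continue
        if in_xydata:
            parts = line.replace(",", " ").split()
            if not parts:
                continue
            y_values.extend(float(p) for p in parts[1:])
    for required in ("FIRSTX", "LASTX", "NPOINTS"):
        if required not in records:
            raise ParseError(f"JCAMP-DX file missing ##{required}=")
    npoints = int(float(records["NPOINTS"]))
    if npoints != len(y_values):
        raise ParseError(
            f"##NPOINTS={npoints} but {len(y_values)} Y values found"
        )
    firstx = float(records["FIRSTX"]) * float(records.get("XFACTOR", 1.0))
    lastx = float(records["LASTX"]) * float(records.get("XFACTOR", 1.0))
    yfactor = float(records.get("YFACTOR", 1.0))
    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(y_values, dtype=float) * yfactor
    if x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    temperature = float(records.get("TEMPERATURE", records.get("$TEMPERATURE", "25")))
    grid = WavenumberGrid(x)
    return Spectrum(y, temperature), grid


def write_run(run: TgaFtirRun, path) -> Path:
    """Write a run as a CSV matrix (+ TG sidecar) or an HDF5 bundle."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _write_run_h5(run, path)
    header = "wavenumber," + ",".join(_FLOAT_FMT % t for t in run.temperatures)
    body = np.column_stack([run.grid.values, run.spectra_matrix().T])
    np.savetxt(path, body, delimiter=",", header=header, comments="", fmt=_FLOAT_FMT)
    if run.tg is not None:
        table = run.metadata.get("tg_table")
        if table is not None:
            t_raw = np.asarray(table["temperature"], dtype=float)
            v_raw = np.asarray(table["tg"], dtype=float)
        else:
            t_raw, v_raw = run.temperatures, run.tg
        pd.DataFrame({"temperature": t_raw, "tg": v_raw}).to_csv(
            _tg_sidecar(path), index=False, float_format=_FLOAT_FMT
        )
    meta = {k: v for k, v in run.metadata.items() if k not in ("tg_table", "source")}
    if meta:
        path.with_name(path.stem + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _write_run_h5(run: TgaFtirRun, path: Path) -> Path:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "pyroplast-run/1"
        fh.create_dataset("grid", data=run.grid.values)
        fh.create_dataset("temperatures", data=run.temperatures)
        fh.create_dataset("spectra", data=run.spectra_matrix())
        fh.create_dataset("mask", data=run.mask_matrix())
        for name in ("tg", "dtg", "gram_schmidt"):
            arr = getattr(run, name)
            if arr is not None:
                fh.create_dataset(name, data=arr)
        fh.attrs["metadata"] = json.dumps(run.metadata)
    return path


def _read_run_h5(path: Path) -> TgaFtirRun:
    with h5py.File(path, "r") as fh:
        for key in ("grid", "temperatures", "spectra", "mask"):
            if key not in fh:
                raise SchemaError(f"run bundle missing dataset {key!r}")
        grid = WavenumberGrid(fh["grid"][()])
        temps = fh["temperatures"][()]
        spectra_mat = fh["spectra"][()]
        mask_mat = fh["mask"][()].astype(bool)
        spectra = [
            Spectrum(spectra_mat[i], temps[i], mask_mat[i])
            for i in range(temps.size)
        ]
        kwargs = {}
        for name in ("tg", "dtg", "gram_schmidt"):
            if name in fh:
                kwargs[name] = fh[name][()]
        metadata = json.loads(fh.attrs.get("metadata", "{}"))
    return TgaFtirRun(grid=grid, temperatures=temps, spectra=spectra,
                      metadata=metadata, **kwargs)


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------


def write_library(lib: SpectralLibrary, path) -> Path:
    """Write a library to a single HDF5 bundle (lossless to 1e-9)."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "pyroplast-library/1"
        fh.attrs["provenance"] = lib.provenance
        fh.create_dataset("grid", data=lib.grid.values)
        grp = fh.create_group("entries")
        for i, entry in enumerate(lib.entries):
            eg = grp.create_group(f"{i:05d}")
            eg.attrs["polymer_class"] = entry.polymer_class
            eg.attrs["sample_id"] = entry.sample_id
            eg.create_dataset("roi", data=np.asarray(entry.roi, dtype=float).reshape(-1, 2))
            eg.create_dataset(
                "temperatures", data=np.array([s.temperature for s in entry.spectra])
            )
            if entry.spectra:
                eg.create_dataset("spectra", data=np.vstack([s.absorbance for s in entry.spectra]))
                eg.create_dataset("mask", data=np.vstack([s.mask for s in entry.spectra]))
    return path


def read_library(path) -> SpectralLibrary:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if "grid" not in fh or "entries" not in fh:
            raise SchemaError("library bundle missing 'grid' or 'entries'")
        grid = WavenumberGrid(fh["grid"][()])
        entries = []
        for key in sorted(fh["entries"]):
            eg = fh["entries"][key]
            for attr in ("polymer_class", "sample_id"):
                if attr not in eg.attrs:
                    raise SchemaError(f"entry {key} missing attribute {attr!r}")
            if "roi" not in eg or "temperatures" not in eg:
                raise SchemaError(f"entry {key} missing 'roi' or 'temperatures'")
            temps = eg["temperatures"][()]
            spectra = []
            if temps.size:
                spectra_mat = eg["spectra"][()]
                mask_mat = eg["mask"][()].astype(bool)
                spectra = [
                    Spectrum(spectra_mat[i], temps[i], mask_mat[i])
                    for i in range(temps.size)
                ]
            entries.append(
                LibraryEntry(
                    polymer_class=str(eg.attrs["polymer_class"]),
                    sample_id=str(eg.attrs["sample_id"]),
                    roi=tuple(map(tuple, eg["roi"][()])),
                    spectra=spectra,
                )
            )
        provenance = str(fh.attrs.get("provenance", ""))
    return SpectralLibrary(entries=entries, grid=grid, provenance=provenance)


# ---------------------------------------------------------------------------
# Library diagnostics
# ---------------------------------------------------------------------------


def correlation_matrix(lib: SpectralLibrary, use_derivative: bool = False) -> pd.DataFrame:
    """Class-by-class matrix of the maximum pairwise Pearson r.

    Entry (i, j) is the maximum, over all spectrum pairs drawn from classes i
    and j, of the Pearson correlation of the raw spectra (or their
    Savitzky-Golay first derivatives with ``use_derivative``).  High
    off-diagonal values flag materials whose evolved-gas spectra are
    inherently confusable.
    """
    from scipy.signal import savgol_filter

    classes = lib.classes
    if len(classes) < 1:
        raise ValidationError("library has no entries")
    mask = lib.common_mask()
    cols = np.nonzero(mask)[0]
    if cols.size < 3:
        raise ValidationError("fewer than 3 usable wavenumber points")

    blocks: dict[str, np.ndarray] = {}
    for cls in classes:
        rows = []
        for e in lib.entries_of(cls):
            for s in e.spectra:
                filled = fill_masked(s.absorbance, s.mask, lib.grid)
                if use_derivative:
                    window = min(11, filled.size if filled.size % 2 else filled.size - 1)
                    filled = savgol_filter(filled, window, 2, deriv=1)
                rows.append(filled[cols])
        if not rows:
            raise ValidationError(f"class {cls!r} has no spectra")
        X = np.vstack(rows)
        X = X - X.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(X, axis=1, keepdims=True)
        degenerate = norm[:, 0] < 1e-300
        if degenerate.any():
            warnings.warn(f"dropping {degenerate.sum()} constant spectra in class {cls}")
            X = X[~degenerate]
            norm = norm[~degenerate]
            if X.shape[0] == 0:
                raise ValidationError(f"class {cls!r} has only constant spectra")
        blocks[cls] = X / norm

    n = len(classes)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = blocks[classes[i]] @ blocks[classes[j]].T
            out[i, j] = out[j, i] = float(r.max())
    return pd.DataFrame(out, index=list(classes), columns=list(classes))
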