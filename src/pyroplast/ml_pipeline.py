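"""Multilabel one-vs-rest classification of evolved-gas spectra.

Feature pipeline: SNV per spectrum -> ANOVA F-test selection of the most
class-discriminating wavenumber points -> spectrum temperature appended as an
extra feature -> per-feature standardisation.  One binary classifier is
fitted per material class (BLANK is the all-negative case, never a class of
its own), so any spectrum can receive zero, one or several labels.

Training data can be expanded with extended multiplicative scatter
augmentation (EMSA): each synthetic spectrum is a_0 + b * x + c * l + d * l^2
+ noise for a source spectrum x and normalised wavenumber l, i.e. small
multiplicative, additive and wavelength-polynomial perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MultiLabelBinarizer, StandardScaler
from sklearn.svm import SVC

from .core_model import SpectralLibrary, Spectrum, TgaFtirRun, ValidationError
from .preprocess import snv_vector

__all__ = [
    "MODEL_KINDS",
    "EmsaParams",
    "TrainConfig",
    "FeatureSpec",
    "TrainedModel",
    "PredictionMap",
    "emsa_augment",
    "select_features",
    "train",
    "predict_run",
]

MODEL_KINDS = ("knn", "mlp", "rf", "svc")

DEFAULT_GRIDS: dict[str, dict] = {
    "knn": {"estimator__n_neighbors": [3, 5, 9]},
    "mlp": {"estimator__hidden_layer_sizes": [(64,), (128,)], "estimator__alpha": [1e-4]},
    "rf": {"estimator__n_estimators": [100], "estimator__max_depth": [None, 12]},
    "svc": {"estimator__C": [1.0, 10.0], "estimator__gamma": ["scale"]},
}


@dataclass(frozen=True)
class EmsaParams:
    """Perturbation ranges for EMSA augmentation.

    ``multiplicative`` is the +/- half-range around 1 for b; ``additive`` the
    +/- range of the constant offset; ``poly_scale`` bounds the linear and
    quadratic wavelength terms at that fraction of the source signal range;
    ``noise_sd_frac`` sets the white-noise SD as a fraction of max |x|;
    ``temperature_jitter`` is the +/- degC jitter on the copied temperature.
    """

    multiplicative: float = 0.1
    additive: float = 0.02
    poly_scale: float = 0.02
    noise_sd_frac: float = 0.005
    temperature_jitter: float = 2.0


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.25
    cv_folds: int = 3
    k_features: int = 200
    include_temperature: bool = True
    prob_threshold: float = 0.5
    emsa_per_class: int = 0  # 0 disables augmentation
    emsa_params: EmsaParams = field(default_factory=EmsaParams)
    param_grid: dict | None = None  # overrides DEFAULT_GRIDS[model_kind]

    def __post_init__(self) -> None:
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValidationError("prob_threshold must lie in (0, 1)")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValidationError("test_fraction must lie in (0, 1)")


@dataclass
class FeatureSpec:
    """Selected wavenumber positions plus the final feature scaler."""

    selected_indices: np.ndarray  # indices into the grid
    grid_values: np.ndarray  # grid the model was trained on
    include_temperature: bool
    scaler: StandardScaler
    f_scores: np.ndarray | None = None

    def build_matrix(self, spectra: list[Spectrum], scale: bool = True) -> np.ndarray:
        rows = []
        for s in spectra:
            try:
                z = snv_vector(s.absorbance, s.mask)
            except ValidationError:
                z = np.zeros_like(s.absorbance)
            row = z[self.selected_indices]
            if self.include_temperature:
                row = np.append(row, s.temperature)
            rows.append(row)
        X = np.vstack(rows)
        return self.scaler.transform(X) if scale else X


@dataclass
class TrainedModel:
    model_kind: str
    estimator: OneVsRestClassifier
    classes: tuple[str, ...]
    feature_spec: FeatureSpec
    prob_threshold: float
    metadata: dict = field(default_factory=dict)


@dataclass
class PredictionMap:
    """Per-spectrum, per-class probabilities for one run."""

    temperatures: np.ndarray
    classes: tuple[str, ...]
    probabilities: np.ndarray  # (n_spectra, n_classes), in [0, 1]
    threshold: float

    def label_sets(self) -> list[set[str]]:
        out = []
        for row in self.probabilities:
            out.append({cls for cls, p in zip(self.classes, row) if p > self.threshold})
        return out

    @property
    def run_labels(self) -> set[str]:
        labels: set[str] = set()
        for s in self.label_sets():
            labels |= s
        return labels

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probabilities, columns=list(self.classes))
        df.insert(0, "temperature", self.temperatures)
        return df


# ---------------------------------------------------------------------------
# EMSA augmentation
# ---------------------------------------------------------------------------


def emsa_augment(
    labelled: list[tuple[Spectrum, str]],
    n_per_class: int,
    rng_seed: int = 0,
    params: EmsaParams | None = None,
) -> list[tuple[Spectrum, str]]:
    """Generate ``n_per_class`` perturbed copies for every class present.

    Each synthetic spectrum perturbs a randomly chosen source spectrum of its
    class with multiplicative, additive, linear and quadratic wavelength
    terms plus white noise; the label is copied and the temperature jittered.
    """
    if n_per_class <= 0:
        raise ValidationError("n_per_class must be positive")
    params = params or EmsaParams()
    by_class: dict[str, list[Spectrum]] = {}
    for spectrum, label in labelled:
        by_class.setdefault(label, []).append(spectrum)
    rng = np.random.default_rng(rng_seed)
    out: list[tuple[Spectrum, str]] = []
    for label in by_class:
        pool = by_class[label]
        for _ in range(n_per_class):
            src = pool[int(rng.integers(0, len(pool)))]
            x = src.absorbance
            n_pts = x.size
            lam = np.linspace(-1.0, 1.0, n_pts)
            signal_range = float(x.max() - x.min()) or 1.0
            b = 1.0 + rng.uniform(-params.multiplicative, params.multiplicative)
            a = rng.uniform(-params.additive, params.additive)
            c = rng.uniform(-1.0, 1.0) * params.poly_scale * signal_range
            d = rng.uniform(-1.0, 1.0) * params.poly_scale * signal_range
            noise_sd = params.noise_sd_frac * float(np.abs(x).max())
            noise = rng.normal(0.0, noise_sd, n_pts) if noise_sd > 0 else 0.0
            y = a + b * x + c * lam + d * lam**2 + noise
            temperature = src.temperature + rng.uniform(
                -params.temperature_jitter, params.temperature_jitter
            )
            out.append((Spectrum(y, temperature, src.mask.copy()), label))
    return out


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def select_features(
    X: np.ndarray,
    labels,
    k: int = 200,
    column_indices: np.ndarray | None = None,
    include_temperature: bool = True,
    grid_values: np.ndarray | None = None,
    on_degenerate: str = "error",
) -> FeatureSpec:
    """Rank columns by one-way ANOVA F across class groups; keep the top k.

    ``column_indices`` maps the columns of ``X`` back to grid positions (all
    columns if omitted).  The returned scaler is *unfitted*; :func:`train`
    fits it after assembling the final feature matrix.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValidationError("feature selection needs >= 2 classes")
    if k > X.shape[1]:
        raise ValidationError(f"k={k} exceeds {X.shape[1]} available columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield harmless NaN F
        f_stat, _p = f_classif(X, labels)
    f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.finfo(float).max)
    if not np.any(f_stat > 0):
        message = "all ANOVA F statistics are zero (indistinguishable classes)"
        if on_degenerate == "error":
            raise ValidationError(message)
        warnings.warn(message)
    order = np.argsort(-f_stat, kind="stable")[:k]
    order = np.sort(order)  # keep wavenumber order for interpretability
    cols = np.arange(X.shape[1]) if column_indices is None else np.asarray(column_indices)
    return FeatureSpec(
        selected_indices=cols[order],
        grid_values=np.asarray(grid_values) if grid_values is not None else cols.astype(float),
        include_temperature=include_temperature,
        scaler=StandardScaler(),
        f_scores=f_stat[order],
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _base_estimator(model_kind: str, seed: int):
    if model_kind == "knn":
        return KNeighborsClassifier()
    if model_kind == "mlp":
        return MLPClassifier(max_iter=600, random_state=seed)
    if model_kind == "rf":
        return RandomForestClassifier(random_state=seed)
    if model_kind == "svc":
        return SVC(probability=True, random_state=seed)
    raise ValidationError(f"unknown model kind {model_kind!r}; one of {MODEL_KINDS}")


def _sample_level_split(sample_ids, labels, test_fraction: float, rng) -> np.ndarray:
    """Boolean test mask: per-class 75/25 split at the sample level.

    Whole samples go to one side so spectra from the same run never leak
    across the split (stricter than a random spectrum-level split).
    """
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    test_samples: set[str] = set()
    for cls in dict.fromkeys(labels.tolist()):
        samples = list(dict.fromkeys(sample_ids[labels == cls].tolist()))
        if len(samples) < 2:
            continue  # single-sample class stays in training
        perm = rng.permutation(len(samples))
        n_test = max(1, int(round(test_fraction * len(samples))))
        if n_test >= len(samples):
            n_test = len(samples) - 1
        test_samples |= {samples[i] for i in perm[:n_test]}
    return np.isin(sample_ids, list(test_samples))


def _library_rows(lib: SpectralLibrary):
    spectra, labels, sample_ids = [], [], []
    for entry in lib.entries:
        for s in entry.spectra:
            spectra.append(s)
            labels.append(entry.polymer_class)
            sample_ids.append(entry.sample_id)
    return spectra, labels, sample_ids


def train(
    lib: SpectralLibrary,
    model_kind: str = "svc",
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[TrainedModel, dict]:
    """Fit a one-vs-rest multilabel classifier on library spectra.

    The library should contain ROI spectra per material plus BLANK-labelled
    negatives (out-of-ROI and blank-run spectra).  Returns the trained model
    and held-out test metrics.  Fully deterministic under a fixed seed.
    """
    cfg = cfg or TrainConfig()
    model_kind = model_kind.lower()
    rng = np.random.default_rng(seed)

    spectra, labels, sample_ids = _library_rows(lib)
    classes = tuple(c for c in dict.fromkeys(labels) if c != "BLANK")
    if len(classes) < 2:
        raise ValidationError("training needs >= 2 material classes")
    counts: dict[str, int] = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    thin = [c for c, n in counts.items() if n < 3]
    if thin:
        raise ValidationError(f"classes with < 3 spectra: {', '.join(sorted(thin))}")

    test_mask = _sample_level_split(sample_ids, labels, cfg.test_fraction, rng)
    train_pairs = [(s, l) for s, l, t in zip(spectra, labels, test_mask) if not t]
    test_pairs = [(s, l) for s, l, t in zip(spectra, labels, test_mask) if t]

    if cfg.emsa_per_class > 0:
        train_pairs = train_pairs + emsa_augment(
            train_pairs, cfg.emsa_per_class,
            rng_seed=int(rng.integers(0, 2**31)), params=cfg.emsa_params,
        )

    # feature selection on the training rows only, over unmasked columns
    usable = lib.common_mask()
    cols = np.nonzero(usable)[0]
    X_cols = np.vstack(
        [snv_vector(s.absorbance, s.mask)[cols] for s, _ in train_pairs]
    )
    y_train_labels = [l for _, l in train_pairs]
    spec = select_features(
        X_cols, y_train_labels, k=min(cfg.k_features, cols.size),
        column_indices=cols, include_temperature=cfg.include_temperature,
        grid_values=lib.grid.values,
    )

    X_train = spec.build_matrix([s for s, _ in train_pairs], scale=False)
    spec.scaler.fit(X_train)
    X_train = spec.scaler.transform(X_train)
    binarizer = MultiLabelBinarizer(classes=list(classes))
    to_sets = lambda ls: [set() if l == "BLANK" else {l} for l in ls]
    y_train = binarizer.fit_transform(to_sets(y_train_labels))

    grid = cfg.param_grid if cfg.param_grid is not None else DEFAULT_GRIDS[model_kind]
    ovr = OneVsRestClassifier(_base_estimator(model_kind, int(rng.integers(0, 2**31))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OvR warns on labels absent from folds
        cv = KFold(n_splits=cfg.cv_folds, shuffle=True,
                   random_state=int(rng.integers(0, 2**31)))
        search = GridSearchCV(ovr, grid, cv=cv, scoring="f1_macro", n_jobs=1)
        search.fit(X_train, y_train)

    model = TrainedModel(
        model_kind=model_kind,
        estimator=search.best_estimator_,
        classes=classes,
        feature_spec=spec,
        prob_threshold=cfg.prob_threshold,
        metadata={
            "seed": seed,
            "cv_folds": cfg.cv_folds,
            "param_grid": {k: list(map(str, v)) for k, v in grid.items()},
            "best_params": {k: str(v) for k, v in search.best_params_.items()},
            "cv_macro_f1": float(search.best_score_),
            "n_train": len(train_pairs),
            "n_test": len(test_pairs),
            "emsa_per_class": cfg.emsa_per_class,
        },
    )

    metrics: dict = {"cv_macro_f1": float(search.best_score_)}
    if test_pairs:
        X_test = spec.build_matrix([s for s, _ in test_pairs])
        y_test = binarizer.transform(to_sets([l for _, l in test_pairs]))
        y_prob = model.estimator.predict_proba(X_test)
        y_pred = (y_prob > cfg.prob_threshold).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics["test_macro_f1"] = float(f1_score(y_test, y_pred, average="macro"))
            per_class = f1_score(y_test, y_pred, average=None, zero_division=0)
        metrics["test_per_class_f1"] = dict(zip(classes, map(float, per_class)))
        metrics["test_subset_accuracy"] = float(np.mean(np.all(y_pred == y_test, axis=1)))
    model.metadata["test_metrics"] = {
        k: v for k, v in metrics.items() if not isinstance(v, dict)
    }
    return model, metrics


def predict_run(model: TrainedModel, run: TgaFtirRun) -> PredictionMap:
    """Per-spectrum class probabilities for a preprocessed run."""
    spec = model.feature_spec
    if len(run.grid) != spec.grid_values.size or not np.allclose(
        run.grid.values, spec.grid_values, atol=1e-9
    ):
        raise ValidationError(
            "run grid does not match the model's training grid; "
            "resample the run onto the library grid first"
        )
    X = spec.build_matrix(run.spectra)
    probs = model.estimator.predict_proba(X)
    return PredictionMap(
        temperatures=run.temperatures.copy(),
        classes=model.classes,
        probabilities=np.asarray(probs, dtype=float),
        threshold=model.prob_threshold,
    )
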