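"""Strain feature vectors and LGE+/- classification.

The full descriptor of one patient is a 320-entry vector: 2 components
(Ecc, Err) x 2 alignment schemes (ED2K, K2K) x 5 sub-phases x 16 AHA
segments, in a fixed documented order.  Subsets mirror the published
feature combinations:

* ``5K`` uses the four inter-key-frame phases of ED2K (64 per component)
  or the five sequential phases of K2K (80), or both (144);
* ``3K, n-seg`` is the task-tailored set: ED2K's systolic ED-ES phase plus
  K2K's ED-MS, MS-ES and ES-PF phases, restricted to the *n* most
  frequently involved risk segments (ordered 5, 11, 12, 6, 4, 10, 16), so
  e.g. n=5 gives 4 x 5 = 20 features.

Group comparison uses Welch's t-test (unpaired, unequal variances) with
Holm-Bonferroni adjustment at alpha = 0.05, one family per
component-scheme.  Classification is a stratified 4-fold cross-validated
grid search over >= 2000 scikit-learn pipelines selected by mean balanced
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, RidgeClassifier
from sklearn.model_selection import GridSearchCV, ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import RobustScaler, StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from . import aha

COMPONENTS = ("Ecc", "Err")
SCHEMES = ("ED2K", "K2K")
PHASES = {
    "ED2K": ("ED-MS", "ED-ES", "ED-PF", "ED-MD", "ED-ED"),
    "K2K": ("ED-MS", "MS-ES", "ES-PF", "PF-MD", "MD-ED"),
}
#: inter-key-frame phases entering the 5K subsets (full-cycle ED-ED excluded)
PHASES_5K = {
    "ED2K": ("ED-MS", "ED-ES", "ED-PF", "ED-MD"),
    "K2K": ("ED-MS", "MS-ES", "ES-PF", "PF-MD", "MD-ED"),
}
#: phases of the task-tailored 3K subsets
PAIRS_3K = (("ED2K", "ED-ES"), ("K2K", "ED-MS"), ("K2K", "MS-ES"), ("K2K", "ES-PF"))
#: risk segments ordered by cohort involvement frequency
RISK_SEGMENTS = (5, 11, 12, 6, 4, 10, 16)

FEATURE_VECTOR_LENGTH = 320


def feature_index() -> list[tuple[str, str, str, int]]:
    """Fixed feature ordering: (component, scheme, phase, segment)."""
    idx = []
    for comp in COMPONENTS:
        for scheme in SCHEMES:
            for phase in PHASES[scheme]:
                for seg in aha.ALL_SEGMENTS:
                    idx.append((comp, scheme, phase, seg))
    return idx


def feature_names() -> list[str]:
    return [f"{c}_{s}_{p}_seg{g:02d}" for c, s, p, g in feature_index()]


def build_feature_vector(strain_table: pd.DataFrame) -> np.ndarray:
    """Flatten a segmental-strain table into the 320-entry feature vector.

    Assembly is keyed on (scheme, phase, segment), so the input row order is
    irrelevant.  Missing entries raise; NaN values (empty segments) pass
    through for downstream imputation.
    """
    keyed = strain_table.set_index(["scheme", "phase", "aha_segment"])
    if keyed.index.has_duplicates:
        raise ValueError("duplicate (scheme, phase, segment) rows in strain table")
    vec = np.empty(FEATURE_VECTOR_LENGTH)
    for i, (comp, scheme, phase, seg) in enumerate(feature_index()):
        try:
            vec[i] = keyed.at[(scheme, phase, seg), comp]
        except KeyError as exc:
            raise ValueError(f"strain table missing entry {(scheme, phase, seg)}") from exc
    return vec


@dataclass(frozen=True)
class FeatureSubsetSpec:
    """Selection of components, scheme-phase pairs and segments."""

    components: tuple[str, ...] = COMPONENTS
    pairs: tuple[tuple[str, str], ...] = tuple(
        (s, p) for s in SCHEMES for p in PHASES[s]
    )
    segments: tuple[int, ...] = aha.ALL_SEGMENTS

    def __post_init__(self) -> None:
        for c in self.components:
            if c not in COMPONENTS:
                raise ValueError(f"unknown component {c!r}")
        for scheme, phase in self.pairs:
            if scheme not in SCHEMES or phase not in PHASES[scheme]:
                raise ValueError(f"unknown scheme/phase {(scheme, phase)!r}")
        for seg in self.segments:
            if seg not in aha.ALL_SEGMENTS:
                raise ValueError(f"unknown AHA segment {seg}")

    @property
    def dimensionality(self) -> int:
        return len(self.components) * len(self.pairs) * len(self.segments)

    @classmethod
    def five_k(cls, schemes: Iterable[str] = SCHEMES, component: str = "Ecc") -> "FeatureSubsetSpec":
        """The 5K subsets: ED2K 4x16=64, K2K 5x16=80, combined 144 per component."""
        pairs = tuple((s, p) for s in schemes for p in PHASES_5K[s])
        return cls(components=(component,), pairs=pairs)

    @classmethod
    def three_k(cls, n_segments: int, component: str = "Ecc") -> "FeatureSubsetSpec":
        """Task-tailored subset: significant phases x top-n risk segments."""
        if not 1 <= n_segments <= len(RISK_SEGMENTS):
            raise ValueError(f"n_segments must be in [1, {len(RISK_SEGMENTS)}]")
        return cls(
            components=(component,),
            pairs=PAIRS_3K,
            segments=tuple(RISK_SEGMENTS[:n_segments]),
        )


def select_features(
    vector: np.ndarray, spec: FeatureSubsetSpec
) -> tuple[np.ndarray, list[str]]:
    """Extract the requested entries (in full-vector order) with their names."""
    vector = np.asarray(vector)
    if vector.shape[-1] != FEATURE_VECTOR_LENGTH:
        raise ValueError(f"expected {FEATURE_VECTOR_LENGTH}-entry vectors")
    keep, names = [], []
    for i, (comp, scheme, phase, seg) in enumerate(feature_index()):
        if comp in spec.components and (scheme, phase) in spec.pairs and seg in spec.segments:
            keep.append(i)
            names.append(f"{comp}_{scheme}_{phase}_seg{seg:02d}")
    assert len(keep) == spec.dimensionality
    return vector[..., keep], names


def cohort_feature_matrix(strain_tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Stack per-patient strain tables into an (n_patients, 320) feature frame."""
    X = np.vstack([build_feature_vector(t) for t in strain_tables])
    return pd.DataFrame(X, columns=feature_names())


# ---------------------------------------------------------------------------
# group statistics


def welch_holm(
    values_pos: np.ndarray,
    values_neg: np.ndarray,
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch's t-test per column with Holm-Bonferroni adjustment.

    ``values_pos``/``values_neg`` are (n_samples, n_tests) matrices of one
    family.  Degenerate tests (a group with < 2 finite samples or zero
    variance in both groups) get p = 1 and a warning flag.  Significance is
    adjusted p < ``alpha``.
    """
    pos = np.atleast_2d(np.asarray(values_pos, float))
    neg = np.atleast_2d(np.asarray(values_neg, float))
    if pos.shape[1] != neg.shape[1]:
        raise ValueError("groups must test the same family of columns")
    n_tests = pos.shape[1]
    raw = np.ones(n_tests)
    degenerate = np.zeros(n_tests, bool)
    for j in range(n_tests):
        a = pos[:, j][np.isfinite(pos[:, j])]
        b = neg[:, j][np.isfinite(neg[:, j])]
        if a.size < 2 or b.size < 2 or (np.var(a) == 0 and np.var(b) == 0):
            degenerate[j] = True
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = stats.ttest_ind(a, b, equal_var=False)
        raw[j] = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
        degenerate[j] |= np.isnan(t.pvalue)
    _, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    return pd.DataFrame(
        {
            "name": list(names) if names is not None else list(range(n_tests)),
            "p_raw": raw,
            "p_adjusted": adjusted,
            "significant": (adjusted < alpha) & ~degenerate,
            "degenerate": degenerate,
        }
    )


def significant_segments(
    features: pd.DataFrame,
    lge_positive: np.ndarray,
    component: str = "Ecc",
    scheme: str = "K2K",
    alpha: float = 0.05,
) -> tuple[set[int], pd.DataFrame]:
    """Segments significant in any phase of one component-scheme family."""
    cols = [
        (i, name, seg)
        for i, (c, s, p, seg) in enumerate(feature_index())
        for name in [feature_names()[i]]
        if c == component and s == scheme
    ]
    idx = [i for i, _, _ in cols]
    X = features.to_numpy()
    table = welch_holm(
        X[np.asarray(lge_positive, bool)][:, idx],
        X[~np.asarray(lge_positive, bool)][:, idx],
        names=[n for _, n, _ in cols],
        alpha=alpha,
    )
    table["aha_segment"] = [seg for _, _, seg in cols]
    segs = set(table.loc[table["significant"], "aha_segment"].astype(int))
    return segs, table


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts and the derived binary-classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both classes must be present")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def f1(self) -> float:
        return 2 * self.tp / (2 * self.tp + self.fp + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
        }


def report_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassificationReport:
    """Sensitivity, specificity, balanced accuracy and F1 from confusion counts."""
    return ClassificationReport(tp=tp, fp=fp, tn=tn, fn=fn)


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ClassificationReport:
    y_true = np.asarray(y_true, bool)
    y_pred = np.asarray(y_pred, bool)
    return ClassificationReport(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def default_grid(seed: int = 0) -> list[dict]:
    """Reproducible hyperparameter lattice of > 2000 pipeline candidates."""
    scalers = [StandardScaler(), RobustScaler(), "passthrough"]
    log3 = np.logspace(-3, 3, 18).tolist()
    grids: list[dict] = [
        {
            "clf": [SVC(kernel="rbf", random_state=seed)],
            "clf__C": log3,
            "clf__gamma": np.logspace(-4, 2, 18).tolist(),
        },
        {"clf": [SVC(kernel="linear", random_state=seed)], "clf__C": np.logspace(-3, 3, 24).tolist()},
        {
            "clf": [LogisticRegression(max_iter=2000, random_state=seed)],
            "clf__C": np.logspace(-3, 3, 48).tolist(),
            "clf__solver": ["lbfgs", "liblinear"],
        },
        {"clf": [RidgeClassifier()], "clf__alpha": np.logspace(-3, 3, 48).tolist()},
        {
            "clf": [KNeighborsClassifier()],
            "clf__n_neighbors": list(range(1, 33)),
            "clf__weights": ["uniform", "distance"],
            "clf__p": [1, 2],
        },
        {
            "clf": [RandomForestClassifier(random_state=seed)],
            "clf__n_estimators": [50, 100],
            "clf__max_depth": [2, 3, 5, None],
            "clf__max_features": ["sqrt", None],
            "clf__min_samples_leaf": [1, 3],
        },
        {
            "clf": [GradientBoostingClassifier(random_state=seed)],
            "clf__n_estimators": [50, 100],
            "clf__learning_rate": [0.05, 0.1, 0.2],
            "clf__max_depth": [1, 2],
        },
        {"clf": [GaussianNB()], "clf__var_smoothing": np.logspace(-11, -5, 12).tolist()},
        {"clf": [LinearDiscriminantAnalysis()]},
    ]
    out = []
    for g in grids:
        out.append({"scale": scalers, **g})
    return out


def grid_size(grid: list[dict]) -> int:
    return len(ParameterGrid(grid))


@dataclass
class CohortFitResult:
    """Best pipeline from the grid search plus cross-validated metrics."""

    estimator: Pipeline
    search: GridSearchCV
    report: dict[str, tuple[float, float]]  # metric -> (mean, sd) over folds
    n_candidates: int

    @property
    def balanced_accuracy(self) -> float:
        return self.report["balanced_accuracy"][0]

    def summary(self) -> str:
        lines = [f"grid-search over {self.n_candidates} pipelines", "-" * 40]
        for metric, (mean, sd) in self.report.items():
            lines.append(f"{metric:>18s}: {mean:.3f} +/- {sd:.3f}")
        lines.append(f"best params: {self.search.best_params_}")
        return "\n".join(lines)


def grid_search_fit(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 4,
    seed: int = 0,
    grid: list[dict] | None = None,
) -> CohortFitResult:
    """Stratified k-fold grid search selected by mean balanced accuracy.

    Missing feature entries are mean-imputed inside the pipeline (fitted on
    training folds only).  Deterministic for a fixed seed; the returned
    estimator is refit on the full cohort.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, bool)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for classification")
    grid = default_grid(seed) if grid is None else grid
    pipe = Pipeline(
        [("impute", SimpleImputer(strategy="mean")), ("scale", "passthrough"), ("clf", SVC())]
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scoring = {
        "balanced_accuracy": "balanced_accuracy",
        "f1": "f1",
        "sensitivity": "recall",
        "specificity": make_specificity_scorer(),
    }
    search = GridSearchCV(
        pipe,
        grid,
        scoring=scoring,
        refit="balanced_accuracy",
        cv=cv,
        n_jobs=1,
        error_score=0.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    res = search.cv_results_
    i = search.best_index_
    report = {}
    for metric in scoring:
        means = res[f"mean_test_{metric}"][i]
        sds = res[f"std_test_{metric}"][i]
        report[metric] = (float(means), float(sds))
    return CohortFitResult(
        estimator=search.best_estimator_,
        search=search,
        report=report,
        n_candidates=grid_size(grid),
    )


def make_specificity_scorer():
    from sklearn.metrics import make_scorer, recall_score

    return make_scorer(recall_score, pos_label=0)


def classify(model, vectors: np.ndarray) -> np.ndarray:
    """Binary LGE+/- prediction; accepts a single vector or a batch."""
    vectors = np.asarray(vectors, float)
    single = vectors.ndim == 1
    X = vectors[None] if single else vectors
    estimator = model.estimator if isinstance(model, CohortFitResult) else model
    n_expected = estimator.named_steps["impute"].statistics_.shape[0]
    if X.shape[1] != n_expected:
        raise ValueError(f"expected {n_expected} features, got {X.shape[1]}")
    pred = estimator.predict(X).astype(bool)
    return pred[0] if single else pred
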