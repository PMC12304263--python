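"""Supervised evaluation engine and unsupervised PCA exploration.

The supervised design: patients (never individual spectra) are randomly
allocated to a 70% training / 30% testing partition, stratified by class;
the randomisation is repeated ten times. Within each iteration PCA is fitted
on the training spectra only, retaining the smallest number of components
whose cumulative explained variance reaches 95%; four classifiers (SVM, RF,
kNN, LR) are trained on the training scores, optionally characterised by
stratified 10-fold cross-validation on the training set, and evaluated on
the spectra of the held-out patients. Sensitivity, specificity, accuracy and
AUC are aggregated across iterations as mean, SD, t-based confidence
interval and coefficient of variation.

No test-patient spectrum ever enters PCA fitting, cross-validation or
classifier training; per-iteration provenance is recorded so this contract
can be audited structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .spectral_io import SampleRecord

__all__ = [
    "EvalConfig",
    "SplitPlan",
    "PCAModel",
    "PerformanceMetrics",
    "PerformanceSummary",
    "CLASSIFIER_KINDS",
    "make_split_plan",
    "fit_pca",
    "train_classifier",
    "cross_validate",
    "evaluate_model",
    "auc_from_scores",
    "run_supervised_study",
    "unsupervised_pca_scatter",
    "StudyResult",
]

CLASSIFIER_KINDS = ("SVM", "RF", "kNN", "LR")
POSITIVE = "cancer"
NEGATIVE = "control"


@dataclass
class EvalConfig:
    train_frac: float = 0.7
    n_iterations: int = 10
    cv_folds: int = 10
    variance_target: float = 0.95
    classifiers: tuple[str, ...] = CLASSIFIER_KINDS
    hyperparams: dict = field(default_factory=dict)
    master_seed: int = 0
    ci_level: float = 0.95
    run_cv: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifier kind(s): {sorted(unknown)}")


@dataclass
class SplitPlan:
    """Patient-level train/test partitions shared by every dataset."""

    iterations: list[tuple[frozenset, frozenset]]
    seeds: list[int]

    def __iter__(self):
        return iter(self.iterations)


def _stratified_counts(class_counts: dict[str, int], train_frac: float) -> dict[str, int]:
    """Per-class training counts: floors + largest remainders, total = round(f·n)."""
    n = sum(class_counts.values())
    total = int(round(train_frac * n))
    exact = {c: train_frac * k for c, k in class_counts.items()}
    take = {c: int(np.floor(v)) for c, v in exact.items()}
    short = total - sum(take.values())
    # distribute the remainder by descending fractional part, larger class first
    order = sorted(
        class_counts,
        key=lambda c: (exact[c] - take[c], class_counts[c]),
        reverse=True,
    )
    for c in order[:short]:
        take[c] += 1
    return take


def make_split_plan(
    patients: Sequence[SampleRecord], cfg: EvalConfig
) -> SplitPlan:
    """Ten class-stratified random 70/30 patient partitions.

    Deterministic in ``cfg.master_seed``; every class must contribute at
    least 2 patients so both sides of every split contain both classes.
    """
    by_class: dict[str, list[str]] = {}
    seen: set[str] = set()
    for p in patients:
        if p.patient_id in seen:
            continue
        seen.add(p.patient_id)
        by_class.setdefault(p.class_label, []).append(p.patient_id)
    for c, pids in by_class.items():
        if len(pids) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 patients")

    counts = _stratified_counts({c: len(v) for c, v in by_class.items()}, cfg.train_frac)
    ss = np.random.SeedSequence((cfg.master_seed, 101))
    seeds = [int(s % 2**31) for s in ss.generate_state(cfg.n_iterations)]

    iterations = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        train: set[str] = set()
        for c in sorted(by_class):
            pids = sorted(by_class[c])
            chosen = rng.choice(len(pids), size=counts[c], replace=False)
            train.update(pids[i] for i in chosen)
        test = seen - train
        iterations.append((frozenset(train), frozenset(test)))
    return SplitPlan(iterations=iterations, seeds=seeds)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.mean) @ self.loadings.T


def fit_pca(train_matrix: np.ndarray, variance_target: float = 0.95) -> PCAModel:
    """Mean-centred PCA keeping the fewest components reaching the target.

    Raises on a zero-variance (constant) training matrix.
    """
    X = np.asarray(train_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate constant training matrix (zero variance)")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    return PCAModel(
        mean=pca.mean_,
        loadings=pca.components_[:k],
        explained_variance_ratio=pca.explained_variance_ratio_[:k],
        n_components=k,
    )


# ---------------------------------------------------------------------------
# classifiers


def _build_estimator(kind: str, hyperparams: Mapping, seed: int):
    hp = dict(hyperparams.get(kind, {})) if hyperparams else {}
    if kind == "SVM":
        return SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                   gamma=hp.pop("gamma", "scale"), random_state=seed, **hp)
    if kind == "RF":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=seed, **hp,
        )
    if kind == "kNN":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    if kind == "LR":
        return LogisticRegression(C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 2000),
                                  **hp)
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class TrainedModel:
    kind: str
    estimator: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def cancer_score(self, X: np.ndarray) -> np.ndarray:
        """Continuous score increasing with evidence for the cancer class."""
        est = self.estimator
        classes = list(est.classes_)
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, classes.index(POSITIVE)]
        df = est.decision_function(X)
        return df if classes[1] == POSITIVE else -df


def train_classifier(
    kind: str,
    X: np.ndarray,
    y: np.ndarray,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> TrainedModel:
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ValueError("training labels contain a single class")
    if len(y) != np.asarray(X).shape[0]:
        raise ValueError("X rows != len(y)")
    est = _build_estimator(kind, hyperparams or {}, seed)
    est.fit(X, y)
    return TrainedModel(kind=kind, estimator=est)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class PerformanceMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    classifier: str = ""
    iteration: int = -1


def auc_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank (Mann–Whitney) AUC with ties contributing ½.

    Equals the probability a random cancer sample scores above a random
    control sample.
    """
    y = np.asarray(y)
    pos = np.asarray(scores)[y == POSITIVE]
    neg = np.asarray(scores)[y == NEGATIVE]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: need both classes in the test set")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def evaluate_model(
    model: TrainedModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    iteration: int = -1,
) -> PerformanceMetrics:
    """Confusion-matrix metrics (cancer = positive) plus rank AUC."""
    y_test = np.asarray(y_test)
    if len(set(y_test)) < 2:
        raise ValueError("test labels contain a single class; AUC undefined")
    pred = model.predict(X_test)
    tp = int(np.sum((pred == POSITIVE) & (y_test == POSITIVE)))
    fn = int(np.sum((pred == NEGATIVE) & (y_test == POSITIVE)))
    tn = int(np.sum((pred == NEGATIVE) & (y_test == NEGATIVE)))
    fp = int(np.sum((pred == POSITIVE) & (y_test == NEGATIVE)))
    auc = auc_from_scores(model.cancer_score(X_test), y_test)
    return PerformanceMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y_test),
        auc=auc,
        classifier=model.kind,
        iteration=iteration,
    )


def cross_validate(
    kind: str,
    hyperparams: Mapping | None,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int,
) -> list[PerformanceMetrics]:
    """Stratified k-fold CV on the training rows; per-fold metrics."""
    y = np.asarray(y)
    if folds > len(y):
        raise ValueError("more folds than rows")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = train_classifier(kind, X[tr], y[tr], hyperparams, seed)
        out.append(evaluate_model(model, X[te], y[te], iteration=f))
    return out


@dataclass
class PerformanceSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    cv: float
    n: int


def summarize(values: Sequence[float], ci_level: float = 0.95) -> PerformanceSummary:
    """Mean, SD, t-based CI and coefficient of variation across iterations."""
    v = np.asarray(values, dtype=float)
    n = v.size
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n > 1 else 0.0
    if n > 1 and sd > 0:
        half = float(stats.t.ppf(0.5 + ci_level / 2, n - 1) * sd / np.sqrt(n))
    else:
        half = 0.0
    cv = sd / mean if mean != 0 else 0.0
    return PerformanceSummary(mean=mean, sd=sd, ci_low=mean - half,
                              ci_high=mean + half, cv=cv, n=n)


# ---------------------------------------------------------------------------
# the study driver


@dataclass
class IterationProvenance:
    """Row-level audit trail of one train/test iteration for one dataset."""

    train_patients: frozenset
    test_patients: frozenset
    pca_row_patients: frozenset
    train_row_patients: frozenset


@dataclass
class StudyResult:
    plan: SplitPlan
    #: (dataset, classifier) -> list of per-iteration test PerformanceMetrics
    test_metrics: dict[tuple[str, str], list[PerformanceMetrics]]
    #: (dataset, classifier) -> per-iteration lists of CV fold metrics
    cv_metrics: dict[tuple[str, str], list[list[PerformanceMetrics]]]
    #: (dataset, classifier, metric) -> PerformanceSummary over iterations
    summaries: dict[tuple[str, str, str], PerformanceSummary]
    #: dataset -> per-iteration provenance
    provenance: dict[str, list[IterationProvenance]]
    #: dataset -> per-iteration retained PCA component counts
    pca_components: dict[str, list[int]]

    def summary(self, dataset: str, classifier: str, metric: str) -> PerformanceSummary:
        return self.summaries[(dataset, classifier, metric)]


_METRICS = ("sensitivity", "specificity", "accuracy", "auc")


def run_supervised_study(
    datasets: Mapping[str, object],
    cfg: EvalConfig,
    plan: SplitPlan | None = None,
) -> StudyResult:
    """Run the repeated patient-level 70/30 evaluation on every dataset.

    All datasets must share one patient list; a single :class:`SplitPlan`
    drives them so per-iteration comparisons across datasets are paired.
    Datasets may be :class:`~plasmavib.spectral_io.SpectralDataset` or
    :class:`~plasmavib.fuse.FusedDataset` (anything exposing ``matrix``,
    ``class_labels``, ``patient_ids`` and ``rows_for_patients``).
    """
    names = list(datasets)
    if not names:
        raise ValueError("no datasets supplied")
    patient_sets = {n: frozenset(datasets[n].patient_ids) for n in names}
    ref = patient_sets[names[0]]
    for n in names[1:]:
        if patient_sets[n] != ref:
            raise ValueError(f"dataset {n!r} has a different patient list")

    if plan is None:
        records = [
            s for s in datasets[names[0]].samples
        ]
        plan = make_split_plan(records, cfg)

    clf_ss = np.random.SeedSequence((cfg.master_seed, 202))
    clf_seeds = [
        int(s % 2**31)
        for s in clf_ss.generate_state(cfg.n_iterations * len(cfg.classifiers) + 1)
    ]

    test_metrics: dict[tuple[str, str], list[PerformanceMetrics]] = {
        (n, c): [] for n in names for c in cfg.classifiers
    }
    cv_metrics: dict[tuple[str, str], list[list[PerformanceMetrics]]] = {
        (n, c): [] for n in names for c in cfg.classifiers
    }
    provenance: dict[str, list[IterationProvenance]] = {n: [] for n in names}
    pca_components: dict[str, list[int]] = {n: [] for n in names}

    for it, (train_pids, test_pids) in enumerate(plan):
        for n in names:
            ds = datasets[n]
            tr_rows = ds.rows_for_patients(train_pids)
            te_rows = ds.rows_for_patients(test_pids)
            X_tr = ds.matrix[tr_rows]
            y_tr = ds.class_labels[tr_rows]
            X_te = ds.matrix[te_rows]
            y_te = ds.class_labels[te_rows]

            pca = fit_pca(X_tr, cfg.variance_target)
            S_tr = pca.transform(X_tr)
            S_te = pca.transform(X_te)
            pca_components[n].append(pca.n_components)

            row_pids = np.array([s.patient_id for s in ds.samples])
            provenance[n].append(
                IterationProvenance(
                    train_patients=train_pids,
                    test_patients=test_pids,
                    pca_row_patients=frozenset(row_pids[tr_rows]),
                    train_row_patients=frozenset(row_pids[tr_rows]),
                )
            )

            for ci, kind in enumerate(cfg.classifiers):
                seed = clf_seeds[it * len(cfg.classifiers) + ci]
                model = train_classifier(kind, S_tr, y_tr, cfg.hyperparams, seed)
                test_metrics[(n, kind)].append(
                    evaluate_model(model, S_te, y_te, iteration=it)
                )
                if cfg.run_cv:
                    folds = min(cfg.cv_folds, len(y_tr))
                    cv_metrics[(n, kind)].append(
                        cross_validate(kind, cfg.hyperparams, S_tr, y_tr, folds, seed)
                    )

    summaries = {}
    for (n, c), ms in test_metrics.items():
        for metric in _METRICS:
            summaries[(n, c, metric)] = summarize(
                [getattr(m, metric) for m in ms], cfg.ci_level
            )
    return StudyResult(
        plan=plan,
        test_metrics=test_metrics,
        cv_metrics=cv_metrics,
        summaries=summaries,
        provenance=provenance,
        pca_components=pca_components,
    )


# ---------------------------------------------------------------------------
# unsupervised exploration


@dataclass
class GroupEllipse:
    """95% confidence ellipse of a group's PC1/PC2 score cloud."""

    group: str
    center: np.ndarray
    axis_lengths: np.ndarray  # semi-axes, descending
    angle_rad: float
    n: int


def unsupervised_pca_scatter(
    ds, groups: str = "2-class", ci_level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, list[GroupEllipse]]:
    """Label-free PCA of all rows; PC1/PC2 scores with group ellipses.

    ``groups`` selects the colouring only (PCA itself never sees labels):
    ``"2-class"`` uses cancer/control, ``"3-class"`` splits the controls
    into healthy and PCOS. Each ellipse is the χ²₂-scaled eigen-decomposition
    of the group's 2×2 score covariance at the requested level; groups with
    fewer than 3 rows get no ellipse.
    """
    if groups not in ("2-class", "3-class"):
        raise ValueError("groups must be '2-class' or '3-class'")
    labels = ds.class_labels if groups == "2-class" else ds.groups

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(np.asarray(ds.matrix, dtype=float))

    q = stats.chi2.ppf(ci_level, df=2)
    ellipses = []
    for g in sorted(set(labels)):
        pts = scores[labels == g]
        if pts.shape[0] < 3:
            continue
        cov = np.cov(pts, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        ellipses.append(
            GroupEllipse(
                group=str(g),
                center=pts.mean(axis=0),
                axis_lengths=np.sqrt(np.clip(evals, 0, None) * q),
                angle_rad=float(np.arctan2(evecs[1, 0], evecs[0, 0])),
                n=pts.shape[0],
            )
        )
    return scores, labels, ellipses
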