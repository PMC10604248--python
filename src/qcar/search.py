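"""Two-phase random combination search over pretreatment × classifier space.

Each candidate combination pairs a :class:`~qcar.pretreatment.PretreatmentParams`
setting with one of five classifier families (SVM, random forest, gradient
boosting, decision tree, k-NN) and a hyperparameter assignment from that
family's grid.  A combination is scored by the Matthews correlation of its
predictions on a stratified held-out split (MCC_pred); a coarse random sample
of the full Cartesian space is followed by a refined sample restricted to the
best-performing (family, pretreatment) cells, and the winner is refitted on
the full dataset.  Robustness is characterised afterwards by repeated
stratified k-fold cross-validation (MCC_CV), never during selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import CompositionTable
from .exceptions import (
    ClassDegeneracyError,
    EmptyFeatureError,
    ParameterError,
)
from .pretreatment import (
    FittedTransform,
    PretreatmentParams,
    apply_pretreatment,
    binarize_activity,
)

FAMILIES = ("svm", "random_forest", "gradient_boosting", "decision_tree", "knn")

#: Default per-family hyperparameter grids — standard small-data grids,
#: fully configurable through :class:`SearchSpace`.
DEFAULT_GRIDS: dict[str, dict[str, tuple]] = {
    "svm": {
        "C": (0.1, 1.0, 10.0, 100.0),
        "kernel": ("linear", "rbf"),
        "gamma": ("scale", 0.01, 0.1),
    },
    "random_forest": {
        "n_estimators": (50, 100, 300),
        "max_depth": (None, 3, 5),
        "min_samples_leaf": (1, 3),
    },
    "gradient_boosting": {
        "n_estimators": (50, 100, 300),
        "learning_rate": (0.05, 0.1, 0.3),
        "max_depth": (2, 3),
    },
    "decision_tree": {
        "max_depth": (None, 3, 5, 8),
        "min_samples_leaf": (1, 3, 5),
    },
    "knn": {
        "n_neighbors": (3, 5, 7, 9),
        "weights": ("uniform", "distance"),
    },
}

DEFAULT_THRESHOLDS = (0.1, 0.25, 0.5, 1.0)
DEFAULT_N_LEVELS = (0, 1, 2, 3, 4)
DEFAULT_SCALING = (False, True)
DEFAULT_PCA_LEVELS = (None, 0.60, 0.70, 0.80, 0.90, 0.99)


def _sortable(v) -> tuple:
    # mixed None/str/number grid values need a total order for determinism
    if v is None:
        return (0, "", 0.0)
    if isinstance(v, bool):
        return (1, "", float(v))
    if isinstance(v, (int, float)):
        return (1, "", float(v))
    return (2, str(v), 0.0)


@dataclass(frozen=True)
class Combination:
    """One sampled point: pretreatment setting + family + hyperparameters."""

    params: PretreatmentParams
    family: str
    hyper: tuple[tuple[str, object], ...]  # sorted (name, value) pairs

    def hyper_dict(self) -> dict:
        return dict(self.hyper)

    def sort_key(self) -> tuple:
        return (
            self.params.sort_key(),
            self.family,
            tuple((k, _sortable(v)) for k, v in self.hyper),
        )

    def describe(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in self.hyper)
        p = self.params
        pca = "none" if p.pca_level is None else f"{p.pca_level:.2f}"
        return (
            f"{self.family}({hp}) | threshold={p.threshold}, "
            f"n_level={p.n_level}, scaling={'on' if p.scaling else 'off'}, "
            f"pca={pca}"
        )


@dataclass
class SearchSpace:
    """The Cartesian search space of pretreatment and classifier settings."""

    grids: dict[str, dict[str, tuple]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRIDS.items()}
    )
    thresholds: tuple = DEFAULT_THRESHOLDS
    n_levels: tuple = DEFAULT_N_LEVELS
    scaling_flags: tuple = DEFAULT_SCALING
    pca_levels: tuple = DEFAULT_PCA_LEVELS
    split_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ParameterError(
                f"split_fraction must be in (0, 1), got {self.split_fraction}"
            )
        unknown = set(self.grids) - set(FAMILIES)
        if unknown:
            raise ParameterError(f"unknown families: {sorted(unknown)}")
        for fam, grid in self.grids.items():
            if not grid or any(len(vs) == 0 for vs in grid.values()):
                raise ParameterError(f"empty hyperparameter grid for {fam}")
        for name in ("thresholds", "n_levels", "scaling_flags", "pca_levels"):
            if len(getattr(self, name)) == 0:
                raise ParameterError(f"empty candidate list: {name}")

    # -- enumeration -------------------------------------------------------
    def pretreatments(self) -> list[PretreatmentParams]:
        out = [
            PretreatmentParams(t, n, s, p)
            for t in self.thresholds
            for n in self.n_levels
            for s in self.scaling_flags
            for p in self.pca_levels
        ]
        return sorted(out, key=PretreatmentParams.sort_key)

    def family_configs(self) -> list[tuple[str, tuple]]:
        """All (family, hyper) assignments in deterministic order."""
        out: list[tuple[str, tuple]] = []
        for fam in sorted(self.grids):
            grid = self.grids[fam]
            names = sorted(grid)
            pools = [grid[n] for n in names]
            idx = [0] * len(pools)
            while True:
                hyper = tuple(
                    (n, pool[i]) for n, pool, i in zip(names, pools, idx)
                )
                out.append((fam, hyper))
                for j in range(len(pools) - 1, -1, -1):
                    idx[j] += 1
                    if idx[j] < len(pools[j]):
                        break
                    idx[j] = 0
                else:
                    break
        return out

    def size(self) -> int:
        return len(self.pretreatments()) * len(self.family_configs())

    @classmethod
    def from_yaml(cls, path) -> "SearchSpace":
        import yaml
        from pathlib import Path

        payload = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "grids" in payload:
            kwargs["grids"] = {
                fam: {k: tuple(v) for k, v in grid.items()}
                for fam, grid in payload["grids"].items()
            }
        for name in ("thresholds", "n_levels", "scaling_flags", "pca_levels"):
            if name in payload:
                kwargs[name] = tuple(payload[name])
        if "split_fraction" in payload:
            kwargs["split_fraction"] = float(payload["split_fraction"])
        return cls(**kwargs)


@dataclass
class SearchResult:
    """Metrics of one evaluated combination on its held-out split."""

    combination: Combination
    mcc_pred: float
    acc: float
    f1: float
    nmcc_pred: float
    phase: str
    class_counts: tuple[int, int]  # (inactive, active) after thresholding
    n_features: int = 0
    reason: str | None = None  # set on sentinel (degenerate) results

    @property
    def is_sentinel(self) -> bool:
        return self.reason is not None


@dataclass
class FinalModel:
    """The chosen combination refitted on the full dataset."""

    combination: Combination
    transform: FittedTransform
    classifier: object
    labels: np.ndarray
    train_acc: float
    train_f1: float
    train_mcc: float
    train_nmcc: float
    component_names: list[str]
    assay: str | None = None
    mcc_cv: float | None = None
    nmcc_cv: float | None = None

    def predict(self, X: CompositionTable | np.ndarray) -> np.ndarray:
        return self.classifier.predict(self.transform.transform(X))

    def predict_proba_active(
        self, X: CompositionTable | np.ndarray
    ) -> np.ndarray:
        """P(active) per row; decision-function fallback via logistic map."""
        M = self.transform.transform(X)
        clf = self.classifier
        try:
            proba = clf.predict_proba(M)
        except (AttributeError, TypeError):
            score = clf.decision_function(M)
            return 1.0 / (1.0 + np.exp(-score))
        col = list(clf.classes_).index(1)
        return proba[:, col]


def build_classifier(
    family: str, hyper: dict, seed: int, needs_proba: bool = False
):
    """Instantiate a seeded scikit-learn classifier for one family.

    ``needs_proba`` is advisory: SVMs serve probabilities through a logistic
    map of their decision function (see
    :meth:`FinalModel.predict_proba_active`), so no per-family switch is
    needed here.
    """
    if family == "svm":
        return SVC(random_state=seed, **hyper)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hyper)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hyper)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hyper)
    if family == "knn":
        return KNeighborsClassifier(**hyper)
    raise ParameterError(f"unknown classifier family {family!r}")


def stratified_split(
    labels: np.ndarray, split_fraction: float = 0.80, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test indices; test size = ceil(n·(1 − fraction))."""
    labels = np.asarray(labels)
    if not 0.0 < split_fraction < 1.0:
        raise ParameterError(
            f"split_fraction must be in (0, 1), got {split_fraction}"
        )
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassDegeneracyError("stratified split needs both classes")
    if counts.min() < 2:
        raise ClassDegeneracyError(
            "each class needs ≥ 2 members for a stratified split"
        )
    n = len(labels)
    test_size = math.ceil(n * (1.0 - split_fraction))
    train_idx, test_idx = train_test_split(
        np.arange(n),
        test_size=test_size,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    return np.sort(train_idx), np.sort(test_idx)


def confusion_metrics(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> tuple[float, float, float, float]:
    """(ACC, F1, MCC, nMCC) of a binary prediction.

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as 0
    when any denominator factor vanishes; F1 = 2TP/(2TP+FP+FN), 0 when the
    denominator vanishes; nMCC = (MCC + 1)/2 rescales [−1, 1] to [0, 1].
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ParameterError("need equal-length non-empty label vectors")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    f1_den = 2 * tp + fp + fn
    f1 = 2 * tp / f1_den if f1_den > 0 else 0.0
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den > 0 else 0.0
    return acc, f1, mcc, (mcc + 1.0) / 2.0


def sample_combinations(
    space: SearchSpace,
    budget: int,
    seed: int = 0,
    restrict_to: Iterable[tuple[str, PretreatmentParams]] | None = None,
) -> list[Combination]:
    """Uniform sample without replacement from the (restricted) space.

    ``restrict_to`` limits sampling to given (family, pretreatment) cells,
    hyperparameters remaining free.  A budget at or above the space size
    enumerates it exhaustively.
    """
    if budget < 1:
        raise ParameterError(f"budget must be ≥ 1, got {budget}")
    pres = space.pretreatments()
    configs = space.family_configs()
    if restrict_to is not None:
        allowed = set(restrict_to)
        pool = [
            Combination(p, fam, hyper)
            for p in pres
            for fam, hyper in configs
            if (fam, p) in allowed
        ]
    else:
        pool = [
            Combination(p, fam, hyper) for p in pres for fam, hyper in configs
        ]
    if not pool:
        raise ParameterError("restricted search space is empty")
    if budget >= len(pool):
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=budget, replace=False)
    return [pool[i] for i in sorted(idx)]


def evaluate_combination(
    X: CompositionTable,
    y_values: np.ndarray,
    censored: np.ndarray,
    combination: Combination,
    split_seed: int = 0,
    split_fraction: float = 0.80,
    phase: str = "coarse",
    assay: str | None = None,
) -> SearchResult:
    """Score one combination on a stratified held-out split.

    Degenerate cases (single-class labels, empty features after filtering,
    single-class training split) never raise: they return a sentinel result
    with ``mcc_pred = −1`` and a reason code, so the search can rank past
    them.
    """
    labels = binarize_activity(y_values, censored, combination.params.threshold)
    counts = (int(np.sum(labels == 0)), int(np.sum(labels == 1)))

    def sentinel(reason: str) -> SearchResult:
        return SearchResult(
            combination=combination,
            mcc_pred=-1.0, acc=0.0, f1=0.0, nmcc_pred=0.0,
            phase=phase, class_counts=counts, reason=reason,
        )

    if min(counts) < 2:
        return sentinel("single_class")
    try:
        train_idx, test_idx = stratified_split(
            labels, split_fraction, seed=split_seed
        )
        train, test, ft = apply_pretreatment(
            X, y_values, censored, combination.params,
            train_idx, test_idx, assay=assay,
        )
    except ClassDegeneracyError:
        return sentinel("class_degeneracy")
    except EmptyFeatureError:
        return sentinel("empty_features")
    clf = build_classifier(
        combination.family, combination.hyper_dict(), seed=split_seed
    )
    clf.fit(train.X, train.y)
    acc, f1, mcc, nmcc = confusion_metrics(test.y, clf.predict(test.X))
    return SearchResult(
        combination=combination,
        mcc_pred=mcc, acc=acc, f1=f1, nmcc_pred=nmcc,
        phase=phase, class_counts=counts,
        n_features=ft.n_features_out,
    )


def _rank_key(r: SearchResult) -> tuple:
    # maximise MCC_pred; break ties toward fewer features, then the
    # lexicographically smallest combination — deterministic and
    # parsimony-favouring
    return (-r.mcc_pred, r.n_features, r.combination.sort_key())


@dataclass
class SearchOutcome:
    """Full log of a two-phase search plus the chosen combination."""

    results: list[SearchResult]
    chosen: Combination
    best: SearchResult

    def ranked(self) -> list[SearchResult]:
        return sorted(self.results, key=_rank_key)


def run_search(
    X: CompositionTable,
    y_values: np.ndarray,
    censored: np.ndarray,
    space: SearchSpace | None = None,
    coarse_budget: int = 100,
    refined_budget: int = 1000,
    seed: int = 0,
    top_fraction: float = 0.25,
    assay: str | None = None,
) -> SearchOutcome:
    """Two-phase random combination search selected by MCC_pred.

    Phase 1 samples ``coarse_budget`` combinations from the full space; the
    top ``top_fraction`` of (family, pretreatment) cells by best coarse
    MCC_pred survive, and phase 2 samples ``refined_budget`` combinations
    restricted to them (skipping already-evaluated points).  The final
    choice is the MCC_pred argmax over both phases; sentinels are never
    chosen while a non-sentinel exists.  Deterministic given (data, space,
    seed); one stratified split seed (the run seed) is shared by every
    evaluation — a single 80:20 division of the panel, re-stratified per
    threshold because the labels change.
    """
    if coarse_budget < 1 or refined_budget < 1:
        raise ParameterError("budgets must be ≥ 1")
    space = space or SearchSpace()
    results: list[SearchResult] = []
    coarse = sample_combinations(space, coarse_budget, seed=seed)
    for comb in coarse:
        results.append(
            evaluate_combination(
                X, y_values, censored, comb,
                split_seed=seed, split_fraction=space.split_fraction,
                phase="coarse", assay=assay,
            )
        )
    # survivors: best coarse MCC_pred per (family, pretreatment) cell
    cell_best: dict[tuple[str, PretreatmentParams], float] = {}
    for r in results:
        key = (r.combination.family, r.combination.params)
        cell_best[key] = max(cell_best.get(key, -np.inf), r.mcc_pred)
    n_keep = max(1, math.ceil(top_fraction * len(cell_best)))
    survivors = sorted(
        cell_best,
        key=lambda k: (-cell_best[k], k[0], k[1].sort_key()),
    )[:n_keep]
    seen = {r.combination for r in results}
    refined = sample_combinations(
        space, refined_budget, seed=seed + 1, restrict_to=survivors
    )
    for comb in refined:
        if comb in seen:
            continue
        results.append(
            evaluate_combination(
                X, y_values, censored, comb,
                split_seed=seed, split_fraction=space.split_fraction,
                phase="refined", assay=assay,
            )
        )
    non_sentinel = [r for r in results if not r.is_sentinel]
    pool = non_sentinel if non_sentinel else results
    best = min(pool, key=_rank_key)
    return SearchOutcome(results=results, chosen=best.combination, best=best)


def finalize_model(
    X: CompositionTable,
    y_values: np.ndarray,
    censored: np.ndarray,
    combination: Combination,
    seed: int = 0,
    assay: str | None = None,
) -> FinalModel:
    """Refit the chosen combination on the full dataset.

    Pretreatment statistics and the classifier are refitted on all rows;
    training-set confusion metrics are reported.  Class degeneracy on the
    full data is fatal here (there is nothing to rank past).
    """
    n = X.n_oils
    all_idx = np.arange(n)
    train, _, ft = apply_pretreatment(
        X, y_values, censored, combination.params,
        all_idx, apply_index=np.empty(0, dtype=int), assay=assay,
    )
    clf = build_classifier(
        combination.family, combination.hyper_dict(), seed=seed,
        needs_proba=True,
    )
    clf.fit(train.X, train.y)
    acc, f1, mcc, nmcc = confusion_metrics(train.y, clf.predict(train.X))
    return FinalModel(
        combination=combination,
        transform=ft,
        classifier=clf,
        labels=train.y,
        train_acc=acc, train_f1=f1, train_mcc=mcc, train_nmcc=nmcc,
        component_names=list(X.component_names),
        assay=assay,
    )


def repeated_cv(
    X: CompositionTable,
    y_values: np.ndarray,
    censored: np.ndarray,
    combination: Combination,
    k: int = 5,
    iterations: int = 50,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Mean MCC over repeated stratified k-fold cross-validation.

    Each iteration draws a freshly seeded stratified k-fold partition,
    refits pretreatment inside every training fold, and computes the MCC of
    the pooled out-of-fold predictions.  Returns the mean and the
    per-iteration vector.
    """
    if k < 2 or iterations < 1:
        raise ParameterError("need k ≥ 2 and iterations ≥ 1")
    labels = binarize_activity(y_values, censored, combination.params.threshold)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClassDegeneracyError("repeated CV needs both classes")
    if counts.min() < k:
        raise ParameterError(
            f"smallest class ({counts.min()}) is below k={k}"
        )
    per_iter = np.empty(iterations)
    for it in range(iterations):
        it_seed = seed + 1000 * it
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=it_seed)
        oof = np.empty(len(labels), dtype=int)
        for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
            train, test, _ = apply_pretreatment(
                X, y_values, censored, combination.params,
                train_idx, test_idx,
            )
            clf = build_classifier(
                combination.family, combination.hyper_dict(), seed=it_seed,
            )
            clf.fit(train.X, train.y)
            oof[test_idx] = clf.predict(test.X)
        _, _, mcc, _ = confusion_metrics(labels, oof)
        per_iter[it] = mcc
    return float(per_iter.mean()), per_iter
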