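"""Dataset pretreatment: activity thresholding, rare-component filtering,
min–max scaling and PCA variance retention.

The four pretreatment parameters (threshold, n-level, scaling, PCA level)
turn a composition/EC50 pair into a model-ready binary classification
dataset.  All fitted statistics — occurrence counts, per-component min/max,
the PCA basis — are computed on training rows only and then applied to
held-out rows, so selection by predictive MCC is not optimistically biased
by leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .dataset import CompositionTable, LabeledDataset
from .exceptions import ClassDegeneracyError, EmptyFeatureError, ParameterError

#: Admissible PCA explained-variance settings (None = no PCA).
PCA_LEVELS = (None, 0.60, 0.70, 0.80, 0.90, 0.99)

#: Admissible n-level settings (0 = keep all components).
N_LEVELS = (0, 1, 2, 3, 4)


@dataclass(frozen=True)
class PretreatmentParams:
    """One pretreatment setting.

    threshold
        EC50 cut-off in μg/mL; oils at or below it (uncensored) are active.
    n_level
        Components occurring in ≤ n_level training oils are dropped (0: none).
    scaling
        Min–max scale each component to [0, 1] on the training rows.
    pca_level
        Retain the fewest PCA axes reaching this explained-variance fraction
        (None: no PCA).
    """

    threshold: float
    n_level: int = 0
    scaling: bool = False
    pca_level: float | None = None

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ParameterError(f"threshold must be > 0, got {self.threshold}")
        if self.n_level not in N_LEVELS:
            raise ParameterError(
                f"n_level must be in {N_LEVELS}, got {self.n_level}"
            )
        if self.pca_level is not None and self.pca_level not in PCA_LEVELS:
            raise ParameterError(
                f"pca_level must be in {PCA_LEVELS}, got {self.pca_level}"
            )

    def sort_key(self) -> tuple:
        return (
            self.threshold,
            self.n_level,
            self.scaling,
            -1.0 if self.pca_level is None else self.pca_level,
        )


def binarize_activity(
    values: np.ndarray, censored: np.ndarray, threshold: float
) -> np.ndarray:
    """Label oils active (1) iff uncensored and EC50 ≤ threshold.

    Censored records ("EC50 > limit") are always inactive: their true value
    exceeds the limit, hence any threshold at or below it.
    """
    if threshold <= 0:
        raise ParameterError(f"threshold must be > 0, got {threshold}")
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if np.any(values <= 0):
        raise ParameterError("EC50 values must be positive")
    return ((values <= threshold) & ~censored).astype(int)


def occurrence_counts(X: np.ndarray) -> np.ndarray:
    """Per-component count of strictly positive entries (a trace counts)."""
    return (np.asarray(X) > 0).sum(axis=0)


def filter_rare_components(
    X: CompositionTable, n_level: int
) -> CompositionTable:
    """Drop components present in ≤ ``n_level`` oils of the table."""
    if n_level not in N_LEVELS:
        raise ParameterError(f"n_level must be in {N_LEVELS}, got {n_level}")
    keep = occurrence_counts(X.values) > n_level
    if not keep.any():
        raise EmptyFeatureError(
            f"n_level={n_level} removed every component"
        )
    names = [n for n, k in zip(X.component_names, keep) if k]
    return X.subset_components(names)


def scale_minmax(
    X_train: np.ndarray, X_apply: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component (x − min)/(max − min) using training statistics.

    Constant training components map to 0; applied rows may fall outside
    [0, 1] and are deliberately not clipped.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_apply = np.asarray(X_apply, dtype=float)
    mins = X_train.min(axis=0)
    maxs = X_train.max(axis=0)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    train_s = np.where(span > 0, (X_train - mins) / safe, 0.0)
    apply_s = np.where(span > 0, (X_apply - mins) / safe, 0.0)
    return train_s, apply_s


def n_axes_for_level(explained_ratio: np.ndarray, level: float) -> int:
    """Smallest leading-axis count with cumulative explained variance ≥ level."""
    cum = np.cumsum(explained_ratio)
    cum[-1] = max(cum[-1], 1.0)  # guard rounding: full basis explains all
    return int(np.searchsorted(cum, level - 1e-12) + 1)


def pca_reduce(
    X_train: np.ndarray, X_apply: np.ndarray, level: float
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Centered PCA fitted on training rows; minimal axes reaching ``level``."""
    if not 0.0 < level <= 1.0:
        raise ParameterError(f"pca level must be in (0, 1], got {level}")
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ParameterError("PCA needs ≥ 2 training rows")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X_train)
    k = n_axes_for_level(pca.explained_variance_ratio_, level)
    train_r = pca.transform(X_train)[:, :k]
    apply_r = pca.transform(np.asarray(X_apply, dtype=float))[:, :k]
    return train_r, apply_r, pca


@dataclass
class FittedTransform:
    """Training-fitted pretreatment state, applicable to unseen rows.

    Holds the surviving component names, min–max statistics (when scaling)
    and the PCA basis with its retained-axis count (when PCA), in original
    component space so new oils can be transformed without refitting.
    """

    params: PretreatmentParams
    input_components: list[str]
    kept_components: list[str]
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None
    pca: PCA | None = None
    n_axes: int | None = None

    @property
    def n_features_out(self) -> int:
        if self.pca is not None:
            return int(self.n_axes)
        return len(self.kept_components)

    def transform(self, X: CompositionTable | np.ndarray) -> np.ndarray:
        """Apply the fitted pipeline to rows in original component space."""
        if isinstance(X, CompositionTable):
            missing = set(self.input_components) - set(X.component_names)
            if missing:
                raise ParameterError(
                    f"table lacks fitted components: {sorted(missing)[:5]}"
                )
            M = X.subset_components(self.kept_components).values
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] == len(self.input_components):
                idx = [self.input_components.index(c) for c in self.kept_components]
                M = M[:, idx]
            elif M.shape[1] != len(self.kept_components):
                raise ParameterError(
                    f"expected {len(self.input_components)} or "
                    f"{len(self.kept_components)} columns, got {M.shape[1]}"
                )
        if self.mins is not None:
            span = self.maxs - self.mins
            safe = np.where(span > 0, span, 1.0)
            M = np.where(span > 0, (M - self.mins) / safe, 0.0)
        if self.pca is not None:
            M = self.pca.transform(M)[:, : self.n_axes]
        return M


def fit_pretreatment(
    X: CompositionTable, train_index: Sequence[int], params: PretreatmentParams
) -> FittedTransform:
    """Fit filtering/scaling/PCA statistics on the training rows only."""
    train_rows = X.values[np.asarray(train_index, dtype=int)]
    keep = occurrence_counts(train_rows) > params.n_level
    if not keep.any():
        raise EmptyFeatureError(
            f"n_level={params.n_level} removed every component "
            "on the training rows"
        )
    kept_names = [n for n, k in zip(X.component_names, keep) if k]
    M = train_rows[:, keep]
    ft = FittedTransform(
        params=params,
        input_components=list(X.component_names),
        kept_components=kept_names,
    )
    if params.scaling:
        ft.mins = M.min(axis=0)
        ft.maxs = M.max(axis=0)
        span = ft.maxs - ft.mins
        safe = np.where(span > 0, span, 1.0)
        M = np.where(span > 0, (M - ft.mins) / safe, 0.0)
    if params.pca_level is not None:
        pca = PCA(n_components=None, svd_solver="full")
        pca.fit(M)
        ft.pca = pca
        ft.n_axes = n_axes_for_level(
            pca.explained_variance_ratio_, params.pca_level
        )
    return ft


def apply_pretreatment(
    X: CompositionTable,
    y_values: np.ndarray,
    censored: np.ndarray,
    params: PretreatmentParams,
    train_index: Sequence[int],
    apply_index: Sequence[int] | None = None,
    assay: str | None = None,
) -> tuple[LabeledDataset, LabeledDataset, FittedTransform]:
    """Full pipeline: binarize → filter rare → scale → PCA, train-fitted.

    Returns the transformed training split, the transformed apply split
    (the complement of ``train_index`` unless given) and the fitted state.
    A single-class training split raises :class:`ClassDegeneracyError`
    (callers in the model search catch it as a sentinel, not a failure).
    """
    train_index = np.asarray(train_index, dtype=int)
    if apply_index is None:
        apply_index = np.setdiff1d(np.arange(X.n_oils), train_index)
    apply_index = np.asarray(apply_index, dtype=int)
    y = binarize_activity(y_values, censored, params.threshold)
    if len(set(y[train_index].tolist())) < 2:
        raise ClassDegeneracyError(
            "training split has a single activity class at threshold "
            f"{params.threshold}"
        )
    ft = fit_pretreatment(X, train_index, params)
    oil_ids = np.asarray(X.oil_ids)
    names = (
        [f"pc_{i + 1}" for i in range(ft.n_features_out)]
        if ft.pca is not None
        else list(ft.kept_components)
    )
    train = LabeledDataset(
        X=ft.transform(X.values[train_index]),
        y=y[train_index],
        feature_names=names,
        oil_ids=list(oil_ids[train_index]),
        threshold_used=params.threshold,
        assay=assay,
    )
    apply = LabeledDataset(
        X=ft.transform(X.values[apply_index]) if len(apply_index) else
        np.empty((0, ft.n_features_out)),
        y=y[apply_index],
        feature_names=names,
        oil_ids=list(oil_ids[apply_index]),
        threshold_used=params.threshold,
        assay=assay,
    )
    return train, apply, ft
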