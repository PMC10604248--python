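"""Model-agnostic interpretation: permutation feature importance, partial
dependence, Spearman weighting and the weighted-feature-importance (WFI)
contributor report.

All quantities are computed per chemical component in the original
composition space, even when the final model was fitted on principal axes:
forced or permuted component values pass through the model's fitted
pretreatment before prediction, so the report always names chemical
components, not abstract axes.

The sign convention follows the activity labels: a component whose growing
percentage raises the predicted active-class probability (rising partial
dependence, positive Spearman rho) is a positive contributor to antioxidant
potency, and WFI = FI × rho carries that sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CompositionTable
from .exceptions import ParameterError
from .search import FinalModel, confusion_metrics

#: |rho| below this is reported as a neutral sign (flat dependence).
NEUTRAL_RHO = 0.1


@dataclass
class PdCurve:
    """Partial-dependence curve of one component.

    ``pd[i]`` is the mean predicted active-class probability over all oils
    with the component's percentage forced to ``grid[i]``; the grid spans 0
    to the component's observed maximum.
    """

    component: str
    grid: np.ndarray
    pd: np.ndarray


@dataclass
class ComponentReport:
    """One component's contribution summary: FI, rho, WFI = FI × rho, sign."""

    component: str
    fi: float
    rho: float
    wfi: float
    sign: str  # positive | negative | neutral


def _as_matrix(model: FinalModel, X: CompositionTable | np.ndarray) -> np.ndarray:
    if isinstance(X, CompositionTable):
        order = model.component_names
        missing = set(order) - set(X.component_names)
        if missing:
            raise ParameterError(
                f"table lacks model components: {sorted(missing)[:5]}"
            )
        return X.subset_components(order).values
    M = np.asarray(X, dtype=float)
    if M.shape[1] != len(model.component_names):
        raise ParameterError(
            f"expected {len(model.component_names)} columns, got {M.shape[1]}"
        )
    return M


def feature_importance(
    model: FinalModel,
    X: CompositionTable | np.ndarray,
    n_repeats: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Permutation importance per component, normalised to sum 1.

    For each component the column is shuffled ``n_repeats`` times and the
    mean decrease in training-label MCC recorded; negative raw decreases are
    floored at 0.  A model that ignores every component yields an all-zero
    vector with a warning.
    """
    M = _as_matrix(model, X)
    y = model.labels
    if len(y) != M.shape[0]:
        raise ParameterError("X rows do not match the model's fitted labels")
    rng = np.random.default_rng(seed)
    _, _, base_mcc, _ = confusion_metrics(y, model.predict(M))
    raw = np.zeros(M.shape[1])
    for j in range(M.shape[1]):
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            Mp = M.copy()
            Mp[:, j] = rng.permutation(Mp[:, j])
            _, _, mcc, _ = confusion_metrics(y, model.predict(Mp))
            drops[r] = base_mcc - mcc
        raw[j] = max(drops.mean(), 0.0)
    total = raw.sum()
    if total <= 0:
        warnings.warn(
            "model shows zero permutation importance for every component",
            stacklevel=2,
        )
        return raw
    return raw / total


def partial_dependence(
    model: FinalModel,
    X: CompositionTable | np.ndarray,
    component: str,
    n_grid: int = 20,
) -> PdCurve:
    """Mean predicted active probability as one component is forced along a grid.

    The grid is ``n_grid`` evenly spaced percentages from 0 to the observed
    maximum of the component; a component never observed above 0 yields a
    single-point curve with a warning.
    """
    M = _as_matrix(model, X)
    try:
        j = model.component_names.index(component)
    except ValueError:
        raise ParameterError(f"unknown component {component!r}") from None
    vmax = M[:, j].max()
    if vmax <= 0:
        warnings.warn(
            f"component {component!r} is constant at 0; single-point curve",
            stacklevel=2,
        )
        grid = np.array([0.0])
    else:
        grid = np.linspace(0.0, vmax, n_grid)
    pd_vals = np.empty(len(grid))
    for i, v in enumerate(grid):
        Mf = M.copy()
        Mf[:, j] = v
        pd_vals[i] = model.predict_proba_active(Mf).mean()
    return PdCurve(component=component, grid=grid, pd=pd_vals)


def spearman_weight(curve: PdCurve) -> float:
    """Spearman rank correlation between the PD grid and the PD values.

    Flat or single-point curves give rho = 0 (with a warning): no monotone
    association to weight the importance by.
    """
    if len(curve.grid) < 3 or np.ptp(curve.pd) < 1e-12:
        warnings.warn(
            f"degenerate PD curve for {curve.component!r}; rho set to 0",
            stacklevel=2,
        )
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(curve.grid, curve.pd).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def spearman_weight_samples(
    model: FinalModel, X: CompositionTable | np.ndarray, component: str
) -> float:
    """Alternative rho: observed percentages vs per-sample PD predictions.

    Correlates each oil's raw percentage of the component with the model's
    predicted active probability when the component is forced to that oil's
    own value in every row — the per-sample reading of the same weighting
    idea (grid form is the default elsewhere).
    """
    M = _as_matrix(model, X)
    j = model.component_names.index(component)
    values = M[:, j]
    if np.ptp(values) < 1e-12:
        return 0.0
    per_sample = np.empty(len(values))
    for i, v in enumerate(values):
        Mf = M.copy()
        Mf[:, j] = v
        per_sample[i] = model.predict_proba_active(Mf).mean()
    if np.ptp(per_sample) < 1e-12:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(values, per_sample).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _sign(wfi: float, rho: float) -> str:
    if abs(rho) < NEUTRAL_RHO:
        return "neutral"
    return "positive" if wfi > 0 else "negative"


def component_report(
    model: FinalModel,
    X: CompositionTable | np.ndarray,
    top_k: int | None = 20,
    n_grid: int = 20,
    n_repeats: int = 20,
    seed: int = 0,
) -> list[ComponentReport]:
    """Per-component FI/rho/WFI report, sorted by |WFI| descending.

    ``top_k`` limits the returned list (None returns every component); the
    top-20 convention matches how contributor lists are usually read.
    """
    fi = feature_importance(model, X, n_repeats=n_repeats, seed=seed)
    reports: list[ComponentReport] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(model.component_names):
            curve = partial_dependence(model, X, name, n_grid=n_grid)
            rho = spearman_weight(curve)
            wfi = fi[j] * rho
            reports.append(
                ComponentReport(
                    component=name, fi=float(fi[j]), rho=rho,
                    wfi=float(wfi), sign=_sign(wfi, rho),
                )
            )
    reports.sort(key=lambda r: (-abs(r.wfi), -r.fi, r.component))
    return reports if top_k is None else reports[:top_k]
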