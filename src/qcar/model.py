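"""Statsmodels-style entry point: a model object built from data whose
``fit()`` returns a results object with estimates, diagnostics and summary.

    >>> from qcar import QcarModel, synthetic
    >>> spec = synthetic.GeneratorSpec(driver_set=[(2, -0.04), (0, 0.04)], seed=7)
    >>> comps, records = synthetic.generate_dataset(spec)
    >>> res = QcarModel(comps, records, assay="dpph").fit(seed=7)
    >>> print(res.summary())          # doctest: +SKIP

The heavy lifting lives in :mod:`qcar.search`, :mod:`qcar.pretreatment` and
:mod:`qcar.interpret`; this module only arranges those pieces the way a
modelling session uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import interpret as _interpret
from .dataset import (
    ActivityRecord,
    CompositionTable,
    align,
    read_activity,
    read_composition,
)
from .exceptions import ParameterError
from .search import (
    FinalModel,
    SearchOutcome,
    SearchSpace,
    finalize_model,
    repeated_cv,
    run_search,
)


class QcarModel:
    """Quantitative composition–activity relationship model.

    Parameters
    ----------
    compositions
        Oils × components percentage table.
    activities
        Long-form activity records (one per oil × assay).
    assay
        Which assay's potencies to model (see :data:`qcar.dataset.ASSAYS`).
    search_space
        Candidate pretreatments and classifier grids; defaults to the
        package's standard small-data space.
    """

    def __init__(
        self,
        compositions: CompositionTable,
        activities: Sequence[ActivityRecord],
        assay: str,
        search_space: SearchSpace | None = None,
    ) -> None:
        self.assay = assay
        self.search_space = search_space or SearchSpace()
        self.compositions, self.y_values, self.censored = align(
            compositions, activities, assay
        )
        self.nobs = self.compositions.n_oils

    @classmethod
    def from_csv(
        cls,
        composition_path: str | Path,
        activity_path: str | Path,
        assay: str,
        search_space: SearchSpace | None = None,
    ) -> "QcarModel":
        return cls(
            read_composition(composition_path),
            read_activity(activity_path),
            assay,
            search_space=search_space,
        )

    def fit(
        self,
        coarse_budget: int = 100,
        refined_budget: int = 1000,
        seed: int = 0,
        cv_iterations: int = 50,
        cv_folds: int = 5,
    ) -> "QcarResults":
        """Run the two-phase search, refit the winner, characterise robustness.

        ``cv_iterations=0`` skips the repeated cross-validation (it can be
        run later via :meth:`QcarResults.repeated_cv`).
        """
        outcome = run_search(
            self.compositions, self.y_values, self.censored,
            space=self.search_space,
            coarse_budget=coarse_budget, refined_budget=refined_budget,
            seed=seed, assay=self.assay,
        )
        final = finalize_model(
            self.compositions, self.y_values, self.censored,
            outcome.chosen, seed=seed, assay=self.assay,
        )
        res = QcarResults(model=self, search=outcome, final=final, seed=seed)
        if cv_iterations > 0:
            res.repeated_cv(iterations=cv_iterations, k=cv_folds)
        return res


@dataclass
class QcarResults:
    """Fitted QCAR model: chosen combination, metrics, CV, interpretation."""

    model: QcarModel
    search: SearchOutcome
    final: FinalModel
    seed: int = 0
    mcc_cv: float | None = None
    cv_values: np.ndarray | None = None
    _report_cache: dict = field(default_factory=dict, repr=False)

    # -- headline numbers --------------------------------------------------
    @property
    def combination(self):
        return self.search.chosen

    @property
    def mcc_pred(self) -> float:
        return self.search.best.mcc_pred

    @property
    def nmcc_pred(self) -> float:
        return self.search.best.nmcc_pred

    @property
    def nmcc_cv(self) -> float | None:
        return None if self.mcc_cv is None else (self.mcc_cv + 1.0) / 2.0

    # -- post-fit computations --------------------------------------------
    def repeated_cv(self, iterations: int = 50, k: int = 5) -> float:
        """Mean MCC over repeated stratified k-fold CV of the chosen model."""
        mean, values = repeated_cv(
            self.model.compositions, self.model.y_values, self.model.censored,
            self.search.chosen, k=k, iterations=iterations, seed=self.seed,
        )
        self.mcc_cv, self.cv_values = mean, values
        self.final.mcc_cv = mean
        self.final.nmcc_cv = (mean + 1.0) / 2.0
        return mean

    def predict(self, X: CompositionTable | np.ndarray) -> np.ndarray:
        """Binary activity prediction for new oils."""
        return self.final.predict(X)

    def predict_proba(self, X: CompositionTable | np.ndarray) -> np.ndarray:
        """Predicted active-class probability for new oils."""
        return self.final.predict_proba_active(X)

    def component_report(
        self, top_k: int | None = 20, n_repeats: int = 20
    ) -> list[_interpret.ComponentReport]:
        """WFI contributor report (cached per (top_k, n_repeats))."""
        key = (top_k, n_repeats)
        if key not in self._report_cache:
            self._report_cache[key] = _interpret.component_report(
                self.final, self.model.compositions,
                top_k=top_k, n_repeats=n_repeats, seed=self.seed,
            )
        return self._report_cache[key]

    def partial_dependence(
        self, component: str, n_grid: int = 20
    ) -> _interpret.PdCurve:
        return _interpret.partial_dependence(
            self.final, self.model.compositions, component, n_grid=n_grid
        )

    def results_frame(self) -> pd.DataFrame:
        """Every evaluated combination and its metrics, best first."""
        rows = []
        for r in self.search.ranked():
            p = r.combination.params
            rows.append(
                {
                    "family": r.combination.family,
                    "hyperparameters": dict(r.combination.hyper),
                    "threshold": p.threshold,
                    "n_level": p.n_level,
                    "scaling": p.scaling,
                    "pca_level": p.pca_level,
                    "phase": r.phase,
                    "mcc_pred": r.mcc_pred,
                    "nmcc_pred": r.nmcc_pred,
                    "acc": r.acc,
                    "f1": r.f1,
                    "n_features": r.n_features,
                    "reason": r.reason,
                }
            )
        return pd.DataFrame(rows)

    def report_frame(self, top_k: int | None = 20) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "component": r.component,
                    "fi": r.fi,
                    "rho": r.rho,
                    "wfi": r.wfi,
                    "sign": r.sign,
                }
                for r in self.component_report(top_k=top_k)
            ]
        )

    # -- presentation ------------------------------------------------------
    def summary(self, top_k: int = 10) -> str:
        """Plain-text summary table of the fitted model."""
        m = self.model
        b = self.search.best
        counts = b.class_counts
        lines = [
            "QCAR classification results",
            "=" * 64,
            f"Assay:               {m.assay}",
            f"No. oils:            {m.nobs}",
            f"Class balance:       {counts[1]} active / {counts[0]} inactive "
            f"(threshold {b.combination.params.threshold} μg/mL)",
            f"Chosen combination:  {b.combination.describe()}",
            f"Combinations tried:  {len(self.search.results)}",
            "-" * 64,
            f"MCC_pred:  {self.mcc_pred:8.4f}    nMCC_pred: {self.nmcc_pred:8.4f}",
            f"ACC_pred:  {b.acc:8.4f}    F1_pred:   {b.f1:8.4f}",
            f"Train MCC: {self.final.train_mcc:8.4f}    "
            f"Train ACC: {self.final.train_acc:8.4f}",
        ]
        if self.mcc_cv is not None:
            lines.append(
                f"MCC_CV:    {self.mcc_cv:8.4f}    nMCC_CV:   {self.nmcc_cv:8.4f}"
                f"    ({len(self.cv_values)} iterations)"
            )
        lines.append("-" * 64)
        lines.append(f"Top {top_k} components by |WFI|:")
        lines.append(f"{'component':<22}{'FI':>8}{'rho':>8}{'WFI':>9}  sign")
        for r in self.component_report(top_k=top_k):
            lines.append(
                f"{r.component:<22}{r.fi:8.3f}{r.rho:8.3f}{r.wfi:9.4f}  {r.sign}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize the fitted results (joblib blob)."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "QcarResults":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, QcarResults):
            raise ParameterError(f"{path} does not hold QcarResults")
        return obj
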