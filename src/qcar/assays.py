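"""Assay quantification: percent inhibition, sigmoidal EC50, RBD50, comet scores.

The in vitro antioxidant assays (FRAP-type metal chelation, DPPH, ABTS, lipid
peroxidation, deoxyribose/HORAC) all reduce to a percent-inhibition readout
over a serial-dilution series, summarised by the EC50 of a four-parameter
logistic (4PL) dose–response curve.  DNA-protection gels are summarised by the
RBD50 — the concentration producing a 50% increase in relative electrophoretic
band density over the radical-damaged control — and comet assays by the total
comet score over damage classes T0–T4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    DegenerateRegressionError,
    DomainError,
    InsufficientDataError,
    ParameterError,
)

# 4PL parameter bounds used for fitting percent-inhibition curves.
HILL_BOUNDS = (0.2, 10.0)
TOP_BOUNDS = (50.0, 110.0)
BOTTOM_BOUNDS = (-10.0, 50.0)


@dataclass
class DoseResponseCurve:
    """Concentration/response pairs from one dilution series.

    ``response_kind`` is ``"inhibition"`` (percent inhibition, for EC50
    fitting) or ``"rbd"`` (relative band density ratio, for RBD50).
    Concentrations must be strictly increasing and positive.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    response_kind: str = "inhibition"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ParameterError("concentrations and responses differ in length")
        if self.concentrations.ndim != 1:
            raise ParameterError("curve arrays must be one-dimensional")
        if np.any(self.concentrations <= 0):
            raise ParameterError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ParameterError("concentrations must be strictly increasing")
        if self.response_kind not in ("inhibition", "rbd"):
            raise ParameterError(f"unknown response_kind {self.response_kind!r}")

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class Ec50Fit:
    """Result of a 4PL fit; ``ec50`` is the concentration at the curve midpoint."""

    ec50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    rss: float


@dataclass
class CometCounts:
    """Cell counts in comet damage classes T0 (undamaged) … T4 (maximal)."""

    n0: int
    n1: int
    n2: int
    n3: int
    n4: int

    def __post_init__(self) -> None:
        for k, n in zip("n0 n1 n2 n3 n4".split(), self.as_array()):
            if n < 0:
                raise ParameterError(f"negative count {k}={n}")

    def as_array(self) -> np.ndarray:
        return np.array([self.n0, self.n1, self.n2, self.n3, self.n4], dtype=int)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


def percent_inhibition(a_control: float, a_sample: float) -> float:
    """Percent inhibition from control and sample absorbances.

    %inhibition = (A_c − A_t) / A_c × 100, where A_c is the absorbance of the
    radical-only control and A_t that of the treated sample.  May be negative
    (pro-oxidant behaviour).
    """
    if a_control <= 0:
        raise DomainError(f"control absorbance must be positive, got {a_control}")
    if a_sample < 0:
        raise DomainError(f"sample absorbance must be non-negative, got {a_sample}")
    return (a_control - a_sample) / a_control * 100.0


def four_pl(conc: np.ndarray, log_ec50: float, hill: float, top: float, bottom: float) -> np.ndarray:
    """4PL response at ``conc``, parameterised by log10(EC50).

    response = bottom + (top − bottom) / (1 + 10^(hill·(log10 EC50 − log10 c)))
    so that response(EC50) = (top + bottom)/2 and response → top as c → ∞
    (hill > 0).
    """
    logc = np.log10(np.asarray(conc, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ec50 - logc)))


def fit_ec50(curve: DoseResponseCurve) -> Ec50Fit:
    """Least-squares 4PL fit of a percent-inhibition dilution series.

    Never raises on optimizer failure: ``converged`` is False when the fit
    fails, the curve is flat, or the fitted EC50 falls outside
    [min conc / 10, max conc × 10].  Fewer than 4 points raises
    :class:`InsufficientDataError`.
    """
    if curve.response_kind != "inhibition":
        raise ParameterError("fit_ec50 expects an inhibition curve")
    if len(curve) < 4:
        raise InsufficientDataError(
            f"need ≥4 points for a 4PL fit, got {len(curve)}"
        )
    conc = curve.concentrations
    resp = curve.responses

    def _failed() -> Ec50Fit:
        return Ec50Fit(
            ec50=float("nan"), hill=float("nan"),
            top=float(resp.max()), bottom=float(resp.min()),
            converged=False, rss=float(np.sum((resp - resp.mean()) ** 2)),
        )

    if np.ptp(resp) < 1e-9:  # flat curve: EC50 undefined
        return _failed()

    logc = np.log10(conc)
    lo = np.array([logc.min() - 1.0, HILL_BOUNDS[0], TOP_BOUNDS[0], BOTTOM_BOUNDS[0]])
    hi = np.array([logc.max() + 1.0, HILL_BOUNDS[1], TOP_BOUNDS[1], BOTTOM_BOUNDS[1]])
    # initial guess: midpoint crossing, unit slope, observed extremes
    mid = (resp.max() + resp.min()) / 2.0
    guess_log_ec50 = logc[np.argmin(np.abs(resp - mid))]
    p0 = np.clip(
        np.array([guess_log_ec50, 1.0, resp.max(), resp.min()]), lo, hi
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                four_pl, conc, resp, p0=p0, bounds=(lo, hi),
                method="trf", maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return _failed()
    log_ec50, hill, top, bottom = popt
    ec50 = 10.0 ** log_ec50
    rss = float(np.sum((four_pl(conc, *popt) - resp) ** 2))
    # strict with a ppm margin: an optimum pinned (numerically) at the
    # log-EC50 bound wanted to go further
    converged = bool(
        conc.min() / 10.0 * (1 + 1e-6) < ec50 < conc.max() * 10.0 * (1 - 1e-6)
    )
    return Ec50Fit(
        ec50=float(ec50), hill=float(hill), top=float(top),
        bottom=float(bottom), converged=converged, rss=rss,
    )


def rbd50(
    curve: DoseResponseCurve,
    baseline_rbd: float,
    span_reference: bool = False,
) -> float | None:
    """Concentration producing a 50% increase in relative band density.

    The target is 1.5 × ``baseline_rbd`` (the RBD of the radical-damaged,
    oil-free control lane).  With ``span_reference=True`` the target is
    instead halfway between the damaged control and full protection (RBD 1):
    baseline + 0.5 × (1 − baseline).

    Returns the smallest concentration at which the curve, linearly
    interpolated in log10 concentration, reaches the target — or ``None``
    when the target is never reached (an undetermined RBD50; such oils were
    deprioritised in practice).
    """
    if curve.response_kind != "rbd":
        raise ParameterError("rbd50 expects an rbd curve")
    if not 0.0 < baseline_rbd < 1.0:
        raise DomainError(
            f"baseline RBD must be in (0, 1), got {baseline_rbd}"
        )
    if span_reference:
        target = baseline_rbd + 0.5 * (1.0 - baseline_rbd)
    else:
        target = 1.5 * baseline_rbd
    conc = curve.concentrations
    rbd = curve.responses
    if rbd[0] >= target:
        return float(conc[0])
    logc = np.log10(conc)
    for i in range(1, len(conc)):
        if rbd[i] >= target:
            # linear interpolation in log10 concentration on [i-1, i]
            frac = (target - rbd[i - 1]) / (rbd[i] - rbd[i - 1])
            return float(10.0 ** (logc[i - 1] + frac * (logc[i] - logc[i - 1])))
    return None


def total_comet_score(counts: CometCounts) -> int:
    """TCS = Σ i·n_i over damage classes T0…T4 (0 = undamaged, 4 = maximal)."""
    return int(np.dot(np.arange(5), counts.as_array()))


def percent_reduction(
    tcs_negative: float, tcs_positive: float, tcs_treated: float
) -> float:
    """Percentage reduction of DNA damage relative to the two controls.

    %R = (TCS_positive − TCS_treated) / (TCS_positive − TCS_negative) × 100.
    Reported raw: it may be negative (damage beyond the positive control) or
    exceed 100 (protection beyond the negative control).
    """
    if tcs_positive <= tcs_negative:
        raise DomainError(
            "positive-control TCS must exceed negative-control TCS "
            f"({tcs_positive} ≤ {tcs_negative})"
        )
    return (tcs_positive - tcs_treated) / (tcs_positive - tcs_negative) * 100.0


def cross_assay_regression(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """OLS of one assay's EC50s on another's: (slope, intercept, r²).

    Censored values must be excluded upstream.  r² is the squared Pearson
    correlation; a constant ``y`` yields slope 0 and r² 0, a constant ``x``
    raises :class:`DegenerateRegressionError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise InsufficientDataError("need ≥3 pairs for cross-assay regression")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("zero variance in predictor EC50s")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
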