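"""Synthetic composition–activity data with the structure the analysis assumes.

Real essential-oil datasets are sparse compositional matrices: each oil is
dominated by a handful of major terpenes (a phenol like carvacrol can reach
~77% of a mixture) over a long tail of sub-percent traces, and a few
components recur across many oils.  Antioxidant potency is generated
log-linearly from planted "driver" components:

    log10 EC50 = intercept + Σ_j β_j · x_j + ε,   ε ~ N(0, noise_sd)

where x_j is the percentage of component j and a negative β marks a potency
driver (more of it lowers the EC50).  EC50s above the censoring limit are
reported right-censored at the limit, mirroring "> 1 μg/mL" reporting.

The generators also produce dilution-series inhibition curves (4PL), gel
densitometry series (RBD vs concentration) and comet-class counts so every
downstream stage can be exercised without laboratory data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .assays import DoseResponseCurve, four_pl
from .dataset import ActivityRecord, CompositionTable
from .exceptions import ParameterError

# fixed per-operation child-seed offsets (partial re-runs stay reproducible)
_SEED_COMPOSITIONS = 11
_SEED_ACTIVITY = 29

#: Common essential-oil constituents used as component names (most frequent
#: first; popularity-biased sampling makes low-index components recur, the
#: way limonene or linalool recur across real oils).
COMPONENT_NAMES = [
    "limonene", "linalool", "carvacrol", "eucalyptol", "alpha-pinene",
    "thymol", "caryophyllene", "p-cymene", "eugenol", "chrysanthone",
    "gamma-terpinene", "beta-pinene", "myrcene", "terpinen-4-ol", "camphor",
    "geraniol", "citral", "borneol", "sabinene", "alpha-terpineol",
    "citronellal", "menthol", "menthone", "carvone", "anethole",
    "estragole", "cinnamaldehyde", "geranyl-acetate", "linalyl-acetate",
    "bornyl-acetate", "alpha-thujone", "beta-thujone", "camphene",
    "delta-3-carene", "alpha-phellandrene", "terpinolene", "ocimene",
    "nerol", "neral", "citronellol", "germacrene-d", "alpha-humulene",
    "farnesene", "bisabolene", "spathulenol", "caryophyllene-oxide",
    "viridiflorol", "elemol", "cedrol", "santalol",
]


@dataclass
class GeneratorSpec:
    """Parameters of the composition–activity generator.

    Parameters
    ----------
    n_oils, n_components
        Dataset dimensions (defaults mirror a ~61-oil panel).
    dominance
        Mean number of major components per oil (≥ 1); per-oil counts are
        1 + Poisson(dominance − 1).
    driver_set
        Planted effects as ``(component_index, beta)`` pairs or
        ``(component_index, sign, size)`` triples, beta in log10-EC50 units
        per percentage point; negative beta = potency driver.
    noise_sd
        Standard deviation of the log10 EC50 noise.
    intercept_log10
        log10 EC50 (μg/mL) of an oil containing none of the drivers.
    censor_limit
        EC50s above this (μg/mL) are reported censored at the limit.
    """

    n_oils: int = 61
    n_components: int = 50
    dominance: float = 2.0
    driver_set: Sequence[tuple] = field(default_factory=tuple)
    noise_sd: float = 0.1
    intercept_log10: float = 0.0
    censor_limit: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oils < 4:
            raise ParameterError(f"n_oils must be ≥ 4, got {self.n_oils}")
        if self.n_components < 2:
            raise ParameterError(
                f"n_components must be ≥ 2, got {self.n_components}"
            )
        if self.dominance < 1:
            raise ParameterError(f"dominance must be ≥ 1, got {self.dominance}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be ≥ 0, got {self.noise_sd}")
        if self.censor_limit <= 0:
            raise ParameterError(
                f"censor_limit must be > 0, got {self.censor_limit}"
            )
        for beta in self.betas().values():
            if not np.isfinite(beta):
                raise ParameterError("driver effect sizes must be finite")

    def betas(self) -> dict[int, float]:
        """Signed effect per percentage point, keyed by component index."""
        out: dict[int, float] = {}
        for entry in self.driver_set:
            if len(entry) == 2:
                idx, beta = entry
                beta = float(beta)
            elif len(entry) == 3:
                idx, sign, size = entry
                s = {-1: -1.0, 1: 1.0, "negative": -1.0, "positive": 1.0}.get(sign)
                if s is None:
                    raise ParameterError(f"unknown driver sign {sign!r}")
                beta = s * float(size)
            else:
                raise ParameterError(f"malformed driver entry {entry!r}")
            out[int(idx)] = beta
        return out

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "n_oils": self.n_oils,
            "n_components": self.n_components,
            "dominance": self.dominance,
            "driver_set": [list(e) for e in self.driver_set],
            "noise_sd": self.noise_sd,
            "intercept_log10": self.intercept_log10,
            "censor_limit": self.censor_limit,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorSpec":
        payload = yaml.safe_load(Path(path).read_text())
        payload["driver_set"] = [tuple(e) for e in payload.get("driver_set", [])]
        return cls(**payload)


def _component_names(n: int) -> list[str]:
    names = list(COMPONENT_NAMES[:n])
    names += [f"component_{i + 1:03d}" for i in range(len(names), n)]
    return names


def generate_compositions(spec: GeneratorSpec) -> CompositionTable:
    """Draw a sparse oils × components percentage matrix.

    Per oil: 1 + Poisson(dominance − 1) major components are chosen with
    popularity-biased (1/rank) weights, given stick-breaking percentages
    scaled to a total in [60, 95], with the largest share forced above 10%;
    a few trace components (< 1%) are added on top.  Row sums stay in
    (0, 100]; a fixed seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed + _SEED_COMPOSITIONS)
    n, p = spec.n_oils, spec.n_components
    weights = 1.0 / np.arange(1, p + 1)
    weights /= weights.sum()
    X = np.zeros((n, p))
    for i in range(n):
        k = 1 + rng.poisson(spec.dominance - 1.0)
        k = min(k, max(1, p // 2))
        majors = rng.choice(p, size=k, replace=False, p=weights)
        # stick-breaking shares, front-loaded, normalised and sorted
        betas = rng.beta(1.0, 1.5, size=k)
        remaining = 1.0
        shares = np.empty(k)
        for j in range(k):
            shares[j] = remaining * betas[j]
            remaining -= shares[j]
        shares /= shares.sum()
        shares[::-1].sort()
        total = rng.uniform(60.0, 95.0)
        pct = shares * total
        if pct[0] <= 10.0:  # guarantee one dominant component
            target = 0.35 * total
            pct[1:] *= (total - target) / (total - pct[0])
            pct[0] = target
        X[i, majors] = pct
        # sub-percent traces on a few of the remaining components
        free = np.setdiff1d(np.arange(p), majors)
        m = min(int(rng.poisson(4.0)), 6, len(free))
        if m:
            traced = rng.choice(free, size=m, replace=False)
            X[i, traced] = rng.uniform(0.02, 0.8, size=m)
    oil_ids = [f"oil_{i + 1:03d}" for i in range(n)]
    import pandas as pd

    return CompositionTable(
        pd.DataFrame(X, index=oil_ids, columns=_component_names(p))
    )


def generate_activity(
    comps: CompositionTable,
    spec: GeneratorSpec,
    assay: str = "dpph",
) -> list[ActivityRecord]:
    """Generate per-oil potencies from the planted log-linear model.

    log10 EC50 = intercept + Σ β_j x_j + ε; EC50s above ``censor_limit`` are
    reported censored at the limit.
    """
    betas = spec.betas()
    for idx in betas:
        if not 0 <= idx < comps.n_components:
            raise ParameterError(
                f"driver index {idx} out of range for "
                f"{comps.n_components} components"
            )
    rng = np.random.default_rng(spec.seed + _SEED_ACTIVITY)
    beta_vec = np.zeros(comps.n_components)
    for idx, b in betas.items():
        beta_vec[idx] = b
    log_ec50 = spec.intercept_log10 + comps.values @ beta_vec
    if spec.noise_sd > 0:
        log_ec50 = log_ec50 + rng.normal(0.0, spec.noise_sd, size=comps.n_oils)
    ec50 = 10.0**log_ec50
    records = []
    for oid, value in zip(comps.oil_ids, ec50):
        censored = value > spec.censor_limit
        records.append(
            ActivityRecord(
                oil_id=oid,
                assay=assay,
                value=float(spec.censor_limit if censored else value),
                censored=bool(censored),
            )
        )
    return records


def generate_dataset(
    spec: GeneratorSpec, assay: str = "dpph"
) -> tuple[CompositionTable, list[ActivityRecord]]:
    """Compositions plus matching activity records in one call."""
    comps = generate_compositions(spec)
    return comps, generate_activity(comps, spec, assay=assay)


def default_dilution_grid() -> np.ndarray:
    """Nine two-fold dilutions from 2 down to 0.0078 μg/mL, ascending."""
    return 2.0 / 2.0 ** np.arange(8, -1, -1)


def generate_dose_response(
    ec50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponseCurve:
    """Noisy 4PL percent-inhibition readings over a dilution grid."""
    if ec50 <= 0:
        raise ParameterError(f"ec50 must be positive, got {ec50}")
    if top <= bottom:
        raise ParameterError(f"top ({top}) must exceed bottom ({bottom})")
    grid = default_dilution_grid() if grid is None else np.asarray(grid, float)
    if np.any(grid <= 0):
        raise ParameterError("concentration grid must be strictly positive")
    grid = np.sort(grid)
    resp = four_pl(grid, np.log10(ec50), hill, top, bottom)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, size=grid.shape)
    return DoseResponseCurve(grid, resp, response_kind="inhibition")


def generate_gel_series(
    protection_ec: float,
    baseline_rbd: float,
    grid: np.ndarray,
    direction: str = "rising",
    noise_sd: float = 0.0,
    seed: int = 0,
    hill: float = 1.5,
) -> DoseResponseCurve:
    """Gel densitometry series: relative band density (RBD) vs concentration.

    ``rising`` emulates dose-dependent DNA protection (RBD grows from the
    damaged-control baseline toward ~1); ``falling`` emulates protection lost
    with concentration.  The curve is built so the 1.5 × baseline protection
    target is crossed at ``protection_ec`` whenever that target is reachable.
    Values are clipped to (0, 1.2]; monotone per direction before noise.
    """
    if not 0.0 < baseline_rbd < 1.0:
        raise ParameterError(
            f"baseline RBD must be in (0, 1), got {baseline_rbd}"
        )
    if protection_ec <= 0:
        raise ParameterError("protection_ec must be positive")
    grid = np.sort(np.asarray(grid, dtype=float))
    if np.any(grid <= 0):
        raise ParameterError("concentration grid must be strictly positive")
    if direction not in ("rising", "falling"):
        raise ParameterError(f"unknown direction {direction!r}")
    top = 1.1
    target_frac = 0.5 * baseline_rbd / (top - baseline_rbd)
    if not 0.0 < target_frac < 1.0:  # target unreachable; keep midpoint at ec
        ec_mid = protection_ec
    elif direction == "rising":
        ec_mid = protection_ec * ((1.0 - target_frac) / target_frac) ** (1.0 / hill)
    else:
        ec_mid = protection_ec / (1.0 / target_frac - 1.0) ** (1.0 / hill)
    if direction == "rising":
        s = 1.0 / (1.0 + (ec_mid / grid) ** hill)
    else:
        s = 1.0 / (1.0 + (grid / ec_mid) ** hill)
    rbd = baseline_rbd + (top - baseline_rbd) * s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rbd = rbd + rng.normal(0.0, noise_sd, size=grid.shape)
    rbd = np.clip(rbd, 1e-6, 1.2)
    return DoseResponseCurve(grid, rbd, response_kind="rbd")


def generate_comet_counts(
    mean_damage: float, n_cells: int, seed: int = 0
) -> "CometCounts":
    """Sample comet-class counts with mean class ``mean_damage`` ∈ [0, 4].

    Each cell's class is Binomial(4, mean_damage/4), so the expected total
    comet score is mean_damage × n_cells; the five counts sum to n_cells.
    """
    from .assays import CometCounts

    if n_cells < 1:
        raise ParameterError(f"n_cells must be ≥ 1, got {n_cells}")
    if not 0.0 <= mean_damage <= 4.0:
        raise ParameterError(
            f"mean_damage must be in [0, 4], got {mean_damage}"
        )
    rng = np.random.default_rng(seed)
    pmf = stats.binom.pmf(np.arange(5), 4, mean_damage / 4.0)
    pmf = pmf / pmf.sum()
    counts = rng.multinomial(n_cells, pmf)
    return CometCounts(*[int(c) for c in counts])
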