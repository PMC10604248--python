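"""Data model and CSV I/O for composition and activity tables.

An essential oil (EO) is represented as a vector of chemical-component
percentages (GC-MS area %), collected for many oils into a wide
:class:`CompositionTable`.  Antioxidant potencies are stored long-form as
:class:`ActivityRecord` rows — one (oil, assay) pair per record, the value an
EC50 or RBD50 in μg/mL, optionally right-censored ("> limit").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyJoinError, SchemaError

logger = logging.getLogger(__name__)

#: Recognised assay identifiers. The five EC50-based in vitro assays
#: (ferrous-ion chelation, DPPH and ABTS radical scavenging, lipid
#: peroxidation inhibition, hydroxyl-radical capacity) plus the two
#: DNA-protection RBD50 readouts against peroxyl and hydroxyl radicals.
ASSAYS = (
    "metal_chelation",
    "dpph",
    "lpi",
    "abts",
    "horac",
    "roo_rbd50",
    "oh_rbd50",
)

#: GC-MS rounding slack on a row sum of percentages.
ROW_SUM_TOL = 0.5

UNIT = "μg/mL"


@dataclass
class CompositionTable:
    """Oils × components percentage matrix.

    Parameters
    ----------
    data
        DataFrame indexed by oil identifier with one column per chemical
        component; values are percentages of the mixture.  Rows must be
        non-negative and sum to at most ``100 + ROW_SUM_TOL``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise SchemaError(f"duplicate oil identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate component identifiers: {dups}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise SchemaError("composition table contains non-numeric cells")
        neg = np.argwhere(values < 0)
        if neg.size:
            i, j = neg[0]
            raise SchemaError(
                f"negative percentage at oil {df.index[i]!r}, "
                f"component {df.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        bad = np.flatnonzero(sums > 100.0 + ROW_SUM_TOL)
        if bad.size:
            i = bad[0]
            raise SchemaError(
                f"row sum {sums[i]:.4g} > {100 + ROW_SUM_TOL} for oil "
                f"{df.index[i]!r}"
            )
        self.data = df.astype(float)

    # -- accessors ---------------------------------------------------------
    @property
    def oil_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def component_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_oils(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def subset_oils(self, oil_ids: Sequence[str]) -> "CompositionTable":
        return CompositionTable(self.data.loc[list(oil_ids)])

    def subset_components(self, names: Sequence[str]) -> "CompositionTable":
        return CompositionTable(self.data.loc[:, list(names)])

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="oil_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompositionTable":
        return read_composition(path)


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement: EC50 or RBD50 of one oil in one assay.

    ``censored`` marks a right-censored value ("EC50 > limit"); by convention
    the record then carries the censor limit itself in ``value``.
    """

    oil_id: str
    assay: str
    value: float
    censored: bool = False
    unit: str = UNIT

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise SchemaError(
                f"unknown assay {self.assay!r}; expected one of {ASSAYS}"
            )
        if not np.isfinite(self.value) or self.value <= 0:
            raise SchemaError(
                f"non-positive value {self.value!r} for oil {self.oil_id!r}"
            )


@dataclass
class LabeledDataset:
    """Model-ready features plus binary activity labels.

    ``y`` is 1 for active (EC50 ≤ threshold, uncensored) and 0 otherwise.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    oil_ids: list[str]
    threshold_used: float
    assay: str | None = None

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise SchemaError("label vector length does not match X rows")


def read_composition(path: str | Path) -> CompositionTable:
    """Read a wide composition CSV (first column = oil identifier).

    Blank cells are read as 0 (trace components are recorded either way in
    practice).  Schema violations raise :class:`SchemaError` naming the
    offending row or column.
    """
    df = pd.read_csv(path, index_col=0)
    df = df.fillna(0.0)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric composition cell: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return CompositionTable(df)


def _parse_value(raw: object) -> tuple[float, bool]:
    """Parse an activity value cell; ``">x"`` means censored at x."""
    if isinstance(raw, str):
        s = raw.strip()
        if s.startswith(">"):
            return float(s[1:]), True
        return float(s), False
    return float(raw), False


def read_activity(path: str | Path) -> list[ActivityRecord]:
    """Read a long-form activity CSV with columns oil_id, assay, value[, censored]."""
    df = pd.read_csv(path, dtype={"value": str})
    required = {"oil_id", "assay", "value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"activity CSV missing columns: {sorted(missing)}")
    records: list[ActivityRecord] = []
    for row in df.itertuples(index=False):
        value, censored = _parse_value(row.value)
        if "censored" in df.columns:
            censored = censored or bool(row.censored)
        records.append(
            ActivityRecord(
                oil_id=str(row.oil_id).strip(),
                assay=str(row.assay).strip(),
                value=value,
                censored=censored,
            )
        )
    return records


def write_activity(records: Iterable[ActivityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "oil_id": r.oil_id,
                "assay": r.assay,
                "value": r.value,
                "censored": r.censored,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def align(
    comps: CompositionTable,
    records: Sequence[ActivityRecord],
    assay: str,
) -> tuple[CompositionTable, np.ndarray, np.ndarray]:
    """Join composition rows with one assay's activity values.

    Returns the composition restricted to oils having a record for ``assay``
    (in composition row order), the EC50/RBD50 vector and the censoring flags.
    Oils without a record are dropped with a logged count; records for oils
    absent from the composition table raise :class:`SchemaError`.
    """
    if assay not in ASSAYS:
        raise SchemaError(f"unknown assay {assay!r}")
    by_oil: dict[str, ActivityRecord] = {}
    for r in records:
        if r.assay != assay:
            continue
        if r.oil_id in by_oil:
            raise SchemaError(
                f"duplicate activity record for oil {r.oil_id!r}, assay {assay!r}"
            )
        by_oil[r.oil_id] = r
    known = set(comps.oil_ids)
    kept = [oid for oid in comps.oil_ids if oid in by_oil]
    if not kept:
        raise EmptyJoinError(
            f"no oils shared between composition table and {assay!r} records"
        )
    stray = sorted(set(by_oil) - known)
    if stray:
        raise SchemaError(f"activity records for unknown oils: {stray}")
    dropped = comps.n_oils - len(kept)
    if dropped:
        logger.info("align: dropped %d oils without a %s record", dropped, assay)
    sub = comps.subset_oils(kept)
    values = np.array([by_oil[o].value for o in kept], dtype=float)
    censored = np.array([by_oil[o].censored for o in kept], dtype=bool)
    return sub, values, censored
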