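"""Synthetic inter-industry flow tables.

National statistical offices publish Supply and Use Tables from which a
square industry-by-industry flow matrix is derived; such tables are rarely
redistributable.  This module generates synthetic economies with the same
accounting structure — nonnegative inter-industry flows ``Z``, total output
``x``, final demand ``f`` and value added ``va`` satisfying the row identity
``x_i = sum_j Z_ij + f_i`` and the column identity
``x_j = sum_i Z_ij + va_j`` — and with a technical-coefficient matrix that
is productive (Hawkins-Simon condition holds) by construction.

All monetary quantities are in million USD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, InvalidParameterError, InvalidSizeError, LabelError

__all__ = [
    "DEFAULT_SECTORS_27",
    "FlowTable",
    "Household",
    "Violation",
    "default_labels",
    "generate_economy",
    "validate_economy",
    "read_flow_table",
    "write_flow_table",
]

#: Sector labels for the default 27-sector productive economy.  The mix —
#: primary production, processing industries, knowledge sectors and services —
#: mirrors the sectoral breadth of a middle-income national account.
DEFAULT_SECTORS_27: tuple[str, ...] = (
    "agriculture",
    "fishing",
    "forestry",
    "mining",
    "food_processing",
    "textiles",
    "manufacturing",
    "chemicals",
    "pharmaceuticals",
    "energy",
    "water",
    "construction",
    "trade",
    "transport",
    "hospitality",
    "information",
    "telecommunications",
    "finance",
    "insurance",
    "real_estate",
    "professional_services",
    "R&D",
    "education",
    "health",
    "public_administration",
    "arts_recreation",
    "services",
)


def default_labels(n: int) -> list[str]:
    """Sector labels for an ``n``-sector economy.

    The first 27 names come from :data:`DEFAULT_SECTORS_27`; beyond that,
    generic ``sector_k`` names are appended.
    """
    if n < 1:
        raise InvalidSizeError(f"sector count must be >= 1, got {n}")
    labels = list(DEFAULT_SECTORS_27[:n])
    labels.extend(f"sector_{k}" for k in range(len(labels) + 1, n + 1))
    return labels


@dataclass(frozen=True)
class Household:
    """Household account for Type II closure.

    consumption
        Column ``h_c``: household purchases from each sector (million USD).
        A component of that sector's final demand.
    income
        Row ``h_r``: labor income paid by each sector (million USD).
        A component of that sector's value added.
    """

    consumption: np.ndarray
    income: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "consumption", np.asarray(self.consumption, dtype=float))
        object.__setattr__(self, "income", np.asarray(self.income, dtype=float))
        if self.consumption.ndim != 1 or self.income.ndim != 1:
            raise DimensionError("household consumption and income must be 1-D")
        if self.consumption.shape != self.income.shape:
            raise DimensionError(
                f"household consumption ({self.consumption.shape[0]}) and income "
                f"({self.income.shape[0]}) lengths differ"
            )


@dataclass(frozen=True)
class FlowTable:
    """A square inter-industry economy.

    ``Z[i, j]`` is the value of sector *i*'s sales used as intermediate input
    by sector *j*; ``x`` is total output, ``f`` final demand and ``va`` value
    added per sector.  Construction checks dimensional consistency only; the
    accounting identities are checked by :func:`validate_economy`.
    """

    labels: Sequence[str]
    Z: np.ndarray
    x: np.ndarray
    f: np.ndarray
    va: np.ndarray
    household: Household | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        object.__setattr__(self, "Z", np.asarray(self.Z, dtype=float))
        for name in ("x", "f", "va"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.labels)
        if n == 0:
            raise InvalidSizeError("a flow table needs at least one sector")
        if len(set(self.labels)) != n:
            raise LabelError("sector labels must be unique")
        if self.Z.shape != (n, n):
            raise DimensionError(f"Z must be {n}x{n}, got {self.Z.shape}")
        for name in ("x", "f", "va"):
            vec = getattr(self, name)
            if vec.shape != (n,):
                raise DimensionError(f"{name} must have length {n}, got {vec.shape}")
        if self.household is not None and self.household.consumption.shape != (n,):
            raise DimensionError("household vectors must match the sector count")

    @property
    def n(self) -> int:
        return len(self.labels)

    def intermediate_sales(self) -> np.ndarray:
        """Row sums of Z: each sector's sales to other industries."""
        return self.Z.sum(axis=1)

    def intermediate_purchases(self) -> np.ndarray:
        """Column sums of Z: each sector's purchases from other industries."""
        return self.Z.sum(axis=0)


class Violation(NamedTuple):
    """One failed check: which rule, where, and by how much."""

    kind: str
    sector: int | tuple[int, int] | None
    magnitude: float


def _relative_gap(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.maximum(np.abs(lhs), np.abs(rhs)), 1.0)
    return np.abs(lhs - rhs) / scale


def hawkins_simon_minors(A: np.ndarray) -> np.ndarray:
    """Leading principal minors of ``I - A``.

    The Hawkins-Simon condition — all minors strictly positive — is
    equivalent to productivity (spectral radius of ``A`` below one) for a
    nonnegative coefficient matrix.
    """
    M = np.eye(A.shape[0]) - A
    return np.array([np.linalg.det(M[: k + 1, : k + 1]) for k in range(A.shape[0])])


def validate_economy(
    table: FlowTable,
    rtol: float = 1e-9,
    minor_tol: float = 1e-12,
) -> list[Violation]:
    """Check every accounting invariant of a flow table.

    Returns an empty list iff all entries are nonnegative, the row and column
    identities hold to relative tolerance ``rtol``, and the implied
    coefficient matrix satisfies the Hawkins-Simon condition.  Dimensional
    inconsistencies are structural and raise at :class:`FlowTable`
    construction, not here.
    """
    out: list[Violation] = []

    neg = np.argwhere(table.Z < 0)
    out.extend(
        Violation("negative_flow", (int(i), int(j)), float(-table.Z[i, j])) for i, j in neg
    )
    for name, kind in (("x", "negative_output"), ("f", "negative_final_demand"), ("va", "negative_value_added")):
        vec = getattr(table, name)
        for (i,) in np.argwhere(vec < 0):
            out.append(Violation(kind, int(i), float(-vec[i])))
    if table.household is not None:
        for vec, kind in (
            (table.household.consumption, "negative_household_consumption"),
            (table.household.income, "negative_household_income"),
        ):
            for (i,) in np.argwhere(vec < 0):
                out.append(Violation(kind, int(i), float(-vec[i])))

    row_gap = _relative_gap(table.x, table.intermediate_sales() + table.f)
    for (i,) in np.argwhere(row_gap > rtol):
        out.append(Violation("row_identity", int(i), float(row_gap[i])))
    col_gap = _relative_gap(table.x, table.intermediate_purchases() + table.va)
    for (j,) in np.argwhere(col_gap > rtol):
        out.append(Violation("column_identity", int(j), float(col_gap[j])))

    if np.all(table.x > 0):
        A = table.Z / table.x[np.newaxis, :]
        minors = hawkins_simon_minors(A)
        for (k,) in np.argwhere(minors <= minor_tol):
            out.append(Violation("hawkins_simon", int(k), float(minors[k])))
    else:
        for (j,) in np.argwhere(table.x <= 0):
            out.append(Violation("nonpositive_output", int(j), float(table.x[j])))

    return out


def generate_economy(
    n: int,
    seed: int = 0,
    spectral_cap: float = 0.9,
    labels: Sequence[str] | None = None,
    with_household: bool = False,
) -> FlowTable:
    """Draw a random balanced economy with a productive coefficient matrix.

    The recipe works backwards from the coefficients: draw a nonnegative
    ``A`` and rescale each column so its sum is uniform on
    ``[min(0.2, cap/2), cap)`` — for a nonnegative matrix the spectral radius
    is bounded by the largest column sum, so productivity (and the spectral
    cap) holds by construction.  Then draw positive final demand ``f``, solve
    ``x = (I - A)^{-1} f`` and set ``Z = A diag(x)``; both accounting
    identities and nonnegative value added follow exactly, with no rejection
    step.

    Parameters
    ----------
    n
        Number of sectors (>= 1).
    seed
        RNG seed; identical arguments give a bit-identical table.
    spectral_cap
        Strict upper bound, in (0, 1), on the spectral radius of the implied
        coefficient matrix.
    labels
        Optional sector names (length ``n``, unique); defaults to
        :func:`default_labels`.
    with_household
        Also generate a household account (labor-income shares of value
        added, consumption proportional to final demand) for Type II closure.
    """
    if n < 1:
        raise InvalidSizeError(f"sector count must be >= 1, got {n}")
    if not 0.0 < spectral_cap < 1.0:
        raise InvalidParameterError(f"spectral_cap must lie in (0, 1), got {spectral_cap}")
    if labels is None:
        labels = default_labels(n)
    else:
        labels = list(labels)
        if len(labels) != n:
            raise LabelError(f"expected {n} labels, got {len(labels)}")
        if len(set(labels)) != n:
            raise LabelError("sector labels must be unique")

    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.05, 1.0, size=(n, n))
    lo = min(0.2, spectral_cap / 2.0)
    col_sums = rng.uniform(lo, spectral_cap, size=n)
    A = raw / raw.sum(axis=0, keepdims=True) * col_sums[np.newaxis, :]

    f = rng.uniform(50.0, 500.0, size=n)
    x = np.linalg.solve(np.eye(n) - A, f)
    Z = A * x[np.newaxis, :]
    va = x - Z.sum(axis=0)

    household = None
    if with_household:
        labor_share = rng.uniform(0.4, 0.7, size=n)
        income = labor_share * va
        propensity = rng.uniform(0.5, 0.8)
        consumption = f / f.sum() * propensity * income.sum()
        household = Household(consumption=consumption, income=income)

    return FlowTable(labels=labels, Z=Z, x=x, f=f, va=va, household=household)


# -- CSV dialect -------------------------------------------------------------
#
# First row: "sector", sector names..., "final_demand", "total_output".
# Next n rows: sector name, flow values..., f_i, x_i.
# Last row: "value_added", va values..., two empty cells.
# UTF-8, "." decimal, no thousands separators.  Household data (used only by
# the optional Type II closure) is not part of the dialect.

_FD = "final_demand"
_TO = "total_output"
_VA = "value_added"


def write_flow_table(table: FlowTable, path) -> None:
    """Write a flow table as CSV in the package's dialect."""
    cols = list(table.labels) + [_FD, _TO]
    frame = pd.DataFrame(
        np.column_stack([table.Z, table.f, table.x]),
        index=list(table.labels),
        columns=cols,
    )
    frame.loc[_VA] = list(table.va) + [np.nan, np.nan]
    frame.index.name = "sector"
    frame.to_csv(path, encoding="utf-8")


def read_flow_table(path) -> FlowTable:
    """Read a flow table from the CSV dialect written by :func:`write_flow_table`."""
    frame = pd.read_csv(path, index_col=0, encoding="utf-8")
    if _VA not in frame.index:
        raise DimensionError(f"flow-table CSV lacks a '{_VA}' row")
    for col in (_FD, _TO):
        if col not in frame.columns:
            raise DimensionError(f"flow-table CSV lacks a '{col}' column")
    labels = [str(s) for s in frame.index if s != _VA]
    body = frame.loc[labels]
    if list(body.columns[: len(labels)]) != labels:
        raise LabelError("row and column sector labels disagree")
    return FlowTable(
        labels=labels,
        Z=body[labels].to_numpy(dtype=float),
        x=body[_TO].to_numpy(dtype=float),
        f=body[_FD].to_numpy(dtype=float),
        va=frame.loc[_VA, labels].to_numpy(dtype=float),
    )
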