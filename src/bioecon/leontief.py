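"""Leontief input-output machinery.

Technical coefficients ``A_ij = Z_ij / x_j`` (column *j* is the input recipe
of the purchasing sector), the Leontief inverse ``L = (I - A)^{-1}``, output
impacts of a final-demand injection ``x = L F``, output multipliers (column
sums of ``L``), and the direct / indirect / induced decomposition.

Induced effects are obtained by household endogenization (Type II closure):
the coefficient matrix is augmented with a household consumption column and
a labor-income row, the ``(n+1)``-system is inverted, and the induced effect
is the industry-block difference ``(L_II - L_I) F``.  Type I (no household)
is the default, with induced effects identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .economy import FlowTable, Household, hawkins_simon_minors
from .errors import (
    DimensionError,
    InvalidParameterError,
    LabelError,
    MissingClosureError,
    NonProductiveEconomyError,
    UndefinedSharesError,
    ZeroOutputError,
)

__all__ = [
    "CoefficientMatrix",
    "LeontiefInverse",
    "DemandShock",
    "ImpactResult",
    "HouseholdCoefficients",
    "technical_coefficients",
    "household_coefficients",
    "leontief_inverse",
    "total_output_impact",
    "output_multipliers",
    "decompose_impacts",
    "sector_shares",
    "spectral_radius",
]

#: refuse to invert when the spectral radius is this close to 1
_PRODUCTIVITY_MARGIN = 1e-9


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(A))))


def _check_labels(a: Sequence[str], b: Sequence[str], what: str) -> None:
    if tuple(a) != tuple(b):
        raise LabelError(f"{what}: sector labels do not match")


@dataclass(frozen=True)
class CoefficientMatrix:
    """Technical coefficients: input value per unit of output value."""

    A: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "A", np.asarray(self.A, dtype=float))
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        n = len(self.labels)
        if self.A.shape != (n, n):
            raise DimensionError(f"A must be {n}x{n}, got {self.A.shape}")
        if np.any(self.A < 0):
            raise InvalidParameterError("technical coefficients must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.A)

    def is_productive(self, margin: float = _PRODUCTIVITY_MARGIN) -> bool:
        """True when the economy can meet any nonnegative final demand."""
        return self.spectral_radius < 1.0 - margin

    def hawkins_simon_holds(self, tol: float = 1e-12) -> bool:
        return bool(np.all(hawkins_simon_minors(self.A) > tol))

    def index_of(self, sector: str) -> int:
        try:
            return self.labels.index(sector)
        except ValueError:
            raise LabelError(f"unknown sector {sector!r}") from None


@dataclass(frozen=True)
class LeontiefInverse:
    """``L = (I - A)^{-1}``: total output per unit of final demand."""

    L: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "L", np.asarray(self.L, dtype=float))
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        n = len(self.labels)
        if self.L.shape != (n, n):
            raise DimensionError(f"L must be {n}x{n}, got {self.L.shape}")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class DemandShock:
    """A final-demand injection (million USD per sector).

    Negative entries are rejected by default; pass ``allow_negative=True``
    for contraction scenarios.
    """

    F: np.ndarray
    labels: Sequence[str]
    allow_negative: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "F", np.asarray(self.F, dtype=float))
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        if self.F.shape != (len(self.labels),):
            raise DimensionError("shock vector length must match the label count")
        if not self.allow_negative and np.any(self.F < 0):
            raise InvalidParameterError("negative demand shock (pass allow_negative=True)")


@dataclass(frozen=True)
class ImpactResult:
    """Per-sector impact decomposition, million USD.

    ``direct + indirect + induced == total`` per sector; ``shares`` are
    percentages of the all-sector total and sum to 100, or ``None`` when the
    total impact is zero (shares undefined).
    """

    labels: Sequence[str]
    direct: np.ndarray
    indirect: np.ndarray
    induced: np.ndarray
    total: np.ndarray
    shares: np.ndarray | None
    closure_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        for name in ("direct", "indirect", "induced", "total"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.shares is not None:
            object.__setattr__(self, "shares", np.asarray(self.shares, dtype=float))

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "direct": self.direct.tolist(),
            "indirect": self.indirect.tolist(),
            "induced": self.induced.tolist(),
            "total": self.total.tolist(),
            "shares": None if self.shares is None else self.shares.tolist(),
            "closure_type": self.closure_type,
        }


@dataclass(frozen=True)
class HouseholdCoefficients:
    """Per-unit household coefficients for Type II closure.

    consumption
        ``c_i``: household spending on sector *i* per unit of labor income.
    income
        ``w_j``: labor income paid by sector *j* per unit of its output.
    """

    consumption: np.ndarray
    income: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "consumption", np.asarray(self.consumption, dtype=float))
        object.__setattr__(self, "income", np.asarray(self.income, dtype=float))
        if self.consumption.shape != self.income.shape or self.consumption.ndim != 1:
            raise DimensionError("household coefficient vectors must be equal-length 1-D")
        if np.any(self.consumption < 0) or np.any(self.income < 0):
            raise InvalidParameterError("household coefficients must be nonnegative")


def technical_coefficients(table: FlowTable) -> CoefficientMatrix:
    """``A_ij = Z_ij / x_j``: divide each column of Z by that sector's output."""
    zero = np.flatnonzero(table.x == 0)
    if zero.size:
        names = ", ".join(table.labels[j] for j in zero)
        raise ZeroOutputError(f"zero total output for sector(s): {names}")
    return CoefficientMatrix(A=table.Z / table.x[np.newaxis, :], labels=table.labels)


def household_coefficients(table: FlowTable) -> HouseholdCoefficients:
    """Derive per-unit household coefficients from a table's household account."""
    if table.household is None:
        raise MissingClosureError("flow table carries no household account")
    hh: Household = table.household
    total_income = hh.income.sum()
    if total_income <= 0:
        raise MissingClosureError("household account has zero total labor income")
    if np.any(table.x == 0):
        raise ZeroOutputError("zero total output; income coefficients undefined")
    return HouseholdCoefficients(
        consumption=hh.consumption / total_income,
        income=hh.income / table.x,
    )


def leontief_inverse(coeffs: CoefficientMatrix) -> LeontiefInverse:
    """Invert ``I - A``, refusing when the economy is not productive."""
    rho = coeffs.spectral_radius
    if rho >= 1.0 - _PRODUCTIVITY_MARGIN:
        raise NonProductiveEconomyError(
            f"coefficient matrix is not productive: spectral radius {rho:.6f} >= 1"
        )
    n = coeffs.n
    L = np.linalg.solve(np.eye(n) - coeffs.A, np.eye(n))
    return LeontiefInverse(L=L, labels=coeffs.labels)


def total_output_impact(inverse: LeontiefInverse, shock: DemandShock) -> np.ndarray:
    """Total output required across sectors to meet the injection: ``L F``."""
    _check_labels(inverse.labels, shock.labels, "total_output_impact")
    return inverse.L @ shock.F


def output_multipliers(inverse: LeontiefInverse) -> np.ndarray:
    """Column sums of L: total output per unit of final demand in each sector."""
    return inverse.L.sum(axis=0)


def _augmented_inverse(
    coeffs: CoefficientMatrix, household: HouseholdCoefficients
) -> np.ndarray:
    n = coeffs.n
    if household.consumption.shape != (n,):
        raise DimensionError("household coefficients must match the sector count")
    A2 = np.zeros((n + 1, n + 1))
    A2[:n, :n] = coeffs.A
    A2[:n, n] = household.consumption
    A2[n, :n] = household.income
    rho = spectral_radius(A2)
    if rho >= 1.0 - _PRODUCTIVITY_MARGIN:
        raise NonProductiveEconomyError(
            f"household-augmented matrix not productive: spectral radius {rho:.6f}"
        )
    return np.linalg.solve(np.eye(n + 1) - A2, np.eye(n + 1))


def decompose_impacts(
    coeffs: CoefficientMatrix,
    shock: DemandShock,
    closure: str = "type_I",
    household: HouseholdCoefficients | None = None,
) -> ImpactResult:
    """Split the total output impact into direct, indirect and induced parts.

    direct
        The injection ``F`` itself.
    indirect
        The supply-chain ripple ``(L_I - I) F``.
    induced
        The household-spending ripple: the industry block of the Type II
        inverse minus the Type I inverse, applied to ``F``.  Zero under
        Type I closure.
    """
    _check_labels(coeffs.labels, shock.labels, "decompose_impacts")
    if closure not in ("type_I", "type_II"):
        raise InvalidParameterError(f"closure must be 'type_I' or 'type_II', got {closure!r}")

    L1 = leontief_inverse(coeffs).L
    direct = shock.F.copy()
    indirect = (L1 - np.eye(coeffs.n)) @ shock.F

    if closure == "type_II":
        if household is None:
            raise MissingClosureError("type_II closure requires household coefficients")
        L2 = _augmented_inverse(coeffs, household)
        induced = (L2[: coeffs.n, : coeffs.n] - L1) @ shock.F
    else:
        induced = np.zeros(coeffs.n)

    total = direct + indirect + induced
    grand = total.sum()
    shares = 100.0 * total / grand if grand > 0 else None
    return ImpactResult(
        labels=coeffs.labels,
        direct=direct,
        indirect=indirect,
        induced=induced,
        total=total,
        shares=shares,
        closure_type=closure,
    )


def sector_shares(
    impacts: Mapping[str, float],
    total: float | None = None,
    ndigits: int | None = None,
) -> dict[str, float]:
    """Percentage share of each named impact.

    By default the denominator is the sum of the given impacts; pass
    ``total`` to express each impact as a share of an externally known
    all-sector total instead (e.g. a single sector against a published
    aggregate).  ``ndigits`` rounds for reporting; shares sum to 100 before
    rounding.
    """
    values = np.array([float(v) for v in impacts.values()])
    if np.any(values < 0):
        raise InvalidParameterError("impacts must be nonnegative")
    denom = float(total) if total is not None else float(values.sum())
    if denom <= 0:
        raise UndefinedSharesError("shares undefined: total impact is zero")
    shares = 100.0 * values / denom
    if ndigits is not None:
        shares = np.round(shares, ndigits)
    return dict(zip(impacts.keys(), (float(s) for s in shares)))
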