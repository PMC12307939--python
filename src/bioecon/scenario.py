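"""Investment scenarios: demand injection, productivity gain, linkage change.

The appraisal compares a *base* case (the economy as observed) with an
*adjusted* case in which the investment has altered the production structure:

* a final-demand injection — the investment total split across recipient
  sectors by allocation weights;
* a productivity gain in target sectors, modelled as input efficiency: each
  target column of the coefficient matrix is scaled by ``1/(1+g)`` (the same
  output is produced from proportionally fewer intermediate inputs);
* strengthened inter-sector linkages: the coefficient of a source sector's
  row is raised by a fixed delta in target columns (those sectors buy more
  of the source's output per unit of their own output).

Adjustments compose in a fixed, documented order: productivity gain first,
then linkage strengthening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    AllocationError,
    InvalidParameterError,
    LabelError,
    NonProductiveEconomyError,
)
from .economy import FlowTable
from .leontief import (
    CoefficientMatrix,
    DemandShock,
    ImpactResult,
    decompose_impacts,
    household_coefficients,
    spectral_radius,
    technical_coefficients,
)

__all__ = [
    "Scenario",
    "BaseAdjustedResult",
    "build_final_demand",
    "apply_productivity_gain",
    "strengthen_linkages",
    "run_base_and_adjusted",
]

_ALLOC_TOL = 1e-9


@dataclass(frozen=True)
class Scenario:
    """An investment scenario.

    Defaults describe a US$20M genome-sequencing investment split equally
    between R&D and agriculture, with a 10% productivity improvement in the
    agriculture-related sectors and (optionally) strengthened R&D linkages
    toward education, fishing and agriculture.  ``linkage_delta`` defaults to
    zero — linkage strengthening is off unless a magnitude is chosen.
    """

    investment_total: float = 20.0
    allocation: Mapping[str, float] = field(
        default_factory=lambda: {"R&D": 0.5, "agriculture": 0.5}
    )
    productivity_gain: float = 0.10
    productivity_targets: tuple[str, ...] = ("agriculture", "fishing")
    linkage_source: str = "R&D"
    linkage_targets: tuple[str, ...] = ("education", "fishing", "agriculture")
    linkage_delta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "allocation", dict(self.allocation))
        object.__setattr__(self, "productivity_targets", tuple(self.productivity_targets))
        object.__setattr__(self, "linkage_targets", tuple(self.linkage_targets))
        if self.investment_total < 0:
            raise InvalidParameterError("investment_total must be >= 0")
        if self.productivity_gain <= -1:
            raise InvalidParameterError("productivity_gain must exceed -1")
        if self.linkage_delta < 0:
            raise InvalidParameterError("linkage_delta must be >= 0")
        weights = np.array(list(self.allocation.values()), dtype=float)
        if weights.size == 0:
            raise AllocationError("allocation must name at least one sector")
        if np.any(weights < 0):
            raise AllocationError("allocation weights must be nonnegative")
        if abs(weights.sum() - 1.0) > _ALLOC_TOL:
            raise AllocationError(
                f"allocation weights must sum to 1, got {weights.sum():.12g}"
            )

    _KEYS = (
        "investment_total",
        "allocation",
        "productivity_gain",
        "productivity_targets",
        "linkage_source",
        "linkage_targets",
        "linkage_delta",
    )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "Scenario":
        """Build from a config mapping; unknown keys are rejected.

        A nested ``linkage: {source, targets, delta}`` block is accepted as
        an alternative to the three flat linkage keys.
        """
        data = dict(data)
        if "linkage" in data:
            link = dict(data.pop("linkage"))
            for src, dst in (("source", "linkage_source"), ("targets", "linkage_targets"), ("delta", "linkage_delta")):
                if src in link:
                    data[dst] = link.pop(src)
            if link:
                raise InvalidParameterError(f"unknown linkage keys: {sorted(link)}")
        unknown = set(data) - set(cls._KEYS)
        if unknown:
            raise InvalidParameterError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "Scenario":
        """Load a scenario from a YAML or JSON file."""
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data or {})

    def to_dict(self) -> dict:
        return {
            "investment_total": self.investment_total,
            "allocation": dict(self.allocation),
            "productivity_gain": self.productivity_gain,
            "productivity_targets": list(self.productivity_targets),
            "linkage_source": self.linkage_source,
            "linkage_targets": list(self.linkage_targets),
            "linkage_delta": self.linkage_delta,
        }


def build_final_demand(scenario: Scenario, labels: Sequence[str]) -> DemandShock:
    """Spread the investment over the allocated sectors; zero elsewhere."""
    labels = tuple(labels)
    F = np.zeros(len(labels))
    for sector, weight in scenario.allocation.items():
        try:
            j = labels.index(sector)
        except ValueError:
            raise LabelError(f"allocation names unknown sector {sector!r}") from None
        F[j] += scenario.investment_total * weight
    return DemandShock(F=F, labels=labels)


def apply_productivity_gain(
    coeffs: CoefficientMatrix, targets: Sequence[str], gain: float
) -> CoefficientMatrix:
    """Scale target columns of A by ``1/(1+gain)``.

    A positive gain means the sector produces the same output from fewer
    intermediate inputs; its input coefficients shrink.  The result is
    checked to remain productive (only reachable for negative gains).
    """
    if gain <= -1:
        raise InvalidParameterError("gain must exceed -1")
    if gain == 0:
        return coeffs
    idx = [coeffs.index_of(t) for t in targets]
    A = coeffs.A.copy()
    A[:, idx] /= 1.0 + gain
    out = CoefficientMatrix(A=A, labels=coeffs.labels)
    if not out.is_productive():
        raise NonProductiveEconomyError(
            f"productivity change leaves a non-productive matrix "
            f"(spectral radius {out.spectral_radius:.6f})"
        )
    return out


def strengthen_linkages(
    coeffs: CoefficientMatrix,
    source: str,
    targets: Sequence[str],
    delta: float,
) -> CoefficientMatrix:
    """Raise ``A[source, t]`` by ``delta`` for each target sector ``t``.

    Rejected (input unchanged) if any affected column sum reaches 1 or the
    matrix stops being productive.
    """
    if delta < 0:
        raise InvalidParameterError("delta must be >= 0")
    if delta == 0:
        return coeffs
    i = coeffs.index_of(source)
    idx = [coeffs.index_of(t) for t in targets]
    A = coeffs.A.copy()
    A[i, idx] += delta
    bad = [j for j in idx if A[:, j].sum() >= 1.0]
    if bad:
        names = ", ".join(coeffs.labels[j] for j in bad)
        raise NonProductiveEconomyError(
            f"linkage delta {delta} drives column sum(s) to >= 1 for: {names}"
        )
    rho = spectral_radius(A)
    if rho >= 1.0 - 1e-9:
        raise NonProductiveEconomyError(
            f"linkage change leaves a non-productive matrix (spectral radius {rho:.6f})"
        )
    return CoefficientMatrix(A=A, labels=coeffs.labels)


@dataclass(frozen=True)
class BaseAdjustedResult:
    """Impacts under the base and adjusted production structures.

    ``incremental`` is the adjusted-minus-base total output impact per
    sector (both cases evaluated at the same final-demand injection).
    """

    base: ImpactResult
    adjusted: ImpactResult
    incremental: np.ndarray

    def to_dict(self) -> dict:
        return {
            "base": self.base.to_dict(),
            "adjusted": self.adjusted.to_dict(),
            "incremental": self.incremental.tolist(),
        }


def run_base_and_adjusted(
    table: FlowTable,
    scenario: Scenario,
    closure: str = "type_I",
) -> BaseAdjustedResult:
    """Evaluate the scenario's injection under base and adjusted coefficients.

    The adjusted coefficients apply the productivity gain first, then the
    linkage strengthening.  Both cases use the scenario's final-demand
    vector and the same closure.
    """
    coeffs = technical_coefficients(table)
    shock = build_final_demand(scenario, table.labels)
    hh = household_coefficients(table) if closure == "type_II" else None

    adjusted_coeffs = apply_productivity_gain(
        coeffs, scenario.productivity_targets, scenario.productivity_gain
    )
    if scenario.linkage_delta > 0:
        adjusted_coeffs = strengthen_linkages(
            adjusted_coeffs,
            scenario.linkage_source,
            scenario.linkage_targets,
            scenario.linkage_delta,
        )

    base = decompose_impacts(coeffs, shock, closure=closure, household=hh)
    adjusted = decompose_impacts(adjusted_coeffs, shock, closure=closure, household=hh)
    return BaseAdjustedResult(
        base=base, adjusted=adjusted, incremental=adjusted.total - base.total
    )
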