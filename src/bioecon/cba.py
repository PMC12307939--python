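"""Cost-benefit analysis: discounting, NPV and the benefit-cost ratio.

Flows are annual, in million USD, with year-end timing: the first flow
arrives one year out, so a flow at year ``t`` is discounted by
``(1 + r)^t`` for ``t = 1..T``.  This convention matters — under
beginning-of-year timing every present value would be larger by a factor
``(1 + r)``.

    PV(stream) = sum_{t=1..T} stream_t / (1+r)^t
    NPV        = PV(benefits) - PV(costs)
    BCR        = PV(benefits) / PV(costs)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DimensionError,
    InvalidParameterError,
    InvalidRateError,
    InvalidSizeError,
    InvalidSpreadError,
    UndefinedRatioError,
)

__all__ = [
    "CashFlowSeries",
    "CBAResult",
    "present_value",
    "npv",
    "bcr",
    "build_default_cost_stream",
]

DEFAULT_DISCOUNT_RATE = 0.05
DEFAULT_HORIZON_YEARS = 10


@dataclass(frozen=True)
class CashFlowSeries:
    """Annual benefit and cost streams under a common discount rate."""

    benefits: np.ndarray
    costs: np.ndarray
    rate: float = DEFAULT_DISCOUNT_RATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "benefits", np.asarray(self.benefits, dtype=float))
        object.__setattr__(self, "costs", np.asarray(self.costs, dtype=float))
        if self.benefits.ndim != 1 or self.costs.ndim != 1:
            raise DimensionError("benefit and cost streams must be 1-D")
        if self.benefits.shape != self.costs.shape:
            raise DimensionError(
                f"benefit ({self.benefits.size}) and cost ({self.costs.size}) "
                "streams must have equal length"
            )
        if self.benefits.size < 1:
            raise InvalidSizeError("streams must cover at least one year")
        if self.rate <= -1:
            raise InvalidRateError(f"discount rate must exceed -1, got {self.rate}")
        if np.any(self.benefits < 0) or np.any(self.costs < 0):
            raise InvalidParameterError("flow amounts must be nonnegative")

    @property
    def horizon(self) -> int:
        return int(self.benefits.size)


@dataclass(frozen=True)
class CBAResult:
    """Appraisal metrics; ``bcr`` is None when discounted costs are zero."""

    pv_benefits: float
    pv_costs: float
    npv: float
    bcr: float | None
    total_benefits: float
    total_costs: float

    def to_dict(self) -> dict:
        return {
            "pv_benefits": self.pv_benefits,
            "pv_costs": self.pv_costs,
            "npv": self.npv,
            "bcr": self.bcr,
            "total_benefits": self.total_benefits,
            "total_costs": self.total_costs,
        }


def present_value(stream, rate: float) -> float:
    """Discount an annual stream (years 1..T) back to the present."""
    if rate <= -1:
        raise InvalidRateError(f"discount rate must exceed -1, got {rate}")
    amounts = np.asarray(stream, dtype=float)
    if amounts.ndim != 1 or amounts.size < 1:
        raise InvalidSizeError("stream must be a nonempty 1-D sequence")
    t = np.arange(1, amounts.size + 1)
    return float(np.sum(amounts / (1.0 + rate) ** t))


def npv(flows: CashFlowSeries) -> CBAResult:
    """Full appraisal: present values, NPV, BCR and undiscounted totals."""
    pv_b = present_value(flows.benefits, flows.rate)
    pv_c = present_value(flows.costs, flows.rate)
    return CBAResult(
        pv_benefits=pv_b,
        pv_costs=pv_c,
        npv=pv_b - pv_c,
        bcr=pv_b / pv_c if pv_c > 0 else None,
        total_benefits=float(flows.benefits.sum()),
        total_costs=float(flows.costs.sum()),
    )


def bcr(flows: CashFlowSeries) -> float:
    """Discounted benefits over discounted costs."""
    pv_c = present_value(flows.costs, flows.rate)
    if pv_c <= 0:
        raise UndefinedRatioError("benefit-cost ratio undefined: zero discounted cost")
    return present_value(flows.benefits, flows.rate) / pv_c


def build_default_cost_stream(
    investment_total: float, spread_years: int, T: int
) -> np.ndarray:
    """Spread the investment evenly over the first ``spread_years`` years.

    The remaining ``T - spread_years`` years carry zero cost; the stream
    sums to the investment total exactly.  ``spread_years = 1`` gives the
    lump-sum (all cost up front) reading.
    """
    if investment_total < 0:
        raise InvalidParameterError("investment_total must be >= 0")
    if T < 1:
        raise InvalidSizeError("horizon must be >= 1 year")
    if not 1 <= spread_years <= T:
        raise InvalidSpreadError(
            f"spread_years must lie in [1, {T}], got {spread_years}"
        )
    stream = np.zeros(T)
    stream[:spread_years] = investment_total / spread_years
    return stream
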