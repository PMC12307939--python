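"""Multi-horizon cumulative benefit projections.

The benefit stream is geometric: an initial annual benefit ``b`` (million
USD/year) growing at a constant rate ``g`` per year, with year-end timing
``t = 1..T``.  The cumulative benefit through horizon ``T`` is

    C(T) = sum_{t=1}^{T} b (1+g)^{t-1} = b * S_T(g),
    S_T(g) = ((1+g)^T - 1) / g        (S_T(0) = T).

Two printed cumulative totals at distinct horizons identify ``(b, g)``
exactly; :func:`calibrate_projection` recovers them by root-finding on the
ratio equation ``S_{T2}(g) / S_{T1}(g) = C2 / C1``, which is strictly
increasing in ``g``.  Note that anchors whose ratio falls below ``T2/T1``
force a *negative* growth rate — a decelerating benefit stream — which the
calibrated parameters make explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (
    InfeasibleAnchorsError,
    InvalidParameterError,
    InvalidSizeError,
    LabelError,
)
from .leontief import sector_shares

__all__ = [
    "ProjectionParams",
    "project_cumulative_benefits",
    "calibrate_projection",
    "project_by_sector",
    "SectorProjection",
]

DEFAULT_HORIZONS: tuple[int, ...] = (5, 10, 20)

_GROWTH_EPS = 1e-12


@dataclass(frozen=True)
class ProjectionParams:
    """Parameters of the geometric benefit stream."""

    initial_benefit: float
    growth: float = 0.0
    horizons: tuple[int, ...] = DEFAULT_HORIZONS

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizons", tuple(int(T) for T in self.horizons))
        if self.initial_benefit < 0:
            raise InvalidParameterError("initial annual benefit must be >= 0")
        if self.growth <= -1:
            raise InvalidParameterError("annual growth must exceed -1")
        if not self.horizons:
            raise InvalidSizeError("at least one horizon required")
        if any(T <= 0 for T in self.horizons):
            raise InvalidSizeError(f"horizons must be positive integers: {self.horizons}")
        if list(self.horizons) != sorted(self.horizons):
            raise InvalidSizeError("horizons must be sorted ascending")

    def annual_stream(self, T: int) -> np.ndarray:
        """Year-by-year benefits for years 1..T."""
        t = np.arange(T)
        return self.initial_benefit * (1.0 + self.growth) ** t


def _series_sum(g: float, T: int) -> float:
    """``S_T(g) = sum_{t=1..T} (1+g)^(t-1)``, with the g=0 limit handled."""
    if abs(g) < _GROWTH_EPS:
        return float(T)
    return ((1.0 + g) ** T - 1.0) / g


def project_cumulative_benefits(params: ProjectionParams) -> dict[int, float]:
    """Cumulative benefit (million USD) at each horizon."""
    return {T: params.initial_benefit * _series_sum(params.growth, T) for T in params.horizons}


def calibrate_projection(
    anchors: Sequence[tuple[int, float]],
    horizons: Sequence[int] = DEFAULT_HORIZONS,
) -> ProjectionParams:
    """Fit ``(b, g)`` to two (horizon, cumulative total) anchors.

    Solves ``S_{T2}(g)/S_{T1}(g) = C2/C1`` for ``g`` by Brent root-finding
    on ``[-0.99, g_hi]`` (the bracket is widened upward as needed), then
    sets ``b = C1 / S_{T1}(g)``.  When the anchor ratio equals ``T2/T1``
    the stream is flat and ``g = 0`` exactly.
    """
    if len(anchors) != 2:
        raise InvalidParameterError("exactly two anchors required")
    (T1, C1), (T2, C2) = sorted(anchors)
    T1, T2 = int(T1), int(T2)
    if T1 <= 0 or T2 <= T1:
        raise InvalidParameterError(f"anchors need distinct positive horizons, got {T1}, {T2}")
    if C1 < 0 or C2 < C1:
        raise InfeasibleAnchorsError(
            f"cumulative totals cannot decrease: C({T1})={C1}, C({T2})={C2}"
        )
    if C1 == 0:
        if C2 > 0:
            raise InfeasibleAnchorsError("zero early total with positive later total")
        return ProjectionParams(initial_benefit=0.0, growth=0.0, horizons=tuple(horizons))

    ratio = C2 / C1
    flat_ratio = T2 / T1
    if abs(ratio - flat_ratio) < 1e-12:
        g = 0.0
    else:
        def gap(g: float) -> float:
            return _series_sum(g, T2) / _series_sum(g, T1) - ratio

        lo = -0.99
        if gap(lo) >= 0:
            raise InfeasibleAnchorsError(
                f"anchor ratio {ratio:.6g} too close to 1 for a geometric stream"
            )
        hi = 1.0
        while gap(hi) < 0:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - unreachable for sane anchors
                raise InfeasibleAnchorsError("anchor ratio too large to bracket")
        g = brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16)

    b = C1 / _series_sum(g, T1)
    return ProjectionParams(initial_benefit=b, growth=g, horizons=tuple(horizons))


@dataclass(frozen=True)
class SectorProjection:
    """Per-sector cumulative projections with totals and shares."""

    sectors: tuple[str, ...]
    horizons: tuple[int, ...]
    per_sector: dict[str, dict[int, float]]
    totals: dict[int, float]
    shares: dict[int, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "sectors": list(self.sectors),
            "horizons": list(self.horizons),
            "per_sector": {s: {str(T): v for T, v in row.items()} for s, row in self.per_sector.items()},
            "totals": {str(T): v for T, v in self.totals.items()},
            "shares": {str(T): dict(row) for T, row in self.shares.items()},
        }


def project_by_sector(
    initial_benefits: Mapping[str, float],
    growth: Mapping[str, float] | float,
    horizons: Sequence[int] = DEFAULT_HORIZONS,
) -> SectorProjection:
    """Project each sector's geometric stream and the cross-sector shares.

    ``growth`` may be a single rate applied to every sector or a per-sector
    map with exactly the same keys as ``initial_benefits``.  With equal
    growth, sector shares are constant across horizons.
    """
    sectors = tuple(initial_benefits)
    if isinstance(growth, Mapping):
        if set(growth) != set(sectors):
            raise LabelError(
                f"growth sectors {sorted(growth)} do not match benefit sectors {sorted(sectors)}"
            )
        rates = {s: float(growth[s]) for s in sectors}
    else:
        rates = {s: float(growth) for s in sectors}

    horizons = tuple(int(T) for T in horizons)
    per_sector: dict[str, dict[int, float]] = {}
    for s in sectors:
        params = ProjectionParams(
            initial_benefit=float(initial_benefits[s]), growth=rates[s], horizons=horizons
        )
        per_sector[s] = project_cumulative_benefits(params)

    totals = {T: sum(per_sector[s][T] for s in sectors) for T in horizons}
    shares = {
        T: sector_shares({s: per_sector[s][T] for s in sectors}) for T in horizons
    }
    return SectorProjection(
        sectors=sectors, horizons=horizons, per_sector=per_sector, totals=totals, shares=shares
    )
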