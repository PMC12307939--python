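"""End-to-end appraisal pipeline and report rendering.

One call chains the full analysis: build (or load) a flow table, derive
technical coefficients, evaluate the investment scenario under base and
adjusted production structures, project cumulative benefits over the report
horizons, and run the cost-benefit appraisal.  The result is a
:class:`PipelineReport` whose JSON serialization is byte-identical across
runs with identical inputs, carries full-precision values (rounding happens
only in :func:`render_summary`), and validates against the schema shipped
as ``report_schema.json``.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .cba import CashFlowSeries, build_default_cost_stream, npv
from .economy import FlowTable, generate_economy, read_flow_table, validate_economy
from .errors import InvalidParameterError, MissingSectionError, BioeconError
from .projection import (
    DEFAULT_HORIZONS,
    ProjectionParams,
    calibrate_projection,
    project_cumulative_benefits,
)
from .scenario import BaseAdjustedResult, Scenario, run_base_and_adjusted

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "render_summary"]

#: cumulative-benefit anchors used when no projection inputs are supplied:
#: US$35M over the first 5 years rising to US$79M by year 20.
DEFAULT_ANCHORS: tuple[tuple[int, float], ...] = ((5, 35.0), (20, 79.0))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a report.

    Either ``table_path`` (a flow-table CSV) or the synthetic-economy
    triple (``n_sectors``, ``seed``, ``spectral_cap``) defines the economy.
    Projection parameters come either from explicit ``projection_params``
    or by calibrating to two ``anchors``.  The appraisal discounts an
    ``appraisal_years``-long window at ``discount_rate``, with the
    investment spread evenly over ``cost_spread_years`` (default: the whole
    window).
    """

    n_sectors: int = 27
    seed: int = 0
    spectral_cap: float = 0.9
    table_path: str | None = None
    scenario: Scenario = field(default_factory=Scenario)
    closure: str = "type_I"
    anchors: tuple[tuple[int, float], ...] | None = DEFAULT_ANCHORS
    projection_params: ProjectionParams | None = None
    horizons: tuple[int, ...] = DEFAULT_HORIZONS
    discount_rate: float = 0.05
    appraisal_years: int = 10
    cost_spread_years: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizons", tuple(int(T) for T in self.horizons))
        if self.anchors is not None:
            object.__setattr__(
                self, "anchors", tuple((int(T), float(C)) for T, C in self.anchors)
            )
        if self.anchors is None and self.projection_params is None:
            raise InvalidParameterError("either anchors or projection_params required")
        if self.closure not in ("type_I", "type_II"):
            raise InvalidParameterError(f"unknown closure {self.closure!r}")

    _KEYS = (
        "n_sectors",
        "seed",
        "spectral_cap",
        "table_path",
        "scenario",
        "closure",
        "anchors",
        "projection_params",
        "horizons",
        "discount_rate",
        "appraisal_years",
        "cost_spread_years",
    )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        unknown = set(data) - set(cls._KEYS)
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("scenario"), Mapping):
            data["scenario"] = Scenario.from_mapping(data["scenario"])
        if isinstance(data.get("projection_params"), Mapping):
            pp = dict(data["projection_params"])
            pp.setdefault("horizons", data.get("horizons", DEFAULT_HORIZONS))
            data["projection_params"] = ProjectionParams(**pp)
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_mapping(data or {})

    def to_dict(self) -> dict:
        return {
            "n_sectors": self.n_sectors,
            "seed": self.seed,
            "spectral_cap": self.spectral_cap,
            "table_path": self.table_path,
            "scenario": self.scenario.to_dict(),
            "closure": self.closure,
            "anchors": None if self.anchors is None else [list(a) for a in self.anchors],
            "projection_params": (
                None
                if self.projection_params is None
                else {
                    "initial_benefit": self.projection_params.initial_benefit,
                    "growth": self.projection_params.growth,
                    "horizons": list(self.projection_params.horizons),
                }
            ),
            "horizons": list(self.horizons),
            "discount_rate": self.discount_rate,
            "appraisal_years": self.appraisal_years,
            "cost_spread_years": self.cost_spread_years,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class PipelineReport:
    """The full appraisal, serializable to deterministic JSON."""

    provenance: dict
    impacts: dict
    projections: dict
    cba: dict
    rounding: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": "1",
            "provenance": self.provenance,
            "impacts": self.impacts,
            "projections": self.projections,
            "cba": self.cba,
            "rounding": self.rounding,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=False) + "\n"


def _stage(name: str, quiet: bool):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if not quiet:
                status = "failed" if exc_type else "done"
                print(
                    f"[bioecon] {name}: {status} ({time.perf_counter() - self.t0:.3f}s)",
                    file=sys.stderr,
                )
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, quiet: bool = True) -> PipelineReport:
    """Execute all stages in fixed order and assemble the report.

    Any stage failure propagates with the stage name prepended; nothing is
    written to disk here, so a failed run leaves no partial output.
    """
    stage = "load-table"
    try:
        with _stage(stage, quiet):
            if config.table_path is not None:
                table = read_flow_table(config.table_path)
                source = str(config.table_path)
            else:
                table = generate_economy(
                    config.n_sectors,
                    seed=config.seed,
                    spectral_cap=config.spectral_cap,
                    with_household=config.closure == "type_II",
                )
                source = (
                    f"synthetic(n={config.n_sectors}, seed={config.seed}, "
                    f"spectral_cap={config.spectral_cap})"
                )
            violations = validate_economy(table)
            if violations:
                raise InvalidParameterError(
                    f"flow table failed validation: {violations[:3]}"
                )

        stage = "impacts"
        with _stage(stage, quiet):
            impacts: BaseAdjustedResult = run_base_and_adjusted(
                table, config.scenario, closure=config.closure
            )

        stage = "projection"
        with _stage(stage, quiet):
            if config.projection_params is not None:
                params = ProjectionParams(
                    initial_benefit=config.projection_params.initial_benefit,
                    growth=config.projection_params.growth,
                    horizons=config.horizons,
                )
                calibrated = False
            else:
                params = calibrate_projection(config.anchors, horizons=config.horizons)
                calibrated = True
            totals = project_cumulative_benefits(params)

        stage = "cba"
        with _stage(stage, quiet):
            T = config.appraisal_years
            spread = config.cost_spread_years if config.cost_spread_years else T
            benefits = params.annual_stream(T)
            costs = build_default_cost_stream(
                config.scenario.investment_total, spread, T
            )
            cba_result = npv(
                CashFlowSeries(benefits=benefits, costs=costs, rate=config.discount_rate)
            )
    except BioeconError as exc:
        raise type(exc)(f"pipeline stage '{stage}': {exc}") from exc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}': {exc}") from exc

    provenance = {
        "package": "bioecon",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "table_source": source,
        "config": config.to_dict(),
    }
    projections = {
        "initial_annual_benefit": params.initial_benefit,
        "annual_growth": params.growth,
        "calibrated": calibrated,
        "anchors": None if config.anchors is None else [list(a) for a in config.anchors],
        "totals": {str(T): v for T, v in totals.items()},
    }
    cba_section = cba_result.to_dict()
    cba_section.update(
        discount_rate=config.discount_rate,
        horizon_years=config.appraisal_years,
        cost_spread_years=int(spread),
    )
    return PipelineReport(
        provenance=provenance,
        impacts=impacts.to_dict(),
        projections=projections,
        cba=cba_section,
        rounding={
            "currency_decimals": 2,
            "share_decimals": 0,
            "note": "rounding applied at render time only; JSON carries full precision",
        },
    )


def render_summary(report: PipelineReport | dict) -> str:
    """Human-readable summary with the fixed Fig-style row order.

    Currency in million USD rounded to 2 decimals; sector shares to the
    nearest percent.  Raises :class:`MissingSectionError` when a section
    is absent or empty.
    """
    doc = report.to_dict() if isinstance(report, PipelineReport) else dict(report)
    for section in ("impacts", "projections", "cba"):
        if not doc.get(section):
            raise MissingSectionError(f"report is missing the '{section}' section")
    cba = doc["cba"]
    for key in ("total_costs", "pv_costs", "total_benefits", "pv_benefits", "npv"):
        if key not in cba:
            raise MissingSectionError(f"cba section lacks '{key}'")

    lines = [
        f"Total Cost: {cba['total_costs']:.2f}",
        f"Discounted Cost: {cba['pv_costs']:.2f}",
        f"Total Benefit: {cba['total_benefits']:.2f}",
        f"Discounted Benefit: {cba['pv_benefits']:.2f}",
        f"NPV: {cba['npv']:.2f}",
        "BCR: n/a" if cba.get("bcr") is None else f"BCR: {cba['bcr']:.2f}",
    ]

    adjusted = doc["impacts"].get("adjusted")
    if not adjusted:
        raise MissingSectionError("impacts section lacks the adjusted case")
    shares = adjusted.get("shares")
    if shares is not None:
        lines.append("Sector shares (adjusted case):")
        for name, share in zip(adjusted["labels"], shares):
            if round(share) > 0:
                lines.append(f"  {name}: {share:.0f}%")

    totals = doc["projections"].get("totals")
    if not totals:
        raise MissingSectionError("projections section lacks horizon totals")
    lines.append("Cumulative benefits by horizon:")
    for T, v in totals.items():
        lines.append(f"  {T} years: {v:.2f}")
    return "\n".join(lines) + "\n"
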