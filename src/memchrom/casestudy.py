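"""Batch-vs-sequential performance arithmetic and pressure-constraint checks.

Given a fed-batch upstream (fermenter volume, titer, batches per year) and a
capture-module size, this module derives the campaign-level figures of merit
for a batch process and for a sequential counter-current capture process:
capacity utilisation, number of runs/cycles, runtime, per-cycle and
batch-to-batch productivity, and eluent consumption.

Definitions
-----------
* capacity (g/L-membrane): product mass processed per run divided by module
  volume, ``fermenter_volume * titer / (runs * module_volume)``.  Sequential
  loading raises it by the ``capacity_gain_factor`` measured in the
  series-loading study.
* cycle time (min): loading time of the (first) module plus the full
  wash/gradient/regeneration/equilibration protocol, un-overlapped.
  Loading time in CV of feed is ``capacity / titer``.
* per-cycle productivity (g/L/day): ``capacity * 1440 / cycle_time``.
* eluent consumption (L/g): total pumped liquid (feed + protocol buffer)
  per gram of product, ``(capacity/titer + protocol_cv) / capacity`` —
  module volume cancels.
* batch-to-batch productivity (g/L/day): ``capacity / harvest_interval``.
* pressure: module backpressure is linear in flow; modules in series add up,
  instruments contribute a constant offset.  The head module must stay below
  the pressure limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "PressureModel",
    "CaseStudySpec",
    "PerformanceReport",
    "pressure_drop",
    "check_pressure",
    "batch_capacity",
    "cycle_time",
    "productivity_per_cycle",
    "eluent_consumption",
    "size_sequential",
    "batch_runtime",
    "batch_report",
    "sequential_report",
    "compare",
    "case_study_table",
]


@dataclass(frozen=True)
class PressureModel:
    """Linear module backpressure model: bar = coeff * flow(CV/min) per module."""

    per_module_coefficient: float = 0.2  # bar per (CV/min)
    instrument_offset: float = 1.1  # bar
    limit: float = 4.0  # bar

    def __post_init__(self) -> None:
        if self.per_module_coefficient < 0 or self.instrument_offset < 0:
            raise ValueError("pressure coefficients must be >= 0")
        if self.limit <= 0:
            raise ValueError("pressure limit must be > 0")


@dataclass(frozen=True)
class CaseStudySpec:
    """A fed-batch capture case study (one fermenter scale)."""

    fermenter_volume: float  # L
    titer: float = 5.0  # g/L
    batches_per_year: int = 40
    module_volume: float = 5.0  # L
    batch_runs: int = 3
    n_modules_sequential: int = 4
    load_flow_batch: float = 5.0  # CV/min
    load_flow_seq: float = 3.0  # CV/min
    elution_protocol_cv: float = 15.0  # CV (3 wash + 6 gradient + 3 regen + 3 equil)
    elution_flow: float = 5.0  # CV/min
    capacity_gain_factor: float = 1.71
    harvest_interval: float = 365.0 / 40.0  # days
    pressure: PressureModel = field(default_factory=PressureModel)

    def __post_init__(self) -> None:
        for name in (
            "fermenter_volume", "titer", "batches_per_year", "module_volume",
            "batch_runs", "n_modules_sequential", "load_flow_batch",
            "load_flow_seq", "elution_protocol_cv", "elution_flow",
            "harvest_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.capacity_gain_factor < 1:
            raise ValueError("capacity_gain_factor must be >= 1")


@dataclass(frozen=True)
class PerformanceReport:
    """Campaign figures for one mode (batch or sequential) at one scale."""

    mode: str
    capacity: float  # g/L-membrane
    total_membrane_volume: float  # L
    runs_or_cycles: int
    runtime_h: float
    productivity_per_cycle: float  # g/L/day
    productivity_batch_to_batch: float  # g/L/day
    eluent_consumption: float  # L/g
    pressure_bar: float
    pressure_limit: float

    @property
    def pressure_ok(self) -> bool:
        return self.pressure_bar <= self.pressure_limit


def pressure_drop(
    flow_cv_min: float,
    n_modules: int,
    model: PressureModel,
    include_instruments: bool = True,
) -> float:
    """Total backpressure (bar) seen by the head module of a train."""
    if flow_cv_min <= 0:
        raise ValueError("flow must be > 0")
    p = n_modules * model.per_module_coefficient * flow_cv_min
    if include_instruments:
        p += model.instrument_offset
    return p


def check_pressure(flow_cv_min: float, n_modules: int, model: PressureModel) -> float:
    """Pressure check raising on violation; returns the total pressure."""
    p = pressure_drop(flow_cv_min, n_modules, model)
    if p > model.limit:
        raise ValueError(
            f"pressure {p:.2f} bar exceeds the {model.limit:.2f} bar limit "
            f"({n_modules} modules at {flow_cv_min} CV/min)"
        )
    return p


def batch_capacity(spec: CaseStudySpec) -> float:
    """Loading per run in g per L membrane; scale-invariant by construction."""
    return spec.fermenter_volume * spec.titer / (spec.batch_runs * spec.module_volume)


def cycle_time(
    capacity: float, titer: float, load_flow: float, elution_cv: float, elution_flow: float
) -> float:
    """Cycle duration in minutes: feed loading (capacity/titer CV) + protocol."""
    for name, v in (("capacity", capacity), ("titer", titer), ("load_flow", load_flow),
                    ("elution_flow", elution_flow)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return (capacity / titer) / load_flow + elution_cv / elution_flow


def productivity_per_cycle(capacity: float, cycle_time_min: float) -> float:
    """Per-cycle productivity in g per L membrane per day."""
    if cycle_time_min <= 0:
        raise ValueError("cycle time must be > 0")
    return capacity * 1440.0 / cycle_time_min


def eluent_consumption(capacity: float, titer: float, elution_cv: float) -> float:
    """Pumped liquid (feed + protocol buffer) per gram of product, L/g."""
    if capacity <= 0:
        raise ValueError("capacity must be > 0")
    return (capacity / titer + elution_cv) / capacity


def size_sequential(spec: CaseStudySpec) -> tuple[float, int]:
    """Total membrane volume (L, rounded to the nearest liter) and cycle count.

    The sequential process needs ``1/gain`` of the batch membrane volume;
    the cycle count follows from the unrounded volume and the per-cycle
    train volume.
    """
    batch_total = spec.batch_runs * spec.module_volume
    total = batch_total / spec.capacity_gain_factor
    n_cycles = int(round(total / (spec.n_modules_sequential * spec.module_volume)))
    return float(round(total)), max(n_cycles, 1)


def batch_runtime(spec: CaseStudySpec) -> float:
    """Total batch campaign runtime in hours."""
    cap = batch_capacity(spec)
    t_cycle = cycle_time(cap, spec.titer, spec.load_flow_batch,
                         spec.elution_protocol_cv, spec.elution_flow)
    return spec.batch_runs * t_cycle / 60.0


def batch_report(spec: CaseStudySpec) -> PerformanceReport:
    cap = batch_capacity(spec)
    t_cycle = cycle_time(cap, spec.titer, spec.load_flow_batch,
                         spec.elution_protocol_cv, spec.elution_flow)
    return PerformanceReport(
        mode="batch",
        capacity=cap,
        total_membrane_volume=spec.batch_runs * spec.module_volume,
        runs_or_cycles=spec.batch_runs,
        runtime_h=spec.batch_runs * t_cycle / 60.0,
        productivity_per_cycle=productivity_per_cycle(cap, t_cycle),
        productivity_batch_to_batch=cap / spec.harvest_interval,
        eluent_consumption=eluent_consumption(cap, spec.titer, spec.elution_protocol_cv),
        pressure_bar=pressure_drop(spec.load_flow_batch, 1, spec.pressure),
        pressure_limit=spec.pressure.limit,
    )


def sequential_report(spec: CaseStudySpec) -> PerformanceReport:
    """Sequential figures; runtime is the un-overlapped bound
    ``n_cycles * n_modules * cycle_time`` (a modeling choice, see docs)."""
    cap = batch_capacity(spec) * spec.capacity_gain_factor
    t_cycle = cycle_time(cap, spec.titer, spec.load_flow_seq,
                         spec.elution_protocol_cv, spec.elution_flow)
    total_volume, n_cycles = size_sequential(spec)
    return PerformanceReport(
        mode="sequential",
        capacity=cap,
        total_membrane_volume=total_volume,
        runs_or_cycles=n_cycles,
        runtime_h=n_cycles * spec.n_modules_sequential * t_cycle / 60.0,
        productivity_per_cycle=productivity_per_cycle(cap, t_cycle),
        productivity_batch_to_batch=cap / spec.harvest_interval,
        eluent_consumption=eluent_consumption(cap, spec.titer, spec.elution_protocol_cv),
        pressure_bar=pressure_drop(spec.load_flow_seq, spec.n_modules_sequential, spec.pressure),
        pressure_limit=spec.pressure.limit,
    )


def compare(batch: PerformanceReport, sequential: PerformanceReport) -> dict[str, float]:
    """Percentage changes of the sequential mode relative to batch."""

    def delta(a: float, b: float) -> float:
        return (b / a - 1.0) * 100.0

    return {
        "capacity_pct": delta(batch.capacity, sequential.capacity),
        "productivity_pct": delta(batch.productivity_per_cycle, sequential.productivity_per_cycle),
        "eluent_pct": delta(batch.eluent_consumption, sequential.eluent_consumption),
        "runtime_pct": delta(batch.runtime_h, sequential.runtime_h),
    }


def case_study_table(specs: dict[str, CaseStudySpec]) -> pd.DataFrame:
    """Assemble a campaign-comparison table (rows = figures of merit).

    ``specs`` maps scenario labels (e.g. ``"2000 L"``) to their case-study
    specifications; each scenario yields a batch and a sequential column.
    """
    columns: dict[str, dict[str, float]] = {}
    for label, spec in specs.items():
        for report in (batch_report(spec), sequential_report(spec)):
            columns[f"{label} {report.mode}"] = {
                "Total membrane volume (L)": report.total_membrane_volume,
                "Module size (L)": spec.module_volume,
                "Modules per cycle (-)": 1 if report.mode == "batch" else spec.n_modules_sequential,
                "Runs/cycles (-)": report.runs_or_cycles,
                "Runtime (h)": round(report.runtime_h, 2),
                "Capacity (g/L)": round(report.capacity, 2),
                "Productivity run/cycle (g/L/day)": round(report.productivity_per_cycle),
                "Productivity batch-to-batch (g/L/day)": round(report.productivity_batch_to_batch, 2),
                "Eluent consumption (L/g)": round(report.eluent_consumption, 2),
                "Pressure head module (bar)": round(report.pressure_bar, 2),
            }
    return pd.DataFrame(columns)
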