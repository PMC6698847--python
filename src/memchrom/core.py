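"""Shared domain types, unit conventions and configuration schema.

Unit conventions used throughout the package
--------------------------------------------
* protein concentrations            g/L
* modifier (salt) concentration     mol/L
* membrane loading ``q``            g per L of membrane bed volume
* volumes                           mL  (module geometry), L (case studies)
* volumetric flow                   mL/min, or CV/min resolved against the
                                    membrane volume of the module it acts on
* lengths                           cm
* axial dispersion coefficients     cm**2/s (the customary literature unit;
                                    converted internally where minutes are the
                                    time base)
* time                              min internally; hours only in reports
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "Component",
    "ComponentSystem",
    "ModuleGeometry",
    "ZoneFluidParams",
    "FlowState",
    "OperatingStep",
    "ProcessSchedule",
    "Chromatogram",
    "cv_to_volume",
    "validate_config",
    "serialize_config",
    "DEFAULT_VOIDAGE",
    "DEFAULT_DAX",
]

#: total voidage of a membrane module: liquid-accessible fraction of the
#: membrane bed volume including the hold-up zones (size-independent because
#: membrane pores are convective).
DEFAULT_VOIDAGE = 0.8

#: per-zone axial dispersion coefficients, cm^2/s, zones 1..5
#: (inlet pipe, annular gap, membrane, inner cylinder, outlet pipe).
DEFAULT_DAX = (9e-4, 9e-4, 5e-3, 250.0, 250.0)

COMPONENT_ROLES = ("product", "weak_binder", "strong_binder", "tracer", "modifier")


class ConfigError(ValueError):
    """Raised when a configuration violates a domain invariant."""


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Component:
    """A chemical species tracked by the simulator.

    ``id`` follows the convention product = 1, weak binder = 2,
    strong binder = 3; the modifier (salt) is a separate species.
    """

    id: int
    name: str
    role: str = "product"

    def __post_init__(self) -> None:
        if self.role not in COMPONENT_ROLES:
            raise ConfigError(
                f"component {self.name!r}: role must be one of {COMPONENT_ROLES}, got {self.role!r}"
            )


@dataclass(frozen=True)
class ComponentSystem:
    """The feed: a list of components plus their feed concentrations (g/L)."""

    components: tuple[Component, ...]
    feed_concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"component ids must be unique, got {ids}")
        if len(self.feed_concentrations) != len(self.components):
            raise ConfigError(
                "feed_concentrations must match components "
                f"({len(self.feed_concentrations)} vs {len(self.components)})"
            )
        if any(c < 0 for c in self.feed_concentrations):
            raise ConfigError("feed concentrations must be >= 0")
        n_mod = sum(1 for c in self.components if c.role == "modifier")
        if n_mod > 1:
            raise ConfigError("at most one modifier component per system")

    @property
    def binding(self) -> tuple[Component, ...]:
        """Components that can adsorb (everything except modifier/tracer)."""
        return tuple(c for c in self.components if c.role not in ("modifier", "tracer"))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def concentration(self, name: str) -> float:
        for c, conc in zip(self.components, self.feed_concentrations):
            if c.name == name:
                return conc
        raise KeyError(name)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

ZONE_NAMES = ("inlet", "annular_gap", "membrane", "inner_cylinder", "outlet")


@dataclass(frozen=True)
class ModuleGeometry:
    """Physical description of a wrap-around membrane module.

    The module is resolved into five 1-D flow zones: inlet pipe (1),
    flow-splitting annular gap (2), radial-flow membrane (3), stream-merging
    inner cylinder (4) and outlet pipe (5).  ``membrane_volume`` is the
    membrane bed volume and defines the column volume (CV).  ``voidage`` is
    the *total* voidage: the liquid-accessible fraction of the membrane bed
    volume, hold-up zones included; the internal membrane porosity follows
    from it (see :meth:`membrane_porosity`).
    """

    membrane_volume: float  # mL, = CV
    bed_height: float = 0.8  # cm, radial thickness of the membrane wrap
    voidage: float = DEFAULT_VOIDAGE
    #: zone lengths cm, zones 1..5 (zone 3 length equals bed_height)
    zone_lengths: tuple[float, float, float, float, float] = (2.0, 2.5, 0.8, 2.5, 2.0)
    #: hold-up volumes of zones 1, 2, 4, 5 in mL (zone 3 volume = membrane_volume)
    holdup_volumes: tuple[float, float, float, float] = (0.05, 0.2, 0.25, 0.1)

    def __post_init__(self) -> None:
        if not self.membrane_volume > 0:
            raise ConfigError(f"membrane_volume must be > 0, got {self.membrane_volume}")
        if not 0 < self.voidage < 1:
            raise ConfigError(f"voidage must lie in (0, 1), got {self.voidage}")
        if len(self.zone_lengths) != 5:
            raise ConfigError("exactly five zone lengths required")
        if any(l <= 0 for l in self.zone_lengths):
            raise ConfigError(f"zone lengths must be > 0, got {self.zone_lengths}")
        if any(v <= 0 for v in self.holdup_volumes):
            raise ConfigError(f"hold-up volumes must be > 0, got {self.holdup_volumes}")
        if abs(self.zone_lengths[2] - self.bed_height) > 1e-9:
            raise ConfigError(
                "zone 3 length must equal the membrane bed height "
                f"({self.zone_lengths[2]} vs {self.bed_height})"
            )
        if not 0 < self.membrane_porosity < 1:
            raise ConfigError(
                "total voidage inconsistent with hold-up volumes: implied membrane "
                f"porosity {self.membrane_porosity:.3f} outside (0, 1)"
            )

    @property
    def zone_volumes(self) -> tuple[float, float, float, float, float]:
        """Zone volumes in mL, zones 1..5."""
        h = self.holdup_volumes
        return (h[0], h[1], self.membrane_volume, h[2], h[3])

    @property
    def zone_cross_sections(self) -> tuple[float, float, float, float, float]:
        """Flow cross-section of each zone in cm^2 (volume / length)."""
        return tuple(v / l for v, l in zip(self.zone_volumes, self.zone_lengths))

    @property
    def membrane_porosity(self) -> float:
        """Internal porosity of the membrane bed.

        Consistency with the tracer-measured total voidage requires
        ``holdup + eps_m * Vm = voidage * Vm``; the hold-up zones are fully
        liquid-accessible.
        """
        holdup = sum(self.holdup_volumes)
        return (self.voidage * self.membrane_volume - holdup) / self.membrane_volume

    @property
    def accessible_volume(self) -> float:
        """Total liquid-accessible volume in mL (= voidage * membrane_volume)."""
        return sum(self.holdup_volumes) + self.membrane_porosity * self.membrane_volume


@dataclass(frozen=True)
class ZoneFluidParams:
    """Per-zone axial dispersion coefficients (cm^2/s)."""

    dax: tuple[float, float, float, float, float] = DEFAULT_DAX

    def __post_init__(self) -> None:
        if len(self.dax) != 5:
            raise ConfigError("five per-zone Dax values required")
        if any(d <= 0 for d in self.dax):
            raise ConfigError(f"Dax must be > 0 in every zone, got {self.dax}")


@dataclass(frozen=True)
class FlowState:
    """Superficial and interstitial velocities implied by a volumetric flow."""

    volumetric_flow: float  # mL/min
    geometry: ModuleGeometry

    def __post_init__(self) -> None:
        if not self.volumetric_flow > 0:
            raise ConfigError(f"volumetric flow must be > 0, got {self.volumetric_flow}")

    @property
    def cv_per_min(self) -> float:
        return self.volumetric_flow / self.geometry.membrane_volume

    def superficial_velocity(self, zone: int) -> float:
        """Superficial linear velocity u = V'/A in zone ``zone`` (1-based), cm/min.

        In zones 2 and 4 the axial flow varies along the zone; the value here
        is for the full volumetric flow (zone entry for 2, zone exit for 4).
        For zone 3 the flow is radial and distributed across the membrane area.
        """
        area = self.geometry.zone_cross_sections[zone - 1]
        return self.volumetric_flow / area

    @property
    def interstitial_velocity(self) -> float:
        """Interstitial radial velocity in the membrane zone, cm/min."""
        return self.superficial_velocity(3) / self.geometry.membrane_porosity


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OperatingStep:
    """One operating step: load / wash / gradient / regenerate / equilibrate.

    ``duration`` in CV, ``flow`` in CV/min; modifier concentration follows a
    linear gradient from ``modifier_start`` to ``modifier_end`` across the
    step's CV span.
    """

    name: str
    duration: float  # CV
    flow: float  # CV/min
    inlet_composition: Mapping[str, float] = field(default_factory=dict)  # g/L
    modifier_start: float = 0.0  # mol/L
    modifier_end: float | None = None  # mol/L; None -> constant

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ConfigError(f"step {self.name!r}: duration must be > 0")
        if not self.flow > 0:
            raise ConfigError(f"step {self.name!r}: flow must be > 0")
        if self.modifier_start < 0 or (self.modifier_end is not None and self.modifier_end < 0):
            raise ConfigError(f"step {self.name!r}: modifier bounds must be >= 0")
        if any(v < 0 for v in self.inlet_composition.values()):
            raise ConfigError(f"step {self.name!r}: inlet concentrations must be >= 0")

    @property
    def modifier_stop(self) -> float:
        return self.modifier_start if self.modifier_end is None else self.modifier_end

    def duration_min(self, geometry: ModuleGeometry) -> float:
        """Step duration in minutes (CV / (CV/min) — geometry-independent)."""
        return self.duration / self.flow


@dataclass(frozen=True)
class ProcessSchedule:
    """An ordered, non-empty list of operating steps with unique names."""

    steps: tuple[OperatingStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ConfigError("schedule must contain at least one step")
        names = [s.name for s in self.steps]
        if len(set(names)) != len(names):
            raise ConfigError(f"step names must be unique within a schedule, got {names}")

    @property
    def total_cv(self) -> float:
        return sum(s.duration for s in self.steps)

    def total_minutes(self, geometry: ModuleGeometry) -> float:
        return sum(s.duration_min(geometry) for s in self.steps)

    def __iter__(self):
        return iter(self.steps)

    def __len__(self) -> int:
        return len(self.steps)


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------


@dataclass
class Chromatogram:
    """Outlet time series of a simulation or measurement.

    ``concentrations`` maps component name -> g/L on the shared time grid;
    ``modifier`` is the salt trace in mol/L, ``flow`` the volumetric flow in
    mL/min.
    """

    time: np.ndarray  # min, strictly increasing
    concentrations: dict[str, np.ndarray]  # g/L
    modifier: np.ndarray | None = None  # mol/L
    flow: np.ndarray | None = None  # mL/min
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) < 2:
            raise ConfigError("chromatogram needs a 1-D time grid with >= 2 points")
        if np.any(np.diff(self.time) <= 0):
            raise ConfigError("chromatogram time grid must be strictly increasing")
        for name, c in self.concentrations.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.time.shape:
                raise ConfigError(f"trace {name!r} length mismatch with time grid")
            self.concentrations[name] = c
        for attr in ("modifier", "flow"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise ConfigError(f"{attr} trace length mismatch with time grid")
                setattr(self, attr, v)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(self.concentrations)

    def mass(self, name: str, t0: float | None = None, t1: float | None = None) -> float:
        """Eluted mass of ``name`` in mg over [t0, t1] (defaults: whole trace).

        Requires a flow trace; mass = integral of c * V' dt.
        """
        if self.flow is None:
            raise ConfigError("chromatogram has no flow trace; cannot integrate mass")
        t0 = self.time[0] if t0 is None else t0
        t1 = self.time[-1] if t1 is None else t1
        mask = (self.time >= t0) & (self.time <= t1)
        if mask.sum() < 2:
            return 0.0
        t = self.time[mask]
        return float(np.trapezoid(self.concentrations[name][mask] * self.flow[mask], t))

    def pool(self, t0: float, t1: float) -> tuple[float, dict[str, float]]:
        """Volume (mL) and per-component mass (mg) collected over [t0, t1]."""
        if self.flow is None:
            raise ConfigError("chromatogram has no flow trace; cannot pool")
        mask = (self.time >= t0) & (self.time <= t1)
        if mask.sum() < 2:
            return 0.0, {k: 0.0 for k in self.concentrations}
        t = self.time[mask]
        vol = float(np.trapezoid(self.flow[mask], t))
        masses = {k: float(np.trapezoid(self.concentrations[k][mask] * self.flow[mask], t))
                  for k in self.concentrations}
        return vol, masses


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def cv_to_volume(duration_cv: float, geometry: ModuleGeometry) -> float:
    """Convert a CV count into mL against a module's membrane volume."""
    if duration_cv < 0:
        raise ConfigError(f"CV count must be >= 0, got {duration_cv}")
    return duration_cv * geometry.membrane_volume


# ---------------------------------------------------------------------------
# configuration parsing
# ---------------------------------------------------------------------------

_DEFAULT_COMPONENTS = (
    {"id": 1, "name": "product", "role": "product", "feed": 5.0},
    {"id": 2, "name": "weak_binder", "role": "weak_binder", "feed": 0.5},
    {"id": 3, "name": "strong_binder", "role": "strong_binder", "feed": 0.5},
)


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise ConfigError(f"missing required field {key!r} in section {where!r}")
    return section[key]


def validate_config(raw: str | Mapping):
    """Parse and validate a YAML configuration.

    Returns ``(geometry, fluidics, components, schedule)``.  Omitted fields
    receive the documented defaults (voidage 0.8, the per-zone dispersion
    set, the three-component feed).  Violated invariants raise
    :class:`ConfigError` naming the offending field.
    """
    if isinstance(raw, str):
        data = yaml.safe_load(io.StringIO(raw))
    else:
        data = dict(raw)
    if not isinstance(data, Mapping):
        raise ConfigError("configuration must be a mapping")

    geo = dict(data.get("geometry") or {})
    vm = _require(geo, "membrane_volume_mL", "geometry")
    kwargs = {"membrane_volume": float(vm)}
    if "voidage" in geo:
        kwargs["voidage"] = float(geo["voidage"])
    if "bed_height_cm" in geo:
        kwargs["bed_height"] = float(geo["bed_height_cm"])
    if "zone_lengths_cm" in geo:
        kwargs["zone_lengths"] = tuple(float(x) for x in geo["zone_lengths_cm"])
        kwargs.setdefault("bed_height", kwargs["zone_lengths"][2])
    elif "bed_height_cm" in geo:
        base = list((2.0, 2.5, 0.8, 2.5, 2.0))
        base[2] = kwargs["bed_height"]
        kwargs["zone_lengths"] = tuple(base)
    if "holdup_volumes_mL" in geo:
        kwargs["holdup_volumes"] = tuple(float(x) for x in geo["holdup_volumes_mL"])
    geometry = ModuleGeometry(**kwargs)

    flu = dict(data.get("fluidics") or {})
    if "dax_cm2_s" in flu:
        dax = tuple(float(x) for x in flu["dax_cm2_s"])
    else:
        dax = DEFAULT_DAX
    fluidics = ZoneFluidParams(dax=dax)

    comp_section = data.get("components")
    comp_specs = comp_section if comp_section else _DEFAULT_COMPONENTS
    comps, feeds = [], []
    for spec in comp_specs:
        comps.append(
            Component(
                id=int(_require(spec, "id", "components")),
                name=str(_require(spec, "name", "components")),
                role=str(spec.get("role", "product")),
            )
        )
        feeds.append(float(spec.get("feed", 0.0)))
    components = ComponentSystem(components=tuple(comps), feed_concentrations=tuple(feeds))

    sched_section = data.get("schedule")
    if sched_section:
        steps = []
        for s in sched_section:
            steps.append(
                OperatingStep(
                    name=str(_require(s, "name", "schedule")),
                    duration=float(_require(s, "duration_cv", "schedule")),
                    flow=float(_require(s, "flow_cv_min", "schedule")),
                    inlet_composition=dict(s.get("inlet_g_L") or {}),
                    modifier_start=float(s.get("modifier_start_M", 0.0)),
                    modifier_end=(None if s.get("modifier_end_M") is None
                                  else float(s["modifier_end_M"])),
                )
            )
        schedule = ProcessSchedule(steps=tuple(steps))
    else:
        schedule = None

    return geometry, fluidics, components, schedule


def serialize_config(
    geometry: ModuleGeometry,
    fluidics: ZoneFluidParams,
    components: ComponentSystem,
    schedule: ProcessSchedule | None,
) -> str:
    """Serialize a validated configuration back to YAML (round-trippable)."""
    data: dict = {
        "geometry": {
            "membrane_volume_mL": geometry.membrane_volume,
            "bed_height_cm": geometry.bed_height,
            "voidage": geometry.voidage,
            "zone_lengths_cm": list(geometry.zone_lengths),
            "holdup_volumes_mL": list(geometry.holdup_volumes),
        },
        "fluidics": {"dax_cm2_s": list(fluidics.dax)},
        "components": [
            {"id": c.id, "name": c.name, "role": c.role, "feed": f}
            for c, f in zip(components.components, components.feed_concentrations)
        ],
    }
    if schedule is not None:
        data["schedule"] = [
            {
                "name": s.name,
                "duration_cv": s.duration,
                "flow_cv_min": s.flow,
                "inlet_g_L": dict(s.inlet_composition),
                "modifier_start_M": s.modifier_start,
                "modifier_end_M": s.modifier_end,
            }
            for s in schedule.steps
        ]
    return yaml.safe_dump(data, sort_keys=False)
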