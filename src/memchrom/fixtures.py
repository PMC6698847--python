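"""Deterministic synthetic fixtures: everything measured but not published.

The quantitative isotherm and mass-transfer parameters of the original
membrane modules are not public, so this module provides a fully
parameterised *synthetic* reference setup that reproduces the qualitative
behaviour of a laboratory-scale ("Nano"-like) wrap-around membrane module:

* a 3 mL module with 8 mm bed height, total voidage 0.8 and the per-zone
  dispersion set (9e-4 / 9e-4 / 5e-3 / 250 / 250 cm^2/s) that makes the
  hold-up zones behave like stirred tanks (sharp front, long tailing);
* SYNTHETIC salt-dependent Langmuir parameter sets for an ion-exchange and a
  hydrophobic-interaction membrane, with IgG-like static capacities of a few
  tens of g/L and opposing salt behaviour;
* three-component feeds (product / weak binder / strong binder) at the
  validation scale (1 g/L + 0.2 g/L side components) or the case-study
  scale (5 g/L + 1 g/L);
* tracer pulse curves generated by the zonal model itself, and finite-bath
  batch-adsorption datasets solved self-consistently from the Langmuir
  equilibrium and the bath mass balance.

All stochastic outputs are reproducible from ``(seed, spec)`` alone.  The
parameter presets are labelled SYNTHETIC in metadata: they are this
package's choices, not fitted values of any real membrane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .core import (
    Component,
    ComponentSystem,
    ModuleGeometry,
    OperatingStep,
    ProcessSchedule,
    ZoneFluidParams,
)
from .isotherms import BatchAdsorptionPoint, IsothermDataset, IsothermParams, q_equilibrium
from .tracer import TracerCurve
from .zonal import MembraneModule

__all__ = [
    "FixtureSpec",
    "nano_geometry",
    "iex_isotherm",
    "hic_isotherm",
    "make_feed",
    "make_tracer_curve",
    "make_isotherm_dataset",
    "make_module",
    "make_symmetric_module",
    "default_elution_protocol",
    "IEX_MODIFIER_LEVELS",
    "HIC_MODIFIER_LEVELS",
    "FEED_FRACTIONS",
]

#: ammonium-sulfate levels of the ion-exchange isotherm series, mol/L.
IEX_MODIFIER_LEVELS = (0.02, 0.05, 0.1, 0.15, 0.2, 0.3)
#: ammonium-sulfate levels of the hydrophobic-interaction series, mol/L.
HIC_MODIFIER_LEVELS = (0.2, 0.5, 0.6, 0.8, 1.0)
#: feed volume fractions of the five bath points (x mL of feed in 6 mL total).
FEED_FRACTIONS = (1 / 6, 2 / 6, 3 / 6, 5 / 6, 1.0)

#: single-layer 13 mm membrane coupon volume, mL (pi * 0.65^2 * 0.0275 cm).
COUPON_VOLUME_ML = 0.0365
#: liquid bath volume after removing the pre-binding sample, mL.
BATH_VOLUME_ML = 5.0


@dataclass(frozen=True)
class FixtureSpec:
    """Reproducible fixture configuration.

    ``noise_cv`` is the coefficient of variation of multiplicative Gaussian
    measurement noise (0 = noise-free); all randomness derives from
    ``seed``.
    """

    seed: int = 0
    noise_cv: float = 0.0
    module_volume: float = 3.0  # mL, Nano-like preset
    feed_preset: str = "case_study"  # or "validation" / "zero"
    resolution = None  # zonal-model grid override

    metadata: dict = field(default_factory=lambda: {"parameter_origin": "SYNTHETIC"})


def nano_geometry(module_volume: float = 3.0) -> ModuleGeometry:
    """Nano-like module: 3 mL bed, 8 mm bed height, total voidage 0.8.

    The internal zone dimensions (pipe, annular gap, inner cylinder) are not
    published for any real device; the defaults here are assumptions
    consistent with a laboratory module of this size whose outlet hold-up
    dominates the residence-time tailing (inner cylinder + outlet pipe are
    ~30% of the accessible volume, membrane porosity 0.5), and are scaled
    with the bed volume.
    """
    scale = module_volume / 3.0
    return ModuleGeometry(
        membrane_volume=module_volume,
        holdup_volumes=(0.1 * scale, 0.1 * scale, 0.5 * scale, 0.2 * scale),
    )


def iex_isotherm(kla: float = 6.0) -> IsothermParams:
    """SYNTHETIC ion-exchange parameter set (binds at low salt, elutes high).

    Components ordered product (ID 1), weak binder (ID 2), strong binder
    (ID 3).  Capacities of a few tens of g/L and Henry coefficients falling
    steeply with ammonium sulfate are typical for IgG on a cation-exchange
    membrane; the numbers are this package's synthetic choice.
    """
    return IsothermParams(
        a1=np.array([-35.0, -6.0, -40.0]),
        a2=np.array([55.0, 10.0, 150.0]),
        b1=np.array([0.05, 0.02, 0.10]),
        b2=np.array([-1.9, -1.7, -2.0]),
        l1=0.0,
        kla=kla,
        modifier_range=(0.01, 1.1),
    )


def hic_isotherm(kla: float = 6.0) -> IsothermParams:
    """SYNTHETIC hydrophobic-interaction set (binds at high salt, elutes low).

    The Henry coefficients grow as a power of the salt concentration and a
    small linear ``l1`` term adds the salting-out excess above Langmuir
    saturation.
    """
    return IsothermParams(
        a1=np.array([20.0, 8.0, 15.0]),
        a2=np.array([35.0, 12.0, 60.0]),
        b1=np.array([40.0, 15.0, 90.0]),
        b2=np.array([2.2, 1.8, 2.6]),
        l1=0.3,
        kla=kla,
        modifier_range=(0.01, 1.1),
    )


def make_feed(spec: FixtureSpec | None = None, preset: str | None = None) -> ComponentSystem:
    """Three-component feed plus modifier slot.

    Presets: ``case_study`` (5 g/L product, 1 g/L total side components),
    ``validation`` (1 g/L product, 0.2 g/L side components), ``zero``.
    """
    preset = preset or (spec.feed_preset if spec else "case_study")
    # side components split between the weak binder (fragments, host-cell
    # proteins) and the strong binder (aggregates, ~1% of a clarified culture)
    levels = {
        "case_study": (5.0, 0.95, 0.05),
        "validation": (1.0, 0.19, 0.01),
        "zero": (0.0, 0.0, 0.0),
    }
    if preset not in levels:
        raise ValueError(f"unknown feed preset {preset!r}")
    p, w, s = levels[preset]
    return ComponentSystem(
        components=(
            Component(1, "product", "product"),
            Component(2, "weak_binder", "weak_binder"),
            Component(3, "strong_binder", "strong_binder"),
            Component(9, "salt", "modifier"),
        ),
        feed_concentrations=(p, w, s, 0.0),
    )


def make_module(
    spec: FixtureSpec | None = None,
    resin: str = "IEX",
    resolution=None,
    name: str | None = None,
) -> MembraneModule:
    """A fully parameterised synthetic reference module."""
    spec = spec or FixtureSpec()
    iso = iex_isotherm() if resin.upper() == "IEX" else hic_isotherm()
    return MembraneModule(
        nano_geometry(spec.module_volume),
        ZoneFluidParams(),
        iso,
        species=make_feed(spec),
        resolution=resolution,
        name=name or f"{resin.lower()}_module",
    )


def make_symmetric_module(
    spec: FixtureSpec | None = None,
    resin: str = "IEX",
    resolution=None,
    name: str | None = None,
) -> MembraneModule:
    """A membrane stack packed in a column: symmetric-peak comparator.

    Emulates mounting the membrane layers in a plain chromatography column:
    negligible hold-up zones and ordinary (small) dispersion everywhere, so
    the device behaves like a classical 1-D general-rate column and elutes
    symmetric peaks.  Membrane porosity matches the wrap-around module.
    """
    spec = spec or FixtureSpec()
    vm = spec.module_volume
    holdup = (1e-3 * vm / 3.0,) * 4
    voidage = 0.5 + sum(holdup) / vm
    geo = ModuleGeometry(membrane_volume=vm, voidage=voidage, holdup_volumes=holdup)
    iso = iex_isotherm() if resin.upper() == "IEX" else hic_isotherm()
    return MembraneModule(
        geo,
        ZoneFluidParams(dax=(9e-4, 9e-4, 5e-3, 9e-4, 9e-4)),
        iso,
        species=make_feed(spec),
        resolution=resolution,
        name=name or f"{resin.lower()}_stack",
    )


def default_elution_protocol(
    resin: str = "IEX", flow: float = 5.0, gradient_cv: float = 6.0
) -> ProcessSchedule:
    """Wash 3 CV / gradient / regenerate 3 CV / equilibrate 3 CV.

    The modifier gradient runs 0.02 -> 1 M for ion exchange and 1 -> 0.02 M
    for hydrophobic interaction (opposing salt behaviour).  The default is
    the 6 CV gradient at 5 CV/min of the capture protocol; steeper gradients
    (1 CV) at lower flow resolve the hold-up tailing and are used for the
    fractionating (iCCC) runs.
    """
    lo, hi = 0.02, 1.0
    start, stop = (lo, hi) if resin.upper() == "IEX" else (hi, lo)
    return ProcessSchedule(
        (
            OperatingStep("wash", 3.0, flow, {}, start),
            OperatingStep("gradient", gradient_cv, flow, {}, start, stop),
            OperatingStep("regenerate", 3.0, flow, {}, stop),
            OperatingStep("equilibrate", 3.0, flow, {}, stop, start),
        )
    )


def make_tracer_curve(
    spec: FixtureSpec,
    flow: float,
    pulse_volume: float = 0.099,  # mL injected
    tracer_concentration: float = 5.0,  # g/L
    horizon_tbar: float = 8.0,
    molecular_weight: float | None = None,
    resolution=None,
) -> TracerCurve:
    """Run the zonal model with a non-binding tracer pulse at ``flow`` mL/min.

    Returns the outlet detector trace; with ``spec.noise_cv > 0``,
    multiplicative Gaussian noise (seeded) is added.  The injection centroid
    ``pulse_volume / (2 flow)`` plays the role of the instrument dead time
    when the curve is analysed with the voidage relation.
    """
    geo = nano_geometry(spec.module_volume)
    module = MembraneModule(
        geo,
        ZoneFluidParams(),
        species=ComponentSystem((Component(1, "tracer", "tracer"),), (0.0,)),
        resolution=resolution,
        name="tracer_fixture",
    )
    flow_cv = flow / geo.membrane_volume
    pulse_cv = pulse_volume / geo.membrane_volume
    tbar = geo.accessible_volume / flow
    wash_cv = flow_cv * horizon_tbar * tbar
    sched = ProcessSchedule(
        (
            OperatingStep("inject", pulse_cv, flow_cv, {"tracer": tracer_concentration}),
            OperatingStep("wash", wash_cv, flow_cv),
        )
    )
    res = module.simulate(sched)
    signal = res.chromatogram.concentrations["tracer"]
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal * rng.normal(1.0, spec.noise_cv, signal.shape)
        signal = np.clip(signal, 0.0, None)
    return TracerCurve(
        time=res.chromatogram.time,
        signal=signal,
        volumetric_flow=flow,
        tracer_molecular_weight=molecular_weight,
    )


def _bath_equilibrium(
    c_feed: np.ndarray, c_mod: float, params: IsothermParams, v_total: float, v_ads: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the finite-bath equilibrium: supernatant c* and loading q.

    Mass balance per component: ``c_feed V_total = c* V_total + q(c*) V_ads``.
    """
    phase = v_ads / v_total

    def balance(c):
        c = np.maximum(c, 0.0)
        return c + q_equilibrium(c, c_mod, params) * phase - c_feed

    sol = root(balance, x0=np.minimum(c_feed, c_feed / (1.0 + phase)), method="hybr", tol=1e-12)
    c_star = np.maximum(sol.x, 0.0)
    if np.max(np.abs(balance(sol.x))) > 1e-8 * max(c_feed.max(), 1.0):
        raise RuntimeError(
            f"no finite-bath equilibrium at cmod={c_mod}: unphysical isotherm preset?"
        )
    return c_star, q_equilibrium(c_star, c_mod, params)


def make_isotherm_dataset(
    spec: FixtureSpec,
    params: IsothermParams | None = None,
    modifier_levels=IEX_MODIFIER_LEVELS,
    feed_fractions=FEED_FRACTIONS,
    resin_label: str = "IEX",
    feed_preset: str | None = None,
) -> IsothermDataset:
    """Generate a batch-adsorption dataset from a known parameter set.

    For every (modifier level, feed dilution) pair the supernatant and
    loading are solved self-consistently from the competitive Langmuir
    equilibrium and the bath mass balance; elution concentrations are the
    loss-free counterpart ``c_elu = q V_ads / V_total``.  Multiplicative
    noise (``spec.noise_cv``) is applied to the measured supernatants.
    """
    if not len(modifier_levels) or not len(feed_fractions):
        raise ValueError("modifier levels and feed fractions must be non-empty")
    params = params or (iex_isotherm() if resin_label.upper() == "IEX" else hic_isotherm())
    feed = make_feed(spec, preset=feed_preset)
    names = tuple(c.name for c in feed.binding)
    c_stock = np.array([feed.concentration(n) for n in names])
    rng = np.random.default_rng(spec.seed)
    points = []
    for c_mod in modifier_levels:
        for frac in feed_fractions:
            c_feed = c_stock * frac
            c_star, q = _bath_equilibrium(c_feed, c_mod, params, BATH_VOLUME_ML, COUPON_VOLUME_ML)
            c_elu = q * COUPON_VOLUME_ML / BATH_VOLUME_ML
            if spec.noise_cv > 0:
                c_star = np.clip(c_star * rng.normal(1.0, spec.noise_cv, c_star.shape), 0.0, c_feed)
                c_elu = np.clip(c_elu * rng.normal(1.0, spec.noise_cv, c_elu.shape), 0.0, None)
            points.append(
                BatchAdsorptionPoint(
                    names=names,
                    c_feed=c_feed,
                    c_star_binding=c_star,
                    c_star_elution=c_elu,
                    v_total=BATH_VOLUME_ML,
                    v_ads=COUPON_VOLUME_ML,
                    c_mod=float(c_mod),
                )
            )
    return IsothermDataset(points=tuple(points), resin_label=resin_label)
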