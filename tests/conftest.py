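import numpy as np
import pytest

from memchrom import (
    Component,
    ComponentSystem,
    ModuleGeometry,
    OperatingStep,
    ProcessSchedule,
    ZoneFluidParams,
)
from memchrom.fixtures import (
    FixtureSpec,
    default_elution_protocol,
    iex_isotherm,
    make_feed,
    make_module,
    nano_geometry,
)


@pytest.fixture(scope="session")
def geometry() -> ModuleGeometry:
    return nano_geometry()


@pytest.fixture(scope="session")
def fluidics() -> ZoneFluidParams:
    return ZoneFluidParams()


@pytest.fixture(scope="session")
def feed() -> ComponentSystem:
    return make_feed(preset="case_study")


@pytest.fixture(scope="session")
def iex_params():
    return iex_isotherm()


@pytest.fixture(scope="session")
def tracer_system() -> ComponentSystem:
    return ComponentSystem(
        components=(Component(1, "tracer", "tracer"),), feed_concentrations=(0.0,)
    )


@pytest.fixture(scope="session")
def capture_protocol() -> ProcessSchedule:
    return default_elution_protocol("IEX")


@pytest.fixture(scope="session")
def tracer_pulse_schedule(geometry):
    """99 uL tracer pulse at 1 mL/min followed by a long wash."""
    flow_cv = 1.0 / geometry.membrane_volume
    tbar = geometry.accessible_volume / 1.0
    return ProcessSchedule(
        (
            OperatingStep("inject", 0.099 / geometry.membrane_volume, flow_cv,
                          {"tracer": 5.0}),
            OperatingStep("wash", flow_cv * 10 * tbar, flow_cv),
        )
    )
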