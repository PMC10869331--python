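import numpy as np
import pytest

from ecpella.mcs_devices import DeviceSettings, HQCurve
from ecpella.presets import get_scenario, initial_state
from ecpella.sim_engine import ProtocolSchedule, run_simulation

# Reduced-resolution engine settings used throughout the unit suite; the
# acceptance tests use the full 0.2 ms step where the criterion demands it.
FAST_DT = 0.0005
FAST_DECIMATION = 2


@pytest.fixture(scope="session")
def hq_default():
    return HQCurve.default()


@pytest.fixture(scope="session")
def normal_scenario():
    return get_scenario("NORMAL")


@pytest.fixture(scope="session")
def lvf_scenario():
    return get_scenario("LVF")


@pytest.fixture(scope="session")
def bvf_scenario():
    return get_scenario("BVF")


@pytest.fixture(scope="session")
def bvf_ph_scenario():
    return get_scenario("BVF_PH")


def settled_run(scenario, duration=20.0, vaecmo=0.0, level=0,
                dt=FAST_DT, decimation=FAST_DECIMATION):
    sched = ProtocolSchedule(
        segments=((duration, DeviceSettings(vaecmo_flow=vaecmo,
                                            impella_level=level)),),
        dt=dt)
    return run_simulation(scenario.params, scenario.chambers, sched,
                          initial_state(scenario),
                          limiter_gain=scenario.devices["limiter_gain"],
                          decimation=decimation)


def last_beats(ts, cycle_length, n_beats=2):
    """Window spanning the final `n_beats` complete beats."""
    spb = int(round(cycle_length / ts.dt_sample))
    n = n_beats * spb
    return ts.window(len(ts) - n - 1, len(ts) - 1)


@pytest.fixture(scope="session")
def normal_settled(normal_scenario):
    """A 20 s settled NORMAL run shared across tests."""
    return settled_run(normal_scenario, duration=20.0)


@pytest.fixture(scope="session")
def lvf_settled(lvf_scenario):
    return settled_run(lvf_scenario, duration=20.0)
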