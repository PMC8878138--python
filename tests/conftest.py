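"""Shared fixtures: default model objects and session-scoped scenario runs.

The three study-condition runs are expensive enough (a mechanics re-solve
per simulated day) to be shared across test modules; every test treats
them as read-only.
"""

import numpy as np
import pytest

from osteoremod import (
    BoneGeometry,
    DelayParams,
    DensityProfileParams,
    MaterialParams,
    build_mesh,
    initial_density_field,
    run_scenario,
    scenario_preset,
)


@pytest.fixture(scope="session")
def geometry():
    return BoneGeometry()


@pytest.fixture(scope="session")
def profile():
    return DensityProfileParams()


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture(scope="session")
def mesh(geometry):
    return build_mesh(geometry, 0.1)


@pytest.fixture(scope="session")
def arctan_density(mesh, profile):
    return initial_density_field(mesh, profile)


@pytest.fixture(scope="session")
def run_sedentary():
    return run_scenario(scenario_preset("sedentary"))


@pytest.fixture(scope="session")
def run_intermittent():
    return run_scenario(scenario_preset("intermittent"))


@pytest.fixture(scope="session")
def run_continuous():
    """Continuous running, no activation delay, full 8 weeks."""
    return run_scenario(scenario_preset("continuous"))


@pytest.fixture(scope="session")
def run_continuous_slow():
    """Continuous running with the delayed ('slow') activation, 30 days."""
    return run_scenario(
        scenario_preset("continuous", delay=DelayParams(mode="slow"), duration=30.0)
    )


def snapshot_at(result, day: float):
    """Index of the snapshot closest to a given simulated day."""
    return int(np.argmin(np.abs(result.times - day)))


def forward_round_trip(duration: float = 14.0):
    """Forward-simulate synthetic observations and re-derive the activity set.

    A reduced-magnitude activity law drives two modulation-free runs at the
    W1 and W3 energy levels with frozen mechanics, so the density change is
    spatially uniform and unclamped.  The mean-density changes are turned
    into equivalent cortical-thickness observations and fed back through
    the calibration.  Returns ``(generating_params, calibration_report)``.
    """
    from osteoremod import (
        ActivityParams,
        GroupObservation,
        ModulationParams,
        ScenarioConfig,
        derive_rate_params,
    )
    from osteoremod.calibration import shift_from_mean_density_change

    ref = ActivityParams()
    gen = ActivityParams(
        k1=ref.k1 / 1000.0, k2=ref.k2 / 1000.0,
        A1=ref.A1 / 1000.0, A2=ref.A2 / 1000.0,
    )
    profile = DensityProfileParams(amplitude_divisor=5.0, offset=0.5)
    geometry = BoneGeometry()
    changes = {}
    for name, W in (("intermittent", gen.W1), ("continuous", gen.W3)):
        cfg = ScenarioConfig(
            scenario_energy=W,
            duration=duration,
            activity=gen,
            modulation=ModulationParams(enabled=False),
            coupling_interval=1e9,
            snapshot_interval=duration,
            profile=profile,
            mesh_size=0.15,
        )
        res = run_scenario(cfg)
        changes[name] = res.mean_density[-1] - res.mean_density[0]

    control = 957.0
    obs = [GroupObservation("sedentary", control, 1.0, duration)]
    for name, dm in changes.items():
        shift = shift_from_mean_density_change(dm, geometry, profile)
        obs.append(GroupObservation(name, control - shift * 1000.0, 1.0, duration))
    report = derive_rate_params(
        tuple(obs), geometry=geometry, profile=profile, reference=ref
    )
    return gen, report
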