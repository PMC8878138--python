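"""Mechanobiological core: cell-activity law, modulation, delay, time stepping.

Bone density evolves through the combined action of osteoblasts (formation)
and osteoclasts (resorption).  Both activities are piecewise-linear in the
elastic mechanical energy W developed in the structure, measured as a
deviation from the homeostatic level W0 where no net remodeling occurs:

* osteoblasts:  0 for W <= W0, k1*(W - W0) on (W0, W1), capped at A1 above;
* osteoclasts:  0 for W <= W0, k2*(W - W0) on (W0, W3) (k2 < 0), capped at
  A2 above.

The printed parameter set satisfies A1 = k1*(W1 - W0) and
A2 = k2*(W3 - W0), so the caps are exactly the linear branches evaluated at
their upper thresholds.  The combined activity is positive on (W0, W2),
zero at W0 and at W2, and negative above W2.

A second, density-dependent factor (alpha - rho)^n modulates each activity:
it is maximal where bone is sparse (marrow side, cells abundant) and
vanishes as rho approaches alpha (dense cortex, no active remodeling
cells).  alpha and n are tabulated at the two energy levels W1 and W3 and
interpolated in W between them.

Rates carry the unit mg/mm^3 per 56 days; dividing by the mass-density
scale rho_ref (1 mg/mm^3) turns them into dimensionless-density rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .geometry import (
    BoneGeometry,
    DensityProfileParams,
    MaterialParams,
    Mesh,
    build_mesh,
    initial_density_field,
)
from .mechanics import (
    DENSITY_FLOOR,
    EnergyField,
    LoadCase,
    scenario_energy_scaling,
    solve_axial_compression,
)

RATE_PERIOD_DAYS = 56.0  # activity rates are "per 56 days"


@dataclass(frozen=True)
class ActivityParams:
    """Piecewise-linear cell-activity law parameters.

    Slopes k1 > 0 and k2 < 0 in mg/(mJ mm^3 56 d); caps A1 > 0, A2 < 0 in
    mg/(mm^3 56 d); energy thresholds W0 < W1 < W2 < W3 in mJ.
    ``rho_bone_ini`` is the homeostatic baseline density the activities are
    deviations from (it enters the law only through W0).
    """

    k1: float = 386.64e5
    k2: float = -375.0e5
    A1: float = 1992.36
    A2: float = -2232.38
    W0: float = 3.1847e-4
    W1: float = 3.7e-4
    W2: float = 3.72e-4
    W3: float = 3.78e-4
    rho_bone_ini: float = 0.56

    def __post_init__(self) -> None:
        if not (self.W0 < self.W1 < self.W2 < self.W3):
            raise ValueError("energy thresholds must satisfy W0 < W1 < W2 < W3")
        if self.k1 <= 0 or self.k2 >= 0 or self.A1 <= 0 or self.A2 >= 0:
            raise ValueError("require k1 > 0, k2 < 0, A1 > 0, A2 < 0")
        if abs(self.A1 - self.k1 * (self.W1 - self.W0)) / self.A1 > 1e-3:
            raise ValueError("A1 must equal k1*(W1 - W0) within 0.1%")
        if abs(self.A2 - self.k2 * (self.W3 - self.W0)) / abs(self.A2) > 1e-3:
            raise ValueError("A2 must equal k2*(W3 - W0) within 0.1%")


@dataclass(frozen=True)
class ModulationParams:
    """(alpha - rho)^n modulation parameters at the two energy anchors."""

    alpha_ob_W1: float = 1.0009
    alpha_oc_W1: float = 1.0
    alpha_ob_W3: float = 1.0007
    alpha_oc_W3: float = 1.0
    n_W1: float = 13.6
    n_W3: float = 5.0
    n_interpolation: Literal["linear", "quadratic"] = "linear"
    enabled: bool = True

    def __post_init__(self) -> None:
        for a in (self.alpha_ob_W1, self.alpha_oc_W1, self.alpha_ob_W3, self.alpha_oc_W3):
            if a < 1.0 - 1e-12:
                raise ValueError("alpha must not be below 1")
        if self.n_W1 <= 0 or self.n_W3 <= 0:
            raise ValueError("n must be positive")
        if self.n_interpolation not in ("linear", "quadratic"):
            raise ValueError("n_interpolation must be 'linear' or 'quadratic'")


#: Mapping from the dimensionless delay coefficient c to a first-order-lag
#: rate per day: rate = -DELAY_RATE_SCALE / ln(c).  The scale is calibrated
#: once so that the delayed ("slow") continuous run spreads the bulk of its
#: density loss from the first week out to about a month (roughly 1% lost
#: over 30 days, against more than 1.5% within 7 days undelayed); see
#: docs/methods.md.
DELAY_RATE_SCALE = 2e-3


@dataclass(frozen=True)
class DelayParams:
    """Activation-delay configuration.

    ``none`` applies the target activity instantly.  ``slow`` (coefficient
    1e-5) and ``low`` (coefficient 1e-8) low-pass filter the realized cell
    activity with a first-order lag whose rate per day is
    ``-DELAY_RATE_SCALE / ln(coefficient)``.
    """

    mode: Literal["none", "slow", "low"] = "none"
    coefficient: float | None = None

    _DEFAULTS = {"slow": 1e-5, "low": 1e-8}

    def __post_init__(self) -> None:
        if self.mode not in ("none", "slow", "low"):
            raise ValueError("delay mode must be none, slow or low")
        if self.mode != "none":
            c = self.coefficient
            if c is None:
                object.__setattr__(self, "coefficient", self._DEFAULTS[self.mode])
            elif c <= 0 or c >= 1:
                raise ValueError("delay coefficient must be in (0, 1)")

    @property
    def rate_per_day(self) -> float | None:
        if self.mode == "none":
            return None
        return -DELAY_RATE_SCALE / np.log(self.coefficient)


def osteoblast_activity(W, params: ActivityParams | None = None):
    """Osteoblast activity (mg/mm^3 per 56 d) at energy W (mJ).

    Zero at and below homeostasis, linear in (W - W0) up to W1, capped at A1
    from W1 on (the cap applies at exactly W = W1).
    """
    if params is None:
        params = ActivityParams()
    W = np.asarray(W, dtype=float)
    # the cap applies at exactly W = W1 (closed upper branch); below it the
    # linear branch k1*(W - W0) may differ from A1 in the last printed digit
    out = np.where(
        W >= params.W1,
        params.A1,
        np.clip(params.k1 * (W - params.W0), 0.0, params.A1),
    )
    return out if out.ndim else float(out)


def osteoclast_activity(W, params: ActivityParams | None = None):
    """Osteoclast activity (negative, mg/mm^3 per 56 d) at energy W (mJ)."""
    if params is None:
        params = ActivityParams()
    W = np.asarray(W, dtype=float)
    out = np.where(
        W >= params.W3,
        params.A2,
        np.clip(params.k2 * (W - params.W0), params.A2, 0.0),
    )
    return out if out.ndim else float(out)


def combined_activity(W, params: ActivityParams | None = None):
    """Net cell activity: sum of osteoblast and osteoclast terms.

    Positive on (W0, W2), zero at W0 and W2, negative above W2 and constant
    at A1 + A2 for W >= W3.
    """
    return osteoblast_activity(W, params) + osteoclast_activity(W, params)


def modulation(density, alpha: float, n: float):
    """Density modulation factor (alpha - rho)^n, clamped to 0 above alpha."""
    rho = np.asarray(density, dtype=float)
    base = np.clip(alpha - rho, 0.0, None)
    out = base**n
    return out if out.ndim else float(out)


def _blend(W, lo: float, hi: float, params: ActivityParams, mode: str):
    """Interpolate a tabulated quantity between the W1 and W3 anchors."""
    W = np.asarray(W, dtype=float)
    t = np.clip((W - params.W1) / (params.W3 - params.W1), 0.0, 1.0)
    if mode == "quadratic":
        t = t**2
    return lo + (hi - lo) * t


def interpolate_n(W, mod: ModulationParams | None = None,
                  activity_params: ActivityParams | None = None):
    """Power n at energy W: n_W1 below W1, n_W3 above W3, blended between."""
    if mod is None:
        mod = ModulationParams()
    if activity_params is None:
        activity_params = ActivityParams()
    out = _blend(W, mod.n_W1, mod.n_W3, activity_params, mod.n_interpolation)
    return out if np.ndim(out) else float(out)


def interpolate_alpha(W, cell: Literal["ob", "oc"],
                      mod: ModulationParams | None = None,
                      activity_params: ActivityParams | None = None):
    """Modulation amplitude alpha for one cell type at energy W."""
    if mod is None:
        mod = ModulationParams()
    if activity_params is None:
        activity_params = ActivityParams()
    if cell == "ob":
        lo, hi = mod.alpha_ob_W1, mod.alpha_ob_W3
    elif cell == "oc":
        lo, hi = mod.alpha_oc_W1, mod.alpha_oc_W3
    else:
        raise ValueError("cell must be 'ob' or 'oc'")
    out = _blend(W, lo, hi, activity_params, mod.n_interpolation)
    return out if np.ndim(out) else float(out)


def delayed_activity(target_activity, current_filtered, delay: DelayParams, dt: float):
    """One first-order-lag update of the realized cell activity.

    With mode ``none`` the target is returned unchanged; otherwise
    ``new = current + rate_per_day * (target - current) * dt`` so the
    filtered activity approaches the target monotonically.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if delay.mode == "none":
        return target_activity
    r = delay.rate_per_day
    step = min(r * dt, 1.0)  # unconditionally stable
    return current_filtered + step * (np.asarray(target_activity) - current_filtered)


@dataclass
class MassLedger:
    """Bookkeeping of bone mass formed and resorbed (mg), full bone."""

    formed: float = 0.0
    resorbed: float = 0.0

    @property
    def net(self) -> float:
        return self.formed + self.resorbed

    def record(self, delta_rho: np.ndarray, element_volume: np.ndarray,
               rho_ref: float, volume_factor: float) -> None:
        dm = delta_rho * element_volume * rho_ref * volume_factor
        self.formed += float(dm[dm > 0].sum())
        self.resorbed += float(dm[dm < 0].sum())


@dataclass
class RemodelingState:
    """Evolving simulation state (per-element fields)."""

    time: float
    density: np.ndarray
    activity_ob: np.ndarray     # realized (delay-filtered) activities
    activity_oc: np.ndarray
    energy: EnergyField
    element_energy: np.ndarray  # per-element driving energy W_e (mJ)
    applied_ob: np.ndarray | None = None   # effective activities after the
    applied_oc: np.ndarray | None = None   # density clamp (zero where pinned)


def element_energies(
    energy: EnergyField,
    scenario_energy: float,
    mode: Literal["global", "local"],
    initial_reference_sed: float,
) -> np.ndarray:
    """Per-element driving energy from one solved configuration.

    ``global``: every element is driven by the current total structure
    energy.  ``local``: the scenario energy is redistributed in proportion
    to the element's strain-energy density relative to the volume-mean SED
    of the initial configuration, so the volume mean of W_e at t = 0 equals
    the scenario energy.
    """
    if mode == "global":
        return np.full_like(energy.sed, energy.total_energy)
    if mode == "local":
        return scenario_energy * energy.sed / initial_reference_sed
    raise ValueError("energy mode must be 'global' or 'local'")


def density_rate(
    density: np.ndarray,
    W_e: np.ndarray,
    activity: ActivityParams,
    mod: ModulationParams,
    material: MaterialParams,
):
    """Target (undelayed) modulated activities and the density cap.

    Returns ``(a_ob, a_oc, cap)``: modulated activities in mg/mm^3 per
    56 d and the per-element maximum admissible density (the larger of the
    two interpolated alphas).
    """
    a_ob = osteoblast_activity(W_e, activity)
    a_oc = osteoclast_activity(W_e, activity)
    if mod.enabled:
        n = interpolate_n(W_e, mod, activity)
        alpha_ob = interpolate_alpha(W_e, "ob", mod, activity)
        alpha_oc = interpolate_alpha(W_e, "oc", mod, activity)
        a_ob = modulation_arr(density, alpha_ob, n) * a_ob
        a_oc = modulation_arr(density, alpha_oc, n) * a_oc
        cap = np.maximum(alpha_ob, alpha_oc)
    else:
        cap = np.ones_like(np.asarray(density, float))
    return a_ob, a_oc, np.broadcast_to(cap, np.shape(density))


def modulation_arr(density, alpha, n):
    """Vectorized (alpha - rho)^n with element-wise alpha and n."""
    base = np.clip(np.asarray(alpha, float) - np.asarray(density, float), 0.0, None)
    return base ** np.asarray(n, float)


@dataclass
class SimulationResult:
    """Recorded output of one scenario run."""

    times: np.ndarray                      # snapshot times (days)
    mean_density: np.ndarray               # volume-averaged density per snapshot
    front_radius: np.ndarray               # mid-density interface radius (mm; nan if absent)
    global_activity_ob: np.ndarray         # volume-averaged realized activities
    global_activity_oc: np.ndarray
    density_snapshots: list                # per-element density arrays
    mesh: Mesh
    geometry: BoneGeometry
    initial_density: np.ndarray
    final_state: RemodelingState
    mass_ledger: MassLedger
    load_scale: float
    homeostatic_energy: float
    config: object = None

    @property
    def mean_density_change_pct(self) -> float:
        return 100.0 * (self.mean_density[-1] / self.mean_density[0] - 1.0)


def step_density(
    state: RemodelingState,
    dt: float,
    activity: ActivityParams,
    mod: ModulationParams,
    material: MaterialParams,
    delay: DelayParams,
    mesh: Mesh,
    ledger: MassLedger | None = None,
    *,
    density_floor: float = DENSITY_FLOOR,
    volume_factor: float = 2.0,
) -> RemodelingState:
    """One explicit-Euler density update at fixed mechanics.

    d rho/dt = (mod_ob * A_ob + mod_oc * A_oc) / (rho_ref * 56 d), with the
    realized activities optionally low-pass filtered by the activation
    delay, and the density clamped to [floor, alpha].
    """
    if dt <= 0 or dt > 0.5:
        raise ValueError("dt must be in (0, 0.5] days")
    t_ob, t_oc, cap = density_rate(state.density, state.element_energy,
                                   activity, mod, material)
    a_ob = delayed_activity(t_ob, state.activity_ob, delay, dt)
    a_oc = delayed_activity(t_oc, state.activity_oc, delay, dt)
    rate = (a_ob + a_oc) / (material.rho_ref * RATE_PERIOD_DAYS)
    proposed = state.density + rate * dt
    if not np.all(np.isfinite(proposed)):
        raise FloatingPointError(
            "non-finite density after step at t=%.3f d" % (state.time + dt)
        )
    new_density = np.clip(proposed, density_floor, cap)
    # effective activities: scaled by how much of the proposed change the
    # clamp let through (zero for elements pinned at the floor or at alpha)
    delta_prop = proposed - state.density
    delta_real = new_density - state.density
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(delta_prop != 0.0, delta_real / delta_prop, 1.0)
    if ledger is not None:
        ledger.record(delta_real, mesh.element_volume,
                      material.rho_ref, volume_factor)
    return RemodelingState(
        time=state.time + dt,
        density=new_density,
        activity_ob=np.asarray(a_ob, float),
        activity_oc=np.asarray(a_oc, float),
        energy=state.energy,
        element_energy=state.element_energy,
        applied_ob=np.asarray(a_ob, float) * ratio,
        applied_oc=np.asarray(a_oc, float) * ratio,
    )


def run_scenario(config) -> SimulationResult:
    """Integrate a remodeling scenario and record summary time series.

    ``config`` is a :class:`osteoremod.scenarios.ScenarioConfig`.  The
    mechanics problem is re-solved every ``coupling_interval`` days of
    simulated time (staggered coupling); between re-solves the density
    field evolves with frozen element energies.
    """
    from .metrics import radial_average_profile, volume_averaged_density

    geometry: BoneGeometry = config.geometry
    profile: DensityProfileParams = config.profile
    material: MaterialParams = config.material
    activity: ActivityParams = config.activity
    mod: ModulationParams = config.modulation
    delay: DelayParams = config.delay

    mesh = build_mesh(geometry, config.mesh_size)
    density = initial_density_field(mesh, profile)
    volume_factor = 2.0 if geometry.axisymmetric_half_model else 1.0

    base_load = LoadCase(body_mass=config.body_mass)
    _, hom_energy = solve_axial_compression(
        mesh, density, material, base_load, half_model=geometry.axisymmetric_half_model
    )
    W_hom = hom_energy.total_energy
    load_scale = scenario_energy_scaling(config.scenario_energy, W_hom)
    load = base_load.scaled(load_scale)

    _, energy0 = solve_axial_compression(
        mesh, density, material, load, half_model=geometry.axisymmetric_half_model
    )
    ref_sed0 = energy0.reference_sed
    W_e = element_energies(energy0, config.scenario_energy, config.energy_mode, ref_sed0)

    state = RemodelingState(
        time=0.0,
        density=density.copy(),
        activity_ob=np.zeros(mesh.n_elements),
        activity_oc=np.zeros(mesh.n_elements),
        energy=energy0,
        element_energy=W_e,
    )
    ledger = MassLedger()

    times = [0.0]
    radii, prof = radial_average_profile(state.density, mesh)
    mean0 = volume_averaged_density(state.density, mesh)
    means = [mean0]
    fronts = [_safe_front(radii, prof, config.front_threshold)]
    g_ob = [float(state.activity_ob @ mesh.element_volume / mesh.element_volume.sum())]
    g_oc = [float(state.activity_oc @ mesh.element_volume / mesh.element_volume.sum())]
    snapshots = [state.density.copy()]

    dt = config.dt
    n_steps = int(round(config.duration / dt))
    next_couple = config.coupling_interval
    next_snap = config.snapshot_interval
    eps = 1e-9
    for i in range(n_steps):
        state = step_density(
            state, dt, activity, mod, material, delay, mesh, ledger,
            density_floor=config.density_floor, volume_factor=volume_factor,
        )
        if state.time + eps >= next_couple and i < n_steps - 1:
            _, energy = solve_axial_compression(
                mesh, state.density, material, load,
                half_model=geometry.axisymmetric_half_model,
                density_floor=config.density_floor,
            )
            state.energy = energy
            state.element_energy = element_energies(
                energy, config.scenario_energy, config.energy_mode, ref_sed0
            )
            next_couple += config.coupling_interval
        if state.time + eps >= next_snap or i == n_steps - 1:
            radii, prof = radial_average_profile(state.density, mesh)
            times.append(state.time)
            means.append(volume_averaged_density(state.density, mesh))
            fronts.append(_safe_front(radii, prof, config.front_threshold))
            vols = mesh.element_volume
            g_ob.append(float(state.applied_ob @ vols / vols.sum()))
            g_oc.append(float(state.applied_oc @ vols / vols.sum()))
            snapshots.append(state.density.copy())
            while next_snap <= state.time + eps:
                next_snap += config.snapshot_interval

    return SimulationResult(
        times=np.asarray(times),
        mean_density=np.asarray(means),
        front_radius=np.asarray(fronts),
        global_activity_ob=np.asarray(g_ob),
        global_activity_oc=np.asarray(g_oc),
        density_snapshots=snapshots,
        mesh=mesh,
        geometry=geometry,
        initial_density=snapshots[0],
        final_state=state,
        mass_ledger=ledger,
        load_scale=load_scale,
        homeostatic_energy=W_hom,
        config=config,
    )


def _safe_front(radii, profile, threshold):
    from .metrics import interface_radius

    try:
        return interface_radius(radii, profile, threshold)
    except ValueError:
        return float("nan")
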