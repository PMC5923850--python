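"""Explicit finite-difference time integration of the Pennes bioheat equation.

The solver advances a forward-time, centered-space (FTCS) discretization of

    rho*C dT/dt = d/dx( k dT/dx ) + W_b*rho_b*C_b*(T_b - T) + Q_met

on the cell-centered mesh from :mod:`scaldsim.mesh`, under a three-phase
boundary schedule: (i) hot porridge in contact with the skin, convectively
cooled by ambient air at its outer surface; (ii) after instantaneous porridge
removal, the bare skin surface exposed to ambient air; (iii) optionally,
tempered-water cooling of the skin surface.  The inner (deep-muscle) boundary
is adiabatic throughout.  All convective exchanges are Robin conditions
applied as face fluxes on the boundary cell.

Two implementations of the update coexist on purpose: :func:`pennes_step` is
a transparent numpy single step used as the reference in tests, and
``_advance`` is a numba-compiled multi-step kernel used by
:func:`run_schedule` for production runs; a test pins their equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .config import NumericsConfig
from .damage import damage_rate
from .materials import (
    DamageKinetics,
    PerfusionModel,
    PorridgeModel,
    standard_skin_stack,
)
from .mesh import Mesh, build_mesh, check_domain_size, check_stability, interface_conductance

__all__ = [
    "BoundaryPhase",
    "SimulationState",
    "TraceRecord",
    "robin_flux",
    "pennes_step",
    "remove_porridge",
    "run_schedule",
]


@dataclass(frozen=True)
class BoundaryPhase:
    """One contiguous stretch of the boundary schedule.

    The outer boundary is a Robin condition with coefficient ``h`` (W/m^2 K)
    against ambient temperature ``t_ambient`` (°C); the inner boundary is
    always adiabatic.  ``porridge_present`` says whether the porridge layer is
    still on the skin during this phase.
    """

    t_start: float
    t_end: float
    h: float
    t_ambient: float
    porridge_present: bool

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("convective coefficient h must be non-negative")
        if self.t_end <= self.t_start:
            raise ValueError("phase must have positive duration")


@dataclass
class SimulationState:
    """Node temperatures (°C), current time (s), accumulated basal damage."""

    temperatures: np.ndarray
    time: float = 0.0
    omega: float = 0.0


@dataclass
class TraceRecord:
    """Sampled time series at named depths plus the damage integral.

    Porridge columns are NaN after removal.  ``snapshots`` maps requested
    times to full depth profiles (position, temperature).
    """

    times: np.ndarray
    series: dict[str, np.ndarray]
    snapshots: dict[float, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times})
        for name, values in self.series.items():
            df[name] = values
        return df

    @property
    def omega(self) -> float:
        return float(self.series["omega"][-1])

    def omega_at(self, t: float) -> float:
        """Damage integral at the last sample time <= t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.series["omega"][idx])

    @property
    def peak_basal_temperature(self) -> float:
        return float(np.nanmax(self.series["T_basal"]))


def robin_flux(h: float, t_surface: float, t_ambient: float) -> float:
    """Convective heat flux h*(T_surface - T_ambient), W/m^2.

    Positive when heat leaves the domain (surface hotter than ambient).
    """
    if h < 0:
        raise ValueError("convective coefficient h must be non-negative")
    return h * (t_surface - t_ambient)


# ---------------------------------------------------------------------------
# Reference numpy step


def _boundary_conductance(h: float, k0: float, dx: float) -> float:
    # Robin exchange in series with conduction through the outer half-cell,
    # so the "surface" the ambient sees is the cell face, not the cell center.
    if h <= 0.0:
        return 0.0
    return 1.0 / (1.0 / h + dx / (2.0 * k0))


def pennes_step(
    state: SimulationState,
    mesh: Mesh,
    phase: BoundaryPhase,
    perfusion: PerfusionModel,
    dt: float,
    kinetics: DamageKinetics | None = None,
    basal_weights: tuple[float, float] = (1.0, 0.0),
) -> SimulationState:
    """One explicit FTCS update of the Pennes equation (reference version).

    Refuses to step if ``dt`` violates the Fourier stability bound.  When
    ``kinetics`` is given, the basal damage integral is advanced one
    rectangle-rule increment using the post-step basal temperature sampled
    with ``basal_weights`` across the epidermis-dermis interface.
    """
    report = check_stability(mesh, dt)
    if not report.stable:
        raise ValueError(
            f"unstable time step: max Fourier number {report.max_fourier:.3f} >= 0.5"
        )
    if not (phase.t_start <= state.time < phase.t_end):
        raise ValueError("phase does not cover the current simulation time")
    T = state.temperatures
    kf = interface_conductance(mesh, T)
    k = mesh.node_conductivity(T)
    rhoc = mesh.node_heat_capacity(T)

    face = kf * np.diff(T) / mesh.dx  # energy flux from node i+1 into node i
    net = np.zeros_like(T)
    net[:-1] += face
    net[1:] -= face
    u = _boundary_conductance(phase.h, k[0], mesh.dx)
    net[0] += u * (phase.t_ambient - T[0])
    # inner face adiabatic: nothing to add at the last node

    perfused = np.zeros(mesh.n_nodes, dtype=bool)
    names = [layer.name for layer in mesh.stack]
    for i, m in enumerate(mesh.material):
        perfused[i] = m >= 0 and names[m] in perfusion.perfused_layers
    src = np.where(
        perfused, perfusion.volumetric_coefficient * (perfusion.t_b - T) + perfusion.q_met, 0.0
    )

    t_new = T + dt * (net / mesh.dx + src) / rhoc
    omega = state.omega
    if kinetics is not None:
        w1, w2 = basal_weights
        tb = w1 * t_new[mesh.basal_index] + w2 * t_new[mesh.basal_index + 1]
        omega += damage_rate(kinetics, float(tb)) * dt
    return SimulationState(temperatures=t_new, time=state.time + dt, omega=omega)


def remove_porridge(state: SimulationState, mesh: Mesh) -> tuple[SimulationState, Mesh]:
    """Instantaneously remove the porridge layer.

    Tissue temperatures are preserved node-for-node; the outer Robin boundary
    subsequently applies at the skin surface (x = 0).
    """
    if not mesh.has_porridge:
        raise ValueError("porridge already removed")
    npor = mesh.n_porridge
    new_state = SimulationState(
        temperatures=state.temperatures[npor:].copy(),
        time=state.time,
        omega=state.omega,
    )
    return new_state, mesh.without_porridge()


# ---------------------------------------------------------------------------
# Production kernel


@njit(cache=True, fastmath=True)
def _advance(
    T,
    n_por,
    g,
    coef_a,
    coef_b,
    coef_c,
    k_loc,
    kq,
    rq,
    cq,
    update_porridge,
    k_tis0,
    dx,
    dt,
    n_steps,
    h_out,
    t_amb,
    t_b,
    basal_i,
    basal_w1,
    basal_w2,
    p_factor,
    de_over_r,
    t_threshold,
    omega,
):  # pragma: no cover - exercised via run_schedule and the equivalence test
    # g[i] = k_face/dx on face i (between nodes i, i+1), W/(m^2 K);
    # coef_a = dt/(rho*c*dx); coef_b = dt*W_b*rho_b*c_b/(rho*c);
    # coef_c = dt*Q_met/(rho*c).  Tissue entries are static; porridge
    # entries (and the porridge faces) are refreshed each step when the
    # property polynomials follow the local temperature.
    n = T.size
    face = np.empty(n - 1)
    if h_out > 0.0:
        k0 = k_loc[0] if n_por > 0 else k_tis0
        u = 1.0 / (1.0 / h_out + dx / (2.0 * k0))
    else:
        u = 0.0
    for _ in range(n_steps):
        if update_porridge:
            for i in range(n_por):
                t = T[i]
                k_loc[i] = (kq[0] * t + kq[1]) * t + kq[2]
                rhoc = ((rq[0] * t + rq[1]) * t + rq[2]) * (
                    (cq[0] * t + cq[1]) * t + cq[2]
                )
                coef_a[i] = dt / (rhoc * dx)
            for i in range(n_por - 1):
                g[i] = 2.0 * k_loc[i] * k_loc[i + 1] / (k_loc[i] + k_loc[i + 1]) / dx
            g[n_por - 1] = (
                2.0 * k_loc[n_por - 1] * k_tis0 / (k_loc[n_por - 1] + k_tis0) / dx
            )
            if h_out > 0.0:
                u = 1.0 / (1.0 / h_out + dx / (2.0 * k_loc[0]))
        for i in range(n - 1):
            face[i] = g[i] * (T[i + 1] - T[i])
        T[0] = (
            T[0]
            + coef_a[0] * (face[0] + u * (t_amb - T[0]))
            + coef_b[0] * (t_b - T[0])
            + coef_c[0]
        )
        for i in range(1, n - 1):
            T[i] = (
                T[i]
                + coef_a[i] * (face[i] - face[i - 1])
                + coef_b[i] * (t_b - T[i])
                + coef_c[i]
            )
        T[n - 1] = (
            T[n - 1]
            - coef_a[n - 1] * face[n - 2]
            + coef_b[n - 1] * (t_b - T[n - 1])
            + coef_c[n - 1]
        )
        tb = basal_w1 * T[basal_i] + basal_w2 * T[basal_i + 1]
        if tb > t_threshold:
            omega += dt * p_factor * np.exp(-de_over_r / (tb + 273.15))
    return omega


def _kernel_inputs(
    mesh: Mesh, perfusion: PerfusionModel, numerics: NumericsConfig, dt: float
):
    """Precompute the per-node/per-face coefficient arrays the kernel consumes.

    Porridge properties are seeded at the initial spill temperature; when the
    polynomials track the local temperature the kernel refreshes the porridge
    entries itself each step.
    """
    n = mesh.n_nodes
    npor = mesh.n_porridge
    dx = mesh.dx
    k_arr = np.empty(n)
    rhoc_arr = np.empty(n)
    k_arr[npor:] = mesh.tissue_conductivity()
    rhoc_arr[npor:] = mesh.tissue_heat_capacity()
    if npor:
        t0 = mesh.porridge.temperature
        k_arr[:npor] = mesh.porridge.conductivity(t0)
        rhoc_arr[:npor] = mesh.porridge.density(t0) * mesh.porridge.specific_heat(t0)
    g = 2.0 * k_arr[1:] * k_arr[:-1] / (k_arr[1:] + k_arr[:-1]) / dx
    coef_a = dt / (rhoc_arr * dx)
    coef_b = np.zeros(n)
    coef_c = np.zeros(n)
    names = [layer.name for layer in mesh.stack]
    for i, m in enumerate(mesh.material):
        if m >= 0 and names[m] in perfusion.perfused_layers:
            coef_b[i] = dt * perfusion.volumetric_coefficient / rhoc_arr[i]
            coef_c[i] = dt * perfusion.q_met / rhoc_arr[i]
    k_loc = k_arr[:npor].copy() if npor else np.empty(0)
    update_porridge = bool(npor) and numerics.porridge_properties == "local"
    k_tis0 = float(k_arr[npor]) if npor < n else 0.0
    return g, coef_a, coef_b, coef_c, k_loc, update_porridge, k_tis0


def _basal_weights(mesh: Mesh, sampling: str) -> tuple[float, float]:
    """Weights on the (deepest-epidermis, first-dermis) node pair.

    ``interface`` interpolates the temperature at the epidermis-dermis
    junction itself from the two adjacent cell centers, using flux continuity
    across the interface (conductivity-weighted); the two single-node options
    sample one cell center, half a cell above or below the junction.
    """
    if sampling == "last_epidermis":
        return 1.0, 0.0
    if sampling == "first_dermis":
        return 0.0, 1.0
    if sampling == "interface":
        k1 = mesh.stack[0].k
        k2 = mesh.stack[1].k
        return k1 / (k1 + k2), k2 / (k1 + k2)
    raise ValueError(f"unknown basal sampling mode {sampling!r}")


# Named trace depths.  Porridge: outer surface, center, skin-contact side;
# tissue: skin surface, basal layer, mid-dermis, mid-muscle.
_TRACE_COLUMNS = (
    "T_p_a",
    "T_p_c",
    "T_p_s",
    "T_s_s",
    "T_basal",
    "T_dermis_mid",
    "T_muscle_mid",
)


def _trace_indices(mesh: Mesh) -> dict[str, int | None]:
    npor = mesh.n_porridge
    idx: dict[str, int | None] = {}
    if npor:
        idx["T_p_a"] = 0
        idx["T_p_c"] = npor // 2
        idx["T_p_s"] = npor - 1
    else:
        idx["T_p_a"] = idx["T_p_c"] = idx["T_p_s"] = None
    idx["T_s_s"] = npor
    idx["T_basal"] = None  # interpolated, handled separately
    thick = [layer.thickness for layer in mesh.stack]
    dermis_mid = thick[0] + 0.5 * thick[1]
    muscle_mid = sum(thick[:3]) + 0.5 * thick[3] if len(thick) > 3 else None
    idx["T_dermis_mid"] = npor + int(round(dermis_mid / mesh.dx))
    idx["T_muscle_mid"] = (
        npor + int(round(muscle_mid / mesh.dx)) if muscle_mid is not None else None
    )
    return idx


def run_schedule(
    scenario,
    numerics: NumericsConfig | None = None,
    perfusion: PerfusionModel | None = None,
    kinetics: DamageKinetics | None = None,
    snapshot_times: tuple[float, ...] = (),
) -> TraceRecord:
    """Simulate one scald scenario through its full boundary schedule.

    The tissue starts uniformly at 37 °C and the porridge uniformly at its
    spill temperature.  The schedule is: contact until ``scenario.t_off``
    (or the full duration when the porridge is never removed), then ambient
    air until ``scenario.t_cool``, then tempered-water cooling.  The basal
    damage integral is accumulated at every solver step; traces are sampled
    every ``numerics.sample_interval`` seconds.

    ``scenario`` is duck-typed: any object with the attributes of
    :class:`scaldsim.scenarios.Scenario` works.
    """
    numerics = numerics or NumericsConfig()
    perfusion = perfusion or PerfusionModel()
    kinetics = kinetics or DamageKinetics()
    dt = numerics.dt
    dx = numerics.dx

    t_off = getattr(scenario, "t_off", None)
    t_cool = getattr(scenario, "t_cool", None)
    t_end = scenario.t_end
    if t_off is not None and t_cool is not None and not (t_off < t_cool):
        raise ValueError("porridge removal must precede water cooling")
    if t_off is None and t_cool is not None:
        raise ValueError("water cooling requires prior porridge removal")
    for t_event in (t_off, t_cool):
        if t_event is not None and t_event > t_end:
            raise ValueError("schedule event lies beyond the simulated duration")

    stack = standard_skin_stack(scenario.epidermis_thickness)
    porridge = PorridgeModel().with_conditions(
        scenario.porridge_temperature, scenario.porridge_thickness
    )
    mesh = build_mesh(stack, porridge, dx=dx)
    report = check_stability(mesh, dt)
    if not report.stable:
        raise ValueError(
            f"unstable time step: max Fourier number {report.max_fourier:.3f} >= 0.5"
        )
    ok, penetration = check_domain_size(mesh, t_end) if t_end > 0 else (True, 0.0)
    if not ok:
        raise ValueError(
            f"tissue domain {mesh.domain_depth:.4f} m shallower than thermal "
            f"penetration estimate {penetration:.4f} m"
        )

    n_steps_total = int(round(t_end / dt))
    s_off = int(round(t_off / dt)) if t_off is not None else None
    s_cool = int(round(t_cool / dt)) if t_cool is not None else None
    stride = max(1, int(round(numerics.sample_interval / dt)))
    snap_steps = {int(round(t / dt)): t for t in snapshot_times}

    breakpoints = set(range(0, n_steps_total + 1, stride))
    breakpoints.add(n_steps_total)
    if s_off is not None:
        breakpoints.add(s_off)
    if s_cool is not None:
        breakpoints.add(s_cool)
    breakpoints.update(snap_steps)
    schedule = sorted(breakpoints)

    T = np.empty(mesh.n_nodes)
    T[: mesh.n_porridge] = porridge.temperature
    T[mesh.n_porridge :] = 37.0
    omega = 0.0
    kq = np.asarray(porridge.k_coeffs)
    rq = np.asarray(porridge.rho_coeffs)
    cq = np.asarray(porridge.c_coeffs)
    de_over_r = kinetics.de / kinetics.r
    w1, w2 = _basal_weights(mesh, numerics.basal_sampling)

    kernel = _kernel_inputs(mesh, perfusion, numerics, dt)
    tr_idx = _trace_indices(mesh)

    times = []
    series: dict[str, list[float]] = {c: [] for c in _TRACE_COLUMNS}
    series["omega"] = []
    snapshots: dict[float, pd.DataFrame] = {}

    def record(step: int) -> None:
        times.append(step * dt)
        for col in _TRACE_COLUMNS:
            if col == "T_basal":
                tb = w1 * T[mesh.basal_index] + w2 * T[mesh.basal_index + 1]
                series[col].append(float(tb))
            else:
                i = tr_idx[col]
                series[col].append(float(T[i]) if i is not None else np.nan)
        series["omega"].append(omega)
        if step in snap_steps:
            snapshots[snap_steps[step]] = pd.DataFrame(
                {"position_m": mesh.positions, "temperature_C": T.copy()}
            )

    record(0)
    for s_prev, s_next in zip(schedule[:-1], schedule[1:]):
        if s_off is not None and s_prev == s_off and mesh.has_porridge:
            state, mesh = remove_porridge(
                SimulationState(T, s_prev * dt, omega), mesh
            )
            T = state.temperatures
            kernel = _kernel_inputs(mesh, perfusion, numerics, dt)
            tr_idx = _trace_indices(mesh)
        if s_cool is not None and s_prev >= s_cool:
            h_out, t_amb = scenario.h_water, scenario.t_water
        else:
            h_out, t_amb = scenario.h_air, scenario.t_air
        g, coef_a, coef_b, coef_c, k_loc, update_porridge, k_tis0 = kernel
        omega = _advance(
            T,
            mesh.n_porridge,
            g,
            coef_a,
            coef_b,
            coef_c,
            k_loc,
            kq,
            rq,
            cq,
            update_porridge,
            k_tis0,
            dx,
            dt,
            s_next - s_prev,
            h_out,
            t_amb,
            perfusion.t_b,
            mesh.basal_index,
            w1,
            w2,
            kinetics.p,
            de_over_r,
            kinetics.t_threshold,
            omega,
        )
        record(s_next)

    # drop duplicate records at coincident breakpoints
    times_arr = np.asarray(times)
    keep = np.concatenate([[True], np.diff(times_arr) > 0])
    return TraceRecord(
        times=times_arr[keep],
        series={k: np.asarray(v)[keep] for k, v in series.items()},
        snapshots=snapshots,
    )
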