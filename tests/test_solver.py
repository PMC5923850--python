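import numpy as np
import pytest
from scipy.special import erf

from scaldsim.config import NumericsConfig
from scaldsim.materials import (
    DamageKinetics,
    PerfusionModel,
    PorridgeModel,
    TissueLayer,
    standard_skin_stack,
    thermal_effusivity,
)
from scaldsim.mesh import build_mesh
from scaldsim.scenarios import Scenario
from scaldsim.solver import (
    BoundaryPhase,
    SimulationState,
    pennes_step,
    remove_porridge,
    robin_flux,
    run_schedule,
)

NO_SOURCES = PerfusionModel(w_b=0.0, q_met=0.0)


@pytest.mark.parametrize(
    "h, ts, ta, expected",
    [
        (10.0, 70.0, 20.0, 500.0),
        (10.0, 45.0, 45.0, 0.0),  # equilibrium
        (600.0, 50.0, 15.0, 21000.0),  # tempered-water magnitude
    ],
)
def test_robin_flux_values(h, ts, ta, expected):
    assert robin_flux(h, ts, ta) == pytest.approx(expected)


def test_robin_flux_rejects_negative_coefficient():
    with pytest.raises(ValueError):
        robin_flux(-1.0, 50.0, 20.0)
    with pytest.raises(ValueError):
        BoundaryPhase(0.0, 10.0, h=-5.0, t_ambient=20.0, porridge_present=False)


def _uniform_state(mesh, temperature):
    return SimulationState(temperatures=np.full(mesh.n_nodes, temperature))


def test_uniform_body_temperature_is_a_fixed_point():
    # bare skin at 37 °C against 37 °C air with sources off does not move
    mesh = build_mesh(standard_skin_stack(), None, dx=10e-6)
    phase = BoundaryPhase(0.0, 1.0, h=10.0, t_ambient=37.0, porridge_present=False)
    state = pennes_step(_uniform_state(mesh, 37.0), mesh, phase, NO_SOURCES, dt=2e-4)
    np.testing.assert_allclose(state.temperatures, 37.0, rtol=0, atol=1e-13)


def test_metabolic_source_heats_perfused_nodes_only():
    # at T = T_b the perfusion term vanishes and only Q_met acts
    mesh = build_mesh(standard_skin_stack(), None, dx=10e-6)
    perf = PerfusionModel(q_met=400.0)
    phase = BoundaryPhase(0.0, 1.0, h=0.0, t_ambient=37.0, porridge_present=False)
    dt = 2e-4
    state = pennes_step(_uniform_state(mesh, 37.0), mesh, phase, perf, dt=dt)
    rise = state.temperatures - 37.0
    npor_epi = round(mesh.stack[0].thickness / mesh.dx)
    assert np.all(rise[:npor_epi] == 0)  # avascular epidermis
    rc = mesh.tissue_heat_capacity()
    # rise is ~2e-8 °C on top of 37 °C, so allow for float cancellation
    np.testing.assert_allclose(rise[npor_epi:], 400.0 * dt / rc[npor_epi:], rtol=1e-6)


def test_pennes_step_refuses_unstable_dt():
    mesh = build_mesh(standard_skin_stack(), None, dx=10e-6)
    phase = BoundaryPhase(0.0, 1.0, h=10.0, t_ambient=20.0, porridge_present=False)
    with pytest.raises(ValueError, match="[Uu]nstable"):
        pennes_step(_uniform_state(mesh, 37.0), mesh, phase, NO_SOURCES, dt=5e-4)


def test_remove_porridge_preserves_tissue_state():
    mesh = build_mesh(standard_skin_stack(), PorridgeModel(), dx=10e-6)
    rng = np.random.default_rng(0)
    T = np.concatenate(
        [rng.uniform(60, 70, mesh.n_porridge), rng.uniform(37, 55, mesh.n_tissue)]
    )
    state = SimulationState(temperatures=T, time=10.0, omega=0.07)
    bare_state, bare_mesh = remove_porridge(state, mesh)
    assert bare_mesh.n_nodes == 4206
    np.testing.assert_array_equal(bare_state.temperatures, T[mesh.n_porridge :])
    assert bare_state.omega == state.omega and bare_state.time == state.time
    with pytest.raises(ValueError):
        remove_porridge(bare_state, bare_mesh)


def test_surface_cools_after_removal_into_colder_air():
    mesh = build_mesh(standard_skin_stack(), None, dx=10e-6)
    phase = BoundaryPhase(0.0, 1.0, h=10.0, t_ambient=20.0, porridge_present=False)
    state = _uniform_state(mesh, 50.0)
    for _ in range(50):
        new = pennes_step(state, mesh, phase, NO_SOURCES, dt=2e-4)
        assert new.temperatures[0] < state.temperatures[0]
        state = new


def test_contact_temperature_is_effusivity_weighted():
    # 70 °C porridge on epidermis: the contact temperature jumps to ~57 °C
    # (effusivity weighting); on the full layered stack the surface then
    # settles between the epidermis- and dermis-weighted values once the
    # higher-effusivity dermis is felt, staying nearly constant
    e_p = PorridgeModel().effusivity(70.0)
    e_epi = thermal_effusivity(0.22, 1200.0, 3600.0)
    e_der = thermal_effusivity(0.40, 1200.0, 3600.0)
    t_epi = (e_p * 70.0 + e_epi * 37.0) / (e_p + e_epi)
    t_der = (e_p * 70.0 + e_der * 37.0) / (e_p + e_der)
    assert t_epi == pytest.approx(57.0, abs=0.1)
    trace = run_schedule(Scenario(id="contact", t_end=2.0), perfusion=NO_SOURCES)
    early = trace.series["T_s_s"][trace.times >= 0.05]
    assert np.all(early < t_epi + 0.2)
    assert np.all(early > t_der - 0.2)
    assert early.max() - early.min() < 1.0  # near-constant surface temperature


def test_two_slab_contact_matches_semi_infinite_solution():
    # constant-property porridge slab on a uniform tissue slab, no sources,
    # no outer losses: the cell-centered solution must follow the closed-form
    # semi-infinite contact profile T_c + (T_i - T_c)*erf(x/(2 sqrt(a t)))
    k_p, rho_p, c_p = 0.5817, 1032.58, 3737.9
    porridge = PorridgeModel(
        temperature=70.0,
        thickness=3e-3,
        k_coeffs=(0.0, 0.0, k_p),
        rho_coeffs=(0.0, 0.0, rho_p),
        c_coeffs=(0.0, 0.0, c_p),
    )
    slab = TissueLayer("slab", 0.22, 1200.0, 3600.0, 10e-3)
    dx, dt = 25e-6, 1e-3
    mesh = build_mesh([slab], porridge, dx=dx)
    e_p = thermal_effusivity(k_p, rho_p, c_p)
    e_s = slab.effusivity
    t_contact = (e_p * 70.0 + e_s * 37.0) / (e_p + e_s)

    T = np.empty(mesh.n_nodes)
    T[: mesh.n_porridge] = 70.0
    T[mesh.n_porridge :] = 37.0
    state = SimulationState(temperatures=T)
    phase = BoundaryPhase(0.0, 3.0, h=0.0, t_ambient=20.0, porridge_present=True)
    perfusion = PerfusionModel(w_b=0.0, q_met=0.0, perfused_layers=())
    a_s = slab.diffusivity
    for step in range(2000):
        state = pennes_step(state, mesh, phase, perfusion, dt=dt)
        t_now = (step + 1) * dt
        if abs(t_now % 0.5) < dt / 2 and t_now >= 0.5:
            x = mesh.positions[mesh.n_porridge :]
            exact = t_contact + (37.0 - t_contact) * erf(x / (2 * np.sqrt(a_s * t_now)))
            sim = state.temperatures[mesh.n_porridge :]
            assert np.max(np.abs(sim - exact)) < 0.2


def test_production_kernel_matches_reference_step():
    # the numba kernel and the numpy reference step implement the same
    # update; march both through half a second of porridge contact
    dx, dt = 20e-6, 5e-4
    scenario = Scenario(id="equiv", porridge_temperature=95.0, t_end=0.5)
    numerics = NumericsConfig(dx=dx, dt=dt, sample_interval=0.1)
    perfusion = PerfusionModel()
    kinetics = DamageKinetics()
    trace = run_schedule(scenario, numerics, perfusion, kinetics)

    stack = standard_skin_stack(scenario.epidermis_thickness)
    porridge = PorridgeModel().with_conditions(95.0, 3e-3)
    mesh = build_mesh(stack, porridge, dx=dx)
    k1, k2 = stack[0].k, stack[1].k
    weights = (k1 / (k1 + k2), k2 / (k1 + k2))
    T = np.empty(mesh.n_nodes)
    T[: mesh.n_porridge] = 95.0
    T[mesh.n_porridge :] = 37.0
    state = SimulationState(temperatures=T)
    phase = BoundaryPhase(0.0, 1.0, h=10.0, t_ambient=20.0, porridge_present=True)
    ref_basal = {}
    for step in range(1000):
        state = pennes_step(
            state, mesh, phase, perfusion, dt, kinetics=kinetics, basal_weights=weights
        )
        if (step + 1) % 200 == 0:
            tb = weights[0] * state.temperatures[mesh.basal_index] + weights[1] * (
                state.temperatures[mesh.basal_index + 1]
            )
            ref_basal[round((step + 1) * dt, 6)] = tb

    for t, tb in ref_basal.items():
        i = np.argmin(np.abs(trace.times - t))
        assert trace.series["T_basal"][i] == pytest.approx(tb, abs=1e-6)
    assert trace.omega == pytest.approx(state.omega, rel=1e-6)


def test_enthalpy_conserved_with_exchanges_off():
    # h = 0 at the outer face, perfusion and metabolism off, porridge
    # properties frozen: total enthalpy must be constant to 1e-6 relative
    # over 1e5 explicit steps
    scenario = Scenario(id="closed", h_air=0.0, t_end=20.0)
    numerics = NumericsConfig(porridge_properties="frozen")
    trace = run_schedule(
        scenario, numerics, NO_SOURCES, snapshot_times=(20.0,)
    )
    mesh = build_mesh(standard_skin_stack(), PorridgeModel(), dx=numerics.dx)
    t0 = np.where(np.arange(mesh.n_nodes) < mesh.n_porridge, 70.0, 37.0)
    rhoc = mesh.node_heat_capacity(np.full(mesh.n_nodes, 70.0))
    h_initial = np.sum(rhoc * t0) * mesh.dx
    t_final = trace.snapshots[20.0]["temperature_C"].to_numpy()
    h_final = np.sum(rhoc * t_final) * mesh.dx
    assert abs(h_final - h_initial) / abs(h_initial) < 1e-6


def test_discrete_maximum_principle():
    # with sources off no node may leave the envelope of the initial and
    # ambient temperatures
    scenario = Scenario(id="bounds", t_end=5.0)
    trace = run_schedule(scenario, perfusion=NO_SOURCES)
    for col in ("T_p_a", "T_p_s", "T_s_s", "T_basal", "T_muscle_mid"):
        values = trace.series[col]
        assert np.nanmax(values) <= 70.0 + 1e-9
        assert np.nanmin(values) >= 20.0 - 1e-9


def test_basal_temperature_monotone_during_early_contact(case_results):
    # no-removal spill: the basal layer heats monotonically toward a plateau
    trace = case_results("A").trace
    mask = trace.times <= 10.0  # basal peak arrives near 15 s in this case
    assert np.all(np.diff(trace.series["T_basal"][mask]) >= -1e-9)
    # and the later decline (porridge cooling, perfusion) is gentle
    assert np.all(np.diff(trace.series["T_basal"]) > -0.05)


def test_damage_series_is_non_decreasing(case_results):
    trace = case_results("A").trace
    assert np.all(np.diff(trace.series["omega"]) >= 0)


def test_zero_duration_schedule_returns_initial_condition():
    trace = run_schedule(Scenario(id="noop", t_end=0.0))
    assert trace.omega == 0.0
    assert trace.series["T_s_s"][0] == pytest.approx(37.0)
    assert trace.series["T_p_a"][0] == pytest.approx(70.0)


def test_schedule_rejects_inconsistent_phase_times():
    with pytest.raises(ValueError):
        Scenario(id="bad", t_off=20.0, t_cool=10.0)
    with pytest.raises(ValueError):
        Scenario(id="late", t_off=90.0, t_end=60.0)
    with pytest.raises(ValueError, match="[Uu]nstable"):
        run_schedule(Scenario(id="s", t_end=1.0), NumericsConfig(dt=5e-4))


def test_trace_export_columns(case_results):
    df = case_results("H").trace.to_frame()
    assert list(df.columns) == [
        "time_s",
        "T_p_a",
        "T_p_c",
        "T_p_s",
        "T_s_s",
        "T_basal",
        "T_dermis_mid",
        "T_muscle_mid",
        "omega",
    ]
    # porridge columns are blank after removal at 10 s
    after = df[df.time_s > 10.0]
    assert after[["T_p_a", "T_p_c", "T_p_s"]].isna().all().all()
    before = df[df.time_s < 10.0]
    assert before[["T_p_a", "T_p_c", "T_p_s"]].notna().all().all()
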