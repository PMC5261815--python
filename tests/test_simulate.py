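"""Steady states, integration, observables and tracer kinetics."""

import numpy as np
import pytest

import ferroflux as ff
from ferroflux.simulate import (default_observation_map, observe,
                                rescale_tracer_data, simulate_tracer)


# ----------------------------------------------------------------------
# steady state
# ----------------------------------------------------------------------

def test_one_pool_toy_closed_form(ref_params):
    """Only dietary influx and shedding: Fe_duo* = influx / l_duo."""
    zeros = {n: 0.0 for n in ff.KINETIC_PARAM_NAMES if not n.startswith("K")}
    p = ref_params.replace(**zeros).replace(V_duo=36.0, l_duo=1.5)
    y = ff.steady_state(p, guess=np.array([1e-6, 1e-6, 1e-6, 1.0,
                                           1e-6, 1e-6, 1e-6]))
    influx = ff.duodenal_uptake(p.Fe_food, p.V_duo, p.K_duo)
    assert y[ff.state_index("Fe_duodenum")] == pytest.approx(influx / 1.5)


def test_steady_state_matches_long_integration(ref_params, baseline):
    traj = ff.integrate(ref_params, 0.5 * baseline + 1.0,
                        np.array([0.0, 1e5]), rtol=1e-10, atol=1e-12)
    y_long = traj.states[-1]
    mask = baseline > 1e-6
    np.testing.assert_allclose(y_long[mask], baseline[mask], rtol=1e-3)


def test_steady_state_is_fixed_point_of_integration(ref_params, baseline):
    traj = ff.integrate(ref_params, baseline, np.array([0.0, 1000.0]))
    np.testing.assert_allclose(traj.states[-1], baseline, rtol=1e-6,
                               atol=1e-9)


def test_steady_state_residual_is_small(ref_params, baseline):
    res = np.max(np.abs(ff.rhs(0.0, baseline, ref_params)))
    assert res < 1e-9 * max(1.0, np.max(baseline))


def test_steady_state_rejects_clamped_models(ref_params):
    with pytest.raises(ValueError):
        ff.steady_state(ref_params.replace(clamps=("Hep",)))


# ----------------------------------------------------------------------
# integration
# ----------------------------------------------------------------------

def test_unperturbed_trajectory_is_constant(ref_params, baseline):
    traj = ff.simulate_scenario(ref_params, ff.PerturbationScenario(),
                                np.linspace(0, 72, 13), baseline=baseline)
    np.testing.assert_allclose(traj.states, np.tile(baseline, (13, 1)),
                               rtol=1e-5, atol=1e-7)
    np.testing.assert_array_equal(traj.states[0], baseline)


def test_acute_lps_drop_and_recovery(ref_params, baseline):
    """1 ug/g LPS: serum iron bottoms out within a day, then recovers."""
    traj = ff.simulate_scenario(ref_params,
                                ff.PerturbationScenario(lps_bolus=1.0),
                                np.linspace(0, 72, 145), baseline=baseline)
    ser = traj["Fe_serum"]
    t_min = traj.times[np.argmin(ser)]
    assert t_min < 24.0
    assert ser.min() < 0.6 * ser[0]
    assert ser[-1] > 0.85 * ser[0]


def test_tolerance_refinement(ref_params, baseline):
    scen = ff.PerturbationScenario(lps_bolus=1.0)
    t = np.linspace(0, 72, 7)
    a = ff.simulate_scenario(ref_params, scen, t, rtol=1e-8, baseline=baseline)
    b = ff.simulate_scenario(ref_params, scen, t, rtol=5e-9, baseline=baseline)
    scale = np.maximum(np.abs(a.states[-1]), 1e-6)
    assert np.max(np.abs(a.states[-1] - b.states[-1]) / scale) < 1e-4


def test_clamped_states_stay_constant(ref_params, baseline):
    scen = ff.PerturbationScenario(lps_bolus=1.0, clamps=frozenset({"Hep"}))
    traj = ff.simulate_scenario(ref_params, scen, np.linspace(0, 48, 25),
                                baseline=baseline)
    np.testing.assert_allclose(traj["Hep"], traj["Hep"][0], rtol=1e-9)


def test_integrate_rejects_negative_start(ref_params, baseline):
    y = baseline.copy()
    y[0] = -1.0
    with pytest.raises(ValueError):
        ff.integrate(ref_params, y, np.array([0.0, 1.0]))


# ----------------------------------------------------------------------
# observables
# ----------------------------------------------------------------------

def test_observation_map_has_exactly_20_scaling_parameters():
    omap = default_observation_map()
    assert omap.n_scalings == 20
    assert len(set(omap.scaling_groups())) == 20


def test_absolute_observable_returns_state_itself(ref_params, baseline):
    traj = ff.Trajectory(times=np.array([0.0, 1.0]),
                         states=np.vstack([baseline, baseline]))
    df = observe(traj, observables=["fe_liver"])
    np.testing.assert_allclose(df["value"], baseline[1])


def test_arbitrary_observable_is_scaled_pointwise(ref_params, baseline):
    traj = ff.Trajectory(times=np.array([0.0, 1.0]),
                         states=np.vstack([baseline, 2 * baseline]))
    omap = default_observation_map(ref_params)
    scaled = omap.evaluate(traj, "hep_mrna_liver", "lps72:hep_mrna_liver",
                           {"lps72:hep_mrna_liver": 3.5})
    np.testing.assert_allclose(scaled, 3.5 * traj["Hep"])


def test_unknown_observable_raises(baseline):
    traj = ff.Trajectory(times=np.array([0.0, 1.0]),
                         states=np.vstack([baseline, baseline]))
    omap = default_observation_map()
    with pytest.raises(KeyError):
        omap.quantity(traj, "fe_brain")


# ----------------------------------------------------------------------
# tracer
# ----------------------------------------------------------------------

def test_tracer_starts_as_100_in_serum(ref_params, baseline):
    df = simulate_tracer(ref_params, 1.0, [0.0, 24.0], y_ss=baseline)
    assert df["tracer_total"].iloc[0] == pytest.approx(100.0)
    assert df["tracer_serum"].iloc[0] == pytest.approx(100.0)


def test_lossfree_tracer_conserves_total(ref_params, baseline):
    t = np.linspace(0, 672, 8)
    df = simulate_tracer(ref_params, 1.0, t, lossfree=True, y_ss=baseline)
    np.testing.assert_allclose(df["tracer_total"], 100.0, rtol=1e-9)


def test_tracer_total_decays_with_losses(ref_params, baseline):
    df = simulate_tracer(ref_params, 1.0, np.linspace(0, 672, 8),
                         y_ss=baseline)
    assert df["tracer_total"].iloc[-1] < 100.0
    assert (df["tracer_total"].diff().dropna() <= 1e-9).all()


def test_rescale_tracer_closed_form_at_28_days():
    raw = np.array([[5.0, 3.0, 2.0]])
    out = rescale_tracer_data(raw, 0.005, [28.0])
    assert out.sum() == pytest.approx(100.0 * np.exp(-0.14))


def test_rescale_tracer_properties():
    rng = np.random.default_rng(3)
    raw = rng.uniform(0.5, 5.0, size=(4, 7))
    t = np.array([1.0, 7.0, 14.0, 28.0])
    out = rescale_tracer_data(raw, 0.01, t)
    np.testing.assert_allclose(out.sum(axis=1), 100.0 * np.exp(-0.01 * t))
    # scale invariance of the raw counts
    np.testing.assert_allclose(rescale_tracer_data(7.0 * raw, 0.01, t), out)
    # already-normalized input is unchanged; r = 0 keeps sums at 100
    np.testing.assert_allclose(rescale_tracer_data(out, 0.01, t), out)
    flat = rescale_tracer_data(raw, 0.0, t)
    np.testing.assert_allclose(flat.sum(axis=1), 100.0)
    with pytest.raises(ValueError):
        rescale_tracer_data(np.zeros((1, 3)), 0.01, [1.0])
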