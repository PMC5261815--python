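"""χ² objective, scaling profiling, multi-start fitting, sensitivities."""

import numpy as np
import pandas as pd
import pytest

import ferroflux as ff
from ferroflux.calibrate import (FitEnsemble, FitResult, TimeCourseDataset,
                                 chi2, ensemble_predict, multistart_fit,
                                 predict_records, profile_scalings,
                                 sensitivity)
from ferroflux.perturb import PerturbationScenario


def _dataset_from_model(params, scenario, scenario_id, observables, times,
                        study="lps72", sd=0.1, n=4):
    """Noise-free dataset whose means equal the model predictions."""
    from ferroflux.simulate import default_observation_map, simulate_scenario

    omap = default_observation_map(params)
    traj = simulate_scenario(params, scenario, times)
    tidx = {t: k for k, t in enumerate(traj.times)}
    rows = []
    for obs in observables:
        series = omap.quantity(traj, obs)
        group = omap.group_for(study, obs)
        for t in times:
            rows.append(dict(scenario=scenario_id, observable=obs,
                             time_h=float(t), mean=float(series[tidx[t]]),
                             sd=sd, n=n,
                             units="absolute" if group == "abs" else "arbitrary",
                             scale_group=group))
    return TimeCourseDataset(records=pd.DataFrame(rows),
                             scenarios={scenario_id: scenario})


@pytest.fixture(scope="module")
def tiny_dataset(ref_params):
    scen = PerturbationScenario(lps_bolus=1.0, duration=48.0)
    return _dataset_from_model(ref_params, scen, "lps",
                               ("fe_serum", "hep_mrna_liver"),
                               (2.0, 6.0, 18.0, 48.0))


def test_chi2_zero_when_model_equals_data(ref_params, tiny_dataset):
    c2, c2n, scal = chi2(ref_params, [tiny_dataset])
    assert c2 == pytest.approx(0.0, abs=1e-6)
    assert scal["lps72:hep_mrna_liver"] == pytest.approx(1.0)


def test_chi2_single_record_one_sigma(ref_params, baseline):
    """A single absolute record displaced by one SEM contributes chi2 = 1."""
    x = baseline[1]
    sd, n = 0.4, 4
    rec = pd.DataFrame([dict(scenario="none", observable="fe_liver",
                             time_h=0.0, mean=x + sd / np.sqrt(n), sd=sd,
                             n=n, units="absolute", scale_group="abs")])
    ds = TimeCourseDataset(records=rec,
                           scenarios={"none": PerturbationScenario()})
    c2, c2n, _ = chi2(ref_params, [ds])
    assert c2 == pytest.approx(1.0, rel=1e-6)
    assert c2n == pytest.approx(1.0, rel=1e-6)


def test_profile_scaling_recovers_exact_factor(ref_params, tiny_dataset):
    ds = tiny_dataset
    scaled = ds.records.copy()
    arb = scaled["scale_group"] != "abs"
    scaled.loc[arb, "mean"] *= 3.0
    ds3 = TimeCourseDataset(records=scaled, scenarios=ds.scenarios)
    x = predict_records(ref_params, [ds3])
    scal = profile_scalings(x, [ds3])
    assert scal["lps72:hep_mrna_liver"] == pytest.approx(3.0, rel=1e-5)
    assert "abs" not in scal


def test_profile_scaling_matches_grid_search_oracle(rng):
    """The closed-form scaling equals a 1e-6-resolution grid search."""
    x = rng.uniform(0.5, 2.0, 40)
    y = 1.7 * x + rng.normal(0, 0.2, 40)
    sd = rng.uniform(0.1, 0.5, 40)
    rec = pd.DataFrame(dict(scenario="s", observable="hep_mrna_liver",
                            time_h=np.arange(40.0), mean=y, sd=sd, n=4,
                            units="arbitrary", scale_group="g"))
    ds = TimeCourseDataset(records=rec, scenarios={"s": PerturbationScenario()})
    s_star = profile_scalings(x, [ds])["g"]
    sem = sd / 2.0
    grid = np.arange(0.5, 3.0, 1e-6)
    cost = ((grid[:, None] * x[None, :] - y[None, :]) / sem[None, :]) ** 2
    s_grid = grid[np.argmin(cost.sum(axis=1))]
    assert s_star == pytest.approx(s_grid, abs=2e-6)


def test_profiled_scaling_never_increases_chi2(ref_params, tiny_dataset, rng):
    noisy = tiny_dataset.records.copy()
    noisy["mean"] = noisy["mean"] * rng.uniform(0.7, 1.3, len(noisy))
    ds = TimeCourseDataset(records=noisy, scenarios=tiny_dataset.scenarios)
    c2_prof, _, scal = chi2(ref_params, [ds])
    for s_try in (0.5, 0.9, 1.5, 3.0):
        c2_fixed, _, _ = chi2(ref_params, [ds],
                              scalings={g: s_try for g in scal})
        assert c2_prof <= c2_fixed + 1e-9


def test_expected_chi2_per_point_is_one_at_truth(ref_params, tiny_dataset,
                                                 rng):
    """Noise-matched data: E[chi2/N] = 1 at the true parameters (less the
    degrees of freedom absorbed by scaling profiling)."""
    x = predict_records(ref_params, [tiny_dataset])
    recs = tiny_dataset.records
    sem = recs["sd"].to_numpy() / np.sqrt(recs["n"].to_numpy())
    vals = []
    for _ in range(100):
        noisy = recs.copy()
        noisy["mean"] = x + sem * rng.standard_normal(len(x))
        ds = TimeCourseDataset(records=noisy, scenarios=tiny_dataset.scenarios)
        _, c2n, _ = chi2(ref_params, [ds])
        vals.append(c2n)
    n_groups = recs.loc[recs["scale_group"] != "abs", "scale_group"].nunique()
    expected = 1.0 - n_groups / len(recs)
    assert np.mean(vals) == pytest.approx(expected, abs=0.15)


def test_selfconsistency_fit_on_noisefree_data(ref_params, tiny_dataset):
    """With the truth among the starts, noise-free data give chi2 ~ 0."""
    ens = multistart_fit([tiny_dataset], n_starts=2, seed=0,
                         free=("d_hep", "d_LPS"), base_params=ref_params,
                         include_base_start=True, max_nfev=10)
    assert ens.best.chi2 == pytest.approx(0.0, abs=1e-6)
    assert ens.best.values["d_hep"] == pytest.approx(ref_params.d_hep, rel=1e-3)


def test_more_starts_never_increase_best_chi2(ref_params, tiny_dataset, rng):
    noisy = tiny_dataset.records.copy()
    noisy["mean"] = noisy["mean"] * rng.uniform(0.8, 1.2, len(noisy))
    ds = TimeCourseDataset(records=noisy, scenarios=tiny_dataset.scenarios)
    kw = dict(free=("d_hep",), base_params=ref_params, max_nfev=6, seed=5)
    best2 = multistart_fit([ds], n_starts=2, **kw).best.chi2
    best4 = multistart_fit([ds], n_starts=4, **kw).best.chi2
    assert best4 <= best2 + 1e-12


def _fake_ensemble(ref_params, spread):
    results = []
    for i, f in enumerate(spread):
        p = ref_params.replace(d_hep=ref_params.d_hep * f)
        results.append(FitResult(values={"d_hep": p.d_hep}, params=p,
                                 scalings={}, chi2=float(i), chi2_per_n=0.1,
                                 n_records=10, start_index=i))
    return FitEnsemble(results=results, seed=0, free=("d_hep",),
                       bounds={"d_hep": (1e-3, 1e3)})


def test_ensemble_band_properties(ref_params):
    scen = PerturbationScenario(lps_bolus=1.0)
    t = np.linspace(0, 24, 5)
    singleton = _fake_ensemble(ref_params, [1.0])
    band1 = ensemble_predict(singleton, scen, "fe_serum", t)
    np.testing.assert_allclose(band1["lo"], band1["hi"])
    ens = _fake_ensemble(ref_params, [1.0, 0.8, 1.25, 0.9, 1.1])
    band = ensemble_predict(ens, scen, "fe_serum", t)
    best = ensemble_predict(singleton, scen, "fe_serum", t)["mean"]
    assert ((band["lo"] - 1e-12 <= best) & (best <= band["hi"] + 1e-12)).all()
    # truncating the ensemble can only narrow the band
    ens.ensemble_size = 3
    band3 = ensemble_predict(ens, scen, "fe_serum", t)
    assert (band3["lo"] >= band["lo"] - 1e-12).all()
    assert (band3["hi"] <= band["hi"] + 1e-12).all()


def test_sensitivity_one_pool_closed_form(ref_params):
    """Duodenum-only toy: Fe_duo* = influx/l_duo gives m = +1 / -1."""
    zeros = {n: 0.0 for n in ff.KINETIC_PARAM_NAMES if not n.startswith("K")}
    p = ref_params.replace(**zeros).replace(V_duo=36.0, l_duo=1.5)
    m = sensitivity(p, "pools", param_names=("V_duo", "l_duo", "r_loss"),
                    pools=("Fe_duodenum",))
    assert m.loc["V_duo", "Fe_duodenum"] == pytest.approx(1.0, abs=1e-3)
    assert m.loc["l_duo", "Fe_duodenum"] == pytest.approx(-1.0, abs=1e-3)
    # a parameter with no path to the pool
    assert m.loc["r_loss", "Fe_duodenum"] == pytest.approx(0.0, abs=1e-9)


def test_sensitivity_step_refinement(ref_params):
    m1 = sensitivity(ref_params, "pools", param_names=("d_hep",),
                     pools=("Fe_serum",), step=0.01)
    m2 = sensitivity(ref_params, "pools", param_names=("d_hep",),
                     pools=("Fe_serum",), step=0.005)
    a, b = m1.iloc[0, 0], m2.iloc[0, 0]
    assert abs(a - b) < 0.01 * max(abs(a), abs(b))


def test_dataset_validation():
    rec = pd.DataFrame([dict(scenario="s", observable="fe_liver", time_h=0.0,
                             mean=1.0, sd=0.0, n=4, units="absolute",
                             scale_group="abs")])
    with pytest.raises(ValueError, match="SD"):
        TimeCourseDataset(records=rec, scenarios={"s": PerturbationScenario()})
    with pytest.raises(ValueError, match="unknown scenario"):
        TimeCourseDataset(records=rec.assign(sd=1.0), scenarios={})
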