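"""Synthetic time-course data with the statistical structure of the mouse
calibration design.

The generator simulates a scenario with a chosen "true" parameter set, draws
replicate measurements with multiplicative Gaussian noise and emits tidy
records (scenario, observable, time, mean, SD, n).  The recorded SD is the
*generative* noise SD (cv × |model value|), i.e. the known uncertainty of a
single replicate; the recorded mean is the sample mean of the replicates.
Together with the SD/sqrt(n) weighting of the χ² objective this makes the
synthetic data exactly noise-matched: at the true parameters E[χ²/N] = 1 (less
the degrees of freedom absorbed by scaling profiling).

:func:`generate_calibration_suite` reproduces the full calibration design —
acute LPS (72 h), LPS after dietary loading (48 h), 9-week diet modulation,
28-day tracer kinetics under three diets, and hepcidin-knockout iron pools —
totalling exactly 344 records by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import TimeCourseDataset
from .params import ParameterSet
from .perturb import PerturbationScenario
from .simulate import (ObservationMap, default_observation_map,
                       simulate_scenario, simulate_tracer, steady_state)

__all__ = ["generate_timecourse", "generate_calibration_suite", "SUITE_DESIGN"]


def _records_from_values(values: dict[tuple[str, float], float], study: str,
                         scenario_id: str, omap: ObservationMap,
                         n_replicates: int, cv: float,
                         rng: np.random.Generator) -> list[dict]:
    rows = []
    for (obs, t), x in values.items():
        sd = max(cv * abs(x), 1e-9)
        reps = x + sd * rng.standard_normal(n_replicates)
        group = omap.group_for(study, obs)
        rows.append(dict(
            scenario=scenario_id, observable=obs, time_h=float(t),
            mean=float(np.mean(reps)), sd=float(sd), n=int(n_replicates),
            units="absolute" if group == "abs" else "arbitrary",
            scale_group=group,
        ))
    return rows


def generate_timecourse(true_params: ParameterSet,
                        scenario: PerturbationScenario,
                        observables: Sequence[str],
                        times: Sequence[float],
                        n_replicates: int = 4, cv: float = 0.2,
                        seed: int = 0, *, study: str = "lps72",
                        scenario_id: str = "scenario",
                        name: str | None = None,
                        obs_map: ObservationMap | None = None,
                        baseline: np.ndarray | None = None
                        ) -> TimeCourseDataset:
    """Simulate one scenario and emit noisy replicate records.

    Multiplicative Gaussian noise with coefficient of variation ``cv`` is
    added independently per replicate; deterministic given ``seed``.  For
    tracer scenarios the observables are the ``tracer_*`` compartments (% of
    injected dose).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if cv <= 0:
        raise ValueError("cv must be > 0")
    rng = np.random.default_rng(seed)
    omap = obs_map or default_observation_map(true_params)
    times = np.asarray(sorted(set(float(t) for t in times)))
    values: dict[tuple[str, float], float] = {}
    if scenario.tracer_injection:
        df = simulate_tracer(true_params, scenario.diet_fold,
                             times).set_index("time_h")
        for obs in observables:
            for t in times:
                values[(obs, t)] = float(df.loc[t, obs])
    else:
        traj = simulate_scenario(true_params, scenario, times,
                                 baseline=baseline)
        tidx = {t: k for k, t in enumerate(traj.times)}
        for obs in observables:
            series = omap.quantity(traj, obs)
            for t in times:
                values[(obs, t)] = float(series[tidx[t]])
    rows = _records_from_values(values, study, scenario_id, omap,
                                n_replicates, cv, rng)
    return TimeCourseDataset(records=pd.DataFrame(rows),
                             scenarios={scenario_id: scenario},
                             name=name or scenario_id)


#: The default allocation of the 344-record calibration design.
SUITE_DESIGN: dict[str, dict] = {
    # 72-h acute inflammation: serum iron + 8 molecular readouts, 10 times
    "lps_acute": dict(
        study="lps72",
        scenario=dict(lps_bolus=1.0, duration=72.0),
        observables=("fe_serum", "hep_mrna_liver", "bmp6_mrna_liver",
                     "il6_serum", "pstat3_liver", "psmad_liver",
                     "fpn_mrna_spleen", "fpn_mrna_liver", "fpn_prot_liver"),
        times=(0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0, 36.0, 48.0, 72.0),
    ),  # 90 records
    # LPS bolus at normal diet, 12 readouts at 0/6/18/48 h
    "lpsdiet_normal": dict(
        study="lpsdiet",
        scenario=dict(lps_bolus=1.0, duration=48.0),
        observables=("fe_serum", "fe_liver", "fe_spleen", "fe_duodenum",
                     "fe_rbc", "hep_mrna_liver", "bmp6_mrna_liver",
                     "fpn_mrna_liver", "pstat3_liver", "psmad_liver",
                     "fpn_prot_liver", "fpn_prot_spleen"),
        times=(0.0, 6.0, 18.0, 48.0),
    ),  # 48 records
    # state after 4 weeks of 2 % carbonyl-iron diet, before LPS
    "lpsdiet_high_baseline": dict(
        study="lpsdiet",
        scenario=dict(diet_fold=100.0, pre_h=672.0, duration=0.0),
        observables=("fe_serum", "fe_liver", "fe_spleen", "fe_duodenum",
                     "fe_rbc", "hep_mrna_liver", "bmp6_mrna_liver",
                     "fpn_mrna_liver", "pstat3_liver", "psmad_liver",
                     "fpn_prot_liver", "fpn_prot_spleen"),
        times=(0.0,),
    ),  # 12 records
    # 9-week dietary modulation, reduced (100 ppm) and loaded (2 %) diets
    "diet9w_low": dict(
        study="diet9w",
        scenario=dict(diet_fold=0.5, duration=1512.0),
        observables=("fe_serum", "fe_liver", "fe_spleen", "hep_mrna_liver",
                     "bmp6_mrna_liver", "psmad_liver", "pstat3_liver",
                     "fpn_mrna_spleen"),
        times=(168.0, 336.0, 672.0, 1008.0, 1512.0),
    ),  # 40 records
    "diet9w_high": dict(
        study="diet9w",
        scenario=dict(diet_fold=100.0, duration=1512.0),
        observables=("fe_serum", "fe_liver", "fe_spleen", "hep_mrna_liver",
                     "bmp6_mrna_liver", "psmad_liver", "pstat3_liver",
                     "fpn_mrna_spleen"),
        times=(168.0, 336.0, 672.0, 1008.0, 1512.0),
    ),  # 40 records
    # 28-day radio-iron tracer under three diets
    "tracer_low": dict(
        study="tracer",
        scenario=dict(diet_fold=0.03, tracer_injection=True, duration=672.0),
        observables=("tracer_serum", "tracer_liver", "tracer_spleen",
                     "tracer_duodenum", "tracer_bm", "tracer_rbc",
                     "tracer_other"),
        times=(24.0, 72.0, 168.0, 336.0, 672.0),
    ),  # 35 records
    "tracer_normal": dict(
        study="tracer",
        scenario=dict(diet_fold=1.0, tracer_injection=True, duration=672.0),
        observables=("tracer_serum", "tracer_liver", "tracer_spleen",
                     "tracer_duodenum", "tracer_bm", "tracer_rbc",
                     "tracer_other"),
        times=(24.0, 72.0, 168.0, 336.0, 672.0),
    ),  # 35 records
    "tracer_high": dict(
        study="tracer",
        scenario=dict(diet_fold=100.0, tracer_injection=True, duration=672.0),
        observables=("tracer_serum", "tracer_liver", "tracer_spleen",
                     "tracer_duodenum", "tracer_bm", "tracer_rbc",
                     "tracer_other"),
        times=(24.0, 72.0, 168.0, 336.0, 672.0),
    ),  # 35 records
    # hepcidin knockout: serum response to LPS (2 µg/g) in adult KO mice
    "hampko_lps": dict(
        study="hampko",
        scenario=dict(hamp_ko=True, pre_h=1440.0, lps_bolus=2.0, duration=6.0),
        observables=("fe_serum",),
        times=(0.0, 6.0),
    ),  # 2 records
    "wt_lps2": dict(
        study="hampko",
        scenario=dict(lps_bolus=2.0, duration=6.0),
        observables=("fe_serum",),
        times=(0.0, 6.0),
    ),  # 2 records
    # age-dependent liver iron accumulation in knockout mice (2-8 months)
    "hampko_liver": dict(
        study="hampko",
        scenario=dict(hamp_ko=True, duration=5040.0),
        observables=("fe_liver",),
        times=(720.0, 1440.0, 2160.0, 3600.0, 5040.0),
    ),  # 5 records
}


def generate_calibration_suite(true_params: ParameterSet, seed: int = 0, *,
                               n_replicates: int = 4, cv: float = 0.2,
                               design: dict[str, dict] | None = None
                               ) -> list[TimeCourseDataset]:
    """The full synthetic calibration design (344 records by default).

    One dataset per design entry; sub-seeds are derived deterministically from
    ``seed``.  Every scenario id in the suite is simulatable by the
    perturbation module, and the record count of the default design is exactly
    344 (90 + 60 + 80 + 105 + 9).
    """
    design = SUITE_DESIGN if design is None else design
    omap = default_observation_map(true_params)
    baseline = steady_state(true_params)
    out = []
    for k, (sid, spec) in enumerate(sorted(design.items())):
        scen = PerturbationScenario.from_dict(spec["scenario"])
        ds = generate_timecourse(
            true_params, scen, spec["observables"], spec["times"],
            n_replicates=n_replicates, cv=cv, seed=seed * 1009 + k,
            study=spec["study"], scenario_id=sid, obs_map=omap,
            baseline=None if scen.tracer_injection else baseline,
        )
        out.append(ds)
    return out
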