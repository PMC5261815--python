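"""In-silico experiments: hypoferremia dissection, chronic inflammation,
knockout panels, dietary homeostasis scans and liver-mechanism model selection.

These are the scripted counterparts of the perturbation studies the model is
built for.  Each function returns a tidy table; the CLI exposes each as a
subcommand.
"""

from __future__ import annotations

from dataclasses import replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibrate import TimeCourseDataset, chi2, multistart_fit
from .model import state_index
from .params import ParameterSet
from .perturb import PerturbationScenario, apply
from .simulate import (SteadyStateError, simulate_scenario, steady_state)

__all__ = [
    "hypoferremia_dissection", "chronic_inflammation", "knockout_panel",
    "diet_scan", "model_selection_liver", "loglog_slopes",
]

_MRNA_CLAMPS = frozenset({"FpnmRNA_liver", "FpnmRNA_spleen", "FpnmRNA_duo",
                          "FpnmRNA_other"})

#: Homeostasis classification thresholds for log-log slopes of steady-state
#: serum iron against dietary fold: below `HOMEOSTASIS_SLOPE` the pool is
#: considered buffered, above `LOST_SLOPE` homeostasis is considered lost.
HOMEOSTASIS_SLOPE = 0.3
LOST_SLOPE = 0.8


def hypoferremia_dissection(params: ParameterSet, diet_fold: float = 1.0,
                            lps_dose: float = 1.0, *, window_h: float = 72.0,
                            pre_h: float = 672.0, rtol: float = 1e-7,
                            n_times: int = 145) -> pd.DataFrame:
    """Relative contributions of the two ferroportin-repressing arms to
    LPS-induced hypoferremia.

    Simulates the acute LPS response for the full model and for variants in
    which one regulatory arm is frozen from the moment of injection: hepcidin
    clamped (only transcriptional Fpn repression acts) or all Fpn mRNAs
    clamped (only hepcidin-mediated degradation acts), plus the both-clamped
    control.  All runs start from the same pre-perturbation state; the drop is
    baseline minus the serum-iron minimum over the acute window, and each
    variant's drop is reported as a fraction of the full model's.
    """
    times = np.linspace(0.0, window_h, n_times)
    base_scen = PerturbationScenario(
        lps_bolus=lps_dose, diet_fold=diet_fold,
        pre_h=pre_h if diet_fold != 1.0 else 0.0, duration=window_h)
    variants = {
        "full": frozenset(),
        "hepcidin_clamped": frozenset({"Hep"}),
        "mrna_clamped": _MRNA_CLAMPS,
        "both_clamped": _MRNA_CLAMPS | {"Hep"},
    }
    baseline = steady_state(params)
    rows = []
    drops = {}
    for name, clamps in variants.items():
        scen = dc_replace(base_scen, clamps=clamps)
        traj = simulate_scenario(params, scen, times, rtol=rtol,
                                 baseline=baseline)
        ser = traj["Fe_serum"]
        ser0 = ser[0]
        drops[name] = (ser0 - float(ser.min())) / ser0
    for name in variants:
        rows.append(dict(variant=name, serum_drop=drops[name],
                         fraction_of_full=drops[name] / drops["full"]))
    return pd.DataFrame(rows)


def chronic_inflammation(params: ParameterSet, dose: float = 0.17,
                         horizon_h: float = 1440.0, *, rtol: float = 1e-7,
                         n_times: int = 241) -> dict:
    """Anemia of inflammation under a persistent LPS source.

    Simulates a constant LPS plateau of ``dose`` µg/g over the horizon and
    summarizes: the serum-iron nadir fraction within the first two days, the
    RBC iron fraction at the horizon, and the direction of liver iron.  The
    full trajectory is returned for plotting.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    times = np.linspace(0.0, horizon_h, n_times)
    baseline = steady_state(params)
    scen = PerturbationScenario(lps_chronic=dose, duration=horizon_h) \
        if dose > 0 else PerturbationScenario(duration=horizon_h)
    traj = simulate_scenario(params, scen, times, rtol=rtol, baseline=baseline)
    ser0, rbc0, liv0 = baseline[0], baseline[5], baseline[1]
    early = times <= 48.0
    nadir_2d = float(traj["Fe_serum"][early].min()) / ser0
    return {
        "trajectory": traj,
        "serum_nadir_fraction_2d": nadir_2d,
        "serum_drop_2d": 1.0 - nadir_2d,
        "rbc_fraction_horizon": float(traj["Fe_RBC"][-1]) / rbc0,
        "liver_fold_horizon": float(traj["Fe_liver"][-1]) / liv0,
        "liver_increases": bool(traj["Fe_liver"][-1] > liv0),
    }


_PANEL_SCENARIOS: dict[str, dict] = {
    "wild_type": {},
    "hamp_ko": dict(hamp_ko=True),
    "c326s_global": dict(c326s_organs=frozenset({"liver", "duo", "spleen", "rest"})),
    "c326s_liver": dict(c326s_organs=frozenset({"liver"})),
    "c326s_duodenum": dict(c326s_organs=frozenset({"duo"})),
    "c326s_spleen": dict(c326s_organs=frozenset({"spleen"})),
    "smad4_ko": dict(smad4_ko=True),
}


def knockout_panel(params: ParameterSet, *,
                   scenarios: Mapping[str, dict] | None = None
                   ) -> pd.DataFrame:
    """Steady-state fold changes versus wild type for the knockout panel.

    Covers hepcidin knockout, globally and organ-specifically
    hepcidin-resistant ferroportin (C326S), and liver SMAD4 knockout.
    Reported per genotype: serum/liver/spleen/total-body iron and hepcidin,
    as fold of the wild-type steady state.
    """
    scenarios = dict(_PANEL_SCENARIOS if scenarios is None else scenarios)
    y_wt = steady_state(params)
    hep_i = state_index("Hep")
    rows = []
    for name, kw in scenarios.items():
        scen = PerturbationScenario(**kw)
        p2, _ = apply(scen, params, y_wt)
        y = steady_state(p2, guess=y_wt[:7])
        rows.append(dict(
            genotype=name,
            serum=float(y[0] / y_wt[0]),
            liver=float(y[1] / y_wt[1]),
            spleen=float(y[2] / y_wt[2]),
            total=float(y[:7].sum() / y_wt[:7].sum()),
            hepcidin=float(y[hep_i] / y_wt[hep_i]) if y_wt[hep_i] > 0 else np.nan,
        ))
    return pd.DataFrame(rows).set_index("genotype")


def _variant_params(params: ParameterSet, variant: str) -> ParameterSet:
    if variant == "full":
        return params
    if variant == "no_hepcidin":
        return params.replace(k2_liver=0.0, k2_duo=0.0, k2_spleen=0.0,
                              k2_rest=0.0)
    if variant == "no_saturation":
        return params.replace(linear_uptake=True)
    if variant == "both_removed":
        return params.replace(k2_liver=0.0, k2_duo=0.0, k2_spleen=0.0,
                              k2_rest=0.0, linear_uptake=True)
    raise ValueError(f"unknown model variant {variant!r}")


DIET_VARIANTS = ("full", "no_hepcidin", "no_saturation", "both_removed")


def diet_scan(params: ParameterSet,
              fold_grid: Sequence[float] = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0),
              variants: Sequence[str] = DIET_VARIANTS) -> pd.DataFrame:
    """Steady-state serum iron and dietary absorption across diets and model
    variants (the homeostasis scan).

    For each variant the scan walks the fold grid with warm-started steady
    states.  A variant losing any bounded steady state at some fold (runaway
    liver loading) yields NaN there — that diet regime has no homeostatic
    set point for the variant.

    Because removing a mechanism (e.g. zeroing the k2 constants) also shifts
    the normal-diet baseline, homeostasis curves are additionally reported
    relative to each variant's own normal-diet steady state
    (``fe_serum_rel``); on that scale all variants share the fold-1 anchor
    and log-log slopes are unchanged.
    """
    fold_grid = np.asarray(sorted(fold_grid), dtype=float)
    if np.any(fold_grid <= 0):
        raise ValueError("fold_grid must be positive")
    rows = []
    for variant in variants:
        pv = _variant_params(params, variant)
        guess = None
        for fold in fold_grid:
            try:
                y = steady_state(pv, float(fold), guess=guess)
                guess = y[:7]
                absorption = pv.u_duo * y[state_index("Fpn_duo")] * y[3]
                rows.append(dict(variant=variant, diet_fold=float(fold),
                                 fe_serum=float(y[0]), fe_liver=float(y[1]),
                                 uptake=float(absorption),
                                 hepcidin=float(y[state_index("Hep")])))
            except SteadyStateError:
                rows.append(dict(variant=variant, diet_fold=float(fold),
                                 fe_serum=np.nan, fe_liver=np.nan,
                                 uptake=np.nan, hepcidin=np.nan))
    df = pd.DataFrame(rows)
    anchors = df[df["diet_fold"] == 1.0].set_index("variant")["fe_serum"] \
        if (df["diet_fold"] == 1.0).any() else None
    if anchors is not None:
        df["fe_serum_rel"] = df.apply(
            lambda r: r["fe_serum"] / anchors.get(r["variant"], np.nan), axis=1)
    return df


def loglog_slopes(scan: pd.DataFrame, column: str = "fe_serum",
                  lo: float = 0.1, hi: float = 100.0) -> dict[str, float]:
    """Mean log-log slope of a scan column over a fold window, per variant.

    Slopes are computed between consecutive grid points whose values exist and
    whose folds lie within [lo, hi], then averaged.  NaN if no usable segment.
    """
    out: dict[str, float] = {}
    for variant, df in scan.groupby("variant"):
        df = df.sort_values("diet_fold")
        mask = (df["diet_fold"] >= lo) & (df["diet_fold"] <= hi) \
            & df[column].notna() & (df[column] > 0)
        f = df.loc[mask, "diet_fold"].to_numpy(float)
        v = df.loc[mask, column].to_numpy(float)
        if len(f) < 2:
            out[variant] = np.nan
            continue
        slopes = np.diff(np.log(v)) / np.diff(np.log(f))
        out[variant] = float(np.mean(slopes))
    return out


LIVER_VARIANTS = ("full", "no_ntbi", "no_ferritin_cap", "neither")


def _liver_variant(params: ParameterSet, variant: str) -> ParameterSet:
    if variant == "full":
        return params
    if variant == "no_ntbi":
        return params.replace(v_NTBI=0.0)
    if variant == "no_ferritin_cap":
        return params.replace(Fe_max=np.inf)
    if variant == "neither":
        return params.replace(v_NTBI=0.0, Fe_max=np.inf)
    raise ValueError(f"unknown liver variant {variant!r}")


def model_selection_liver(params: ParameterSet,
                          datasets: Sequence[TimeCourseDataset],
                          variants: Sequence[str] = LIVER_VARIANTS, *,
                          refit: bool = True,
                          free: Sequence[str] = ("v_liver", "v_NTBI", "K_NTBI"),
                          n_starts: int = 3, seed: int = 0,
                          max_nfev: int = 25) -> pd.DataFrame:
    """Compare liver-iron fit quality across liver-mechanism variants.

    Variants remove NTBI uptake (``v_NTBI = 0``), the ferritin storage cap
    (``Fe_max = inf``) or both.  Each reduced variant is (optionally) refit
    over its remaining free liver parameters before scoring, so a variant is
    not penalized merely for losing a calibrated parameter.  Reported per
    variant: total χ²/N and the χ² restricted to liver-iron records.
    """
    recs = pd.concat([d.records for d in datasets], ignore_index=True)
    liver_mask = recs["observable"].isin(["fe_liver"]).to_numpy()
    rows = []
    for variant in variants:
        pv = _liver_variant(params, variant)
        frees = [f for f in free
                 if not (variant in ("no_ntbi", "neither") and f in ("v_NTBI", "K_NTBI"))]
        if refit and frees:
            ens = multistart_fit(datasets, n_starts=n_starts, seed=seed,
                                 free=frees, base_params=pv,
                                 include_base_start=True, max_nfev=max_nfev)
            pv = ens.best.params
        c2, c2n, scal = chi2(pv, datasets)
        from .calibrate import predict_records, _sigma
        x = predict_records(pv, datasets)
        s = np.array([1.0 if g == "abs" else scal.get(g, 1.0)
                      for g in recs["scale_group"]])
        r = (s * x - recs["mean"].to_numpy(float)) / _sigma(recs)
        rows.append(dict(variant=variant, chi2=c2, chi2_per_n=c2n,
                         chi2_liver=float(np.sum(r[liver_mask] ** 2)),
                         n_liver=int(liver_mask.sum())))
    return pd.DataFrame(rows).set_index("variant")
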