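"""Model calibration: χ² objective, scaling profiling, multi-start fitting,
prediction ensembles and steady-state log-sensitivities.

The objective is the standard weighted sum of squares

    χ² = Σ_i ((s_{g(i)} · x(t_i; θ) − y_i) / σ_i)²

over time-course records; y_i is the recorded replicate mean and σ_i its
uncertainty, SD_i / sqrt(n_i) (records carry the noise SD and the replicate
count, so the weight is the standard error of the mean).  Molecular observables measured
in arbitrary units carry one multiplicative scaling parameter s_g per scaling
group; these enter the objective linearly-in-square and are therefore profiled
analytically (per group, s*_g = Σ x y/σ² / Σ x²/σ²) instead of being optimized
as free coordinates, which shrinks the search space without moving the
optimum.  Kinetic parameters are searched in log space by a multi-start local
least-squares optimizer; the best 30 fits define the prediction ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import IRON_POOLS
from .params import DEFAULT_BOUNDS_DECADES, KINETIC_PARAM_NAMES, ParameterSet
from .perturb import PerturbationScenario
from .simulate import (ObservationMap, SteadyStateError,
                       default_observation_map, simulate_scenario,
                       simulate_tracer, steady_state)

__all__ = [
    "TimeCourseDataset", "FitResult", "FitEnsemble", "predict_records",
    "chi2", "profile_scalings", "multistart_fit", "ensemble_predict",
    "sensitivity",
]

DATASET_COLUMNS = ("scenario", "observable", "time_h", "mean", "sd", "n",
                   "units", "scale_group")


@dataclass
class TimeCourseDataset:
    """Observed time-course records plus the scenarios that generated them.

    ``records`` is a tidy DataFrame with columns ``scenario, observable,
    time_h, mean, sd, n, units, scale_group``; ``scenarios`` maps scenario ids
    to :class:`PerturbationScenario` objects.  Absolute-unit records have
    ``scale_group == "abs"`` and a fixed scaling of 1.
    """

    records: pd.DataFrame
    scenarios: dict[str, PerturbationScenario] = field(default_factory=dict)
    name: str = "dataset"

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset is missing columns {sorted(missing)}")
        self.records = self.records.reset_index(drop=True)
        if (self.records["sd"] <= 0).any():
            bad = self.records.index[self.records["sd"] <= 0].tolist()
            raise ValueError(f"records with SD <= 0 cannot be fitted (rows {bad})")
        unknown = set(self.records["scenario"]) - set(self.scenarios)
        if unknown:
            raise ValueError(f"records reference unknown scenarios {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.records)


def _concat(datasets: Sequence[TimeCourseDataset]) -> tuple[pd.DataFrame, dict]:
    if isinstance(datasets, TimeCourseDataset):
        datasets = [datasets]
    frames, scen = [], {}
    for ds in datasets:
        frames.append(ds.records)
        scen.update(ds.scenarios)
    return pd.concat(frames, ignore_index=True), scen


def predict_records(params: ParameterSet, datasets: Sequence[TimeCourseDataset],
                    *, obs_map: ObservationMap | None = None,
                    rtol: float = 1e-6) -> np.ndarray:
    """Unscaled model values x_i for every record, in record order.

    Each scenario is simulated once on the union of its record times; tracer
    scenarios run through the frozen-coefficient tracer subsystem.  Failed
    simulations propagate as exceptions (callers decide whether to treat them
    as an infinite objective).
    """
    recs, scenarios = _concat(datasets)
    omap = obs_map or default_observation_map(params)
    x = np.empty(len(recs))
    base = steady_state(params)
    for sid, group in recs.groupby("scenario", sort=False):
        scen = scenarios[sid]
        times = np.unique(group["time_h"].to_numpy(float))
        if scen.tracer_injection:
            df = simulate_tracer(
                params.replace(Fe_food=params.Fe_food * scen.diet_fold),
                1.0, times,
                y_ss=steady_state(params, scen.diet_fold) if scen.diet_fold != 1.0 else base)
            df = df.set_index("time_h")
            for i, row in group.iterrows():
                x[i] = df.loc[row["time_h"], row["observable"]]
        else:
            traj = simulate_scenario(params, scen, times, rtol=rtol, baseline=base)
            tidx = {t: k for k, t in enumerate(traj.times)}
            for i, row in group.iterrows():
                series = omap.quantity(traj, row["observable"])
                x[i] = series[tidx[row["time_h"]]]
    return x


def _sigma(recs: pd.DataFrame) -> np.ndarray:
    """Per-record weight: standard error of the mean, SD / sqrt(n)."""
    return recs["sd"].to_numpy(float) / np.sqrt(recs["n"].to_numpy(float))


def profile_scalings(x: np.ndarray, datasets: Sequence[TimeCourseDataset]
                     ) -> dict[str, float]:
    """Exact per-group minimizers of χ² over the scaling parameters.

    For each arbitrary-unit scaling group g, s*_g = Σ(x y/σ²) / Σ(x²/σ²) over
    the group's records; absolute groups are fixed at 1.  A group whose model
    values are identically zero has an undefined scaling and is reported at 1
    (its residuals are then data/σ regardless).
    """
    recs, _ = _concat(datasets)
    y = recs["mean"].to_numpy(float)
    sd = _sigma(recs)
    out: dict[str, float] = {}
    for g, idx in recs.groupby("scale_group").groups.items():
        if g == "abs":
            continue
        xi, yi, si = x[idx], y[idx], sd[idx]
        denom = float(np.sum(xi * xi / si**2))
        out[g] = float(np.sum(xi * yi / si**2)) / denom if denom > 0 else 1.0
    return out


def chi2(params: ParameterSet, datasets: Sequence[TimeCourseDataset],
         scalings: Mapping[str, float] | None = None, *,
         obs_map: ObservationMap | None = None, rtol: float = 1e-6
         ) -> tuple[float, float, dict[str, float]]:
    """χ², χ²/N and the scalings used (profiled when not supplied)."""
    recs, _ = _concat(datasets)
    x = predict_records(params, datasets, obs_map=obs_map, rtol=rtol)
    if scalings is None:
        scalings = profile_scalings(x, datasets)
    s = np.array([1.0 if g == "abs" else scalings.get(g, 1.0)
                  for g in recs["scale_group"]])
    r = (s * x - recs["mean"].to_numpy(float)) / _sigma(recs)
    c2 = float(np.sum(r * r))
    return c2, c2 / len(recs), dict(scalings)


def _residuals(params: ParameterSet, datasets: Sequence[TimeCourseDataset],
               obs_map: ObservationMap | None, rtol: float) -> np.ndarray:
    recs, _ = _concat(datasets)
    x = predict_records(params, datasets, obs_map=obs_map, rtol=rtol)
    scalings = profile_scalings(x, datasets)
    s = np.array([1.0 if g == "abs" else scalings[g] for g in recs["scale_group"]])
    return (s * x - recs["mean"].to_numpy(float)) / _sigma(recs)


@dataclass
class FitResult:
    """One converged local fit."""

    values: dict[str, float]
    params: ParameterSet
    scalings: dict[str, float]
    chi2: float
    chi2_per_n: float
    n_records: int
    start_index: int
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "values": self.values, "scalings": self.scalings,
            "chi2": self.chi2, "chi2_per_n": self.chi2_per_n,
            "n_records": self.n_records, "start_index": self.start_index,
        }


@dataclass
class FitEnsemble:
    """Ranked multi-start fits; the best 30 define prediction bands."""

    results: list[FitResult]
    seed: int
    free: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    ensemble_size: int = 30

    def __post_init__(self) -> None:
        self.results = sorted(self.results, key=lambda r: r.chi2)

    @property
    def best(self) -> FitResult:
        return self.results[0]

    @property
    def members(self) -> list[FitResult]:
        return self.results[: self.ensemble_size]

    def report(self) -> str:
        return json.dumps({
            "seed": self.seed, "free": list(self.free),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "n_fits": len(self.results),
            "best": self.best.to_dict(),
            "ensemble_chi2": [r.chi2 for r in self.members],
        }, indent=2)


def multistart_fit(datasets: Sequence[TimeCourseDataset], n_starts: int = 100,
                   bounds: Mapping[str, tuple[float, float]] | None = None,
                   seed: int = 0, *, free: Sequence[str] | None = None,
                   base_params: ParameterSet | None = None,
                   obs_map: ObservationMap | None = None,
                   include_base_start: bool = False, rtol: float = 1e-6,
                   max_nfev: int | None = None,
                   ensemble_size: int = 30,
                   n_candidates: int | None = None) -> FitEnsemble:
    """Multi-start local optimization of the kinetic parameters.

    Starts are drawn log-uniformly inside ``bounds`` (default: ±3 decades
    around the base parameter values) and refined with a trust-region
    least-squares optimizer in log10-parameter space, with scaling parameters
    profiled analytically inside the objective.  Deterministic given ``seed``.
    ``free`` restricts the search to a named subset of the 48 kinetic
    parameters (the rest stay at their base values).

    When ``n_candidates`` exceeds ``n_starts``, that many candidate points are
    sampled first and only the ``n_starts`` with the lowest objective are
    refined (sample-then-refine preselection, which makes wide search boxes
    far more reliable at the same refinement cost).
    """
    from scipy.optimize import least_squares

    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    base = base_params or ParameterSet()
    free = tuple(free) if free is not None else KINETIC_PARAM_NAMES
    unknown = set(free) - set(KINETIC_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown kinetic parameters {sorted(unknown)}")
    box: dict[str, tuple[float, float]] = {}
    for name in free:
        if bounds and name in bounds:
            lo, hi = bounds[name]
        else:
            ref = getattr(base, name)
            if ref <= 0:
                raise ValueError(f"cannot build default bounds around {name}=0")
            lo, hi = ref * 10.0 ** -DEFAULT_BOUNDS_DECADES, ref * 10.0 ** DEFAULT_BOUNDS_DECADES
        if not (0 < lo < hi < np.inf):
            raise ValueError(f"bounds for {name} must be positive and finite")
        box[name] = (lo, hi)
    lo10 = np.log10([box[n][0] for n in free])
    hi10 = np.log10([box[n][1] for n in free])

    recs, _ = _concat(datasets)
    n_rec = len(recs)

    def obj(theta10: np.ndarray) -> np.ndarray:
        p = base.replace(**{n: 10.0 ** v for n, v in zip(free, theta10)})
        try:
            return _residuals(p, datasets, obs_map, rtol)
        except (RuntimeError, SteadyStateError, FloatingPointError, ValueError):
            return np.full(n_rec, 1e4)

    rng = np.random.default_rng(seed)
    n_draw = max(n_starts, n_candidates or 0)
    starts = [lo10 + rng.random(len(free)) * (hi10 - lo10) for _ in range(n_draw)]
    if include_base_start:
        starts[0] = np.log10([getattr(base, n) for n in free])
    if n_draw > n_starts:
        # keep the best-scoring candidates subject to a minimum separation in
        # log10-parameter space, so refinement covers distinct basins instead
        # of piling into the single best-looking one
        scores = [float(np.sum(obj(x0) ** 2)) for x0 in starts]
        min_sep = 0.5
        chosen: list[np.ndarray] = []
        for i in np.argsort(scores):
            cand = starts[i]
            if all(np.max(np.abs(cand - c)) >= min_sep for c in chosen):
                chosen.append(cand)
            if len(chosen) == n_starts:
                break
        for i in np.argsort(scores):  # backfill if separation left gaps
            if len(chosen) == n_starts:
                break
            if not any(np.array_equal(starts[i], c) for c in chosen):
                chosen.append(starts[i])
        starts = chosen

    results: list[FitResult] = []
    failures: list[str] = []
    for k, x0 in enumerate(starts):
        try:
            sol = least_squares(obj, np.clip(x0, lo10, hi10),
                                bounds=(lo10, hi10), method="trf",
                                x_scale="jac", max_nfev=max_nfev)
            values = {n: float(10.0 ** v) for n, v in zip(free, sol.x)}
            p = base.replace(**values)
            c2, c2n, scal = chi2(p, datasets, obs_map=obs_map, rtol=rtol)
            results.append(FitResult(values=values, params=p, scalings=scal,
                                     chi2=c2, chi2_per_n=c2n, n_records=n_rec,
                                     start_index=k, message=sol.message))
        except Exception as exc:  # noqa: BLE001 - per-start diagnostics
            failures.append(f"start {k}: {exc}")
    if not results:
        raise RuntimeError("all optimizer starts failed:\n" + "\n".join(failures))
    return FitEnsemble(results=results, seed=seed, free=free, bounds=box,
                       ensemble_size=ensemble_size)


def ensemble_predict(ensemble: FitEnsemble, scenario: PerturbationScenario,
                     observable: str, t_grid: Sequence[float], *,
                     obs_map: ObservationMap | None = None,
                     rtol: float = 1e-6) -> pd.DataFrame:
    """Pointwise min/mean/max prediction band across the best-30 members.

    Members whose simulation fails are dropped with a warning; the band always
    contains the best-fit trajectory pointwise.
    """
    import warnings

    if not ensemble.members:
        raise ValueError("empty ensemble")
    omap = obs_map or default_observation_map()
    t_grid = np.asarray(t_grid, dtype=float)
    curves = []
    for m in ensemble.members:
        try:
            traj = simulate_scenario(m.params, scenario, t_grid, rtol=rtol)
            sel = np.isin(traj.times, t_grid)
            curves.append(omap.quantity(traj, observable)[sel])
        except (RuntimeError, SteadyStateError, FloatingPointError) as exc:
            warnings.warn(f"ensemble member dropped: {exc}", stacklevel=2)
    if not curves:
        raise RuntimeError("every ensemble member failed to simulate")
    arr = np.vstack(curves)
    return pd.DataFrame({
        "time_h": t_grid, "lo": arr.min(axis=0), "mean": arr.mean(axis=0),
        "hi": arr.max(axis=0),
    })


def sensitivity(params: ParameterSet,
                targets: str = "pools",
                *, param_names: Sequence[str] | None = None,
                pools: Sequence[str] = IRON_POOLS,
                diet_fold_hi: float = 100.0, step: float = 0.01,
                ) -> pd.DataFrame:
    """Log-sensitivity matrix m_ij = d log x_j / d log p_i at steady state.

    ``targets`` selects the response: steady-state iron pools (``"pools"``),
    the dietary fold-changes of those pools between the normal diet and
    ``diet_fold_hi`` (``"foldchange"``), or both stacked.  Central finite
    differences in log-parameter space with a relative step of ``step``
    (1 % default).  Entries for non-positive pools are NaN.
    """
    from .model import state_index as _sidx

    if targets not in ("pools", "foldchange", "both"):
        raise ValueError("targets must be 'pools', 'foldchange' or 'both'")
    names = tuple(param_names) if param_names is not None else KINETIC_PARAM_NAMES
    pool_idx = [_sidx(s) for s in pools]

    def response(p: ParameterSet) -> np.ndarray:
        cols = []
        if targets in ("pools", "both"):
            y1 = steady_state(p)
            cols.append(y1[pool_idx])
        if targets in ("foldchange", "both"):
            y1 = steady_state(p)
            yh = steady_state(p, diet_fold_hi, guess=y1[:7] * 2)
            cols.append(yh[pool_idx] / np.maximum(y1[pool_idx], 1e-300))
        return np.concatenate(cols)

    h = np.log(1.0 + step)
    rows = []
    for name in names:
        v = getattr(params, name)
        if v == 0:
            rows.append(np.zeros(len(pool_idx) * (2 if targets == "both" else 1)))
            continue
        up = response(params.replace(**{name: v * np.exp(h)}))
        dn = response(params.replace(**{name: v * np.exp(-h)}))
        with np.errstate(divide="ignore", invalid="ignore"):
            m = (np.log(up) - np.log(dn)) / (2 * h)
        rows.append(np.where((up > 0) & (dn > 0), m, np.nan))
    if targets == "both":
        cols = [f"{s}" for s in pools] + [f"{s}_foldchange" for s in pools]
    elif targets == "foldchange":
        cols = [f"{s}_foldchange" for s in pools]
    else:
        cols = list(pools)
    return pd.DataFrame(rows, index=list(names), columns=cols)
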