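"""File formats: the tidy CSV dataset dialect, YAML configuration and
scenarios, and a converter for replicate-table XLSX workbooks."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .calibrate import DATASET_COLUMNS, TimeCourseDataset
from .params import ParameterSet, PromoterParams
from .perturb import PerturbationScenario

__all__ = [
    "read_dataset", "write_dataset", "convert_xlsx",
    "scenario_from_yaml", "scenario_to_yaml",
    "params_from_yaml", "params_to_yaml",
]


def write_dataset(dataset: TimeCourseDataset, path: str | Path) -> None:
    """Write a dataset in the tidy CSV dialect, with scenarios embedded as
    ``# scenario:`` header comments (YAML flow mappings)."""
    path = Path(path)
    lines = []
    for sid, scen in sorted(dataset.scenarios.items()):
        d = {k: (sorted(v) if isinstance(v, frozenset) else v)
             for k, v in scen.__dict__.items()}
        d = {k: v for k, v in d.items() if v not in (0.0, False, [], "zero_synthesis")}
        lines.append("# scenario: " + yaml.safe_dump(
            {sid: d}, default_flow_style=True, width=10**6).strip())
    body = dataset.records[list(DATASET_COLUMNS)].to_csv(index=False)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_dataset(path: str | Path) -> TimeCourseDataset:
    """Read the tidy CSV dialect back into a :class:`TimeCourseDataset`.

    Raises a parse error naming the offending row for missing columns or
    non-numeric cells.
    """
    path = Path(path)
    scenarios: dict[str, PerturbationScenario] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            if line.startswith("# scenario:"):
                block = yaml.safe_load(line[len("# scenario:"):])
                for sid, kw in block.items():
                    scenarios[sid] = PerturbationScenario.from_dict(kw or {})
    df = pd.read_csv(path, skiprows=header_lines)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("time_h", "mean", "sd", "n"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r}, "
                             f"row {int(bad[0]) + 2}")
        df[col] = converted
    for sid in df["scenario"].unique():
        scenarios.setdefault(str(sid), PerturbationScenario())
    zero_sd = df["sd"] <= 0
    if zero_sd.any():
        import warnings
        warnings.warn(f"{path}: dropping {int(zero_sd.sum())} records with "
                      "SD <= 0 (cannot be fitted)", stacklevel=2)
        df = df[~zero_sd]
    return TimeCourseDataset(records=df.reset_index(drop=True),
                             scenarios=scenarios, name=path.stem)


def convert_xlsx(path: str | Path, *, scenario_id: str = "imported",
                 study: str = "lpsdiet") -> TimeCourseDataset:
    """Ingest a replicate-table XLSX workbook and emit the CSV dialect.

    Expected layout (the common way labs share replicate measurements): one
    sheet per observable; column A holds the measurement time in hours, the
    remaining columns hold one replicate each.  Means, SDs and replicate
    counts are computed per row.
    """
    from openpyxl import load_workbook

    from .simulate import ABSOLUTE_OBSERVABLES, default_observation_map

    omap = default_observation_map()
    wb = load_workbook(path, read_only=True, data_only=True)
    rows = []
    for sheet in wb.worksheets:
        obs = sheet.title.strip()
        for row in sheet.iter_rows(min_row=2, values_only=True):
            if row is None or row[0] is None:
                continue
            t = float(row[0])
            reps = np.array([float(v) for v in row[1:] if v is not None])
            if reps.size < 2:
                raise ValueError(
                    f"{path}:{obs}: need >= 2 replicates at t={t}")
            group = ("abs" if obs in ABSOLUTE_OBSERVABLES
                     else omap.group_for(study, obs))
            rows.append(dict(
                scenario=scenario_id, observable=obs, time_h=t,
                mean=float(reps.mean()), sd=float(reps.std(ddof=1)),
                n=int(reps.size),
                units="absolute" if group == "abs" else "arbitrary",
                scale_group=group))
    wb.close()
    return TimeCourseDataset(records=pd.DataFrame(rows),
                             scenarios={scenario_id: PerturbationScenario()},
                             name=Path(path).stem)


# ----------------------------------------------------------------------
# YAML configuration
# ----------------------------------------------------------------------

def scenario_to_yaml(scenario: PerturbationScenario, path: str | Path) -> None:
    d = {k: (sorted(v) if isinstance(v, frozenset) else v)
         for k, v in scenario.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def scenario_from_yaml(path: str | Path) -> PerturbationScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PerturbationScenario.from_dict(d)


def params_to_yaml(params: ParameterSet, path: str | Path) -> None:
    """Serialize a parameter set, promoter block included, to YAML."""
    d = {k: v for k, v in params.__dict__.items() if k != "promoter"}
    d["clamps"] = list(d.get("clamps", ()))
    d["promoter"] = dict(params.promoter.__dict__)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def params_from_yaml(path: str | Path,
                     base: ParameterSet | None = None) -> ParameterSet:
    """Load a parameter set from YAML; missing fields fall back to ``base``
    (default: the packaged reference set)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "promoter" in d:
        d["promoter"] = PromoterParams(**d["promoter"])
    if "clamps" in d:
        d["clamps"] = tuple(d["clamps"])
    base = base if base is not None else ParameterSet()
    return base.replace(**d)
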