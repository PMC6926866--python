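"""Reading and writing campaign tables, specs and scenario files."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .synthetic_data import CAMPAIGN_COLUMNS, CampaignSpec, TaskParams
from .twa_model import Scenario

__all__ = [
    "write_campaign_csv",
    "read_campaign_csv",
    "campaign_spec_to_yaml",
    "campaign_spec_from_yaml",
    "scenarios_to_yaml",
    "scenarios_from_yaml",
]

_NUMERIC = ["duration_min", "flow_l_min", "endotoxin_eu", "concentration_eu_m3"]
_POSITIVE = ["duration_min", "flow_l_min"]


def write_campaign_csv(df: pd.DataFrame, path) -> None:
    """Write a campaign table as UTF-8 CSV with '.' decimal separator."""
    df[CAMPAIGN_COLUMNS].to_csv(path, index=False)


def read_campaign_csv(path) -> pd.DataFrame:
    """Read and validate a campaign CSV.

    Raises ``ValueError`` naming the offending column (and row, for cell
    level problems): missing columns, non-numeric fields, non-positive
    durations or flows.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CAMPAIGN_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    df = raw.copy()
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna()]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"non-numeric value {raw.at[bad[0], col]!r}")
        df[col] = converted.astype(float)
    for col in _POSITIVE:
        bad = df.index[df[col] <= 0]
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{path}: row {row + 2}, column {col!r}: "
                f"must be > 0, got {df.at[bad[0], col]}")
    df["below_lod"] = df["below_lod"].str.strip().str.lower().isin(
        ("true", "1", "yes"))
    return df[CAMPAIGN_COLUMNS]


def _task_to_dict(t: TaskParams) -> dict:
    d = dict(task=t.task, sample_type=t.sample_type, gm=t.gm, gsd=t.gsd,
             between_fraction=t.between_fraction, n_workers=t.n_workers,
             duration_range_min=list(t.duration_range_min),
             flow_range_l_min=list(t.flow_range_l_min))
    if t.samples_per_worker is not None:
        d["samples_per_worker"] = t.samples_per_worker
    else:
        d["n_samples"] = t.n_samples
    return d


def campaign_spec_to_yaml(spec: CampaignSpec, path) -> None:
    doc = dict(seed=spec.seed, lod_per_ml=spec.lod_per_ml,
               extract_volume_ml=spec.extract_volume_ml,
               tasks=[_task_to_dict(t) for t in spec.tasks])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def campaign_spec_from_yaml(path) -> CampaignSpec:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    tasks = []
    for td in doc.get("tasks", []):
        td = dict(td)
        for key in ("duration_range_min", "flow_range_l_min"):
            if key in td:
                td[key] = tuple(td[key])
        tasks.append(TaskParams(**td))
    return CampaignSpec(
        tasks=tuple(tasks),
        seed=int(doc.get("seed", 0)),
        lod_per_ml=float(doc.get("lod_per_ml", 0.15)),
        extract_volume_ml=float(doc.get("extract_volume_ml", 5.0)),
    )


def scenarios_to_yaml(scenarios: Sequence[Scenario], path) -> None:
    doc = [dict(id=s.scenario_id, description=s.description,
                durations={k: float(v) for k, v in s.durations.items()})
           for s in scenarios]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def scenarios_from_yaml(path) -> list[Scenario]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return [Scenario(scenario_id=str(d["id"]),
                     description=str(d.get("description", "")),
                     durations=d.get("durations", {}))
            for d in doc]
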