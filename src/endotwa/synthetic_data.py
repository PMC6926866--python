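"""Synthetic air-sampling campaign generator.

Concentrations follow a two-level (between-worker / within-worker) lognormal
model: for a task with geometric mean ``gm`` and total geometric standard
deviation ``gsd``, each worker receives a personal geometric mean drawn with
log-scale SD ``sqrt(between_fraction) * ln(gsd)``, and individual samples
scatter around that worker mean with log-scale SD
``sqrt(1 - between_fraction) * ln(gsd)``.  Sample durations and pump flow
rates are drawn uniformly on the task's observed ranges, and the endotoxin
mass on the filter is back-computed from concentration x sampled air volume.

Censoring at the analytical limit of detection is applied per filter: the
mass LOD is ``lod_per_ml * extract_volume_ml`` EU, converted to a
concentration LOD through the sample's own air volume; censored samples are
substituted at LOD/sqrt(2), the standard industrial-hygiene convention.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from math import log, sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from . import defaults

__all__ = [
    "TaskParams",
    "CampaignSpec",
    "SampleRecord",
    "generate_campaign",
    "censor_at_lod",
    "default_campaign_spec",
    "CAMPAIGN_COLUMNS",
]

#: Column order of the campaign table / CSV.
CAMPAIGN_COLUMNS = [
    "worker_id",
    "task",
    "sample_type",
    "duration_min",
    "flow_l_min",
    "endotoxin_eu",
    "concentration_eu_m3",
    "below_lod",
]


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


@dataclass(frozen=True)
class TaskParams:
    """Generator parameters for one task.

    Exactly one of ``samples_per_worker`` (balanced design) or ``n_samples``
    (total count, distributed round-robin over workers) must be given.
    """

    task: str
    gm: float
    gsd: float
    sample_type: str = "personal"
    between_fraction: float = defaults.DEFAULT_BETWEEN_FRACTION
    n_workers: int = 3
    samples_per_worker: int | None = None
    n_samples: int | None = None
    duration_range_min: tuple[float, float] = (30.0, 240.0)
    flow_range_l_min: tuple[float, float] = defaults.DEFAULT_FLOW_RANGE

    def __post_init__(self) -> None:
        _require(bool(self.task), "task", "task name must be non-empty")
        _require(self.sample_type in ("personal", "area"), "sample_type",
                 f"must be 'personal' or 'area', got {self.sample_type!r}")
        _require(self.gm > 0, "gm", f"geometric mean must be > 0, got {self.gm}")
        _require(self.gsd >= 1, "gsd", f"geometric SD must be >= 1, got {self.gsd}")
        _require(0.0 <= self.between_fraction <= 1.0, "between_fraction",
                 f"must be in [0, 1], got {self.between_fraction}")
        _require(self.n_workers >= 1, "n_workers", "must be a positive integer")
        _require((self.samples_per_worker is None) != (self.n_samples is None),
                 "samples_per_worker/n_samples",
                 "exactly one of samples_per_worker or n_samples must be set")
        if self.samples_per_worker is not None:
            _require(self.samples_per_worker >= 1, "samples_per_worker",
                     "must be a positive integer")
        if self.n_samples is not None:
            _require(self.n_samples >= 1, "n_samples", "must be a positive integer")
        for name, rng in (("duration_range_min", self.duration_range_min),
                          ("flow_range_l_min", self.flow_range_l_min)):
            _require(len(rng) == 2, name, "must be a (lo, hi) pair")
            _require(rng[0] > 0, name, f"lower bound must be > 0, got {rng[0]}")
            _require(rng[0] <= rng[1], name,
                     f"lower bound exceeds upper: {rng[0]} > {rng[1]}")

    @property
    def total_samples(self) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return self.n_workers * int(self.samples_per_worker)

    def sample_counts(self) -> list[int]:
        """Per-worker sample counts (round-robin for unbalanced totals)."""
        if self.samples_per_worker is not None:
            return [self.samples_per_worker] * self.n_workers
        base, rem = divmod(int(self.n_samples), self.n_workers)
        return [base + (1 if i < rem else 0) for i in range(self.n_workers)]


@dataclass(frozen=True)
class CampaignSpec:
    """Full specification of a synthetic sampling campaign."""

    tasks: tuple[TaskParams, ...]
    seed: int = 0
    lod_per_ml: float = defaults.DEFAULT_LOD_PER_ML
    extract_volume_ml: float = defaults.DEFAULT_EXTRACT_VOLUME_ML

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(self.tasks))
        _require(len(self.tasks) > 0, "tasks", "at least one task is required")
        _require(self.lod_per_ml > 0, "lod_per_ml", "must be > 0")
        _require(self.extract_volume_ml > 0, "extract_volume_ml", "must be > 0")

    @property
    def lod_mass_eu(self) -> float:
        """Per-filter limit of detection in EU (LOD conc x extract volume)."""
        return self.lod_per_ml * self.extract_volume_ml


@dataclass(frozen=True)
class SampleRecord:
    """One air sample: the atomic observation of the campaign."""

    worker_id: str
    task: str
    sample_type: str
    duration_min: float
    flow_l_min: float
    endotoxin_eu: float
    concentration_eu_m3: float
    below_lod: bool = False


def _task_rng(seed: int, params: TaskParams) -> np.random.Generator:
    # Per-task substream keyed on (seed, task identity) so adding or removing
    # one task never perturbs another task's draws.
    key = zlib.crc32(f"{params.sample_type}:{params.task}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def generate_campaign(spec: CampaignSpec) -> pd.DataFrame:
    """Generate a synthetic sampling campaign.

    Parameters
    ----------
    spec
        Campaign specification; ``spec.seed`` fully determines the output.

    Returns
    -------
    pandas.DataFrame
        One row per sample with columns :data:`CAMPAIGN_COLUMNS`.  Records are
        uncensored (``below_lod`` False); apply :func:`censor_at_lod` to
        emulate the analytical detection limit.
    """
    rows: list[dict] = []
    for params in spec.tasks:
        rng = _task_rng(spec.seed, params)
        sigma_b = sqrt(params.between_fraction) * log(params.gsd)
        sigma_w = sqrt(1.0 - params.between_fraction) * log(params.gsd)
        prefix = "W" if params.sample_type == "personal" else "A"
        # multiplicative form keeps the gsd == 1 case an exact point mass
        worker_gms = params.gm * np.exp(rng.normal(0.0, sigma_b, params.n_workers))
        for i, count in enumerate(params.sample_counts()):
            worker_id = f"{prefix}_{params.task}_{i + 1:02d}"
            conc = worker_gms[i] * np.exp(rng.normal(0.0, sigma_w, count))
            dur = rng.uniform(*params.duration_range_min, count)
            flow = rng.uniform(*params.flow_range_l_min, count)
            vol_m3 = flow * dur / 1000.0
            for c, d, f, v in zip(conc, dur, flow, vol_m3):
                rows.append(dict(
                    worker_id=worker_id,
                    task=params.task,
                    sample_type=params.sample_type,
                    duration_min=float(d),
                    flow_l_min=float(f),
                    endotoxin_eu=float(c * v),
                    concentration_eu_m3=float(c),
                    below_lod=False,
                ))
    return pd.DataFrame(rows, columns=CAMPAIGN_COLUMNS)


def censor_at_lod(record, spec: CampaignSpec):
    """Apply limit-of-detection censoring to a record or campaign table.

    The concentration LOD for a sample is
    ``(lod_per_ml * extract_volume_ml) / volume_m3`` with
    ``volume_m3 = flow * duration / 1000``.  Samples below it are flagged
    and substituted at LOD/sqrt(2) (mass and concentration consistently);
    samples at or above the LOD are returned unchanged.

    Accepts a single :class:`SampleRecord` or a campaign ``DataFrame``.
    """
    if isinstance(record, pd.DataFrame):
        return _censor_frame(record, spec)
    if record.duration_min <= 0:
        raise ValueError(f"duration_min: must be > 0, got {record.duration_min}")
    if record.flow_l_min <= 0:
        raise ValueError(f"flow_l_min: must be > 0, got {record.flow_l_min}")
    vol_m3 = record.flow_l_min * record.duration_min / 1000.0
    lod_conc = spec.lod_mass_eu / vol_m3
    if record.concentration_eu_m3 >= lod_conc:
        return record
    sub = lod_conc / sqrt(2.0)
    return replace(record, below_lod=True,
                   concentration_eu_m3=sub, endotoxin_eu=sub * vol_m3)


def _censor_frame(df: pd.DataFrame, spec: CampaignSpec) -> pd.DataFrame:
    bad = df.index[(df["duration_min"] <= 0) | (df["flow_l_min"] <= 0)]
    if len(bad):
        raise ValueError(
            f"duration_min/flow_l_min: must be > 0 (first offending row {bad[0]})")
    out = df.copy()
    vol_m3 = out["flow_l_min"] * out["duration_min"] / 1000.0
    lod_conc = spec.lod_mass_eu / vol_m3
    mask = out["concentration_eu_m3"] < lod_conc
    sub = lod_conc[mask] / sqrt(2.0)
    out.loc[mask, "concentration_eu_m3"] = sub
    out.loc[mask, "endotoxin_eu"] = sub * vol_m3[mask]
    out.loc[mask, "below_lod"] = True
    return out


def default_campaign_spec(
    seed: int = 0,
    between_fraction: float = defaults.DEFAULT_BETWEEN_FRACTION,
) -> CampaignSpec:
    """Campaign spec reproducing the study design of the default campaign.

    Five tasks, 13 personal workers (42 personal samples) plus 20 area
    samples of the latrine task, with per-task GM/GSD, sample counts and
    duration ranges from :data:`endotwa.defaults.CAMPAIGN_TABLE`.
    """
    tasks = []
    for (stype, task), row in defaults.CAMPAIGN_TABLE.items():
        tasks.append(TaskParams(
            task=task,
            sample_type=stype,
            gm=row["gm"],
            gsd=row["gsd"],
            between_fraction=between_fraction,
            n_workers=row["n_workers"],
            n_samples=row["n_samples"],
            duration_range_min=row["duration_range"],
        ))
    return CampaignSpec(tasks=tuple(tasks), seed=seed)


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Convert a sequence of :class:`SampleRecord` to the campaign table."""
    return pd.DataFrame([r.__dict__ for r in records], columns=CAMPAIGN_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SampleRecord]:
    """Convert a campaign table to a list of :class:`SampleRecord`."""
    return [SampleRecord(**row) for row in df[CAMPAIGN_COLUMNS].to_dict("records")]
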