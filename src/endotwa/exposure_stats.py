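"""Summary statistics and lognormal fits for task-based exposure data.

All lognormal fitting is done by log-moments: the geometric mean is
``exp(mean(ln x))`` and the geometric standard deviation ``exp(sd(ln x))``
with the n-1 (sample) denominator.  Worker-level fits are aggregated to a
single task distribution by moment-matching on the log scale to the
equal-weight worker mixture, and within/between-worker variance components
are estimated with the one-way random-effects ANOVA (method-of-moments)
estimator, using the standard unbalanced divisor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import exp, log, sqrt

import numpy as np
import pandas as pd

__all__ = [
    "TaskDistribution",
    "VarianceComponents",
    "sampled_volume",
    "geometric_stats",
    "task_summary_table",
    "fit_worker_distributions",
    "aggregate_task_distribution",
    "variance_components",
    "personal_area_gm_ratio",
]


@dataclass(frozen=True)
class TaskDistribution:
    """Fitted lognormal concentration distribution for one task."""

    task: str
    mu_log: float
    sigma_log: float
    n_samples: int = 0
    n_workers: int = 0

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError(f"sigma_log: must be >= 0, got {self.sigma_log}")

    @property
    def gm(self) -> float:
        return exp(self.mu_log)

    @property
    def gsd(self) -> float:
        return exp(self.sigma_log)

    @property
    def am(self) -> float:
        """Arithmetic mean of the lognormal, exp(mu + sigma^2 / 2)."""
        return exp(self.mu_log + 0.5 * self.sigma_log ** 2)

    @classmethod
    def from_gm_gsd(cls, task: str, gm: float, gsd: float,
                    n_samples: int = 0, n_workers: int = 0) -> "TaskDistribution":
        if gm <= 0:
            raise ValueError(f"gm: must be > 0, got {gm}")
        if gsd < 1:
            raise ValueError(f"gsd: must be >= 1, got {gsd}")
        return cls(task=task, mu_log=log(gm), sigma_log=log(gsd),
                   n_samples=n_samples, n_workers=n_workers)


@dataclass(frozen=True)
class VarianceComponents:
    """One-way random-effects decomposition of log-concentration variance."""

    mu_log: float
    sigma2_between: float
    sigma2_within: float

    def __post_init__(self) -> None:
        if self.sigma2_between < 0 or self.sigma2_within < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_between + self.sigma2_within


def sampled_volume(flow_l_min, duration_min):
    """Air volume sampled, in m^3, from pump flow (L/min) and duration (min)."""
    flow = np.asarray(flow_l_min, dtype=float)
    dur = np.asarray(duration_min, dtype=float)
    if np.any(flow <= 0):
        raise ValueError(f"flow_l_min: must be > 0, got {flow_l_min}")
    if np.any(dur <= 0):
        raise ValueError(f"duration_min: must be > 0, got {duration_min}")
    vol = flow * dur / 1000.0
    return float(vol) if vol.ndim == 0 else vol


def geometric_stats(values) -> tuple[float, float]:
    """Geometric mean and geometric SD (n-1 denominator) of positive values.

    A single value has a defined GM but an undefined GSD (returned as NaN,
    not 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("values: at least one value is required")
    if np.any(x <= 0):
        raise ValueError(f"values: all values must be > 0, got min {x.min()}")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    gsd = float(np.exp(logs.std(ddof=1))) if x.size > 1 else float("nan")
    return gm, gsd


def task_summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(sample_type, task) summary of concentrations and durations.

    One row per group with sample count, GM/GSD and AM/SD of concentration,
    the concentration range, and duration AM/SD/range.  Empty input yields
    an empty table.  Below-LOD records are expected to carry their
    substituted concentrations already; ``n_below_lod`` reports how many.
    """
    cols = ["sample_type", "task", "n", "gm", "gsd", "am", "sd",
            "conc_min", "conc_max", "duration_am", "duration_sd",
            "duration_min", "duration_max", "n_below_lod"]
    if len(records) == 0:
        return pd.DataFrame(columns=cols)
    rows = []
    for (stype, task), grp in records.groupby(["sample_type", "task"], sort=True):
        conc = grp["concentration_eu_m3"].to_numpy(dtype=float)
        dur = grp["duration_min"].to_numpy(dtype=float)
        gm, gsd = geometric_stats(conc)
        n = len(grp)
        rows.append(dict(
            sample_type=stype, task=task, n=n, gm=gm, gsd=gsd,
            am=float(conc.mean()),
            sd=float(conc.std(ddof=1)) if n > 1 else float("nan"),
            conc_min=float(conc.min()), conc_max=float(conc.max()),
            duration_am=float(dur.mean()),
            duration_sd=float(dur.std(ddof=1)) if n > 1 else float("nan"),
            duration_min=float(dur.min()), duration_max=float(dur.max()),
            n_below_lod=int(grp["below_lod"].sum()) if "below_lod" in grp else 0,
        ))
    return pd.DataFrame(rows, columns=cols)


def _single_task(records: pd.DataFrame) -> str:
    tasks = records["task"].unique()
    if len(tasks) != 1:
        raise ValueError(f"task: expected records for one task, got {sorted(tasks)}")
    return str(tasks[0])


def fit_worker_distributions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-worker lognormal log-moments for one task's records.

    Workers with a single sample get their ``sigma_log`` imputed from the
    pooled within-worker SD of the task's multi-sample workers (0 with a
    warning when no worker has two samples); the ``sigma_imputed`` column
    flags them.
    """
    if len(records) == 0:
        raise ValueError("records: no records to fit")
    _single_task(records)
    fits = []
    for worker, grp in records.groupby("worker_id", sort=True):
        logs = np.log(grp["concentration_eu_m3"].to_numpy(dtype=float))
        fits.append(dict(
            worker_id=worker, n=len(logs),
            mu_log=float(logs.mean()),
            sigma_log=float(logs.std(ddof=1)) if len(logs) > 1 else float("nan"),
        ))
    df = pd.DataFrame(fits)
    multi = df[df["n"] > 1]
    if len(multi):
        # pooled within-worker SD, weighting each worker by its df (n_i - 1)
        dof = (multi["n"] - 1).to_numpy()
        pooled = sqrt(float((dof * multi["sigma_log"] ** 2).sum() / dof.sum()))
    else:
        pooled = 0.0
        warnings.warn("no worker has >= 2 samples; imputing sigma_log = 0",
                      stacklevel=2)
    df["sigma_imputed"] = df["sigma_log"].isna()
    df["sigma_log"] = df["sigma_log"].fillna(pooled)
    return df


def aggregate_task_distribution(worker_fits, task: str | None = None) -> TaskDistribution:
    """Aggregate per-worker lognormals into one task distribution.

    The task lognormal is moment-matched on the log scale to the
    equal-weight worker mixture: its log-mean is the unweighted mean of the
    worker log-means, and its log-variance is the (n-1) variance of the
    worker log-means plus the mean worker log-variance.
    """
    if isinstance(worker_fits, pd.DataFrame):
        mus = worker_fits["mu_log"].to_numpy(dtype=float)
        sigmas = worker_fits["sigma_log"].to_numpy(dtype=float)
        n_samples = int(worker_fits["n"].sum()) if "n" in worker_fits else 0
    else:
        pairs = list(worker_fits)
        if not pairs:
            raise ValueError("worker_fits: at least one worker is required")
        mus = np.array([p[0] for p in pairs], dtype=float)
        sigmas = np.array([p[1] for p in pairs], dtype=float)
        n_samples = 0
    if mus.size == 0:
        raise ValueError("worker_fits: at least one worker is required")
    mu = float(mus.mean())
    between = float(mus.var(ddof=1)) if mus.size > 1 else 0.0
    within = float(np.mean(sigmas ** 2))
    return TaskDistribution(task=task or "", mu_log=mu,
                            sigma_log=sqrt(between + within),
                            n_samples=n_samples, n_workers=int(mus.size))


def variance_components(records: pd.DataFrame) -> VarianceComponents:
    """ANOVA (method-of-moments) variance components on ln concentration.

    One-way random-effects model with worker as the grouping factor.  For
    unbalanced data the between-group mean square is scaled by the standard
    divisor ``n0 = (N - sum(n_i^2)/N) / (k - 1)``; a negative between-worker
    estimate is truncated to zero.
    """
    if len(records) == 0:
        raise ValueError("records: no records")
    _single_task(records)
    groups = [np.log(g["concentration_eu_m3"].to_numpy(dtype=float))
              for _, g in records.groupby("worker_id", sort=True)]
    k = len(groups)
    if k < 2:
        raise ValueError("between-worker variance unidentifiable: "
                         "all samples are from one worker")
    n_i = np.array([len(g) for g in groups])
    N = int(n_i.sum())
    if N == k:
        raise ValueError("within-worker variance unidentifiable: "
                         "every worker has a single sample")
    grand = float(np.concatenate(groups).mean())
    means = np.array([g.mean() for g in groups])
    ssb = float((n_i * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - float((n_i ** 2).sum()) / N) / (k - 1)
    between = max(0.0, (msb - msw) / n0)
    return VarianceComponents(mu_log=grand, sigma2_between=between,
                              sigma2_within=msw)


def personal_area_gm_ratio(records: pd.DataFrame, task: str = "latrine") -> float:
    """Ratio of personal to area geometric means for one task."""
    sel = records[records["task"] == task]
    per = sel[sel["sample_type"] == "personal"]["concentration_eu_m3"]
    area = sel[sel["sample_type"] == "area"]["concentration_eu_m3"]
    if len(per) == 0 or len(area) == 0:
        raise ValueError(f"task: need both personal and area samples for {task!r}")
    gm_p, _ = geometric_stats(per)
    gm_a, _ = geometric_stats(area)
    return gm_p / gm_a
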