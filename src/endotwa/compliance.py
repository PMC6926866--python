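"""Exceedance probabilities and acceptability against an OEL.

The exceedance of a scenario is the probability that a randomly selected
worker's full-shift exposure exceeds the occupational exposure limit on a
randomly selected day.  Two routes are provided, because the underlying
variance decomposition can be applied either to the simulated draws or to
fitted within/between-worker components:

* empirical -- the fraction of simulated TWA draws strictly above the OEL;
* parametric -- the lognormal tail probability
  ``Phi((mu_log - ln OEL) / sqrt(sigma2_between + sigma2_within))``.

An exposure profile is conventionally acceptable when the exceedance is
strictly below 0.10.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, sqrt
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import defaults
from .exposure_stats import VarianceComponents
from .twa_model import TWASummary

__all__ = [
    "ComplianceResult",
    "empirical_exceedance",
    "parametric_exceedance",
    "compliance_report",
]


@dataclass(frozen=True)
class ComplianceResult:
    """Exceedance of one scenario under one estimation method."""

    scenario_id: str
    oel: float
    exceedance: float
    method: str  # "empirical" | "parametric"
    threshold: float = defaults.DEFAULT_EXCEEDANCE_THRESHOLD

    def __post_init__(self) -> None:
        if not 0.0 <= self.exceedance <= 1.0:
            raise ValueError(f"exceedance: must be in [0, 1], got {self.exceedance}")

    @property
    def acceptable(self) -> bool:
        """True iff exceedance is strictly below the threshold."""
        return self.exceedance < self.threshold


def empirical_exceedance(draws, oel: float = defaults.DEFAULT_OEL) -> float:
    """Fraction of simulated exposures strictly greater than the OEL."""
    x = np.asarray(draws, dtype=float)
    if x.size == 0:
        raise ValueError("draws: at least one draw is required")
    if oel <= 0:
        raise ValueError(f"oel: must be > 0, got {oel}")
    return float((x > oel).mean())


def parametric_exceedance(vc: VarianceComponents,
                          oel: float = defaults.DEFAULT_OEL) -> float:
    """Lognormal tail probability above the OEL from variance components.

    With zero total variance the exposure is deterministic at
    ``exp(mu_log)`` and the exceedance degenerates to 0 or 1.
    """
    if oel <= 0:
        raise ValueError(f"oel: must be > 0, got {oel}")
    total = vc.sigma2_total
    if total == 0.0:
        return 1.0 if exp(vc.mu_log) > oel else 0.0
    return float(norm.cdf((vc.mu_log - log(oel)) / sqrt(total)))


def _draws_components(summary: TWASummary) -> VarianceComponents:
    logs = np.log(summary.draws)
    within = float(logs.var(ddof=1)) if logs.size > 1 else 0.0
    return VarianceComponents(mu_log=float(logs.mean()), sigma2_between=0.0,
                              sigma2_within=within)


def compliance_report(summaries: Iterable[TWASummary],
                      oel: float = defaults.DEFAULT_OEL,
                      threshold: float = defaults.DEFAULT_EXCEEDANCE_THRESHOLD,
                      ) -> pd.DataFrame:
    """Exceedance and acceptability per scenario, by both methods.

    The parametric route fits a lognormal to each scenario's TWA draws by
    log-moments and evaluates its analytic tail above the OEL; the empirical
    route counts draws.  Returns one row per (scenario, method).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold: must be in (0, 1), got {threshold}")
    rows = []
    for s in summaries:
        results = [
            ComplianceResult(s.scenario_id, oel,
                             empirical_exceedance(s.draws, oel),
                             "empirical", threshold),
            ComplianceResult(s.scenario_id, oel,
                             parametric_exceedance(_draws_components(s), oel),
                             "parametric", threshold),
        ]
        for r in results:
            rows.append(dict(scenario_id=r.scenario_id, oel=r.oel,
                             method=r.method, exceedance=r.exceedance,
                             threshold=r.threshold, acceptable=r.acceptable))
    return pd.DataFrame(rows, columns=["scenario_id", "oel", "method",
                                       "exceedance", "threshold", "acceptable"])
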