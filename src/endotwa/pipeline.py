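"""End-to-end pipeline: generate -> stats -> simulate -> comply, plus
publication-style table rendering.

All persisted numbers keep full precision; rounding to significant figures
happens only in the plain-text renderings.  Every output file names the
seed and a hash of the configuration, and a rerun with an identical
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from . import defaults, io
from .compliance import compliance_report
from .exposure_stats import (TaskDistribution, aggregate_task_distribution,
                             fit_worker_distributions, task_summary_table)
from .synthetic_data import CampaignSpec, censor_at_lod, default_campaign_spec, \
    generate_campaign
from .twa_model import Scenario, build_rotation_scenarios, simulate_scenario

__all__ = ["PipelineConfig", "run_pipeline", "render_table", "format_sig",
           "task_distributions_from_campaign"]


def format_sig(x, sig_figs: int = 2) -> str:
    """Format a number to ``sig_figs`` significant figures, publication style.

    ``3652.1 -> '3700'``, ``1.97 -> '2.0'``, ``0.043 -> '0.043'``;
    NaN/None render as ``'NA'``.
    """
    if x is None:
        return "NA"
    x = float(x)
    if math.isnan(x):
        return "NA"
    if x == 0:
        return "0"
    exp10 = math.floor(math.log10(abs(x)))
    q = round(x, -(exp10 - sig_figs + 1))
    exp10 = math.floor(math.log10(abs(q))) if q != 0 else 0
    decimals = max(0, sig_figs - 1 - exp10)
    return f"{q:.{decimals}f}"


def _fmt_range(lo, hi, sig_figs):
    return f"{format_sig(lo, sig_figs)}–{format_sig(hi, sig_figs)}"


def _fmt_pair(a, b, sig_figs):
    return f"{format_sig(a, sig_figs)} ({format_sig(b, sig_figs)})"


# (required columns) -> (header, cell builder); order defines column order
_COMPOSITES = [
    (("sample_type",), "Sample Type", lambda r, s: str(r["sample_type"])),
    (("scenario_id",), "Scenario", lambda r, s: str(r["scenario_id"])),
    (("task",), "Task", lambda r, s: str(r["task"])),
    (("description",), "Description", lambda r, s: str(r["description"])),
    (("n",), "n", lambda r, s: str(int(r["n"]))),
    (("n_iter",), "Iterations", lambda r, s: str(int(r["n_iter"]))),
    (("gm", "gsd"), "GM (GSD)", lambda r, s: _fmt_pair(r["gm"], r["gsd"], s)),
    (("am", "sd"), "AM (SD)", lambda r, s: _fmt_pair(r["am"], r["sd"], s)),
    (("conc_min", "conc_max"), "Range",
     lambda r, s: _fmt_range(r["conc_min"], r["conc_max"], s)),
    (("duration_am", "duration_sd"), "Duration AM (SD)",
     lambda r, s: _fmt_pair(r["duration_am"], r["duration_sd"], s)),
    (("duration_min", "duration_max"), "Duration Range",
     lambda r, s: _fmt_range(r["duration_min"], r["duration_max"], s)),
    (("p95",), "95th Percentile", lambda r, s: format_sig(r["p95"], s)),
    (("exceedance_empirical",), "Exceedance (empirical)",
     lambda r, s: format_sig(r["exceedance_empirical"], s)),
    (("exceedance_parametric",), "Exceedance (parametric)",
     lambda r, s: format_sig(r["exceedance_parametric"], s)),
    (("acceptable",), "Acceptable", lambda r, s: str(bool(r["acceptable"]))),
]


def render_table(rows: pd.DataFrame, sig_figs: int = 2) -> str:
    """Render a summary table as aligned plain text with composite cells.

    Pairs such as (gm, gsd) become a single "GM (GSD)" column and
    (min, max) pairs become "lo-hi" ranges, rounded to ``sig_figs``
    significant figures.  Empty input yields a header-only table.
    """
    cols = [(header, build) for needed, header, build in _COMPOSITES
            if all(c in rows.columns for c in needed)]
    if not cols:  # nothing recognised: render raw columns
        cols = [(c, (lambda c: lambda r, s: str(r[c]))(c)) for c in rows.columns]
    headers = [h for h, _ in cols]
    body = [[build(row, sig_figs) for _, build in cols]
            for _, row in rows.iterrows()]
    widths = [max(len(h), *(len(line[i]) for line in body)) if body else len(h)
              for i, h in enumerate(headers)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(headers, widths)).rstrip()]
    lines.append("  ".join("-" * w for w in widths))
    for line in body:
        lines.append("  ".join(c.ljust(w) for c, w in zip(line, widths)).rstrip())
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run.

    ``campaign`` is either a :class:`CampaignSpec` (synthetic campaign),
    the literal ``"default"`` (the built-in campaign at the configured
    seed), or a path to a sample CSV.  ``scenarios`` is ``"default"`` for
    the built-in eight rotation scenarios or a path to a YAML scenario
    file.
    """

    campaign: CampaignSpec | str | Path = "default"
    scenarios: str | Path = "default"
    n_iter: int = 10_000
    oel: float = defaults.DEFAULT_OEL
    threshold: float = defaults.DEFAULT_EXCEEDANCE_THRESHOLD
    seed: int = 0
    output_dir: str | Path = "outputs"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError(f"n_iter: must be >= 1, got {self.n_iter}")
        if self.oel <= 0:
            raise ValueError(f"oel: must be > 0, got {self.oel}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold: must be in (0, 1), got {self.threshold}")

    def resolved_campaign(self) -> CampaignSpec | Path:
        if isinstance(self.campaign, CampaignSpec):
            return self.campaign
        if str(self.campaign) == "default":
            return default_campaign_spec(seed=self.seed)
        return Path(self.campaign)

    def to_dict(self) -> dict:
        camp = self.resolved_campaign()
        if isinstance(camp, CampaignSpec):
            camp_repr = dict(
                seed=camp.seed, lod_per_ml=camp.lod_per_ml,
                extract_volume_ml=camp.extract_volume_ml,
                tasks=[t.__dict__ | {
                    "duration_range_min": list(t.duration_range_min),
                    "flow_range_l_min": list(t.flow_range_l_min)}
                    for t in camp.tasks])
        else:
            camp_repr = str(camp)
        return dict(campaign=camp_repr, scenarios=str(self.scenarios),
                    n_iter=self.n_iter, oel=self.oel, threshold=self.threshold,
                    seed=self.seed)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        campaign = doc.get("campaign", "default")
        if isinstance(campaign, dict):
            from .synthetic_data import TaskParams
            tasks = []
            for td in campaign.get("tasks", []):
                td = dict(td)
                for key in ("duration_range_min", "flow_range_l_min"):
                    if key in td:
                        td[key] = tuple(td[key])
                tasks.append(TaskParams(**td))
            campaign = CampaignSpec(
                tasks=tuple(tasks),
                seed=int(campaign.get("seed", doc.get("seed", 0))),
                lod_per_ml=float(campaign.get("lod_per_ml", 0.15)),
                extract_volume_ml=float(campaign.get("extract_volume_ml", 5.0)))
        return cls(campaign=campaign,
                   scenarios=doc.get("scenarios", "default"),
                   n_iter=int(doc.get("n_iter", 10_000)),
                   oel=float(doc.get("oel", defaults.DEFAULT_OEL)),
                   threshold=float(doc.get("threshold",
                                           defaults.DEFAULT_EXCEEDANCE_THRESHOLD)),
                   seed=int(doc.get("seed", 0)),
                   output_dir=doc.get("output_dir", "outputs"))


def task_distributions_from_campaign(campaign: pd.DataFrame,
                                     sample_type: str = "personal",
                                     ) -> dict[str, TaskDistribution]:
    """Fit per-worker lognormals per task and aggregate them.

    Only records of the requested ``sample_type`` contribute (area samples
    do not describe a worker's breathing zone).
    """
    sel = campaign[campaign["sample_type"] == sample_type]
    dists: dict[str, TaskDistribution] = {}
    for task, grp in sel.groupby("task", sort=True):
        fits = fit_worker_distributions(grp)
        dists[task] = aggregate_task_distribution(fits, task=task)
    return dists


def _stamp(path: Path, seed: int, cfg_hash: str) -> str:
    return f"# seed={seed} config={cfg_hash}\n"


def _write_csv(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(stamp)
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run generate -> stats -> simulate -> comply and write all artifacts.

    Returns a mapping of artifact name to path: ``campaign``, ``table1``
    (+ ``table1_txt``), ``table2`` (+ ``table2_json``, ``table2_txt``),
    ``compliance`` and ``log``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    stamp = _stamp(outdir, config.seed, cfg_hash)
    log: list[str] = [f"endotwa pipeline  seed={config.seed}  config={cfg_hash}"]
    paths: dict[str, Path] = {}

    # 1. campaign
    source = config.resolved_campaign()
    if isinstance(source, CampaignSpec):
        campaign = censor_at_lod(generate_campaign(source), source)
        log.append(f"generate: synthetic campaign, {len(campaign)} samples, "
                   f"{campaign['below_lod'].sum()} below LOD, "
                   f"substreams keyed on (seed, sample_type:task)")
    else:
        campaign = io.read_campaign_csv(source)
        log.append(f"load: {source} ({len(campaign)} samples)")
    paths["campaign"] = outdir / "campaign.csv"
    _write_csv(campaign, paths["campaign"], stamp)

    # 2. summary statistics
    table1 = task_summary_table(campaign)
    paths["table1"] = outdir / "table1.csv"
    _write_csv(table1, paths["table1"], stamp)
    paths["table1_txt"] = outdir / "table1.txt"
    paths["table1_txt"].write_text(stamp + render_table(table1), encoding="utf-8")
    log.append(f"stats: {len(table1)} task summary rows")

    # 3. task distributions and scenario simulation
    dists = task_distributions_from_campaign(campaign)
    if str(config.scenarios) == "default":
        scenarios = build_rotation_scenarios()
    else:
        scenarios = io.scenarios_from_yaml(config.scenarios)
    summaries = []
    for sc in scenarios:
        s = simulate_scenario(dists, sc, n_iter=config.n_iter, seed=config.seed)
        summaries.append((sc, s))
        log.append(f"simulate: {sc.scenario_id} n_iter={config.n_iter} "
                   f"substream=(seed, crc32({sc.scenario_id}))")
    if config.n_iter == 1:
        log.append("warning: n_iter=1, SD and GSD are undefined (NaN)")

    # 4. compliance
    comp = compliance_report([s for _, s in summaries],
                             oel=config.oel, threshold=config.threshold)
    wide = comp.pivot(index="scenario_id", columns="method",
                      values="exceedance").rename(
        columns=lambda m: f"exceedance_{m}")
    table2 = pd.DataFrame([dict(
        scenario_id=sc.scenario_id, description=sc.description,
        n_iter=s.n_iter, gm=s.gm, gsd=s.gsd, am=s.am, sd=s.sd, p95=s.p95,
    ) for sc, s in summaries]).merge(wide, on="scenario_id")
    table2["acceptable"] = table2["exceedance_empirical"] < config.threshold

    paths["table2"] = outdir / "table2.csv"
    _write_csv(table2, paths["table2"], stamp)
    paths["table2_json"] = outdir / "table2.json"
    doc = dict(seed=config.seed, config=cfg_hash, oel=config.oel,
               threshold=config.threshold,
               scenarios=table2.to_dict("records"))
    paths["table2_json"].write_text(json.dumps(doc, indent=2, sort_keys=True),
                                    encoding="utf-8")
    paths["table2_txt"] = outdir / "table2.txt"
    paths["table2_txt"].write_text(stamp + render_table(table2), encoding="utf-8")

    paths["compliance"] = outdir / "compliance.csv"
    _write_csv(comp, paths["compliance"], stamp)
    log.append(f"comply: OEL {config.oel} EU/m^3, threshold {config.threshold}, "
               f"{int(comp['acceptable'].sum())}/{len(comp)} "
               "(scenario, method) results acceptable")

    paths["log"] = outdir / "run.log"
    paths["log"].write_text("\n".join(log) + "\n", encoding="utf-8")
    return paths
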