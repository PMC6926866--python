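"""Default study conditions for the fecal-sludge resource-recovery campaign.

The defaults mirror a task-based sampling campaign at a municipal
fecal-sludge-to-fuel plant: five tasks along the collection and resource
recovery chain (pit-latrine emptying, waste release at the plant inlet,
mechanical dewatering, solar dehydration in greenhouses, thermal drying),
13 workers contributing 42 personal breathing-zone samples plus 20 area
samples collected during latrine emptying.  Per-task geometric means,
geometric standard deviations, sample counts and task-duration statistics
are the published campaign summaries; the between-worker variance fraction
is a modelling parameter (the campaign reports only total GSDs).
"""

from __future__ import annotations

#: Reference shift length in minutes (8 h) for time-weighted averages.
SHIFT_MIN = 480.0

#: Health-based occupational exposure limit for inhaled endotoxin,
#: EU/m^3 as an 8-h TWA (DECOS, Health Council of the Netherlands).
DEFAULT_OEL = 90.0

#: Conventional acceptability bound on the exceedance probability.
DEFAULT_EXCEEDANCE_THRESHOLD = 0.10

#: Analytical limit of detection, EU per mL of filter extract.
DEFAULT_LOD_PER_ML = 0.15

#: Filter extraction volume, mL (sonication buffer volume).
DEFAULT_EXTRACT_VOLUME_ML = 5.0

#: Personal sampling-pump flow range, L/min.
DEFAULT_FLOW_RANGE = (1.0, 3.5)

#: Default fraction of total log-variance attributed to between-worker
#: differences, typical of occupational-hygiene variance decompositions.
DEFAULT_BETWEEN_FRACTION = 0.3

#: Canonical task names along the process chain.
TASK_NAMES = (
    "latrine",
    "inlet",
    "mechanical_dewatering",
    "solar_dehydration",
    "thermal_drying",
)

#: Per-(sample_type, task) campaign summaries: concentration GM/GSD (EU/m^3),
#: sample count, worker count (allocation chosen so personal workers sum to
#: 13; the published campaign does not give the per-task split), and task
#: duration statistics in minutes (arithmetic mean, SD, observed range).
CAMPAIGN_TABLE = {
    ("area", "latrine"): dict(
        gm=12.0, gsd=4.0, n_samples=20, n_workers=4,
        duration_mean=190.0, duration_sd=67.0, duration_range=(109.0, 394.0),
    ),
    ("personal", "latrine"): dict(
        gm=75.0, gsd=2.4, n_samples=11, n_workers=3,
        duration_mean=130.0, duration_sd=57.0, duration_range=(73.0, 251.0),
    ),
    ("personal", "inlet"): dict(
        gm=11.0, gsd=4.8, n_samples=2, n_workers=1,
        duration_mean=75.0, duration_sd=37.0, duration_range=(48.0, 101.0),
    ),
    ("personal", "mechanical_dewatering"): dict(
        gm=11.0, gsd=3.5, n_samples=10, n_workers=3,
        duration_mean=96.0, duration_sd=44.0, duration_range=(31.0, 167.0),
    ),
    ("personal", "solar_dehydration"): dict(
        gm=140.0, gsd=4.8, n_samples=10, n_workers=3,
        duration_mean=53.0, duration_sd=19.0, duration_range=(28.0, 95.0),
    ),
    ("personal", "thermal_drying"): dict(
        gm=3700.0, gsd=2.0, n_samples=9, n_workers=3,
        duration_mean=80.0, duration_sd=24.0, duration_range=(48.0, 105.0),
    ),
}

#: Observed task-duration statistics (minutes) used to build rotation
#: scenarios; personal rows only, keyed by task name.
DEFAULT_DURATION_STATS = {
    task: dict(
        mean=row["duration_mean"],
        min=row["duration_range"][0],
        max=row["duration_range"][1],
    )
    for (stype, task), row in CAMPAIGN_TABLE.items()
    if stype == "personal"
}
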