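"""Subject-level exposure reconstruction from residential histories.

Each subject carries a case/control status, a reference year (diagnosis
year for cases, an assigned index year for controls) and a residential
history of (node, move-in year, move-out year) spans.  Combining the spans
with the per-node annual dose field gives an annual relative-delivered-dose
(RDD) series; latency-windowed summaries of that series (cumulative, peak,
years exposed) are the exposure metrics the case-control analysis uses.

Accounting conventions: whole calendar years; the move-in and move-out
years both count; exposure is strictly before the reference year; under a
latency assumption of ``L`` years only calendar years ``<= reference - L``
count.  Index years for controls are drawn from the empirical distribution
of the cases' diagnosis years so both groups share the same calendar frame.

Exposure categories are defined from the cumulative-RDD distribution among
exposed controls: at or below the median is "low", and three nested "high"
definitions are above the median, above the 75th and above the 90th
percentile.  The referent group everywhere is women never exposed during
the entire study period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MappingError, ParameterError
from .leach import DoseHistory

logger = logging.getLogger(__name__)

LATENCIES = (0, 5, 7, 9, 11, 13, 15, 17, 19)

SUBJECT_COLUMNS = [
    "subject_id", "status", "reference_year", "age", "vital_status",
    "family_history", "personal_history", "age_first_birth",
    "occupational_pce", "study_origin", "bottled_water",
]
RESIDENCE_COLUMNS = ["subject_id", "node_id", "move_in_year", "move_out_year"]


@dataclass(frozen=True)
class ExposureMetrics:
    """Latency-windowed summaries of a subject's annual RDD series."""

    latency: int
    cumulative_rdd: float
    peak_rdd: float
    duration: int
    ever_exposed: bool


@dataclass(frozen=True)
class PercentileCuts:
    """Median/75th/90th cumulative-RDD percentiles among exposed controls."""

    median: float
    p75: float
    p90: float
    n: int
    stable: bool  # flagged False when based on < 10 exposed controls

    def __post_init__(self):
        if not (self.median <= self.p75 <= self.p90):
            raise ParameterError("percentile cuts must be ordered")


@dataclass(frozen=True)
class ExposureCategory:
    """Membership flags; the three high categories are nested."""

    unexposed: bool
    low: bool          # exposed, cumulative <= median
    above_median: bool
    above_p75: bool
    above_p90: bool


def assign_index_years(n_controls: int, case_diagnosis_years,
                       seed: int | np.random.Generator) -> np.ndarray:
    """Draw an index year per control from the cases' diagnosis years."""
    years = np.asarray(list(case_diagnosis_years), dtype=int)
    if years.size == 0:
        raise ParameterError("need at least one case diagnosis year")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return rng.choice(years, size=int(n_controls), replace=True)


def annual_rdd_series(residences, history: DoseHistory, reference_year: int,
                      missing_node: str = "error") -> pd.Series:
    """Annual dose series for one subject, summed across residences.

    ``residences`` is an iterable of (node_id, move_in_year, move_out_year).
    Years at and after ``reference_year`` never contribute.  A residence at
    a node absent from the dose history raises :class:`MappingError`, or
    contributes zero with a warning when ``missing_node="zero"``.
    """
    series: dict[int, float] = {}
    for node_id, y0, y1 in residences:
        if node_id not in history._row:
            if missing_node == "zero":
                logger.warning("residence node %r outside network; "
                               "contributes zero", node_id)
                continue
            raise MappingError(f"residence node {node_id!r} not in network")
        hi = min(int(y1), reference_year - 1)
        for y in range(int(y0), hi + 1):
            series[y] = series.get(y, 0.0) + history.dose(node_id, y)
    return pd.Series(series, dtype=float).sort_index()


def exposure_metrics(series: pd.Series, latency: int,
                     reference_year: int) -> ExposureMetrics:
    """Windowed cumulative/peak/duration for one latency assumption."""
    if latency < 0:
        raise ParameterError("latency must be non-negative")
    if len(series):
        w = series[series.index <= reference_year - latency]
    else:
        w = series
    positive = w[w > 0]
    return ExposureMetrics(
        latency=int(latency),
        cumulative_rdd=float(w.sum()),
        peak_rdd=float(w.max()) if len(w) else 0.0,
        duration=int((w > 0).sum()),
        ever_exposed=bool(len(positive)),
    )


def control_percentiles(exposed_control_rdds) -> PercentileCuts:
    """Quantile cuts (linear interpolation) of exposed-control RDDs."""
    v = np.asarray(list(exposed_control_rdds), dtype=float)
    if v.size == 0:
        raise ParameterError("no exposed controls to take percentiles of")
    med, p75, p90 = np.percentile(v, [50, 75, 90])
    stable = v.size >= 10
    if not stable:
        logger.warning("percentile cuts based on only %d exposed controls; "
                       "flagged unstable", v.size)
    return PercentileCuts(float(med), float(p75), float(p90),
                          n=int(v.size), stable=stable)


def categorize(cumulative_rdd: float, cuts: PercentileCuts,
               ever_exposed: bool = True) -> ExposureCategory:
    """Nested category membership; a value exactly at the median is low."""
    if not ever_exposed or cumulative_rdd <= 0:
        return ExposureCategory(True, False, False, False, False)
    c = float(cumulative_rdd)
    return ExposureCategory(
        unexposed=False,
        low=c <= cuts.median,
        above_median=c > cuts.median,
        above_p75=c > cuts.p75,
        above_p90=c > cuts.p90,
    )


# ---------------------------------------------------------------------------
# Cohort-level vectorized computation and CSV interchange


def compute_cohort_metrics(subjects: pd.DataFrame, residences: pd.DataFrame,
                           history: DoseHistory,
                           latencies=LATENCIES,
                           missing_node: str = "error") -> pd.DataFrame:
    """Exposure metrics for every subject at every latency.

    Returns a long frame with columns subject_id, latency, cumulative,
    peak, duration, ever.  Equivalent to calling :func:`annual_rdd_series`
    + :func:`exposure_metrics` per subject, but vectorized over the cohort.
    """
    years = history.years
    y_lo, y_hi = int(years[0]), int(years[-1])
    n_years = y_hi - y_lo + 1
    sub_ids = list(subjects["subject_id"])
    srow = {sid: i for i, sid in enumerate(sub_ids)}
    ref = subjects.set_index("subject_id")["reference_year"].astype(int)

    dose = np.zeros((len(sub_ids), n_years))
    mat = history.matrix.to_numpy()
    for row in residences.itertuples(index=False):
        sid = row.subject_id
        if sid not in srow:
            continue
        node = row.node_id
        if node not in history._row:
            if missing_node == "zero":
                logger.warning("residence node %r outside network; "
                               "contributes zero", node)
                continue
            raise MappingError(f"residence node {node!r} not in network")
        a = max(int(row.move_in_year), y_lo)
        b = min(int(row.move_out_year), int(ref[sid]) - 1, y_hi)
        if b < a:
            continue
        dose[srow[sid], a - y_lo:b - y_lo + 1] += \
            mat[history._row[node], a - y_lo:b - y_lo + 1]

    ref_arr = ref.loc[sub_ids].to_numpy()
    year_axis = np.arange(y_lo, y_hi + 1)
    out = []
    for L in latencies:
        if L < 0:
            raise ParameterError("latency must be non-negative")
        mask = year_axis[None, :] <= (ref_arr - L)[:, None]
        w = np.where(mask, dose, 0.0)
        cum = w.sum(axis=1)
        peak = w.max(axis=1, initial=0.0)
        dur = (w > 0).sum(axis=1)
        out.append(pd.DataFrame({
            "subject_id": sub_ids, "latency": int(L), "cumulative": cum,
            "peak": peak, "duration": dur, "ever": dur > 0,
        }))
    return pd.concat(out, ignore_index=True)


def read_cohort(subjects_csv, residences_csv):
    """Read the subject and residence tables from CSV paths or buffers."""
    subjects = pd.read_csv(subjects_csv)
    residences = pd.read_csv(residences_csv)
    missing = [c for c in ("subject_id", "status", "reference_year")
               if c not in subjects.columns]
    if missing:
        raise ParameterError(f"subject table missing columns {missing}")
    if list(residences.columns[:4]) != RESIDENCE_COLUMNS[:4] and \
            not set(RESIDENCE_COLUMNS).issubset(residences.columns):
        raise ParameterError("residence table needs columns "
                             f"{RESIDENCE_COLUMNS}")
    return subjects, residences


def write_metrics(metrics: pd.DataFrame, path) -> None:
    cols = ["subject_id", "latency", "cumulative", "peak", "duration", "ever"]
    metrics[cols].to_csv(path, index=False)
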