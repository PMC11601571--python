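"""Quantitative trait variables (QTVs) derived from daily EAE score series.

From each preprocessed mouse we derive: cumulative disease scores (combined,
classic-only, AR-only), EAE incidence with onset day, a mutually exclusive
disease subtype (classic vs AR), and a disease-course class
(monophasic / relapsing-remitting / chronic).  Per-strain summaries
aggregate these to the incidence percentages and mean scores used for
mapping.

Definitions
-----------
* A mouse is *incident* if its combined daily disease score is > 0 for at
  least 2 consecutive days; the onset day is the first day of the first
  such run.
* The combined daily score is the classic score when only classic disease
  is present, the AR score when only AR disease is present, and the mean
  of the two on days when both are scored.
* Monophasic: one initial bout then scores of 0 for the remainder of the
  window.  Relapsing-remitting (RR): initial bout, remission of >= 3
  consecutive zero days, then a relapse of >= 2 consecutive days > 0.
  Chronic is the catch-all for every other incident trajectory
  (persistent disease, including 1-2 day zero dips too short to count as
  remission).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .scores import ENDPOINT, CohortTable, ScoreSeries, _runs

logger = logging.getLogger(__name__)

MONOPHASIC, RR, CHRONIC, NONE = "monophasic", "RR", "chronic", "none"
CLASSIC, AR = "classic", "AR"

MIN_BOUT_DAYS = 2  # >= 2 consecutive days of score > 0 establish disease
MIN_REMISSION_DAYS = 3  # >= 3 consecutive zero days count as remission
MIN_RELAPSE_DAYS = 2  # >= 2 consecutive days > 0 after remission


@dataclass
class QTVRow:
    """Per-mouse derived trait variables."""

    mouse_id: str
    strain: str
    sex: str
    cohort: str
    cds: float  # cumulative combined disease score
    classic_cds: int
    ar_cds: int
    eae_incident: bool
    subtype: str  # classic / AR / none
    course: str  # monophasic / RR / chronic / none
    onset_day: Optional[int]
    endpoint: bool
    subtype_tie: bool = False


def combine_daily(classic, ar):
    """Combined daily disease score.

    Returns 0 when both scales are 0, the nonzero scale's value when only
    one is scored, and the arithmetic mean on days with simultaneous
    classic and AR scoring.  Accepts scalars or arrays.
    """
    c = np.asarray(classic, dtype=float)
    a = np.asarray(ar, dtype=float)
    out = np.where((c > 0) & (a > 0), (c + a) / 2.0, c + a)
    if out.ndim == 0:
        return float(out)
    return out


def cumulative_scores(series: ScoreSeries):
    """(cds, classic_cds, ar_cds): sums of daily scores over the window.

    cds sums the *combined* daily score, so on simultaneous days it adds
    the mean of the two scales rather than their sum; cds is therefore not
    in general classic_cds + ar_cds.
    """
    cds = float(combine_daily(series.classic, series.ar).sum())
    return cds, int(series.classic.sum()), int(series.ar.sum())


def eae_incidence(series: ScoreSeries):
    """(incident, onset_day): >= 2 consecutive days with combined score > 0."""
    disease = combine_daily(series.classic, series.ar) > 0
    for start, stop in _runs(disease):
        if stop - start >= MIN_BOUT_DAYS:
            return True, int(series.days[start])
    return False, None


def subtype_assignment(series: ScoreSeries):
    """(subtype, tie_flag): mutually exclusive classic / AR assignment.

    Single-presentation mice take their only subtype.  Combined-type mice
    (both scales scored, same day or different days) are assigned by
    comparing exclusive day counts - days scored classic-only versus
    AR-only, with simultaneous days excluded from both counts.  An exact
    tie is assigned classic and flagged.
    """
    incident, _ = eae_incidence(series)
    if not incident:
        return NONE, False
    has_classic = bool((series.classic > 0).any())
    has_ar = bool((series.ar > 0).any())
    if has_classic and not has_ar:
        return CLASSIC, False
    if has_ar and not has_classic:
        return AR, False
    classic_only = int(((series.classic > 0) & (series.ar == 0)).sum())
    ar_only = int(((series.ar > 0) & (series.classic == 0)).sum())
    if classic_only > ar_only:
        return CLASSIC, False
    if ar_only > classic_only:
        return AR, False
    logger.info("mouse %s: combined-type day counts tied; assigning classic", series.mouse.mouse_id)
    return CLASSIC, True


def course_classification(series: ScoreSeries):
    """Disease course: monophasic, RR, or chronic (none if not incident).

    Runs on the combined disease-score series.  The initial bout is the
    maximal run of positive days containing onset.  Monophasic requires
    every day after that bout to be 0.  RR requires, after the bout, a
    remission of >= 3 consecutive zero days followed later by a relapse of
    >= 2 consecutive positive days.  Everything else is chronic.
    """
    incident, _ = eae_incidence(series)
    if not incident:
        return NONE
    disease = combine_daily(series.classic, series.ar) > 0
    runs = list(_runs(disease))
    # initial bout = first run of >= MIN_BOUT_DAYS positive days
    bout_end = None
    for start, stop in runs:
        if stop - start >= MIN_BOUT_DAYS:
            bout_end = stop
            break
    assert bout_end is not None  # guaranteed by incidence
    if bout_end >= disease.size:
        return CHRONIC  # disease persists to experiment termination
    if not disease[bout_end:].any():
        return MONOPHASIC
    # first qualifying remission strictly after the initial bout
    zeros = ~disease
    remission_end = None
    for start, stop in _runs(zeros):
        if start >= bout_end and stop - start >= MIN_REMISSION_DAYS:
            remission_end = stop
            break
    if remission_end is not None:
        for start, stop in _runs(disease):
            if start >= remission_end and stop - start >= MIN_RELAPSE_DAYS:
                return RR
    return CHRONIC


def derive_qtv(table: CohortTable) -> pd.DataFrame:
    """Per-mouse QTV table from a preprocessed (endpoint-ruled) cohort."""
    rows = []
    for s in table.series:
        cds, ccds, acds = cumulative_scores(s)
        incident, onset = eae_incidence(s)
        subtype, tie = subtype_assignment(s)
        course = course_classification(s)
        rows.append(
            QTVRow(
                mouse_id=s.mouse.mouse_id,
                strain=s.mouse.strain,
                sex=s.mouse.sex,
                cohort=s.mouse.cohort,
                cds=cds,
                classic_cds=ccds,
                ar_cds=acds,
                eae_incident=incident,
                subtype=subtype,
                course=course,
                onset_day=onset,
                endpoint=bool((s.status == ENDPOINT).any()),
                subtype_tie=tie,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        df = pd.DataFrame(columns=[f.name for f in QTVRow.__dataclass_fields__.values()])
    return df


def summarize_strain(qtv: pd.DataFrame, by=("strain",)) -> pd.DataFrame:
    """Per-strain (or per strain x sex, etc.) summary statistics.

    Percentages and means are computed over the post-exclusion mice in the
    QTV table; excluded mice never enter denominators.  Subtype incidences
    are mutually exclusive and sum to the total incidence.
    """
    if qtv.empty:
        raise ValueError("empty QTV table")
    by = list(by)

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        pct = lambda mask: 100.0 * mask.sum() / n  # noqa: E731
        return pd.Series(
            {
                "n_mice": n,
                "incidence_pct": pct(g["eae_incident"]),
                "classic_incidence_pct": pct(g["subtype"] == CLASSIC),
                "ar_incidence_pct": pct(g["subtype"] == AR),
                "chronic_pct": pct(g["course"] == CHRONIC),
                "rr_pct": pct(g["course"] == RR),
                "mono_pct": pct(g["course"] == MONOPHASIC),
                "mean_cds": g["cds"].mean(),
                "mean_classic_cds": g["classic_cds"].mean(),
                "mean_ar_cds": g["ar_cds"].mean(),
                "endpoint_pct": pct(g["endpoint"]),
            }
        )

    out = qtv.groupby(by, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_mice"] = out["n_mice"].astype(int)
    return out


def strain_phenotype(summary: pd.DataFrame, trait: str) -> pd.Series:
    """Extract one per-strain phenotype column, indexed by strain."""
    if trait not in summary.columns:
        raise KeyError(f"unknown trait column {trait!r}")
    return summary.set_index("strain")[trait]
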