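"""Daily EAE clinical-score tables: reading, validation, and endpoint rules.

Mice are scored daily on two 0-5 scales: the classic ascending-paralysis
scale and the atypical axial-rotary (AR) scale.  This module reads a
long-format score table, validates it, fills gaps in the daily record, and
applies the humane-endpoint and mortality rules that must run before any
trait is derived:

* a mouse holding a maximal score of 5 (either scale) for 72 hours is
  euthanized and scored 5 on that scale for the remainder of the window;
* a mouse that dies after more than 2 consecutive days of clinical disease
  is likewise carried forward at 5 on its presenting scale;
* a mouse that dies with no clinical signs, or with at most 2 days of
  disease, is excluded from all downstream analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default observation window, days post-induction (closed interval).
DEFAULT_WINDOW = (5, 50)

SCORE_MIN, SCORE_MAX = 0, 5

ALIVE, ENDPOINT, DEAD = "alive", "endpoint", "dead"
_STATUSES = frozenset({ALIVE, ENDPOINT, DEAD})

#: Exclusion reason for mice dying without established disease.
DEATH_WITHOUT_EAE = "death-without-established-EAE"

REQUIRED_COLUMNS = ("mouse_id", "strain", "sex", "cohort", "day", "classic", "ar")


class ValidationError(ValueError):
    """A score table violated a structural or range constraint."""


class ScoreParseError(ValueError):
    """A score table could not be parsed at all."""


@dataclass(frozen=True)
class MouseMeta:
    """Identity and design metadata for one mouse."""

    mouse_id: str
    strain: str
    sex: str  # "M" or "F"
    cohort: str  # experimental batch label, e.g. "C1"

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"mouse {self.mouse_id}: sex must be M or F, got {self.sex!r}")
        if not self.cohort:
            raise ValidationError(f"mouse {self.mouse_id}: cohort must be non-empty")


@dataclass
class ScoreSeries:
    """One mouse's daily classic and AR scores over the observation window."""

    mouse: MouseMeta
    days: np.ndarray  # strictly increasing integer day indices
    classic: np.ndarray  # int 0-5 per day
    ar: np.ndarray  # int 0-5 per day
    status: np.ndarray  # per-day flag: alive / endpoint / dead
    imputed_days: list = field(default_factory=list)  # days filled by carry-forward
    subtype_tie: bool = False  # set by qtv.subtype_assignment on a tie-break

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.classic = np.asarray(self.classic, dtype=int)
        self.ar = np.asarray(self.ar, dtype=int)
        self.status = np.asarray(self.status, dtype=object)
        n = len(self.days)
        if not (len(self.classic) == len(self.ar) == len(self.status) == n):
            raise ValidationError(f"mouse {self.mouse.mouse_id}: ragged series")
        if n and np.any(np.diff(self.days) <= 0):
            raise ValidationError(f"mouse {self.mouse.mouse_id}: days not strictly increasing")
        for arr, name in ((self.classic, "classic"), (self.ar, "ar")):
            if n and (arr.min() < SCORE_MIN or arr.max() > SCORE_MAX):
                raise ValidationError(
                    f"mouse {self.mouse.mouse_id}: {name} score outside {SCORE_MIN}-{SCORE_MAX}"
                )
        bad = set(self.status) - _STATUSES
        if bad:
            raise ValidationError(f"mouse {self.mouse.mouse_id}: unknown status {sorted(bad)}")

    def copy(self) -> "ScoreSeries":
        return ScoreSeries(
            mouse=self.mouse,
            days=self.days.copy(),
            classic=self.classic.copy(),
            ar=self.ar.copy(),
            status=self.status.copy(),
            imputed_days=list(self.imputed_days),
            subtype_tie=self.subtype_tie,
        )


@dataclass
class CohortTable:
    """A collection of validated score series plus the excluded-mouse log."""

    series: list  # of ScoreSeries
    excluded: list = field(default_factory=list)  # of (mouse_id, reason)

    def __post_init__(self):
        ids = [s.mouse.mouse_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate mouse_id in series: {dupes}")
        overlap = set(ids) & {m for m, _ in self.excluded}
        if overlap:
            raise ValidationError(f"mouse_id in both series and excluded: {sorted(overlap)}")

    def __len__(self):
        return len(self.series)

    def get(self, mouse_id: str) -> ScoreSeries:
        for s in self.series:
            if s.mouse.mouse_id == mouse_id:
                return s
        raise KeyError(mouse_id)

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame mirroring the on-disk layout."""
        chunks = []
        for s in self.series:
            chunks.append(
                pd.DataFrame(
                    {
                        "mouse_id": s.mouse.mouse_id,
                        "strain": s.mouse.strain,
                        "sex": s.mouse.sex,
                        "cohort": s.mouse.cohort,
                        "day": s.days,
                        "classic": s.classic,
                        "ar": s.ar,
                        "status": s.status,
                    }
                )
            )
        if not chunks:
            return pd.DataFrame(columns=list(REQUIRED_COLUMNS) + ["status"])
        return pd.concat(chunks, ignore_index=True)


def _detect_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_scores(path, window=DEFAULT_WINDOW) -> CohortTable:
    """Read and validate a long-format daily score table.

    Expected columns: mouse_id, strain, sex, cohort, day, classic, ar and an
    optional status column (defaults to alive).  Comma or tab delimited,
    auto-detected, header required.

    Missing leading days are treated as score 0; missing interior or
    trailing days are filled by carrying the previous day's record forward,
    and every filled day is logged on the series as imputed.
    """
    try:
        df = pd.read_csv(path, sep=_detect_sep(path), dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - surface as our parse error
        raise ScoreParseError(f"{path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScoreParseError(f"{path}: missing required columns {missing}")
    if "status" not in df.columns:
        df["status"] = ALIVE
    df.loc[df["status"] == "", "status"] = ALIVE

    for col in ("day", "classic", "ar"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ScoreParseError(
                f"{path}: non-integer value in column {col!r} at data line {bad + 2}"
            ) from exc

    for col in ("classic", "ar"):
        bad = df[(df[col] < SCORE_MIN) | (df[col] > SCORE_MAX)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"{path}: {col} score {row[col]} outside {SCORE_MIN}-{SCORE_MAX} "
                f"for mouse {row['mouse_id']} day {row['day']}"
            )
    dupes = df.duplicated(subset=["mouse_id", "day"], keep=False)
    if dupes.any():
        row = df[dupes].iloc[0]
        raise ValidationError(
            f"{path}: duplicate (mouse, day) record: mouse {row['mouse_id']} day {row['day']}"
        )

    lo, hi = window
    all_days = np.arange(lo, hi + 1)
    out = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("day")
        meta_rows = grp[["strain", "sex", "cohort"]].drop_duplicates()
        if len(meta_rows) > 1:
            raise ValidationError(f"{path}: inconsistent metadata for mouse {mouse_id}")
        meta = MouseMeta(str(mouse_id), *meta_rows.iloc[0])
        grp = grp[(grp["day"] >= lo) & (grp["day"] <= hi)]
        recorded = dict(
            zip(grp["day"], zip(grp["classic"], grp["ar"], grp["status"]))
        )
        classic, ar, status, imputed = [], [], [], []
        prev = (0, 0, ALIVE)
        seen_any = False
        for d in all_days:
            if d in recorded:
                prev = recorded[d]
                seen_any = True
            else:
                if seen_any:
                    imputed.append(int(d))
                    logger.warning("mouse %s: day %d missing, carried forward", mouse_id, d)
                # leading gap: healthy baseline (0, 0, alive)
            classic.append(prev[0])
            ar.append(prev[1])
            status.append(prev[2])
        out.append(
            ScoreSeries(
                mouse=meta,
                days=all_days.copy(),
                classic=np.array(classic),
                ar=np.array(ar),
                status=np.array(status, dtype=object),
                imputed_days=imputed,
            )
        )
    return CohortTable(series=out)


def _runs(mask: np.ndarray):
    """Yield (start_idx, stop_idx) half-open runs of True in *mask*."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    yield from zip(starts, stops)


def _max_run_length(mask: np.ndarray) -> int:
    return max((stop - start for start, stop in _runs(mask)), default=0)


def apply_endpoint_rules(table: CohortTable, consecutive_max_days: int = 3) -> CohortTable:
    """Apply humane-endpoint carry-forward and mortality exclusion rules.

    Three rules, in order of precedence:

    a. A score of 5 (classic or AR) held for ``consecutive_max_days``
       recorded days (72 h at daily scoring) triggers the humane endpoint:
       that scale is scored 5 for every later day and status becomes
       ``endpoint``.  If both scales trigger, both are carried forward.
    b. A mouse that dies after more than 2 consecutive days of clinical
       signs is scored 5 on its presenting scale (the scale with the higher
       score on the last day observed alive; tie goes to classic) from the
       day of death onward.
    c. A mouse that dies with no clinical signs or with at most 2 days of
       disease is moved to ``excluded``.

    Idempotent: a second application is a no-op.
    """
    kept, excluded = [], list(table.excluded)
    for orig in table.series:
        s = orig.copy()
        n = len(s.days)
        dead_idx = np.flatnonzero(s.status == DEAD)
        first_dead = int(dead_idx[0]) if dead_idx.size else None

        if first_dead is not None:
            # Signs are judged on the days observed alive (pre-death record).
            alive_mask = np.arange(n) < first_dead
            signs = ((s.classic > 0) | (s.ar > 0)) & alive_mask
            if _max_run_length(signs) <= 2:
                excluded.append((s.mouse.mouse_id, DEATH_WITHOUT_EAE))
                continue

        # Rule (a): 72-hour maximal score -> endpoint, carried forward.
        triggered = False
        for channel in ("classic", "ar"):
            arr = getattr(s, channel)
            for start, stop in _runs(arr == SCORE_MAX):
                if stop - start >= consecutive_max_days:
                    fill_from = start + consecutive_max_days
                    if fill_from < n:
                        arr[fill_from:] = SCORE_MAX
                    triggered = max(triggered, True)
                    trigger_idx = start + consecutive_max_days
                    s._endpoint_from = min(
                        getattr(s, "_endpoint_from", n), trigger_idx
                    )
                    break
        if triggered:
            fill_from = s._endpoint_from
            if fill_from < n:
                keep_dead = s.status[fill_from:] == DEAD
                s.status[fill_from:] = np.where(keep_dead, DEAD, ENDPOINT)

        # Rule (b): death with established disease -> presenting scale at 5.
        if first_dead is not None:
            last_alive = first_dead - 1
            if last_alive >= 0:
                if s.classic[last_alive] >= s.ar[last_alive]:
                    channel = s.classic  # tie goes to classic
                else:
                    channel = s.ar
                channel[first_dead:] = SCORE_MAX
            s.status[first_dead:] = DEAD

        kept.append(s)
    result = CohortTable(series=kept, excluded=excluded)
    return result


def write_scores(table: CohortTable, path, sep: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=sep, index=False)
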