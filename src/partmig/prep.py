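"""Turn dated detection records into seasonal encounter histories.

This module owns the data objects the likelihood consumes (the binary
individuals x occasions :class:`EncounterHistory` and the per-individual
covariate table) and the three preparation steps that precede model fitting:

1. classify each bird's migratory strategy from its dated records
   (:func:`classify_strategy`),
2. apply the cohort exclusion filters (:func:`apply_exclusion_filters`),
3. collapse records to the seasonal 0/1 matrix (:func:`build_encounter_matrix`).

Record tables are pandas DataFrames with columns ``id``, ``date`` (ISO date
or datetime), ``event`` in {"detection", "nocturnal_departure"}.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seasons import SeasonCalendar

__all__ = [
    "EncounterHistory",
    "StrategyClassification",
    "classify_strategy",
    "classify_all",
    "apply_exclusion_filters",
    "build_encounter_matrix",
    "validate_covariates",
    "read_encounter_csv",
    "write_encounter_csv",
]

STRATEGIES = ("resident", "migrant", "winter_departer", "switcher", "undetermined")
SEXES = ("female", "male")
AGES = ("juvenile", "adult")

#: residency requires continuous presence at least through this (month, day)
RESIDENCY_CUTOFF = (11, 30)
#: autumn migration window (month, day) bounds within a calendar year
AUTUMN_WINDOW = ((9, 1), (11, 30))
#: spring boundary (month, day): departures after the residency cutoff and
#: before this date the following year count as winter departures
SPRING_START = (3, 2)


@dataclass
class EncounterHistory:
    """Binary detection matrix (individuals x occasions) plus its calendar."""

    ids: np.ndarray  # shape (n,), individual identifiers
    matrix: np.ndarray  # shape (n, T), int 0/1
    calendar: SeasonCalendar

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[0] != len(self.ids):
            raise ValueError("ids and matrix rows disagree")
        if self.matrix.shape[1] != self.calendar.n_occasions:
            raise ValueError("matrix columns and calendar occasions disagree")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        if len(self.ids) and (self.matrix.sum(axis=1) < 1).any():
            bad = self.ids[self.matrix.sum(axis=1) < 1]
            raise ValueError(f"individuals with no detections: {list(bad[:5])}")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]

    @property
    def first_occasion(self) -> np.ndarray:
        """Index of first detection (the occasion the history is conditioned on)."""
        return self.matrix.argmax(axis=1)

    def subset(self, ids) -> "EncounterHistory":
        keep = np.isin(self.ids, np.asarray(list(ids)))
        return EncounterHistory(self.ids[keep], self.matrix[keep], self.calendar)


@dataclass
class StrategyClassification:
    """Outcome of migratory-strategy classification for one individual."""

    strategy: str
    year_labels: dict[int, str] = field(default_factory=dict)
    departure_date: dt.date | None = None
    arrival_date: dt.date | None = None
    last_presence: dt.date | None = None
    reason: str = ""


def _as_date(x) -> dt.date:
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    return pd.Timestamp(x).date()


def _classify_year(
    year: int,
    detections: list[dt.date],
    departures: list[dt.date],
    min_absence_days: int,
    residency_cutoff: tuple[int, int],
) -> tuple[str, dt.date | None]:
    """Classify one bird-year.  Returns (label, departure date if any)."""
    cutoff = dt.date(year, *residency_cutoff)
    a_lo = dt.date(year, *AUTUMN_WINDOW[0])
    spring_next = dt.date(year + 1, *SPRING_START)

    def absent_after(d: dt.date) -> bool:
        horizon = d + dt.timedelta(days=min_absence_days)
        return not any(d < x <= horizon for x in detections)

    # winter departure: nocturnal departure after the residency cutoff but
    # before the next spring
    for d in departures:
        if cutoff < d < spring_next and absent_after(d):
            return "winter_departer", d
    # autumn migration: nocturnal departure inside the autumn window followed
    # by a sustained absence
    for d in departures:
        if a_lo <= d <= cutoff and absent_after(d):
            return "migrant", d
    # residency: continuous presence (no gap > min_absence_days) from the
    # start of autumn through the cutoff
    autumn_dets = sorted(x for x in detections if a_lo <= x)
    if autumn_dets and autumn_dets[-1] >= cutoff:
        span = [a_lo] + [x for x in autumn_dets if x <= cutoff] + [cutoff]
        gaps = [(b - a).days for a, b in zip(span, span[1:])]
        if max(gaps) <= min_absence_days:
            return "resident", None
    return "undetermined", None


def classify_strategy(
    records: pd.DataFrame,
    calendar: SeasonCalendar | None = None,
    *,
    min_absence_days: int = 14,
    residency_cutoff: tuple[int, int] = RESIDENCY_CUTOFF,
) -> StrategyClassification:
    """Classify the migratory strategy of a single individual.

    Year-level rules (applied to each autumn the bird has records for):
    migrant if a nocturnal departure falls in September-November followed by
    a >= ``min_absence_days`` absence; resident if continuously present (no
    gap longer than ``min_absence_days``) through 30 November; winter
    departer if the nocturnal departure comes after 30 November but before
    spring; undetermined otherwise.  Year labels are then combined: a
    migrant/resident conflict across years marks a switcher; any winter
    departure dominates the remaining labels.
    """
    if records is None or len(records) == 0:
        return StrategyClassification("undetermined", reason="no_records")
    recs = records.copy()
    recs["date"] = [_as_date(x) for x in recs["date"]]
    recs = recs.sort_values("date")
    detections = [r.date for r in recs.itertuples() if r.event == "detection"]
    departures = [r.date for r in recs.itertuples() if r.event == "nocturnal_departure"]
    if not detections and not departures:
        return StrategyClassification("undetermined", reason="no_records")

    all_dates = detections + departures
    y0, y1 = min(d.year for d in all_dates), max(d.year for d in all_dates)
    year_labels: dict[int, str] = {}
    dep_dates: dict[int, dt.date] = {}
    for year in range(y0, y1 + 1):
        # only attempt years with any autumn-or-earlier record activity
        if not any(d.year == year for d in all_dates):
            continue
        label, dep = _classify_year(
            year, detections, departures, min_absence_days, residency_cutoff
        )
        year_labels[year] = label
        if dep is not None:
            dep_dates[year] = dep

    determined = {y: l for y, l in year_labels.items() if l != "undetermined"}
    labels = set(determined.values())
    last_presence = max(detections) if detections else None
    departure = min(dep_dates.values()) if dep_dates else None
    arrival = None
    if departure is not None:
        later = [d for d in detections if d > departure]
        if later:
            arrival = min(later)

    if {"migrant", "resident"} <= labels:
        strat, reason = "switcher", "conflicting_year_labels"
    elif "winter_departer" in labels:
        strat, reason = "winter_departer", "departure_after_cutoff"
    elif labels == {"migrant"}:
        strat, reason = "migrant", "autumn_nocturnal_departure"
    elif labels == {"resident"}:
        strat, reason = "resident", "continuous_presence"
    else:
        strat, reason = "undetermined", "records_end_before_cutoff"
    return StrategyClassification(
        strategy=strat,
        year_labels=year_labels,
        departure_date=departure,
        arrival_date=arrival,
        last_presence=last_presence,
        reason=reason,
    )


def classify_all(
    records: pd.DataFrame,
    calendar: SeasonCalendar | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Classify every individual in a multi-individual record table."""
    rows = []
    for ind, grp in records.groupby("id", sort=True):
        c = classify_strategy(grp, calendar, **kwargs)
        rows.append(
            {
                "id": ind,
                "strategy": c.strategy,
                "reason": c.reason,
                "departure_date": c.departure_date,
                "arrival_date": c.arrival_date,
                "last_presence": c.last_presence,
            }
        )
    return pd.DataFrame(rows)


#: exclusion reasons checked in order; a bird counts under the first that applies
EXCLUSION_REASONS = ("undetermined", "winter_departer", "switcher", "unsexed_juvenile")


def apply_exclusion_filters(
    individuals: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort exclusion rules.

    Excludes birds whose strategy is undetermined, winter departers,
    strategy switchers, and juveniles whose sex could not be determined.
    Returns the included subset and a tally of exclusions by reason.  The
    tallies partition the input: ``len(included) + sum(tally.values()) ==
    len(individuals)``.
    """
    tally = {r: 0 for r in EXCLUSION_REASONS}
    if len(individuals) == 0:
        return individuals.copy(), tally
    keep = np.ones(len(individuals), dtype=bool)
    strat = individuals["strategy"].to_numpy()
    sex = individuals["sex"] if "sex" in individuals else pd.Series(["female"] * len(individuals))
    age = individuals["age"] if "age" in individuals else pd.Series(["adult"] * len(individuals))
    sex_missing = sex.isna().to_numpy() | (sex.astype(str).str.lower().isin(["unknown", "na", ""])).to_numpy()
    juvenile = (age.astype(str).str.lower() == "juvenile").to_numpy()
    for i in range(len(individuals)):
        if strat[i] == "undetermined":
            tally["undetermined"] += 1
            keep[i] = False
        elif strat[i] == "winter_departer":
            tally["winter_departer"] += 1
            keep[i] = False
        elif strat[i] == "switcher":
            tally["switcher"] += 1
            keep[i] = False
        elif sex_missing[i] and juvenile[i]:
            tally["unsexed_juvenile"] += 1
            keep[i] = False
    return individuals.loc[keep].reset_index(drop=True), tally


def build_encounter_matrix(
    records: pd.DataFrame,
    calendar: SeasonCalendar,
    ids=None,
) -> tuple[EncounterHistory, int]:
    """Collapse dated detection records to the seasonal 0/1 matrix.

    A cell is 1 iff the individual has at least one ``detection`` record
    inside the occasion's half-open [start, next start) window.  Records
    outside the calendar's span are dropped with a warning; the count of
    dropped records is returned alongside the matrix.  Individuals in
    ``ids`` with no in-calendar detection are dropped with a warning
    (an encounter history row must contain at least one 1).
    """
    det = records[records["event"] == "detection"]
    if ids is None:
        ids = sorted(det["id"].unique())
    ids = list(ids)
    index = {ind: i for i, ind in enumerate(ids)}
    T = calendar.n_occasions
    mat = np.zeros((len(ids), T), dtype=np.int8)
    dropped = 0
    for r in det.itertuples():
        if r.id not in index:
            continue
        occ = calendar.index_of_date(_as_date(r.date))
        if occ is None:
            dropped += 1
            continue
        mat[index[r.id], occ] = 1
    if dropped:
        warnings.warn(f"{dropped} detection record(s) outside the calendar were dropped")
    empty = mat.sum(axis=1) < 1
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} individual(s) had no in-calendar detections and were dropped"
        )
        mat = mat[~empty]
        ids = [ind for ind, e in zip(ids, empty) if not e]
    return EncounterHistory(np.asarray(ids), mat, calendar), dropped


def validate_covariates(cov: pd.DataFrame, *, included_only: bool = False) -> None:
    """Check the covariate table's categorical domains."""
    required = {"id", "sex", "age", "strategy"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    allowed = set(("resident", "migrant") if included_only else STRATEGIES)
    bad = set(cov["strategy"].dropna()) - allowed
    if bad:
        raise ValueError(f"unknown strategy values: {sorted(bad)}")
    if not set(cov["age"].dropna()) <= set(AGES):
        raise ValueError("age must be 'juvenile' or 'adult'")


def write_encounter_csv(eh: EncounterHistory, cov: pd.DataFrame, path) -> None:
    """Write histories + covariates as `id,sex,age,strategy,first_occasion,o1..oT`."""
    cov = cov.set_index("id")
    T = eh.n_occasions
    out = pd.DataFrame({"id": eh.ids})
    for c in ("sex", "age", "strategy"):
        out[c] = cov.reindex(eh.ids)[c].to_numpy()
    out["first_occasion"] = eh.first_occasion + 1  # 1-based in the file
    for t in range(T):
        out[f"o{t + 1}"] = eh.matrix[:, t]
    out.to_csv(path, index=False)


def read_encounter_csv(path, calendar: SeasonCalendar) -> tuple[EncounterHistory, pd.DataFrame]:
    df = pd.read_csv(path)
    occ_cols = [c for c in df.columns if c.startswith("o") and c[1:].isdigit()]
    occ_cols.sort(key=lambda c: int(c[1:]))
    if len(occ_cols) != calendar.n_occasions:
        raise ValueError(
            f"file has {len(occ_cols)} occasion columns, calendar has {calendar.n_occasions}"
        )
    eh = EncounterHistory(df["id"].to_numpy(), df[occ_cols].to_numpy(), calendar)
    cov = df[["id", "sex", "age", "strategy"]].copy()
    return eh, cov
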