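"""Synthetic partially-migratory cohort generator.

Generates the data-generating twin of the fitted model: a cohort of
residents and migrants entering at (summer) capture occasions, surviving
each seasonal interval with a season-type- and strategy-dependent Bernoulli
rate, and being detected at each post-entry occasion with a
strategy-dependent probability (detection at the entry occasion is
guaranteed -- the likelihood conditions on first capture).  Defaults follow
the field study the package models: 192 residents and 70 migrants over
eight years (15 alternating summer/winter occasions), summer survival 0.89,
winter survival 0.57 (residents) / 0.73 (migrants), per-occasion detection
0.74 (residents) / 0.19 (migrants), migrant departures centred on 16
October inside 19 September - 12 November and arrivals centred on 14 March
inside 17 February - 25 March.

:func:`simulate_detection_records` additionally emits the dated raw records
(daily automated-station presence for residents, presence-until-departure
plus a nocturnal-departure event for migrants, occasional aerial winter
fixes of migrants) that the classification stage consumes; the records are
consistent with the encounter matrix the same seed produces, so
records -> matrix round-trips exactly.  Optional "planted" individuals
(winter departers, strategy switchers, tag-failure birds, unsexed
juveniles) exercise the exclusion filters.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .prep import EncounterHistory
from .seasons import SeasonCalendar, build_season_calendar

__all__ = ["Phenology", "SimulationConfig", "simulate_population", "simulate_detection_records"]


@dataclass(frozen=True)
class Phenology:
    """Departure/arrival timing and season boundaries ((month, day), days)."""

    departure_mean: tuple[int, int] = (10, 16)
    departure_sd: float = 12.0
    departure_window: tuple[tuple[int, int], tuple[int, int]] = ((9, 19), (11, 12))
    arrival_mean: tuple[int, int] = (3, 14)
    arrival_sd: float = 8.0
    arrival_window: tuple[tuple[int, int], tuple[int, int]] = ((2, 17), (3, 25))
    summer_start: tuple[int, int] = (3, 2)
    summer_start_sd: float = 14.5
    winter_start: tuple[int, int] = (11, 3)
    winter_start_sd: float = 7.4


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of the simulation; defaults mirror the field study."""

    n_residents: int = 192
    n_migrants: int = 70
    years: int = 8
    start_year: int = 2009
    phi_summer: float = 0.89
    phi_winter_resident: float = 0.57
    phi_winter_migrant: float = 0.73
    #: migrant summer survival; None derives it additively on the logit
    #: scale (logit phi_summer + the winter strategy contrast), making the
    #: generator the exact data-generating twin of the additive
    #: season + strategy survival model
    phi_summer_migrant: float | None = None
    p_resident: float = 0.74
    p_migrant: float = 0.19
    # sex/age composition of the included cohort in the study
    female_fraction_resident: float = 69 / 192
    female_fraction_migrant: float = 45 / 70
    juvenile_fraction_resident: float = 44 / 192
    juvenile_fraction_migrant: float = 25 / 70
    entry_weights: tuple | None = None  # per-occasion first-capture weights
    phenology: Phenology = field(default_factory=Phenology)
    # planted individuals for the exclusion filters (all default 0)
    n_winter_departers: int = 0
    n_switchers: int = 0
    n_undetermined: int = 0
    n_unsexed_juveniles: int = 0
    resident_sampling_days: int = 1
    migrant_sampling_days: int = 3
    seed: int = 0

    @property
    def n_occasions(self) -> int:
        return 2 * self.years - 1

    @property
    def effective_phi_summer_migrant(self) -> float:
        """Migrant summer survival; derived logit-additively unless set.

        Falls back to ``phi_summer`` when any rate sits on the {0, 1}
        boundary (the logit contrast is undefined there).
        """
        if self.phi_summer_migrant is not None:
            return self.phi_summer_migrant
        from scipy.special import expit, logit

        rates = (self.phi_summer, self.phi_winter_resident, self.phi_winter_migrant)
        if any(r in (0.0, 1.0) for r in rates):
            return self.phi_summer
        contrast = logit(self.phi_winter_migrant) - logit(self.phi_winter_resident)
        return float(expit(logit(self.phi_summer) + contrast))

    def validate(self) -> None:
        for name in (
            "phi_summer",
            "phi_winter_resident",
            "phi_winter_migrant",
            "p_resident",
            "p_migrant",
            "female_fraction_resident",
            "female_fraction_migrant",
            "juvenile_fraction_resident",
            "juvenile_fraction_migrant",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.phi_summer_migrant is not None and not 0.0 <= self.phi_summer_migrant <= 1.0:
            raise ValueError("phi_summer_migrant outside [0, 1]")
        for name in (
            "n_residents",
            "n_migrants",
            "n_winter_departers",
            "n_switchers",
            "n_undetermined",
            "n_unsexed_juveniles",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_occasions < 2:
            raise ValueError("need at least 2 occasions (years >= 2)")
        if self.entry_weights is not None:
            w = np.asarray(self.entry_weights, dtype=float)
            if w.shape != (self.n_occasions,):
                raise ValueError("entry_weights must have one weight per occasion")
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("entry_weights must be non-negative and sum to 1")
        if self.n_switchers and self.years < 3:
            raise ValueError("switcher injection needs at least 3 years")
        if self.n_winter_departers and self.years < 2:
            raise ValueError("winter-departer injection needs at least 2 years")

    def calendar(self) -> SeasonCalendar:
        ph = self.phenology
        return build_season_calendar(
            range(self.start_year, self.start_year + self.years),
            summer_start=ph.summer_start,
            winter_start=ph.winter_start,
        )

    def default_entry_weights(self) -> np.ndarray:
        """Uniform over summer occasions, excluding the final one."""
        T = self.n_occasions
        w = np.zeros(T)
        summers = [t for t in range(T) if t % 2 == 0]
        if len(summers) > 1:
            summers = summers[:-1]
        w[summers] = 1.0 / len(summers)
        return w


def _trunc_date(rng, year: int, mean_md, sd, window) -> dt.date:
    """Truncated-normal date draw around (month, day) of ``year``."""
    mean = dt.date(year, *mean_md).toordinal()
    lo = dt.date(year, *window[0]).toordinal()
    hi = dt.date(year, *window[1]).toordinal()
    a, b = (lo - mean) / sd, (hi - mean) / sd
    x = truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return dt.date.fromordinal(int(round(np.clip(x, lo, hi))))


def _date_range(start: dt.date, end_inclusive: dt.date, step_days: int) -> list[dt.date]:
    if end_inclusive < start:
        return []
    n = (end_inclusive - start).days
    return [start + dt.timedelta(days=d) for d in range(0, n + 1, max(1, step_days))]


def _simulate(config: SimulationConfig, with_records: bool):
    config.validate()
    cal = config.calendar()
    T = cal.n_occasions
    season = cal.season_types
    # independent streams: population draws must not depend on whether the
    # dated records are materialised
    rng_pop = np.random.default_rng([config.seed % (2**31), 11])
    rng_rec = np.random.default_rng([config.seed % (2**31), 23])
    rng_spec = np.random.default_rng([config.seed % (2**31), 37])

    n_norm = config.n_residents + config.n_migrants
    strategies = np.array(
        ["resident"] * config.n_residents + ["migrant"] * config.n_migrants
    )
    ids = np.array(
        [f"r{i + 1:05d}" for i in range(config.n_residents)]
        + [f"m{i + 1:05d}" for i in range(config.n_migrants)]
    )
    fem_frac = np.where(
        strategies == "migrant",
        config.female_fraction_migrant,
        config.female_fraction_resident,
    )
    juv_frac = np.where(
        strategies == "migrant",
        config.juvenile_fraction_migrant,
        config.juvenile_fraction_resident,
    )
    sex = np.where(rng_pop.random(n_norm) < fem_frac, "female", "male")
    age = np.where(rng_pop.random(n_norm) < juv_frac, "juvenile", "adult")
    weights = (
        np.asarray(config.entry_weights, dtype=float)
        if config.entry_weights is not None
        else config.default_entry_weights()
    )
    entry = rng_pop.choice(T, size=n_norm, p=weights) if n_norm else np.empty(0, int)

    phi_winter = np.where(
        strategies == "migrant", config.phi_winter_migrant, config.phi_winter_resident
    )
    phi_summer = np.where(
        strategies == "migrant", config.effective_phi_summer_migrant, config.phi_summer
    )
    p_det = np.where(strategies == "migrant", config.p_migrant, config.p_resident)

    alive = np.zeros((n_norm, T), dtype=bool)
    y = np.zeros((n_norm, T), dtype=np.int8)
    if n_norm:
        alive[np.arange(n_norm), entry] = True
        y[np.arange(n_norm), entry] = 1
    for t in range(T - 1):
        phi_t = np.where(season[t] == "summer", phi_summer, phi_winter)
        active = alive[:, t] & (entry <= t)
        survive = rng_pop.random(n_norm) < phi_t
        alive[:, t + 1] = (active & survive) | (entry == t + 1)
    for t in range(T):
        post = (entry < t) & alive[:, t]
        det = rng_pop.random(n_norm) < p_det
        y[post & det, t] = 1

    # mark some juveniles as unsexed (for the exclusion-filter stage)
    n_unsexed = min(config.n_unsexed_juveniles, n_norm)
    if n_unsexed:
        pick = rng_pop.choice(n_norm, size=n_unsexed, replace=False)
        age[pick] = "juvenile"
        sex = sex.astype(object)
        sex[pick] = "unknown"

    planted = np.array([""] * n_norm, dtype=object)
    if n_unsexed:
        planted[pick] = "unsexed_juvenile"

    # ---- planted special individuals (records scripted, matrix derived) ----
    ph = config.phenology
    special_rows: list[tuple[str, str, str, str, list, list, str]] = []
    # (id, strategy_truth, sex, age, detection dates, departure dates, reason)
    summers = [t for t in range(T) if t % 2 == 0]
    entry_summers = summers[:-1] if len(summers) > 1 else summers

    def scripted(kind: str, i: int):
        sid = f"{kind}{i + 1:03d}"
        if kind == "wd":  # winter departer
            t0 = entry_summers[int(rng_spec.integers(len(entry_summers)))]
            year = cal[t0].start.year
            dep = dt.date(year, 12, 20)
            dets = _date_range(cal[t0].start, dep - dt.timedelta(days=1), 1)
            return sid, "winter_departer", dets, [dep]
        if kind == "sw":  # migrant year 1, resident year 2
            cands = [t for t in entry_summers if cal[t].start.year <= config.start_year + config.years - 3]
            t0 = cands[int(rng_spec.integers(len(cands)))]
            year = cal[t0].start.year
            dep = _trunc_date(rng_spec, year, ph.departure_mean, ph.departure_sd, ph.departure_window)
            arr = _trunc_date(rng_spec, year + 1, ph.arrival_mean, ph.arrival_sd, ph.arrival_window)
            dets = _date_range(cal[t0].start, min(dep, cal[t0].end - dt.timedelta(days=1)), 1)
            dets += _date_range(max(arr, cal[t0].start), dt.date(year + 1, 12, 31), 1)
            dets = [d for d in dets if cal.index_of_date(d) is not None]
            return sid, "switcher", dets, [dep]
        if kind == "ud":  # tag failure before the residency cutoff
            t0 = entry_summers[int(rng_spec.integers(len(entry_summers)))]
            year = cal[t0].start.year
            dets = _date_range(cal[t0].start, dt.date(year, 10, 1), 1)
            return sid, "undetermined", dets, []
        raise ValueError(kind)

    for kind, count in (
        ("wd", config.n_winter_departers),
        ("sw", config.n_switchers),
        ("ud", config.n_undetermined),
    ):
        for i in range(count):
            sid, strat, dets, deps = scripted(kind, i)
            s_sex = "female" if rng_spec.random() < 0.5 else "male"
            s_age = "juvenile" if rng_spec.random() < 0.25 else "adult"
            special_rows.append((sid, strat, s_sex, s_age, dets, deps, strat))

    n_spec = len(special_rows)
    if n_spec:
        y_spec = np.zeros((n_spec, T), dtype=np.int8)
        alive_spec = np.zeros((n_spec, T), dtype=bool)
        for i, (_, _, _, _, dets, _, _) in enumerate(special_rows):
            for d in dets:
                occ = cal.index_of_date(d)
                if occ is not None:
                    y_spec[i, occ] = 1
                    alive_spec[i, occ] = True
        ids = np.concatenate([ids, [r[0] for r in special_rows]])
        strategies = np.concatenate([strategies, [r[1] for r in special_rows]])
        sex = np.concatenate([np.asarray(sex, dtype=object), [r[2] for r in special_rows]])
        age = np.concatenate([age, [r[3] for r in special_rows]])
        y = np.vstack([y, y_spec]) if n_norm else y_spec
        alive = np.vstack([alive, alive_spec]) if n_norm else alive_spec
        entry = np.concatenate([entry, y_spec.argmax(axis=1)])
        planted = np.concatenate([planted, [r[6] for r in special_rows]])

    eh = EncounterHistory(ids, y, cal)
    cov = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "age": age,
            "strategy": strategies,
            "first_occasion": entry,
        }
    )
    truth = pd.DataFrame({"id": ids, "strategy": strategies, "planted_reason": planted})
    for t in range(T):
        truth[f"alive_{t + 1}"] = alive[:, t]

    records = None
    if with_records:
        records = _emit_records(
            config, cal, ids, strategies, entry, y, rng_rec, special_rows
        )
    return eh, cov, truth, records


def _emit_records(config, cal, ids, strategies, entry, y, rng, special_rows):
    T = cal.n_occasions
    ph = config.phenology
    rows: list[tuple[str, dt.date, str]] = []
    n_norm = len(ids) - len(special_rows)
    for i in range(n_norm):
        strat = strategies[i]
        if strat == "resident":
            for t in range(T):
                if not y[i, t]:
                    continue
                rows += [
                    (ids[i], d, "detection")
                    for d in _date_range(
                        cal[t].start,
                        cal[t].end - dt.timedelta(days=1),
                        config.resident_sampling_days,
                    )
                ]
        else:  # migrant
            for t in range(T):
                if t % 2 == 0:  # summer occasion
                    year = cal[t].start.year
                    dep = _trunc_date(rng, year, ph.departure_mean, ph.departure_sd, ph.departure_window)
                    if not y[i, t]:
                        # ARUs still record the nocturnal departure of a bird
                        # present but undetected by the CMR protocol; only
                        # emit it when the bird has already entered the study
                        if t >= entry[i] and _alive_proxy(y, i, t):
                            rows.append((ids[i], dep, "nocturnal_departure"))
                        continue
                    start = cal[t].start
                    if t > entry[i]:
                        arr = _trunc_date(rng, year, ph.arrival_mean, ph.arrival_sd, ph.arrival_window)
                        start = max(start, arr)
                    stop = min(dep, cal[t].end - dt.timedelta(days=1))
                    dets = _date_range(start, stop, config.migrant_sampling_days)
                    if not dets:
                        dets = [start]
                    rows += [(ids[i], d, "detection") for d in dets]
                    rows.append((ids[i], dep, "nocturnal_departure"))
                else:  # winter occasion: aerial fix at the wintering grounds
                    if y[i, t]:
                        wy = cal[t].start.year
                        off = int(rng.integers(0, 62))
                        rows.append(
                            (ids[i], dt.date(wy, 12, 1) + dt.timedelta(days=off), "detection")
                        )
    for sid, _, _, _, dets, deps, _ in special_rows:
        rows += [(sid, d, "detection") for d in dets]
        rows += [(sid, d, "nocturnal_departure") for d in deps]
    df = pd.DataFrame(rows, columns=["id", "date", "event"])
    return df.sort_values(["id", "date", "event"], kind="mergesort").reset_index(drop=True)


def _alive_proxy(y: np.ndarray, i: int, t: int) -> bool:
    """Detected at or after t -> certainly alive at t (used for ARU events).

    Departure events for undetected-but-alive birds are only emitted when a
    later detection proves the bird was alive, so the record stream never
    contradicts the truth log.
    """
    return bool(y[i, t:].any())


def simulate_population(config: SimulationConfig):
    """Simulate the cohort: (EncounterHistory, covariates, truth log).

    The truth log carries each individual's true per-occasion alive state
    (columns ``alive_1..alive_T``) and any planted exclusion reason, for
    oracle tests.  Deterministic given ``config.seed``.
    """
    eh, cov, truth, _ = _simulate(config, with_records=False)
    return eh, cov, truth


def simulate_detection_records(config: SimulationConfig) -> pd.DataFrame:
    """Emit dated raw records consistent with :func:`simulate_population`.

    Columns ``id, date, event`` with event in {detection,
    nocturnal_departure}.  Rebuilding the encounter matrix from these
    records through :func:`partmig.prep.build_encounter_matrix` reproduces
    the matrix the same seed generates.
    """
    _, _, _, records = _simulate(config, with_records=True)
    return records
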