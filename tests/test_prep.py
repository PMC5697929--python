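"""Season calendar, strategy classification, exclusion filters, matrix build."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from partmig.prep import (
    EncounterHistory,
    apply_exclusion_filters,
    build_encounter_matrix,
    classify_all,
    classify_strategy,
    read_encounter_csv,
    write_encounter_csv,
)
from partmig.seasons import build_season_calendar
from partmig.simulate import SimulationConfig, simulate_detection_records, simulate_population

from .conftest import make_cov, make_eh


class TestSeasonCalendar:
    def test_study_calendar_15_occasions(self, cal15):
        assert cal15.n_occasions == 15
        types = cal15.season_types
        assert types.count("summer") == 8 and types.count("winter") == 7
        assert types[0] == "summer" and types[-1] == "summer"
        assert all(a != b for a, b in zip(types, types[1:]))
        assert cal15[0].start == dt.date(2009, 3, 2)
        assert cal15[1].start == dt.date(2009, 11, 3)

    def test_single_year_degenerate(self):
        cal = build_season_calendar([2009])
        assert cal.n_occasions == 1 and cal[0].season == "summer"
        cal2 = build_season_calendar(
            [2009], final_spring_start=dt.date(2010, 3, 2)
        )
        assert cal2.n_occasions == 2 and cal2[1].season == "winter"

    def test_first_capture_override(self):
        cal = build_season_calendar(
            range(2009, 2017), first_summer_start=dt.date(2009, 4, 23)
        )
        assert cal[0].start == dt.date(2009, 4, 23)
        assert cal.n_occasions == 15

    def test_unordered_boundaries_error(self):
        with pytest.raises(ValueError, match="not after"):
            build_season_calendar(
                [2009],
                per_year={2009: {"summer_start": dt.date(2009, 12, 1),
                                 "winter_start": dt.date(2009, 11, 3)}},
            )

    def test_boundary_date_maps_to_starting_occasion(self, cal15):
        # half-open windows: a date equal to an occasion's start belongs to it
        assert cal15.index_of_date(dt.date(2009, 11, 3)) == 1
        assert cal15.index_of_date(dt.date(2009, 11, 2)) == 0
        assert cal15.index_of_date(dt.date(2008, 7, 1)) is None


def records_from(rows):
    return pd.DataFrame(rows, columns=["id", "date", "event"])


def daily(ind, start, end):
    n = (end - start).days + 1
    return [(ind, start + dt.timedelta(days=d), "detection") for d in range(n)]


class TestClassifyStrategy:
    def test_migrant(self, cal15):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 10, 15))
        rows.append(("b1", dt.date(2009, 10, 16), "nocturnal_departure"))
        rows += daily("b1", dt.date(2010, 3, 14), dt.date(2010, 6, 1))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "migrant"
        assert c.departure_date == dt.date(2009, 10, 16)
        assert c.arrival_date == dt.date(2010, 3, 14)

    def test_resident(self, cal15):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 12, 5))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "resident"

    def test_winter_departer(self, cal15):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 12, 19))
        rows.append(("b1", dt.date(2009, 12, 20), "nocturnal_departure"))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "winter_departer"

    def test_switcher(self, cal15):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 10, 15))
        rows.append(("b1", dt.date(2009, 10, 16), "nocturnal_departure"))
        rows += daily("b1", dt.date(2010, 3, 14), dt.date(2010, 12, 5))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "switcher"
        assert c.year_labels[2009] == "migrant"
        assert c.year_labels[2010] == "resident"

    def test_records_ending_early_undetermined(self, cal15):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 9, 30))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "undetermined"
        assert c.reason == "records_end_before_cutoff"

    def test_empty_records_undetermined_with_reason(self, cal15):
        c = classify_strategy(records_from([]), cal15)
        assert c.strategy == "undetermined"
        assert c.reason == "no_records"

    def test_order_insensitive_and_idempotent(self, cal15, rng):
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 10, 15))
        rows.append(("b1", dt.date(2009, 10, 16), "nocturnal_departure"))
        rows += daily("b1", dt.date(2010, 3, 14), dt.date(2010, 6, 1))
        df = records_from(rows)
        base = classify_strategy(df, cal15)
        for _ in range(3):
            shuffled = df.sample(frac=1.0, random_state=int(rng.integers(1e6)))
            c = classify_strategy(shuffled, cal15)
            assert (c.strategy, c.departure_date) == (base.strategy, base.departure_date)

    def test_detection_gap_not_mistaken_for_migration(self, cal15):
        # nocturnal event followed by detections within 14 days: not migration
        rows = daily("b1", dt.date(2009, 6, 1), dt.date(2009, 10, 16))
        rows.append(("b1", dt.date(2009, 10, 16), "nocturnal_departure"))
        rows += daily("b1", dt.date(2009, 10, 20), dt.date(2009, 12, 5))
        c = classify_strategy(records_from(rows), cal15)
        assert c.strategy == "resident"


def study_cohort():
    """The published cohort tallies: 469 birds, 262 included."""
    rows = []

    def add(n, strategy, sex, age):
        for _ in range(n):
            rows.append({"strategy": strategy, "sex": sex, "age": age})

    # included: 192 residents (69 F: 52 ad + 17 juv; 123 M: 96 ad + 27 juv)
    add(52, "resident", "female", "adult")
    add(17, "resident", "female", "juvenile")
    add(96, "resident", "male", "adult")
    add(27, "resident", "male", "juvenile")
    # included: 70 migrants (45 F: 28 ad + 17 juv; 25 M: 17 ad + 8 juv)
    add(28, "migrant", "female", "adult")
    add(17, "migrant", "female", "juvenile")
    add(17, "migrant", "male", "adult")
    add(8, "migrant", "male", "juvenile")
    # excluded
    add(158, "undetermined", "female", "adult")
    add(11, "winter_departer", "male", "adult")
    add(11, "switcher", "female", "adult")
    add(27, "resident", "unknown", "juvenile")  # unsexed juveniles
    df = pd.DataFrame(rows)
    df.insert(0, "id", [f"b{i:04d}" for i in range(len(df))])
    return df


class TestExclusionFilters:
    def test_published_cohort_arithmetic(self):
        df = study_cohort()
        assert len(df) == 469
        included, tally = apply_exclusion_filters(df)
        assert tally == {
            "undetermined": 158,
            "winter_departer": 11,
            "switcher": 11,
            "unsexed_juvenile": 27,
        }
        assert len(included) == 262
        assert (included["strategy"] == "resident").sum() == 192
        assert (included["strategy"] == "migrant").sum() == 70
        # tallies partition the input
        assert len(included) + sum(tally.values()) == len(df)

    def test_no_exclusions_identity(self):
        df = make_cov(5, strategy="migrant")
        included, tally = apply_exclusion_filters(df)
        assert len(included) == 5 and sum(tally.values()) == 0

    def test_empty_input(self):
        included, tally = apply_exclusion_filters(pd.DataFrame(columns=["id", "sex", "age", "strategy"]))
        assert len(included) == 0 and sum(tally.values()) == 0

    def test_planted_reasons_recovered_exactly(self):
        """Generator-planted exclusion reasons are recovered by the full
        classify -> filter chain (perfect detection makes it deterministic)."""
        cfg = SimulationConfig(
            n_residents=30, n_migrants=15, years=5, seed=3,
            p_resident=1.0, p_migrant=1.0,
            n_winter_departers=4, n_switchers=3, n_undetermined=5,
            n_unsexed_juveniles=6,
        )
        eh, cov, truth = simulate_population(cfg)
        rec = simulate_detection_records(cfg)
        classes = classify_all(rec, eh.calendar)
        ind = classes.merge(cov[["id", "sex", "age"]], on="id", how="left")
        included, tally = apply_exclusion_filters(ind)

        # expected reasons from the generator's truth log: planted specials
        # keep their plant; normal birds that died before reaching any
        # winter occasion are genuinely unclassifiable (mortality)
        alive = truth[[c for c in truth.columns if c.startswith("alive_")]].to_numpy()
        first = eh.first_occasion
        winter = np.array([t % 2 == 1 for t in range(eh.n_occasions)])
        expected = {"undetermined": 0, "winter_departer": 0, "switcher": 0,
                    "unsexed_juvenile": 0}
        n_included = 0
        for i, reason in enumerate(truth["planted_reason"]):
            if reason in ("winter_departer", "switcher", "undetermined"):
                expected[reason] += 1
                continue
            survived_to_winter = (alive[i] & winter & (np.arange(len(winter)) >= first[i])).any()
            if not survived_to_winter:
                expected["undetermined"] += 1
            elif reason == "unsexed_juvenile":
                expected["unsexed_juvenile"] += 1
            else:
                n_included += 1
        assert tally == expected
        assert len(included) == n_included


class TestEncounterMatrix:
    def test_roundtrip_identity_over_seeds(self):
        """Matrix rebuilt from simulated records equals the simulator's own."""
        for seed in (0, 7, 123):
            cfg = SimulationConfig(
                n_residents=25, n_migrants=12, years=4, seed=seed,
                n_winter_departers=2, n_switchers=1, n_undetermined=2,
            )
            eh, _, _ = simulate_population(cfg)
            rec = simulate_detection_records(cfg)
            eh2, dropped = build_encounter_matrix(rec, eh.calendar, list(eh.ids))
            assert dropped == 0
            assert list(eh2.ids) == list(eh.ids)
            assert (eh2.matrix == eh.matrix).all()

    def test_boundary_detection_assignment(self, cal15):
        rec = records_from([("b1", dt.date(2009, 11, 3), "detection")])
        eh, _ = build_encounter_matrix(rec, cal15)
        assert eh.matrix[0, 1] == 1 and eh.matrix[0].sum() == 1

    def test_out_of_calendar_records_dropped_with_warning(self, cal15):
        rec = records_from(
            [("b1", dt.date(2009, 6, 1), "detection"),
             ("b1", dt.date(2030, 6, 1), "detection")]
        )
        with pytest.warns(UserWarning, match="dropped"):
            eh, dropped = build_encounter_matrix(rec, cal15)
        assert dropped == 1 and eh.matrix.sum() == 1

    def test_departure_events_do_not_count_as_detections(self, cal15):
        rec = records_from(
            [("b1", dt.date(2009, 6, 1), "detection"),
             ("b1", dt.date(2009, 10, 16), "nocturnal_departure")]
        )
        eh, _ = build_encounter_matrix(rec, cal15)
        assert eh.matrix[0].sum() == 1

    def test_encounter_history_invariants(self, cal15):
        with pytest.raises(ValueError, match="no detections"):
            EncounterHistory(np.array(["a"]), np.zeros((1, 15), dtype=int), cal15)
        with pytest.raises(ValueError):
            EncounterHistory(np.array(["a"]), 2 * np.ones((1, 15), dtype=int), cal15)

    def test_csv_roundtrip(self, tmp_path, cal15):
        cfg = SimulationConfig(n_residents=10, n_migrants=5, years=8, seed=1)
        eh, cov, _ = simulate_population(cfg)
        path = tmp_path / "hist.csv"
        write_encounter_csv(eh, cov, path)
        eh2, cov2 = read_encounter_csv(path, cal15)
        assert (eh2.matrix == eh.matrix).all()
        assert list(cov2["strategy"]) == list(cov["strategy"])
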