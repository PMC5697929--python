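"""Seasonal occasion calendar for the capture-mark-recapture analysis.

Each study year is split into two operational seasons: "summer" (roughly the
period migrants are on the breeding grounds, default start 2 March) and
"winter" (default start 3 November).  A study of Y years yields 2Y - 1
occasions -- the final year contributes only its summer -- alternating
summer, winter, summer, ...  Occasion windows are half-open [start, next
start) so every calendar date maps to at most one occasion.
"""

from __future__ import annotations

import bisect
import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = ["Occasion", "SeasonCalendar", "build_season_calendar"]

#: default mean season boundaries (month, day)
DEFAULT_SUMMER_START = (3, 2)
DEFAULT_WINTER_START = (11, 3)


@dataclass(frozen=True)
class Occasion:
    """One sampling occasion: a named seasonal window [start, end)."""

    label: str
    season: str  # "summer" or "winter"
    start: dt.date
    end: dt.date  # exclusive

    def __post_init__(self) -> None:
        if self.season not in ("summer", "winter"):
            raise ValueError(f"unknown season type {self.season!r}")
        if self.end <= self.start:
            raise ValueError(
                f"occasion {self.label!r}: end {self.end} not after start {self.start}"
            )

    def contains(self, day: dt.date) -> bool:
        return self.start <= day < self.end


class SeasonCalendar:
    """Ordered, contiguous, alternating sequence of seasonal occasions."""

    def __init__(self, occasions: Sequence[Occasion]):
        occasions = list(occasions)
        if not occasions:
            raise ValueError("calendar needs at least one occasion")
        for a, b in zip(occasions, occasions[1:]):
            if b.start != a.end:
                raise ValueError(
                    f"occasions {a.label!r} and {b.label!r} are not contiguous"
                )
            if b.season == a.season:
                raise ValueError("occasion season types must alternate")
        self.occasions = occasions
        self._starts = [o.start for o in occasions]

    def __len__(self) -> int:
        return len(self.occasions)

    def __iter__(self):
        return iter(self.occasions)

    def __getitem__(self, i: int) -> Occasion:
        return self.occasions[i]

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def season_types(self) -> list[str]:
        return [o.season for o in self.occasions]

    @property
    def labels(self) -> list[str]:
        return [o.label for o in self.occasions]

    @property
    def start(self) -> dt.date:
        return self.occasions[0].start

    @property
    def end(self) -> dt.date:
        return self.occasions[-1].end

    def index_of_date(self, day: dt.date) -> int | None:
        """Occasion index containing ``day``, or None if outside the calendar."""
        if day < self.start or day >= self.end:
            return None
        return bisect.bisect_right(self._starts, day) - 1

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": self.labels,
                "type": self.season_types,
                "start": [o.start.isoformat() for o in self.occasions],
                "end": [o.end.isoformat() for o in self.occasions],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SeasonCalendar":
        import pandas as pd

        df = pd.read_csv(path)
        occ = [
            Occasion(
                label=r.label,
                season=r.type,
                start=dt.date.fromisoformat(r.start),
                end=dt.date.fromisoformat(r.end),
            )
            for r in df.itertuples()
        ]
        return cls(occ)


def _mk_date(year: int, month_day: tuple[int, int]) -> dt.date:
    return dt.date(year, *month_day)


def build_season_calendar(
    years: Iterable[int],
    *,
    summer_start: tuple[int, int] = DEFAULT_SUMMER_START,
    winter_start: tuple[int, int] = DEFAULT_WINTER_START,
    first_summer_start: dt.date | None = None,
    final_spring_start: dt.date | None = None,
    per_year: Mapping[int, Mapping[str, dt.date]] | None = None,
) -> SeasonCalendar:
    """Build the alternating summer/winter occasion calendar.

    Parameters
    ----------
    years
        Study years, e.g. ``range(2009, 2017)``.  Y years produce 2Y - 1
        occasions; the last year contributes only a summer, unless
        ``final_spring_start`` supplies the end of a trailing winter, in
        which case 2Y occasions are produced.
    summer_start, winter_start
        Default (month, day) season boundaries applied to every year.
    first_summer_start
        Overrides the start date of the very first summer (e.g. the date of
        the first capture in the first field season).
    per_year
        Optional per-year overrides: ``{year: {"summer_start": date,
        "winter_start": date}}``.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("need at least one study year")
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("years must be consecutive")
    per_year = per_year or {}

    def boundary(year: int, key: str, default: tuple[int, int]) -> dt.date:
        ov = per_year.get(year, {})
        return ov.get(key, _mk_date(year, default))

    occasions: list[Occasion] = []
    for i, y in enumerate(years):
        s_start = boundary(y, "summer_start", summer_start)
        if i == 0 and first_summer_start is not None:
            s_start = first_summer_start
        w_start = boundary(y, "winter_start", winter_start)
        if w_start <= s_start:
            raise ValueError(
                f"year {y}: winter start {w_start} not after summer start {s_start}"
            )
        occasions.append(Occasion(f"summer-{y}", "summer", s_start, w_start))
        if i < len(years) - 1:
            w_end = boundary(years[i + 1], "summer_start", summer_start)
            if i == 0 and first_summer_start is not None and y + 1 == years[i + 1]:
                w_end = boundary(years[i + 1], "summer_start", summer_start)
            occasions.append(
                Occasion(f"winter-{y}/{(y + 1) % 100:02d}", "winter", w_start, w_end)
            )
        elif final_spring_start is not None:
            if final_spring_start <= w_start:
                raise ValueError("final spring start must fall after the last winter start")
            occasions.append(
                Occasion(f"winter-{y}/{(y + 1) % 100:02d}", "winter", w_start, final_spring_start)
            )
    return SeasonCalendar(occasions)
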