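import datetime as dt

import numpy as np
import pandas as pd
import pytest

from partmig.prep import EncounterHistory
from partmig.seasons import SeasonCalendar, build_season_calendar


def calendar_for(n_occasions: int, start_year: int = 2009) -> SeasonCalendar:
    """Calendar with exactly n_occasions alternating seasons (first is summer)."""
    if n_occasions % 2 == 1:
        return build_season_calendar(range(start_year, start_year + (n_occasions + 1) // 2))
    years = n_occasions // 2
    return build_season_calendar(
        range(start_year, start_year + years),
        final_spring_start=dt.date(start_year + years, 3, 2),
    )


def make_eh(histories, calendar=None) -> EncounterHistory:
    """EncounterHistory from a list of 0/1 strings."""
    mat = np.array([[int(c) for c in h] for h in histories], dtype=np.int8)
    cal = calendar or calendar_for(mat.shape[1])
    ids = np.array([f"i{k}" for k in range(len(histories))])
    return EncounterHistory(ids, mat, cal)


def make_cov(n, strategy="resident", sex="female", age="adult") -> pd.DataFrame:
    def col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n

    return pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "sex": col(sex),
            "age": col(age),
            "strategy": col(strategy),
        }
    )


@pytest.fixture
def cal15() -> SeasonCalendar:
    return build_season_calendar(range(2009, 2017))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20090423)
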