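"""Logit-scale design matrices for the survival and detection sub-models.

Survival rows index (individual, interval); the interval leaving occasion t
carries occasion t's season type, i.e. "summer survival" links a summer
occasion to the following winter occasion.  Detection rows index
(individual, occasion) and use that occasion's season type.  Factors are
treatment-coded against the references resident / female / adult / summer /
first time level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import ModelSpec, PHI_FACTOR_ORDER, P_FACTOR_ORDER
from .prep import EncounterHistory
from .seasons import SeasonCalendar

__all__ = ["DesignMatrices", "build_design", "RankDeficientError"]


class RankDeficientError(ValueError):
    pass


@dataclass
class DesignMatrices:
    """Survival and detection designs on the (individual, time) grid."""

    x_phi: np.ndarray  # (n, T-1, k_phi)
    x_p: np.ndarray  # (n, T, k_p)
    phi_names: list[str]
    p_names: list[str]

    @property
    def k_phi(self) -> int:
        return self.x_phi.shape[2]

    @property
    def k_p(self) -> int:
        return self.x_p.shape[2]

    @property
    def k(self) -> int:
        return self.k_phi + self.k_p

    @property
    def names(self) -> list[str]:
        return [f"phi:{c}" for c in self.phi_names] + [f"p:{c}" for c in self.p_names]


def _factor_column(factor: str, cov: pd.DataFrame) -> np.ndarray:
    if factor == "migr":
        return (cov["strategy"].to_numpy() == "migrant").astype(float)
    if factor == "sex":
        return (cov["sex"].to_numpy() == "male").astype(float)
    if factor == "age":
        return (cov["age"].to_numpy() == "juvenile").astype(float)
    raise KeyError(factor)


def _build_side(
    terms,
    order,
    cov: pd.DataFrame,
    season_winter: np.ndarray,  # (n_time,) 0/1 winter indicator per time cell
    n_time: int,
    time_ref: int,
) -> tuple[np.ndarray, list[str]]:
    n = len(cov)
    cols: list[np.ndarray] = [np.ones((n, n_time))]
    names = ["(Intercept)"]
    for f in order:
        if f not in terms:
            continue
        if f == "season":
            cols.append(np.broadcast_to(season_winter, (n, n_time)).astype(float))
            names.append("season[winter]")
        elif f == "t":
            for t in range(n_time):
                if t == time_ref:
                    continue
                col = np.zeros((n, n_time))
                col[:, t] = 1.0
                cols.append(col)
                names.append(f"t[{t}]")
        else:
            level = {"migr": "migrant", "sex": "male", "age": "juvenile"}[f]
            v = _factor_column(f, cov)
            cols.append(np.repeat(v[:, None], n_time, axis=1))
            names.append(f"{f}[{level}]")
    x = np.stack(cols, axis=2)
    return x, names


def build_design(
    spec: ModelSpec,
    covariates: pd.DataFrame,
    calendar: SeasonCalendar,
    *,
    eh: EncounterHistory | None = None,
    check_rank: bool = True,
) -> DesignMatrices:
    """Realise a model formula as numeric design arrays.

    ``covariates`` must be row-aligned with the encounter-history matrix the
    design will be used with.  When ``eh`` is given, the full-column-rank
    check is restricted to rows that actually enter the likelihood (cells at
    or after each individual's first capture).
    """
    T = calendar.n_occasions
    season = np.array([1.0 if s == "winter" else 0.0 for s in calendar.season_types])
    # interval t carries occasion t's season type
    x_phi, phi_names = _build_side(
        spec.phi_terms, PHI_FACTOR_ORDER, covariates, season[: T - 1], T - 1, time_ref=0
    )
    # detection at occasion t uses occasion t's season; occasion 0 never
    # contributes an emission term, so occasion 1 is the time reference
    x_p, p_names = _build_side(
        spec.p_terms, P_FACTOR_ORDER, covariates, season, T, time_ref=1
    )
    dm = DesignMatrices(x_phi, x_p, phi_names, p_names)
    if check_rank and len(covariates):
        _check_rank(dm, eh)
    return dm


def _active_rows(x: np.ndarray, first: np.ndarray | None, kind: str) -> np.ndarray:
    n, n_time, k = x.shape
    flat = x.reshape(n * n_time, k)
    if first is None:
        return flat
    t_idx = np.tile(np.arange(n_time), n)
    f_rep = np.repeat(first, n_time)
    mask = t_idx >= f_rep if kind == "phi" else t_idx > f_rep
    return flat[mask]


def _check_rank(dm: DesignMatrices, eh: EncounterHistory | None) -> None:
    first = eh.first_occasion if eh is not None else None
    for x, names, kind in (
        (dm.x_phi, dm.phi_names, "phi"),
        (dm.x_p, dm.p_names, "p"),
    ):
        rows = _active_rows(x, first, kind)
        if rows.shape[0] == 0:
            continue
        rank = np.linalg.matrix_rank(rows)
        if rank < x.shape[2]:
            # identify columns that add no rank
            confounded = []
            kept: list[int] = []
            for j in range(x.shape[2]):
                r_new = np.linalg.matrix_rank(rows[:, kept + [j]])
                if r_new == len(kept):
                    confounded.append(names[j])
                else:
                    kept.append(j)
            raise RankDeficientError(
                f"{kind} design is rank deficient; confounded column(s): {confounded}"
            )
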