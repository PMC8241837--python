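"""Actuarial life tables for infant and under-five mortality rates.

Rates per 1000 livebirths are built the classical way: follow-up is divided
into age segments, the conditional probability of dying in each segment is
q = deaths / (entrants - censored/2) (half-exposure for within-segment
censoring), and the window rate is 1000 * (1 - prod(1 - q)) over segments up
to 12 months (INMR) or 60 months (U5MR).  With no censoring inside the
window this reduces exactly to 1000 times the simple proportion dying.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DHS_SEGMENTS", "LifeTableResult", "mortality_rate", "stratified_rates"]

#: Conventional DHS age-segment boundaries in months.
DHS_SEGMENTS = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0, 36.0, 48.0, 60.0)


@dataclass(frozen=True)
class LifeTableResult:
    """Per-segment life table plus the cumulative rate for the window."""

    window: float
    table: pd.DataFrame  # columns a, b, n_enter, deaths, censored, q
    rate_per_1000: float

    @property
    def q_segment(self) -> np.ndarray:
        return self.table["q"].to_numpy()


def _segment_boundaries(window: float, segments: Sequence[float] | None) -> np.ndarray:
    if segments is None:
        b = np.asarray([s for s in DHS_SEGMENTS if s < window] + [window], dtype=float)
    else:
        b = np.asarray(segments, dtype=float)
    if b[0] != 0.0 or b[-1] != window or np.any(np.diff(b) <= 0):
        raise ValueError(
            f"segments must partition [0, {window}) with increasing boundaries "
            "starting at 0"
        )
    return b


def mortality_rate(records: pd.DataFrame, window: float = 12,
                   segments: Sequence[float] | None = None,
                   weight_col: str | None = None) -> LifeTableResult:
    """Life-table mortality rate per 1000 livebirths over ``[0, window)``.

    A death at a segment boundary counts in the segment it closes; a child
    censored exactly at a boundary has completed the closing segment and is
    not treated as censored within it.  An optional per-record weight column
    multiplies both exposures and deaths.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    t = records["t_obs_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    if np.any(t <= 0):
        raise ValueError("t_obs_months must be > 0")
    w = (records[weight_col].to_numpy(dtype=float) if weight_col
         else np.ones(len(records)))
    b = _segment_boundaries(float(window), segments)
    rows = []
    surv = 1.0
    for a, bb in zip(b[:-1], b[1:]):
        enter = float(w[t > a].sum())
        deaths = float(w[e & (t > a) & (t <= bb)].sum())
        censored = float(w[~e & (t > a) & (t < bb)].sum())
        denom = enter - censored / 2.0
        q = deaths / denom if denom > 0 else 0.0
        surv *= 1.0 - q
        rows.append((a, bb, enter, deaths, censored, q))
    table = pd.DataFrame(rows, columns=["a", "b", "n_enter", "deaths", "censored", "q"])
    return LifeTableResult(window=float(window), table=table,
                           rate_per_1000=1000.0 * (1.0 - surv))


def stratified_rates(records: pd.DataFrame, group_by: str | Sequence[str],
                     windows: Sequence[float] = (12, 60),
                     segments: Sequence[float] | None = None,
                     weight_col: str | None = None) -> pd.DataFrame:
    """Mortality rates per stratum, in the layout of a descriptive rate table.

    Returns one row per stratum with its frequency, percentage of the cohort
    and one ``rate_<window>`` column per requested window (e.g. ``rate_12``
    is the INMR, ``rate_60`` the U5MR).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    for col in group_by:
        if col not in records.columns:
            raise KeyError(f"unknown grouping column {col!r}")
    w = (records[weight_col].to_numpy(dtype=float) if weight_col
         else np.ones(len(records)))
    total = w.sum()
    rows = []
    for key, chunk in records.groupby(list(group_by), sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        n = (chunk[weight_col].sum() if weight_col else len(chunk))
        row = dict(zip(group_by, key))
        row["n"] = n
        row["percent"] = 100.0 * n / total
        for win in windows:
            row[f"rate_{int(win)}"] = mortality_rate(
                chunk, win, segments, weight_col
            ).rate_per_1000
        rows.append(row)
    return pd.DataFrame(rows)
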