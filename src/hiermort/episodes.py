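"""Counting-process expansion of survival records for Poisson fitting.

Each child's follow-up (0, t_obs] is split at grid boundaries into episodes
[a, b'); every episode carries its time at risk gamma = b' - a, the offset
log(gamma), and an event indicator d that is 1 only on the last episode of a
child who died.  A Poisson model with this offset then has the likelihood of
a piecewise-exponential survival model; when the grid is the set of unique
event times and the baseline is saturated per interval, its covariate
estimates coincide with the Cox partial-likelihood estimates (Breslow ties).

The smooth baseline uses a polynomial basis (default order 4) in scaled time
s = midpoint / horizon, orthogonalised over the grid by default because raw
high-order polynomials on [0, 60] months are badly conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitGrid", "split_episodes", "polynomial_basis", "time_basis",
           "GridTimeBasis", "EPISODE_COLUMNS"]

EPISODE_COLUMNS = ("state_id", "neigh_id", "child_id", "k", "a", "b",
                   "gamma", "offset", "d")

_MAX_ORDER = 10


@dataclass(frozen=True)
class SplitGrid:
    """Ordered cut points in months, starting at 0."""

    boundaries: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2 or b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must start at 0 and be strictly increasing")

    @classmethod
    def monthly(cls, horizon: float, width: float = 1.0) -> "SplitGrid":
        n = int(np.ceil(horizon / width))
        return cls(tuple(np.round(np.arange(n + 1) * width, 10)))

    @classmethod
    def from_event_times(cls, records: pd.DataFrame) -> "SplitGrid":
        """Cut at the unique observed event times (plus the maximum follow-up
        so the grid covers every record)."""
        t = records["t_obs_months"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=bool)
        cuts = np.unique(t[e])
        if len(cuts) == 0:
            raise ValueError("no events in the data; event-time grid undefined")
        tmax = t.max()
        if tmax > cuts[-1]:
            cuts = np.append(cuts, tmax)
        return cls((0.0, *cuts))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.boundaries, dtype=float)


def split_episodes(records: pd.DataFrame, grid: SplitGrid) -> pd.DataFrame:
    """Expand child records into one row per (child x interval entered).

    Intervals are half-open [a, b); an event at an interior boundary belongs
    to the interval it closes.  Exposure and events are conserved exactly:
    the per-child gammas sum to t_obs and the per-child d's sum to event.
    """
    bounds = grid.array
    t = records["t_obs_months"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=bool)
    if np.any(t <= 0):
        raise ValueError("t_obs_months must be > 0")
    if t.max() > bounds[-1] + 1e-12:
        raise ValueError(
            f"follow-up {t.max()} exceeds grid coverage {bounds[-1]}"
        )
    n_ep = np.searchsorted(bounds, np.minimum(t, bounds[-1]), side="left")
    total = int(n_ep.sum())
    child = np.repeat(np.arange(len(records)), n_ep)
    k = np.arange(total) - np.repeat(np.cumsum(n_ep) - n_ep, n_ep)
    a = bounds[k]
    b_clip = np.minimum(bounds[k + 1], t[child])
    gamma = b_clip - a
    is_last = k == (n_ep - 1)[child]
    d = (is_last & event[child]).astype(np.int8)

    out = records.drop(columns=["t_obs_months", "event"]).iloc[child].reset_index(drop=True)
    out.insert(3, "k", k)
    out.insert(4, "a", a)
    out.insert(5, "b", b_clip)
    out.insert(6, "gamma", gamma)
    out.insert(7, "offset", np.log(gamma))
    out.insert(8, "d", d)
    return out


def polynomial_basis(s, order: int = 4) -> np.ndarray:
    """Raw power basis (1, s, ..., s^order) at scaled time s."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > _MAX_ORDER:
        raise ValueError(f"order > {_MAX_ORDER} rejected on numerical grounds")
    s = np.asarray(s, dtype=float)
    return np.power.outer(s, np.arange(order + 1))


def time_basis(interval, order: int = 4, horizon: float | None = None) -> np.ndarray:
    """Raw polynomial basis for one interval, evaluated at its midpoint
    after mapping [0, horizon] -> [0, 1]."""
    a, b = float(interval[0]), float(interval[1])
    if b <= a:
        raise ValueError("interval must satisfy b > a")
    mid = 0.5 * (a + b)
    if mid < 0:
        raise ValueError("negative interval midpoint")
    if horizon is None:
        horizon = b
    return polynomial_basis(mid / horizon, order)


class GridTimeBasis:
    """Polynomial time basis evaluated per grid interval.

    ``matrix`` has one row per interval and order+1 columns; with
    ``orthogonal=True`` (default) the columns are orthonormalised over the
    grid rows by a QR decomposition with a fixed sign convention, so the
    basis is reproducible and well conditioned.
    """

    def __init__(self, grid: SplitGrid, order: int = 4,
                 horizon: float | None = None, orthogonal: bool = True):
        bounds = grid.array
        if horizon is None:
            horizon = float(bounds[-1])
        mids = 0.5 * (bounds[:-1] + bounds[1:])
        raw = polynomial_basis(mids / horizon, order)
        if orthogonal and raw.shape[0] > raw.shape[1]:
            q, r = np.linalg.qr(raw)
            sign = np.sign(np.diag(r))
            sign[sign == 0] = 1.0
            self.matrix = q * sign
        else:
            self.matrix = raw
        self.order = order
        self.horizon = horizon
        self.orthogonal = orthogonal

    def rows(self, k) -> np.ndarray:
        """Basis rows for interval indices ``k`` (e.g. an episode column)."""
        return self.matrix[np.asarray(k, dtype=int)]
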