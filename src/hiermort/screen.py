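"""Pre-modelling utilities: collinearity screen and covariate recodes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["CollinearityReport", "collinearity_screen", "categorize_rural_pct"]


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations over coded covariates.

    ``flagged`` lists (name_a, name_b, r) for |r| >= cutoff, names sorted
    within each pair; ``degenerate`` lists constant columns excluded from
    the matrix.
    """

    correlations: pd.DataFrame
    cutoff: float
    flagged: list[tuple[str, str, float]] = field(default_factory=list)
    degenerate: list[str] = field(default_factory=list)

    def flagged_pairs(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b, _ in self.flagged}


def _code_column(series: pd.Series, order: Sequence[str] | None) -> pd.Series:
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    levels = list(order) if order is not None else sorted(pd.unique(series.dropna()))
    mapping = {lev: i for i, lev in enumerate(levels)}
    unknown = set(series.dropna()) - set(mapping)
    if unknown:
        raise ValueError(f"values {sorted(unknown)} not covered by the "
                         f"declared level order for {series.name!r}")
    return series.map(mapping).astype(float)


def collinearity_screen(table: pd.DataFrame, cutoff: float = 0.6,
                        columns: Sequence[str] | None = None,
                        ordinal_orders: Mapping[str, Sequence[str]] | None = None,
                        ) -> CollinearityReport:
    """Flag covariate pairs whose Pearson correlation reaches the cutoff.

    Categorical columns are coded to integer ranks first (in the order given
    by ``ordinal_orders`` when supplied, otherwise sorted level labels).
    Constant columns have no defined correlation; they are reported as
    degenerate and excluded from pairing.  The result is invariant to the
    order of columns and rows.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if c not in ("state_id", "neigh_id", "child_id",
                                "t_obs_months", "event")]
    if len(columns) < 2:
        raise ValueError("need at least two covariate columns to screen")
    ordinal_orders = ordinal_orders or {}
    coded = pd.DataFrame({
        c: _code_column(table[c], ordinal_orders.get(c)) for c in columns
    })
    degenerate = [c for c in columns if coded[c].nunique(dropna=True) <= 1]
    keep = [c for c in columns if c not in degenerate]
    corr = coded[keep].corr(method="pearson")
    flagged = []
    for i, a in enumerate(sorted(keep)):
        for b in sorted(keep)[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= cutoff:
                flagged.append((a, b, r))
    return CollinearityReport(correlations=corr, cutoff=cutoff,
                              flagged=flagged, degenerate=degenerate)


def categorize_rural_pct(percent: float) -> str:
    """Band a state's rural-population percentage into Low/Middle/High.

    0-33.3% is Low, 33.4-66.7% Middle, 66.8-100% High; values between the
    published band edges are resolved by rounding to one decimal first.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError(f"rural percentage {percent} outside [0, 100]")
    p = float(np.round(percent, 1))
    if p <= 33.3:
        return "Low"
    if p <= 66.7:
        return "Middle"
    return "High"
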