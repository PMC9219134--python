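"""Descriptive coverage tables and temporal trends.

Coverage for a stratum (a region, or the whole country) in a survey year
is 100 × Σ Y_j / Σ n_j over that stratum's clusters — a count-weighted
ratio, not a mean of cluster percentages.  The pooled all-years column is
likewise computed from summed counts, so it equals the count-weighted
combination of the per-year cells by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import copysign, floor
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ClusterRecord

__all__ = [
    "CoverageTable",
    "coverage_by_stratum",
    "relative_change",
    "trend_series",
    "round_half_away",
]

NATIONAL = "NATIONAL"
POOLED = "POOLED"


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention; 0.05 -> 0.1)."""
    f = 10.0**decimals
    return copysign(floor(abs(x) * f + 0.5), x) / f


@dataclass
class CoverageTable:
    """Counts and percentages per stratum × year, with national and pooled margins."""

    vaccinated: pd.DataFrame  # integer counts, index strata (+NATIONAL), cols years (+POOLED)
    children: pd.DataFrame
    n_unassigned: int = 0

    @property
    def percent(self) -> pd.DataFrame:
        """100 × vaccinated / children; NaN where a stratum-year is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.vaccinated / self.children.where(self.children > 0)

    def percent_display(self) -> pd.DataFrame:
        """Percentages rounded to 1 decimal, half away from zero."""
        return self.percent.map(lambda v: np.nan if pd.isna(v) else round_half_away(v, 1))


def _assign_regions(records: Sequence[ClusterRecord], polygons: Mapping[str, object] | None):
    if polygons is None:
        return [r.region for r in records]
    from shapely.geometry import Point

    labels = []
    for r in records:
        pt = Point(r.lon, r.lat)
        label = None
        for name, geom in polygons.items():
            if geom.covers(pt):
                label = name
                break
        labels.append(label)
    return labels


def coverage_by_stratum(
    records: Sequence[ClusterRecord],
    polygons: Mapping[str, object] | None = None,
) -> CoverageTable:
    """Tabulate coverage per stratum × survey year.

    Strata come from each record's region label, or from point-in-polygon
    assignment when ``polygons`` (name → shapely geometry, lon/lat) is
    given.  Unassigned records are excluded from regional rows but always
    counted in the NATIONAL row; their count is reported.
    """
    labels = _assign_regions(records, polygons)
    df = pd.DataFrame(
        {
            "region": labels,
            "year": [r.year for r in records],
            "n_vaccinated": [r.n_vaccinated for r in records],
            "n_children": [r.n_children for r in records],
        }
    )
    years = sorted(df["year"].unique())
    strata = sorted({l for l in labels if l is not None})
    idx = strata + [NATIONAL]
    cols = years + [POOLED]
    vacc = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    chil = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    grouped = df.dropna(subset=["region"]).groupby(["region", "year"])[["n_vaccinated", "n_children"]].sum()
    for (reg, yr), row in grouped.iterrows():
        vacc.loc[reg, yr] = row["n_vaccinated"]
        chil.loc[reg, yr] = row["n_children"]
    nat = df.groupby("year")[["n_vaccinated", "n_children"]].sum()
    for yr, row in nat.iterrows():
        vacc.loc[NATIONAL, yr] = row["n_vaccinated"]
        chil.loc[NATIONAL, yr] = row["n_children"]
    vacc[POOLED] = vacc[years].sum(axis=1)
    chil[POOLED] = chil[years].sum(axis=1)
    return CoverageTable(
        vaccinated=vacc, children=chil,
        n_unassigned=int(sum(l is None for l in labels)),
    )


def relative_change(coverage_start: float, coverage_end: float) -> float:
    """Percent change relative to the starting coverage:
    100 × (end − start) / start."""
    if coverage_start <= 0:
        raise ValueError("relative change undefined for non-positive starting coverage")
    return 100.0 * (coverage_end - coverage_start) / coverage_start


def trend_series(table: CoverageTable, stratum: str = NATIONAL) -> pd.DataFrame:
    """Year-ordered coverage for one stratum with interval changes.

    Columns: year, coverage (%), abs_change (percentage points vs the
    previous survey) and rel_change (% of the previous survey's value).
    """
    if stratum not in table.percent.index:
        raise KeyError(f"unknown stratum {stratum!r}")
    years = [c for c in table.percent.columns if c != POOLED]
    s = table.percent.loc[stratum, years].dropna()
    if len(s) < 2:
        raise ValueError("trend needs at least two survey years with data")
    s = s.sort_index()
    cov = s.to_numpy(dtype=float)
    out = pd.DataFrame({"year": s.index.to_numpy(), "coverage": cov})
    out["abs_change"] = np.concatenate([[np.nan], np.diff(cov)])
    prev = np.concatenate([[np.nan], cov[:-1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        out["rel_change"] = 100.0 * (cov - prev) / prev
    return out
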