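"""Annual soil-water indices computed from daily series.

Two indices summarise a year of daily water availability:

* ``d1rew`` — the lowest decile of the year's daily relative extractable
  water (REW, 1 at field capacity, 0 at permanent wilting point).  Roughly
  the REW below which lie the driest ~10% of days of the year.
* ``mjja_index`` — cumulative rain minus potential evapotranspiration (PET)
  over May 1 – August 31, in mm.

The daily water-balance model that produces REW is out of scope; this
module starts from its output (or from rain/PET gauges).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DailySeries", "d1rew", "mjja_index", "annual_indices"]


@dataclass
class DailySeries:
    """One year of daily values with calendar dates."""

    dates: pd.DatetimeIndex
    values: np.ndarray

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError("dates and values differ in length")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value") -> "DailySeries":
        return cls(pd.DatetimeIndex(df["date"]), df[value_col].to_numpy())


def d1rew(series: DailySeries, q: float = 10.0, method: str = "linear") -> float:
    """Lowest decile of the year's daily REW values.

    Empirical quantile with linear interpolation between order statistics by
    default; ``method`` accepts any numpy percentile method.  Values must
    lie in [0, 1].
    """
    v = series.values
    if v.size == 0:
        raise ValueError("empty daily series")
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("REW values must lie within [0, 1]")
    return float(np.percentile(v, q, method=method))


def mjja_index(rain: DailySeries, pet: DailySeries) -> float:
    """Sum of rain minus PET over May 1 – August 31 (mm).

    Both series must cover the full window for the same year.
    """
    year = int(rain.dates[0].year)
    lo, hi = pd.Timestamp(year, 5, 1), pd.Timestamp(year, 8, 31)

    def window(s: DailySeries, name: str) -> np.ndarray:
        mask = (s.dates >= lo) & (s.dates <= hi)
        got = pd.DatetimeIndex(s.dates[mask])
        expected = pd.date_range(lo, hi, freq="D")
        if not expected.isin(got).all():
            raise ValueError(
                f"{name} series does not cover May 1 - Aug 31 of {year}"
            )
        return s.values[mask]

    return float(window(rain, "rain").sum() - window(pet, "pet").sum())


def annual_indices(df: pd.DataFrame, index: str = "d1rew") -> pd.DataFrame:
    """Annual index table from a long daily table.

    ``df`` has columns date, value and optionally tree_id; one index value
    is computed per (tree_id, year).  Returns columns tree_id, year, index.
    """
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    if "tree_id" not in df.columns:
        df["tree_id"] = ""
    rows = []
    for (tree, year), g in df.groupby(["tree_id", "year"], sort=True):
        s = DailySeries(pd.DatetimeIndex(g["date"]), g["value"].to_numpy())
        if index == "d1rew":
            val = d1rew(s)
        else:
            raise ValueError(f"unknown index {index!r}")
        rows.append({"tree_id": tree, "year": int(year), "index": val})
    return pd.DataFrame(rows)
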