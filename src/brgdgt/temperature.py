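"""Aggregation of monthly temperature records into in-situ regression parameters.

Soil-calibration work regresses lipid indices against several summaries of
the annual temperature cycle: mean annual temperature (MAT), mean
temperature of months above freezing (MAF), mean summer June-July-August
temperature (JJA), and the temperature of the warmest month (WMT).
Multi-year records are averaged month-wise before aggregation.  "Above
freezing" is strict (> 0 degC); a month at exactly 0 is excluded.  For
southern-hemisphere sites the summer months default to calendar JJA with a
warning (set ``southern_summer=True`` to use Dec-Jan-Feb).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .samples import MonthlyTemperatureRecord

__all__ = ["aggregate_temperatures", "read_monthly_temperatures", "write_temperature_table"]

logger = logging.getLogger(__name__)

_JJA_MONTHS = (5, 6, 7)  # zero-based June, July, August
_DJF_MONTHS = (11, 0, 1)


def aggregate_temperatures(
    record: MonthlyTemperatureRecord, southern_summer: bool = False
) -> dict[str, float]:
    """Compute {MAT, MAF, JJA, WMT} in degC from a monthly record.

    MAF is NaN (flagged undefined) when no month is above freezing.  WMT is
    the warmest month of the across-year monthly climatology, so WMT >= MAT
    and WMT >= JJA by construction.
    """
    monthly = record.monthly_means.mean(axis=0)  # month-wise across years
    mat = float(monthly.mean())
    above = monthly[monthly > 0.0]
    if above.size:
        maf = float(above.mean())
    else:
        maf = math.nan
        logger.warning("site %s: no month above freezing, MAF undefined", record.site_id)
    months = _JJA_MONTHS
    if record.hemisphere == "S":
        if southern_summer:
            months = _DJF_MONTHS
        else:
            logger.warning(
                "site %s: southern hemisphere, using calendar JJA months "
                "(pass southern_summer=True for Dec-Jan-Feb)",
                record.site_id,
            )
    jja = float(monthly[list(months)].mean())
    wmt = float(monthly.max())
    return {"MAT": mat, "MAF": maf, "JJA": jja, "WMT": wmt}


def read_monthly_temperatures(path_or_buf) -> list[MonthlyTemperatureRecord]:
    """Read a long-format CSV (site_id, year, month, mean_temp[, hemisphere]).

    Every (site, year) must contribute all 12 months; incomplete years are
    rejected with the missing months listed.
    """
    df = pd.read_csv(path_or_buf)
    required = {"site_id", "year", "month", "mean_temp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records = []
    for site_id, site_df in df.groupby("site_id", sort=True):
        years = []
        for year, ydf in site_df.groupby("year", sort=True):
            present = set(ydf["month"].astype(int))
            absent = sorted(set(range(1, 13)) - present)
            if absent:
                raise ValueError(
                    f"site {site_id!r}, year {year}: missing months {absent}"
                )
            vals = ydf.sort_values("month")["mean_temp"].to_numpy(dtype=float)
            years.append(vals[:12])
        hemisphere = "N"
        if "hemisphere" in site_df.columns:
            hemisphere = str(site_df["hemisphere"].iloc[0])
        records.append(
            MonthlyTemperatureRecord(str(site_id), np.vstack(years), hemisphere)
        )
    return records


def write_temperature_table(records: list[MonthlyTemperatureRecord], path) -> pd.DataFrame:
    """Aggregate every record and write a (site_id, MAT, MAF, JJA, WMT) CSV."""
    rows = []
    for rec in records:
        agg = aggregate_temperatures(rec)
        rows.append({"site_id": rec.site_id, **agg})
    out = pd.DataFrame(rows, columns=["site_id", "MAT", "MAF", "JJA", "WMT"])
    out.to_csv(path, index=False, float_format="%.6g")
    return out
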