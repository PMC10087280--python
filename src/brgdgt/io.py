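"""Reading and writing culture lipid tables, environmental tables, and OD series.

Everything is plain CSV/TSV with a header row, decimal point ".", no
thousands separators.  Compound column headers are normalized through the
controlled vocabulary, so prime / subscript / plain-suffix isomer notations
all land on the same canonical code.  Missing compound cells mean "not
detected" and are read as 0 with a logged count.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd

from .compounds import normalize_compound_code
from .samples import BrgdgtProfile, CultureSample, EnvironmentalSample, GrowthCurve

__all__ = [
    "read_lipid_table",
    "write_lipid_table",
    "read_environmental_table",
    "write_environmental_table",
    "read_od_series",
    "write_od_series",
    "write_report",
]

logger = logging.getLogger(__name__)

_CONDITION_COLUMNS = {
    "sample_id": "sample_id",
    "temperature": "temperature",
    "ph": "ph",
    "pH": "ph",
    "o2": "o2",
    "replicate": "replicate",
    "growth_rate": "growth_rate",
    "fa_total": "fa_total",
    "mage_total": "mage_total",
    "dage_total": "dage_total",
}

_REQUIRED = ("sample_id", "temperature", "ph", "o2", "replicate")


def _classify_columns(columns, column_map: dict[str, str] | None):
    """Split header names into condition fields, compound codes, and unknowns."""
    column_map = column_map or {}
    condition, compounds, unknown = {}, {}, []
    for col in columns:
        mapped = column_map.get(col, col)
        if mapped in _CONDITION_COLUMNS:
            condition[col] = _CONDITION_COLUMNS[mapped]
            continue
        try:
            compounds[col] = normalize_compound_code(mapped)
        except ValueError:
            unknown.append(col)
    return condition, compounds, unknown


def read_lipid_table(path_or_buf, dialect: str = "csv",
                     column_map: dict[str, str] | None = None) -> list[CultureSample]:
    """Read a culture lipid table into one CultureSample per row.

    ``column_map`` renames nonstandard headers onto the expected schema
    (condition fields sample_id/temperature/pH/o2/replicate plus optional
    growth_rate and FA/MAGE/DAGE totals; remaining columns are compound
    codes).  Unknown columns are reported and skipped; missing abundance
    cells become 0; negative abundances and duplicate sample ids are
    rejected naming the offending row.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.read_csv(path_or_buf, sep=sep)
    condition, compounds, unknown = _classify_columns(df.columns, column_map)
    if unknown:
        logger.warning("ignoring %d unknown columns: %s", len(unknown), unknown)
    have = set(condition.values())
    missing = [c for c in _REQUIRED if c not in have]
    if missing:
        raise ValueError(f"missing required condition columns: {missing}")
    if not compounds:
        raise ValueError("no compound columns found in header")

    ids = df[[c for c, m in condition.items() if m == "sample_id"][0]]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate sample_id values: {sorted(set(dup))}")

    n_missing = int(df[list(compounds)].isna().sum().sum())
    if n_missing:
        logger.info("read_lipid_table: %d missing abundance cells treated as 0", n_missing)

    samples = []
    for _, row in df.iterrows():
        fields = {m: row[c] for c, m in condition.items()}
        sid = str(fields.pop("sample_id"))
        abundance = {}
        for col, code in compounds.items():
            v = row[col]
            v = 0.0 if pd.isna(v) else float(v)
            if v < 0:
                raise ValueError(f"row {sid!r}: negative abundance in column {col!r}")
            abundance[code] = abundance.get(code, 0.0) + v
        totals = {k: (None if pd.isna(fields.get(k, np.nan)) else float(fields[k]))
                  for k in ("fa_total", "mage_total", "dage_total")}
        profile = BrgdgtProfile(sample_id=sid, abundance=abundance, **totals)
        gr = fields.get("growth_rate", np.nan)
        samples.append(CultureSample(
            profile=profile,
            temperature=float(fields["temperature"]),
            ph=float(fields["ph"]),
            o2=float(fields["o2"]),
            replicate=int(fields["replicate"]),
            growth_rate=None if pd.isna(gr) else float(gr),
        ))
    return samples


def _culture_frame(samples: list[CultureSample]) -> pd.DataFrame:
    codes = sorted({c for s in samples for c in s.profile.abundance})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "temperature": s.temperature,
            "pH": s.ph,
            "o2": s.o2,
            "replicate": s.replicate,
            "growth_rate": s.growth_rate,
            "fa_total": s.profile.fa_total,
            "mage_total": s.profile.mage_total,
            "dage_total": s.profile.dage_total,
        }
        for c in codes:
            row[c] = s.profile.get(c)
        rows.append(row)
    return pd.DataFrame(rows)


def write_lipid_table(samples: list[CultureSample], path, dialect: str = "csv") -> None:
    """Write culture samples in the same schema read_lipid_table reads."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    _culture_frame(samples).to_csv(path, sep=sep, index=False)


def read_environmental_table(path_or_buf) -> list[EnvironmentalSample]:
    """Read an environmental calibration table.

    Expected columns: sample_id, sample_type, optional pH, optional index
    columns (e.g. MBT'5Me, CBT5Me), optional temperature-parameter columns
    (MAT/MAF/JJA/WMT/SST/water_temp), remaining columns compound codes.
    """
    from .samples import TEMPERATURE_PARAMETERS

    df = pd.read_csv(path_or_buf)
    for col in ("sample_id", "sample_type"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    index_cols = [c for c in df.columns if c in ("MBT'5Me", "CBT5Me", "DC")]
    temp_cols = [c for c in df.columns if c in TEMPERATURE_PARAMETERS]
    other = [c for c in df.columns
             if c not in index_cols + temp_cols + ["sample_id", "sample_type", "pH", "ph"]]
    compound_cols = {}
    for c in other:
        try:
            compound_cols[c] = normalize_compound_code(c)
        except ValueError:
            logger.warning("ignoring unknown column %r", c)
    out = []
    for _, row in df.iterrows():
        indices = {c: float(row[c]) for c in index_cols if pd.notna(row[c])} or None
        abundances = {code: float(row[c]) for c, code in compound_cols.items()
                      if pd.notna(row[c])} or None
        tparams = {c: float(row[c]) for c in temp_cols if pd.notna(row[c])}
        ph = row.get("pH", row.get("ph", np.nan))
        out.append(EnvironmentalSample(
            sample_id=str(row["sample_id"]),
            sample_type=str(row["sample_type"]),
            abundances=abundances,
            indices=indices,
            temperature_params=tparams,
            ph=None if pd.isna(ph) else float(ph),
        ))
    return out


def write_environmental_table(samples: list[EnvironmentalSample], path) -> None:
    rows = []
    for s in samples:
        row: dict = {"sample_id": s.sample_id, "sample_type": s.sample_type}
        if s.ph is not None:
            row["pH"] = s.ph
        row.update(s.temperature_params)
        if s.indices:
            row.update(s.indices)
        if s.abundances:
            row.update(s.abundances)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_od_series(path_or_buf, meta: dict | None = None) -> GrowthCurve:
    """Read a two-column (time, od) CSV into a GrowthCurve.

    Rows are sorted by time and duplicate timestamps averaged; fewer than 4
    resulting points is rejected as unfittable.
    """
    df = pd.read_csv(path_or_buf)
    if df.shape[1] < 2:
        raise ValueError("need two numeric columns (time, od)")
    time_col, od_col = df.columns[:2]
    df = df[[time_col, od_col]].astype(float)
    df = df.groupby(time_col, sort=True, as_index=False).mean()
    if len(df) < 4:
        raise ValueError(f"unfittable: need >= 4 time points, got {len(df)}")
    return GrowthCurve(df[time_col].to_numpy(), df[od_col].to_numpy(), meta=meta or {})


def write_od_series(curve: GrowthCurve, path) -> None:
    pd.DataFrame({"time_days": curve.times, "od": curve.od}).to_csv(path, index=False)


def _round_sig(x, digits: int):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    if isinstance(x, (int, np.integer)) or not isinstance(x, (float, np.floating)):
        return x
    return float(f"{x:.{digits}g}")


def write_report(results, path, format: str = "csv", sig_digits: int = 6) -> None:
    """Write pipeline results (a list of row dicts or a DataFrame) to disk.

    Column order is deterministic (first-seen order), floats serialize with
    fixed significant digits, and the JSON form round-trips losslessly
    through ``json.load``.
    """
    if isinstance(results, pd.DataFrame):
        rows = results.to_dict(orient="records")
    else:
        rows = list(results)
    columns: list[str] = []
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)
    rounded = [{k: _round_sig(row.get(k), sig_digits) for k in columns} for row in rows]
    if format == "csv":
        df = pd.DataFrame(rounded, columns=columns)
        df.to_csv(path, index=False, float_format=f"%.{sig_digits}g")
    elif format == "json":
        clean = [
            {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
             for k, v in row.items()}
            for row in rounded
        ]
        with open(path, "w") as fh:
            json.dump(clean, fh, indent=2, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
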