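"""End-to-end analysis: indices per replicate, growth summaries, subset
correlations/regressions, filters, and coincidence tests against
environmental calibrations, emitted as a three-panel report (correlations /
regressions-for-significant-correlations / culture-vs-environment
comparisons)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as idx
from .growth import fit_logistic
from .samples import CultureSample, EnvironmentalSample, GrowthCurve
from .stats import (
    coincidence_test,
    filter_saturated,
    multiple_ols,
    ols_fit,
    pearson_test,
    remove_rmse_outliers,
    subset_analysis,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "culture_index_table"]

logger = logging.getLogger(__name__)

#: Designated regression parameter per environmental sample type (index -> x).
ENV_PARAMETER_DEFAULTS = {
    ("bone", idx.MBT_NAME): "WMT",
    ("lacustrine_sediment", idx.MBT_NAME): "MAF",
    ("lacustrine_SPM", idx.MBT_NAME): "water_temp",
    ("marine_sediment", idx.MBT_NAME): "SST",
    ("peat", idx.MBT_NAME): "WMT",
    ("soil", idx.MBT_NAME): "WMT",
    ("bone", idx.CBT_NAME): "pH",
    ("lacustrine_sediment", idx.CBT_NAME): "pH",
    ("lacustrine_SPM", idx.CBT_NAME): "pH",
    ("marine_sediment", idx.CBT_NAME): "pH",
    ("peat", idx.CBT_NAME): "pH",
    ("soil", idx.CBT_NAME): "pH",
}

#: Culture-side regression parameter used when comparing to an environmental
#: temperature parameter (any registered temperature name maps to the culture
#: growth temperature).
_CULTURE_X = {"pH": "pH"}


@dataclass
class AnalysisConfig:
    """Configuration of the full analysis run."""

    indices: tuple[str, ...] = (idx.MBT_NAME, idx.CBT_NAME)
    parameters: tuple[str, ...] = ("temperature", "growth_rate", "pH", "o2")
    alpha: float = 0.05
    replicate_mode: str = "replicates"  # or "means"
    saturation_filter_indices: tuple[str, ...] = (idx.MBT_NAME,)
    saturation_value: float = 1.0
    rmse_outlier_k: float = 3.0
    apply_rmse_outliers_env: bool = True
    #: temperature subsets get per-T correlations for these (index, parameter)
    per_temperature: tuple[tuple[str, str], ...] = (
        (idx.MBT_NAME, "growth_rate"),
        (idx.MBT_NAME, "pH"),
    )
    o2_subset_condition: tuple[float, float] = (25.0, 5.5)
    env_parameters: dict = field(default_factory=lambda: dict(ENV_PARAMETER_DEFAULTS))


@dataclass
class AnalysisReport:
    indices: pd.DataFrame
    panel_a: pd.DataFrame
    panel_b: pd.DataFrame
    env_fits: pd.DataFrame
    panel_c: pd.DataFrame
    growth: pd.DataFrame
    multivariable: pd.DataFrame

    def rows(self) -> list[dict]:
        """Flatten all panels into report rows (for write_report)."""
        out = []
        for panel, df in (
            ("A", self.panel_a), ("B", self.panel_b), ("env", self.env_fits),
            ("C", self.panel_c), ("growth", self.growth),
            ("multivariable", self.multivariable),
        ):
            for rec in df.to_dict(orient="records"):
                out.append({"panel": panel, **rec})
        return out


def culture_index_table(samples: list[CultureSample]) -> pd.DataFrame:
    """Per-replicate table of condition metadata and all computed indices."""
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "temperature": s.temperature,
            "pH": s.ph,
            "o2": s.o2,
            "replicate": s.replicate,
            "growth_rate": s.growth_rate,
        }
        for name, iv in idx.compute_all_indices(s.profile).items():
            row[name] = iv.value if iv.defined else np.nan
            row[f"{name}__defined"] = iv.defined
        try:
            meth = idx.structural_set_fractions(s.profile, "Meth")
            row["fIa_Meth"] = meth.get("Ia")
            row["fIb_Meth"] = meth.get("Ib")
        except ValueError:
            row["fIa_Meth"] = row["fIb_Meth"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _env_xy(samples: list[EnvironmentalSample], index_name: str, parameter: str):
    xs, ys = [], []
    for s in samples:
        if s.indices and index_name in s.indices:
            y = s.indices[index_name]
        else:
            continue  # abundance-only environmental inputs need precomputed indices
        x = s.ph if parameter == "pH" else s.temperature_params.get(parameter)
        if x is None:
            continue
        xs.append(x)
        ys.append(y)
    return np.asarray(xs, dtype=float), np.asarray(ys, dtype=float)


def _condition_means(table: pd.DataFrame) -> pd.DataFrame:
    keys = ("temperature", "pH", "o2")
    value_cols = [
        c for c in table.columns
        if table[c].dtype.kind == "f" and not c.endswith("__defined") and c not in keys
    ]
    return table.groupby(["temperature", "pH", "o2"], as_index=False)[value_cols].mean()


def _culture_subsets(table: pd.DataFrame, config: AnalysisConfig) -> dict[str, np.ndarray]:
    subs: dict[str, np.ndarray] = {"all": np.ones(len(table), dtype=bool)}
    for t in sorted(table["temperature"].unique()):
        subs[f"{t:g}C"] = (table["temperature"] == t).to_numpy()
    t0, p0 = config.o2_subset_condition
    subs["O2"] = ((table["temperature"] == t0) & (table["pH"] == p0)).to_numpy()
    return subs


def _plan(config: AnalysisConfig, subsets: dict[str, np.ndarray]):
    """(index, parameter, subset) triples mirroring the report layout."""
    per_t = [k for k in subsets if k.endswith("C") and k != "all"]
    plan = []
    for index_name in config.indices:
        for parameter in config.parameters:
            if parameter == "o2":
                plan.append((index_name, "o2", "O2"))
                continue
            plan.append((index_name, parameter, "all"))
            if (index_name, parameter) in config.per_temperature:
                plan.extend((index_name, parameter, s) for s in per_t)
    return plan


_PARAM_COL = {"temperature": "temperature", "pH": "pH", "o2": "o2", "growth_rate": "growth_rate"}


def run_analysis(
    culture_samples: list[CultureSample],
    env_datasets: dict[str, list[EnvironmentalSample]] | None = None,
    config: AnalysisConfig | None = None,
    od_curves: dict[str, GrowthCurve] | None = None,
) -> AnalysisReport:
    """Run the full analysis; deterministic for identical inputs and config."""
    config = config or AnalysisConfig()
    env_datasets = env_datasets or {}

    table = culture_index_table(culture_samples)
    stats_table = _condition_means(table) if config.replicate_mode == "means" else table

    # panels A and B: culture correlations, regressions where significant
    subsets = _culture_subsets(stats_table, config)
    rows_a, rows_b = [], []
    for index_name, parameter, subset in _plan(config, subsets):
        x = stats_table[_PARAM_COL[parameter]].to_numpy(dtype=float)
        y = stats_table[index_name].to_numpy(dtype=float)
        mask = subsets[subset].copy()
        if index_name in config.saturation_filter_indices:
            mask &= filter_saturated(y, config.saturation_value)
        res = subset_analysis(x, y, {subset: mask}, alpha=config.alpha)[subset]
        base = {"dataset": "culture", "index": index_name,
                "parameter": parameter, "subset": subset}
        if not res["evaluable"]:
            rows_a.append({**base, "n": res["n"], "r": np.nan, "p": np.nan,
                           "significant": False, "evaluable": False})
            continue
        corr = res["correlation"]
        rows_a.append({**base, "n": corr.n, "r": corr.r, "p": corr.p,
                       "significant": corr.p < config.alpha, "evaluable": True})
        reg = res["regression"]
        if reg is not None:
            rows_b.append({**base, "n": reg.n, "slope": reg.slope,
                           "slope_se": reg.slope_se, "intercept": reg.intercept,
                           "intercept_se": reg.intercept_se, "r2": reg.r2,
                           "rmse": reg.rmse, "p_slope": reg.p_slope})

    # environmental fits and panel C coincidence comparisons
    rows_env, rows_c = [], []
    for name in sorted(env_datasets):
        samples = env_datasets[name]
        sample_type = samples[0].sample_type if samples else name
        for index_name in config.indices:
            parameter = config.env_parameters.get((sample_type, index_name))
            if parameter is None:
                continue
            ex, ey = _env_xy(samples, index_name, parameter)
            if ex.size < 3:
                continue
            if index_name in config.saturation_filter_indices:
                keep = filter_saturated(ey, config.saturation_value)
                ex, ey = ex[keep], ey[keep]
            n_outliers = 0
            if config.apply_rmse_outliers_env and ex.size >= 4:
                ex, ey, removed = remove_rmse_outliers(ex, ey, config.rmse_outlier_k)
                n_outliers = len(removed)
            corr = pearson_test(ex, ey)
            env_row = {"dataset": name, "index": index_name, "parameter": parameter,
                       "n": corr.n, "n_outliers_removed": n_outliers,
                       "r": corr.r, "p": corr.p, "significant": corr.p < config.alpha}
            if corr.p < config.alpha:
                reg = ols_fit(ex, ey)
                env_row.update(slope=reg.slope, slope_se=reg.slope_se,
                               intercept=reg.intercept, intercept_se=reg.intercept_se,
                               r2=reg.r2)
            rows_env.append(env_row)

            # culture side: index vs temperature (for any temperature
            # parameter) or vs pH
            culture_param = _CULTURE_X.get(parameter, "temperature")
            cx = stats_table[_PARAM_COL[culture_param]].to_numpy(dtype=float)
            cy = stats_table[index_name].to_numpy(dtype=float)
            cmask = np.isfinite(cx) & np.isfinite(cy)
            if index_name in config.saturation_filter_indices:
                cmask &= filter_saturated(cy, config.saturation_value)
            if cmask.sum() < 3:
                continue
            co = coincidence_test(ex, ey, cx[cmask], cy[cmask], alpha=config.alpha)
            rows_c.append({
                "dataset": name, "index": index_name, "parameter": parameter,
                "culture_parameter": culture_param,
                "slope": co.slope, "intercept": co.intercept,
                "delta_slope": co.delta_slope, "delta_slope_se": co.delta_slope_se,
                "p_delta_slope": co.p_delta_slope,
                "delta_intercept": co.delta_intercept,
                "delta_intercept_se": co.delta_intercept_se,
                "p_delta_intercept": co.p_delta_intercept,
                "n_env": co.n_env, "n_culture": co.n_culture,
                "classification": "+".join(sorted(co.classification)),
            })

    # growth-curve summaries: per-replicate fits, then condition means
    rows_g = []
    if od_curves:
        meta = {s.sample_id: s for s in culture_samples}
        for sid in sorted(od_curves):
            fit = fit_logistic(od_curves[sid])
            s = meta.get(sid)
            rows_g.append({
                "sample_id": sid,
                "temperature": s.temperature if s else np.nan,
                "pH": s.ph if s else np.nan,
                "o2": s.o2 if s else np.nan,
                "K": fit.K, "mu": fit.mu, "n0": fit.n0, "rmse": fit.rmse,
                "doubling_time_days": (np.log(2) / fit.mu) if fit.converged else np.nan,
                "converged": fit.converged,
            })

    # multivariable check: does growth rate predict the methylation index
    # once temperature is controlled for?
    rows_m = []
    if idx.MBT_NAME in config.indices and "growth_rate" in config.parameters:
        y = stats_table[idx.MBT_NAME].to_numpy(dtype=float)
        keep = np.isfinite(y) & np.isfinite(stats_table["growth_rate"].to_numpy(dtype=float))
        if idx.MBT_NAME in config.saturation_filter_indices:
            keep &= filter_saturated(y, config.saturation_value)
        if keep.sum() > 4:
            coefs = multiple_ols(
                y[keep],
                {
                    "temperature": stats_table["temperature"].to_numpy(dtype=float)[keep],
                    "growth_rate": stats_table["growth_rate"].to_numpy(dtype=float)[keep],
                },
            )
            for pred, row in coefs.iterrows():
                rows_m.append({"index": idx.MBT_NAME, "predictor": pred,
                               "estimate": row["estimate"], "se": row["se"],
                               "p": row["p"]})

    return AnalysisReport(
        indices=table,
        panel_a=pd.DataFrame(rows_a),
        panel_b=pd.DataFrame(rows_b),
        env_fits=pd.DataFrame(rows_env),
        panel_c=pd.DataFrame(rows_c),
        growth=pd.DataFrame(rows_g),
        multivariable=pd.DataFrame(rows_m),
    )
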