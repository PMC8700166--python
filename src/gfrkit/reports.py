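"""Report assembly: benchmark-table evaluation and REC curves over cohorts.

Produces long-format tables (metric × equation × subgroup with bootstrap CI
columns) mirroring the layout of clinical eGFR validation tables, plus the
pairwise significance tests of every benchmark equation against a reference
equation, Benjamini-Hochberg adjusted within each performance indicator.
In-memory values are full precision; rounding is left to serialization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import equations as eqs
from . import metrics as met

__all__ = ["EGFR_RANGE_BINS", "prediction_pairs", "evaluate_cohort",
           "rec_curve_table"]

#: eGFR range bins used for per-range reporting (bin by the equation's own
#: estimate; right-open intervals).
EGFR_RANGE_BINS = ((0, 15, "<15"), (15, 30, "15-29"), (30, 60, "30-59"),
                   (60, 90, "60-89"), (90, np.inf, ">=90"))

_METRIC_UNITS = {"median_bias": "mL/min/1.73m2", "iqr_precision": "mL/min/1.73m2",
                 "mae": "mL/min/1.73m2", "rmsle": "1", "outside_p15": "%",
                 "outside_p20": "%", "outside_p30": "%"}


def prediction_pairs(df: pd.DataFrame, equation: str,
                     mgfr_col: str = "mgfr_ml_min_173") -> met.PairedPredictions:
    """Paired predictions for one equation; reuses a precomputed
    ``egfr_<equation>`` column when present."""
    col = f"egfr_{equation}"
    egfr = df[col].to_numpy(dtype=float) if col in df.columns \
        else eqs.estimate(df, equation)
    return met.PairedPredictions(egfr, df[mgfr_col].to_numpy(dtype=float),
                                 equation_id=equation,
                                 sample_ids=df["id"].to_numpy() if "id" in df.columns
                                 else None)


def _report_rows(pairs, subgroup, n_boot, seed):
    rows = []
    for r in met.metric_report(pairs, n_boot=n_boot, seed=seed, subgroup=subgroup):
        rows.append({"equation": r.equation_id, "subgroup": r.subgroup,
                     "metric": r.metric_id, "unit": _METRIC_UNITS[r.metric_id],
                     "estimate": r.estimate, "ci_low": r.ci_low,
                     "ci_high": r.ci_high, "n": r.n})
    return rows


def evaluate_cohort(df: pd.DataFrame, equations: list[str],
                    mgfr_col: str = "mgfr_ml_min_173", n_boot: int = 1000,
                    seed: int | None = None, group_by: str | None = None,
                    by_egfr_range: bool = False,
                    reference: str | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark equations on a cohort with measured GFR.

    Returns ``(metrics, comparisons)``: the long metric table (with
    percentile-bootstrap CIs), and the paired tests of each equation
    against the reference (default: the first listed), BH-adjusted across
    equations within each indicator.  ``group_by`` adds per-subgroup rows
    for a categorical column; ``by_egfr_range`` adds rows per eGFR range,
    each equation binned by its own estimate.
    """
    reference = reference or equations[0]
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(10_000))

    all_pairs = {eq: prediction_pairs(df, eq, mgfr_col) for eq in equations}
    rows = []
    for eq, pairs in all_pairs.items():
        rows += _report_rows(pairs, "overall", n_boot, int(next(seeds)))
        if group_by is not None:
            for level, sub in df.groupby(group_by, observed=True):
                rows += _report_rows(prediction_pairs(sub, eq, mgfr_col),
                                     f"{group_by}={level}", n_boot,
                                     int(next(seeds)))
        if by_egfr_range:
            for lo, hi, label in EGFR_RANGE_BINS:
                mask = (pairs.egfr >= lo) & (pairs.egfr < hi)
                if not mask.any():
                    continue
                rows += _report_rows(pairs.take(np.flatnonzero(mask)),
                                     f"egfr_range={label}", n_boot,
                                     int(next(seeds)))
    metrics_table = pd.DataFrame(rows)

    comp_rows = []
    others = [eq for eq in equations if eq != reference]
    for eq in others:
        ps = met.compare_equations(all_pairs[reference], all_pairs[eq],
                                   n_boot=n_boot, seed=int(next(seeds)))
        for kpi, p in ps.items():
            comp_rows.append({"reference": reference, "equation": eq,
                              "kpi": kpi.removeprefix("p_"), "p_raw": p})
    comparisons = pd.DataFrame(comp_rows)
    if not comparisons.empty:
        comparisons["p_adj"] = np.nan
        for kpi, grp in comparisons.groupby("kpi"):
            comparisons.loc[grp.index, "p_adj"] = met.bh_adjust(grp["p_raw"])
    return metrics_table, comparisons


def rec_curve_table(df: pd.DataFrame, equations: list[str],
                    grid=None, mgfr_col: str = "mgfr_ml_min_173") -> pd.DataFrame:
    """Px-vs-tolerance table for several equations on one cohort."""
    grid = np.arange(1.0, 51.0) if grid is None else np.asarray(grid, float)
    out = []
    for eq in equations:
        curve = met.rec_curve(prediction_pairs(df, eq, mgfr_col), grid)
        curve.insert(0, "equation", eq)
        out.append(curve)
    return pd.concat(out, ignore_index=True)
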