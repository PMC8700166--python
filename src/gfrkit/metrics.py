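"""Validation metrics for eGFR equations against tracer-measured GFR.

All metrics work on paired eGFR/mGFR vectors.  The error convention is
``d = eGFR − mGFR`` so that underestimation is negative.  Quantiles use the
type-7 linear-interpolation convention throughout.  Accuracy is reported as
1-Px: the percentage of samples whose estimate falls *outside* x% of
measured GFR (a deviation of exactly x% counts as within).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

__all__ = [
    "PairedPredictions",
    "MetricReport",
    "error_summary",
    "accuracy_outside",
    "rec_curve",
    "bootstrap_ci",
    "compare_equations",
    "bh_adjust",
    "metric_report",
]

log = logging.getLogger(__name__)

METRIC_IDS = ("median_bias", "iqr_precision", "mae", "rmsle",
              "outside_p15", "outside_p20", "outside_p30")


@dataclass
class PairedPredictions:
    """Aligned eGFR/mGFR vectors for one equation on one cohort."""

    egfr: np.ndarray
    mgfr: np.ndarray
    equation_id: str = ""
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.egfr = np.asarray(self.egfr, dtype=float)
        self.mgfr = np.asarray(self.mgfr, dtype=float)
        if self.egfr.shape != self.mgfr.shape or self.egfr.ndim != 1:
            raise ValueError("egfr and mgfr must be 1-d and equally long")
        if self.egfr.size == 0:
            raise ValueError("empty prediction set")
        if np.any(~(self.mgfr > 0)):
            raise ValueError("mGFR must be strictly positive")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.egfr.size)
        else:
            self.sample_ids = np.asarray(self.sample_ids)
            if self.sample_ids.shape != self.egfr.shape:
                raise ValueError("sample_ids misaligned")

    def __len__(self) -> int:
        return self.egfr.size

    @property
    def errors(self) -> np.ndarray:
        """Signed differences eGFR − mGFR (underestimation negative)."""
        return self.egfr - self.mgfr

    def take(self, idx) -> "PairedPredictions":
        return PairedPredictions(self.egfr[idx], self.mgfr[idx],
                                 self.equation_id, self.sample_ids[idx])


@dataclass
class MetricReport:
    """One metric's point estimate with an optional bootstrap CI."""

    metric_id: str
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0
    equation_id: str = ""
    subgroup: str = "overall"
    extras: dict = field(default_factory=dict)


def _as_pairs(pairs) -> PairedPredictions:
    if isinstance(pairs, PairedPredictions):
        return pairs
    egfr, mgfr = pairs
    return PairedPredictions(egfr, mgfr)


def error_summary(pairs) -> dict:
    """Median signed bias, IQR of the differences, MAE and RMSLE.

    Bias and IQR are in mL/min/1.73 m²; RMSLE uses ln(1+·).
    """
    p = _as_pairs(pairs)
    d = p.errors
    q1, q3 = np.quantile(d, [0.25, 0.75])  # type-7 interpolation (numpy default)
    with np.errstate(invalid="ignore"):  # RMSLE undefined for estimates <= -1
        logd = np.log1p(p.egfr) - np.log1p(p.mgfr)
    return {
        "median_bias": float(np.median(d)),
        "iqr_precision": float(q3 - q1),
        "mae": float(np.mean(np.abs(d))),
        "rmsle": float(np.sqrt(np.mean(logd ** 2))),
    }


def accuracy_outside(pairs, x: float) -> float:
    """1-Px: percentage of samples with |eGFR − mGFR| > x% of mGFR."""
    if not x > 0:
        raise ValueError("tolerance x must be positive")
    p = _as_pairs(pairs)
    outside = np.abs(p.errors) > (x / 100.0) * p.mgfr
    return float(100.0 * np.mean(outside))


def rec_curve(pairs, grid) -> pd.DataFrame:
    """Regression-error-characteristic curve: Px over a tolerance grid.

    Returns a DataFrame with columns ``tolerance_pct`` and ``within_pct``
    (Px = 100 − 1-Px), non-decreasing in the tolerance.
    """
    g = np.asarray(grid, dtype=float)
    if g.size == 0:
        raise ValueError("empty tolerance grid")
    if np.any(~(g > 0)) or np.any(np.diff(g) < 0):
        raise ValueError("grid must be positive and ascending")
    p = _as_pairs(pairs)
    within = [100.0 - accuracy_outside(p, x) for x in g]
    return pd.DataFrame({"tolerance_pct": g, "within_pct": within})


def bootstrap_ci(statistic, pairs, n_boot: int = 1000, seed: int | None = None,
                 alpha: float = 0.05) -> dict:
    """Percentile bootstrap CI of a statistic of paired predictions.

    Whole pairs are resampled with replacement; the CI is the (α/2, 1−α/2)
    percentile interval of the replicate statistics.  Replicates on which
    the statistic is undefined are skipped with a warning; more than 10%
    skipped is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    p = _as_pairs(pairs)
    rng = np.random.default_rng(seed)
    n = len(p)
    reps = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = statistic(p.take(idx))
        except Exception:  # undefined on this resample (e.g. empty subgroup)
            reps[b] = np.nan
            skipped += 1
    if skipped:
        log.warning("bootstrap: %d/%d replicates skipped", skipped, n_boot)
        if skipped > 0.1 * n_boot:
            raise RuntimeError(f"bootstrap: {skipped}/{n_boot} replicates undefined")
    lo, hi = np.nanquantile(reps, [alpha / 2, 1 - alpha / 2])
    return {"estimate": float(statistic(p)), "ci_low": float(lo), "ci_high": float(hi)}


def _wilcoxon_p(diffs: np.ndarray) -> float:
    d = diffs[diffs != 0]
    if d.size == 0:
        log.warning("all paired differences zero; p = 1 by convention")
        return 1.0
    return float(stats.wilcoxon(d, alternative="two-sided").pvalue)


def mcnemar_p(flags_a: np.ndarray, flags_b: np.ndarray, exact: bool = False) -> float:
    """McNemar test on paired binary indicators (continuity-corrected χ²
    by default; exact binomial behind the flag)."""
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    if n01 + n10 == 0:
        log.warning("no discordant pairs; p = 1 by convention")
        return 1.0
    table = [[int(np.sum(a & b)), n01], [n10, int(np.sum(~a & ~b))]]
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.pvalue)


def compare_equations(pairs_a, pairs_b, n_boot: int = 1000,
                      seed: int | None = None, bias_on: str = "signed") -> dict:
    """Paired significance tests between two equations on identical samples.

    * bias — two-sided Wilcoxon signed-rank on per-sample signed-error
      differences (or on |error| differences with ``bias_on="absolute"``);
    * mae  — Wilcoxon on |error| differences;
    * p15/p20/p30 — McNemar on the paired within/outside indicators;
    * iqr  — two-sided percentile-bootstrap test on the IQR difference.
    """
    a, b = _as_pairs(pairs_a), _as_pairs(pairs_b)
    if len(a) != len(b) or not np.array_equal(a.sample_ids, b.sample_ids):
        raise ValueError("compared predictions must cover identical samples")
    if not np.array_equal(a.mgfr, b.mgfr):
        raise ValueError("mGFR vectors differ between the two prediction sets")

    da, db = a.errors, b.errors
    bias_diff = (da - db) if bias_on == "signed" else (np.abs(da) - np.abs(db))
    out = {
        "p_bias": _wilcoxon_p(bias_diff),
        "p_mae": _wilcoxon_p(np.abs(da) - np.abs(db)),
    }
    for x in (15, 20, 30):
        tol = (x / 100.0) * a.mgfr
        out[f"p_p{x}"] = mcnemar_p(np.abs(da) > tol, np.abs(db) > tol)

    # bootstrap test on the IQR difference: doubled one-sided crossing fraction
    rng = np.random.default_rng(seed)
    n = len(a)
    point = (error_summary(a)["iqr_precision"] - error_summary(b)["iqr_precision"])
    if point == 0:
        out["p_iqr"] = 1.0
        return out
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        qa = np.quantile(da[idx], [0.25, 0.75])
        qb = np.quantile(db[idx], [0.25, 0.75])
        reps[i] = (qa[1] - qa[0]) - (qb[1] - qb[0])
    crossing = np.mean(reps <= 0) if point > 0 else np.mean(reps >= 0)
    out["p_iqr"] = float(min(1.0, 2.0 * crossing))
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def metric_report(pairs, n_boot: int = 1000, seed: int | None = None,
                  subgroup: str = "overall") -> list[MetricReport]:
    """All standard metrics with bootstrap CIs for one prediction set."""
    p = _as_pairs(pairs)
    stats_fns = {
        "median_bias": lambda q: error_summary(q)["median_bias"],
        "iqr_precision": lambda q: error_summary(q)["iqr_precision"],
        "mae": lambda q: error_summary(q)["mae"],
        "rmsle": lambda q: error_summary(q)["rmsle"],
        "outside_p15": lambda q: accuracy_outside(q, 15),
        "outside_p20": lambda q: accuracy_outside(q, 20),
        "outside_p30": lambda q: accuracy_outside(q, 30),
    }
    reports = []
    ss = np.random.SeedSequence(seed).spawn(len(stats_fns))
    for (mid, fn), child in zip(stats_fns.items(), ss):
        ci = bootstrap_ci(fn, p, n_boot=n_boot,
                          seed=np.random.default_rng(child))
        reports.append(MetricReport(metric_id=mid, estimate=ci["estimate"],
                                    ci_low=ci["ci_low"], ci_high=ci["ci_high"],
                                    n=len(p), equation_id=p.equation_id,
                                    subgroup=subgroup))
    return reports
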