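"""Seeded synthetic patient cohorts for exercising the toolkit end to end.

No patient-level data accompany the study this package operationalizes, so
every workflow is testable on generated cohorts that emulate the published
cohort marginals: mGFR ~ 67 ± 28 mL/min/1.73 m² truncated to (3, 183), age
~ 56 ± 14 years on (18, 88), ~55% male, BMI ~ 30 ± 6 kg/m².  Serum markers
follow lognormal links to mGFR with the observed directionality —
creatinine, cystatin C and myo-inositol fall with rising GFR, valine rises.
The link coefficients themselves are synthetic package choices (anchored so
typical healthy values appear near mGFR 90), NOT estimates from any study;
joint marker-mGFR distributions were never published.

A second generator draws markers independently and computes mGFR *from* the
piecewise estimating equation plus lognormal noise; cohorts built this way
have a known ground-truth structure and are what the parameter-recovery
tests fit against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equations import PiecewiseCoefficientTable, default_nmr_table, estimate_gfr_nmr

__all__ = [
    "GeneratorConfig",
    "default_marker_links",
    "generate_cohort",
    "generate_equation_cohort",
    "stratified_partition",
]

CANONICAL_COLUMNS = [
    "id", "age_years", "sex", "black", "height_cm", "weight_kg",
    "scr_umol_l", "scys_mg_l", "valine_umol_l", "myo_inositol_umol_l",
    "mgfr_ml_min_173", "tracer",
]

#: (healthy anchor value at mGFR 90 for males, slope on ln mGFR,
#:  additive male shift on the log scale, log-scale noise sd)
_LINK_ANCHORS = {
    "scr_umol_l": (80.0, -0.85, 0.18, 0.15),
    "scys_mg_l": (0.90, -0.75, 0.05, 0.12),
    "myo_inositol_umol_l": (30.0, -0.70, 0.00, 0.20),
    "valine_umol_l": (240.0, 0.15, 0.08, 0.12),
}


def default_marker_links() -> dict:
    """Per-marker lognormal link coefficients.

    ln(marker) = intercept + mgfr_log_slope·ln(mGFR) + sex_shift·male + ε,
    ε ~ N(0, noise_sd²).  Intercepts are derived from healthy-value anchors
    at mGFR = 90 (male): creatinine 80 µmol/L, cystatin C 0.9 mg/L,
    myo-inositol 30 µmol/L, valine 240 µmol/L.
    """
    links = {}
    for marker, (anchor, slope, shift, noise) in _LINK_ANCHORS.items():
        links[marker] = {
            "intercept": float(np.log(anchor) - slope * np.log(90.0) - shift),
            "mgfr_log_slope": slope,
            "sex_shift": shift,
            "noise_sd": noise,
        }
    return links


@dataclass
class GeneratorConfig:
    """Cohort generator settings (defaults emulate the published marginals)."""

    n: int = 600
    seed: int = 0
    mgfr_mean: float = 67.0
    mgfr_sd: float = 28.0
    mgfr_range: tuple[float, float] = (3.0, 183.0)
    age_mean: float = 56.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (18.0, 88.0)
    male_fraction: float = 0.55
    black_fraction: float = 0.025
    bmi_mean: float = 30.0
    bmi_sd: float = 6.0
    bmi_range: tuple[float, float] = (16.0, 58.0)
    liver_disease_fraction: float = 0.15
    marker_links: dict = field(default_factory=default_marker_links)
    max_rejection_rounds: int = 1000

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("mgfr_sd", "age_sd", "bmi_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mgfr_range", "age_range", "bmi_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must lie in [0, 1]")
        for marker, link in self.marker_links.items():
            if link["noise_sd"] < 0:
                raise ValueError(f"{marker}: noise_sd must be non-negative")
        slopes = {m: l["mgfr_log_slope"] for m, l in self.marker_links.items()}
        for m in ("scr_umol_l", "scys_mg_l", "myo_inositol_umol_l"):
            if m in slopes and slopes[m] >= 0:
                raise ValueError(f"{m} must decrease with mGFR (negative slope)")
        if "valine_umol_l" in slopes and slopes["valine_umol_l"] <= 0:
            raise ValueError("valine_umol_l must increase with mGFR (positive slope)")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int, max_rounds: int) -> np.ndarray:
    """Rejection-sampled truncated normal; errors out past the resample cap."""
    out = np.empty(size)
    filled = 0
    for _ in range(max_rounds):
        draw = rng.normal(mean, sd, size=size - filled)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + ok.size] = ok
        filled += ok.size
        if filled == size:
            return out
    raise RuntimeError(
        f"truncated-normal rejection cap exceeded (mean={mean}, sd={sd}, "
        f"range=({lo}, {hi}))")


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate a canonical-schema cohort table, deterministic given the seed."""
    cfg = config or GeneratorConfig()
    if overrides:
        cfg = GeneratorConfig(**{**cfg.__dict__, **overrides})
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, cap = cfg.n, cfg.max_rejection_rounds

    mgfr = _truncated_normal(rng, cfg.mgfr_mean, cfg.mgfr_sd, *cfg.mgfr_range, n, cap)
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range, n, cap)
    male = rng.random(n) < cfg.male_fraction
    black = rng.random(n) < cfg.black_fraction
    # sex-specific stature; overall ~170 ± 10 cm
    height = np.where(male,
                      _truncated_normal(rng, 176.0, 8.0, 145.0, 205.0, n, cap),
                      _truncated_normal(rng, 164.0, 8.0, 140.0, 195.0, n, cap))
    bmi = _truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd, *cfg.bmi_range, n, cap)
    weight = bmi * (height / 100.0) ** 2

    df = pd.DataFrame({
        "id": [f"S{i:05d}" for i in range(n)],
        "age_years": age,
        "sex": np.where(male, "M", "F"),
        "black": black.astype(int),
        "height_cm": height,
        "weight_kg": weight,
    })
    for marker, link in cfg.marker_links.items():
        eps = rng.normal(0.0, link["noise_sd"], size=n)
        df[marker] = np.exp(link["intercept"]
                            + link["mgfr_log_slope"] * np.log(mgfr)
                            + link["sex_shift"] * male
                            + eps)
    df["mgfr_ml_min_173"] = mgfr
    df["tracer"] = "iothalamate"
    # inert stratification labels (no disease model behind them)
    df["liver_disease"] = (rng.random(n) < cfg.liver_disease_fraction).astype(int)
    df["indication"] = rng.choice(
        ["ckd_workup", "donor_eval", "transplant_followup"], size=n)
    return df


def generate_equation_cohort(n: int, seed: int, sigma_log: float = 0.1,
                             table: PiecewiseCoefficientTable | None = None
                             ) -> pd.DataFrame:
    """Cohort whose mGFR is generated *from* the piecewise equation.

    Markers and demographics are drawn independently from lognormal/uniform
    marginals spanning the clinical range (cystatin C straddles the sex
    cutoffs), then mGFR = equation(markers) · exp(ε), ε ~ N(0, σ_log²).
    Refitting the equation's structure on such a cohort must recover the
    generating exponents and bases.
    """
    tab = table or default_nmr_table()
    rng = np.random.default_rng(seed)
    male = rng.random(n) < 0.55
    sex = np.where(male, "M", "F")
    age = rng.uniform(20.0, 85.0, size=n)
    cys = np.exp(rng.normal(np.log(1.15), 0.40, size=n))
    cre = np.exp(rng.normal(np.log(95.0), 0.45, size=n))
    val = np.exp(rng.normal(np.log(230.0), 0.20, size=n))
    myo = np.exp(rng.normal(np.log(40.0), 0.45, size=n))

    true = estimate_gfr_nmr(age, sex, creatinine=cre, cystatin_c=cys,
                            valine=val, myo_inositol=myo, table=tab)
    mgfr = true * np.exp(rng.normal(0.0, sigma_log, size=n))
    return pd.DataFrame({
        "id": [f"E{i:05d}" for i in range(n)],
        "age_years": age,
        "sex": sex,
        "black": 0,
        "scr_umol_l": cre,
        "scys_mg_l": cys,
        "valine_umol_l": val,
        "myo_inositol_umol_l": myo,
        "mgfr_ml_min_173": mgfr,
    })


def stratified_partition(cohort: pd.DataFrame, fractions: tuple[float, float, float],
                         strata: list[str] | None = None, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a cohort into three disjoint sets, stratified on columns.

    Within every stratum cell rows are shuffled (seeded) and allocated in
    the given proportions with largest-remainder rounding, so per-cell set
    sizes deviate from the targets by at most one row.  The union is the
    input, the parts are pairwise disjoint.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ValueError("fractions must be three non-negative numbers summing to 1")
    if len(cohort) == 0:
        return cohort.copy(), cohort.copy(), cohort.copy()
    strata = strata or []
    for col in strata:
        if col not in cohort.columns:
            raise KeyError(f"unknown stratum column '{col}'")

    rng = np.random.default_rng(seed)
    parts: list[list[pd.DataFrame]] = [[], [], []]
    groups = cohort.groupby(strata, sort=True, observed=True) if strata \
        else [((), cohort)]
    for _, cell in groups:
        idx = rng.permutation(cell.index.to_numpy())
        m = idx.size
        exact = fr * m
        base = np.floor(exact).astype(int)
        rem = exact - base
        for k in np.argsort(-rem, kind="stable")[: m - base.sum()]:
            base[k] += 1
        bounds = np.cumsum(base)
        chunks = np.split(idx, bounds[:-1])
        for part, chunk in zip(parts, chunks):
            part.append(cell.loc[chunk])
    out = []
    for part in parts:
        df = pd.concat(part) if part else cohort.iloc[0:0]
        out.append(df.sort_index())
    return tuple(out)
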