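"""Serum-marker GFR estimating equations.

Implements the metabolite-constellation equation ``gfr_nmr`` (myo-inositol,
valine, creatinine and cystatin C plus age and sex, piecewise by sex and a
sex-specific cystatin C cutoff) together with the benchmark equations it is
compared against: the CKD-EPI 2009 creatinine, CKD-EPI 2012 cystatin C,
CKD-EPI 2012 creatinine-cystatin C, and EKFC creatinine equations.  All
coefficients live in versioned YAML documents under ``gfrkit/data/equations``
so printed values are data, not code.

Unit conventions
----------------
Creatinine, valine and myo-inositol are serum concentrations in µmol/L;
cystatin C in mg/L; age in years; all outputs in mL/min/1.73 m².  The
benchmark equations are published with creatinine in mg/dL and convert
internally (1 mg/dL = 88.42 µmol/L).  Every equation returns unrounded
floats; rounding happens only in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "UMOL_PER_MG_DL",
    "EQUATION_IDS",
    "GfrInputError",
    "MissingMarkerError",
    "PatientSample",
    "PiecewiseCoefficientTable",
    "load_equation_config",
    "convert_creatinine",
    "dubois_bsa",
    "normalize_clearance",
    "estimate_gfr_nmr",
    "estimate_ckd_epi",
    "estimate_ekfc",
    "estimate",
    "add_estimates",
]

#: µmol of creatinine per mg (molar mass 113.12 g/mol).
UMOL_PER_MG_DL = 88.42

EQUATION_IDS = ("gfr_nmr", "ckd_epi_2009", "ckd_epi_cys", "ckd_epi_2012", "ekfc")

#: Canonical cohort column backing each equation input.
_MARKER_COLUMNS = {
    "creatinine": "scr_umol_l",
    "cystatin_c": "scys_mg_l",
    "valine": "valine_umol_l",
    "myo_inositol": "myo_inositol_umol_l",
}


class GfrInputError(ValueError):
    """Invalid equation input (non-positive concentration, bad unit, ...)."""


class MissingMarkerError(GfrInputError):
    """A marker required by the requested equation is absent."""

    def __init__(self, marker: str, equation: str = ""):
        self.marker = marker
        where = f" required by {equation}" if equation else ""
        super().__init__(f"missing marker '{marker}'{where}")


def _load_yaml(name: str) -> dict:
    path = resources.files("gfrkit.data.equations").joinpath(f"{name}.yaml")
    return yaml.safe_load(path.read_text())


def load_equation_config(name: str) -> dict:
    """Return the shipped coefficient document for one equation."""
    aliases = {
        "gfr_nmr": "gfr_nmr",
        "ckd_epi_2009": "ckd_epi_2009",
        "ckd_epi_cys": "ckd_epi_cys_2012",
        "ckd_epi_2012": "ckd_epi_crcys_2012",
        "ekfc": "ekfc",
    }
    try:
        return _load_yaml(aliases[name])
    except KeyError:
        raise KeyError(f"unknown equation '{name}'; known: {sorted(aliases)}") from None


@dataclass
class PatientSample:
    """One subject's demographics, anthropometrics and serum markers.

    Concentrations: creatinine, valine, myo_inositol in µmol/L, cystatin_c
    in mg/L.  ``mgfr`` is the tracer-measured GFR in mL/min/1.73 m² when
    available.  Markers not measured are ``None``.
    """

    id: str
    age: float
    sex: str  # "female" | "male"
    black: bool = False
    height: float | None = None  # cm
    weight: float | None = None  # kg
    creatinine: float | None = None
    cystatin_c: float | None = None
    valine: float | None = None
    myo_inositol: float | None = None
    mgfr: float | None = None
    tracer: str = "none"

    def __post_init__(self) -> None:
        sex = str(self.sex).strip().lower()
        if sex in {"f", "female"}:
            self.sex = "female"
        elif sex in {"m", "male"}:
            self.sex = "male"
        else:
            raise GfrInputError(f"sex must be female/male, got {self.sex!r}")
        if self.age <= 0:
            raise GfrInputError("age must be positive")
        if self.age < 18:
            warnings.warn(
                f"sample {self.id}: age {self.age} < 18; equations were developed on adults",
                stacklevel=2,
            )
        for name in ("height", "weight", "creatinine", "cystatin_c", "valine",
                     "myo_inositol", "mgfr"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise GfrInputError(f"{name} must be strictly positive, got {v}")


@dataclass
class PiecewiseCoefficientTable:
    """Branch table of a piecewise power-law GFR equation.

    ``branches`` carries one entry per (sex, cutoff side) with its intercept
    and pivot-marker exponent; ``shared`` carries the exponents and decay
    bases common to all branches (creatinine/valine exponents, per-µmol/L
    myo-inositol base and per-year age base).
    """

    branches: list[dict] = field(default_factory=list)
    shared: dict = field(default_factory=dict)
    pivot_marker: str = "cystatin_c"

    @classmethod
    def from_config(cls, doc: Mapping) -> "PiecewiseCoefficientTable":
        tab = cls(branches=[dict(b) for b in doc["branches"]],
                  shared=dict(doc["shared"]),
                  pivot_marker=doc.get("pivot_marker", "cystatin_c"))
        tab.validate()
        return tab

    def validate(self) -> None:
        if len({(b["sex"], b["side"]) for b in self.branches}) != len(self.branches):
            raise ValueError("duplicate (sex, side) branch")
        for key in ("myo_inositol_base", "age_base"):
            if not 0 < self.shared[key] <= 1:
                raise ValueError(f"{key} must lie in (0, 1]")

    def branch(self, sex: str, at_or_above: bool) -> dict:
        side = "at_or_above" if at_or_above else "below"
        for b in self.branches:
            if b["sex"] == sex and b["side"] == side:
                return b
        raise KeyError(f"no branch for sex={sex}, side={side}")

    def cutoff(self, sex: str) -> float:
        return self.branch(sex, True)["cutoff"]


_DEFAULT_NMR_TABLE: PiecewiseCoefficientTable | None = None


def default_nmr_table() -> PiecewiseCoefficientTable:
    global _DEFAULT_NMR_TABLE
    if _DEFAULT_NMR_TABLE is None:
        _DEFAULT_NMR_TABLE = PiecewiseCoefficientTable.from_config(
            load_equation_config("gfr_nmr"))
    return _DEFAULT_NMR_TABLE


# ---------------------------------------------------------------------------
# plumbing: units, body surface area
# ---------------------------------------------------------------------------

def convert_creatinine(value, from_unit: str):
    """Convert serum creatinine to µmol/L.

    ``from_unit`` is ``"mg_dl"`` (multiplied by 88.42) or ``"umol_l"``
    (identity).  Values must be strictly positive.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(~(arr > 0)):
        raise GfrInputError("creatinine must be strictly positive")
    if from_unit == "mg_dl":
        out = arr * UMOL_PER_MG_DL
    elif from_unit == "umol_l":
        out = arr.copy()
    else:
        raise GfrInputError(f"unknown creatinine unit {from_unit!r}")
    return float(out) if np.isscalar(value) else out


def dubois_bsa(height, weight):
    """Dubois body surface area in m²: 0.007184 · height^0.725 · weight^0.425.

    Height in cm, weight in kg, both strictly positive.
    """
    h = np.asarray(height, dtype=float)
    w = np.asarray(weight, dtype=float)
    if np.any(~(h > 0)) or np.any(~(w > 0)):
        raise GfrInputError("height and weight must be strictly positive")
    out = 0.007184 * h ** 0.725 * w ** 0.425
    return float(out) if np.isscalar(height) and np.isscalar(weight) else out


def normalize_clearance(raw_clearance, bsa):
    """Rescale a raw clearance (mL/min) to the 1.73 m² reference body surface."""
    b = np.asarray(bsa, dtype=float)
    if np.any(~(b > 0)):
        raise GfrInputError("body surface area must be strictly positive")
    out = np.asarray(raw_clearance, dtype=float) * 1.73 / b
    return float(out) if np.isscalar(raw_clearance) and np.isscalar(bsa) else out


# ---------------------------------------------------------------------------
# input validation helpers
# ---------------------------------------------------------------------------

def _female_mask(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind == "b":  # boolean meaning "is female" is ambiguous; refuse
        raise GfrInputError("sex must be given as 'F'/'M' or 'female'/'male'")
    low = np.char.lower(s.astype(str))
    female = np.isin(low, ("f", "female"))
    male = np.isin(low, ("m", "male"))
    if not np.all(female | male):
        bad = np.unique(s[~(female | male)])
        raise GfrInputError(f"unrecognized sex labels: {bad.tolist()}")
    return female


def _require(values, marker: str, equation: str) -> np.ndarray:
    if values is None:
        raise MissingMarkerError(marker, equation)
    arr = np.asarray(values, dtype=float)
    if np.any(np.isnan(arr)):
        raise MissingMarkerError(marker, equation)
    if np.any(~(arr > 0)):
        raise GfrInputError(f"{marker} must be strictly positive")
    return arr


# ---------------------------------------------------------------------------
# the equations
# ---------------------------------------------------------------------------

def estimate_gfr_nmr(age, sex, creatinine=None, cystatin_c=None, valine=None,
                     myo_inositol=None, table: PiecewiseCoefficientTable | None = None):
    """Metabolite-constellation eGFR (mL/min/1.73 m²).

    ``intercept × cysC^e_cys × creat^e_cr × valine^e_val × b_myo^myo × b_age^age``
    with the intercept and cystatin C exponent selected by sex and by the
    sex-specific cystatin C cutoff (1.02 mg/L female, 1.22 mg/L male); a
    value exactly at the cutoff takes the upper branch.  Creatinine, valine,
    myo-inositol in µmol/L; cystatin C in mg/L.
    """
    tab = table or default_nmr_table()
    eq = "gfr_nmr"
    cys = _require(cystatin_c, "cystatin_c", eq)
    cre = _require(creatinine, "creatinine", eq)
    val = _require(valine, "valine", eq)
    myo = _require(myo_inositol, "myo_inositol", eq)
    a = np.asarray(age, dtype=float)
    female = _female_mask(sex)

    cys, cre, val, myo, a, female = np.broadcast_arrays(cys, cre, val, myo, a, female)
    sh = tab.shared
    intercept = np.empty_like(cys)
    e_cys = np.empty_like(cys)
    for is_female in (True, False):
        sx = "female" if is_female else "male"
        cut = tab.cutoff(sx)
        for upper in (False, True):
            b = tab.branch(sx, upper)
            m = (female == is_female) & ((cys >= cut) == upper)
            intercept[m] = b["intercept"]
            e_cys[m] = b["pivot_exponent"]

    out = (intercept
           * cys ** e_cys
           * cre ** sh["creatinine_exponent"]
           * val ** sh["valine_exponent"]
           * sh["myo_inositol_base"] ** myo
           * sh["age_base"] ** a)
    return float(out) if out.ndim == 0 else out


def estimate_ckd_epi(age, sex, creatinine=None, cystatin_c=None, black=False,
                     variant: str = "cr2009"):
    """CKD-EPI eGFR: ``cr2009`` (creatinine), ``cys2012`` (cystatin C) or
    ``crcys2012`` (both).  Creatinine is taken in µmol/L and converted to
    mg/dL internally; cystatin C in mg/L."""
    a = np.asarray(age, dtype=float)
    female = _female_mask(sex)
    blk = np.broadcast_to(np.asarray(black, dtype=bool), female.shape)

    if variant == "cr2009":
        cfg = load_equation_config("ckd_epi_2009")
        scr = _require(creatinine, "creatinine", "ckd_epi_2009") / UMOL_PER_MG_DL
        scr, a, female, blk = np.broadcast_arrays(scr, a, female, blk)
        kappa = np.where(female, cfg["kappa"]["female"], cfg["kappa"]["male"])
        alpha = np.where(female, cfg["alpha"]["female"], cfg["alpha"]["male"])
        r = scr / kappa
        out = (cfg["intercept"]
               * np.minimum(r, 1.0) ** alpha
               * np.maximum(r, 1.0) ** cfg["max_exponent"]
               * cfg["age_base"] ** a
               * np.where(female, cfg["female_factor"], 1.0)
               * np.where(blk, cfg["black_factor"], 1.0))
    elif variant == "cys2012":
        cfg = load_equation_config("ckd_epi_cys")
        cys = _require(cystatin_c, "cystatin_c", "ckd_epi_cys")
        cys, a, female = np.broadcast_arrays(cys, a, female)
        r = cys / cfg["knot"]
        out = (cfg["intercept"]
               * np.minimum(r, 1.0) ** cfg["min_exponent"]
               * np.maximum(r, 1.0) ** cfg["max_exponent"]
               * cfg["age_base"] ** a
               * np.where(female, cfg["female_factor"], 1.0))
    elif variant == "crcys2012":
        cfg = load_equation_config("ckd_epi_2012")
        scr = _require(creatinine, "creatinine", "ckd_epi_2012") / UMOL_PER_MG_DL
        cys = _require(cystatin_c, "cystatin_c", "ckd_epi_2012")
        scr, cys, a, female, blk = np.broadcast_arrays(scr, cys, a, female, blk)
        kappa = np.where(female, cfg["kappa"]["female"], cfg["kappa"]["male"])
        alpha = np.where(female, cfg["alpha"]["female"], cfg["alpha"]["male"])
        rc = scr / kappa
        ry = cys / cfg["cys_knot"]
        out = (cfg["intercept"]
               * np.minimum(rc, 1.0) ** alpha
               * np.maximum(rc, 1.0) ** cfg["cr_max_exponent"]
               * np.minimum(ry, 1.0) ** cfg["cys_min_exponent"]
               * np.maximum(ry, 1.0) ** cfg["cys_max_exponent"]
               * cfg["age_base"] ** a
               * np.where(female, cfg["female_factor"], 1.0)
               * np.where(blk, cfg["black_factor"], 1.0))
    else:
        raise GfrInputError(f"unknown CKD-EPI variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def _ekfc_q_mg_dl(age: np.ndarray, female: np.ndarray, cfg: dict) -> np.ndarray:
    """Sex- (and below 25, age-) specific creatinine rescaling constant Q."""
    q = np.where(female, cfg["adult_q_mg_dl"]["female"], cfg["adult_q_mg_dl"]["male"])
    young = age < cfg["adult_age"]
    if np.any(young):
        q = np.array(q, dtype=float)
        for sx, is_f in (("female", True), ("male", False)):
            m = young & (female == is_f)
            if np.any(m):
                c0, c1, c2, c3, c4 = cfg["young_lnq_poly"][sx]
                a = age[m]
                lnq = c0 + c1 * a + c2 * np.log(a) + c3 * a ** 2 + c4 * a ** 3
                q[m] = np.exp(lnq) / UMOL_PER_MG_DL  # polynomial gives µmol/L
    return q


def estimate_ekfc(age, sex, creatinine=None):
    """EKFC creatinine eGFR: ``107.3 / (Scr/Q)^α``, α = 0.322 for Scr/Q < 1
    else 1.132, times 0.990^(age−40) above age 40.  Q is the sex-specific
    median creatinine of healthy adults (0.70 / 0.90 mg/dL) with an
    age-dependent value below 25."""
    cfg = load_equation_config("ekfc")
    scr = _require(creatinine, "creatinine", "ekfc") / UMOL_PER_MG_DL
    a = np.asarray(age, dtype=float)
    female = _female_mask(sex)
    scr, a, female = np.broadcast_arrays(scr, a, female)

    q = _ekfc_q_mg_dl(a, female, cfg)
    r = scr / q
    alpha = np.where(r < 1.0, cfg["alpha_low"], cfg["alpha_high"])
    age_factor = np.where(a > cfg["age_knot"],
                          cfg["age_base"] ** (a - cfg["age_knot"]), 1.0)
    out = cfg["intercept"] * r ** -alpha * age_factor
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dispatch over cohort tables
# ---------------------------------------------------------------------------

def estimate(df, equation: str):
    """Evaluate one equation over a canonical cohort DataFrame.

    Expects the canonical columns ``age_years``, ``sex`` and the marker
    columns the equation needs (``scr_umol_l``, ``scys_mg_l``,
    ``valine_umol_l``, ``myo_inositol_umol_l``, optional ``black``).
    Returns a numpy array aligned with the frame.
    """
    def col(marker):
        name = _MARKER_COLUMNS[marker]
        if name not in df.columns:
            raise MissingMarkerError(marker, equation)
        return df[name].to_numpy(dtype=float)

    age = df["age_years"].to_numpy(dtype=float)
    sex = df["sex"].to_numpy()
    black = df["black"].to_numpy(dtype=bool) if "black" in df.columns else False

    if equation == "gfr_nmr":
        return estimate_gfr_nmr(age, sex, creatinine=col("creatinine"),
                                cystatin_c=col("cystatin_c"), valine=col("valine"),
                                myo_inositol=col("myo_inositol"))
    if equation == "ckd_epi_2009":
        return estimate_ckd_epi(age, sex, creatinine=col("creatinine"),
                                black=black, variant="cr2009")
    if equation == "ckd_epi_cys":
        return estimate_ckd_epi(age, sex, cystatin_c=col("cystatin_c"),
                                variant="cys2012")
    if equation == "ckd_epi_2012":
        return estimate_ckd_epi(age, sex, creatinine=col("creatinine"),
                                cystatin_c=col("cystatin_c"), black=black,
                                variant="crcys2012")
    if equation == "ekfc":
        return estimate_ekfc(age, sex, creatinine=col("creatinine"))
    raise KeyError(f"unknown equation '{equation}'; known: {EQUATION_IDS}")


def add_estimates(df, equations: Iterable[str]):
    """Return a copy of the cohort with one ``egfr_<id>`` column per equation."""
    out = df.copy()
    for eq in equations:
        out[f"egfr_{eq}"] = estimate(df, eq)
    return out
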