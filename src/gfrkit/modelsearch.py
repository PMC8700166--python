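"""Equation-development machinery.

The search space is every linear model over a pool of serum markers where
each marker may enter raw or natural-log transformed, subject to four
structural constraints:

1. a model has two to five features;
2. at most one feature is an interaction (a product of two transformed
   markers of distinct parameters);
3. an interaction must anchor on a parameter already present as a main
   effect;
4. no parameter may appear under two different transforms anywhere in the
   model.

Each admissible formula is trained by OLS with the measured GFR either raw
or log-transformed as response (two response variants per formula
structure), predictions are back-transformed to the GFR scale before any
performance indicator is computed, and candidates are screened by a
configurable ordered rule pipeline (error/accuracy thresholds,
cross-validation stability, upper-range reach, residual heteroscedasticity,
redundancy pruning).  Surviving candidates can be refined into piecewise
(sex- and cutoff-dependent) equations and compared by Vuong's
log-likelihood test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations, product
from math import comb
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import RepeatedKFold

__all__ = [
    "Feature",
    "FeaturePool",
    "SearchConstraints",
    "ModelFormula",
    "TrainedCandidate",
    "PiecewiseBranch",
    "PiecewiseCandidate",
    "validate_formula",
    "enumerate_formulas",
    "count_formulas",
    "fit_formula",
    "cross_validate",
    "default_filter_rules",
    "apply_filters",
    "engineer_piecewise",
    "vuong_test",
    "FilterConfigError",
]

TRANSFORMS = ("raw", "log")

#: Default marker pool: nine NMR metabolites plus immunoassay cystatin C.
DEFAULT_PARAMETERS = (
    "creatinine", "creatine", "dimethylamine", "dimethyl_sulfone", "glycerol",
    "isoleucine", "leucine", "myo_inositol", "valine", "cystatin_c",
)

Feature = tuple[str, str]  # (parameter/column name, transform)


class FilterConfigError(ValueError):
    """A filter rule references an unknown field or comparator."""


@dataclass(frozen=True)
class FeaturePool:
    """Markers available to the search; each may enter raw or log."""

    parameters: tuple[str, ...] = DEFAULT_PARAMETERS
    transforms: tuple[str, ...] = TRANSFORMS

    def __post_init__(self):
        if len(set(self.parameters)) != len(self.parameters):
            raise ValueError("duplicate parameter names in pool")

    @property
    def n_features(self) -> int:
        return len(self.parameters) * len(self.transforms)


@dataclass(frozen=True)
class SearchConstraints:
    """Toggles for the four structural constraints."""

    min_features: int = 2
    max_features: int = 5
    allow_interactions: bool = True
    allow_self_interaction: bool = False  # squares, for sensitivity analysis
    responses: tuple[str, ...] = ("raw", "log")


@dataclass(frozen=True)
class ModelFormula:
    """A candidate equation: main effects, optional interaction, response."""

    main_effects: tuple[Feature, ...]
    interaction: tuple[Feature, Feature] | None = None
    response_transform: str = "raw"

    @property
    def n_terms(self) -> int:
        return len(self.main_effects) + (1 if self.interaction else 0)

    @property
    def features(self) -> tuple[Feature, ...]:
        extra = self.interaction if self.interaction else ()
        return self.main_effects + tuple(extra)

    def describe(self) -> str:
        parts = [f"{t}({p})" if t == "log" else p for p, t in self.main_effects]
        if self.interaction:
            (p1, t1), (p2, t2) = self.interaction
            a = f"log({p1})" if t1 == "log" else p1
            b = f"log({p2})" if t2 == "log" else p2
            parts.append(f"{a}:{b}")
        resp = "log(mgfr)" if self.response_transform == "log" else "mgfr"
        return f"{resp} ~ " + " + ".join(parts)


def validate_formula(formula: ModelFormula,
                     constraints: SearchConstraints = SearchConstraints()) -> bool:
    """Independent checker of the four structural constraints."""
    c = constraints
    if formula.response_transform not in c.responses:
        return False
    if not c.min_features <= formula.n_terms <= c.max_features:
        return False
    if len(set(formula.main_effects)) != len(formula.main_effects):
        return False
    # constraint 4: one transform per parameter across the whole formula
    seen: dict[str, str] = {}
    for p, t in formula.features:
        if t not in TRANSFORMS:
            return False
        if seen.setdefault(p, t) != t:
            return False
    if formula.interaction is not None:
        if not c.allow_interactions:
            return False
        (p1, _), (p2, _) = formula.interaction
        if p1 == p2 and not c.allow_self_interaction:
            return False
        main_params = {p for p, _ in formula.main_effects}
        if p1 not in main_params and p2 not in main_params:
            return False  # constraint 3
    return True


def enumerate_formulas(pool: FeaturePool,
                       constraints: SearchConstraints = SearchConstraints()
                       ) -> Iterator[ModelFormula]:
    """Yield every admissible formula exactly once, in canonical order.

    Canonical order: response transform, then main-effect parameter subset
    (pool order), then transform assignment, then interaction choice.
    Streams with constant memory; materializing the default 10-marker pool
    is ~487k formulas.
    """
    params = pool.parameters
    c = constraints
    for resp in c.responses:
        # main-effects-only models
        for k in range(max(c.min_features, 1), c.max_features + 1):
            for subset in combinations(params, k):
                for transforms in product(pool.transforms, repeat=k):
                    yield ModelFormula(tuple(zip(subset, transforms)),
                                       None, resp)
        if not c.allow_interactions:
            continue
        # one interaction + m main effects (total m+1 features)
        for m in range(max(c.min_features - 1, 1), c.max_features):
            for subset in combinations(params, m):
                for transforms in product(pool.transforms, repeat=m):
                    mains = tuple(zip(subset, transforms))
                    # pair two mains: transforms fixed by constraint 4
                    for fa, fb in combinations(mains, 2):
                        yield ModelFormula(mains, (fa, fb), resp)
                    # self-product of a main (optional)
                    if c.allow_self_interaction:
                        for f in mains:
                            yield ModelFormula(mains, (f, f), resp)
                    # one main × one outside parameter (free transform)
                    outside = [p for p in params if p not in subset]
                    for f in mains:
                        for q in outside:
                            for tq in pool.transforms:
                                yield ModelFormula(mains, (f, (q, tq)), resp)


def count_formulas(pool: FeaturePool,
                   constraints: SearchConstraints = SearchConstraints()) -> int:
    """Closed-form size of the search space (must equal the stream length).

    Per response: Σ_k C(P,k)·2^k main-only models over the admissible sizes,
    plus, when interactions are on, Σ_m C(P,m)·2^m·[C(m,2) + 2·m·(P−m)
    (+ m for self-products)] for m main effects and one interaction.
    """
    P = len(pool.parameters)
    T = len(pool.transforms)
    c = constraints
    main_only = sum(comb(P, k) * T ** k
                    for k in range(max(c.min_features, 1), c.max_features + 1))
    inter = 0
    if c.allow_interactions:
        for m in range(max(c.min_features - 1, 1), c.max_features):
            pairings = comb(m, 2) + T * m * (P - m)
            if c.allow_self_interaction:
                pairings += m
            inter += comb(P, m) * T ** m * pairings
    return len(c.responses) * (main_only + inter)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _term_column(df: pd.DataFrame, feature: Feature) -> np.ndarray:
    p, t = feature
    x = df[p].to_numpy(dtype=float)
    if t == "log":
        if np.any(~(x > 0)):
            raise ValueError(f"log transform of non-positive values in '{p}'")
        return np.log(x)
    return x


def design_matrix(formula: ModelFormula, df: pd.DataFrame) -> pd.DataFrame:
    """Design matrix (with intercept) implied by a formula."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for f in formula.main_effects:
        name = f"{f[1]}({f[0]})" if f[1] == "log" else f[0]
        cols[name] = _term_column(df, f)
    if formula.interaction:
        fa, fb = formula.interaction
        na = f"{fa[1]}({fa[0]})" if fa[1] == "log" else fa[0]
        nb = f"{fb[1]}({fb[0]})" if fb[1] == "log" else fb[0]
        cols[f"{na}:{nb}"] = _term_column(df, fa) * _term_column(df, fb)
    return pd.DataFrame(cols, index=df.index)


@dataclass
class TrainedCandidate:
    """A fitted formula with training and (optionally) CV statistics."""

    formula: ModelFormula
    coefficients: pd.Series
    bse: pd.Series
    n: int
    sigma2: float  # MLE residual variance on the response scale
    train_mae: float
    train_p15: float
    train_p20: float
    train_p30: float
    het_score: float            # |Spearman| of |residual| vs fitted (GFR scale)
    upper_range_frac: float     # fraction of mGFR>=90 samples predicted >=90
    cv_mae_mean: float | None = None
    cv_mae_cv: float | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Predicted GFR (back-transformed for log response, no smearing)."""
        X = design_matrix(self.formula, df)
        yhat = X.to_numpy() @ self.coefficients.to_numpy()
        return np.exp(yhat) if self.formula.response_transform == "log" else yhat

    def loglik_pointwise(self, df: pd.DataFrame,
                         response: str = "mgfr_ml_min_173") -> np.ndarray:
        """Per-sample Gaussian log-likelihood on the model's response scale."""
        y = df[response].to_numpy(dtype=float)
        if self.formula.response_transform == "log":
            y = np.log(y)
        X = design_matrix(self.formula, df)
        resid = y - X.to_numpy() @ self.coefficients.to_numpy()
        s2 = self.sigma2
        return -0.5 * np.log(2 * np.pi * s2) - resid ** 2 / (2 * s2)


def _gfr_scale_stats(yhat_gfr: np.ndarray, y_gfr: np.ndarray) -> dict:
    d = yhat_gfr - y_gfr
    within = lambda x: 100.0 * np.mean(np.abs(d) <= (x / 100.0) * y_gfr)
    upper = y_gfr >= 90
    upper_frac = float(np.mean(yhat_gfr[upper] >= 90)) if np.any(upper) else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs yield NaN rho
        rho = stats.spearmanr(np.abs(d), yhat_gfr).statistic
    return {
        "train_mae": float(np.mean(np.abs(d))),
        "train_p15": within(15), "train_p20": within(20), "train_p30": within(30),
        "het_score": float(abs(rho)) if np.isfinite(rho) else 0.0,
        "upper_range_frac": upper_frac,
    }


def fit_formula(formula: ModelFormula, cohort: pd.DataFrame,
                response: str = "mgfr_ml_min_173") -> TrainedCandidate:
    """OLS fit of one formula; KPIs are computed on the GFR scale."""
    n = len(cohort)
    X = design_matrix(formula, cohort)
    if n <= X.shape[1]:
        raise ValueError(f"n={n} too small for {X.shape[1]} coefficients")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear design for formula '{formula.describe()}'")
    y_gfr = cohort[response].to_numpy(dtype=float)
    y = np.log(y_gfr) if formula.response_transform == "log" else y_gfr
    res = sm.OLS(y, X).fit()
    yhat = res.fittedvalues.to_numpy() if hasattr(res.fittedvalues, "to_numpy") \
        else np.asarray(res.fittedvalues)
    yhat_gfr = np.exp(yhat) if formula.response_transform == "log" else yhat
    return TrainedCandidate(
        formula=formula,
        coefficients=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        n=n,
        sigma2=float(np.mean(res.resid ** 2)),
        **_gfr_scale_stats(yhat_gfr, y_gfr),
    )


def cross_validate(formula: ModelFormula, cohort: pd.DataFrame,
                   repeats: int = 5, folds: int = 5, seed: int | None = None,
                   response: str = "mgfr_ml_min_173") -> dict:
    """Repeated k-fold CV; out-of-fold MAE on the GFR scale.

    Returns the mean and the coefficient of variation (sd/mean) of the
    repeats×folds fold MAEs, plus the fold values.
    """
    n = len(cohort)
    n_coef = formula.n_terms + 1
    if n < folds * (n_coef + 1):
        raise ValueError(f"n={n} too small for {folds}-fold CV of this formula")
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    idx = np.arange(n)
    fold_maes = []
    for train_ix, test_ix in rkf.split(idx):
        cand = fit_formula(formula, cohort.iloc[train_ix], response=response)
        pred = cand.predict(cohort.iloc[test_ix])
        truth = cohort[response].to_numpy(dtype=float)[test_ix]
        fold_maes.append(float(np.mean(np.abs(pred - truth))))
    fold_maes = np.asarray(fold_maes)
    mean = float(fold_maes.mean())
    return {
        "cv_mae_mean": mean,
        "cv_mae_cv": float(fold_maes.std(ddof=1) / mean) if mean > 0 else 0.0,
        "fold_maes": fold_maes,
    }


# ---------------------------------------------------------------------------
# the KPI filter pipeline
# ---------------------------------------------------------------------------

_OPS = {"le": np.less_equal, "lt": np.less, "ge": np.greater_equal,
        "gt": np.greater}

#: Candidate fields a threshold rule may reference.
_RULE_FIELDS = ("train_mae", "train_p15", "train_p20", "train_p30",
                "cv_mae_mean", "cv_mae_cv", "het_score", "upper_range_frac", "n")


def default_filter_rules(max_mae: float = 15.0, min_p30: float = 70.0,
                         max_cv_instability: float = 0.25,
                         min_upper_range_frac: float = 0.5,
                         max_het: float = 0.5,
                         redundancy_shared: int = 2) -> list[dict]:
    """The shipped screening pipeline: one rule per deselection class.

    Thresholds are package defaults for synthetic cohorts, configurable per
    study; the ordered classes are error/accuracy screens, CV stability,
    upper-GFR-range reach, residual heteroscedasticity and redundancy
    pruning among closely related formulas.
    """
    return [
        {"name": "error_screen", "field": "train_mae", "op": "le", "threshold": max_mae},
        {"name": "accuracy_screen", "field": "train_p30", "op": "ge", "threshold": min_p30},
        {"name": "cv_stability", "field": "cv_mae_cv", "op": "le",
         "threshold": max_cv_instability},
        {"name": "upper_range_reach", "field": "upper_range_frac", "op": "ge",
         "threshold": min_upper_range_frac},
        {"name": "heteroscedasticity", "field": "het_score", "op": "le",
         "threshold": max_het},
        {"name": "redundancy", "kind": "redundancy",
         "min_shared_features": redundancy_shared},
    ]


def _redundancy_prune(candidates: list[TrainedCandidate],
                      min_shared: int) -> list[TrainedCandidate]:
    """Within groups sharing >= min_shared features, drop dominated models.

    A candidate is dropped when a related candidate is at least as good on
    both MAE and P20 and strictly better on one.
    """
    keep = [True] * len(candidates)
    feats = [set(c.formula.features) for c in candidates]
    for i, j in combinations(range(len(candidates)), 2):
        if len(feats[i] & feats[j]) < min_shared:
            continue
        a, b = candidates[i], candidates[j]
        if (a.train_mae <= b.train_mae and a.train_p20 >= b.train_p20
                and (a.train_mae < b.train_mae or a.train_p20 > b.train_p20)):
            keep[j] = False
        elif (b.train_mae <= a.train_mae and b.train_p20 >= a.train_p20
                and (b.train_mae < a.train_mae or b.train_p20 > a.train_p20)):
            keep[i] = False
    return [c for c, k in zip(candidates, keep) if k]


def apply_filters(candidates: Sequence[TrainedCandidate],
                  rules: Sequence[dict]) -> tuple[list[TrainedCandidate], pd.DataFrame]:
    """Apply an ordered deselection pipeline; return survivors + audit log.

    Each threshold rule keeps candidates whose ``field`` satisfies
    ``op threshold`` (candidates with the field unset/NaN are removed).
    The audit log records removal counts per rule.
    """
    survivors = list(candidates)
    audit = []
    for rule in rules:
        before = len(survivors)
        if rule.get("kind") == "redundancy":
            survivors = _redundancy_prune(survivors, rule["min_shared_features"])
        else:
            f, op = rule.get("field"), rule.get("op")
            if f not in _RULE_FIELDS:
                raise FilterConfigError(f"rule {rule.get('name')}: unknown field {f!r}")
            if op not in _OPS:
                raise FilterConfigError(f"rule {rule.get('name')}: unknown op {op!r}")

            def ok(c, f=f, op=op, t=rule["threshold"]):
                v = getattr(c, f)
                return v is not None and np.isfinite(v) and bool(_OPS[op](v, t))

            survivors = [c for c in survivors if ok(c)]
        audit.append({"rule": rule.get("name", rule.get("kind", "?")),
                      "before": before, "removed": before - len(survivors),
                      "remaining": len(survivors)})
    return survivors, pd.DataFrame(audit)


# ---------------------------------------------------------------------------
# piecewise model engineering
# ---------------------------------------------------------------------------

@dataclass
class PiecewiseBranch:
    sex: str            # "female"/"male", or "all" when not sex-dependent
    side: str           # "below" / "at_or_above"
    cutoff: float
    intercept: float    # multiplicative intercept on the GFR scale
    pivot_exponent: float
    intercept_se: float
    pivot_exponent_se: float
    n: int


@dataclass
class PiecewiseCandidate:
    """A branched refit: shared non-pivot terms, branch-specific pivot."""

    pivot: str
    branches: list[PiecewiseBranch]
    shared_coefficients: pd.Series
    shared_bse: pd.Series
    n: int
    sigma2: float
    train_mae: float
    train_p30: float
    _design_info: dict = field(default_factory=dict, repr=False)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = _piecewise_design(df, **self._design_info)
        beta = pd.concat([self._branch_params(), self.shared_coefficients])
        return np.exp(X[beta.index].to_numpy() @ beta.to_numpy())

    def _branch_params(self) -> pd.Series:
        vals, idx = [], []
        for b in self.branches:
            key = f"{b.sex}|{b.side}"
            idx += [f"int[{key}]", f"pivot[{key}]"]
            vals += [np.log(b.intercept), b.pivot_exponent]
        return pd.Series(vals, index=idx)


def _branch_key(df: pd.DataFrame, pivot: str, cutoffs: dict,
                sex_dependent: bool) -> pd.Series:
    x = df[pivot].to_numpy(dtype=float)
    if sex_dependent:
        sex = df["sex"].astype(str).str.lower().map(
            {"f": "female", "female": "female", "m": "male", "male": "male"})
        cut = sex.map(cutoffs).to_numpy(dtype=float)
        side = np.where(x >= cut, "at_or_above", "below")
        return pd.Series(sex.to_numpy() + "|" + side, index=df.index)
    cut = cutoffs if np.isscalar(cutoffs) else cutoffs["all"]
    return pd.Series(np.where(x >= cut, "all|at_or_above", "all|below"),
                     index=df.index)


def _piecewise_design(df: pd.DataFrame, pivot: str, cutoffs: dict,
                      sex_dependent: bool, shared_features: tuple,
                      add_age: bool, branch_order: tuple) -> pd.DataFrame:
    key = _branch_key(df, pivot, cutoffs, sex_dependent)
    lnp = np.log(df[pivot].to_numpy(dtype=float))
    cols = {}
    for k in branch_order:
        ind = (key == k).to_numpy(dtype=float)
        cols[f"int[{k}]"] = ind
        cols[f"pivot[{k}]"] = ind * lnp
    for f in shared_features:
        name = f"{f[1]}({f[0]})" if f[1] == "log" else f[0]
        cols[name] = _term_column(df, f)
    if add_age and "age_years" not in [f[0] for f in shared_features]:
        cols["age_years"] = df["age_years"].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def engineer_piecewise(candidate: TrainedCandidate, cohort: pd.DataFrame,
                       pivot: str, cutoffs, sex_dependent: bool = True,
                       add_age: bool = False,
                       response: str = "mgfr_ml_min_173") -> PiecewiseCandidate:
    """Refit a candidate with branch-specific pivot exponent and intercept.

    A single joint OLS on the log scale: branch indicators (sex × cutoff
    side when ``sex_dependent``) interact with the intercept and the
    log-pivot term only; every other term of the candidate's formula keeps
    one shared coefficient across branches.  ``cutoffs`` is a per-sex
    mapping (or a scalar when not sex-dependent).  An optional linear age
    term can be added in the same refit.
    """
    feats = candidate.formula.features
    if pivot not in {p for p, _ in feats}:
        raise ValueError(f"pivot '{pivot}' is not a parameter of the candidate")
    shared = tuple(f for f in feats if f[0] != pivot)
    if np.isscalar(cutoffs):
        cutoffs = ({"female": float(cutoffs), "male": float(cutoffs)}
                   if sex_dependent else {"all": float(cutoffs)})

    branch_order = tuple(
        f"{sx}|{side}" for sx in (("female", "male") if sex_dependent else ("all",))
        for side in ("below", "at_or_above"))
    info = dict(pivot=pivot, cutoffs=cutoffs, sex_dependent=sex_dependent,
                shared_features=shared, add_age=add_age, branch_order=branch_order)
    X = _piecewise_design(cohort, **info)
    key = _branch_key(cohort, pivot, cutoffs, sex_dependent)
    n_coef = X.shape[1]
    for k in branch_order:
        n_k = int((key == k).sum())
        if n_k < 2 + len(shared) + (1 if add_age else 0):
            raise ValueError(f"branch '{k}' has only {n_k} samples; too few to fit")
    if len(cohort) <= n_coef:
        raise ValueError("cohort smaller than coefficient count")

    y = np.log(cohort[response].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)

    branches = []
    for k in branch_order:
        sx, side = k.split("|")
        branches.append(PiecewiseBranch(
            sex=sx, side=side,
            cutoff=cutoffs[sx] if sex_dependent else cutoffs["all"],
            intercept=float(np.exp(params[f"int[{k}]"])),
            pivot_exponent=float(params[f"pivot[{k}]"]),
            intercept_se=float(bse[f"int[{k}]"]),  # SE on the log scale
            pivot_exponent_se=float(bse[f"pivot[{k}]"]),
            n=int((key == k).sum())))

    shared_names = [c for c in X.columns if not c.startswith(("int[", "pivot["))]
    yhat_gfr = np.exp(np.asarray(res.fittedvalues))
    y_gfr = cohort[response].to_numpy(dtype=float)
    st = _gfr_scale_stats(yhat_gfr, y_gfr)
    return PiecewiseCandidate(
        pivot=pivot, branches=branches,
        shared_coefficients=params[shared_names], shared_bse=bse[shared_names],
        n=len(cohort), sigma2=float(np.mean(res.resid ** 2)),
        train_mae=st["train_mae"], train_p30=st["train_p30"],
        _design_info=info)


# ---------------------------------------------------------------------------
# Vuong comparison
# ---------------------------------------------------------------------------

def vuong_test(candidate_a: TrainedCandidate, candidate_b: TrainedCandidate,
               cohort: pd.DataFrame, response: str = "mgfr_ml_min_173") -> dict:
    """Classical Vuong statistic between two fitted candidates.

    z = √n · mean(ℓᵃᵢ − ℓᵇᵢ) / sd(ℓᵃᵢ − ℓᵇᵢ) against N(0,1), two-sided,
    with Gaussian pointwise log-likelihoods from the OLS residual variance.
    Both candidates must share the response transform (otherwise the
    likelihoods live on different scales).
    """
    ra = candidate_a.formula.response_transform
    if ra != candidate_b.formula.response_transform:
        raise ValueError("Vuong comparison requires a common response transform")
    la = candidate_a.loglik_pointwise(cohort, response)
    lb = candidate_b.loglik_pointwise(cohort, response)
    d = la - lb
    sd = float(np.std(d, ddof=1))
    n = d.size
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn("identical pointwise log-likelihoods; Vuong test undefined")
        return {"statistic": np.nan, "p": 1.0, "defined": False}
    z = float(np.sqrt(n) * np.mean(d) / sd)
    return {"statistic": z, "p": float(2 * stats.norm.sf(abs(z))), "defined": True}
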