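"""KDIGO CKD staging from GFR and categorical net-reclassification analysis.

Stages partition (0, ∞) mL/min/1.73 m² into G1 [90, ∞), G2 [60, 90),
G3a [45, 60), G3b [30, 45), G4 [15, 30) and G5 (0, 15), applied to the
unrounded GFR value.

The reclassification analysis compares a new estimating equation against a
comparator relative to the measured-GFR stage: among samples where the two
equations stage differently, a sample counts as *correctly reclassified*
when the new equation matches the mGFR stage and the comparator does not,
and *incorrectly reclassified* in the mirror case.  The net reclassification
index (NRI) is reported in two flavours: ``nri_printed_style``, the
difference of the correct and incorrect percentages each first rounded to
one decimal (the convention clinical tables use), and ``nri_exact``,
100·(correct − incorrect)/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STAGE_LABELS",
    "STAGE_EDGES",
    "ckd_stage",
    "nri_from_counts",
    "ReclassificationSummary",
    "reclassification_summary",
    "reclassification_table",
]

#: Stage labels from most to least severe with their lower GFR bounds.
STAGE_LABELS = ("G5", "G4", "G3b", "G3a", "G2", "G1")
STAGE_EDGES = (0.0, 15.0, 30.0, 45.0, 60.0, 90.0, np.inf)


def ckd_stage(gfr, coarse_g3: bool = False):
    """KDIGO G-stage label(s) for unrounded GFR value(s).

    Boundaries belong to the higher-GFR stage (90 → G1, 60 → G2, ...).
    ``coarse_g3=True`` merges G3a/G3b into G3.
    """
    g = np.asarray(gfr, dtype=float)
    if np.any(~(g > 0)):
        raise ValueError("GFR must be strictly positive for staging")
    idx = np.searchsorted(STAGE_EDGES[1:-1], np.atleast_1d(g), side="right")
    labels = np.array(STAGE_LABELS, dtype=object)[idx]
    if coarse_g3:
        labels = np.where(np.isin(labels, ("G3a", "G3b")), "G3", labels)
    return labels[0] if g.ndim == 0 else labels


def _round1(x: float) -> float:
    # half-away-from-zero at one decimal, matching printed clinical tables
    return float(np.floor(abs(x) * 10 + 0.5) / 10 * np.sign(x)) if x else 0.0


def nri_from_counts(n: int, correct: int, incorrect: int) -> dict:
    """NRI variants from reclassification counts within a group of size n."""
    if n <= 0:
        return {"pct_correct": np.nan, "pct_incorrect": np.nan,
                "nri_printed_style": np.nan, "nri_exact": np.nan}
    pc = _round1(100.0 * correct / n)
    pi = _round1(100.0 * incorrect / n)
    return {
        "pct_correct": pc,
        "pct_incorrect": pi,
        "nri_printed_style": _round1(pc - pi),
        "nri_exact": 100.0 * (correct - incorrect) / n,
    }


@dataclass
class ReclassificationSummary:
    """Reclassification counts and NRI for one mGFR stratum (or overall)."""

    stratum: str
    n: int
    total_discordant: int
    correct: int
    incorrect: int
    both_wrong_discordant: int
    pct_correct: float
    pct_incorrect: float
    nri_printed_style: float
    nri_exact: float


def _summary_for(mask, stratum, s_m, s_new, s_cmp) -> ReclassificationSummary:
    n = int(np.sum(mask))
    discordant = mask & (s_new != s_cmp)
    correct = discordant & (s_new == s_m)
    incorrect = discordant & (s_cmp == s_m)
    both_wrong = discordant & (s_new != s_m) & (s_cmp != s_m)
    nri = nri_from_counts(n, int(correct.sum()), int(incorrect.sum()))
    return ReclassificationSummary(
        stratum=stratum, n=n, total_discordant=int(discordant.sum()),
        correct=int(correct.sum()), incorrect=int(incorrect.sum()),
        both_wrong_discordant=int(both_wrong.sum()), **nri)


def reclassification_summary(mgfr, egfr_new, egfr_comparator,
                             stratify: bool = True) -> list[ReclassificationSummary]:
    """Stage all three GFR vectors and summarize reclassification.

    Returns the overall summary first, then (if ``stratify``) one summary
    per mGFR-based stage from G5 up to G1.  Empty strata report n = 0 with
    NRI undefined (NaN).
    """
    m = np.asarray(mgfr, dtype=float)
    new = np.asarray(egfr_new, dtype=float)
    cmp_ = np.asarray(egfr_comparator, dtype=float)
    if not (m.shape == new.shape == cmp_.shape):
        raise ValueError("mgfr/egfr vectors must be aligned")

    s_m, s_new, s_cmp = ckd_stage(m), ckd_stage(new), ckd_stage(cmp_)
    out = [_summary_for(np.ones(m.size, dtype=bool), "overall", s_m, s_new, s_cmp)]
    if stratify:
        for label in STAGE_LABELS:
            out.append(_summary_for(s_m == label, label, s_m, s_new, s_cmp))
    return out


def reclassification_table(summaries: list[ReclassificationSummary]) -> pd.DataFrame:
    """Serialize summaries to a report table: one column per stratum."""
    rows = ["n", "total_discordant", "correct", "incorrect",
            "both_wrong_discordant", "pct_correct", "pct_incorrect",
            "nri_printed_style", "nri_exact"]
    data = {s.stratum: [getattr(s, r) for r in rows] for s in summaries}
    return pd.DataFrame(data, index=rows)
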