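"""Stem/progenitor scoring of transplanted daughter cells from
longitudinal peripheral-blood chimerism.

Each daughter of a divided HSC was transplanted into its own recipient
and donor chimerism (percent donor-derived white blood cells) plus the
lineage split among donor cells (B, T, myeloid) followed to week 24.  A
daughter is a stem cell (S) when week-24 engraftment exceeds 0.1% AND
all three lineages are detected; otherwise a progenitor (P).  The
mother's division outcome follows: two S daughters = symmetric
self-renewal (SymS), two P = symmetric differentiation (SymD), one of
each = asymmetric (Asym).  A mother is a "true HSC" when at least one
daughter scored S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator

__all__ = [
    "ChimerismRecord",
    "ChimerismSeries",
    "PairOutcome",
    "ChimerismScorer",
    "UnscorableError",
    "score_daughter",
    "score_pair",
    "cohort_summary",
]

FINAL_WEEK = 24


class UnscorableError(ValueError):
    """Raised for a daughter without a week-24 record."""


@dataclass(frozen=True)
class ChimerismRecord:
    week: int
    donor_percent: float
    b_percent: float
    t_percent: float
    myeloid_percent: float

    def __post_init__(self):
        for name in ("donor_percent", "b_percent", "t_percent", "myeloid_percent"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class ChimerismSeries:
    """Longitudinal chimerism of one transplanted daughter."""

    mouse_id: str
    pair_id: str
    daughter_slot: str  # "A" or "B"
    condition: str
    records: tuple[ChimerismRecord, ...] = field(default_factory=tuple)
    engrafted: bool = True  # False mirrors "n.e." annotations

    def __post_init__(self):
        weeks = [r.week for r in self.records]
        if sorted(set(weeks)) != weeks:
            raise ValueError("record weeks must be unique and ascending")

    def at_week(self, week: int) -> ChimerismRecord | None:
        for r in self.records:
            if r.week == week:
                return r
        return None


@dataclass(frozen=True)
class PairOutcome:
    pair_id: str
    condition: str
    call_a: str  # "S" or "P"
    call_b: str

    @property
    def division_call(self) -> str:
        return score_pair(self.call_a, self.call_b)

    @property
    def true_hsc_mother(self) -> bool:
        return "S" in (self.call_a, self.call_b)


def score_pair(a: str, b: str) -> str:
    """Map daughter calls to the division outcome (SymS / SymD / Asym)."""
    if {a, b} - {"S", "P"}:
        raise ValueError("daughter calls must be 'S' or 'P'")
    if a == b:
        return "SymS" if a == "S" else "SymD"
    return "Asym"


class ChimerismScorer(BaseEstimator):
    """Rule-based stem/progenitor caller on chimerism series.

    Parameters
    ----------
    engraft_threshold : float
        Week-24 overall donor chimerism (%) that must be exceeded.
    lineage_detect : float
        Minimum percentage for each of B / T / myeloid among donor
        cells for the lineage to count as detected.
    """

    def __init__(self, engraft_threshold: float = 0.1,
                 lineage_detect: float = 0.1):
        self.engraft_threshold = engraft_threshold
        self.lineage_detect = lineage_detect

    def fit(self, X=None, y=None):
        return self

    def score_daughter(self, series: ChimerismSeries) -> str:
        if not series.engrafted:
            return "P"
        rec = series.at_week(FINAL_WEEK)
        if rec is None:
            raise UnscorableError(
                f"{series.mouse_id}: no week-{FINAL_WEEK} record; daughter unscorable")
        multilineage = all(v >= self.lineage_detect for v in
                           (rec.b_percent, rec.t_percent, rec.myeloid_percent))
        return "S" if rec.donor_percent > self.engraft_threshold and multilineage else "P"

    def predict(self, series_list: list[ChimerismSeries]) -> np.ndarray:
        return np.array([self.score_daughter(s) for s in series_list])

    def score_cohort(self, series_list: list[ChimerismSeries]) -> dict:
        """Score every pair with both daughters followed to week 24.

        Returns per-daughter calls, per-pair outcomes, the pooled and
        per-condition true-HSC mother fractions, asymmetric/symmetric
        fractions, and pairwise chi-squared comparisons of division
        outcomes between conditions.  Pairs with an unscorable daughter
        are excluded and counted.
        """
        calls: dict[tuple[str, str], dict] = {}
        daughters, n_excluded = [], 0
        by_pair: dict[str, dict] = {}
        for s in series_list:
            try:
                call = self.score_daughter(s)
            except UnscorableError:
                n_excluded += 1
                by_pair.setdefault(s.pair_id, {})["unscorable"] = True
                continue
            daughters.append({"mouse_id": s.mouse_id, "pair_id": s.pair_id,
                              "slot": s.daughter_slot, "condition": s.condition,
                              "call": call, "not_engrafted": not s.engrafted})
            d = by_pair.setdefault(s.pair_id, {})
            d[s.daughter_slot] = call
            d["condition"] = s.condition
        outcomes = []
        n_incomplete = 0
        for pid, d in by_pair.items():
            if d.get("unscorable") or "A" not in d or "B" not in d:
                n_incomplete += 1
                continue
            outcomes.append(PairOutcome(pair_id=pid, condition=d["condition"],
                                        call_a=d["A"], call_b=d["B"]))
        return {
            "per_daughter": pd.DataFrame(daughters),
            "outcomes": outcomes,
            "n_excluded_daughters": n_excluded,
            "n_incomplete_pairs": n_incomplete,
            **cohort_summary(outcomes),
        }


def score_daughter(series: ChimerismSeries, engraft_threshold: float = 0.1,
                   lineage_detect: float = 0.1) -> str:
    return ChimerismScorer(engraft_threshold, lineage_detect).score_daughter(series)


def cohort_summary(outcomes: list[PairOutcome]) -> dict:
    """Summaries over scored pair outcomes.

    ``true_hsc_fraction`` is pooled over all scorable mothers; it equals
    the fraction of non-SymD outcomes by construction.
    """
    if not outcomes:
        return {"per_pair": pd.DataFrame(), "per_condition": {},
                "true_hsc_fraction": float("nan"), "comparisons": []}
    rows = [{"pair_id": o.pair_id, "condition": o.condition,
             "call_a": o.call_a, "call_b": o.call_b,
             "division_call": o.division_call,
             "true_hsc_mother": o.true_hsc_mother} for o in outcomes]
    table = pd.DataFrame(rows)
    per_condition = {}
    for cond, sub in table.groupby("condition", sort=False):
        counts = sub["division_call"].value_counts()
        n = len(sub)
        per_condition[cond] = {
            "n_pairs": int(n),
            "n_SymS": int(counts.get("SymS", 0)),
            "n_SymD": int(counts.get("SymD", 0)),
            "n_Asym": int(counts.get("Asym", 0)),
            "fraction_asymmetric": float(counts.get("Asym", 0) / n),
            "fraction_symmetric": float((counts.get("SymS", 0) + counts.get("SymD", 0)) / n),
            "true_hsc_fraction": float(sub["true_hsc_mother"].mean()),
        }
    tests = []
    conds = list(per_condition)
    import itertools
    for a, b in itertools.combinations(conds, 2):
        ca, cb = per_condition[a], per_condition[b]
        obs = np.array([[ca["n_Asym"], ca["n_pairs"] - ca["n_Asym"]],
                        [cb["n_Asym"], cb["n_pairs"] - cb["n_Asym"]]])
        if obs.sum(axis=0).min() == 0:
            continue  # degenerate margin
        stat, p, _, _ = chi2_contingency(obs, correction=False)
        tests.append({"condition_a": a, "condition_b": b,
                      "chi2": float(stat), "p_value": float(p)})
    return {"per_pair": table, "per_condition": per_condition,
            "true_hsc_fraction": float(table["true_hsc_mother"].mean()),
            "comparisons": tests}
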