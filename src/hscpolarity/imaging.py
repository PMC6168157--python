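"""Scoring of imaged daughter-cell pairs from fluorescence signal volumes.

A division is asymmetric when the daughters inherit markedly unequal
amounts of the polarity marker (Cdc42 or H4K16ac).  The rule is a 1:4
amount ratio: with the higher-signal daughter as reference, a pair with

    difference% = 100 * (higher - lower) / higher >= 75

(equivalently lower/higher <= 0.25) is asymmetric, boundary inclusive.
Only telophase and late-anaphase pairs are admitted.  An alternative
legend-style reading (lower/higher <= 0.75) is exposed as a sensitivity
flag on the classifier.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "Condition",
    "Marker",
    "Phase",
    "DaughterPairSignal",
    "ImagingPairClassifier",
    "difference_percent",
    "classify_pair",
    "condition_summary",
]

ADMITTED_PHASES = ("telophase", "late_anaphase")


class Condition(str, enum.Enum):
    young = "young"
    aged = "aged"
    aged_CASIN = "aged_CASIN"
    young_Wnt5a = "young_Wnt5a"


class Marker(str, enum.Enum):
    Cdc42 = "Cdc42"
    H4K16ac = "H4K16ac"


class Phase(str, enum.Enum):
    telophase = "telophase"
    late_anaphase = "late_anaphase"
    other = "other"


@dataclass(frozen=True)
class DaughterPairSignal:
    pair_id: str
    condition: str
    marker: str
    volume_a: float
    volume_b: float
    phase: str = "telophase"

    def __post_init__(self):
        if self.volume_a < 0 or self.volume_b < 0:
            raise ValueError("signal volumes must be non-negative")
        if self.volume_a == 0 and self.volume_b == 0:
            raise ValueError(f"pair {self.pair_id}: both volumes zero, ratio undefined")


def difference_percent(pair: DaughterPairSignal) -> float:
    """Percent difference between daughters relative to the higher signal."""
    hi = max(pair.volume_a, pair.volume_b)
    lo = min(pair.volume_a, pair.volume_b)
    return 100.0 * (hi - lo) / hi


class ImagingPairClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based asymmetric/symmetric classifier for imaged pairs.

    Parameters
    ----------
    threshold_percent : float
        Minimum percent difference called asymmetric (boundary
        inclusive).  The default 75 corresponds to a 1:4 amount ratio.
    legend_ratio_rule : bool
        When True, use the alternative reading where a pair is
        asymmetric iff lower/higher <= threshold_percent/100 (e.g. a
        0.75 ratio cutoff) instead of the percent-difference rule.
    """

    classes_ = np.array(["symmetric", "asymmetric"])

    def __init__(self, threshold_percent: float = 75.0,
                 legend_ratio_rule: bool = False):
        self.threshold_percent = threshold_percent
        self.legend_ratio_rule = legend_ratio_rule

    def fit(self, X=None, y=None):
        """No parameters are learned; kept for estimator-API symmetry."""
        self.n_features_in_ = 2
        return self

    def predict(self, pairs: list[DaughterPairSignal]) -> np.ndarray:
        return np.array([self.classify(p) for p in pairs])

    def classify(self, pair: DaughterPairSignal) -> str:
        if pair.phase not in ADMITTED_PHASES:
            raise ValueError(
                f"pair {pair.pair_id}: phase {pair.phase!r} rejected; only "
                f"telophase and late anaphase pairs are scored")
        if self.legend_ratio_rule:
            hi = max(pair.volume_a, pair.volume_b)
            lo = min(pair.volume_a, pair.volume_b)
            asym = (lo / hi) <= self.threshold_percent / 100.0
        else:
            asym = difference_percent(pair) >= self.threshold_percent
        return "asymmetric" if asym else "symmetric"

    def summarize(self, pairs: list[DaughterPairSignal],
                  comparisons: list[tuple[str, str]] | None = None) -> dict:
        """Per-condition asymmetric fractions plus 2x2 chi-squared tests.

        Pairs in non-admitted phases are excluded (counted); conditions
        without admitted pairs are dropped from comparisons with a
        warning entry.
        """
        admitted, rejected = [], 0
        for p in pairs:
            if p.phase in ADMITTED_PHASES:
                admitted.append(p)
            else:
                rejected += 1
        rows = [{"pair_id": p.pair_id, "condition": p.condition,
                 "marker": p.marker,
                 "difference_percent": difference_percent(p),
                 "call": self.classify(p)} for p in admitted]
        table = pd.DataFrame(rows)
        per_condition = {}
        if len(table):
            for cond, sub in table.groupby("condition", sort=False):
                n_asym = int((sub["call"] == "asymmetric").sum())
                per_condition[cond] = {
                    "n_pairs": int(len(sub)), "n_asymmetric": n_asym,
                    "fraction_asymmetric": n_asym / len(sub)}
        conds = list(per_condition)
        if comparisons is None:
            comparisons = list(itertools.combinations(conds, 2))
        tests, warnings = [], []
        for a, b in comparisons:
            missing = [c for c in (a, b) if c not in per_condition]
            if missing:
                warnings.append(f"comparison {a} vs {b} skipped: no admitted "
                                f"pairs in {missing}")
                continue
            ca, cb = per_condition[a], per_condition[b]
            obs = np.array([
                [ca["n_asymmetric"], ca["n_pairs"] - ca["n_asymmetric"]],
                [cb["n_asymmetric"], cb["n_pairs"] - cb["n_asymmetric"]]])
            stat, p, _, _ = chi2_contingency(obs, correction=False)
            tests.append({"condition_a": a, "condition_b": b,
                          "chi2": float(stat), "p_value": float(p)})
        return {"per_pair": table, "per_condition": per_condition,
                "comparisons": tests, "n_rejected_phase": rejected,
                "warnings": warnings}


def classify_pair(pair: DaughterPairSignal, threshold_percent: float = 75.0) -> str:
    return ImagingPairClassifier(threshold_percent=threshold_percent).classify(pair)


def condition_summary(pairs: list[DaughterPairSignal],
                      threshold_percent: float = 75.0, **kwargs) -> dict:
    return ImagingPairClassifier(threshold_percent=threshold_percent
                                 ).summarize(pairs, **kwargs)
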