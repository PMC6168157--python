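"""Transcriptome concordance of daughter-cell pairs.

For each daughter, per-gene log fold changes are computed against the
mean expression profile of the whole cohort, and per-cell significant
genes are found by a leave-one-out z-test with Benjamini-Hochberg
correction.  A pair's concordance is then summarized by the quadrant
count ratio (QCR): over the union of the daughters' significant genes,
genes are placed in the four quadrants of the (logFC_A, logFC_B) plane
and

    QCR = (n_I + n_III - n_II - n_IV) / (n_I + n_II + n_III + n_IV)

where quadrants I/III (same sign in both daughters) are concordant and
II/IV discordant.  Significance comes from a chi-squared test of
concordant vs discordant counts against 50/50 and from a Monte-Carlo
permutation of daughter-B fold changes across genes (exhaustive
enumeration available for small instances).

Signature-level concordance uses upper-tail hypergeometric enrichment
of each daughter's significant genes in published HSC/polarity
signatures, followed by a goodness-of-fit comparison of the two
daughters' binary significance patterns.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, chisquare, hypergeom
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ConcordanceResult",
    "GeneSignature",
    "PairConcordance",
    "logfc_vs_mean",
    "significant_genes",
    "pair_qcr",
    "signature_enrichment",
    "pair_signature_concordance",
    "arm_directional_sets",
]


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of normalized non-negative abundance plus
    per-cell metadata (pair_id, slot, condition)."""

    values: pd.DataFrame  # index: genes, columns: cells
    metadata: pd.DataFrame  # index: cells; columns: pair_id, slot, condition

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"cells without metadata: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    def pair_cells(self, pair_id: str) -> tuple[str, str]:
        cells = self.metadata.index[self.metadata["pair_id"] == pair_id]
        cells = [c for c in cells if c in self.values.columns]
        if len(cells) != 2:
            raise ValueError(f"pair {pair_id}: expected 2 cells, found {len(cells)}")
        slots = self.metadata.loc[cells, "slot"]
        return tuple(pd.Series(cells, index=slots).sort_index())


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"signature {self.name}: empty gene set")


@dataclass
class ConcordanceResult:
    pair_id: str
    n_I: int
    n_II: int
    n_III: int
    n_IV: int
    qcr: float
    chi2_p: float
    mc_p: float
    call: str  # "concordant" | "discordant"
    degenerate: bool = False


def logfc_vs_mean(matrix: ExpressionMatrix, cell: str,
                  pseudocount: float = 1.0) -> pd.Series:
    """Per-gene log2 fold change of one cell against the cohort mean."""
    if cell not in matrix.values.columns:
        raise KeyError(cell)
    mean = matrix.values.mean(axis=1)
    return np.log2((matrix.values[cell] + pseudocount) / (mean + pseudocount))


def significant_genes(matrix: ExpressionMatrix, cell: str,
                      alpha: float = 0.05, pseudocount: float = 1.0
                      ) -> frozenset[str]:
    """Genes whose log-abundance in ``cell`` is an outlier against the
    cross-cell distribution (p and BH q below ``alpha``).

    The reference mean and SD exclude the tested cell AND its pair
    partner: an outlier must not inflate its own null spread, and a
    daughter sharing its sibling's expression program would otherwise
    mask exactly the concordant signal this test feeds downstream.
    Zero-variance genes are excluded from testing.
    """
    X = np.log2(matrix.values.to_numpy(dtype=float) + pseudocount)
    cols = list(matrix.values.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 cells to estimate dispersion")
    j = cols.index(cell)
    mask = np.ones(len(cols), dtype=bool)
    mask[j] = False
    if cell in matrix.metadata.index and "pair_id" in matrix.metadata:
        pid = matrix.metadata.loc[cell, "pair_id"]
        partners = matrix.metadata.index[matrix.metadata["pair_id"] == pid]
        for p in partners:
            if p in cols:
                mask[cols.index(p)] = False
    if mask.sum() < 2:
        raise ValueError("need at least 2 reference cells outside the pair")
    ref = X[:, mask]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    testable = sd > 0
    z = np.full(X.shape[0], np.nan)
    z[testable] = (X[testable, j] - mu[testable]) / sd[testable]
    if not testable.any():
        return frozenset()
    # Student-t tails: the reference SD comes from few cells
    from scipy.stats import t as t_dist
    p = 2 * t_dist.sf(np.abs(z[testable]), df=int(mask.sum()) - 1)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    hits = matrix.genes[testable][(p < alpha) & (q < alpha)]
    return frozenset(hits)


def _quadrant_counts(fa: np.ndarray, fb: np.ndarray) -> tuple[int, int, int, int]:
    # genes with an exactly-zero fold change in either daughter are excluded
    nz = (fa != 0) & (fb != 0)
    fa, fb = fa[nz], fb[nz]
    n_I = int(((fa > 0) & (fb > 0)).sum())
    n_II = int(((fa < 0) & (fb > 0)).sum())
    n_III = int(((fa < 0) & (fb < 0)).sum())
    n_IV = int(((fa > 0) & (fb < 0)).sum())
    return n_I, n_II, n_III, n_IV


def _qcr(counts: tuple[int, int, int, int]) -> float:
    n_I, n_II, n_III, n_IV = counts
    tot = n_I + n_II + n_III + n_IV
    return (n_I + n_III - n_II - n_IV) / tot if tot else 0.0


def pair_qcr(matrix: ExpressionMatrix, pair_id: str, alpha: float = 0.05,
             pseudocount: float = 1.0, n_permutations: int = 10000,
             exact: bool | None = None,
             random_state: int | np.random.Generator = 0) -> ConcordanceResult:
    """Quadrant-count-ratio concordance of one daughter pair.

    The gene universe is the union of the two daughters' significant
    gene sets.  The Monte-Carlo p permutes daughter-B fold changes
    across that universe (tail in the direction of the observed QCR
    sign); with ``exact=True`` (or automatically for <= 8 genes) all
    permutations are enumerated instead.
    """
    cell_a, cell_b = matrix.pair_cells(pair_id)
    sig = significant_genes(matrix, cell_a, alpha, pseudocount) | \
        significant_genes(matrix, cell_b, alpha, pseudocount)
    if not sig:
        return ConcordanceResult(pair_id, 0, 0, 0, 0, 0.0, 1.0, 1.0,
                                 "concordant", degenerate=True)
    genes = sorted(sig)
    fa = logfc_vs_mean(matrix, cell_a, pseudocount).loc[genes].to_numpy()
    fb = logfc_vs_mean(matrix, cell_b, pseudocount).loc[genes].to_numpy()
    return _qcr_from_logfc(pair_id, fa, fb, n_permutations, exact, random_state)


def _qcr_from_logfc(pair_id: str, fa: np.ndarray, fb: np.ndarray,
                    n_permutations: int, exact: bool | None,
                    random_state) -> ConcordanceResult:
    counts = _quadrant_counts(fa, fb)
    qcr = _qcr(counts)
    n_conc = counts[0] + counts[2]
    n_disc = counts[1] + counts[3]
    tot = n_conc + n_disc
    if tot == 0:
        return ConcordanceResult(pair_id, *counts, 0.0, 1.0, 1.0,
                                 "concordant", degenerate=True)
    chi2_p = float(chisquare([n_conc, n_disc]).pvalue)
    mc_p = _permutation_p(fa, fb, qcr, n_permutations, exact, random_state)
    significant = mc_p < 0.05
    call = "concordant" if (qcr > 0 and significant) else "discordant"
    return ConcordanceResult(pair_id, *counts, qcr, chi2_p, mc_p, call)


def _permutation_p(fa, fb, qcr_obs, n_permutations, exact, random_state) -> float:
    """P(permuted QCR at least as extreme, in the observed direction)."""
    n = len(fb)
    if exact is None:
        exact = n <= 8
    def stat(perm_fb):
        return _qcr(_quadrant_counts(fa, perm_fb))
    if exact:
        vals = np.array([stat(np.asarray(p)) for p in itertools.permutations(fb)])
        if qcr_obs >= 0:
            return float((vals >= qcr_obs - 1e-12).mean())
        return float((vals <= qcr_obs + 1e-12).mean())
    rng = random_state if isinstance(random_state, np.random.Generator) \
        else np.random.default_rng(random_state)
    hits = 0
    for _ in range(n_permutations):
        v = stat(rng.permutation(fb))
        if qcr_obs >= 0:
            hits += v >= qcr_obs - 1e-12
        else:
            hits += v <= qcr_obs + 1e-12
    return (hits + 1) / (n_permutations + 1)


def signature_enrichment(gene_set: frozenset[str] | set[str], universe,
                         signatures: list[GeneSignature],
                         alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in each
    signature, with BH adjustment across signatures.

    ``universe`` is the set (or size-defining collection) of all genes
    that passed the expression filter; the gene set must be a subset.
    """
    universe = frozenset(universe)
    gene_set = frozenset(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    M, N = len(universe), len(gene_set)
    rows = []
    for sig in signatures:
        members = sig.genes & universe
        K = len(members)
        k = len(gene_set & members)
        if K == 0:
            rows.append({"signature": sig.name, "overlap": 0, "members_in_universe": 0,
                         "p_value": 1.0, "disjoint": True})
            continue
        p = float(hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append({"signature": sig.name, "overlap": k,
                     "members_in_universe": K, "p_value": p, "disjoint": False})
    table = pd.DataFrame(rows)
    if len(table):
        _, q, _, _ = multipletests(table["p_value"], alpha=alpha, method="fdr_bh")
        table["q_value"] = q
        table["significant"] = (table["q_value"] < alpha) & ~table["disjoint"]
    return table


def pair_signature_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                               alpha: float = 0.05) -> dict:
    """Compare the two daughters' binary signature-significance patterns.

    The statistic is the number of mismatched signatures (zero when the
    patterns are identical); its p-value is the exact binomial tail at
    mismatch probability 1/2 (the exchangeable null).  Discordant when
    the mismatch count is significantly high.
    """
    if list(table_a["signature"]) != list(table_b["signature"]):
        raise ValueError("both daughters need the same signature list")
    pat_a = table_a["significant"].to_numpy(dtype=bool)
    pat_b = table_b["significant"].to_numpy(dtype=bool)
    n = len(pat_a)
    mismatches = int((pat_a != pat_b).sum())
    degenerate = not pat_a.any() and not pat_b.any()
    # P(Binom(n, 1/2) >= mismatches); monotone decreasing in the statistic
    p = float(binom.sf(mismatches - 1, n, 0.5)) if n else 1.0
    call = "discordant" if (mismatches > 0 and p < alpha) else "concordant"
    return {"statistic": mismatches, "n_signatures": n, "p_value": p,
            "call": call, "degenerate": degenerate}


def _condition_direction(matrix: ExpressionMatrix, condition: str,
                         alpha: float, pseudocount: float
                         ) -> tuple[frozenset[str], frozenset[str]]:
    """Genes significantly up / down in a condition's cells against the
    cohort grand mean (per-gene one-sample t, plain p cutoff)."""
    from scipy.stats import t as t_dist

    X = np.log2(matrix.values.to_numpy(dtype=float) + pseudocount)
    cells = matrix.metadata.index[matrix.metadata["condition"] == condition]
    idx = [list(matrix.values.columns).index(c) for c in cells
           if c in matrix.values.columns]
    if len(idx) < 2:
        raise ValueError(f"condition {condition}: need >= 2 cells")
    sub = X[:, idx]
    grand = X.mean(axis=1)
    m = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m - grand) / (sd / math.sqrt(len(idx)))
    p = 2 * t_dist.sf(np.abs(t), df=len(idx) - 1)
    sig = (p < alpha) & np.isfinite(t)
    up = frozenset(matrix.genes[sig & (t > 0)])
    down = frozenset(matrix.genes[sig & (t < 0)])
    return up, down


def arm_directional_sets(matrix: ExpressionMatrix,
                         arm_a: tuple[str, str], arm_b: tuple[str, str],
                         alpha: float = 0.05, pseudocount: float = 1.0) -> dict:
    """Directional gene-set logic between two treatment arms.

    An arm is a pair of conditions expected to behave alike (e.g. young
    with CASIN-treated aged, versus aged with Wnt5a-treated young).  A
    gene belongs to an arm's set when it changes significantly in the
    same direction in both of the arm's conditions.  Returns the Venn
    partition (per direction): exclusive to each arm and the
    intersection.
    """
    def arm_sets(arm):
        ups, downs = zip(*(_condition_direction(matrix, c, alpha, pseudocount)
                           for c in arm))
        return frozenset.intersection(*ups), frozenset.intersection(*downs)

    up_a, down_a = arm_sets(arm_a)
    up_b, down_b = arm_sets(arm_b)
    return {
        "up": {"arm_a_only": up_a - up_b, "arm_b_only": up_b - up_a,
               "both": up_a & up_b},
        "down": {"arm_a_only": down_a - down_b, "arm_b_only": down_b - down_a,
                 "both": down_a & down_b},
    }


class PairConcordance(BaseEstimator):
    """Cohort-level QCR concordance caller.

    ``fit`` scores every daughter pair in an :class:`ExpressionMatrix`;
    fitted attributes hold per-pair :class:`ConcordanceResult` objects
    and a tidy summary table.
    """

    def __init__(self, alpha: float = 0.05, pseudocount: float = 1.0,
                 n_permutations: int = 10000, random_state: int = 0):
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, matrix: ExpressionMatrix, y=None):
        rng = np.random.default_rng(self.random_state)
        pair_ids = list(dict.fromkeys(matrix.metadata["pair_id"]))
        self.results_ = {}
        for pid in pair_ids:
            self.results_[pid] = pair_qcr(
                matrix, pid, alpha=self.alpha, pseudocount=self.pseudocount,
                n_permutations=self.n_permutations, random_state=rng)
        self.summary_ = pd.DataFrame(
            [{"pair_id": r.pair_id, "qcr": r.qcr, "chi2_p": r.chi2_p,
              "mc_p": r.mc_p, "call": r.call, "degenerate": r.degenerate}
             for r in self.results_.values()])
        return self

    def predict(self, matrix: ExpressionMatrix) -> np.ndarray:
        self.fit(matrix)
        return self.summary_["call"].to_numpy()
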