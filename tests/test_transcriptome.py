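import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, hypergeom

from hscpolarity.transcriptome import (ExpressionMatrix, GeneSignature,
                                       _qcr, _qcr_from_logfc,
                                       arm_directional_sets, logfc_vs_mean,
                                       pair_qcr, pair_signature_concordance,
                                       significant_genes, signature_enrichment)


def make_matrix(values: np.ndarray, pair_ids=None, conditions=None):
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    if pair_ids is None:
        pair_ids = [f"pr{j // 2}" for j in range(values.shape[1])]
    if conditions is None:
        conditions = ["young"] * values.shape[1]
    meta = pd.DataFrame({"pair_id": pair_ids,
                         "slot": ["A", "B"] * (values.shape[1] // 2),
                         "condition": conditions}, index=cells)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes,
                                                columns=cells), metadata=meta)


class TestLogFC:
    def test_cell_at_global_mean_is_zero(self):
        m = make_matrix(np.full((5, 4), 7.0))
        assert np.allclose(logfc_vs_mean(m, "c0"), 0.0)

    def test_threefold_cell_approximates_log2_three(self):
        # one gene where cell c3 sits at 3x the global mean (incl. itself)
        vals = np.full((1, 4), 1000.0)
        vals[0, 3] = 9000.0  # mean = 3000, cell = 3 * mean
        m = make_matrix(vals)
        assert logfc_vs_mean(m, "c3").iloc[0] == pytest.approx(math.log2(3), abs=0.01)

    def test_matches_naive_recomputation(self, rng):
        vals = rng.lognormal(2, 1, size=(30, 6))
        m = make_matrix(vals)
        got = logfc_vs_mean(m, "c2", pseudocount=1.0).to_numpy()
        oracle = np.log2((vals[:, 2] + 1) / (vals.mean(axis=1) + 1))
        assert np.allclose(got, oracle)


class TestSignificantGenes:
    def test_identical_cells_give_empty_set(self):
        m = make_matrix(np.full((20, 6), 5.0))
        assert significant_genes(m, "c0") == frozenset()

    def test_strong_spike_recovered_with_high_power(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = np.exp(r.normal(3, 0.3, size=(501, 12)))
            base_sd_log2 = 0.3 / math.log(2)
            vals[0, 0] = np.exp(3) * 2 ** (10 * base_sd_log2)  # 10 SD up in c0
            m = make_matrix(vals)
            hits += "g0" in significant_genes(m, "c0")
        assert hits / 20 > 0.95

    def test_null_matrix_false_positives_controlled(self):
        counts = []
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            m = make_matrix(np.exp(r.normal(3, 0.5, size=(300, 10))))
            counts.append(len(significant_genes(m, "c0", alpha=0.05)))
        assert np.mean(counts) <= 0.05 * 300

    def test_too_few_cells_rejected(self):
        m = make_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            significant_genes(m, "c0")


class TestQCR:
    def test_quadrant_arithmetic(self):
        assert _qcr((30, 10, 40, 20)) == pytest.approx(0.4)

    def test_identical_folds_give_qcr_one(self, rng):
        f = rng.normal(size=40)
        res = _qcr_from_logfc("p", f, f.copy(), 200, None, 0)
        assert res.qcr == 1.0
        assert res.n_II == res.n_IV == 0

    def test_chi_squared_against_fifty_fifty(self, rng):
        # 70 concordant vs 30 discordant -> statistic 16
        fa = np.concatenate([np.ones(70), np.ones(30)])
        fb = np.concatenate([np.ones(70), -np.ones(30)])
        res = _qcr_from_logfc("p", fa, fb, 200, False, 0)
        assert res.chi2_p == pytest.approx(float(chi2.sf(16.0, 1)))

    def test_antisymmetry_under_sign_flip(self, rng):
        for _ in range(20):
            fa = rng.normal(size=25)
            fb = rng.normal(size=25)
            q1 = _qcr_from_logfc("p", fa, fb, 50, False, 0).qcr
            q2 = _qcr_from_logfc("p", fa, -fb, 50, False, 0).qcr
            assert q1 == -q2

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        fa = rng.normal(size=7)
        fb = rng.normal(size=7)
        exact = _qcr_from_logfc("p", fa, fb, 0, True, 0)
        mc = _qcr_from_logfc("p", fa, fb, 20000, False, rng)
        se = math.sqrt(exact.mc_p * (1 - exact.mc_p) / 20000)
        assert abs(mc.mc_p - exact.mc_p) < 4 * se + 2 / 20001

    def test_pair_call_on_planted_matrix(self, rng):
        # both daughters share a strong program over 30 genes
        vals = np.exp(rng.normal(3, 0.2, size=(300, 8)))
        idx = rng.choice(300, 30, replace=False)
        signs = rng.choice([-1.0, 1.0], 30)
        for c in (0, 1):  # pair pr0
            vals[idx, c] *= 2.0 ** (3 * signs)
        m = make_matrix(vals)
        res = pair_qcr(m, "pr0", n_permutations=2000, random_state=1)
        assert res.call == "concordant"
        assert res.qcr > 0.8

    def test_empty_union_flagged_degenerate(self):
        m = make_matrix(np.full((20, 6), 4.0))
        res = pair_qcr(m, "pr0")
        assert res.degenerate
        assert res.call == "concordant"


class TestSignatureEnrichment:
    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(10)]
        sig = GeneSignature("s", frozenset(universe[:5]))
        t = signature_enrichment(set(universe[:5]), universe, [sig])
        assert t["p_value"].iloc[0] == pytest.approx(1 / 252)

    def test_zero_overlap_not_enriched(self):
        universe = [f"g{i}" for i in range(100)]
        sig = GeneSignature("s", frozenset(universe[:5]))
        t = signature_enrichment(set(universe[50:55]), universe, [sig])
        assert t["p_value"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_signature_flagged(self):
        universe = [f"g{i}" for i in range(10)]
        sig = GeneSignature("s", frozenset(["x1", "x2"]))
        t = signature_enrichment(set(universe[:3]), universe, [sig])
        assert t["disjoint"].iloc[0]
        assert t["p_value"].iloc[0] == 1.0

    def test_matches_pmf_summation_oracle(self, rng):
        universe = [f"g{i}" for i in range(40)]
        for _ in range(10):
            members = frozenset(rng.choice(universe, 12, replace=False))
            cell_set = set(rng.choice(universe, 15, replace=False))
            t = signature_enrichment(cell_set, universe,
                                     [GeneSignature("s", members)])
            k = len(cell_set & members)
            oracle = sum(hypergeom.pmf(x, 40, 12, 15) for x in range(k, 13))
            assert t["p_value"].iloc[0] == pytest.approx(float(oracle), abs=1e-9)

    def test_invariant_to_gene_relabeling(self, rng):
        universe = [f"g{i}" for i in range(30)]
        mapping = {g: f"x{i}" for i, g in enumerate(universe)}
        members = frozenset(universe[:10])
        cell_set = set(universe[5:15])
        p1 = signature_enrichment(cell_set, universe,
                                  [GeneSignature("s", members)])["p_value"].iloc[0]
        p2 = signature_enrichment({mapping[g] for g in cell_set},
                                  [mapping[g] for g in universe],
                                  [GeneSignature("s", frozenset(
                                      mapping[g] for g in members))])["p_value"].iloc[0]
        assert p1 == p2


class TestSignatureConcordance:
    def table(self, pattern):
        return pd.DataFrame({"signature": [f"s{i}" for i in range(len(pattern))],
                             "significant": pattern})

    def test_identical_patterns_concordant_zero_statistic(self):
        pat = [True, False, True] * 4 + [False]
        out = pair_signature_concordance(self.table(pat), self.table(pat))
        assert out["statistic"] == 0
        assert out["call"] == "concordant"

    def test_complementary_patterns_discordant(self):
        pat = [True, False] * 6 + [True]
        out = pair_signature_concordance(self.table(pat),
                                         self.table([not v for v in pat]))
        assert out["statistic"] == 13
        assert out["call"] == "discordant"

    def test_p_monotone_in_mismatch_count(self):
        n = 13
        base = [False] * n
        ps = []
        for m in range(n + 1):
            other = [i < m for i in range(n)]
            ps.append(pair_signature_concordance(
                self.table(base), self.table(other))["p_value"])
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_all_nonsignificant_flagged_degenerate(self):
        pat = [False] * 13
        out = pair_signature_concordance(self.table(pat), self.table(pat))
        assert out["degenerate"]
        assert out["call"] == "concordant"


class TestArmDirectionalSets:
    def planted_matrix(self, rng, effects):
        """effects: condition -> (up gene idx, down gene idx)."""
        n_genes, per_cond = 200, 6
        conds = list(effects)
        vals = np.exp(rng.normal(3, 0.15, size=(n_genes, per_cond * len(conds))))
        conditions = []
        for ci, cond in enumerate(conds):
            up, down = effects[cond]
            cols = slice(ci * per_cond, (ci + 1) * per_cond)
            vals[np.ix_(up, range(*cols.indices(vals.shape[1])))] *= 8.0
            vals[np.ix_(down, range(*cols.indices(vals.shape[1])))] /= 8.0
            conditions += [cond] * per_cond
        return make_matrix(vals, conditions=conditions)

    def test_duplicated_arm_gives_pure_intersection(self, rng):
        up = [0, 1, 2]
        down = [10, 11]
        m = self.planted_matrix(rng, {
            "young": (up, down), "aged_CASIN": (up, down),
            "aged": ([], []), "young_Wnt5a": ([], [])})
        out = arm_directional_sets(m, ("young", "aged_CASIN"),
                                   ("young", "aged_CASIN"))
        assert out["up"]["arm_a_only"] == frozenset()
        assert out["up"]["arm_b_only"] == frozenset()
        assert {f"g{i}" for i in up} <= out["up"]["both"]

    def test_disjoint_planted_signals_recovered(self, rng):
        m = self.planted_matrix(rng, {
            "young": ([0, 1], [20]), "aged_CASIN": ([0, 1], [20]),
            "aged": ([40, 41], [60]), "young_Wnt5a": ([40, 41], [60])})
        out = arm_directional_sets(m, ("young", "aged_CASIN"),
                                   ("aged", "young_Wnt5a"))
        assert {"g0", "g1"} <= out["up"]["arm_a_only"]
        assert {"g40", "g41"} <= out["up"]["arm_b_only"]
        assert "g20" in out["down"]["arm_a_only"]
        assert "g60" in out["down"]["arm_b_only"]

    def test_no_signal_gives_sparse_partitions(self, rng):
        m = self.planted_matrix(rng, {
            "young": ([], []), "aged_CASIN": ([], []),
            "aged": ([], []), "young_Wnt5a": ([], [])})
        out = arm_directional_sets(m, ("young", "aged_CASIN"),
                                   ("aged", "young_Wnt5a"))
        # chance double-hits at alpha 0.05 in two conditions are rare
        total = sum(len(s) for d in out.values() for s in d.values())
        assert total <= 5
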