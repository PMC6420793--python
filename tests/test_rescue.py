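"""Rescue status, fidelity, strength, gene sets and overlap testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rescuemap.rescue import (AnalysisParams, classify_rescue_status,
                              direction_fidelity, rescue_strength,
                              strata_rescue_summary, twofold_gene_sets,
                              venn_overlap_test)

PARAMS = AnalysisParams()


def _de(genes, lfc, padj):
    return pd.DataFrame({"gene": genes, "log2fc": lfc, "padj": padj})


class TestClassification:
    def test_four_way_examples(self):
        endo = _de(["a", "b", "c"], [2.0, 1.0, 0.1], [0.01, 0.01, 0.40])
        cons = _de(["a", "b", "c"], [1.0, -0.2, 0.0], [0.03, 0.50, 0.40])
        out = classify_rescue_status(endo, cons, PARAMS).set_index("gene")
        assert out.at["a", "status"] == "both_significant"
        assert bool(out.at["a", "concordant"]) is True
        assert out.at["b", "status"] == "kd_only"
        assert out.at["c", "status"] == "neither"

    def test_discordant_directions(self):
        endo = _de(["a"], [2.0], [0.01])
        cons = _de(["a"], [-1.0], [0.01])
        out = classify_rescue_status(endo, cons, PARAMS)
        assert bool(out["concordant"].iloc[0]) is False

    def test_missing_gene_conservative_and_flagged(self):
        endo = _de(["a", "b"], [2.0, 1.0], [0.01, 0.01])
        cons = _de(["a"], [1.0], [0.01])
        out = classify_rescue_status(endo, cons, PARAMS).set_index("gene")
        assert out.at["b", "status"] == "kd_only"
        assert bool(out.at["b", "flagged"])

    def test_statuses_partition_universe(self, small_sim):
        from rescuemap.diff_expr import Contrast, differential_expression
        from rescuemap.preprocess import filter_low_counts

        cfg, counts, samples, _ = small_sim
        filt = filter_low_counts(counts)
        endo = differential_expression(filt, samples, Contrast("iLuc", "iEF"))
        cons = differential_expression(filt, samples, Contrast("WT", "iEF"))
        calls = classify_rescue_status(endo, cons, PARAMS)
        universe = set(endo["gene"]) | set(cons["gene"])
        assert len(calls) == len(universe)
        assert calls["status"].value_counts().sum() == len(universe)

    def test_disjoint_universes_error(self):
        with pytest.raises(ValueError, match="share no genes"):
            classify_rescue_status(_de(["a"], [1], [0.1]), _de(["b"], [1], [0.1]), PARAMS)


class TestFidelity:
    def test_dead_construct_all_unchanged(self):
        endo = _de(list("abcd"), [2, -2, 1, 0.1], [0.01, 0.01, 0.01, 0.9])
        cons = _de(list("abcd"), [0, 0, 0, 0], [0.9, 0.9, 0.9, 0.9])
        calls = classify_rescue_status(endo, cons, PARAMS)
        fid = direction_fidelity({"X": calls}, None, PARAMS)
        assert fid["frac_unchanged"].iloc[0] == 1.0

    def test_perfect_rescue(self):
        endo = _de(list("abc"), [2, -2, 1], [0.01, 0.01, 0.01])
        calls = classify_rescue_status(endo, endo.copy(), PARAMS)
        fid = direction_fidelity({"X": calls}, None, PARAMS)
        assert fid["frac_rescued_concordant"].iloc[0] == 1.0
        assert fid["frac_paradoxical"].iloc[0] == 0.0

    def test_fractions_sum_to_one(self, small_sim):
        from rescuemap.diff_expr import Contrast, differential_expression
        from rescuemap.preprocess import filter_low_counts

        cfg, counts, samples, _ = small_sim
        filt = filter_low_counts(counts)
        endo = differential_expression(filt, samples, Contrast("iLuc", "iEF"))
        cons = differential_expression(filt, samples, Contrast("WT", "iEF"))
        calls = classify_rescue_status(endo, cons, PARAMS)
        fid = direction_fidelity({"WT": calls}, None, PARAMS)
        total = (fid["frac_rescued_concordant"] + fid["frac_paradoxical"]
                 + fid["frac_unchanged"])
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_rescue_only_genes_excluded(self):
        endo = _de(list("ab"), [2, 0.1], [0.01, 0.9])
        cons = _de(list("ab"), [1, 3.0], [0.01, 0.001])  # b is rescue_only
        calls = classify_rescue_status(endo, cons, PARAMS)
        fid = direction_fidelity({"X": calls}, None, PARAMS)
        assert fid["n_endo_regulated"].iloc[0] == 1


class TestStrength:
    def test_identity_rescue_exact(self):
        endo = _de([f"g{i}" for i in range(10)],
                   np.linspace(-3, 3, 10), np.full(10, 0.001))
        st_ = rescue_strength(endo, endo.copy(), params=PARAMS)
        assert st_.pearson_r == 1.0
        assert st_.slope == 1.0
        assert st_.r_pvalue == 0.0

    def test_exact_attenuation(self):
        endo = _de([f"g{i}" for i in range(8)],
                   np.linspace(-2, 2, 8), np.full(8, 0.001))
        half = endo.copy()
        half["log2fc"] = 0.5 * half["log2fc"]
        st_ = rescue_strength(endo, half, params=PARAMS)
        assert st_.pearson_r == 1.0
        assert st_.slope == 0.5

    def test_matches_scipy_on_noisy_data(self, rng):
        x = rng.normal(0, 2, 200)
        y = 0.8 * x + rng.normal(0, 0.3, 200)
        genes = [f"g{i}" for i in range(200)]
        endo = _de(genes, x, np.full(200, 0.001))
        cons = _de(genes, y, np.full(200, 0.001))
        st_ = rescue_strength(endo, cons, params=PARAMS)
        ref = stats.linregress(x, y)
        assert st_.slope == pytest.approx(ref.slope, rel=1e-10)
        assert st_.pearson_r == pytest.approx(ref.rvalue, rel=1e-10)
        assert st_.r_pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_attenuation_recovered_with_noise(self, rng):
        x = np.concatenate([rng.normal(3, 0.8, 150), rng.normal(-3, 0.8, 150)])
        y = 0.8 * x + rng.normal(0, 0.3, 300)
        genes = [f"g{i}" for i in range(300)]
        st_ = rescue_strength(_de(genes, x, np.full(300, 1e-3)),
                              _de(genes, y, np.full(300, 1e-3)), params=PARAMS)
        assert 0.7 <= st_.slope <= 0.9

    def test_undefined_below_three_genes(self):
        endo = _de(["a", "b"], [1, 2], [0.01, 0.01])
        st_ = rescue_strength(endo, endo.copy(), params=PARAMS)
        assert st_.n == 2 and np.isnan(st_.slope)


class TestTwofoldSets:
    def test_boundary_strictness(self):
        de = _de(["a", "b", "c"], [1.0, 1.1, 3.0], [0.01, 0.01, 0.2])
        act, rep = twofold_gene_sets(de, PARAMS)
        assert act == {"b"}  # exactly 2-fold excluded; non-significant excluded
        assert rep == set()

    def test_repressed_symmetric(self):
        de = _de(["a", "b"], [-1.5, -0.5], [0.01, 0.01])
        act, rep = twofold_gene_sets(de, PARAMS)
        assert rep == {"a"} and act == set()


class TestVenn:
    def test_identical_sets_closed_form(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(50)}
        res = venn_overlap_test(a, set(a), universe)
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-20

    def test_independence_point_zero_statistic(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(50)}
        b = {f"g{i}" for i in range(25, 75)}  # overlap 25 = |A||B|/N
        res = venn_overlap_test(a, b, universe)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_contingency(self, rng):
        universe = [f"g{i}" for i in range(500)]
        for _ in range(50):
            a = set(rng.choice(universe, 80, replace=False))
            b = set(rng.choice(universe, 120, replace=False))
            res = venn_overlap_test(a, b, set(universe))
            table = np.array([
                [len(a & b), len(a - b)],
                [len(b - a), 500 - len(a | b)],
            ])
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-12)

    def test_swap_symmetry(self, rng):
        universe = {f"g{i}" for i in range(200)}
        a = set(list(universe)[:40])
        b = set(list(universe)[30:90])
        r1 = venn_overlap_test(a, b, universe)
        r2 = venn_overlap_test(b, a, universe)
        assert r1.chi2 == r2.chi2 and r1.p == r2.p

    def test_degenerate_margin_undefined(self):
        universe = {"a", "b", "c"}
        res = venn_overlap_test(set(), {"a"}, universe)
        assert np.isnan(res.p) and res.reason

    def test_type_one_error_rate(self, rng):
        universe = np.array([f"g{i}" for i in range(10_000)])
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            a = set(rng.choice(universe, 1000, replace=False))
            b = set(rng.choice(universe, 1000, replace=False))
            res = venn_overlap_test(a, b, set(universe))
            rejections += res.p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestStrataAndRecovery:
    def test_single_stratum_all_concordant(self):
        genes = [f"g{i}" for i in range(10)]
        endo = _de(genes, np.linspace(1, 3, 10), np.full(10, 0.001))
        calls = classify_rescue_status(endo, endo.copy(), PARAMS)
        out = strata_rescue_summary({"X": calls}, None, endo, {"X": endo.copy()}, PARAMS)
        top = out.sort_values("proportion", ascending=False).iloc[0]
        assert top["status"] == "both_significant"
        assert top["proportion"] == 1.0

    def test_proportions_sum_to_one_per_stratum(self, small_sim):
        from rescuemap.diff_expr import Contrast, differential_expression
        from rescuemap.preprocess import filter_low_counts

        cfg, counts, samples, _ = small_sim
        filt = filter_low_counts(counts)
        endo = differential_expression(filt, samples, Contrast("iLuc", "iEF"))
        cons = {"WT": differential_expression(filt, samples, Contrast("WT", "iEF"))}
        calls = {"WT": classify_rescue_status(endo, cons["WT"], PARAMS)}
        out = strata_rescue_summary(calls, None, endo, cons, PARAMS)
        sums = out.groupby(["construct", "element_class"])["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_paradox_fraction_recovery(self):
        """Planted 30% paradoxical regulation among rescued genes is recovered."""
        from rescuemap.pipeline import rescue_tables
        from rescuemap.simulate import ConstructEffect, simulate_experiment

        from conftest import small_config

        cfg = small_config(
            n_genes=2000, conditions=("iLuc", "iEF", "DAF"),
            frac_endo_activated=0.15, frac_endo_repressed=0.15,
            construct_effects={"DAF": ConstructEffect(0.5, 0.6, 0.30)}, seed=11)
        counts, samples, truth = simulate_experiment(cfg)
        endo, tables, _, _ = rescue_tables(counts, samples, ["DAF"], PARAMS)
        calls = classify_rescue_status(endo, tables["DAF"], PARAMS)
        fid = direction_fidelity({"DAF": calls}, None, PARAMS)
        rescued = fid["frac_rescued_concordant"] + fid["frac_paradoxical"]
        paradox = float(fid["frac_paradoxical"].iloc[0] / rescued.iloc[0])
        assert abs(paradox - 0.30) <= 0.07
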