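"""Differential-expression screen: size factors, dispersion, exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from difconet import (CountMatrix, bh_adjust, call_degs, classify_calls,
                      estimate_dispersion, estimate_size_factors,
                      generate_counts, nb_exact_test, split_by_direction,
                      SimulationConfig)
from oracles import bh_brute, binomial_two_sided_p, nb_exact_p_brute


def frame(rows, samples=None):
    samples = samples or [f"s{j}" for j in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=samples,
                        index=[f"g{i}" for i in range(len(rows))])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        df = frame([[10, 10], [3, 3], [77, 77]])
        assert np.allclose(estimate_size_factors(df), [1.0, 1.0])

    def test_doubled_column(self):
        df = frame([[10, 20], [30, 60], [5, 10]])
        s = estimate_size_factors(df)
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_hand_evaluated_median_of_ratios(self):
        # geometric means: sqrt(200), 30, sqrt(5000); column ratios
        # (0.7071, 1, 1.4142) and (1.4142, 1, 0.7071) -> medians (1, 1)
        df = frame([[10, 20], [30, 30], [100, 50]])
        assert np.allclose(estimate_size_factors(df), [1.0, 1.0])

    def test_no_all_positive_gene_raises(self):
        df = frame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="strictly positive"):
            estimate_size_factors(df)

    @given(st.floats(min_value=0.1, max_value=10.0), st.integers(min_value=0, max_value=3))
    def test_scaling_one_column_scales_its_ratio_by_c(self, c, col):
        rng = np.random.default_rng(0)
        base = frame(rng.integers(1, 200, size=(20, 4)).tolist())
        s0 = estimate_size_factors(base)
        scaled = base.copy().astype(float)
        scaled.iloc[:, col] *= c
        s1 = estimate_size_factors(scaled)
        other = (col + 1) % 4
        ratio0 = s0.iloc[col] / s0.iloc[other]
        ratio1 = s1.iloc[col] / s1.iloc[other]
        assert ratio1 == pytest.approx(c * ratio0, rel=1e-9)


class TestDispersion:
    def test_zero_variance_clamps_to_floor(self):
        cm = CountMatrix(frame([[5, 5, 5, 5]], samples=["A1", "A2", "B1", "B2"]),
                         pd.Series(["A", "A", "B", "B"], index=["A1", "A2", "B1", "B2"]))
        s = estimate_size_factors(cm)
        assert estimate_dispersion(cm, s).iloc[0] == pytest.approx(1e-8)

    def test_monte_carlo_recovery(self):
        # NB(mu=100, alpha=0.2), 50 samples per condition
        rng = np.random.default_rng(12)
        r = 1 / 0.2
        counts = rng.negative_binomial(r, r / (r + 100), size=(40, 100))
        samples = [f"A{i}" for i in range(50)] + [f"B{i}" for i in range(50)]
        cm = CountMatrix(pd.DataFrame(counts, columns=samples,
                                      index=[f"g{i}" for i in range(40)]),
                         pd.Series(["A"] * 50 + ["B"] * 50, index=samples))
        s = estimate_size_factors(cm)
        alpha = estimate_dispersion(cm, s)
        assert np.median(alpha) == pytest.approx(0.2, rel=0.5)

    def test_poisson_gene_estimate_vanishes_with_n(self):
        rng = np.random.default_rng(3)
        n = 2000
        counts = rng.poisson(100, size=(10, 2 * n))
        samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
        cm = CountMatrix(pd.DataFrame(counts, columns=samples,
                                      index=[f"g{i}" for i in range(10)]),
                         pd.Series(["A"] * n + ["B"] * n, index=samples))
        alpha = estimate_dispersion(cm, estimate_size_factors(cm))
        assert alpha.max() < 1e-3


class TestNBExactTest:
    def test_balanced_split_at_mode_gives_p_one(self):
        assert nb_exact_test(30, 30, 30, 30, 50, 50) == pytest.approx(1.0)

    def test_poisson_case_matches_binomial(self):
        # T=4, symmetric Poisson(2) both sides -> conditional is Binomial(4, 1/2)
        for k in range(5):
            p = nb_exact_test(k, 4 - k, 2, 2, 2, 2)
            assert p == pytest.approx(binomial_two_sided_p(k, 4), rel=1e-9)

    def test_small_nb_example_matches_enumeration(self):
        # T=20, mu=10, alpha=0.1 (var = 20), observed split (18, 2)
        p = nb_exact_test(18, 2, 10, 10, 20, 20)
        assert p == pytest.approx(nb_exact_p_brute(18, 2, 10, 10, 20, 20), rel=1e-9)
        assert p < 0.05

    def test_condition_swap_symmetry(self):
        p1 = nb_exact_test(17, 5, 9.0, 13.0, 20.0, 30.0)
        p2 = nb_exact_test(5, 17, 13.0, 9.0, 30.0, 20.0)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_non_integer_sum_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(1.5, 2, 2, 2, 2, 2)

    def test_zero_total(self):
        assert nb_exact_test(0, 0, 5, 5, 10, 10) == 1.0

    def test_normal_approximation_fallback_reasonable(self):
        # same parameters enumerated vs forced approximation: p close
        args = (5400, 4600, 5000.0, 5000.0, 20000.0, 20000.0)
        exact = nb_exact_test(*args)
        approx = nb_exact_test(*args, max_total=100)
        assert approx == pytest.approx(exact, rel=0.1)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_evaluated_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        q = bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=100))
    def test_matches_brute_force_definition(self, ps):
        assert np.allclose(bh_adjust(ps), bh_brute(ps))

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCalls:
    def test_dual_threshold_rule(self):
        calls = classify_calls(
            log2fc=[0.60, 0.50, -0.60, 0.60, -3.0],
            fdr=[0.04, 0.04, 0.04, 0.06, 0.01],
        )
        assert list(calls) == ["up", "ns", "down", "ns", "down"]

    def test_boundary_equalities_included(self):
        calls = classify_calls(log2fc=[0.585, -0.585], fdr=[0.05, 0.05])
        assert list(calls) == ["up", "down"]


class TestCallDegs:
    def test_all_zero_genes_dropped_and_logged(self, small_cm):
        counts = small_cm.counts.copy()
        counts.loc["gdead"] = 0
        cm = CountMatrix(counts, small_cm.condition)
        table = call_degs(cm)
        assert "gdead" not in table.index
        assert table.attrs["dropped_all_zero"] == ["gdead"]
        assert set(table.columns) == {"base_mean_A", "base_mean_B", "log2fc",
                                      "p_value", "fdr", "call"}

    def test_fdr_monotone_and_bounded(self, sim_default):
        _, cm, _ = sim_default
        table = call_degs(cm)
        assert ((table["fdr"] >= table["p_value"] - 1e-12)).all()
        assert table["p_value"].between(0, 1).all()

    def test_planted_recovery_improves_with_effect_size(self):
        detected = []
        for lfc in (0.8, 2.0):
            cfg = SimulationConfig(n_genes=400, deg_fraction=0.1,
                                   lfc_magnitude=lfc, seed=21)
            cm, truth = generate_counts(cfg)
            up, down = split_by_direction(call_degs(cm))
            detected.append(len((up | down) & truth.deg_ids))
        assert detected[1] >= detected[0]

    def test_direction_convention_b_over_a(self):
        # gene with much higher counts in B must be called up
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.poisson(100, size=(60, 6)),
                              index=[f"g{i}" for i in range(60)],
                              columns=["A1", "A2", "A3", "B1", "B2", "B3"])
        counts.loc["g0", ["B1", "B2", "B3"]] = 800
        cm = CountMatrix(counts, pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns))
        table = call_degs(cm)
        assert table.loc["g0", "log2fc"] > 0
        assert table.loc["g0", "call"] == "up"
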