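"""TPM, fold change, Audic-Claverie test, differential calling, ddCt."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import ac_pmf_exact, ac_test_exact
from srnapipe.diffexpr import (
    CountMatrix,
    ac_probability,
    ac_test,
    call_differential,
    de_partition,
    log2_fold_change,
    relative_expression_ddct,
    tpm_normalize,
)


def make_cm(counts: dict, totals: dict) -> CountMatrix:
    return CountMatrix(pd.DataFrame(counts), totals)


class TestTpm:
    def test_formula_identity(self):
        cm = make_cm({"lib": {"m1": 5, "m2": 0}}, {"lib": 1_000_000})
        tpm = tpm_normalize(cm)
        assert tpm.loc["m1", "lib"] == 5.0
        assert tpm.loc["m2", "lib"] == 0.0

    def test_highly_expressed_mirna(self):
        # the most abundant miRNA of the duodenum library
        cm = make_cm({"DU": {"miR-143": 4_606_500}}, {"DU": 27_498_891})
        assert tpm_normalize(cm).loc["miR-143", "DU"] == pytest.approx(
            167_515.9, abs=0.1
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            CountMatrix(pd.DataFrame({"lib": {"m1": 0}}), {"lib": 0})
            tpm_normalize(make_cm({"lib": {"m1": 0}}, {"lib": 0}))


class TestFoldChange:
    def test_examples(self):
        assert log2_fold_change(40, 10, pseudocount=0) == pytest.approx(2.0)
        assert log2_fold_change(7.5, 7.5) == 0.0
        assert log2_fold_change(0, 10, pseudocount=0.01) == pytest.approx(
            math.log2(0.01 / 10.01)
        )


class TestAcProbability:
    def test_trivial_point(self):
        assert ac_probability(0, 0, 10, 10) == pytest.approx(0.5)

    def test_exact_binomial_point(self):
        # x=2, y=5, N1=N2: C(7,5)/2^8 = 21/256
        assert ac_probability(5, 2, 1000, 1000) == pytest.approx(21 / 256, abs=1e-12)

    def test_matches_exact_rational_oracle_small_grid(self):
        for n1, n2 in [(100, 100), (100, 200), (300, 100)]:
            for x in range(0, 13, 3):
                for y in range(0, 13, 3):
                    exact = float(ac_pmf_exact(y, x, n1, n2))
                    assert ac_probability(y, x, n1, n2) == pytest.approx(
                        exact, abs=1e-12
                    )

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    def test_normalization(self, ratio):
        n1 = 1000
        n2 = int(ratio * n1)
        total = sum(ac_probability(y, 10, n1, n2) for y in range(0, 2001))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestAcTest:
    def test_equal_counts_not_significant(self):
        assert ac_test(7, 7, 500, 500) >= 0.5

    def test_extreme_difference_tiny_p(self):
        assert ac_test(100, 0, 10_000, 10_000) < 1e-20

    def test_matches_exact_rational_oracle(self):
        for x, y in [(0, 0), (3, 9), (9, 3), (20, 5), (2, 2)]:
            for n1, n2 in [(100, 100), (100, 200)]:
                exact = float(ac_test_exact(x, y, n1, n2))
                assert ac_test(x, y, n1, n2) == pytest.approx(exact, abs=1e-10)

    def test_upper_tail_monotone_in_y(self):
        prev = None
        for y in range(0, 40):
            one_sided_upper = 1.0 - sum(
                ac_probability(t, 10, 100, 100) for t in range(0, y)
            )
            if prev is not None:
                assert one_sided_upper <= prev + 1e-12
            prev = one_sided_upper

    def test_one_sided_is_half_of_two_sided_when_uncapped(self):
        p2 = ac_test(30, 5, 1000, 1000)
        p1 = ac_test(30, 5, 1000, 1000, alternative="one-sided")
        assert p2 == pytest.approx(min(1.0, 2 * p1))


class TestCallDifferential:
    def test_identical_columns_yield_no_calls(self):
        counts = {"a": {f"m{i}": 50 + i for i in range(8)}}
        counts["b"] = dict(counts["a"])
        cm = make_cm(counts, {"a": 10_000, "b": 10_000})
        result = call_differential(cm, ("a", "b"))
        assert not result["significant"].any()
        assert (result["p_bonferroni"] >= result["p_raw"]).all()

    def test_planted_fold_recovered_with_direction(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(200, 20)
        counts = pd.DataFrame(
            {"a": base.copy(), "b": base.copy()}, index=[f"m{i}" for i in range(20)]
        )
        counts.loc["m0", "a"] = rng.poisson(800)
        cm = CountMatrix(counts, {"a": 50_000, "b": 50_000})
        result = call_differential(cm, ("a", "b")).set_index("mirna")
        assert result.loc["m0", "significant"]
        assert result.loc["m0", "direction"] == "up_in_a"
        assert abs(result.loc["m0", "log2fc"]) >= 1

    def test_partition_identity(self, pipeline_result):
        for result in pipeline_result.de_results.values():
            part = de_partition(result)
            assert part["up_in_a"] + part["up_in_b"] == part["total"]

    def test_bonferroni_uses_tested_count(self):
        counts = pd.DataFrame(
            {"a": [100, 0, 50], "b": [10, 0, 50]}, index=["m0", "m1", "m2"]
        )
        cm = CountMatrix(counts, {"a": 10_000, "b": 10_000})
        result = call_differential(cm, ("a", "b"))
        assert set(result["mirna"]) == {"m0", "m2"}  # all-zero row untested
        row = result.set_index("mirna").loc["m0"]
        assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 2))


class TestDdct:
    def test_examples(self):
        assert relative_expression_ddct(20, 20, 20, 20) == 1.0
        assert relative_expression_ddct(19, 20, 20, 20) == pytest.approx(2.0)
        assert relative_expression_ddct(24.32, 21, 21, 21) == pytest.approx(
            2 ** -3.32
        )
        assert relative_expression_ddct(24.32, 21, 21, 21) == pytest.approx(0.1, abs=0.005)
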