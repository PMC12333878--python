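"""Age residualization, permutation testing and Bonferroni decisions."""

import numpy as np
import pandas as pd
import pytest

from dfcdist import (
    ComparisonResult,
    ComparisonSpec,
    DataError,
    bonferroni_threshold,
    permutation_test,
    regress_out_age,
    run_comparison,
)
from dfcdist.inference import PermutationResult

from oracles import exhaustive_permutation_p


class TestRegressOutAge:
    def test_values_independent_of_age_reduce_to_centering(self):
        ages = np.array([60.0, 65.0, 70.0, 75.0])
        values = np.array([5.0, 3.0, 3.0, 5.0])  # orthogonal to centered age
        resid = regress_out_age(values, ages)
        assert np.allclose(resid, values - values.mean())

    def test_perfect_linear_relation_leaves_zero_residuals(self):
        ages = np.array([60.0, 70.0, 80.0, 90.0])
        resid = regress_out_age(2.0 * ages, ages)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_normal_equations_worked_example(self):
        resid = regress_out_age([1.0, 2.0, 4.0], [60.0, 70.0, 80.0])
        assert np.allclose(resid, [1 / 6, -1 / 3, 1 / 6])

    def test_residuals_centered_and_orthogonal_to_age(self, rng):
        ages = rng.uniform(45, 95, size=30)
        values = 0.03 * ages + rng.normal(size=30)
        resid = regress_out_age(values, ages)
        assert abs(resid.sum()) < 1e-8
        assert abs(resid @ (ages - ages.mean())) < 1e-6

    def test_error_contracts(self):
        with pytest.raises(DataError, match="constant"):
            regress_out_age([1.0, 2.0, 3.0], [70.0, 70.0, 70.0])
        with pytest.raises(DataError, match="equal length"):
            regress_out_age([1.0, 2.0], [70.0, 71.0, 72.0])
        with pytest.raises(DataError, match="at least 3"):
            regress_out_age([1.0, 2.0], [70.0, 71.0])


class TestPermutationTest:
    def test_identical_pooled_values_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        res = permutation_test(x, x.copy(), n_permutations=200, seed=0)
        assert res.t_obs == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_worked_example(self):
        res = permutation_test([10.0, 11.0], [0.0, 1.0])
        assert res.exhaustive
        assert res.t_obs == pytest.approx(10.0)
        assert res.p_value == pytest.approx(2 / 6)
        assert res.n_permutations == 6

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            m = int(rng.integers(1, 6))
            n = int(rng.integers(1, 11 - m))
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            res = permutation_test(x, y, exhaustive=True)
            t_obs, p = exhaustive_permutation_p(x, y)
            assert res.t_obs == pytest.approx(t_obs)
            assert res.p_value == pytest.approx(p)

    def test_monte_carlo_determinism_and_argument_symmetry(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=15)
        a = permutation_test(x, y, n_permutations=500, seed=42, exhaustive=False)
        b = permutation_test(x, y, n_permutations=500, seed=42, exhaustive=False)
        c = permutation_test(y, x, n_permutations=500, seed=42, exhaustive=False)
        assert a.p_value == b.p_value
        assert not a.exhaustive
        assert a.t_obs == pytest.approx(c.t_obs)

    def test_location_and_scale_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        base = permutation_test(x, y, n_permutations=300, seed=7, exhaustive=False)
        shift = permutation_test(x + 5, y + 5, n_permutations=300, seed=7,
                                 exhaustive=False)
        scale = permutation_test(3 * x, 3 * y, n_permutations=300, seed=7,
                                 exhaustive=False)
        assert shift.t_obs == pytest.approx(base.t_obs)
        assert shift.p_value == base.p_value
        assert scale.t_obs == pytest.approx(3 * base.t_obs)
        assert scale.p_value == base.p_value

    def test_smoothed_estimator(self):
        res = permutation_test([10.0, 11.0], [0.0, 1.0], smooth=True)
        assert res.p_value == pytest.approx(3 / 7)  # (1 + 2) / (1 + 6)

    def test_empty_group_rejected(self):
        with pytest.raises(DataError, match="non-empty"):
            permutation_test([], [1.0])


class TestBonferroni:
    def test_family_of_eight(self):
        thr = bonferroni_threshold(0.05, 8)
        assert thr == pytest.approx(0.00625)
        assert f"{thr:.3f}" == "0.006"

    def test_no_correction_and_inverse_identity(self):
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        assert bonferroni_threshold(0.04, 7) * 7 == pytest.approx(0.04)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.002, True), (0.053, False), (0.00625, True), (0.0063, False)],
    )
    def test_decision_rule_is_non_strict(self, p, expected):
        perm = PermutationResult(t_obs=1.0, p_value=p, n_permutations=1000,
                                 group_sizes=(5, 5), exhaustive=False)
        spec = ComparisonSpec(("NC", "DEMENTIA"), "F", "peak_based", "frobenius")
        res = ComparisonResult(spec=spec, permutation=perm,
                               bonferroni_threshold=0.00625)
        assert res.significant is expected


class TestRunComparison:
    def make_tables(self, rng, n=8, dementia_shift=0.0):
        rows, meta = [], []
        k = 0
        for diagnosis in ("NC", "DEMENTIA"):
            for sex in ("F", "M"):
                for _ in range(n):
                    sid = f"s{k}"
                    k += 1
                    mean = rng.normal() + (dementia_shift if diagnosis == "DEMENTIA" else 0)
                    rows.append(dict(subject_id=sid, metric="frobenius",
                                     mean_value=mean, peak_value=mean + 1.0,
                                     series_length=40))
                    meta.append(dict(subject_id=sid, age=float(rng.uniform(50, 90)),
                                     sex=sex, diagnosis=diagnosis))
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def test_detects_large_group_shift(self, rng):
        summaries, meta = self.make_tables(rng, dementia_shift=50.0)
        spec = ComparisonSpec(("NC", "DEMENTIA"), "F", "mean_based", "frobenius",
                              n_permutations=999, seed=1)
        res = run_comparison(summaries, meta, spec)
        assert res.p_value <= 0.01
        assert res.significant

    def test_deterministic_across_calls(self, rng):
        summaries, meta = self.make_tables(rng)
        spec = ComparisonSpec(("NC", "DEMENTIA"), "M", "peak_based", "frobenius",
                              n_permutations=499, seed=5, exhaustive=False)
        assert (run_comparison(summaries, meta, spec).p_value
                == run_comparison(summaries, meta, spec).p_value)

    def test_empty_stratum_reports_counts(self, rng):
        summaries, meta = self.make_tables(rng)
        spec = ComparisonSpec(("NC", "MCI"), "F", "mean_based", "frobenius")
        with pytest.raises(DataError, match="MCI=0"):
            run_comparison(summaries, meta, spec)
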