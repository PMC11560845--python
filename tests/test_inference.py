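import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from symbiopop.inference import (
    RoundMeasurement,
    delayed_fraction,
    estimate_proportion,
    estimate_transmission_params,
    filter_sweeping_mutations,
    fitness_table,
    germination_success,
    model_fit_error,
    sweep_fitness_correlation,
    welch_t_test,
    wilcoxon_signed_rank,
)
from symbiopop.model import TransmissionParams, Trajectory, fitness_index

from ._oracles import spearman_bruteforce, wilcoxon_enumerate


def make_measurement(**overrides):
    base = dict(
        line_id="L1", round=1,
        facs_analyzed=100_000, facs_positive=10,
        wells_sorted_pos=288, germinated_day1_pos=10, germinated_day2_pos=18,
        wells_sorted_neg=96, germinated_day1_neg=55, germinated_day2_neg=60,
    )
    base.update(overrides)
    return RoundMeasurement(**base)


class TestRoundMeasurement:
    def test_day_ordering_enforced(self):
        with pytest.raises(ValueError, match="day1"):
            make_measurement(germinated_day1_pos=20, germinated_day2_pos=18)

    def test_positives_cannot_exceed_analyzed(self):
        with pytest.raises(ValueError, match="facs_positive"):
            make_measurement(facs_positive=200_000)

    def test_optional_negative_arm(self):
        m = make_measurement(
            wells_sorted_neg=None, germinated_day1_neg=None, germinated_day2_neg=None
        )
        assert not m.has_negative_arm

    def test_incomplete_arm_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            make_measurement(wells_sorted_neg=None)


class TestEstimateProportion:
    def test_point(self):
        assert estimate_proportion(63, 100).point == 0.63

    def test_full_success_upper_is_one(self):
        est = estimate_proportion(50, 50, method="clopper_pearson")
        assert est.point == 1.0
        assert est.upper == 1.0

    def test_zero_count_clopper_pearson_bound(self):
        # closed form: upper = 1 - 0.025^(1/n)
        est = estimate_proportion(0, 100, method="clopper_pearson")
        assert est.lower == 0.0
        assert est.upper == pytest.approx(1 - 0.025 ** (1 / 100), rel=1e-9)

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_proportion(0, 0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            estimate_proportion(1, 10, method="wald")

    @given(k=st.integers(0, 50), n=st.integers(1, 50))
    def test_interval_brackets_point(self, k, n):
        if k > n:
            return
        for method in ("wilson", "clopper_pearson"):
            est = estimate_proportion(k, n, method=method)
            assert 0.0 <= est.lower <= est.point <= est.upper <= 1.0

    def test_wilson_coverage(self):
        # 500 synthetic datasets at known p: 95% intervals cover the truth
        # in 90-99% of cases
        rng = np.random.default_rng(2024)
        p_true, n = 0.3, 200
        covered = 0
        for _ in range(500):
            k = rng.binomial(n, p_true)
            est = estimate_proportion(k, n)
            covered += est.lower <= p_true <= est.upper
        assert 0.90 <= covered / 500 <= 0.99


class TestGerminationSuccess:
    def test_full(self):
        assert germination_success(288, 288) == 1.0

    def test_none(self):
        assert germination_success(288, 0) == 0.0

    def test_fraction(self):
        assert germination_success(288, 18) == 0.0625

    def test_zero_wells_rejected(self):
        with pytest.raises(ValueError):
            germination_success(0, 0)


class TestDelayedFraction:
    def test_no_delay(self):
        assert delayed_fraction(50, 50) == 0.0

    def test_fraction(self):
        assert delayed_fraction(40, 50) == pytest.approx(0.2)

    def test_no_germlings_is_undefined(self):
        assert math.isnan(delayed_fraction(0, 0))

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            delayed_fraction(10, 5)


class TestFitnessTable:
    def test_arithmetic_chain(self):
        table = fitness_table([make_measurement()])
        row = table.iloc[0]
        assert row["positive_fraction"] == pytest.approx(1e-4)
        assert row["germination_pos"] == pytest.approx(0.0625)
        assert row["fitness_index"] == pytest.approx(6.25e-6)

    def test_zero_positives(self):
        table = fitness_table([make_measurement(facs_positive=0)])
        assert table.iloc[0]["fitness_index"] == 0.0

    def test_round1_rendering(self):
        # positive fraction 0.01%, germination 6.3% -> 0.0006% at 1 s.f.
        m = make_measurement(
            facs_analyzed=1_000_000, facs_positive=100,
            wells_sorted_pos=1000, germinated_day1_pos=50, germinated_day2_pos=63,
        )
        row = fitness_table([m]).iloc[0]
        assert float(f"{row['fitness_index'] * 100:.1g}") == 0.0006

    def test_missing_negative_arm_flagged(self):
        m = make_measurement(
            wells_sorted_neg=None, germinated_day1_neg=None, germinated_day2_neg=None
        )
        row = fitness_table([m]).iloc[0]
        assert row["missing_neg_arm"]
        assert math.isnan(row["germination_neg"])

    def test_composition_invariant(self):
        # values equal the composition of estimate_proportion and
        # fitness_index applied row-wise
        rows = [make_measurement(line_id=f"L{i}", facs_positive=i * 7) for i in range(1, 6)]
        table = fitness_table(rows)
        for m, (_, row) in zip(rows, table.iterrows()):
            p = estimate_proportion(m.facs_positive, m.facs_analyzed).point
            g = germination_success(m.wells_sorted_pos, m.germinated_day2_pos)
            assert row["fitness_index"] == fitness_index(p, g)


class TestEstimateTransmissionParams:
    def test_parameter_recovery_within_intervals(self, rng):
        truth = TransmissionParams(g=0.063, e=0.63, p0=0.01)
        n = 10_000
        m = RoundMeasurement(
            line_id="L1", round=0,
            facs_analyzed=n, facs_positive=int(rng.binomial(n, truth.p0)),
            wells_sorted_pos=n,
            germinated_day1_pos=0,
            germinated_day2_pos=int(rng.binomial(n, truth.g)),
            wells_sorted_neg=n,
            germinated_day1_neg=0,
            germinated_day2_neg=int(rng.binomial(n, truth.e)),
        )
        est = estimate_transmission_params(m)
        assert est.g_interval.lower <= truth.g <= est.g_interval.upper
        assert est.e_interval.lower <= truth.e <= est.e_interval.upper
        assert est.p0_interval.lower <= truth.p0 <= est.p0_interval.upper
        assert not est.e_is_fallback

    def test_fallback_e(self):
        m = make_measurement(
            wells_sorted_neg=None, germinated_day1_neg=None, germinated_day2_neg=None
        )
        est = estimate_transmission_params(m)
        assert est.e_is_fallback
        assert est.params.e == 0.69
        assert est.e_interval is None

    def test_bias_shrinks_with_arm_size(self):
        truth = TransmissionParams(g=0.3, e=0.69, p0=0.1)
        biases = []
        for n in (100, 1000, 10_000):
            rng = np.random.default_rng(5)
            reps = []
            for _ in range(200):
                m = RoundMeasurement(
                    line_id="L1", round=0,
                    facs_analyzed=n, facs_positive=int(rng.binomial(n, truth.p0)),
                    wells_sorted_pos=n, germinated_day1_pos=0,
                    germinated_day2_pos=int(rng.binomial(n, truth.g)),
                )
                reps.append(estimate_transmission_params(m).params.g)
            biases.append(abs(np.mean(reps) - truth.g))
        assert biases[2] < 0.005

    def test_missing_positive_arm_rejected(self):
        with pytest.raises(ValueError):
            estimate_transmission_params(
                make_measurement(
                    wells_sorted_pos=0, germinated_day1_pos=0, germinated_day2_pos=0
                )
            )


class TestModelFitError:
    def _trajectory(self, fractions, params, start=0):
        return Trajectory.from_fractions(fractions, params, start_round=start)

    def test_identical_gives_zero(self, washout_params):
        t = self._trajectory([0.1, 0.01, 0.001], washout_params)
        assert model_fit_error(t, t) == 0.0

    def test_one_decade_off(self, washout_params):
        obs = self._trajectory([1e-3], washout_params)
        pred = self._trajectory([1e-4], washout_params)
        assert model_fit_error(obs, pred) == pytest.approx(1.0)

    def test_mismatched_rounds_rejected(self, washout_params):
        obs = self._trajectory([0.1, 0.01], washout_params)
        pred = self._trajectory([0.1, 0.01], washout_params, start=1)
        with pytest.raises(ValueError, match="round indices"):
            model_fit_error(obs, pred)

    def test_censored_observations_excluded(self, washout_params):
        obs = self._trajectory([1e-2, 0.0], washout_params)
        pred = self._trajectory([1e-2, 1e-3], washout_params)
        assert model_fit_error(obs, pred) == 0.0

    def test_all_censored_rejected(self, washout_params):
        obs = self._trajectory([0.0, 0.0], washout_params)
        pred = self._trajectory([1e-2, 1e-3], washout_params)
        with pytest.raises(ValueError, match="no comparable"):
            model_fit_error(obs, pred)


class TestFilterSweepingMutations:
    def make_table(self, rows):
        return pd.DataFrame(
            rows, columns=["mutation_id", "round", "frequency", "present_in_ancestor"]
        )

    def test_boundary_inclusive(self):
        table = self.make_table([("m1", 1, 0.50, False)])
        assert filter_sweeping_mutations(table) == ["m1"]

    def test_empty(self):
        assert filter_sweeping_mutations(self.make_table([])) == []

    def test_nine_above_three_below(self):
        rows = []
        for i in range(9):
            rows.append((f"hi{i}", 1, 0.2, False))
            rows.append((f"hi{i}", 2, 0.6 + 0.04 * i, False))
        for i in range(3):
            rows.append((f"lo{i}", 1, 0.1, False))
            rows.append((f"lo{i}", 2, 0.45, False))
        result = filter_sweeping_mutations(self.make_table(rows))
        assert sorted(result) == sorted(f"hi{i}" for i in range(9))

    def test_ancestral_variants_excluded(self):
        table = self.make_table([("anc", 1, 0.99, True), ("new", 1, 0.7, False)])
        assert filter_sweeping_mutations(table) == ["new"]


class TestSweepFitnessCorrelation:
    def test_identical_increasing(self):
        assert sweep_fitness_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed(self):
        assert sweep_fitness_correlation([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        assert math.isnan(sweep_fitness_correlation([1, 1, 1], [1, 2, 3]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sweep_fitness_correlation([1, 2], [1, 2])

    def test_matches_bruteforce_ranks(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        assert sweep_fitness_correlation(x, y) == pytest.approx(
            spearman_bruteforce(x, y), rel=1e-12
        )


class TestWelch:
    def test_identical_samples(self):
        result = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t == 0.0
        assert result.pvalue == pytest.approx(1.0)

    def test_hand_computed_example(self):
        result = welch_t_test([1, 2, 3], [2, 3, 4])
        assert result.t == pytest.approx(-1.2247, abs=5e-5)
        assert result.df == pytest.approx(4.0, rel=1e-12)

    def test_antisymmetric(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(1.0, size=8)
        fwd = welch_t_test(x, y)
        rev = welch_t_test(y, x)
        assert fwd.t == pytest.approx(-rev.t, rel=1e-12)
        assert fwd.pvalue == pytest.approx(rev.pvalue, rel=1e-12)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(0.5, 2.0, size=5)
        ours = welch_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert ours.t == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_both_undefined(self):
        result = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert math.isnan(result.t)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_order_invariance(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        shuffled = welch_t_test(x[::-1], list(reversed(y)))
        assert shuffled.pvalue == pytest.approx(welch_t_test(x, y).pvalue, rel=1e-12)


class TestWilcoxon:
    def test_three_positive_differences(self):
        result = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert result.w == 6.0
        assert result.pvalue == pytest.approx(0.25)
        assert result.exact

    def test_antisymmetric_under_negation(self):
        d = [1.5, -0.5, 2.0, 3.0, -1.0]
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank([-x for x in d])
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)

    def test_zero_differences_dropped(self):
        with_zeros = wilcoxon_signed_rank([0.0, 1.0, 2.0, 0.0, 3.0])
        assert with_zeros.n_used == 3
        assert with_zeros.pvalue == pytest.approx(0.25)

    def test_all_zero_undefined(self):
        result = wilcoxon_signed_rank([0.0, 0.0])
        assert math.isnan(result.pvalue)

    def test_two_sample_form(self):
        paired = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert paired.w == 6.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 11))
            d = np.round(rng.normal(size=n), 1)
            d = d[d != 0]
            if len(d) == 0:
                continue
            ours = wilcoxon_signed_rank(d)
            w_ref, p_ref = wilcoxon_enumerate(d.tolist())
            assert ours.w == pytest.approx(w_ref)
            assert ours.pvalue == pytest.approx(p_ref, rel=1e-9)

    def test_pvalue_in_unit_interval(self, rng):
        for _ in range(30):
            d = rng.normal(size=int(rng.integers(1, 40)))
            result = wilcoxon_signed_rank(d)
            assert 0.0 < result.pvalue <= 1.0

    def test_order_invariance(self, rng):
        d = rng.normal(size=12)
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(d[::-1])
        assert a.pvalue == pytest.approx(b.pvalue, rel=1e-12)
        assert a.w == b.w
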