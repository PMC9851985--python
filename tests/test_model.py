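"""Generative ordinal course model: curves, distributions, likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from ataxiamap.cohort import Cohort
from ataxiamap.model import (
    IndividualParams,
    PopulationParams,
    exceedance,
    level_distribution,
    log_likelihood,
    most_likely_level,
    population_trajectory,
    reparameterize,
)


class TestReparameterize:
    @pytest.mark.parametrize(
        "xi,tau,age,expected",
        [
            (0.7, 40.0, 40.0, 0.0),
            (0.0, 40.0, 45.0, 5.0),
            (np.log(2.0), 40.0, 43.0, 6.0),
        ],
    )
    def test_known_values(self, xi, tau, age, expected):
        psi = reparameterize(age, IndividualParams(xi=xi, tau=tau))
        assert psi == pytest.approx(expected, abs=1e-12)


class TestExceedance:
    def test_midpoint_is_half(self, toy_pop):
        c = toy_pop.thresholds(1)[0]
        assert exceedance(c, 1, 1, toy_pop) == pytest.approx(0.5, abs=1e-12)

    def test_one_steepness_unit_above(self, toy_pop):
        c = toy_pop.thresholds(0)[0]
        s = toy_pop.steepness[0]
        assert exceedance(c + s, 0, 1, toy_pop) == pytest.approx(
            1.0 / (1.0 + np.exp(-1.0)), abs=1e-9
        )

    def test_limits_and_monotonicity(self, toy_pop):
        assert exceedance(-1e6, 0, 1, toy_pop) == pytest.approx(0.0, abs=1e-12)
        psi = np.linspace(-20, 20, 201)
        curve = exceedance(psi, 1, 2, toy_pop)
        assert np.all(np.diff(curve) > 0)

    def test_level_out_of_range(self, toy_pop):
        with pytest.raises(ValueError):
            exceedance(0.0, 0, 3, toy_pop)


class TestLevelDistribution:
    def test_extremes_concentrate(self, toy_pop):
        low = level_distribution(-1e6, 1, toy_pop)
        high = level_distribution(1e6, 1, toy_pop)
        assert low[0] == pytest.approx(1.0, abs=1e-9)
        assert high[-1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_evaluated_logistics(self):
        # 3-level item, psi at the midpoint of its two thresholds, s = 1
        pop = PopulationParams(
            item_names=("x",), maxima=(2,), deltas=[np.array([2.0])],
            offsets=np.array([1.0]), steepness=np.array([1.0]),
            tau_pop=40.0, sigma_tau=5.0, sigma_xi=0.3,
        )
        psi = 2.0  # midpoint of thresholds 1 and 3
        p_ge1 = expit(psi - 1.0)
        p_ge2 = expit(psi - 3.0)
        expected = np.array([1 - p_ge1, p_ge1 - p_ge2, p_ge2])
        assert np.allclose(level_distribution(psi, 0, pop), expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        psi=st.floats(-50, 50),
        d1=st.floats(0.1, 10),
        d2=st.floats(0.1, 10),
        s=st.floats(0.05, 5),
    )
    def test_normalizes_for_any_increasing_thresholds(self, psi, d1, d2, s):
        pop = PopulationParams(
            item_names=("x",), maxima=(3,), deltas=[np.array([d1, d2])],
            offsets=np.array([0.0]), steepness=np.array([s]),
            tau_pop=40.0, sigma_tau=5.0, sigma_xi=0.3,
        )
        probs = level_distribution(psi, 0, pop)
        assert np.all(probs >= 0)
        assert abs(probs.sum() - 1.0) < 1e-12


class TestMostLikelyLevel:
    def test_plateaus_at_extremes(self, toy_pop):
        assert most_likely_level(-1e6, 1, toy_pop) == 0
        assert most_likely_level(1e6, 1, toy_pop) == 3

    def test_matches_argmax_sweep(self, toy_pop):
        psi = np.linspace(-15, 25, 400)
        for k in range(3):
            levels = most_likely_level(psi, k, toy_pop)
            brute = np.array(
                [int(np.argmax(level_distribution(p, k, toy_pop))) for p in psi]
            )
            assert np.array_equal(levels, brute)
            assert np.all(np.diff(levels) >= 0)  # non-decreasing step function

    def test_acceleration_halves_plateau_widths(self, toy_pop):
        # calendar time at level l is delta_l * exp(-xi)
        ages = np.linspace(30, 70, 8001)
        slow = IndividualParams(xi=0.0, tau=40.0)
        fast = IndividualParams(xi=np.log(2.0), tau=40.0)
        k = 1
        lv_slow = most_likely_level(reparameterize(ages, slow), k, toy_pop)
        lv_fast = most_likely_level(reparameterize(ages, fast), k, toy_pop)
        da = ages[1] - ages[0]
        w_slow = np.sum(lv_slow == 1) * da
        w_fast = np.sum(lv_fast == 1) * da
        assert w_fast == pytest.approx(w_slow / 2.0, rel=0.01)


class TestPopulationTrajectory:
    def test_all_zero_before_onset(self, toy_pop):
        traj = population_trajectory(np.array([20.0, 25.0, 30.0]), toy_pop)
        assert (traj[list(toy_pop.item_names)].to_numpy() == 0).all()

    def test_single_item_equal_deltas_steps_yearly(self):
        d = 2.0
        pop = PopulationParams(
            item_names=("x",), maxima=(4,), deltas=[np.full(3, d)],
            offsets=np.array([0.0]), steepness=np.array([0.1]),
            tau_pop=40.0, sigma_tau=5.0, sigma_xi=0.3,
        )
        ages = np.linspace(38, 52, 1401)
        traj = population_trajectory(ages, pop)
        levels = traj["x"].to_numpy()
        # one-point increase every d years after onset
        for level in (1, 2, 3):
            first_age = ages[np.argmax(levels >= level)]
            assert first_age - 40.0 == pytest.approx((level - 1) * d, abs=0.25)

    def test_total_is_sum_and_matches_pointwise_calls(self, toy_pop):
        ages = np.linspace(30, 60, 61)
        traj = population_trajectory(ages, toy_pop)
        total = sum(traj[name] for name in toy_pop.item_names)
        assert np.array_equal(traj["total"].to_numpy(), total.to_numpy())
        psi = ages - toy_pop.tau_pop
        for k, name in enumerate(toy_pop.item_names):
            expected = [most_likely_level(float(p), k, toy_pop) for p in psi]
            assert np.array_equal(traj[name].to_numpy(), expected)


class TestLogLikelihood:
    def test_empty_cohort_is_zero(self, toy_scale, toy_pop):
        import pandas as pd

        df = pd.DataFrame(columns=["subject_id", "age", *toy_scale.columns])
        cohort = Cohort(df=df, scale=toy_scale)
        assert log_likelihood(cohort, toy_pop, {}) == 0.0

    def test_single_observation_is_log_p(self, toy_scale, toy_pop):
        import pandas as pd

        ind = IndividualParams(xi=0.1, tau=41.0)
        df = pd.DataFrame(
            {
                "subject_id": ["s"],
                "age": [45.0],
                "toy_1": [1],
                "toy_2": [np.nan],
                "toy_3": [np.nan],
            }
        )
        cohort = Cohort(df=df, scale=toy_scale)
        psi = reparameterize(45.0, ind)
        expected = np.log(level_distribution(psi, 0, toy_pop)[1])
        assert log_likelihood(cohort, toy_pop, {"s": ind}) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_naive_loop_oracle(self, toy_scale, toy_pop):
        import pandas as pd

        rng = np.random.default_rng(0)
        rows = []
        inds = {}
        for i in range(3):
            sid = f"s{i}"
            inds[sid] = IndividualParams(xi=rng.normal(0, 0.3), tau=rng.normal(40, 3))
            for j, age in enumerate([40.0 + j for j in range(3)]):
                row = {"subject_id": sid, "age": age}
                for col, m in zip(toy_scale.columns, toy_scale.maxima):
                    row[col] = rng.integers(0, m + 1) if rng.uniform() > 0.2 else np.nan
                rows.append(row)
        cohort = Cohort(df=pd.DataFrame(rows), scale=toy_scale)

        expected = 0.0
        for _, row in cohort.df.iterrows():
            ind = inds[row["subject_id"]]
            psi = reparameterize(row["age"], ind)
            for k, col in enumerate(toy_scale.columns):
                if not np.isnan(row[col]):
                    expected += np.log(
                        level_distribution(psi, k, toy_pop)[int(row[col])]
                    )
        assert log_likelihood(cohort, toy_pop, inds) == pytest.approx(
            expected, abs=1e-10
        )


class TestSerialization:
    def test_population_params_json_round_trip(self, toy_pop):
        back = PopulationParams.from_dict(toy_pop.to_dict())
        assert back.item_names == toy_pop.item_names
        for a, b in zip(back.deltas, toy_pop.deltas):
            assert np.array_equal(a, b)
        assert back.tau_pop == toy_pop.tau_pop

    def test_invalid_params_rejected(self, toy_scale):
        with pytest.raises(ValueError):
            PopulationParams.for_scale(
                toy_scale,
                deltas=[np.array([-1.0]), np.array([1.0, 1.0]), np.array([1.0])],
            )
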