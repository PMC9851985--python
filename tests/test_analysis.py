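"""Posterior summaries: delta CIs, linearity, item speeds, groups, correlation."""

import numpy as np
import pytest

from ataxiamap.analysis import (
    cag_onset_correlation,
    group_dynamics,
    item_speeds,
    rate_ratio,
    summarize_deltas,
    test_linearity as assess_linearity,
)
from ataxiamap.inference import PosteriorSamples


def make_samples(deltas_list, xi=None, tau=None, subject_ids=None, seed=0):
    """Assemble a PosteriorSamples object from raw draw arrays."""
    n_draws = deltas_list[0].shape[0]
    n_items = len(deltas_list)
    if subject_ids is None:
        subject_ids = ["s1", "s2"]
    n = len(subject_ids)
    rng = np.random.default_rng(seed)
    return PosteriorSamples(
        item_names=tuple(f"item{k}" for k in range(n_items)),
        maxima=tuple(d.shape[1] + 1 for d in deltas_list),
        subject_ids=subject_ids,
        deltas=[np.asarray(d, dtype=float) for d in deltas_list],
        offsets=np.zeros((n_draws, n_items)),
        steepness=np.full((n_draws, n_items), 0.3),
        tau_pop=np.full(n_draws, 40.0),
        sigma_tau=np.full(n_draws, 5.0),
        sigma_xi=np.full(n_draws, 0.3),
        xi=rng.normal(0, 0.01, size=(n_draws, n)) if xi is None else xi,
        tau=rng.normal(40, 0.1, size=(n_draws, n)) if tau is None else tau,
        chain=np.zeros(n_draws, dtype=int),
        acceptance_rates={},
        config={},
        seed=0,
    )


class TestSummarizeDeltas:
    def test_constant_draws(self):
        samples = make_samples([np.full((200, 2), 2.0)])
        table = summarize_deltas(samples)
        assert np.allclose(table[["median", "ci_low", "ci_high"]], 2.0)

    def test_matches_quantile_oracle(self):
        rng = np.random.default_rng(0)
        draws = rng.permutation(np.arange(1.0, 1001.0))[:, None]
        samples = make_samples([draws])
        row = summarize_deltas(samples).iloc[0]
        assert row["median"] == pytest.approx(500.5)
        assert row["ci_low"] == pytest.approx(np.quantile(draws, 0.025))
        assert row["ci_high"] == pytest.approx(np.quantile(draws, 0.975))

    def test_median_inside_ci_for_symmetric_draws(self):
        rng = np.random.default_rng(1)
        samples = make_samples([3.0 + 0.2 * rng.standard_normal((2000, 3))])
        table = summarize_deltas(samples)
        assert (table["ci_low"] <= table["median"]).all()
        assert (table["median"] <= table["ci_high"]).all()
        assert np.allclose(table["median"], 3.0, atol=0.05)

    def test_too_few_draws_rejected(self):
        samples = make_samples([np.full((50, 2), 1.0)])
        with pytest.raises(ValueError):
            summarize_deltas(samples)


class TestLinearity:
    def test_null_flag_rate_controlled(self):
        # equal-delta null: iid draws from one distribution for every level
        flags = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            draws = 2.0 + 0.3 * rng.standard_normal((800, 3))
            samples = make_samples([draws])
            flags += assess_linearity(samples, 0).nonlinear
        assert flags <= 10  # <= 20% of 50 replicates

    def test_strong_alternative_always_flagged(self):
        for rep in range(10):
            rng = np.random.default_rng(rep)
            draws = 2.0 + 0.3 * rng.standard_normal((800, 3))
            draws[:, 1] += 3.0  # 10 posterior SDs
            samples = make_samples([draws])
            res = assess_linearity(samples, 0)
            assert res.nonlinear
            assert res.range_median > 2.0

    def test_identical_draw_vectors_flag_false(self):
        rng = np.random.default_rng(0)
        col = 2.0 + 0.1 * rng.standard_normal(500)
        samples = make_samples([np.column_stack([col, col])])
        res = assess_linearity(samples, 0)
        assert not res.nonlinear
        assert res.range_ci == (0.0, 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        draws = rng.uniform(1, 3, size=(400, 3))
        samples = make_samples([draws])
        perm = rng.permutation(400)
        shuffled = make_samples([draws[perm]])
        a, b = assess_linearity(samples, 0), assess_linearity(shuffled, 0)
        assert a.nonlinear == b.nonlinear
        assert a.range_median == pytest.approx(b.range_median)

    def test_single_delta_item_rejected(self):
        samples = make_samples([np.full((200, 1), 1.0)])
        with pytest.raises(ValueError):
            assess_linearity(samples, 0)


class TestItemSpeeds:
    def test_constant_deltas(self):
        samples = make_samples([np.tile([2.0, 2.0, 2.0], (300, 1))])
        row = item_speeds(samples).iloc[0]
        assert row["mean_delta_median"] == pytest.approx(2.0)
        assert row["iqr"] == pytest.approx(0.0)

    def test_fast_slow_ordering_and_separation(self):
        rng = np.random.default_rng(0)
        fast = 3.0 + 0.1 * rng.standard_normal((1000, 3))
        slow = 10.0 + 0.1 * rng.standard_normal((1000, 3))
        samples = make_samples([fast, slow])
        table = item_speeds(samples)
        assert table.loc[0, "mean_delta_median"] < table.loc[1, "mean_delta_median"]
        diff = slow.mean(axis=1) - fast.mean(axis=1)
        lo, hi = np.quantile(diff, [0.025, 0.975])
        assert lo > 0  # non-overlapping: difference CI excludes 0

    def test_consistent_with_delta_summaries(self):
        rng = np.random.default_rng(2)
        draws = rng.uniform(1, 4, size=(500, 4))
        samples = make_samples([draws])
        mean_draws = draws.mean(axis=1)
        row = item_speeds(samples).iloc[0]
        assert row["mean_delta_median"] == pytest.approx(
            np.quantile(mean_draws, 0.5), abs=1e-12
        )


class TestGroupDynamics:
    def test_single_group_acceleration_near_one(self):
        rng = np.random.default_rng(0)
        n_draws, n = 500, 40
        xi = rng.normal(0, 0.3, size=(n_draws, n))
        xi -= xi.mean(axis=1, keepdims=True)  # centered, as the sampler enforces
        ids = [f"s{i}" for i in range(n)]
        samples = make_samples([np.full((n_draws, 2), 1.0)], xi=xi,
                               tau=rng.normal(40, 5, size=(n_draws, n)),
                               subject_ids=ids)
        table = group_dynamics(samples, {i: "all" for i in ids})
        assert table.loc[0, "accel_median"] == pytest.approx(
            np.median(np.exp(xi).mean(axis=1)), abs=1e-12
        )
        assert abs(table.loc[0, "accel_median"] - 1.0) < 0.05

    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(1)
        n_draws = 400
        ids = [f"s{i}" for i in range(30)]
        grouping = {i: ("early" if int(i[1:]) < 15 else "late") for i in ids}
        tau = np.where(
            np.array([grouping[i] == "early" for i in ids]),
            rng.normal(33, 1, size=(n_draws, 30)),
            rng.normal(51, 1, size=(n_draws, 30)),
        )
        samples = make_samples([np.full((n_draws, 2), 1.0)],
                               xi=np.zeros((n_draws, 30)), tau=tau, subject_ids=ids)
        table = group_dynamics(samples, grouping).set_index("group")
        gap = table.loc["late", "tau_median"] - table.loc["early", "tau_median"]
        assert gap == pytest.approx(18.0, abs=2.0)

    def test_unmapped_subject_rejected(self):
        samples = make_samples([np.full((200, 2), 1.0)])
        with pytest.raises(KeyError):
            group_dynamics(samples, {"s1": "a"})


class TestCagCorrelation:
    def test_perfect_negative_line(self):
        cag = np.array([40.0, 45, 50, 55, 60])
        tau = 100.0 - 20.0 * np.log(cag)
        res = cag_onset_correlation(tau, cag)
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_null_simulation_coverage(self):
        covered = 0
        for rep in range(30):
            rng = np.random.default_rng(rep)
            tau = rng.normal(40, 5, size=1000)
            cag = rng.uniform(30, 70, size=1000)
            res = cag_onset_correlation(tau, cag)
            assert abs(res.r) < 0.1
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 27  # >= 90% of replicates

    def test_target_correlation_recovered(self):
        from ataxiamap.simulate import GeneratorConfig, generate_cohort

        cfg = GeneratorConfig(
            n_subjects=300,
            genotype_props={"SCA1": 1.0, "SCA2": 0.0, "SCA3": 0.0, "SCA6": 0.0},
        )
        _, truth = generate_cohort(config=cfg, seed=0)
        ind = truth.individuals
        res = cag_onset_correlation(ind["tau"].to_numpy(), ind["cag"].to_numpy(float))
        assert res.r == pytest.approx(-0.7, abs=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cag_onset_correlation([40, 41, 42, 43], [50, 50, 50, 50])
        with pytest.raises(ValueError):
            cag_onset_correlation([40, 41], [50, 51])


class TestRateRatio:
    @pytest.mark.parametrize(
        "fast,slow,expected", [(2.11, 0.8, 2.64), (1.11, 0.99, 1.12)]
    )
    def test_reported_ratios(self, fast, slow, expected):
        assert rate_ratio(fast, slow) == expected

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_ratio(1.0, 0.0)
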