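"""Quantised/raw scores, depth deciles and aggregation."""

import numpy as np
import pandas as pd
import pytest

from asrbench import (
    AMBIGUOUS,
    Mk2Asr,
    ScenarioParams,
    ScoringConfig,
    aggregate,
    depth_deciles,
    derive_seed,
    mpr_reconstruct,
    quantise,
    raw_error,
    score_tree,
    simulate_conditioned,
    tree_summary,
)


class TestQuantise:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.71, 1), (0.29, 0), (0.5, AMBIGUOUS), (0.7, AMBIGUOUS),
         (0.3, AMBIGUOUS), (0.0, 0), (1.0, 1)],
    )
    def test_thresholds(self, p, expected):
        assert quantise(p) == expected

    def test_vectorized(self):
        calls = quantise(np.array([0.1, 0.4, 0.9]))
        assert list(calls) == [0, AMBIGUOUS, 1]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantise(1.2)
        with pytest.raises(ValueError):
            quantise(np.array([0.5, -0.01]))

    def test_custom_thresholds_validated(self):
        with pytest.raises(ValueError):
            ScoringConfig(upper_threshold=0.3, lower_threshold=0.7)


class TestRawError:
    def test_probability_complement_rule(self):
        assert raw_error(np.float64(1.0), 1) == 0.0
        assert raw_error(np.float64(0.85), 1) == pytest.approx(0.15)
        # p1=0.15 means p(state 0)=0.85; truth 0 -> error 0.15
        assert raw_error(np.float64(0.15), 0) == pytest.approx(0.15)

    def test_parsimony_scores(self):
        calls = np.array([0, 1, AMBIGUOUS, 1], np.int8)
        truth = np.array([0, 0, 1, 1])
        np.testing.assert_allclose(raw_error(calls, truth),
                                   [0.0, 1.0, 0.5, 0.0])

    def test_mp_scores_only_three_values(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.3, 0.3, 0.1, 0.1),
                                   30, seed=2)
        df = score_tree(sim.tree, "MP", mpr_reconstruct(sim.tree))
        assert set(df["raw_error"].unique()) <= {0.0, 0.5, 1.0}


class TestDeciles:
    def test_399_internal_nodes_split_40x9_plus_39(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.1, 0.1, 0.05, 0.05),
                                   400, seed=1)
        groups = depth_deciles(sim.tree)
        sizes = pd.Series(list(groups.values())).value_counts().sort_index()
        assert list(sizes) == [39] + [40] * 9
        assert groups[sim.tree.root] == 10

    def test_one_node_per_decile_when_ten_internal(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.1, 0.1, 0.05, 0.05),
                                   11, seed=3)
        groups = depth_deciles(sim.tree)
        assert sorted(groups.values()) == list(range(1, 11))

    def test_percentiles_isolate_basal_nodes(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.1, 0.1, 0.05, 0.05),
                                   400, seed=4)
        groups = depth_deciles(sim.tree, n_quantiles=100)
        deepest = [v for v, g in groups.items() if g == 100]
        assert len(deepest) == 4  # 399 = 3 + 99*4: remainder to the deepest
        assert sim.tree.root in deepest

    def test_deciles_ordered_by_age(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.4, 0.4, 0.1, 0.1),
                                   50, seed=5)
        groups = depth_deciles(sim.tree)
        ages = sim.tree.node_depths()
        df = pd.DataFrame({"age": [ages[v] for v in groups],
                           "dec": list(groups.values())})
        means = df.groupby("dec")["age"].mean()
        assert means.is_monotonic_increasing


@pytest.fixture(scope="module")
def scored():
    sc = ScenarioParams(1, 1, 0.25, 0.25, 0.1, 0.1)
    frames = []
    for rep in range(12):
        sim = simulate_conditioned(sc, 100,
                                   derive_seed(5, sc.scenario_id, rep))
        if tree_summary(sim).invariant:
            continue
        fit = Mk2Asr(sim.tree).fit(init_center=(sc.q01, sc.q10), seed=rep)
        df = score_tree(sim.tree, "Mk2", fit.marginal_asr())
        df["scenario_id"] = sc.scenario_id
        df["replicate"] = rep
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestScoreTree:
    def test_outright_error_definition(self, scored):
        expect = (scored["quantised_call"] != AMBIGUOUS) & (
            scored["quantised_call"] != scored["true_state"]
        )
        assert (scored["outright_error"] == expect).all()

    def test_threshold_bound_on_mean_raw_error(self, scored):
        # every raw error is <= 1 (outright), <= 0.7 (ambiguous) or
        # <= 0.3 (correct call), so the mean obeys the mixture bound
        p_out = scored["outright_error"].mean()
        p_amb = (scored["quantised_call"] == AMBIGUOUS).mean()
        p_cor = 1.0 - p_out - p_amb
        assert scored["raw_error"].mean() <= (
            p_out + 0.7 * p_amb + 0.3 * p_cor + 1e-12
        )

    def test_perfect_reconstruction_scores_zero(self):
        sim = simulate_conditioned(ScenarioParams(1, 1, 0.1, 0.1, 1e-12,
                                                  1e-12), 25, seed=6)
        p1 = Mk2Asr(sim.tree).marginal_asr((1e-10, 1e-10))
        df = score_tree(sim.tree, "Mk2", p1)
        df["scenario_id"] = "x"
        df["replicate"] = 0
        agg = aggregate(df, "scenario_method")
        assert agg["mean_raw_error"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert agg["accuracy"].iloc[0] == pytest.approx(1.0, abs=1e-6)


class TestAggregate:
    def _toy_records(self):
        # two trees with unbalanced decile sizes to distinguish the
        # averaging orders
        rows = []
        for rep, (n, err) in enumerate([(2, 0.0), (6, 0.3)]):
            for i in range(n):
                rows.append(
                    dict(scenario_id="s", method="M", replicate=rep,
                         node=i, decile=10, true_state=0, p1=err,
                         raw_error=err, quantised_call=0,
                         outright_error=False)
                )
        return pd.DataFrame(rows)

    def test_per_tree_then_across_trees(self):
        agg = aggregate(self._toy_records(), "scenario_decile")
        # (0.0 + 0.3)/2, NOT the pooled (6*0.3)/8
        assert agg["mean_raw_error"].iloc[0] == pytest.approx(0.15)

    def test_pooled_alternative(self):
        agg = aggregate(self._toy_records(), "scenario_decile", pooled=True)
        assert agg["mean_raw_error"].iloc[0] == pytest.approx(6 * 0.3 / 8)

    def test_group_modes_and_counts(self):
        df = self._toy_records()
        by_tree = aggregate(df, "tree")
        assert len(by_tree) == 2
        by_meth = aggregate(df, "scenario_method")
        assert by_meth["n_trees"].iloc[0] == 2

    def test_relabeling_invariance(self):
        df = self._toy_records()
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["node"] = np.arange(len(shuffled))[::-1]
        a = aggregate(df, "scenario_decile")
        b = aggregate(shuffled, "scenario_decile")
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame(), "tree")

    def test_deep_error_increases_with_transition_rate(self):
        # statistical monotonicity: deepest-decile MP error is higher at
        # q=0.1 than q=0.01 (other rates equal), >=200 trees per arm
        def deep_mean(q):
            sc = ScenarioParams(1, 1, 0.25, 0.25, q, q)
            vals = []
            for rep in range(200):
                sim = simulate_conditioned(
                    sc, 100, derive_seed(6, sc.scenario_id, rep)
                )
                if tree_summary(sim).invariant:
                    continue
                df = score_tree(sim.tree, "MP", mpr_reconstruct(sim.tree))
                vals.append(df.loc[df["decile"] == 10, "raw_error"].mean())
            return np.mean(vals)

        assert deep_mean(0.1) > deep_mean(0.01)


class TestScoreProperties:
    """Derandomised property checks on the scoring primitives."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(deadline=None)
    def test_quantise_and_raw_error_consistent(self, p):
        call = quantise(p)
        assert call in (0, 1, AMBIGUOUS)
        for truth in (0, 1):
            err = float(raw_error(np.float64(p), truth))
            assert 0.0 <= err <= 1.0
            if call == truth:
                assert err < 0.3
            elif call == AMBIGUOUS:
                assert 0.3 <= err <= 0.7

    @given(st.integers(min_value=2, max_value=60),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_decile_partition_properties(self, n_tips, seed):
        sim = simulate_conditioned(
            ScenarioParams(1, 1, 0.2, 0.2, 0.05, 0.05), n_tips, seed=seed)
        groups = depth_deciles(sim.tree)
        sizes = pd.Series(list(groups.values())).value_counts()
        assert sizes.sum() == n_tips - 1
        assert sizes.max() - sizes.min() <= 1
        assert groups[sim.tree.root] == 10
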