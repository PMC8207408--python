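import numpy as np
import pandas as pd
import pytest

from oracles import nodf_bruteforce
from trophinet import (
    BipartiteNetwork,
    GeneratorConfig,
    InteractionRecord,
    TraitTable,
    delta_regressions,
    generate_nested,
    group_removal_test,
    jackknife_nestedness,
    nodf,
    secondary_resource_comparison,
    trait_degree_regression,
)


def _traits_for(net, mass=None, family="Fam", lifestyle="terrestrial"):
    n = net.n_consumers
    mass = mass if mass is not None else np.full(n, 10.0)
    return TraitTable(
        pd.DataFrame(
            {"family": [family] * n, "body_mass_g": mass, "lifestyle": [lifestyle] * n},
            index=pd.Index(net.consumers, name="species"),
        )
    )


@pytest.fixture
def toy4x3():
    A = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 1, 0]])
    return BipartiteNetwork(list("abcd"), list("xyz"), A)


class TestJackknife:
    def test_each_reduced_nodf_matches_independent_recomputation(self, toy4x3):
        res = jackknife_nestedness(toy4x3)
        for i in range(toy4x3.n_consumers):
            sub = np.delete(toy4x3.A, i, axis=0)
            sub = sub[:, sub.sum(axis=0) > 0]
            assert res.nodf_without[i] == pytest.approx(nodf_bruteforce(sub))
            assert res.delta_n[i] == pytest.approx(res.nodf_full - res.nodf_without[i])

    def test_removing_a_duplicated_staircase_row_changes_nothing(self):
        # two consumers share the middle diet pattern; removing one leaves a
        # perfect staircase with distinct marginals
        A = np.array([[1, 1, 1], [1, 1, 0], [1, 1, 0], [1, 0, 0]])
        net = BipartiteNetwork(list("abcd"), list("xyz"), A)
        res = jackknife_nestedness(net)
        assert res.nodf_without[1] == pytest.approx(100.0)

    def test_too_few_consumers_rejected(self):
        net = BipartiteNetwork(["a", "b"], ["x"], np.array([[1], [1]]))
        with pytest.raises(ValueError):
            jackknife_nestedness(net)


class TestGroupRemoval:
    def test_empty_set_is_identity(self, combined_default):
        net, _ = combined_default
        res = group_removal_test(net, [], n_reps=10, seed=0)
        assert res.observed_n == res.nodf_full
        assert res.p_value == 1.0

    def test_observed_matches_direct_recomputation(self, combined_default):
        net, _ = combined_default
        targets = net.consumers[:4]
        res = group_removal_test(net, targets, n_reps=50, seed=1)
        assert res.observed_n == pytest.approx(nodf(net.remove_consumers(targets)))

    def test_unknown_species_rejected(self, combined_default):
        net, _ = combined_default
        with pytest.raises(KeyError):
            group_removal_test(net, ["not-a-species"], n_reps=10, seed=0)

    def test_random_target_sets_give_calibrated_p(self, combined_default):
        """Removing a random subset should not look special: p approximately
        uniform over repeated trials."""
        net, _ = combined_default
        rng = np.random.default_rng(4)
        n_trials, alpha = 200, 0.1
        hits = 0
        for _ in range(n_trials):
            targets = [net.consumers[i] for i in rng.choice(net.n_consumers, 5, replace=False)]
            res = group_removal_test(net, targets, n_reps=49, seed=int(rng.integers(2**31)))
            hits += res.p_value <= alpha
        se = np.sqrt(alpha * (1 - alpha) / n_trials)
        assert abs(hits / n_trials - alpha) <= 3 * se


class TestSecondaryComparison:
    def test_no_secondary_records_is_degenerate(self):
        records = [InteractionRecord("a", "x"), InteractionRecord("b", "x"),
                   InteractionRecord("b", "y")]
        res = secondary_resource_comparison(records, n_reps=10, seed=0)
        assert res.degenerate and res.p_value == 1.0
        assert res.nodf_full == res.nodf_main_only

    def test_counts_resources_lost_to_filtering(self):
        records = [
            InteractionRecord("a", "x"),
            InteractionRecord("a", "y", "secondary"),
            InteractionRecord("b", "x"),
            InteractionRecord("b", "z"),
            InteractionRecord("c", "x"),
        ]
        res = secondary_resource_comparison(records, n_reps=200, seed=3)
        assert res.n_resources_lost == 1  # column y exists only via secondary
        assert 0 < res.p_value <= 1


class TestRegressions:
    def test_constant_degrees_give_zero_slope(self):
        net = BipartiteNetwork(list("abc"), ["x", "y"],
                               np.array([[1, 0], [1, 0], [1, 0]]))
        traits = _traits_for(net, mass=[1.0, 10.0, 100.0])
        res = trait_degree_regression(net, traits)
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_exact_linear_relationship_recovered(self):
        # degrees 1,2,3 against log10 masses 0,1,2 -> slope exactly 1
        A = np.array([[1, 0, 0], [1, 1, 0], [1, 1, 1]])
        net = BipartiteNetwork(list("abc"), list("xyz"), A)
        traits = _traits_for(net, mass=[1.0, 10.0, 100.0])
        res = trait_degree_regression(net, traits)
        assert res.slope == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_family_subset_filters_points(self):
        A = np.array([[1, 0], [1, 1], [1, 1], [1, 0]])
        net = BipartiteNetwork(list("abcd"), ["x", "y"], A)
        df = pd.DataFrame(
            {
                "family": ["F1", "F1", "F1", "F2"],
                "body_mass_g": [1.0, 10.0, 100.0, 5.0],
                "lifestyle": ["terrestrial"] * 4,
            },
            index=pd.Index(list("abcd"), name="species"),
        )
        res = trait_degree_regression(net, TraitTable(df), subset_family="F1")
        assert res.n == 3
        with pytest.raises(ValueError):
            trait_degree_regression(net, TraitTable(df), subset_family="F9")

    def test_delta_regression_r2_one_on_constructed_collinearity(self, toy4x3):
        res = jackknife_nestedness(toy4x3)
        traits = _traits_for(toy4x3, mass=10.0 ** res.delta_n)
        on_mass, _ = delta_regressions(res, traits)
        assert on_mass.r_squared == pytest.approx(1.0)
        assert on_mass.slope == pytest.approx(1.0)

    def test_generated_slope_recovered_within_ci(self):
        """Parameter recovery at a planted degree-mass slope."""
        import statsmodels.api as sm

        beta = 2.0
        hits = 0
        n_reps = 40
        for s in range(n_reps):
            # intercept 1.0 keeps breadths off the k = 1 floor (censoring
            # there biases the OLS slope downward)
            cfg = GeneratorConfig(n_consumers=60, n_resources=20, breadth_slope=beta,
                                  breadth_intercept=1.0, noise_swap_rate=0.05,
                                  seed=1000 + s)
            net, traits = generate_nested(cfg)
            X = np.log10([traits.mass_of(sp) for sp in net.consumers])
            y = net.consumer_degrees.astype(float)
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            lo, hi = fit.conf_int()[1]
            hits += lo <= beta <= hi
        assert hits / n_reps >= 0.9
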