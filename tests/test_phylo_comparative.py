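import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from oracles import mvn_ancestral_oracle
from repeatscape.phylo_comparative import (
    _label_internal_nodes,
    anc_states_ml,
    correlate_panel,
    niche_width,
    ols_fit,
)
from repeatscape.synthetic_data import (
    simulate_bm_traits,
    simulate_species_panel,
    simulate_tree,
)


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestAncestralStates:
    def test_symmetric_two_tip_root_is_midpoint(self):
        states = anc_states_ml(_tree("(A:1,B:1);"), {"A": 2.0, "B": 4.0})
        assert states.estimates["node1"] == pytest.approx(3.0)

    def test_asymmetric_branch_lengths_weight_inversely(self):
        states = anc_states_ml(_tree("(A:1,B:3);"), {"A": 0.0, "B": 4.0})
        assert states.estimates["node1"] == pytest.approx(1.0)

    def test_star_tree_equal_weights(self):
        states = anc_states_ml(_tree("(A:1,B:1,C:1);"), {"A": 1, "B": 2, "C": 3})
        assert states.estimates["node1"] == pytest.approx(2.0)

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError, match="no trait value"):
            anc_states_ml(_tree("(A:1,B:1);"), {"A": 2.0})

    def test_zero_length_branch_rejected_with_collapse_hint(self):
        with pytest.raises(ValueError, match="collapse"):
            anc_states_ml(
                _tree("((A:1,B:0.0):1,C:1);"), {"A": 1, "B": 2, "C": 3}
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_mvn_conditional_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(int(rng.integers(3, 9)), seed=1000 + seed)
        traits = simulate_bm_traits(tree, 5.0, 2.0, seed=2000 + seed)
        states = anc_states_ml(tree, traits)
        labelled = tree.clone(depth=1)
        _label_internal_nodes(labelled)
        est_o, var_o, sigma2_o = mvn_ancestral_oracle(labelled, traits)
        for label, est in states.estimates.items():
            assert est == pytest.approx(est_o[label], abs=1e-8)
            assert states.variances[label] == pytest.approx(
                sigma2_o * var_o[label], abs=1e-8
            )
        assert states.sigma2_hat == pytest.approx(sigma2_o, abs=1e-10)

    def test_location_scale_equivariance(self):
        tree = simulate_tree(6, seed=42)
        traits = simulate_bm_traits(tree, 1.0, 1.0, seed=43)
        base = anc_states_ml(tree, traits)
        shifted = anc_states_ml(tree, {k: 3.0 * v - 7.0 for k, v in traits.items()})
        for label in base.estimates:
            assert shifted.estimates[label] == pytest.approx(
                3.0 * base.estimates[label] - 7.0
            )

    def test_sigma_zero_traits_reconstruct_root_exactly(self):
        tree = simulate_tree(5, seed=7)
        traits = simulate_bm_traits(tree, 2.5, 0.0, seed=8)
        assert set(traits.values()) == {2.5}
        states = anc_states_ml(tree, traits)
        assert states.estimates[states.root_label] == pytest.approx(2.5)


class TestOlsFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_r2_zero(self):
        fit = ols_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.r_squared == 0.0

    def test_closed_form_normal_equations(self):
        fit = ols_fit([1, 2, 3, 4], [2, 1, 4, 3])
        assert fit.slope == pytest.approx(0.6)
        assert fit.r_squared == pytest.approx(0.36)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_fit([1, 1, 1], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ols_fit([1, 2], [1, 2])

    @given(st.floats(0.1, 10), st.floats(-5, 5), st.floats(0.1, 10), st.floats(-5, 5))
    def test_r_squared_invariant_under_linear_rescaling(self, a, b, c, d):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        base = ols_fit(x, y).r_squared
        assert ols_fit(a * x + b, c * y + d).r_squared == pytest.approx(base)


class TestNicheWidth:
    def test_width_counts_distinct_types(self):
        table = pd.DataFrame(
            {
                "species": ["s1", "s1", "s1", "s2"],
                "habitat_type": ["Forest", "Wetlands", "Grassland", "Forest"],
            }
        )
        profiles, excluded = niche_width(table)
        widths = {p.species: p.niche_width for p in profiles}
        assert widths == {"s1": 3, "s2": 1}
        assert excluded == []

    def test_absent_species_excluded_and_flagged(self):
        table = pd.DataFrame({"species": ["s1"], "habitat_type": ["Forest"]})
        _, excluded = niche_width(table, expected_species=["s1", "s2"])
        assert excluded == ["s2"]

    def test_duplicate_rows_deduplicated(self):
        table = pd.DataFrame(
            {"species": ["s1"] * 3, "habitat_type": ["Forest"] * 3}
        )
        profiles, _ = niche_width(table)
        assert profiles[0].niche_width == 1


class TestCorrelatePanel:
    def test_zero_noise_panel_gives_perfect_fits(self):
        panel = simulate_species_panel(14, seed=5, r2_target=1.0)
        results = correlate_panel(panel).set_index("metric")
        # ssr counts are rounded to integers; repeat_bp is exact
        assert results.loc["repeat_bp"].r_squared == pytest.approx(1.0, abs=1e-9)
        assert results.loc["ssr_count"].r_squared == pytest.approx(1.0, abs=1e-4)

    def test_all_missing_metric_skipped_with_warning(self):
        panel = simulate_species_panel(5, seed=6)
        panel["broken"] = np.nan
        with pytest.warns(UserWarning, match="broken"):
            results = correlate_panel(panel)
        assert "broken" not in set(results.metric)

    def test_single_species_panel_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_panel(1, seed=0)

    def test_planted_population_r2_recovered_on_average(self):
        r2s = []
        for seed in range(120):
            panel = simulate_species_panel(14, seed=seed, r2_target=0.9)
            fit = ols_fit(panel["genome_size"], panel["repeat_bp"])
            r2s.append(fit.r_squared)
        assert np.mean(r2s) == pytest.approx(0.9, abs=0.05)
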