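"""Division rules, pedigrees and culture simulation."""

import io

import numpy as np
import pytest

from matswitch import (
    CellState,
    Trajectory,
    count_switched_granddaughters,
    default_params,
    divide,
    enumerate_pedigree,
    imprinted_fraction,
    make_named_config,
    simulate_culture,
)
from matswitch.choice import params_from_error_rates, perfect_directionality_params
from matswitch.steady import build_transition_matrix, project_fractions


def leaf_labels(tree):
    return [leaf.state.label for leaf in tree.leaves()]


def test_divide_unimprinted_parent_yields_one_switchable_daughter(h90, perfect_params):
    lag, lead = divide(CellState("P", False), h90, perfect_params)
    assert (lag.label, lead.label) == ("Ps", "Pu")


def test_divide_imprinted_parent_switches_leading_daughter(h90, perfect_params):
    lag, lead = divide(CellState("P", True), h90, perfect_params)
    assert (lag.label, lead.label) == ("Ps", "Mu")


def test_divide_futile_cycle_homologous_donor(h09):
    # zero error rates in h09: every completed conversion is homologous
    params = params_from_error_rates(0.0, 0.0, attempt_success=1.0)
    lag, lead = divide(CellState("M", True), h09, params)
    assert (lag.label, lead.label) == ("Ms", "Mu")


def test_divide_no_imprint_no_switch(h90):
    params = params_from_error_rates(0.0, 0.0, imprint_efficiency=0.0, attempt_success=1.0)
    lag, lead = divide(CellState("M", False), h90, params)
    assert (lag.label, lead.label) == ("Mu", "Mu")


def test_divide_deterministic_mode_rejects_unforced_probabilities(h90, params):
    with pytest.raises(ValueError, match="deterministic"):
        divide(CellState("P", True), h90, params)  # s = 0.85 needs an rng


def test_divide_lethal_on_failure(h90):
    params = params_from_error_rates(0.0, 0.0, attempt_success=0.0, lethal_on_failure=True)
    lag, lead = divide(CellState("P", True), h90, params)
    assert lag.label == "Ps" and lead is None


def test_pedigree_reproduces_canonical_switching_pattern(h90, perfect_params):
    # the frozen three-generation pedigree of a newly switched P founder:
    # lagging-first traversal of the deterministic error-free tree
    tree = enumerate_pedigree(CellState("P", False), 3, h90, perfect_params)
    assert leaf_labels(tree) == ["Ps", "Mu", "Ms", "Mu", "Ps", "Mu", "Ps", "Pu"]


def test_one_in_four_rule(h90, perfect_params):
    assert count_switched_granddaughters(CellState("P", False), h90, perfect_params) == 1
    assert count_switched_granddaughters(CellState("M", False), h90, perfect_params) == 1


def test_no_imprint_means_no_switched_granddaughters(h90):
    params = params_from_error_rates(0.0, 0.0, imprint_efficiency=0.0, attempt_success=1.0)
    assert count_switched_granddaughters(CellState("P", False), h90, params) == 0


def test_homologous_only_conversion_never_switches(h09):
    # h09 with zero error rates: all four granddaughters keep the founder type
    params = params_from_error_rates(0.0, 0.0, attempt_success=1.0)
    assert count_switched_granddaughters(CellState("P", False), h09, params) == 0


def test_recurrent_switching_rule(h90, perfect_params):
    # the lagging (switchable) line's leading daughter switches every generation
    tree = enumerate_pedigree(CellState("P", True), 3, h90, perfect_params)
    node = tree
    expected_allele = "P"
    for _ in range(3):
        assert node.state.label == expected_allele + "s"
        assert node.leading.state.allele.value != expected_allele
        node = node.lagging
        # allele of the switchable line itself never changes
        assert node.state.allele.value == "P"


def test_pedigree_depth_guard(h90, perfect_params):
    with pytest.raises(ValueError, match="guard"):
        enumerate_pedigree(CellState("P", False), 21, h90, perfect_params)


def test_population_doubles_without_subsampling(h90, params):
    traj = simulate_culture("Pu", h90, params, generations=6, capacity=100, seed=11)
    totals = traj.counts[["Pu", "Ps", "Mu", "Ms"]].sum(axis=1).to_numpy()
    assert list(totals[:7]) == [1, 2, 4, 8, 16, 32, 64]


def test_capacity_subsampling_caps_population(h90, params):
    traj = simulate_culture("Pu", h90, params, generations=12, capacity=500, seed=11)
    totals = traj.counts[["Pu", "Ps", "Mu", "Ms"]].sum(axis=1)
    assert (totals <= 500).all() and totals.iloc[-1] == 500


def test_simulation_reproducible_given_seed(h09, params):
    a = simulate_culture("Pu", h09, params, 15, 1000, seed=42)
    b = simulate_culture("Pu", h09, params, 15, 1000, seed=42)
    assert a.counts.equals(b.counts)
    c = simulate_culture("Pu", h09, params, 15, 1000, seed=43)
    assert not a.counts.equals(c.counts)


def test_no_switching_without_attempt_success(h90):
    params = params_from_error_rates(0.2, 0.1, attempt_success=0.0)
    traj = simulate_culture("Mu", h90, params, 10, 1000, seed=3)
    assert (traj.counts["Pu"] + traj.counts["Ps"] == 0).all()


def test_founder_independence_of_the_steady_state(h90, params):
    # both rates positive: cultures started from P and M converge together
    fp = np.mean([
        simulate_culture("Pu", h90, params, 60, 10_000, seed=s).final_fraction_P
        for s in range(5)
    ])
    fm = np.mean([
        simulate_culture("Mu", h90, params, 60, 10_000, seed=100 + s).final_fraction_P
        for s in range(5)
    ])
    assert fp == pytest.approx(fm, abs=0.02)


def test_simulation_tracks_analytic_transient(h09, params):
    # h09 switches slowly; at generation 30 the culture is still far from
    # the stationary 1/3 and must instead match the chain's transient
    T = build_transition_matrix(h09, params)
    analytic = project_fractions(T, [1.0, 0, 0, 0], 30)[-1]
    sims = [simulate_culture("Pu", h09, params, 30, 10_000, seed=s).final_fraction_P
            for s in range(5)]
    se = np.sqrt(analytic * (1 - analytic) / 10_000)
    assert np.mean(sims) == pytest.approx(analytic, abs=3 * se)
    assert abs(analytic - 1.0 / 3.0) > 10 * se  # transient, not yet stationary


def test_imprinted_fraction_half_in_deterministic_culture(h90, perfect_params):
    traj = simulate_culture("Pu", h90, perfect_params, 10, capacity=2048, seed=None)
    assert imprinted_fraction(traj, burn_in=0) == pytest.approx(0.5, abs=1e-12)
    per_gen = (traj.counts["Ps"] + traj.counts["Ms"]) / traj.counts[
        ["Pu", "Ps", "Mu", "Ms"]].sum(axis=1)
    assert (per_gen.iloc[1:] == 0.5).all()


def test_imprinted_fraction_zero_without_imprinting(h90):
    params = params_from_error_rates(0.0, 0.0, imprint_efficiency=0.0, attempt_success=1.0)
    traj = simulate_culture("Pu", h90, params, 8, 1000, seed=1)
    assert imprinted_fraction(traj, burn_in=0) == 0.0


def test_imprinted_fraction_matches_stationary_beta(h90):
    # beta < 1: the stationary imprinted share of the lineage chain is beta/2
    params = params_from_error_rates(0.2, 0.1, imprint_efficiency=0.8)
    traj = simulate_culture("Pu", h90, params, 60, 10_000, seed=9)
    assert imprinted_fraction(traj, burn_in=20) == pytest.approx(0.4, abs=0.01)


def test_trajectory_csv_round_trip(h09, params):
    traj = simulate_culture("Pu", h09, params, 10, 1000, seed=5)
    buf = io.StringIO(traj.to_csv())
    rt = Trajectory.from_csv(buf)
    assert rt.counts[["generation", "Pu", "Ps", "Mu", "Ms"]].equals(
        traj.counts[["generation", "Pu", "Ps", "Mu", "Ms"]]
    )


def test_simulate_culture_argument_validation(h90, params):
    with pytest.raises(ValueError):
        simulate_culture("Pu", h90, params, generations=0, capacity=1000, seed=1)
    with pytest.raises(ValueError):
        simulate_culture("Pu", h90, params, generations=5, capacity=10, seed=1)
    with pytest.raises(ValueError):
        simulate_culture("Px", h90, params, generations=5, capacity=1000, seed=1)
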