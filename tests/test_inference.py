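"""Fraction estimation, phenotype calls, grid ML and model comparison."""

import numpy as np
import pandas as pd
import pytest

from matswitch import (
    DonorChoiceModel,
    NonIdentifiableError,
    ObservationSet,
    compare_models,
    default_params,
    dispersion_test,
    estimate_fraction,
    fit_error_rates,
    make_named_config,
    sample_microscopy,
    sample_southern,
    steady_fraction_P,
)


def microscopy_obs(xs, n=500, strain="h90"):
    df = pd.DataFrame({"replicate": np.arange(1, len(xs) + 1), "n_cells": n, "x_P": xs})
    return ObservationSet(strain=strain, method="microscopy", data=df)


# -- estimate_fraction -------------------------------------------------------


def test_estimate_all_positive_replicates():
    est = estimate_fraction(microscopy_obs([500] * 5))
    assert est.estimate == 1.0
    assert est.ci_high == pytest.approx(1.0, abs=1e-12)


def test_estimate_single_replicate_arithmetic():
    est = estimate_fraction(microscopy_obs([250], n=500))
    assert est.estimate == 0.5


def test_estimate_southern_bootstrap_interval():
    obs = sample_southern(0.82, n_rep=9, seed=4)
    est = estimate_fraction(obs, seed=1)
    assert est.method == "southern"
    assert est.ci_low <= est.estimate <= est.ci_high
    assert abs(est.estimate - 0.82) < 0.1


def test_wilson_interval_coverage_is_nominal():
    # ≈95% coverage over 1000 seeded binomial panels at n=500
    rng = np.random.default_rng(2024)
    f = 0.82
    covered = 0
    xs = rng.binomial(500 * 9, f, size=1000)  # pooled counts
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(xs, 500 * 9, alpha=0.05, method="wilson")
    covered = int(((lo <= f) & (f <= hi)).sum())
    assert 920 <= covered <= 980


# -- dispersion_test ---------------------------------------------------------


def test_balanced_panel(params):
    obs = sample_microscopy(0.5, 9, 500, seed=10)
    call = dispersion_test(obs, seed=1)
    assert call.phenotype == "balanced"


def test_biased_panel_matches_side():
    call = dispersion_test(sample_microscopy(0.85, 9, 500, seed=11), seed=1)
    assert call.phenotype == "biased_P"
    call = dispersion_test(sample_microscopy(0.15, 9, 500, seed=12), seed=1)
    assert call.phenotype == "biased_M"


def test_variegated_panel_detected():
    # five cultures near 3% P and four near 97% P: massive overdispersion
    xs = [15, 14, 16, 15, 13, 485, 486, 487, 484]
    call = dispersion_test(microscopy_obs(xs), seed=1)
    assert call.phenotype == "variegated"
    assert call.p_value < 0.01


def test_degenerate_all_one_type():
    call = dispersion_test(microscopy_obs([0, 0, 0]), seed=1)
    assert call.phenotype == "biased_M" and np.isnan(call.p_value)


def test_strict_balance_margin_recovers_interval_rule():
    obs = sample_microscopy(0.53, 9, 5000, seed=13)
    strict = dispersion_test(obs, seed=1, balance_margin=0.0)
    lenient = dispersion_test(obs, seed=1)
    assert strict.phenotype == "biased_P"
    assert lenient.phenotype == "balanced"


def test_dispersion_type_one_error_rate():
    # truly binomial panels: variegation called at most ~alpha of the time
    rng = np.random.default_rng(99)
    calls = 0
    trials = 300
    for _ in range(trials):
        xs = rng.binomial(500, 0.5, size=9)
        call = dispersion_test(microscopy_obs(list(xs)), n_boot=500,
                               seed=int(rng.integers(2**31)))
        calls += call.phenotype == "variegated"
    assert calls <= 9  # 3x the nominal 1% of 300


def test_dispersion_requires_counts_and_replicates():
    with pytest.raises(ValueError, match="count"):
        dispersion_test(sample_southern(0.5, 9, seed=1))
    with pytest.raises(ValueError, match="replicates"):
        dispersion_test(microscopy_obs([250, 251]))


# -- model fitting -----------------------------------------------------------


@pytest.fixture(scope="module")
def joint_data():
    p = default_params()
    f09 = steady_fraction_P(make_named_config("h09"), p).fraction_P
    f90 = steady_fraction_P(make_named_config("h90"), p).fraction_P
    return {
        "h09": sample_microscopy(f09, 9, 500, seed=101, strain="h09"),
        "h90": sample_microscopy(f90, 9, 500, seed=102, strain="h90"),
    }


def test_joint_fit_recovers_both_error_rates(joint_data):
    res = fit_error_rates(joint_data, n_boot=400, seed=7)
    assert res.identifiable
    assert res.conf_int["e_P"][0] <= 0.2 <= res.conf_int["e_P"][1]
    assert res.conf_int["e_M"][0] <= 0.1 <= res.conf_int["e_M"][1]
    assert abs(res.params["e_P"] - 0.2) < 0.1
    assert abs(res.params["e_M"] - 0.1) < 0.06
    assert "e_P" in res.summary()


def test_single_strain_identifies_only_the_ratio(joint_data):
    res = fit_error_rates({"h09": joint_data["h09"]}, n_boot=400, seed=7)
    assert not res.identifiable
    assert set(res.params) == {"e_ratio"}
    lo, hi = res.conf_int["e_ratio"]
    assert lo <= 1.0 / 3.0 <= hi


def test_symmetric_truth_fits_half_ratio():
    obs = sample_microscopy(0.5, 9, 500, seed=103, strain="h09")
    res = fit_error_rates({"h09": obs}, n_boot=0)
    assert res.params["e_ratio"] == pytest.approx(0.5, abs=0.05)


def test_grid_ml_beats_coarse_brute_force(joint_data):
    # refined optimum must dominate an exhaustive 0.01-resolution scan
    model = DonorChoiceModel(joint_data)
    res = model.fit(grid_resolution=0.005, refine=True, n_boot=0)
    grid = np.arange(0.005, 1.0, 0.01)
    best = -np.inf
    for ep in grid:
        for em in grid:
            best = max(best, model.loglike({"e_P": ep, "e_M": em}))
    assert res.llf >= best - 1e-9


def test_ci_width_shrinks_with_cell_count():
    p = default_params()
    f09 = steady_fraction_P(make_named_config("h09"), p).fraction_P
    f90 = steady_fraction_P(make_named_config("h90"), p).fraction_P
    widths = []
    for n_cells in (100, 500, 2000):
        d = {
            "h09": sample_microscopy(f09, 9, n_cells, seed=301, strain="h09"),
            "h90": sample_microscopy(f90, 9, n_cells, seed=302, strain="h90"),
        }
        res = fit_error_rates(d, n_boot=300, seed=5)
        lo, hi = res.conf_int["e_P"]
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]


def test_non_identifiable_configuration_raises():
    # a 2x-enhancer strain has f = 1/2 for every parameter value
    obs = sample_microscopy(0.5, 9, 500, seed=104, strain="2xSRE2")
    with pytest.raises(NonIdentifiableError):
        fit_error_rates({"2xSRE2": obs}, n_boot=0)


def test_fit_rejects_southern_data():
    obs = sample_southern(0.5, 9, seed=1, strain="h90")
    with pytest.raises(ValueError, match="count"):
        DonorChoiceModel({"h90": obs})


def test_fitted_fraction_consistent_with_steady_state_oracle(joint_data):
    # the vectorized fraction map must agree with the chain oracle
    from matswitch.choice import params_from_error_rates

    model = DonorChoiceModel(joint_data)
    res = model.fit(n_boot=0)
    p = params_from_error_rates(res.params["e_P"], res.params["e_M"])
    for strain in ("h09", "h90"):
        oracle = steady_fraction_P(make_named_config(strain), p).fraction_P
        assert res.fitted_fractions[strain] == pytest.approx(oracle, abs=1e-9)


# -- model comparison --------------------------------------------------------


def test_compare_models_empty_map_errors():
    with pytest.raises(ValueError):
        compare_models({})


def test_models_equivalent_on_wild_type_alone():
    # the 2004 rule pins h90 at f = 1/2 for every q (flat likelihood) and
    # the competition model fits the observed fraction freely, so with
    # data generated at f = 1/2 the two optima nearly coincide
    obs = sample_microscopy(0.5, 9, 500, seed=105, strain="h90")
    cmp = compare_models({"h90": obs})
    assert abs(cmp.delta_llf) < 2.0
    assert not cmp.spreading.identifiable


def test_competition_wins_on_swapped_element_panel():
    p = default_params()
    strains = ["h90", "h09", "h09_swapped", "h90_swapped"]
    data = {
        s: sample_microscopy(
            steady_fraction_P(make_named_config(s), p).fraction_P,
            9, 500, seed=400 + i, strain=s)
        for i, s in enumerate(strains)
    }
    cmp = compare_models(data)
    assert cmp.delta_llf > 50
    assert "competition" in cmp.summary()
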