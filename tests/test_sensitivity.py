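"""Finite-difference sensitivities, SUE impacts and reaction classification."""

import numpy as np
import pytest

from basalcal.mechanism import mechanism_from_dict
from basalcal.ranges import BasalRangeSet, SpeciesRange
from basalcal.sensitivity import (
    classify_reactions,
    local_sensitivities,
    sigma_from_f,
    sue_impact,
)


@pytest.fixture(scope="module")
def fixture_sensitivity(truth, conditions):
    sens = local_sensitivities(truth.mechanism, conditions, truth.ranges)
    f = {r.index: r.rate.f_prior for r in truth.mechanism.reactions}
    table = sue_impact(sens, f, equations=[r.equation for r in truth.mechanism.reactions])
    return sens, table


def test_dormant_reactions_have_exactly_zero_sensitivity(truth, fixture_sensitivity):
    sens, table = fixture_sensitivity
    for idx in truth.dormant:
        p = sens.reaction_indices.index(idx)
        assert np.all(sens.S[:, :, p, :] == 0.0)
        assert table.aggregate_impact[p] == 0.0


def test_classification_recovers_constructed_partition(truth, fixture_sensitivity):
    _, table = fixture_sensitivity
    parts = classify_reactions(table)
    assert sorted(parts["dormant"]) == truth.dormant
    assert sorted(parts["influential"]) == truth.influential
    # partition is exhaustive and disjoint
    all_idx = sorted(parts["influential"] + parts["dormant"] + parts["negligible"])
    assert all_idx == sorted(r.index for r in truth.mechanism.reactions)


def test_infinite_threshold_empties_influential(fixture_sensitivity):
    _, table = fixture_sensitivity
    parts = classify_reactions(table, threshold=np.inf)
    assert parts["influential"] == []


def _decay_setup(k_log10=-4.0):
    """Single first-order decay with a grid bracketing t = 1/k."""
    mech = mechanism_from_dict(
        {"species": [{"id": "A", "monitored": True}],
         "reactions": [{"index": 1, "equation": "A -> 0", "log10_k": k_log10}]}
    )
    ranges = BasalRangeSet([SpeciesRange("A", 0.0, 1.6e-10)])  # sigma = 2e-11
    k = 10.0 ** k_log10
    grid = np.linspace(0.0, 2.0 / k, 9)  # includes t = 1/k at index 4
    c0 = np.array([[1e-10]])
    return mech, ranges, grid, c0, k


def test_finite_difference_matches_analytic_decay_derivative():
    """d c / d ln k = -k t c0 e^{-kt}; the +5% difference is within 1%."""
    mech, ranges, grid, c0, k = _decay_setup()
    sens = local_sensitivities(mech, c0, ranges, factor=1.05, grid=grid)
    sigma = ranges["A"].sigma
    analytic = -k * grid * c0[0, 0] * np.exp(-k * grid) / sigma
    got = sens.S[0, 0, 0, :]
    j = 4  # t = 1/k
    assert grid[j] == pytest.approx(1.0 / k)
    assert got[j] == pytest.approx(analytic[j], rel=0.01)


def test_finite_difference_converges_as_factor_shrinks():
    mech, ranges, grid, c0, k = _decay_setup()
    sigma = ranges["A"].sigma
    analytic = -k * grid[4] * c0[0, 0] * np.exp(-k * grid[4]) / sigma
    errs = []
    for factor in (1.10, 1.05, 1.025):
        s = local_sensitivities(mech, c0, ranges, factor=factor, grid=grid)
        errs.append(abs(s.S[0, 0, 0, 4] - analytic))
    assert errs[0] > errs[1] > errs[2]  # one-sided difference: order-1 decay


def test_blowup_production_reaction_ranks_first(truth_blowup):
    from basalcal.ranges import sample_initial_conditions

    conds = sample_initial_conditions(truth_blowup.ranges, truth_blowup.mechanism, 20, seed=100)
    sens = local_sensitivities(truth_blowup.mechanism, conds, truth_blowup.ranges)
    table = sue_impact(sens, 4.0)
    top = table.ranking().iloc[0]["reaction"]
    assert top == 11  # the too-fast catalytic production X -> X + Y


def test_uniform_f_preserves_ranking(fixture_sensitivity):
    sens, _ = fixture_sensitivity
    t1 = sue_impact(sens, 4.0)
    t2 = sue_impact(sens, 1.0)
    order1 = np.argsort(-t1.aggregate_impact, kind="stable")
    order2 = np.argsort(-t2.aggregate_impact, kind="stable")
    np.testing.assert_array_equal(order1, order2)
    # ranking by impact equals ranking by RMS sensitivity alone
    order_rms = np.argsort(-t1.aggregate_rms, kind="stable")
    np.testing.assert_array_equal(order1, order_rms)


def test_impact_linear_in_sigma_n(fixture_sensitivity):
    sens, _ = fixture_sensitivity
    t1 = sue_impact(sens, 2.0)
    t2 = sue_impact(sens, 4.0)
    np.testing.assert_allclose(t2.impact, 2.0 * t1.impact, rtol=1e-12)


def test_negative_f_rejected(fixture_sensitivity):
    sens, _ = fixture_sensitivity
    with pytest.raises(ValueError):
        sue_impact(sens, -1.0)


def test_impact_invariant_under_condition_permutation(truth, conditions):
    rng = np.random.default_rng(3)
    sens_a = local_sensitivities(truth.mechanism, conditions, truth.ranges)
    sens_b = local_sensitivities(truth.mechanism, conditions[rng.permutation(20)], truth.ranges)
    ta, tb = sue_impact(sens_a, 4.0), sue_impact(sens_b, 4.0)
    np.testing.assert_allclose(ta.impact, tb.impact, rtol=1e-6, atol=1e-12)


def test_dormancy_is_seed_independent(truth):
    from basalcal.ranges import sample_initial_conditions

    for seed in (5, 6):
        conds = sample_initial_conditions(truth.ranges, truth.mechanism, 10, seed=seed)
        sens = local_sensitivities(truth.mechanism, conds, truth.ranges)
        parts = classify_reactions(sue_impact(sens, 4.0))
        assert sorted(parts["dormant"]) == truth.dormant


def test_sigma_from_f_uniform_convention():
    # uniform on ±f*ln10 has standard deviation f*ln10/sqrt(3)
    f = 4.0
    assert sigma_from_f(f) == pytest.approx(f * np.log(10) / np.sqrt(3))


def test_perturbation_factor_must_exceed_one(truth, conditions):
    with pytest.raises(ValueError):
        local_sensitivities(truth.mechanism, conditions, truth.ranges, factor=1.0)
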