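"""Mass-action RHS construction and stiff integration."""

import numpy as np
import pytest

from basalcal.mechanism import mechanism_from_dict
from basalcal.simulate import (
    MassActionODE,
    hourly_grid,
    simulate,
    simulate_ensemble,
    simulate_ensemble_stacked,
)

from conftest import brute_force_rhs, random_mass_action_network


def _mech(species, reactions):
    return mechanism_from_dict({"species": species, "reactions": reactions})


def test_zero_state_gives_zero_derivative():
    mech = _mech(["A", "B", "C"],
                 [{"index": 1, "equation": "A + B -> C", "log10_k": 5.0},
                  {"index": 2, "equation": "C -> A + B", "log10_k": -3.0}])
    ode = MassActionODE(mech)
    assert np.all(ode.rhs(0.0, np.zeros(3)) == 0.0)


def test_unimolecular_dissociation_rhs():
    # BCL2_BAX -> BCL2 + BAX with k = 10^-3.5 1/s
    mech = _mech(["BCL2_BAX", "BCL2", "BAX"],
                 [{"index": 10, "equation": "BCL2_BAX -> BCL2 + BAX", "log10_k": -3.5}])
    ode = MassActionODE(mech)
    x = 2.5e-11
    d = ode.rhs(0.0, np.array([x, 0.0, 0.0]))
    k = 10 ** -3.5
    assert d[0] == pytest.approx(-k * x, rel=1e-14)
    assert d[1] == pytest.approx(k * x, rel=1e-14)
    assert d[2] == pytest.approx(k * x, rel=1e-14)


def test_rhs_matches_brute_force_oracle_on_random_networks():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        mech = random_mass_action_network(rng)
        ode = MassActionODE(mech)
        state = rng.uniform(0, 1e-9, size=ode.n)
        expected = brute_force_rhs(mech, state)
        got = ode.rhs(0.0, state)
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-300)


def test_jacobian_matches_finite_differences():
    rng = np.random.default_rng(7)
    mech = random_mass_action_network(rng)
    ode = MassActionODE(mech)
    state = rng.uniform(1e-11, 1e-9, size=ode.n)
    J = ode.jac(0.0, state)
    eps = 1e-6
    scale = np.abs(J).max()
    for j in range(ode.n):
        dx = np.zeros(ode.n)
        dx[j] = eps * state[j]
        num = (ode.rhs(0.0, state + dx) - ode.rhs(0.0, state - dx)) / (2 * dx[j])
        np.testing.assert_allclose(J[:, j], num, rtol=1e-4, atol=1e-8 * scale)


def test_exponential_decay_closed_form():
    # first-order loss at the published ATG5 degradation rate
    k = 10 ** -4.55
    mech = _mech(["A"], [{"index": 1, "equation": "A -> 0", "log10_k": -4.55}])
    c0 = 1e-11
    traj = simulate(mech, np.array([c0]))
    assert traj.success
    t_end = traj.time_grid[-1]
    assert t_end == pytest.approx(86400.0)
    expected = c0 * np.exp(-k * t_end)
    assert traj.conc[-1, 0] == pytest.approx(expected, rel=1e-7)


def test_buffered_synthesis_degradation_steady_state():
    # REF -> A at k_syn (flux = k_syn * [REF] = k_syn), A -> REF at k_deg:
    # steady state c_A = k_syn/k_deg
    mech = mechanism_from_dict({
        "species": [{"id": "REF", "role": "buffered", "activity": 1.0}, {"id": "A"}],
        "reactions": [{"index": 1, "equation": "REF -> A", "log10_k": -15.0},
                       {"index": 2, "equation": "A -> REF", "log10_k": -4.0}],
    })
    grid = np.linspace(0, 10 / 10 ** -4.0, 40)  # ten relaxation times
    traj = simulate(mech, np.array([0.0]), grid)
    assert traj.conc[-1, 0] == pytest.approx(10 ** -15.0 / 10 ** -4.0, rel=1e-6)


def test_binding_pair_conserves_total():
    mech = _mech(
        ["A", "B", "AB"],
        [{"index": 1, "equation": "A + B -> AB", "log10_k": 6.0, "reverse_of": 2},
         {"index": 2, "equation": "AB -> A + B", "log10_k": -3.0, "reverse_of": 1}],
    )
    c0 = np.array([1e-10, 8e-11, 0.0])
    traj = simulate(mech, c0)
    total_a = traj.conc[:, 0] + traj.conc[:, 2]
    total_b = traj.conc[:, 1] + traj.conc[:, 2]
    np.testing.assert_allclose(total_a, total_a[0], rtol=1e-6)
    np.testing.assert_allclose(total_b, total_b[0], rtol=1e-6)


def test_tolerance_refinement_converged(truth, conditions):
    t1 = simulate(truth.mechanism, conditions[0], rtol=1e-8, atol=1e-20)
    t2 = simulate(truth.mechanism, conditions[0], rtol=5e-9, atol=5e-21)
    end1, end2 = t1.conc[-1], t2.conc[-1]
    scale = np.abs(end1).max()
    assert np.max(np.abs(end1 - end2)) / scale < 1e-4


def test_initial_state_preserved_and_grid(truth, conditions):
    traj = simulate(truth.mechanism, conditions[0])
    np.testing.assert_allclose(traj.conc[0], conditions[0], atol=1e-30)
    assert len(traj.time_grid) == 25
    assert np.all(np.diff(traj.time_grid) > 0)
    assert traj.conc.min() >= 0.0


def test_ensemble_shapes_and_order_independence(truth, conditions):
    ens = simulate_ensemble(truth.mechanism, conditions)
    assert ens.n_cond == 20
    assert all(len(t.time_grid) == 25 for t in ens.trajectories)
    perm = np.random.default_rng(0).permutation(20)
    ens_p = simulate_ensemble(truth.mechanism, conditions[perm])
    for i, pi in enumerate(perm):
        np.testing.assert_array_equal(ens_p.trajectories[i].conc, ens.trajectories[pi].conc)


def test_zero_reaction_mechanism_is_constant():
    mech = _mech(["A", "B"], [])
    c0 = np.array([1e-10, 2e-10])
    ens = simulate_ensemble(mech, c0[None, :])
    assert np.all(ens.trajectories[0].conc == c0)


def test_stacked_matches_per_condition(truth, conditions):
    a = simulate_ensemble(truth.mechanism, conditions[:5])
    b = simulate_ensemble_stacked(truth.mechanism, conditions[:5])
    ca, cb = a.concentration_tensor(), b.concentration_tensor()
    scale = ca.max()
    assert np.max(np.abs(ca - cb)) / scale < 1e-6


def test_negative_initial_state_rejected(truth):
    with pytest.raises(ValueError):
        simulate(truth.mechanism, -np.ones(MassActionODE(truth.mechanism).n))


def test_hourly_grid_default():
    g = hourly_grid()
    assert len(g) == 25 and g[0] == 0.0 and g[-1] == 86400.0
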