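"""FOCTOPUS focusing random search and the multi-pass calibration protocol."""

import numpy as np
import pytest
from dataclasses import replace

from basalcal.mechanism import set_log_parameters
from basalcal.metrics import overall_error
from basalcal.optimize import (
    OptimizerConfig,
    calibrate,
    detect_and_reset_pinned,
    foctopus_minimize,
    run_passes,
)
from basalcal.simulate import simulate_ensemble


def test_one_dimensional_quadratic():
    a = 2.0
    cfg = OptimizerConfig(n_samples=32, seed=1, convergence_fraction=1e-3)
    st = foctopus_minimize(
        lambda x: (x[0] - a) ** 2, np.array([a - 4]), np.array([a + 4]), cfg,
        x0=np.array([a - 3.0]),
    )
    assert st.converged
    assert abs(st.center[0] - a) <= 1e-3 * 4.0  # within 1e-3 of the half-width


def test_constant_objective_focuses_and_stops():
    cfg = OptimizerConfig(n_samples=8, seed=3, convergence_fraction=1e-3)
    st = foctopus_minimize(lambda x: 1.0, np.array([0.0]), np.array([1.0]), cfg,
                           x0=np.array([0.25]))
    assert st.converged
    assert st.center[0] == 0.25  # no improvement ever moves the center
    zooms = [z for _, _, z in st.history]
    assert all(zooms[i + 1] < zooms[i] for i in range(1, len(zooms) - 1))


def test_ten_dimensional_sphere():
    cfg = OptimizerConfig(n_samples=32, seed=2, max_evaluations=20000,
                          convergence_fraction=1e-3)
    lo, hi = -4 * np.ones(10), 4 * np.ones(10)
    st = foctopus_minimize(lambda x: float(np.sum(x ** 2)), lo, hi, cfg,
                           x0=np.full(10, 2.0))
    errs = [e for _, e, _ in st.history]
    assert all(errs[i + 1] <= errs[i] for i in range(len(errs) - 1))
    assert st.best_error < 1e-4 * errs[0]


def test_samples_stay_in_box_and_volume_law():
    lo, hi = np.array([-1.0, 0.0]), np.array([1.0, 4.0])
    seen = []

    def obj(x):
        seen.append(x.copy())
        return float(np.sum(x ** 2))

    cfg = OptimizerConfig(n_samples=8, seed=9, max_evaluations=600,
                          convergence_fraction=1e-2)
    st = foctopus_minimize(obj, lo, hi, cfg, x0=np.array([0.5, 3.0]))
    pts = np.array(seen)
    assert np.all(pts >= lo - 1e-12) and np.all(pts <= hi + 1e-12)
    # volume bookkeeping: z after each iteration satisfies z^d = N^(u-d) capped at 1
    d, N = 2, cfg.n_samples
    up = N ** (1.0 / d)
    z = 1.0
    best = st.history[0][1]
    # replay the recorded history: zoom moves by exactly one factor per iteration
    for (n0, e0, z0), (n1, e1, z1) in zip(st.history, st.history[1:]):
        if e1 < e0:
            assert z1 == pytest.approx(min(1.0, z0 * up))
        else:
            assert z1 == pytest.approx(z0 / up)
    assert st.zoom == pytest.approx(st.history[-1][2])


def test_non_finite_objective_mapped_to_penalty():
    cfg = OptimizerConfig(n_samples=4, seed=0, max_evaluations=40)
    st = foctopus_minimize(lambda x: np.nan, np.array([0.0]), np.array([1.0]), cfg)
    assert st.best_error == cfg.penalty


def test_zero_dimensional_active_set_rejected():
    cfg = OptimizerConfig(n_samples=4, seed=0)
    with pytest.raises(ValueError):
        foctopus_minimize(lambda x: 0.0, np.empty(0), np.empty(0), cfg)


def test_reproducible_given_seed():
    cfg = OptimizerConfig(n_samples=8, seed=5, max_evaluations=200)
    runs = [
        foctopus_minimize(lambda x: float((x[0] - 1) ** 2 + x[1] ** 2),
                          np.array([-4.0, -4.0]), np.array([4.0, 4.0]), cfg)
        for _ in range(2)
    ]
    np.testing.assert_array_equal(runs[0].center, runs[1].center)
    assert runs[0].history == runs[1].history


def test_calibrate_empty_active_set_is_noop(truth, conditions):
    cfg = OptimizerConfig(n_samples=4, seed=0, max_evaluations=10)
    mech_opt, rep, st = calibrate(truth.mechanism, truth.ranges, conditions, [], cfg)
    assert mech_opt is truth.mechanism
    base = overall_error(simulate_ensemble(truth.mechanism, conditions), truth.ranges)
    assert rep.E == pytest.approx(base.E, rel=1e-6)


def test_calibrate_improves_blowup_fixture(truth_blowup):
    from basalcal.ranges import sample_initial_conditions

    conds = sample_initial_conditions(truth_blowup.ranges, truth_blowup.mechanism, 20, seed=100)
    start = overall_error(simulate_ensemble(truth_blowup.mechanism, conds), truth_blowup.ranges)
    cfg = OptimizerConfig(n_samples=16, seed=0, max_evaluations=250, convergence_fraction=1e-2)
    mech_opt, rep, st = calibrate(
        truth_blowup.mechanism, truth_blowup.ranges, conds, [11, 12], cfg
    )
    assert rep.E < 0.05 * start.E  # the runaway production arm is tamed
    errs = [e for _, e, _ in st.history]
    assert all(errs[i + 1] <= errs[i] for i in range(len(errs) - 1))


def test_detect_and_reset_pinned(truth):
    mech = truth.mechanism
    lo, hi = mech.reaction_by_index(1).rate.bounds
    at_edge = set_log_parameters(mech, {1: hi})
    reset, idx = detect_and_reset_pinned(at_edge)
    assert idx == [1]
    assert reset.reaction_by_index(1).rate.log10_k == mech.reaction_by_index(1).rate.log10_k0
    # untouched mechanism: identity, empty list
    same, none_idx = detect_and_reset_pinned(mech)
    assert none_idx == []
    for a, b in zip(same.reactions, mech.reactions):
        assert a.rate.log10_k == b.rate.log10_k


def test_out_of_box_truth_is_pinned_and_flagged(truth, conditions):
    """If the optimal rate lies outside the prior band, the optimizer drives the
    coefficient to the band edge; the reset step detects and re-centers it."""
    # blow up the starting value of the Y-degradation rate so the balanced value
    # (the truth) is 5 decades outside the prior box
    mech = truth.mechanism.copy()
    r = mech.reaction_by_index(12)
    r.rate = replace(r.rate, log10_k=r.rate.log10_k + 5.0, log10_k0=r.rate.log10_k + 5.0,
                     f_prior=4.0)
    cfg = OptimizerConfig(n_samples=16, seed=4, max_evaluations=300, convergence_fraction=1e-2)
    mech_opt, rep, st = calibrate(mech, truth.ranges, conditions, [12], cfg)
    lo, hi = mech.reaction_by_index(12).rate.bounds
    assert mech_opt.reaction_by_index(12).rate.log10_k == pytest.approx(lo, abs=0.05)
    _, flagged = detect_and_reset_pinned(mech_opt, epsilon=0.05)
    assert 12 in flagged


def test_pass_trace_continuity(truth, conditions):
    """With nothing reset between passes, pass 2 starts at pass 1's end error."""
    pert_mech = set_log_parameters(truth.mechanism, {11: truth.true_log10_k[11] + 1.0})
    cfg = OptimizerConfig(n_samples=8, seed=7, max_evaluations=120, convergence_fraction=1e-2)
    recs = run_passes(pert_mech, truth.ranges, conditions, [11], cfg, n_passes=2)
    assert len(recs) == 2
    if not recs[0].auto_reset:  # no pins: continuity must hold exactly-ish
        end1 = recs[0].report.E
        start2 = recs[1].state.history[0][1]
        assert start2 == pytest.approx(end1, rel=1e-3)
    for r in recs:
        errs = [e for _, e, _ in r.state.history]
        assert all(errs[i + 1] <= errs[i] for i in range(len(errs) - 1))


def test_manual_reset_between_passes(truth, conditions):
    pert_mech = set_log_parameters(truth.mechanism, {11: truth.true_log10_k[11] + 1.5,
                                                     12: truth.true_log10_k[12] - 1.5})
    cfg = OptimizerConfig(n_samples=8, seed=8, max_evaluations=80, convergence_fraction=1e-2)
    recs = run_passes(pert_mech, truth.ranges, conditions, [11, 12], cfg, n_passes=2,
                      manual_resets={1: [12]})
    assert 12 in recs[0].manual_reset or 12 in recs[0].auto_reset


def test_config_validation():
    with pytest.raises(ValueError):
        OptimizerConfig(n_samples=1)
    with pytest.raises(ValueError):
        OptimizerConfig(convergence_fraction=2.0)
    with pytest.raises(ValueError):
        OptimizerConfig(distribution="other")
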