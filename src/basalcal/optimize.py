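"""FOCTOPUS: focusing robust optimization with uncertainty-based sampling.

A bounded adaptive random search over the log10 rate coefficients of the
active reactions.  Each iteration draws N candidate parameter vectors from
the current sampling distribution (uniform or Gaussian), restricted to the
prior box.  If any candidate improves on the incumbent best error, the
sampling distribution is re-centered there and the sampling volume is
multiplied by N (never beyond the prior volume); otherwise the volume is
divided by N, focusing on the incumbent.  The very first iteration samples
the entire prior box.  The search stops when the per-parameter sampling
radius has shrunk below a small fraction of the prior half-width in every
coordinate, or when the evaluation budget is exhausted.

The sampling volume is maintained as a single scalar zoom factor z in
(0, 1] applied to all prior half-widths, so volume = prior_volume * z^d and
the multiply/divide-by-N bookkeeping is exact in z.

The multi-pass protocol (:func:`run_passes`) re-runs the calibration after
resetting to their nominal values any coefficients that were optimized to
the edge of their prior band (where they either switch a reaction off or
consume its reactants unrealistically fast), optionally together with an
operator-supplied manual reset list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .mechanism import Mechanism, set_log_parameters
from .metrics import ErrorReport, overall_error
from .ranges import BasalRangeSet
from .simulate import MassActionODE, simulate_ensemble

__all__ = [
    "OptimizerConfig",
    "OptimizerState",
    "foctopus_minimize",
    "calibrate",
    "detect_and_reset_pinned",
    "run_passes",
    "PassRecord",
]

PENALTY = 1e12
PIN_EPSILON = 0.01  # log10 units


@dataclass
class OptimizerConfig:
    """Settings of the focusing random search."""

    n_samples: int = 32
    distribution: str = "uniform"  # or "gaussian"
    convergence_fraction: float = 1e-3
    max_evaluations: int = 10_000
    seed: int = 0
    penalty: float = PENALTY
    # solver tolerances for objective evaluations; looser than the reporting
    # defaults because the optimizer only needs ~3 correct digits of E
    sim_rtol: float = 1e-6
    sim_atol: float = 1e-18

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (0.0 < self.convergence_fraction < 1.0):
            raise ValueError("convergence_fraction must be in (0, 1)")
        if self.distribution not in ("uniform", "gaussian"):
            raise ValueError(f"unknown distribution {self.distribution!r}")


@dataclass
class OptimizerState:
    """Result and trace of one FOCTOPUS run."""

    center: np.ndarray  # best parameter vector found (log10 k)
    best_error: float
    zoom: float  # final scalar zoom factor z (volume = prior_volume * z^d)
    n_evaluations: int
    n_iterations: int
    converged: bool
    history: list[tuple[int, float, float]] = field(default_factory=list)
    # (cumulative evaluations, best error, zoom) after each iteration

    @property
    def error_trace(self) -> np.ndarray:
        return np.array([(n, e) for n, e, _ in self.history])


def foctopus_minimize(
    objective: Callable[[np.ndarray], float],
    lower: np.ndarray,
    upper: np.ndarray,
    config: OptimizerConfig,
    x0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> OptimizerState:
    """Minimize ``objective`` over the box [lower, upper] starting from ``x0``.

    ``x0`` defaults to the box center and is evaluated first, so the history
    starts at the incumbent model's error.  Non-finite objective values are
    replaced by the configured penalty.  The run is reproducible given the
    config seed (or a supplied generator).
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = lower.size
    if d == 0:
        raise ValueError("empty active parameter set")
    if np.any(upper < lower):
        raise ValueError("invalid bounds")
    half = 0.5 * (upper - lower)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    def safe_eval(x: np.ndarray) -> float:
        v = float(objective(x))
        return v if np.isfinite(v) else config.penalty

    center = (0.5 * (lower + upper)) if x0 is None else np.asarray(x0, dtype=float).copy()
    center = np.clip(center, lower, upper)
    best = safe_eval(center)
    n_eval = 1
    z = 1.0
    up = config.n_samples ** (1.0 / d)
    history: list[tuple[int, float, float]] = [(n_eval, best, z)]
    n_iter = 0
    converged = False
    while n_eval < config.max_evaluations:
        if z < config.convergence_fraction:
            converged = True
            break
        n = min(config.n_samples, config.max_evaluations - n_eval)
        if n < 1:
            break
        radius = z * half
        if z >= 1.0:
            # first/zoomed-out iterations cover the whole prior box
            xs = lower + rng.random((n, d)) * (upper - lower)
        elif config.distribution == "uniform":
            xs = center + (2.0 * rng.random((n, d)) - 1.0) * radius
            np.clip(xs, lower, upper, out=xs)
        else:
            xs = center + rng.standard_normal((n, d)) * (radius / 2.0)
            np.clip(xs, lower, upper, out=xs)
        vals = np.array([safe_eval(x) for x in xs])
        n_eval += n
        i_best = int(np.argmin(vals))
        if vals[i_best] < best:
            best = float(vals[i_best])
            center = xs[i_best].copy()
            z = min(1.0, z * up)
        else:
            z /= up
        n_iter += 1
        history.append((n_eval, best, z))
    if z < config.convergence_fraction:
        converged = True
    return OptimizerState(
        center=center,
        best_error=best,
        zoom=z,
        n_evaluations=n_eval,
        n_iterations=n_iter,
        converged=converged,
        history=history,
    )


def _make_objective(
    mech: Mechanism,
    ranges: BasalRangeSet,
    conditions: np.ndarray,
    active: Sequence[int],
    grid: np.ndarray | None,
    species: list[str] | None,
    config: OptimizerConfig,
):
    """Ensemble-error objective over log10 k of the active reactions.

    Reuses one compiled ODE system, updating only the perturbed rate
    coefficients, and integrates the frozen condition set through the stacked
    fast path, so repeated evaluations stay cheap.  The same sampled initial
    states are used for every candidate.
    """
    from .simulate import simulate_ensemble_stacked

    ode = MassActionODE(mech)
    pos = {idx: p for p, idx in enumerate(ode.reaction_indices)}
    active_pos = np.array([pos[i] for i in active], dtype=np.intp)
    base_k = ode._k_eff.copy()
    base_log10 = np.array([mech.reaction_by_index(i).rate.log10_k for i in active])
    penalty = config.penalty

    def objective(x: np.ndarray) -> float:
        ode._k_eff[active_pos] = base_k[active_pos] * 10.0 ** (np.asarray(x) - base_log10)
        traj = simulate_ensemble_stacked(
            ode, conditions, grid, rtol=config.sim_rtol, atol=config.sim_atol
        )
        try:
            rep = overall_error(traj, ranges, species=species)
        except Exception:
            return penalty
        return min(rep.E, penalty)

    def restore() -> None:
        ode._k_eff[:] = base_k

    return objective, restore


def calibrate(
    mech: Mechanism,
    ranges: BasalRangeSet,
    conditions: np.ndarray,
    active: Sequence[int],
    config: OptimizerConfig,
    grid: np.ndarray | None = None,
    species: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Mechanism, ErrorReport, OptimizerState]:
    """Minimize the ensemble basal error over the active rate coefficients.

    Bounds are each reaction's prior band ``log10_k0 ± f_prior``; the search
    starts from the mechanism's current values.  With an empty active set the
    input mechanism is returned unchanged (its error is still evaluated).
    """
    if len(active) == 0:
        traj = simulate_ensemble(mech, conditions, grid)
        rep = overall_error(traj, ranges, species=species)
        state = OptimizerState(
            center=np.empty(0), best_error=rep.E, zoom=1.0,
            n_evaluations=1, n_iterations=0, converged=True,
            history=[(1, rep.E, 1.0)],
        )
        return mech, rep, state
    bounds = [mech.reaction_by_index(i).rate.bounds for i in active]
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])
    x0 = np.array([mech.reaction_by_index(i).rate.log10_k for i in active])
    objective, restore = _make_objective(
        mech, ranges, conditions, active, grid, species, config
    )
    state = foctopus_minimize(objective, lower, upper, config, x0=x0, rng=rng)
    restore()
    mech_opt = set_log_parameters(mech, dict(zip(active, state.center)), clip=True)
    traj = simulate_ensemble(mech_opt, conditions, grid)
    rep = overall_error(traj, ranges, species=species)
    return mech_opt, rep, state


def detect_and_reset_pinned(
    mech: Mechanism,
    epsilon: float = PIN_EPSILON,
    active: Sequence[int] | None = None,
) -> tuple[Mechanism, list[int]]:
    """Reset to nominal any rate coefficient optimized to the edge of its band.

    A coefficient within ``epsilon`` log10 units of either prior bound has
    effectively switched its reaction off (lower edge) or made it consume its
    reactants immediately (upper edge); it is set back to ``log10_k0`` so a
    subsequent pass can re-optimize it inside the sensitive range.
    """
    out = mech.copy()
    reset: list[int] = []
    sel = set(active) if active is not None else None
    for r in out.reactions:
        if sel is not None and r.index not in sel:
            continue
        lo, hi = r.rate.bounds
        if r.rate.f_prior == 0:
            continue
        if min(r.rate.log10_k - lo, hi - r.rate.log10_k) <= epsilon:
            r.rate = replace(r.rate, log10_k=r.rate.log10_k0, pinned=False)
            reset.append(r.index)
    return out, reset


@dataclass
class PassRecord:
    """Bookkeeping of one optimization pass."""

    pass_index: int
    state: OptimizerState
    report: ErrorReport
    mechanism: Mechanism
    auto_reset: list[int] = field(default_factory=list)
    manual_reset: list[int] = field(default_factory=list)


def run_passes(
    mech: Mechanism,
    ranges: BasalRangeSet,
    conditions: np.ndarray,
    active: Sequence[int],
    config: OptimizerConfig,
    n_passes: int = 4,
    grid: np.ndarray | None = None,
    species: list[str] | None = None,
    manual_resets: dict[int, Sequence[int]] | None = None,
    pin_epsilon: float = PIN_EPSILON,
) -> list[PassRecord]:
    """Multi-pass calibration with edge-pinned parameter resets between passes.

    ``manual_resets[p]`` lists reaction indices to force back to nominal after
    pass ``p`` (1-based) — the operator intervention for coefficients that
    consume their reactants too quickly without reaching the band edge.
    Each pass uses an independent substream of the config seed, so the whole
    protocol is reproducible.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    manual_resets = manual_resets or {}
    streams = np.random.SeedSequence(config.seed).spawn(n_passes)
    records: list[PassRecord] = []
    current = mech
    for p in range(1, n_passes + 1):
        rng = np.random.default_rng(streams[p - 1])
        mech_opt, rep, state = calibrate(
            current, ranges, conditions, active, config,
            grid=grid, species=species, rng=rng,
        )
        auto: list[int] = []
        manual: list[int] = []
        current = mech_opt
        if p < n_passes:
            current, auto = detect_and_reset_pinned(current, pin_epsilon, active)
            manual = [i for i in manual_resets.get(p, []) if i not in auto]
            if manual:
                current = set_log_parameters(
                    current,
                    {i: current.reaction_by_index(i).rate.log10_k0 for i in manual},
                )
        records.append(
            PassRecord(
                pass_index=p, state=state, report=rep, mechanism=mech_opt,
                auto_reset=auto, manual_reset=list(manual),
            )
        )
    return records
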