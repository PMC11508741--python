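"""Local sensitivity analysis and impact-based reaction ranking.

Each rate coefficient k_n is perturbed by a fixed factor (default +5%) and
the whole condition ensemble is re-simulated, giving sigma-normalized local
sensitivities by one-sided finite differences:

    S_{s,i,n}(t_j) = (1/sigma_s) [c_sim(t_j; 1.05 k_n) - c_sim(t_j; k_n)] / ln 1.05

The SUE impact of reaction n on species s combines the RMS of these
sensitivities over conditions and times with the prior spread of ln k_n:

    I_{n->s} = sigma_n * sqrt( mean_{i,j} S_{s,i,n}^2(t_j) )

where sigma_n is derived from the uncertainty parameter f_n (half-width of
the admissible band in log10 units) under a uniform-prior convention,
sigma_n = f_n * ln(10) / sqrt(3).  With a uniform f across reactions the
impact ranking coincides with the ranking by RMS sensitivity alone.

Classification: a reaction is *dormant* if its sensitivities vanish
identically (zero flux in the basal state — its reactants are absent),
*influential* if its aggregate RMS sensitivity exceeds the significance
threshold (default 0.01), and *negligible* otherwise.  Aggregation across
monitored species is by maximum, so a reaction mattering to any monitored
species is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanism import Mechanism
from .ranges import BasalRangeSet
from .simulate import (
    EnsembleTrajectories,
    MassActionODE,
    simulate_ensemble,
    simulate_ensemble_stacked,
)

__all__ = [
    "SensitivityTensor",
    "ImpactTable",
    "SIGNIFICANCE_THRESHOLD",
    "sigma_from_f",
    "local_sensitivities",
    "sue_impact",
    "classify_reactions",
]

SIGNIFICANCE_THRESHOLD = 0.01

LN10 = np.log(10.0)


def sigma_from_f(f: float | np.ndarray) -> float | np.ndarray:
    """Standard deviation of ln k for a uniform band of half-width f log10 units."""
    return np.asarray(f, dtype=float) * LN10 / np.sqrt(3.0)


@dataclass
class SensitivityTensor:
    """S[s, i, n, j]: species x condition x reaction x time sensitivities."""

    S: np.ndarray
    species: list[str]
    reaction_indices: list[int]
    factor: float
    valid: np.ndarray  # (n_reac, n_cond) bool: perturbed run integrated OK

    @property
    def n_reactions(self) -> int:
        return self.S.shape[2]


@dataclass
class ImpactTable:
    """Per-reaction SUE impacts, aggregates and classification flags."""

    reaction_indices: list[int]
    species: list[str]
    impact: np.ndarray  # (n_reac, n_spec) I_{n->s}
    rms_sensitivity: np.ndarray  # (n_reac, n_spec), impact / sigma_n
    sigma_n: np.ndarray  # (n_reac,)
    equations: list[str] = field(default_factory=list)

    @property
    def aggregate_impact(self) -> np.ndarray:
        """Max over monitored species of I_{n->s}."""
        return self.impact.max(axis=1)

    @property
    def aggregate_rms(self) -> np.ndarray:
        return self.rms_sensitivity.max(axis=1)

    def ranking(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "reaction": self.reaction_indices,
                "equation": self.equations or [""] * len(self.reaction_indices),
                "impact": self.aggregate_impact,
                "rms_sensitivity": self.aggregate_rms,
            }
        )
        df["dormant"] = df["impact"] == 0.0
        df = df.sort_values("impact", ascending=False).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.ranking().to_csv(path, index=False)


def local_sensitivities(
    mech: Mechanism,
    conditions: np.ndarray,
    ranges: BasalRangeSet,
    factor: float = 1.05,
    grid: np.ndarray | None = None,
    species: list[str] | None = None,
    baseline: EnsembleTrajectories | None = None,
    stacked: bool = True,
) -> SensitivityTensor:
    """Finite-difference sigma-normalized sensitivities for every reaction.

    One forward perturbation per reaction: the full ensemble is re-simulated
    with k_n -> factor * k_n (N_reac extra ensemble runs).  A perturbed run
    that fails to integrate marks that (reaction, condition) slice invalid
    (NaN) rather than aborting the analysis.  ``stacked`` integrates each
    ensemble as one block system (faster, same trajectories to tolerance);
    baseline and perturbed runs always use the same path so a reaction with
    zero flux under every condition yields exactly zero sensitivity.
    """
    if factor <= 1.0:
        raise ValueError("perturbation factor must exceed 1")
    ode = MassActionODE(mech)
    run = simulate_ensemble_stacked if stacked else simulate_ensemble
    if baseline is None:
        baseline = run(ode, conditions, grid)
    if species is None:
        species = [s.id for s in mech.monitored_species]
    cols = [baseline.species_ids.index(sid) for sid in species]
    sigma = np.array([ranges.get(sid).sigma for sid in species])
    base = baseline.concentration_tensor()[:, :, cols]  # (cond, time, spec)

    n_cond, n_tim, n_spec = base.shape
    n_reac = mech.n_reactions
    S = np.zeros((n_spec, n_cond, n_reac, n_tim))
    valid = np.ones((n_reac, n_cond), dtype=bool)
    dln = np.log(factor)
    for p, rxn in enumerate(mech.reactions):
        saved = ode._k_eff[p]
        ode._k_eff[p] = saved * factor
        pert = run(ode, conditions, grid)
        ode._k_eff[p] = saved
        for i, t in enumerate(pert.trajectories):
            if not (t.success and baseline.trajectories[i].success):
                valid[p, i] = False
                S[:, i, p, :] = np.nan
                continue
            diff = (t.conc[:, cols] - base[i]) / dln  # (time, spec)
            S[:, i, p, :] = (diff / sigma).T
    return SensitivityTensor(
        S=S, species=list(species), reaction_indices=[r.index for r in mech.reactions],
        factor=factor, valid=valid,
    )


def sue_impact(
    sens: SensitivityTensor,
    f: np.ndarray | float | dict[int, float],
    equations: list[str] | None = None,
) -> ImpactTable:
    """SUE impact table from a sensitivity tensor and prior uncertainty f_n."""
    n_reac = sens.n_reactions
    if isinstance(f, dict):
        f_vec = np.array([f[idx] for idx in sens.reaction_indices], dtype=float)
    else:
        f_vec = np.broadcast_to(np.asarray(f, dtype=float), (n_reac,)).copy()
    if np.any(f_vec < 0):
        raise ValueError("uncertainty parameter f must be nonnegative")
    sigma_n = np.asarray(sigma_from_f(f_vec))
    # RMS over conditions and times, ignoring invalid (NaN) slices
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(np.nanmean(sens.S ** 2, axis=(1, 3)))  # (spec, reac)
    rms = np.nan_to_num(rms.T, nan=0.0)  # (reac, spec)
    impact = sigma_n[:, None] * rms
    return ImpactTable(
        reaction_indices=list(sens.reaction_indices),
        species=list(sens.species),
        impact=impact,
        rms_sensitivity=rms,
        sigma_n=sigma_n,
        equations=equations or [],
    )


def classify_reactions(
    table: ImpactTable, threshold: float = SIGNIFICANCE_THRESHOLD
) -> dict[str, list[int]]:
    """Partition reactions into influential / dormant / negligible sets.

    Dormant: aggregate impact exactly zero (no flux from any basal state).
    Influential: aggregate RMS sensitivity above the significance threshold.
    Negligible: the (nonzero but insignificant) remainder.  The three sets
    are disjoint and exhaustive.
    """
    influential, dormant, negligible = [], [], []
    for idx, agg_imp, agg_rms in zip(
        table.reaction_indices, table.aggregate_impact, table.aggregate_rms
    ):
        if agg_imp == 0.0:
            dormant.append(idx)
        elif agg_rms > threshold:
            influential.append(idx)
        else:
            negligible.append(idx)
    return {"influential": influential, "dormant": dormant, "negligible": negligible}
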