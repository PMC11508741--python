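"""Basal-state deviation error functions.

The objective of the calibration is the sigma-normalized root-mean-square
deviation of the simulated concentrations from the midpoints of the feasible
basal intervals:

    E^2   = (1 / (N_spec N_cond N_tim)) sum_{s,i,j} (c_sij - c_mean_s)^2 / sigma_s^2
    E_s^2 = (1 / (N_cond N_tim))        sum_{i,j}   (c_sij - c_mean_s)^2 / sigma_s^2

so that E = sqrt(mean_s E_s^2) exactly.  All time points on the hourly grid
contribute, including t=0 (the sampled initial values).

A reaction-free model leaves the uniform initial distribution untouched; in
the many-condition limit each E_s (and E) tends to the RMS of a uniform
variable on ±4 sigma, 4/sqrt(3) ≈ 2.309.

Failed-integration conditions contribute a large finite penalty instead of
being dropped, so the condition count entering the average is stable and the
optimizer sees a finite, strongly unfavorable objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ranges import BasalRangeSet
from .simulate import EnsembleTrajectories

__all__ = [
    "ErrorReport",
    "NO_REACTION_LIMIT",
    "PENALTY_ERROR",
    "species_error",
    "overall_error",
    "error_from_residuals",
]

#: many-condition limit of E_s for a reaction-free model, RMS of U(-4, 4)
NO_REACTION_LIMIT = 4.0 / np.sqrt(3.0)

#: per-residual magnitude assigned to a failed integration (in sigma units)
PENALTY_ERROR = 1e12


@dataclass
class ErrorReport:
    """Overall and per-species basal deviation errors."""

    E: float
    E_s: dict[str, float]
    n_spec: int
    n_cond: int
    n_tim: int
    n_failed_conditions: int = 0
    residuals: np.ndarray | None = None  # (n_spec, n_cond, n_tim), optional

    def sorted_species(self) -> list[tuple[str, float]]:
        return sorted(self.E_s.items(), key=lambda kv: kv[1], reverse=True)

    def to_frame(self) -> pd.DataFrame:
        """Per-species errors sorted descending (report table layout)."""
        rows = self.sorted_species()
        return pd.DataFrame(rows, columns=["species", "E_s"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _residual_tensor(
    traj: EnsembleTrajectories,
    ranges: BasalRangeSet,
    species: list[str],
) -> tuple[np.ndarray, int]:
    """Normalized residuals (n_spec, n_cond, n_tim); penalty rows for failures."""
    ids = traj.species_ids
    cols = []
    for sid in species:
        if sid not in ids:
            raise KeyError(f"monitored species {sid!r} missing from trajectories")
        cols.append(ids.index(sid))
    conc = traj.concentration_tensor()  # (n_cond, n_tim, n_dyn)
    sub = conc[:, :, cols]  # (n_cond, n_tim, n_spec)
    mean = np.array([ranges.get(sid).c_mean for sid in species])
    sigma = np.array([ranges.get(sid).sigma for sid in species])
    if np.any(sigma <= 0):
        bad = [sid for sid, sg in zip(species, sigma) if sg <= 0]
        raise ZeroDivisionError(f"zero-width basal range (sigma=0) for {bad}")
    res = (sub - mean) / sigma  # broadcast over species axis
    res = np.moveaxis(res, 2, 0)  # (n_spec, n_cond, n_tim)
    n_failed = 0
    for i, t in enumerate(traj.trajectories):
        if not t.success:
            res[:, i, :] = PENALTY_ERROR
            n_failed += 1
    return res, n_failed


def species_error(
    traj: EnsembleTrajectories, ranges: BasalRangeSet, species_id: str
) -> float:
    """E_s for one monitored species."""
    res, _ = _residual_tensor(traj, ranges, [species_id])
    return float(np.sqrt(np.mean(res[0] ** 2)))


def overall_error(
    traj: EnsembleTrajectories,
    ranges: BasalRangeSet,
    species: list[str] | None = None,
    keep_residuals: bool = False,
) -> ErrorReport:
    """Overall error E and per-species E_s for the monitored set.

    ``species`` defaults to the monitored species of the range set that are
    present in the trajectories.
    """
    if species is None:
        species = [r.species_id for r in ranges if r.monitored and r.species_id in traj.species_ids]
    if not species:
        raise ValueError("no monitored species to evaluate")
    res, n_failed = _residual_tensor(traj, ranges, species)
    per_species = np.sqrt(np.mean(res ** 2, axis=(1, 2)))
    E = float(np.sqrt(np.mean(per_species ** 2)))
    return ErrorReport(
        E=E,
        E_s={sid: float(v) for sid, v in zip(species, per_species)},
        n_spec=len(species),
        n_cond=res.shape[1],
        n_tim=res.shape[2],
        n_failed_conditions=n_failed,
        residuals=res if keep_residuals else None,
    )


def error_from_residuals(res: np.ndarray) -> tuple[float, np.ndarray]:
    """(E, E_s vector) from a raw normalized residual tensor (s, i, j)."""
    per_species = np.sqrt(np.mean(np.asarray(res, dtype=float) ** 2, axis=(1, 2)))
    return float(np.sqrt(np.mean(per_species ** 2))), per_species
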