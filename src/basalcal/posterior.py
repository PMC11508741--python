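"""Posterior parameter uncertainty at the calibrated optimum.

The calibration objective is a sum of squared sigma-normalized residuals
r_{s,i,j} = (c_sim - c_mean_s)/sigma_s.  Linearizing the residual vector in
ln k around the optimum (Gauss-Newton) and combining it with a Gaussian
prior equivalent to the ±f_prior uniform band gives the posterior
covariance over the active ln k:

    Sigma_post = (J^T J + Sigma_prior^{-1})^{-1},
    J_{m,p} = d r_m / d ln k_p  (one-sided finite differences),
    Sigma_prior = diag( (f_prior,p * ln10 / sqrt(3))^2 ).

Each per-reaction posterior standard deviation is converted back to a
uniform-equivalent half-width on the log10 scale, f_posterior =
sqrt(3) * sigma_post(log10 k), with linear-scale uncertainty factor
10^f_posterior.  A parameter the residuals carry no information about
(zero Jacobian column — e.g. a dormant reaction) keeps its prior:
f_posterior = f_prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanism import Mechanism
from .ranges import BasalRangeSet
from .sensitivity import LN10, sigma_from_f
from .simulate import MassActionODE, simulate_ensemble

__all__ = ["PosteriorResult", "posterior_covariance", "uncertainty_bins",
           "covariance_with_prior", "UNCERTAINTY_BANDS"]

UNCERTAINTY_BANDS = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]


@dataclass
class PosteriorResult:
    """Posterior covariance and per-reaction uncertainty parameters."""

    active: list[int]
    covariance: np.ndarray  # over ln k, (m, m)
    f_prior: np.ndarray
    f_posterior: np.ndarray  # log10 half-widths, uniform-equivalent
    log10_k_opt: np.ndarray
    log10_k_ini: np.ndarray

    @property
    def sigma_post_log10(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance)) / LN10

    @property
    def uncertainty_factor(self) -> np.ndarray:
        return 10.0 ** self.f_posterior

    def to_frame(self, mech: Mechanism | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "reaction": self.active,
                "log10_k_ini": self.log10_k_ini,
                "f_prior": self.f_prior,
                "log10_k_opt": self.log10_k_opt,
                "f_posterior": self.f_posterior,
                "uncertainty_factor": self.uncertainty_factor,
            }
        )
        if mech is not None:
            df.insert(1, "equation", [mech.reaction_by_index(i).equation for i in self.active])
        df = df.sort_values("f_posterior").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def to_csv(self, path: str | Path, mech: Mechanism | None = None) -> None:
        self.to_frame(mech).to_csv(path, index=False, float_format="%.4g")


def covariance_with_prior(J: np.ndarray, sigma_prior_ln: np.ndarray) -> np.ndarray:
    """(J^T J + Sigma_prior^{-1})^{-1}, symmetrized for numerical hygiene."""
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite residual Jacobian")
    m = J.shape[1]
    jtj = J.T @ J
    prec = jtj + np.diag(1.0 / np.asarray(sigma_prior_ln, dtype=float) ** 2)
    cov = np.linalg.inv(prec)
    return 0.5 * (cov + cov.T)


def posterior_covariance(
    mech_opt: Mechanism,
    conditions: np.ndarray,
    ranges: BasalRangeSet,
    active: Sequence[int],
    fd_step: float = np.log(1.05),
    grid: np.ndarray | None = None,
    species: list[str] | None = None,
) -> PosteriorResult:
    """Gauss-Newton posterior over the active ln k at the calibrated point.

    ``fd_step`` is the forward finite-difference step in ln k (default the
    +5% perturbation used for the sensitivity analysis).  Raises if any
    Jacobian entry is non-finite (a perturbed integration failed), naming
    the offending reaction.
    """
    active = list(active)
    if species is None:
        species = [s.id for s in mech_opt.monitored_species]
    ode = MassActionODE(mech_opt)
    pos = {idx: p for p, idx in enumerate(ode.reaction_indices)}
    cols = [ode.species_ids.index(sid) for sid in species]
    mean = np.array([ranges.get(sid).c_mean for sid in species])
    sigma = np.array([ranges.get(sid).sigma for sid in species])

    def residuals() -> np.ndarray:
        traj = simulate_ensemble(ode, conditions, grid)
        if not traj.all_success:
            return np.full(1, np.nan)
        sub = traj.concentration_tensor()[:, :, cols]  # (cond, time, spec)
        return ((sub - mean) / sigma).ravel()

    r0 = residuals()
    if not np.all(np.isfinite(r0)):
        raise RuntimeError("baseline ensemble failed at the calibrated parameters")
    J = np.empty((r0.size, len(active)))
    factor = np.exp(fd_step)
    for p_out, idx in enumerate(active):
        p = pos[idx]
        saved = ode._k_eff[p]
        ode._k_eff[p] = saved * factor
        r1 = residuals()
        ode._k_eff[p] = saved
        if not np.all(np.isfinite(r1)) or r1.size != r0.size:
            raise RuntimeError(f"perturbed ensemble failed for reaction {idx}")
        J[:, p_out] = (r1 - r0) / fd_step
    f_prior = np.array([mech_opt.reaction_by_index(i).rate.f_prior for i in active])
    cov = covariance_with_prior(J, np.asarray(sigma_from_f(f_prior)))
    sigma_post_log10 = np.sqrt(np.diag(cov)) / LN10
    f_posterior = np.sqrt(3.0) * sigma_post_log10
    # posterior can never be wider than the prior it includes
    f_posterior = np.minimum(f_posterior, f_prior)
    return PosteriorResult(
        active=active,
        covariance=cov,
        f_prior=f_prior,
        f_posterior=f_posterior,
        log10_k_opt=np.array([mech_opt.reaction_by_index(i).rate.log10_k for i in active]),
        log10_k_ini=np.array([mech_opt.reaction_by_index(i).rate.log10_k0 for i in active]),
    )


def uncertainty_bins(result: PosteriorResult) -> dict[str, int]:
    """Histogram of reactions by f_posterior band (orders of magnitude)."""
    out: dict[str, int] = {}
    for lo, hi in UNCERTAINTY_BANDS:
        n = int(np.sum((result.f_posterior >= lo) & (result.f_posterior < hi)))
        # the uninformed limit f_posterior == f_prior == 4 falls in [4, 5)
        out[f"{lo}-{hi}"] = n
    return out
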