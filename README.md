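# basalcal

Basal-state calibration of mass-action reaction-network models of
autophagy/apoptosis signaling.

A cell that is not under stress should stay in homeostasis: autophagy at a
low basal level, apoptosis off, and every signaling protein within its
literature-supported concentration range.  A kinetic model assembled from
heterogeneous literature sources usually fails this elementary test — some
rate coefficient drives a species (canonically the pro-apoptotic effector
BAX) out of its feasible range within hours.  `basalcal` implements the
workflow that diagnoses and repairs this:

1. **Ensemble simulation.** Initial concentrations are drawn uniformly and
   independently from per-species feasible intervals (complexes start at
   zero); each of the N_cond = 20 conditions is integrated for 24 h under
   mass-action kinetics and recorded hourly (N_tim = 25 points).
2. **Deviation error.** With σ_s one eighth of species *s*'s feasible
   interval and c̄_s its midpoint, the objective is the σ-normalized RMS
   deviation

       E² = (1 / N_spec·N_cond·N_tim) Σ_{s,i,j} (c_sim_{s,i}(t_j) − c̄_s)² / σ_s²,

   with per-species errors E_s defined the same way, so E² = mean_s E_s².
   A reaction-free model tends to E = 4/√3 ≈ 2.31 (the RMS of a uniform
   variable on ±4σ); errors far above that flag escape from the basal state.
3. **Influence ranking.** Each rate coefficient k_n is perturbed by +5% and
   the ensemble re-simulated, giving σ-normalized local sensitivities
   S = (Δc/σ_s)/ln 1.05.  Their RMS over conditions and times, scaled by the
   prior spread of ln k_n, is the per-reaction impact used to select the
   influential set; reactions with zero flux in the basal state (stress
   pathways whose inputs are absent) are *dormant* and drop out exactly.
4. **FOCTOPUS calibration.** A focusing random search over log₁₀k of the
   influential reactions inside ±f_prior (default ±4 decades): N samples per
   iteration, re-center on improvement and multiply the sampling volume by
   N (capped at the prior box), divide by N otherwise, stop when the
   per-parameter radius is a small fraction of the prior half-width.
   Coefficients optimized to a band edge have effectively switched their
   reaction off (or made it instantaneous); between passes they are reset to
   nominal and the search restarted.
5. **Posterior uncertainty.** At the optimum, a Gauss–Newton linearization
   of the normalized residuals with the prior as a Gaussian equivalent gives
   a posterior covariance over ln k; per reaction this is reported as the
   uniform-equivalent half-width f_posterior and the factor 10^f_posterior.

The package ships a full-size synthetic stand-in network (84 species, 113
reactions, 14 reversible pairs, 12 dormant stress reactions) that embeds the
21 published reactions with their printed rate coefficients, plus a small
ground-truth fixture for end-to-end recovery tests.

## Worked example

```python
import numpy as np
from basalcal import (load_standin_model, sample_initial_conditions,
                      simulate_ensemble, overall_error,
                      local_sensitivities, sue_impact, classify_reactions,
                      calibrate, OptimizerConfig)

mech, ranges = load_standin_model()
conds = sample_initial_conditions(ranges, mech, 20, seed=7)
rep = overall_error(simulate_ensemble(mech, conds), ranges)
print(f"initial E = {rep.E:.4g}; worst: {rep.sorted_species()[:2]}")

sens = local_sensitivities(mech, conds, ranges)
table = sue_impact(sens, 4.0, [r.equation for r in mech.reactions])
parts = classify_reactions(table)
print(f"influential {len(parts['influential'])}, dormant {len(parts['dormant'])}")

ranking = table.ranking()
active = [int(r) for r in ranking.loc[~ranking.dormant, "reaction"].head(8)]
cfg = OptimizerConfig(n_samples=16, max_evaluations=300, convergence_fraction=1e-2, seed=1)
mech_opt, rep_opt, state = calibrate(mech, ranges, conds, active, cfg)
print(f"calibrated E = {rep_opt.E:.4g} after {state.n_evaluations} evaluations")
```

Output from this exact snippet:

```
initial E = 616.8; worst: [('BAX', 3595.9503766398198), ('BCL2_BAX', 62.68499292808832)]
influential 99, dormant 12
calibrated E = 1.479 after 300 evaluations
```

Reading: the shipped (uncalibrated) stand-in leaves the basal state —
BAX sits hundreds of σ outside its range because its production reaction is
orders of magnitude too fast, exactly the failure mode of the uncorrected
literature model.  The impact ranking pins that arm at the top, 12 stress
reactions are exactly dormant, and a short focusing search over the eight
highest-impact coefficients brings the model into the basal regime
(E ≈ 1.4, below the 2.31 reaction-free floor because relaxing dynamics pull
the profiles toward the range midpoints).

The numbered scripts under `analysis/` run these stages end to end and
write their tables (trajectories, per-species errors, impact ranking,
error trace, optimized parameters, posterior uncertainties) to `results/`.

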