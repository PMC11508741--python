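# Methods

## Model class

`basalcal` works on chemical reaction networks with uni- and bimolecular
mass-action kinetics.  A network is a list of species and a list of indexed
reactions; each reaction carries a single rate coefficient expressed as
log₁₀k together with a prior uncertainty half-width `f_prior` in decades.
The rate parameterization is the Arrhenius form k = A·Tⁿ·exp(−E/RT) with
n = E = 0 fixed, i.e. temperature-independent kinetics with A = 10^log10_k;
the log-scale parameterization is what the optimizer samples, so all orders
of magnitude of a ±4-decade band are covered evenly.

Units: concentrations are mol/cm³ internally (1 nM = 10⁻¹² mol/cm³), so
first-order coefficients in 1/s and second-order coefficients in
cm³/(mol·s) apply without conversion factors.  All user-facing tables are
in nM.  The single-cell context (volume 10⁻¹² L) only matters when curating
ranges from per-cell copy numbers.

Buffered species: protein synthesis and degradation are written through a
bookkeeping species REF ("REF → X", "X → REF").  REF is held at a fixed
activity of 1 mol/cm³ and carries no ODE, so the flux of a first-order
REF → X reaction numerically equals its k.  This is a convention, not a
physical concentration; the activity is configurable per species.  An empty
product side ("Y → 0") denotes pure degradation and is distinct from an
explicit REF sink.

## Ensemble protocol and error function

Initial conditions are drawn independently and uniformly within each
species' feasible basal interval [c_min, c_max]; complex species (and other
species flagged as starting empty) are forced to zero at t = 0.  Defaults:
N_cond = 20 conditions, 24 h horizon, hourly recording (N_tim = 25 grid
points including t = 0).  Species without curated ranges default to
0–100 nM.

The deviation error normalizes residuals by σ_s = (c_max − c_min)/8 around
the midpoint c̄_s, i.e. the interval is read as c̄ ± 4σ.  E is the RMS of
these normalized residuals over monitored species, conditions and times;
E_s restricts the average to one species, and E² = mean_s E_s² exactly.
All 25 grid points contribute, including the sampled initial values —
that choice makes the reaction-free limit exactly the RMS of U(−4, 4),
4/√3 ≈ 2.309, which the Monte-Carlo acceptance check reproduces.

Failed integrations are not dropped: every residual of a failed condition
is set to a large finite penalty (10¹²), which keeps N_cond stable and
gives the optimizer a finite, strongly unfavorable objective value.

## Numerics

The ODE right-hand side and its analytic Jacobian are assembled once per
mechanism (per-reaction reactant index slots plus a dense stoichiometry
matrix).  Reference integrations use LSODA with rtol 10⁻⁸ and atol
10⁻²⁰ mol/cm³ (≈10⁻⁸ nM); halving the tolerances moves 24 h endpoints by
less than 10⁻⁴ relative on the bundled fixtures.  Concentrations within
integration tolerance below zero are clamped to zero on output; larger
negative excursions mark the trajectory as failed rather than silently
clipped.

Inside the optimization loop the whole ensemble is integrated as one
block-diagonal system (BDF with a precomputed sparsity pattern, optionally
a numba-compiled right-hand side) at rtol 10⁻⁶: the conditions are
independent, so the stacked solution equals the per-condition one to
solver tolerance at a fraction of the overhead, and the objective only
needs ~3 correct digits of E.  Baseline and perturbed runs of the
sensitivity analysis always use the same path, which guarantees that a
reaction with zero flux under every condition has *exactly* zero
finite-difference sensitivity (the Newton iterations never couple an
identically-zero component into the others).

## Sensitivity, impact and classification

Local sensitivities use the one-sided +5% perturbation as printed:
S = (c(1.05k) − c(k)) / (σ_s ln 1.05), one extra ensemble per reaction.
The impact of reaction n on species s is the RMS of S over conditions and
times multiplied by σ_n, the standard deviation of ln k_n implied by the
prior: assuming ln k uniform on ±f_n·ln 10, σ_n = f_n·ln 10/√3.  With a
uniform f across reactions (the default f = 4) any monotone f→σ map leaves
the ranking unchanged.  Aggregation across monitored species is by
maximum — a reaction that matters to any monitored species is kept; the
aggregation rule is a package decision, as is treating each member of a
reversible pair as an independent parameter.

Classification: *dormant* means aggregate impact exactly zero (structurally
zero flux from every in-range initial state); *influential* means the
aggregate RMS sensitivity exceeds 0.01; the remainder is *negligible*.
The 0.01 threshold is low — on a 24 h horizon almost any reaction with
appreciable flux into a monitored species clears it.

## FOCTOPUS optimizer

A bounded focusing random search over the active log₁₀k vector.  State: a
center (incumbent best) and a scalar zoom z ∈ (0, 1] applied to all prior
half-widths, so the sampling volume is (prior volume)·z^d.  Each iteration
draws N samples (uniform by default, Gaussian with σ = radius/2 as an
option) within the current radii, clipped to the prior box; the first
iteration (and any zoomed-out iteration) samples the whole box.  On
improvement the center moves to the best sample and the volume is
multiplied by N (capped at the prior volume); otherwise it is divided by N.
Convergence: z below `convergence_fraction` (default 10⁻³) or the
evaluation budget.  Defaults N = 32, uniform sampling, 10⁴ evaluations.
The incumbent error is non-increasing by construction, and the zoom replay
satisfies volume = prior volume × N^(u−d) (capped) after u up- and d
down-moves.  Runs are bit-reproducible given the seed; the 20 sampled
conditions are frozen for the whole calibration, so the objective is
deterministic.

Multi-pass protocol: a coefficient within ε = 0.01 decades of a band edge
after a pass has effectively switched its reaction off (lower edge) or made
it consume its reactants instantly (upper edge); it is reset to its nominal
value and the optimization restarted.  An operator-supplied manual reset
list between passes covers coefficients that become ineffective without
reaching the edge (e.g. a consumer optimized "too fast"); pass records keep
the full error trace so the best pass can be selected afterwards.

## Posterior uncertainty

At the calibrated point the normalized residual vector r_{s,i,j} =
(c_sim − c̄_s)/σ_s is linearized in ln k over the active set (forward
differences with the sensitivity step ln 1.05), and

    Σ_post = (JᵀJ + Σ_prior⁻¹)⁻¹,   Σ_prior = diag(σ_n²),

a Gauss–Newton posterior with the ±f box mapped to its Gaussian equivalent
(the same f↔σ convention as the impact measure; the linearized form is a
reconstruction of the covariance formula the workflow is built around).
Per reaction the marginal standard deviation is converted back to a
uniform-equivalent half-width f_posterior = √3·σ_post(log₁₀k), reported
with the factor 10^f_posterior and binned by decade.  A parameter with a
zero Jacobian column (a dormant reaction) keeps its prior exactly.  Each
residual enters with unit weight, consistent with the minimized objective;
with thousands of residuals the resulting bands on well-identified
coefficients are narrow (hundredths of a decade).  Being curvature-based,
the estimate is local: it does not see distinct near-equivalent basins of
the error landscape, so it can understate the spread of parameters a
restarted search would return (see Limitations).

## Synthetic networks

**Recovery fixture** (11 species, 14 reactions).  Motifs: REF synthesis/
degradation anchoring X; a reversible binding pair A + B ⇌ AB; a catalytic
activation E + S → E + SA with first-order deactivation; the catalytic
production arm X → X + Y with first-order loss of Y (the pro-apoptotic
production motif — its runaway variant is the classic basal-state failure);
two dormant reactions consuming stress inputs absent from every basal
state.  True rates are chosen so the strong motifs relax to their range
midpoints within ~15 minutes: the hourly profiles are then dominated by the
encoded steady states, freezing or switching a reaction off is visibly
penalized, and the calibration problem has an essentially unique basin.
A and B additionally carry synthesis/degradation pairs at 10⁻⁹/s — present
but far below day-scale visibility, so the influential set is exactly the
eight strong reactions.  With `blow_up=True` the production rate is set to
1/s and Y leaves its range by orders of magnitude within the day.

**Full-size stand-in** (84 species, 113 reactions, 14 reversible pairs,
85 one-way reactions, 34 monitored species).  The 21 reactions whose
identities and published rate coefficients are known — the 19 most
strongly constrained ones plus the BAX production/degradation pair — keep
their indices and printed log₁₀k values.  Everything else is a synthetic
reconstruction labeled as such: synthesis/degradation anchors, binding
pairs, activation/deactivation cycles and a Ca²⁺ pump/leak balance whose
rate constants are solved so that fluxes cancel at the range midpoints,
plus 12 stress-pathway reactions consuming four absent inputs (ER stress,
genotoxic damage, starvation, tBid), which are dormant by construction.
The shipped nominal value of the BAX production rate is deliberately ~3
decades too fast, so the uncalibrated model leaves the basal state the way
the uncorrected literature model does (E in the hundreds, BAX thousands of
σ out of range), and calibration of the top-impact coefficients brings it
back to E ≈ 1.4.  The bundled ranges file uses the printed concentration
scales where available (cytoplasmic Ca²⁺ ~10² nM, ER Ca²⁺ in the μM range,
kinases above executioner proteins, BAX low ~30 nM) and the 0–100 nM
default elsewhere; it is a reconstruction, not the original curation.

What passing tests on these networks do and do not show: they verify the
pipeline's mechanics (simulation, error algebra, ranking, search,
uncertainty) under known ground truth and realistic scales; they do not
validate the biological mechanism itself, and real curated ranges are
heterogeneous in width and provenance in ways the synthetic ranges only
sketch.

## Problem sizes

Default analysis and test runs use the 20-condition ensemble throughout;
the reaction-free Monte-Carlo limit uses 2000 conditions; recovery tests
run the multi-pass search with a few hundred ensemble evaluations per pass
on the small fixture, and the stand-in calibration restricts the active set
to the eight highest-impact coefficients with a 300-evaluation budget —
enough to locate and fix the dominant misfit arm, which is the point of the
exercise at this scale.

## Limitations

- The optimizer is a global random search: with desk-scale budgets it
  reliably restores the basal error regime, but parameter point-recovery in
  sloppy or near-degenerate directions is not guaranteed, and the
  curvature-based posterior can be much narrower than the spread of
  restarted searches.  The midpoint-deviation objective also biases the
  argmin away from the generative truth (it rewards profiles flatter than
  the truth's transients), so truth-recovery within the Gauss–Newton bands
  on strongly identified coefficients should not be expected in general.
- Temperature dependence, compartments, events and stochastic kinetics are
  out of scope; molecularity is capped at 2.
- SBML import is not provided; the YAML dialect plus JSON export are the
  interchange formats.
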