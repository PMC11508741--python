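# Mechanism file format

A mechanism file is a YAML document with three top-level keys: `name`,
`species` and `reactions` (plus an optional free-text `notes`).  The format
is deliberately small: one entry per species, one entry per reaction, with
the reaction chemistry written as a plain equation string.

```yaml
name: mini
species:
  - id: REF
    role: buffered        # fixed activity, no ODE
    activity: 1.0         # mol/cm^3
  - id: BAX
    monitored: true
  - id: BCL2
    monitored: true
  - id: BCL2_BAX
    complex: true         # initial concentration forced to 0
    monitored: true
reactions:
  - index: 9
    equation: BCL2 + BAX -> BCL2_BAX
    log10_k: 6.54
    f_prior: 4.0
    reverse_of: 10
  - index: 10
    equation: BCL2_BAX -> BCL2 + BAX
    log10_k: -3.50
    f_prior: 4.0
    reverse_of: 9
  - index: 12
    equation: BAX -> 0    # pure degradation (empty product side)
    log10_k: -3.50
```

## Grammar

```
mechanism   ::= "name:" string  "species:" species*  "reactions:" reaction*
species     ::= "id:" token ["name:" string] ["role:" ("dynamic"|"buffered")]
                ["complex:" bool] ["monitored:" bool] ["activity:" number]
reaction    ::= "index:" integer  "equation:" equation
                "log10_k:" number ["f_prior:" number]
                ["log10_k0:" number] ["reverse_of:" integer]
equation    ::= side "->" side
side        ::= empty | term ("+" term)*
empty       ::= "0" | "∅" | "⌀"
term        ::= [integer] token          # optional stoichiometric coefficient
```

## Semantics and constraints

- **Units.** First-order `k` in 1/s; second-order `k` in cm³/(mol·s).
  Concentrations are mol/cm³ internally (1 nM = 10⁻¹² mol/cm³), so these
  rate units apply without conversion.  `log10_k` is the base-10 logarithm
  of `k`; `f_prior` is the half-width of the admissible band on the log10
  scale (default 4, i.e. ±4 orders of magnitude); `log10_k0` is the nominal
  value the band is centered on (defaults to `log10_k`).
- Species ids must be unique; every id in an equation must be declared.
- Total reactant stoichiometry (molecularity) is 1 or 2; the product side
  may be empty (`0`), denoting pure degradation — distinct from an explicit
  `X -> REF` sink through the buffered reference species.
- A `buffered` species has a fixed activity (default 1 mol/cm³) and no ODE;
  a first-order `REF -> X` flux therefore numerically equals its `k`.
  A buffered species cannot be a complex.
- `reverse_of` links the two halves of a reversible pair and must be
  symmetric; reaction indices must be unique (they need not be contiguous).
- Temperature dependence is not expressible: the rate parameterization is
  `k = A·T^n·exp(-E/RT)` with `n = E = 0` fixed, i.e. `A = 10^log10_k`.

`basalcal.mechanism.parse_mechanism` / `write_mechanism` round-trip this
format losslessly; `Mechanism.to_json` exports the same structure as JSON
for interop.

## Ranges CSV

Feasible basal intervals ship separately as CSV with header
`species_id,c_min_nM,c_max_nM,monitored,source_note`.  The error-function
normalizer is σ_s = (c_max − c_min)/8 and the midpoint c_mean =
(c_min + c_max)/2, so the interval reads c_mean ± 4σ_s.  Species missing
from the file default to 0–100 nM (unmonitored).
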