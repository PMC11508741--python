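"""Score the uncalibrated stand-in model against the basal ranges.

Computes the overall sigma-normalized RMS deviation E and the per-species
errors E_s, sorted worst-first (results/species_errors.csv).  A species
whose dynamics leave its feasible interval shows E_s far above the ~2.31
statistical floor of a reaction-free model.
"""

from basalcal.metrics import NO_REACTION_LIMIT
from basalcal.reporting import RunConfig, run_evaluate

if __name__ == "__main__":
    config = RunConfig(out_dir="results", seed=1)
    rep = run_evaluate(config)
    print(f"overall error E = {rep.E:.4g}  "
          f"({rep.n_spec} species x {rep.n_cond} conditions x {rep.n_tim} times)")
    print(f"reaction-free statistical floor: {NO_REACTION_LIMIT:.3f}")
    print("worst five species:")
    for sid, e in rep.sorted_species()[:5]:
        print(f"  {sid:10s} E_s = {e:.4g}")
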