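"""Pipeline stages, run configuration, and publication-style artifacts.

Each stage function takes a :class:`RunConfig`, executes one step of the
calibration workflow (sample/simulate, evaluate, sensitivity ranking,
multi-pass optimization, posterior uncertainty), writes its CSV/JSON
artifacts into the configured output directory and returns the in-memory
results.  A saved config re-executes to identical artifacts: every random
draw derives from the config seed through named substreams, so changing
optimizer settings does not alter the sampled condition set.

The numbered scripts under ``analysis/`` are thin drivers over these
functions.  Concentrations in user-facing tables are reported in nM.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .mechanism import Mechanism, parse_mechanism
from .metrics import ErrorReport, overall_error
from .optimize import OptimizerConfig, PassRecord, run_passes
from .posterior import PosteriorResult, posterior_covariance, uncertainty_bins
from .ranges import BasalRangeSet, read_ranges_csv, sample_initial_conditions
from .sensitivity import ImpactTable, classify_reactions, local_sensitivities, sue_impact
from .simulate import EnsembleTrajectories, hourly_grid, simulate_ensemble
from .units import MOLCM3_TO_NM

__all__ = [
    "RunConfig",
    "load_inputs",
    "run_simulate",
    "run_evaluate",
    "run_sensitivity",
    "run_optimize",
    "run_posterior",
    "run_report",
    "trajectories_to_frame",
]

#: substream labels hung off the root seed
_STREAMS = ("conditions", "optimizer")


@dataclass
class RunConfig:
    """Serializable description of one calibration run."""

    mechanism_path: str = ""
    ranges_path: str = ""
    out_dir: str = "results"
    seed: int = 0
    n_cond: int = 20
    horizon_h: float = 24.0
    step_h: float = 1.0
    sensitivity_factor: float = 1.05
    significance_threshold: float = 0.01
    n_passes: int = 1
    manual_resets: dict[int, list[int]] = field(default_factory=dict)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)

    def substream(self, name: str) -> np.random.Generator:
        """Independent generator for one purpose, derived from the root seed."""
        if name not in _STREAMS:
            raise KeyError(f"unknown stream {name!r}")
        child = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))[_STREAMS.index(name)]
        return np.random.default_rng(child)

    def grid(self) -> np.ndarray:
        return hourly_grid(self.horizon_h, self.step_h)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        opt = doc.pop("optimizer", {})
        doc["manual_resets"] = {int(k): list(v) for k, v in doc.get("manual_resets", {}).items()}
        return cls(optimizer=OptimizerConfig(**opt), **doc)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    import basalcal

    return {
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": __import__("scipy").__version__,
            "basalcal": getattr(basalcal, "__version__", "0"),
        },
    }


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_summary(config: RunConfig, stage: str, payload: dict) -> Path:
    out = _outdir(config) / f"{stage}_summary.json"
    doc = {"stage": stage, **payload, "provenance": _provenance(config)}
    out.write_text(json.dumps(doc, indent=1, sort_keys=True, default=float) + "\n")
    return out


def load_inputs(config: RunConfig) -> tuple[Mechanism, BasalRangeSet]:
    """Mechanism + ranges from the configured paths (or the bundled stand-in)."""
    if config.mechanism_path:
        mech = parse_mechanism(config.mechanism_path)
    else:
        from .synthetic import load_standin_model

        mech, ranges = load_standin_model()
        if not config.ranges_path:
            return mech, ranges
    ranges = read_ranges_csv(config.ranges_path)
    return mech, ranges


def sample_conditions(config: RunConfig, mech: Mechanism, ranges: BasalRangeSet) -> np.ndarray:
    return sample_initial_conditions(
        ranges, mech, config.n_cond, config.substream("conditions")
    )


def trajectories_to_frame(traj: EnsembleTrajectories) -> pd.DataFrame:
    """Tidy export: (condition_id, time_h, species, conc_nM)."""
    rows = []
    for i, t in enumerate(traj.trajectories):
        if not t.success:
            continue
        for j, sid in enumerate(t.species_ids):
            rows.append(
                pd.DataFrame(
                    {
                        "condition_id": i,
                        "time_h": t.time_grid / 3600.0,
                        "species": sid,
                        "conc_nM": t.conc[:, j] * MOLCM3_TO_NM,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def run_simulate(config: RunConfig) -> EnsembleTrajectories:
    """Sample the condition ensemble and integrate it over the day."""
    mech, ranges = load_inputs(config)
    conds = sample_conditions(config, mech, ranges)
    traj = simulate_ensemble(mech, conds, config.grid(), seed=config.seed)
    out = _outdir(config)
    trajectories_to_frame(traj).to_csv(out / "trajectories.csv", index=False)
    _write_summary(config, "simulate", {
        "n_cond": traj.n_cond,
        "n_time": len(traj.time_grid),
        "n_failed": sum(not t.success for t in traj.trajectories),
    })
    return traj


def run_evaluate(config: RunConfig) -> ErrorReport:
    """Basal deviation errors of the configured mechanism (report table layout)."""
    mech, ranges = load_inputs(config)
    conds = sample_conditions(config, mech, ranges)
    traj = simulate_ensemble(mech, conds, config.grid())
    rep = overall_error(traj, ranges)
    out = _outdir(config)
    rep.to_csv(out / "species_errors.csv")
    _write_summary(config, "evaluate", {
        "E": rep.E, "n_spec": rep.n_spec, "n_cond": rep.n_cond, "n_tim": rep.n_tim,
        "worst_species": rep.sorted_species()[0][0],
    })
    return rep


def run_sensitivity(config: RunConfig) -> tuple[ImpactTable, dict[str, list[int]]]:
    """+5% local sensitivities, SUE impact ranking and reaction classification."""
    mech, ranges = load_inputs(config)
    conds = sample_conditions(config, mech, ranges)
    sens = local_sensitivities(
        mech, conds, ranges, factor=config.sensitivity_factor, grid=config.grid()
    )
    f = {r.index: r.rate.f_prior for r in mech.reactions}
    table = sue_impact(sens, f, equations=[r.equation for r in mech.reactions])
    parts = classify_reactions(table, config.significance_threshold)
    out = _outdir(config)
    table.to_csv(out / "impact_ranking.csv")
    _write_summary(config, "sensitivity", {
        "n_influential": len(parts["influential"]),
        "n_dormant": len(parts["dormant"]),
        "n_negligible": len(parts["negligible"]),
        "dormant": sorted(parts["dormant"]),
    })
    return table, parts


def run_optimize(
    config: RunConfig, active: Sequence[int] | None = None
) -> list[PassRecord]:
    """Multi-pass FOCTOPUS calibration of the influential rate coefficients."""
    mech, ranges = load_inputs(config)
    conds = sample_conditions(config, mech, ranges)
    if active is None:
        _, parts = run_sensitivity(config)
        active = parts["influential"]
    opt_cfg = OptimizerConfig(**{**asdict(config.optimizer), "seed": config.optimizer.seed or config.seed})
    records = run_passes(
        mech, ranges, conds, active, opt_cfg, n_passes=config.n_passes,
        grid=config.grid(), manual_resets=config.manual_resets,
    )
    out = _outdir(config)
    trace = pd.concat(
        [
            pd.DataFrame(r.state.history, columns=["evaluation", "best_E", "zoom"]).assign(pass_index=r.pass_index)
            for r in records
        ],
        ignore_index=True,
    )
    trace.to_csv(out / "error_trace.csv", index=False)
    final = records[-1]
    table = pd.DataFrame(
        {
            "reaction": list(active),
            "equation": [final.mechanism.reaction_by_index(i).equation for i in active],
            "log10_k_ini": [final.mechanism.reaction_by_index(i).rate.log10_k0 for i in active],
            "f_prior": [final.mechanism.reaction_by_index(i).rate.f_prior for i in active],
            "log10_k_opt": [final.mechanism.reaction_by_index(i).rate.log10_k for i in active],
        }
    )
    table.to_csv(out / "optimized_parameters.csv", index=False, float_format="%.4f")
    final.report.to_csv(out / "species_errors_optimized.csv")
    _write_summary(config, "optimize", {
        "passes": [
            {
                "pass": r.pass_index,
                "E_start": r.state.history[0][1],
                "E_end": r.report.E,
                "evaluations": r.state.n_evaluations,
                "auto_reset": r.auto_reset,
                "manual_reset": r.manual_reset,
            }
            for r in records
        ],
        "E_final": final.report.E,
        "active": list(map(int, active)),
    })
    return records


def run_posterior(
    config: RunConfig, mech_opt: Mechanism, active: Sequence[int]
) -> PosteriorResult:
    """Posterior uncertainty of the calibrated coefficients (table layout)."""
    _, ranges = load_inputs(config)
    conds = sample_conditions(config, mech_opt, ranges)
    post = posterior_covariance(mech_opt, conds, ranges, active, grid=config.grid())
    out = _outdir(config)
    post.to_csv(out / "posterior_parameters.csv", mech_opt)
    _write_summary(config, "posterior", {
        "bins": uncertainty_bins(post),
        "n_active": len(active),
    })
    return post


def run_report(config: RunConfig) -> dict:
    """End-to-end summary: evaluate, rank, report headline numbers."""
    rep = run_evaluate(config)
    table, parts = run_sensitivity(config)
    payload = {
        "E_initial": rep.E,
        "species_errors": dict(rep.sorted_species()),
        "n_influential": len(parts["influential"]),
        "n_dormant": len(parts["dormant"]),
    }
    _write_summary(config, "report", payload)
    return payload
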