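"""End-to-end orchestration with validated configuration and run reports.

A run is described by a single YAML mapping (all angles in degrees, all
lengths in Angstrom, times in seconds, the Foerster radius included as 51 A)
and executes the requested stages in dependency order:

* ``synthetic-map``   - generate a toy hinge pivot-ensemble map (MRC)
* ``quantify``        - measure motion ranges on a map (generated or given)
* ``fret-simulate``   - generate two-state FRET traces (CSV)
* ``fret-analyze``    - correction factors, state fit and dwell analysis

Each stage appends a machine-readable summary (parameters with defaults
resolved, seed, outputs) to the run report; a failed stage records its error
and downstream stages that depend on it are skipped.  Identical config and
seed produce identical report values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .arc_quantifier import motion_range, motion_range_summary, motion_range_table
from .density_sim import read_mrc, write_mrc
from .errors import ConfigError
from .model_geometry import PivotFrame
from .smfret import (
    CorrectionFactors,
    analyze_traces,
    dwell_analysis,
    estimate_direct_excitation,
    estimate_donor_bleed,
    estimate_gamma_pooled,
    fit_states,
    read_traces,
    write_traces,
)
from .synthetic_data import (
    FretGroundTruth,
    HingeGroundTruth,
    make_pivot_map,
    make_toy_hinge_model,
    simulate_fret_traces,
    simulate_reference_traces,
    toy_subunit_config,
)

_STAGES = ("synthetic-map", "quantify", "fret-simulate", "fret-analyze")


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    stages: list
    outdir: str = "igmhinge-run"
    seed: int = 0
    synthetic_map: dict = field(default_factory=dict)
    quantify: dict = field(default_factory=dict)
    fret_simulate: dict = field(default_factory=dict)
    fret_analyze: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = [s for s in self.stages if s not in _STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; known: {list(_STAGES)}")
        if not self.stages:
            raise ConfigError("no stages requested")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        if "map" in data.get("quantify", {}):
            p = Path(data["quantify"]["map"])
            if not p.exists():
                raise ConfigError(f"quantify.map path {p} does not exist")
        if "traces" in data.get("fret_analyze", {}):
            p = Path(data["fret_analyze"]["traces"])
            if not p.exists():
                raise ConfigError(f"fret_analyze.traces path {p} does not exist")
        return cls.from_mapping(data)


def _dataclass_params(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        v = getattr(obj, f.name)
        if dataclasses.is_dataclass(v):
            v = _dataclass_params(v)
        elif isinstance(v, (np.ndarray, tuple)):
            v = [float(x) if isinstance(x, (int, float, np.floating)) else x
                 for x in v]
        out[f.name] = v
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute requested stages; return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed, "stages": {}}
    state = {}
    failed = set()

    def record(stage, status, **extra):
        report["stages"][stage] = {"status": status, **extra}

    for stage in _STAGES:
        if stage not in config.stages:
            continue
        deps = {"quantify": ["synthetic-map"] if "map" not in config.quantify
                else [],
                "fret-analyze": ["fret-simulate"]
                if "traces" not in config.fret_analyze else []}.get(stage, [])
        blocked = [d for d in deps if d in failed
                   or (d in config.stages) is False and d not in state]
        if any(d in failed for d in deps):
            record(stage, "skipped", reason=f"dependency failed: {deps}")
            continue
        try:
            if stage == "synthetic-map":
                truth = HingeGroundTruth(seed=config.seed,
                                         **config.synthetic_map)
                model, frame = make_toy_hinge_model(truth)
                density, _ = make_pivot_map(model, frame, truth)
                path = outdir / "pivot_ensemble.mrc"
                write_mrc(density, path)
                state["map"] = density
                state["frame"] = frame
                state["truth"] = truth
                record(stage, "ok", output=str(path),
                       parameters=_dataclass_params(truth))
            elif stage == "quantify":
                params = dict(config.quantify)
                if "map" in params:
                    density = read_mrc(params.pop("map"))
                    pivot = params.pop("pivot", [0.0, 0.0, 0.0])
                    frame = PivotFrame(pivot,
                                       params.pop("in_plane_zero", (1, 0, 0)),
                                       params.pop("plane_normal", (0, 0, 1)),
                                       params.pop("beta_sign", 1))
                    truth = HingeGroundTruth(
                        arm_length=params.pop("arm_length", 90.0))
                else:
                    density = state["map"]
                    frame = state["frame"]
                    truth = state["truth"]
                cfg = toy_subunit_config(truth, **params)
                ranges = motion_range(density, frame, cfg)
                table = motion_range_table(ranges)
                table.to_csv(outdir / "motion_ranges.csv", index=False)
                summary = motion_range_summary(ranges)
                if "truth" in state:
                    summary["ground_truth"] = {
                        "in_plane_range": state["truth"].in_plane_range,
                        "out_of_plane_range": state["truth"].out_of_plane_range,
                        "splay": state["truth"].splay}
                (outdir / "motion_ranges.json").write_text(
                    json.dumps(summary, indent=2))
                record(stage, "ok", output=str(outdir / "motion_ranges.csv"),
                       summary=summary, parameters=_dataclass_params(cfg))
            elif stage == "fret-simulate":
                truth = FretGroundTruth(seed=config.seed,
                                        **{k: v for k, v in
                                           config.fret_simulate.items()
                                           if k not in ("n_molecules",
                                                        "duration_s")})
                n_mol = config.fret_simulate.get("n_molecules", 100)
                dur = config.fret_simulate.get("duration_s", 10.0)
                sims = simulate_fret_traces(truth, n_mol, dur)
                traces = [s.trace for s in sims]
                write_traces(traces, outdir / "fret_traces.csv")
                state["traces"] = traces
                state["fret_truth"] = truth
                record(stage, "ok", output=str(outdir / "fret_traces.csv"),
                       n_molecules=n_mol,
                       parameters=_dataclass_params(truth))
            elif stage == "fret-analyze":
                params = dict(config.fret_analyze)
                if "traces" in params:
                    traces = read_traces(params.pop("traces"))
                else:
                    traces = state["traces"]
                if "factors" in params:
                    factors = CorrectionFactors(**params.pop("factors"))
                else:
                    truth = state.get("fret_truth", FretGroundTruth())
                    donor_only = simulate_reference_traces(truth, "donor-only")
                    acceptor_only = simulate_reference_traces(
                        truth, "acceptor-only")
                    factors = CorrectionFactors(
                        estimate_donor_bleed(donor_only),
                        estimate_direct_excitation(acceptor_only),
                        estimate_gamma_pooled(traces))
                fret_traces = analyze_traces(traces, factors)
                pooled = np.concatenate(
                    [t.valid_efficiencies for t in fret_traces])
                fit = fit_states(pooled, seed=config.seed)
                dwell = dwell_analysis(fret_traces, fit)
                summary = {
                    "factors": _dataclass_params(factors),
                    "n_molecules": len(fret_traces),
                    "n_frames_pooled": int(pooled.size),
                    "k_states": fit.k,
                    "state_means": [float(x) for x in fit.means],
                    "state_sds": [float(x) for x in fit.sds],
                    "state_weights": [float(x) for x in fit.weights],
                    "transitions_per_s": dwell.transitions_per_s,
                    "occupancy": [float(x) for x in dwell.occupancy],
                }
                (outdir / "fret_summary.json").write_text(
                    json.dumps(summary, indent=2))
                record(stage, "ok", output=str(outdir / "fret_summary.json"),
                       summary=summary)
        except Exception as exc:  # stage failure recorded, downstream skipped
            failed.add(stage)
            record(stage, "failed", error=f"{type(exc).__name__}: {exc}")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
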