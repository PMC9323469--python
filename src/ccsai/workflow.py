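"""Orchestration: run both thermodynamic-cycle legs for a molecule pair.

A :class:`RunConfig` describes one relative free energy calculation between
two fixture molecules sharing a common core: the matching criterion, the
alchemical schedules, the sampler settings per environment, and replicate
bookkeeping.  :func:`run_leg` takes one molecule through one environment
(vacuum-like cluster, or the LJ-bath stand-in for solution) and returns the
MBAR estimate for the leg; :func:`summarize` combines the four legs into
the relative free energy difference with replicate statistics.

Determinism contract: every sampling seed is derived from the base seed,
the replicate index, and the state index, and is recorded in the leg log,
so identical configs reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .common_core import (
    CommonCoreMap,
    MatchCriterion,
    XParams,
    find_common_core,
    insert_junction_particle,
)
from .fixtures import bath_coordinates, make_fixture, with_bath
from .free_energy import (
    FreeEnergyResult,
    CycleResult,
    ddg_from_cycle,
    overlap_matrix,
    reduced_potentials,
    select_frames,
    solve_mbar,
)
from .molecular_model import MolecularSystem, ValidationError
from .mutation_path import MutationPath, ScheduleConfig, plan_path
from .sampling import NonbondedOptions, SamplerConfig, Trajectory, sample

__all__ = ["RunConfig", "run_leg", "prepare_pair", "summarize", "run_pair"]

logger = logging.getLogger("ccsai.workflow")

ENVIRONMENTS = ("vacuum", "bath")


@dataclass
class RunConfig:
    label_a: str = "methane_like"
    label_b: str = "ethane_like"
    criterion: MatchCriterion = field(default_factory=MatchCriterion)
    schedule_a: ScheduleConfig = field(default_factory=ScheduleConfig)
    schedule_b: ScheduleConfig = field(default_factory=ScheduleConfig)
    sampler_vacuum: SamplerConfig = field(default_factory=lambda: SamplerConfig(
        algorithm="metropolis", n_steps=20000, save_interval=100))
    sampler_bath: SamplerConfig = field(default_factory=lambda: SamplerConfig(
        algorithm="metropolis", n_steps=20000, save_interval=100))
    nonbonded_vacuum: NonbondedOptions = field(
        default_factory=lambda: NonbondedOptions(method="none"))
    nonbonded_bath: NonbondedOptions = field(
        default_factory=lambda: NonbondedOptions(
            method="vswitch", r_on=5.0, r_off=7.0))
    x_params: XParams = field(default_factory=XParams)
    n_replicates: int = 5
    base_seed: int = 2026
    n_bath: int = 12
    discard_fraction: float = 0.25
    stride: int = 3
    output_dir: Optional[str] = None

    def schedule_for(self, molecule: str) -> ScheduleConfig:
        if molecule == self.label_a:
            return self.schedule_a
        if molecule == self.label_b:
            return self.schedule_b
        raise ValidationError(f"molecule {molecule!r} is not part of this run")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        plain = {f.name for f in dataclasses.fields(cls)}
        nested = {
            "criterion": MatchCriterion,
            "schedule_a": ScheduleConfig,
            "schedule_b": ScheduleConfig,
            "sampler_vacuum": SamplerConfig,
            "sampler_bath": SamplerConfig,
            "nonbonded_vacuum": NonbondedOptions,
            "nonbonded_bath": NonbondedOptions,
            "x_params": XParams,
        }
        for key, value in raw.items():
            if key not in plain:
                raise ValidationError(f"unknown config key {key!r}")
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def replicate_seed(base_seed: int, replicate: int, state_index: int) -> int:
    """Deterministic per-(replicate, state) sampling seed, < 2^31."""
    return (base_seed + 7919 * replicate + 104729 * state_index) % 2147483647


def prepare_pair(config: RunConfig):
    """Common-core discovery and path planning for both molecules."""
    a = make_fixture(config.label_a)
    b = make_fixture(config.label_b)
    ccmap = find_common_core(a, b, config.criterion)
    ccmap, _, _ = insert_junction_particle(ccmap, a, b, config.x_params)
    paths = {
        config.label_a: plan_path(a, ccmap, config.schedule_a),
        config.label_b: plan_path(b, ccmap, config.schedule_b),
    }
    return ccmap, paths


def _environment_systems(path: MutationPath, environment: str,
                         config: RunConfig, replicate: int):
    """Per-state systems for an environment (bath shell shared across states)."""
    if environment == "vacuum":
        return [st.system for st in path.states]
    if environment != "bath":
        raise ValidationError(f"unknown environment {environment!r}")
    solute = path.states[0].system
    extent = float(np.max(np.linalg.norm(solute.coordinates, axis=1)))
    radius = extent + 4.0
    coords = bath_coordinates(config.n_bath, radius,
                              seed=config.base_seed + replicate)
    return [with_bath(st.system, coords) for st in path.states]


def run_leg(config: RunConfig, molecule: str, environment: str,
            replicate: int = 0,
            path: Optional[MutationPath] = None) -> FreeEnergyResult:
    """Sample every state of one molecule's path in one environment and
    post-process with MBAR.  Fully reproducible from config + seed."""
    if path is None:
        _, paths = prepare_pair(config)
        path = paths[molecule]
    sampler = (config.sampler_vacuum if environment == "vacuum"
               else config.sampler_bath)
    opts = (config.nonbonded_vacuum if environment == "vacuum"
            else config.nonbonded_bath)
    systems = _environment_systems(path, environment, config, replicate)

    log_records = []
    trajectories: List[Trajectory] = []
    for st, system in zip(path.states, systems):
        seed = replicate_seed(config.base_seed, replicate, st.state_index)
        cfg = replace(sampler, seed=seed)
        try:
            traj = sample(system, cfg, opts, minimize_first=True)
        except Exception as exc:
            raise RuntimeError(
                f"sampling failed at state {st.state_index} "
                f"({molecule}, {environment}): {exc}"
            ) from exc
        keep = select_frames(traj.n_frames, config.discard_fraction,
                             config.stride)
        trajectories.append(Trajectory(frames=traj.frames[keep],
                                       state_index=st.state_index,
                                       config=cfg))
        log_records.append({
            "state_index": st.state_index,
            "stage": st.stage,
            "seed": seed,
            "frames_kept": int(keep.size),
        })
        logger.info("sampled %s/%s state %d (%s), seed %d, %d frames kept",
                    molecule, environment, st.state_index, st.stage, seed,
                    keep.size)

    matrix = reduced_potentials(trajectories, systems, opts,
                                sampler.temperature)
    result = solve_mbar(matrix)
    overlap = overlap_matrix(matrix, result)
    min_overlap = float(min(
        overlap[k, k + 1] for k in range(matrix.n_states - 1)
    )) if matrix.n_states > 1 else 1.0

    if config.output_dir:
        leg_dir = os.path.join(config.output_dir, molecule, environment)
        os.makedirs(leg_dir, exist_ok=True)
        with open(os.path.join(leg_dir, f"replicate_{replicate}.json"), "w") as fh:
            json.dump({
                "molecule": molecule,
                "environment": environment,
                "replicate": replicate,
                "states": log_records,
                "f_k": result.f_k.tolist(),
                "se_f_k": result.uncertainties[0, :].tolist(),
                "min_nearest_neighbour_overlap": min_overlap,
                "temperature": sampler.temperature,
            }, fh, indent=2)
    return result


def summarize(results: Dict[str, Dict[str, Sequence[FreeEnergyResult]]],
              label_a: str, label_b: str) -> pd.DataFrame:
    """Replicate statistics per leg, then the cycle-assembled ddG table.

    ``results[molecule][environment]`` holds one FreeEnergyResult per
    replicate.  Raises a :class:`ValidationError` naming any missing leg.
    """
    stats = {}
    for molecule in (label_a, label_b):
        for env in ENVIRONMENTS:
            try:
                reps = results[molecule][env]
            except KeyError:
                raise ValidationError(
                    f"missing leg: {molecule}/{env}") from None
            if not reps:
                raise ValidationError(f"missing leg: {molecule}/{env}")
            dgs = np.array([r.delta_g_kcal() for r in reps])
            sd = float(np.std(dgs, ddof=1)) if len(dgs) > 1 else 0.0
            stats[(molecule, env)] = (float(np.mean(dgs)), sd)

    cycle = ddg_from_cycle(
        stats[(label_a, "vacuum")], stats[(label_a, "bath")],
        stats[(label_b, "vacuum")], stats[(label_b, "bath")])
    rows = [{
        "pair": f"{label_a}->{label_b}",
        "ddg_kcal_mol": cycle.ddg,
        "sd_kcal_mol": cycle.sd,
        "dg_vac_a": stats[(label_a, "vacuum")][0],
        "sd_vac_a": stats[(label_a, "vacuum")][1],
        "dg_solv_a": stats[(label_a, "bath")][0],
        "sd_solv_a": stats[(label_a, "bath")][1],
        "dg_vac_b": stats[(label_b, "vacuum")][0],
        "sd_vac_b": stats[(label_b, "vacuum")][1],
        "dg_solv_b": stats[(label_b, "bath")][0],
        "sd_solv_b": stats[(label_b, "bath")][1],
    }]
    return pd.DataFrame(rows)


def run_pair(config: RunConfig) -> pd.DataFrame:
    """Run all four legs across replicates and emit the ddG table."""
    _, paths = prepare_pair(config)
    results: Dict[str, Dict[str, list]] = {
        m: {e: [] for e in ENVIRONMENTS} for m in paths
    }
    for molecule, path in paths.items():
        for env in ENVIRONMENTS:
            for rep in range(config.n_replicates):
                results[molecule][env].append(
                    run_leg(config, molecule, env, rep, path=path))
    table = summarize(results, config.label_a, config.label_b)
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        table.to_csv(os.path.join(config.output_dir, "ddg_summary.tsv"),
                     sep="\t", index=False)
    return table
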