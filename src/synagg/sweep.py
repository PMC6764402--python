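"""Doped-fraction sweep: the kinetics experiment behind the crossover plot.

For each doped fraction phi a set of independent replicas (fresh build
and noise seeds) is simulated, cluster kinetics are extracted per
frame, replicas are averaged, and the final aggregate sizes versus phi
are summarised with the 3x crossover rule.  The default desk preset
(128 chains, 2e5 steps) keeps a full sweep within interactive reach;
the production preset mirrors the 512-chain system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aggregation import (
    DEFAULT_CUTOFF,
    DEFAULT_MIN_CONTACTS,
    KineticsSeries,
    PhiSweepSummary,
    kinetics_series,
    phi_sweep_summary,
    replica_average,
)
from .cg_model import ForceFieldParams, SystemState, build_system, default_box_length
from .dynamics import IntegratorParams, Trajectory, run_simulation

DEFAULT_PHI_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass
class SweepResult:
    """Everything a sweep produced: averaged kinetics, end states, summary."""

    series: dict[float, KineticsSeries]
    replica_series: dict[float, list[KineticsSeries]]
    end_states: dict[float, list[SystemState]]
    summary: PhiSweepSummary
    n_monomers: int
    seeds: tuple[int, ...]


def run_phi_sweep(
    phis: tuple[float, ...] = DEFAULT_PHI_GRID,
    n_monomers: int = 128,
    seeds: tuple[int, ...] = (1, 2, 3),
    n_steps: int = 200_000,
    ff: ForceFieldParams | None = None,
    temperature: float = 0.6,
    dt: float = 0.005,
    friction: float = 1.0,
    report_interval: int = 2000,
    cutoff: float = DEFAULT_CUTOFF,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
    weighting: str = "number",
    crossover_factor: float = 3.0,
    box_length: float | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run the full phi sweep with replica averaging.

    Each (phi, seed) pair is an independent run: the seed controls both
    the initial packing/doping assignment and the Langevin noise stream.
    Identical seeds across phi values give paired initial packings,
    which sharpens the phi comparison.
    """
    if ff is None:
        ff = ForceFieldParams()
    if box_length is None:
        box_length = default_box_length(n_monomers)
    series: dict[float, KineticsSeries] = {}
    replicas: dict[float, list[KineticsSeries]] = {}
    ends: dict[float, list[SystemState]] = {}
    for phi in phis:
        reps = []
        end_frames = []
        for seed in seeds:
            state = build_system(
                n_monomers, phi, box_length, seed=seed, temperature=temperature
            )
            ip = IntegratorParams(
                dt=dt,
                temperature=temperature,
                friction=friction,
                n_steps=n_steps,
                report_interval=report_interval,
                rng_seed=seed,
            )
            traj = run_simulation(state, ff, ip)
            reps.append(kinetics_series(traj, cutoff, min_contacts, weighting))
            end_frames.append(traj.frame(traj.n_frames - 1))
            if progress:
                print(
                    f"phi={phi:.2f} seed={seed}: final n_mol="
                    f"{reps[-1].n_mol[-1]:.2f} largest={reps[-1].largest_cluster[-1]}",
                    flush=True,
                )
        replicas[phi] = reps
        series[phi] = replica_average(reps)
        ends[phi] = end_frames
    summary = phi_sweep_summary(series, factor=crossover_factor)
    return SweepResult(
        series=series,
        replica_series=replicas,
        end_states=ends,
        summary=summary,
        n_monomers=n_monomers,
        seeds=tuple(seeds),
    )
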