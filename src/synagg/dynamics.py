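"""Langevin (BAOAB) propagation of the bead-spring system.

The integrator splits the update as B-A-O-A-B: half-kick, half-drift,
Ornstein-Uhlenbeck velocity refresh, half-drift, half-kick.  With zero
friction the O-step is the identity and the scheme is exactly velocity
Verlet, which is what the energy-conservation tests exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .cg_model import ForceFieldParams, SystemState

#: desk-scale and production presets: (n_monomers, n_steps)
PRESETS = {"desk": (128, 200_000), "paper": (512, 2_000_000)}


@dataclass(frozen=True)
class IntegratorParams:
    """Reduced-unit integrator settings.

    ``temperature`` is k_B T in units of epsilon; ``friction`` in 1/tau.
    The defaults (dt = 0.005 tau, gamma = 1/tau, k_B T = 0.6 epsilon) put
    the hydrophobic attraction well above thermal energy so that the
    undoped system fibrillates slowly.
    """

    dt: float = 0.005
    temperature: float = 0.6
    friction: float = 1.0
    n_steps: int = 200_000
    report_interval: int = 2000
    rng_seed: int = 0
    neighbor_skin: float = 0.6

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0 or self.friction < 0:
            raise ValueError("temperature and friction must be non-negative")
        if self.n_steps < 0 or self.report_interval <= 0:
            raise ValueError("invalid step counts")
        if self.neighbor_skin <= 0:
            raise ValueError("neighbor_skin must be positive")


@dataclass
class Trajectory:
    """Frames of one run plus scalar logs and provenance.

    ``positions`` has shape (n_frames, n_beads, 3); bead metadata is
    constant across frames and stored once.
    """

    times: np.ndarray
    positions: np.ndarray
    bead_types: np.ndarray
    monomer_id: np.ndarray
    box_length: float
    n_monomers: int
    phi_nominal: float = 0.0
    potential_energy: np.ndarray | None = None
    kinetic_temperature: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, index: int) -> SystemState:
        """Materialise one frame as a SystemState (zero velocities)."""
        pos = self.positions[index]
        return SystemState(
            coordinates=pos.copy(),
            velocities=np.zeros_like(pos),
            bead_types=self.bead_types.copy(),
            monomer_id=self.monomer_id.copy(),
            box_length=self.box_length,
            n_monomers=self.n_monomers,
            phi_nominal=self.phi_nominal,
            time=float(self.times[index]),
        )


def _ff_args(state: SystemState, ff: ForceFieldParams):
    return (
        state.box_length,
        state.hydrophobic_mask().astype(np.int8),
        ff.epsilon,
        ff.sigma,
        ff.lj_cutoff,
        ff.lj_shift,
        ff.bond_k,
        ff.bond_r0,
        ff.angle_k,
        ff.angle_theta0,
    )


def langevin_step(
    state: SystemState,
    ff: ForceFieldParams,
    ip: IntegratorParams,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
) -> tuple[SystemState, np.ndarray]:
    """One BAOAB step; returns the new state and the forces at its end.

    Passing the returned forces back in avoids recomputing them at the
    start of the next step.  Deterministic for a given rng state.
    """
    out = state.copy()
    pos, vel = out.coordinates, out.velocities
    args = _ff_args(out, ff)
    if forces is None:
        forces = np.zeros_like(pos)
        _, _ = _kernels.compute_forces(pos, forces, *args)
    half = 0.5 * ip.dt
    vel += half * forces
    pos += half * vel
    if ip.friction > 0.0:
        c1 = math.exp(-ip.friction * ip.dt)
        c2 = math.sqrt((1.0 - c1 * c1) * ip.temperature)
        vel *= c1
        if c2 > 0.0:
            vel += c2 * rng.standard_normal(vel.shape)
    pos += half * vel
    np.mod(pos, out.box_length, out=pos)
    new_forces = np.zeros_like(pos)
    energy, _ = _kernels.compute_forces(pos, new_forces, *args)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite energy after integration step")
    vel += half * new_forces
    out.time = state.time + ip.dt
    return out, new_forces


def run_simulation(
    state: SystemState,
    ff: ForceFieldParams | None = None,
    ip: IntegratorParams | None = None,
) -> Trajectory:
    """Propagate ``state`` and collect frames every ``report_interval`` steps.

    The t = 0 configuration is always the first frame.  The kernel-side
    RNG is seeded from ``ip.rng_seed`` so equal inputs give bit-identical
    trajectories.  Instantaneous kinetic temperature and potential energy
    are logged at every frame.
    """
    if ff is None:
        ff = ForceFieldParams()
    if ip is None:
        ip = IntegratorParams()
    work = state.wrapped()
    pos, vel = work.coordinates, work.velocities
    # the production kernel keeps coordinates unwrapped so bonded terms
    # and listed pairs need no per-step minimum-image arithmetic
    _kernels.unwrap_chains(pos, work.box_length)
    args = _ff_args(work, ff)
    rng_state = _kernels.seed_state(int(ip.rng_seed))

    n_chunks = ip.n_steps // ip.report_interval
    remainder = ip.n_steps - n_chunks * ip.report_interval
    n_frames = n_chunks + (1 if remainder else 0) + 1
    n_dof = 3 * work.n_beads

    times = np.empty(n_frames)
    positions = np.empty((n_frames, work.n_beads, 3))
    epot = np.empty(n_frames)
    ktemp = np.empty(n_frames)

    forces0 = np.zeros_like(pos)
    e0, _ = _kernels.compute_forces(pos, forces0, *args)
    times[0] = state.time
    positions[0] = np.mod(pos, work.box_length)
    epot[0] = e0
    ktemp[0] = np.sum(vel * vel) / n_dof

    frame = 1
    steps_done = 0
    chunks = [ip.report_interval] * n_chunks + ([remainder] if remainder else [])
    for nsteps in chunks:
        energy, kinetic = _kernels.run_baoab(
            pos, vel, *args, ip.dt, ip.friction, ip.temperature, nsteps,
            rng_state, ip.neighbor_skin,
        )
        steps_done += nsteps
        times[frame] = state.time + steps_done * ip.dt
        positions[frame] = np.mod(pos, work.box_length)
        epot[frame] = energy
        ktemp[frame] = 2.0 * kinetic / n_dof
        frame += 1

    return Trajectory(
        times=times,
        positions=positions,
        bead_types=work.bead_types.copy(),
        monomer_id=work.monomer_id.copy(),
        box_length=work.box_length,
        n_monomers=work.n_monomers,
        phi_nominal=work.phi_nominal,
        potential_energy=epot,
        kinetic_temperature=ktemp,
        provenance={
            "rng_seed": int(ip.rng_seed),
            "dt": ip.dt,
            "friction": ip.friction,
            "temperature": ip.temperature,
            "n_steps": ip.n_steps,
            "report_interval": ip.report_interval,
        },
    )


def brute_force_forces(state: SystemState, ff: ForceFieldParams) -> np.ndarray:
    """All-pairs reference forces (the oracle for the cell-list path)."""
    pos = np.mod(state.coordinates, state.box_length)
    forces = np.zeros_like(pos)
    _kernels.compute_forces_allpairs(pos, forces, *_ff_args(state, ff))
    return forces


def cell_list_forces(state: SystemState, ff: ForceFieldParams) -> np.ndarray:
    """Forces through the production cell-list path."""
    pos = np.mod(state.coordinates, state.box_length)
    forces = np.zeros_like(pos)
    _kernels.compute_forces(pos, forces, *_ff_args(state, ff))
    return forces
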