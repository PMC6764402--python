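"""Coarse-grained bead-spring model of amphiphilic alpha-synuclein monomers.

Each monomer is a linear chain of 15 beads in three 5-bead blocks:
hydrophilic N-terminal block, hydrophobic central block (the NAC domain,
the engine of amyloid stacking), hydrophilic C-terminal block.  An
"FKBP12-doped" monomer carries a hydrophobic SEED bead in place of the
last C-terminal bead, mimicking the exposed beta-strand of a bound
FKBP12.  The solvent is implicit: hydrophobic bead pairs attract through
a truncated-and-shifted 12-6 Lennard-Jones potential, every pair
involving a hydrophilic bead is purely repulsive (WCA), which is the
standard renormalised-interaction picture of aggregation in water.

Reduced Lennard-Jones units throughout: epsilon = sigma = mass = 1,
time unit tau = sigma * sqrt(m / epsilon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

# Bead type codes (integer encoding used by the numeric kernels).
PHILIC = 0
PHOBIC = 1
SEED = 2

BEAD_LABELS = {PHILIC: "PHILIC", PHOBIC: "PHOBIC", SEED: "SEED"}
BEAD_CODES = {v: k for k, v in BEAD_LABELS.items()}
# One-letter species names used in extended-XYZ dumps.
BEAD_SPECIES = {PHILIC: "P", PHOBIC: "H", SEED: "S"}
SPECIES_CODES = {v: k for k, v in BEAD_SPECIES.items()}

N_BEADS_PER_MONOMER = 15
_HYDROPHOBIC_SLICE = slice(5, 10)


def is_hydrophobic(code: int | np.ndarray) -> bool | np.ndarray:
    """PHOBIC and SEED beads share the attractive interaction class."""
    return (np.asarray(code) == PHOBIC) | (np.asarray(code) == SEED)


@dataclass(frozen=True)
class MonomerTopology:
    """The 15-bead chain blueprint: bead types, bonds, angles."""

    bead_types: tuple[int, ...]
    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    doped: bool

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(BEAD_LABELS[t] for t in self.bead_types)


def build_monomer_topology(doped: bool = False) -> MonomerTopology:
    """Build the 15-bead monomer: [PHILIC x5, PHOBIC x5, PHILIC x5].

    The doped variant replaces the final C-terminal bead (position 15)
    with a SEED bead; FKBP12 binds a proline in the hydrophilic
    C-terminus, so the sticky patch sits at the chain end.
    """
    types = [PHILIC] * 5 + [PHOBIC] * 5 + [PHILIC] * 5
    if doped:
        types[-1] = SEED
    n = N_BEADS_PER_MONOMER
    bonds = tuple((i, i + 1) for i in range(n - 1))
    angles = tuple((i, i + 1, i + 2) for i in range(n - 2))
    return MonomerTopology(tuple(types), bonds, angles, bool(doped))


@dataclass(frozen=True)
class ForceFieldParams:
    """Reduced-unit force-field parameters.

    Attractive (hydrophobic-hydrophobic) pairs use 12-6 Lennard-Jones
    truncated at ``lj_cutoff`` (shifted to zero there when
    ``energy_shift``); any pair involving a PHILIC bead uses the WCA
    potential (LJ truncated and shifted at its minimum 2^(1/6) sigma).
    Bonds and angles are harmonic; the straight rest angle (pi) makes
    the chain semiflexible.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    lj_cutoff: float = 2.5
    bond_k: float = 500.0
    bond_r0: float = 1.0
    angle_k: float = 2.0
    angle_theta0: float = math.pi
    energy_shift: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.bond_k < 0 or self.angle_k < 0:
            raise ValueError("stiffnesses must be non-negative")
        if self.bond_r0 <= 0:
            raise ValueError("bond_r0 must be positive")
        if self.lj_cutoff <= self.wca_cutoff:
            raise ValueError("lj_cutoff must exceed the WCA cutoff 2^(1/6) sigma")

    @property
    def wca_cutoff(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma

    @property
    def lj_shift(self) -> float:
        """Energy at the LJ cutoff, subtracted when energy_shift is on."""
        if not self.energy_shift:
            return 0.0
        sr6 = (self.sigma / self.lj_cutoff) ** 6
        return 4.0 * self.epsilon * sr6 * (sr6 - 1.0)


@dataclass
class SystemState:
    """Bead coordinates/velocities plus static system metadata.

    Coordinates are wrapped into the primary cubic periodic box
    ``[0, box_length)``.  Beads of monomer ``m`` occupy the contiguous
    index run ``15*m .. 15*m+14``.
    """

    coordinates: np.ndarray
    velocities: np.ndarray
    bead_types: np.ndarray
    monomer_id: np.ndarray
    box_length: float
    n_monomers: int
    phi_nominal: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.ascontiguousarray(self.coordinates, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.bead_types = np.ascontiguousarray(self.bead_types, dtype=np.int8)
        self.monomer_id = np.ascontiguousarray(self.monomer_id, dtype=np.int64)
        n = self.n_monomers * N_BEADS_PER_MONOMER
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"expected {n} beads x 3 coordinates, got {self.coordinates.shape}"
            )
        if self.velocities.shape != (n, 3):
            raise ValueError("velocities shape mismatch")
        if self.bead_types.shape != (n,) or self.monomer_id.shape != (n,):
            raise ValueError("per-bead arrays must have one entry per bead")

    @property
    def n_beads(self) -> int:
        return self.n_monomers * N_BEADS_PER_MONOMER

    @property
    def doped_mask(self) -> np.ndarray:
        """Boolean per-monomer mask: True where the terminal bead is SEED."""
        return self.bead_types.reshape(self.n_monomers, N_BEADS_PER_MONOMER)[:, -1] == SEED

    @property
    def n_doped(self) -> int:
        return int(self.doped_mask.sum())

    def hydrophobic_mask(self) -> np.ndarray:
        return np.asarray(is_hydrophobic(self.bead_types))

    def wrapped(self) -> "SystemState":
        """Return a copy with coordinates wrapped into the primary box."""
        out = self.copy()
        out.coordinates = np.mod(out.coordinates, self.box_length)
        return out

    def copy(self) -> "SystemState":
        return SystemState(
            self.coordinates.copy(),
            self.velocities.copy(),
            self.bead_types.copy(),
            self.monomer_id.copy(),
            self.box_length,
            self.n_monomers,
            self.phi_nominal,
            self.time,
        )


def doped_count(phi: float, n_monomers: int) -> int:
    """Number of doped monomers: round-half-away-from-zero of phi * N."""
    x = phi * n_monomers
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pair_potential(
    type_i: int | str,
    type_j: int | str,
    r: float,
    ff: ForceFieldParams | None = None,
) -> float:
    """Non-bonded pair energy at separation ``r``.

    Hydrophobic pairs (PHOBIC/SEED with PHOBIC/SEED): truncated(-shifted)
    12-6 LJ; anything touching a PHILIC bead: WCA.  Symmetric in (i, j).
    """
    if ff is None:
        ff = ForceFieldParams()
    if r <= 0:
        raise ValueError("pair separation must be positive")
    ti = BEAD_CODES[type_i] if isinstance(type_i, str) else int(type_i)
    tj = BEAD_CODES[type_j] if isinstance(type_j, str) else int(type_j)
    attractive = bool(is_hydrophobic(ti)) and bool(is_hydrophobic(tj))
    cutoff = ff.lj_cutoff if attractive else ff.wca_cutoff
    if r >= cutoff:
        return 0.0
    sr6 = (ff.sigma / r) ** 6
    u = 4.0 * ff.epsilon * sr6 * (sr6 - 1.0)
    if attractive:
        return u - ff.lj_shift
    return u + ff.epsilon  # WCA: shifted to zero at its minimum


def total_energy_forces(
    state: SystemState, ff: ForceFieldParams | None = None
) -> tuple[float, np.ndarray, bool]:
    """Total potential energy and per-bead forces under minimum image.

    1-2 bonded pairs are excluded from the non-bonded sum; 1-3 pairs are
    kept (the angle term dominates them).  Returns ``(energy, forces,
    overlap)`` where ``overlap`` flags any pair closer than 0.3 sigma —
    the energy is still returned finite.
    """
    from ._kernels import compute_forces

    if ff is None:
        ff = ForceFieldParams()
    pos = np.mod(state.coordinates, state.box_length)
    forces = np.zeros_like(pos)
    energy, min_r = compute_forces(
        pos,
        forces,
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
    overlap = min_r < 0.3 * ff.sigma
    return float(energy), forces, bool(overlap)


def build_system(
    n_monomers: int,
    phi: float,
    box_length: float,
    seed: int,
    temperature: float = 0.6,
    min_separation: float = 0.9,
    max_attempts: int = 100_000,
) -> SystemState:
    """Place ``n_monomers`` straight chains at random, without overlaps.

    Chains are inserted as straight rods with random centre and
    orientation (the rod is the minimum of both the bond and the angle
    terms).  ``round(phi * n)`` monomers, chosen uniformly at random,
    are doped.  Velocities are Maxwell-distributed at ``temperature``
    with the centre-of-mass drift removed.
    """
    from scipy.spatial import cKDTree

    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    # a straight chain spans 14 sigma; anything tighter self-overlaps
    # through the periodic boundary at insertion time
    if box_length < 15.0:
        raise ValueError(
            f"box_length {box_length} too small: a straight 15-bead chain "
            "needs at least 15 sigma of periodic box"
        )
    rng = np.random.default_rng(seed)
    n_beads = n_monomers * N_BEADS_PER_MONOMER
    offsets = np.arange(N_BEADS_PER_MONOMER) - (N_BEADS_PER_MONOMER - 1) / 2.0

    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    attempts = 0
    for _ in range(n_monomers):
        while True:
            attempts += 1
            if attempts > max_attempts:
                density = n_beads / box_length**3
                raise RuntimeError(
                    f"failed to pack {n_monomers} monomers in L={box_length} "
                    f"(bead number density {density:.4f}/sigma^3) "
                    f"within {max_attempts} placement attempts"
                )
            centre = rng.uniform(0.0, box_length, size=3)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            beads = np.mod(centre + offsets[:, None] * axis, box_length)
            if tree is not None:
                dist, _ = tree.query(beads, k=1)
                if np.min(dist) < min_separation:
                    continue
            placed.append(beads)
            flat = np.concatenate(placed)
            tree = cKDTree(np.mod(flat, box_length), boxsize=box_length)
            break

    coords = np.concatenate(placed)
    bead_types = np.tile(
        np.array([PHILIC] * 5 + [PHOBIC] * 5 + [PHILIC] * 5, dtype=np.int8),
        n_monomers,
    )
    n_doped = doped_count(phi, n_monomers)
    doped_ids = rng.choice(n_monomers, size=n_doped, replace=False)
    for m in doped_ids:
        bead_types[m * N_BEADS_PER_MONOMER + N_BEADS_PER_MONOMER - 1] = SEED

    velocities = rng.normal(0.0, math.sqrt(max(temperature, 0.0)), size=(n_beads, 3))
    if n_beads > 1:
        velocities -= velocities.mean(axis=0)
    monomer_id = np.repeat(np.arange(n_monomers), N_BEADS_PER_MONOMER)
    return SystemState(
        coordinates=coords,
        velocities=velocities,
        bead_types=bead_types,
        monomer_id=monomer_id,
        box_length=float(box_length),
        n_monomers=n_monomers,
        phi_nominal=float(phi),
        time=0.0,
    )


def default_box_length(n_monomers: int, reference_box: float = 60.0) -> float:
    """Box length keeping the default dilute density of 512 chains in L=60."""
    return reference_box * (n_monomers / 512.0) ** (1.0 / 3.0)
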