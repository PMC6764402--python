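"""Synthetic inputs with known ground truth.

Two families of fixtures drive validation:

* ThT-like fluorescence curves generated from the same sigmoid(-decay)
  model the fitting code assumes, with stated parameters and seeded
  Gaussian noise — parameter-recovery tests are exact round trips.
* Idealised aggregate geometries (linear stack, branched tree, globule,
  dispersed gas) assembled from the standard 15-bead monomer at the
  force-field bead spacing, so clustering and morphology parameters
  transfer unchanged and every metric has a known expected value.

Every stochastic generator takes a mandatory seed and is bit
reproducible.  The three-condition ThT dataset is an illustrative
emulation of the experimental phenomenology (pure protein slowest;
equimolar FKBP12 faster, larger, overshooting; inhibited intermediate);
none of its parameters is read off any measurement.
"""

from __future__ import annotations

import math

import numpy as np

from .cg_model import (
    N_BEADS_PER_MONOMER,
    PHILIC,
    PHOBIC,
    SEED,
    SystemState,
)
from .tht import ThTSeries, sigmoid_decay_model, sigmoid_model

AGGREGATE_KINDS = ("linear_stack", "branched_tree", "globule", "dispersed")

#: illustrative truth parameters for the three-condition ThT dataset
FIGURE2_LIKE_TRUTH = {
    "alpha_syn": dict(f0=0.10, amplitude=1.00, rate=0.55, t_half=12.0,
                      decay_fraction=0.0, decay_tau=math.inf),
    "alpha_syn_fkbp12": dict(f0=0.10, amplitude=1.80, rate=1.10, t_half=6.0,
                             decay_fraction=0.30, decay_tau=6.0),
    "alpha_syn_fkbp12_elten378": dict(f0=0.10, amplitude=1.30, rate=0.90,
                                      t_half=8.0, decay_fraction=0.25,
                                      decay_tau=7.0),
}


def generate_tht_curve(
    truth: dict,
    n_points: int = 50,
    t_max: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> ThTSeries:
    """Evaluate the sigmoid(-decay) model on a uniform grid plus noise.

    ``truth`` carries f0, amplitude, rate, t_half and optionally
    decay_fraction/decay_tau; it is recorded on the returned series.
    """
    if n_points < 6:
        raise ValueError("need at least 6 points")
    t = np.linspace(0.0, t_max, n_points)
    d = truth.get("decay_fraction", 0.0)
    if d > 0:
        y = sigmoid_decay_model(
            t, truth["f0"], truth["amplitude"], truth["rate"], truth["t_half"],
            d, truth.get("decay_tau", math.inf),
        )
    else:
        y = sigmoid_model(
            t, truth["f0"], truth["amplitude"], truth["rate"], truth["t_half"]
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return ThTSeries(times=t, intensities=y, label=label, truth=dict(truth))


def generate_figure2_like_dataset(
    seed: int,
    n_points: int = 40,
    t_max: float = 20.0,
    noise_sd: float = 0.02,
) -> list[ThTSeries]:
    """Three-condition ThT emulation with documented truth parameters.

    Ordering built into the truth table: the equimolar FKBP12 condition
    has a smaller t_half and larger amplitude than the pure-protein
    condition; the inhibited condition is intermediate, with decay.
    """
    out = []
    for idx, (label, truth) in enumerate(FIGURE2_LIKE_TRUTH.items()):
        out.append(
            generate_tht_curve(
                truth, n_points=n_points, t_max=t_max,
                noise_sd=noise_sd, seed=seed + idx, label=label,
            )
        )
    return out


def _monomer_beads(
    centre: np.ndarray, axis: np.ndarray, doped: bool, spacing: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """A straight 15-bead chain through ``centre`` along ``axis``."""
    offs = (np.arange(N_BEADS_PER_MONOMER) - (N_BEADS_PER_MONOMER - 1) / 2.0)
    coords = centre + spacing * offs[:, None] * axis
    types = np.array([PHILIC] * 5 + [PHOBIC] * 5 + [PHILIC] * 5, dtype=np.int8)
    if doped:
        types[-1] = SEED
    return coords, types


def _assemble(
    placements: list[tuple[np.ndarray, np.ndarray, bool]],
    box_length: float,
    spacing: float,
) -> SystemState:
    coords = []
    types = []
    for centre, axis, doped in placements:
        c, t = _monomer_beads(np.asarray(centre, float), np.asarray(axis, float),
                              doped, spacing)
        coords.append(c)
        types.append(t)
    n = len(placements)
    coords = np.concatenate(coords)
    coords -= coords.min(axis=0) - 2.0  # keep well inside the primary box
    return SystemState(
        coordinates=np.mod(coords, box_length),
        velocities=np.zeros_like(coords),
        bead_types=np.concatenate(types),
        monomer_id=np.repeat(np.arange(n), N_BEADS_PER_MONOMER),
        box_length=box_length,
        n_monomers=n,
        phi_nominal=sum(p[2] for p in placements) / n,
        time=0.0,
    )


def generate_ideal_aggregate(
    kind: str,
    n_monomers: int,
    seed: int = 0,
    spacing: float = 1.0,
    n_branches: int = 3,
    arm_length: int | None = None,
) -> SystemState:
    """Idealised aggregate geometry of a known morphology class.

    linear_stack: in-register chains stacked along x at ``spacing``;
    branched_tree: a main stack with perpendicular arm stacks attached
    at seeded interior branch monomers (hub degree >= 3);
    globule: collapsed random-walk chains packed uniformly in a ball;
    dispersed: chains on a sparse grid, farther apart than any contact
    cutoff.  Chains lie along z so stacking contacts are core-to-core.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if kind not in AGGREGATE_KINDS:
        raise ValueError(f"unknown aggregate kind {kind!r}; one of {AGGREGATE_KINDS}")
    rng = np.random.default_rng(seed)
    z = np.array([0.0, 0.0, 1.0])

    if kind == "linear_stack":
        box = max(4.0 * n_monomers * spacing, 40.0)
        placements = [
            (np.array([m * spacing, 0.0, 0.0]), z, False) for m in range(n_monomers)
        ]
        return _assemble(placements, box, spacing)

    if kind == "dispersed":
        gap = 8.0
        zgap = 24.0  # chains span 14 sigma along z; keep layers clear
        side = int(np.ceil(n_monomers ** (1.0 / 3.0)))
        box = max(side * zgap + 20.0, side * gap + 20.0, 40.0)
        placements = []
        for m in range(n_monomers):
            i, j, k = m % side, (m // side) % side, m // side**2
            placements.append((np.array([i * gap, j * gap, k * zgap]), z, False))
        return _assemble(placements, box, spacing)

    if kind == "globule":
        n_beads = n_monomers * N_BEADS_PER_MONOMER
        radius = (n_beads / (1.0 * 4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)
        box = max(8.0 * radius, 40.0)
        coords = []
        types = []
        for m in range(n_monomers):
            while True:
                centre = rng.normal(size=3)
                r = np.linalg.norm(centre)
                if r > 0:
                    break
            centre = centre / r * radius * rng.uniform(0, 1) ** (1.0 / 3.0)
            # collapsed chain: confined random walk around the centre
            chain = [centre + rng.normal(scale=0.3, size=3)]
            for _ in range(N_BEADS_PER_MONOMER - 1):
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                nxt = chain[-1] + spacing * step
                # pull back toward the centre to stay compact
                d = nxt - centre
                dist = np.linalg.norm(d)
                if dist > 1.5:
                    nxt = centre + d / dist * 1.5
                chain.append(nxt)
            coords.append(np.array(chain))
            types.append(
                np.array([PHILIC] * 5 + [PHOBIC] * 5 + [PHILIC] * 5, dtype=np.int8)
            )
        coords = np.concatenate(coords)
        coords -= coords.min(axis=0) - 2.0
        return SystemState(
            coordinates=np.mod(coords, box),
            velocities=np.zeros_like(coords),
            bead_types=np.concatenate(types),
            monomer_id=np.repeat(np.arange(n_monomers), N_BEADS_PER_MONOMER),
            box_length=box,
            n_monomers=n_monomers,
            phi_nominal=0.0,
            time=0.0,
        )

    # branched_tree: backbone along x, arms along +/- y at doped hubs
    n_branches = min(n_branches, max(1, n_monomers // 4))
    backbone_n = max(n_monomers // 2, n_branches + 2)
    remaining = n_monomers - backbone_n
    if remaining < n_branches:
        backbone_n = n_monomers - n_branches
        remaining = n_branches
    per_arm = remaining // n_branches
    arm_sizes = [per_arm] * n_branches
    for extra in range(remaining - per_arm * n_branches):
        arm_sizes[extra] += 1
    if arm_length is not None:
        arm_sizes = [min(a, arm_length) for a in arm_sizes]
    # seeded choice of interior, non-adjacent branch monomers
    interior = np.arange(2, backbone_n - 2)
    hubs: list[int] = []
    perm = rng.permutation(interior)
    for cand in perm:
        if all(abs(cand - h) >= 3 for h in hubs):
            hubs.append(int(cand))
        if len(hubs) == n_branches:
            break
    hubs.sort()
    attach = 1.2 * spacing  # hub-arm gap: in contact, clear of hub's neighbours
    placements = [
        (np.array([m * spacing, 0.0, 0.0]), z, m in hubs) for m in range(backbone_n)
    ]
    for b, (hub, size) in enumerate(zip(hubs, arm_sizes)):
        side = 1.0 if b % 2 == 0 else -1.0
        for a in range(size):
            y = side * (attach + a * spacing)
            placements.append((np.array([hub * spacing, y, 0.0]), z, False))
    box = max(4.0 * backbone_n * spacing, 40.0)
    return _assemble(placements, box, spacing)
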