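"""Aggregate detection and size kinetics.

Two monomers belong to the same aggregate when at least ``min_contacts``
of their hydrophobic (PHOBIC or SEED) bead pairs lie within the contact
cutoff under minimum image; aggregates are the connected components of
that contact relation (single-linkage clustering via union-find).  The
kinetics observable is the average number of monomers per aggregate,
n_mol(t), reported with both number and mass weighting because either
convention is defensible; singleton monomers count as size-1 clusters,
so a fully dispersed system starts at n_mol = 1.

The total count of inter-monomer hydrophobic contacts is tracked as a
crude stand-in for a ThT-like signal: the dye lights up on packed
cross-beta material, and packed hydrophobic cores are exactly what the
contact count measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cg_model import SystemState
from .dynamics import Trajectory

DEFAULT_CUTOFF = 1.5
DEFAULT_MIN_CONTACTS = 2


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return
        if self.size[ri] < self.size[rj]:
            ri, rj = rj, ri
        self.parent[rj] = ri
        self.size[ri] += self.size[rj]

    def labels(self) -> np.ndarray:
        return np.array([self.find(i) for i in range(len(self.parent))])


@dataclass
class ClusterSet:
    """Single-linkage aggregates of one frame.

    ``clusters`` partition all monomer ids; every cluster is non-empty.
    """

    time: float
    clusters: list[set[int]]
    n_monomers: int
    cutoff: float
    min_contacts: int
    contact_pairs: dict[tuple[int, int], int] = field(default_factory=dict)
    hh_contacts: int = 0

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=np.int64)

    def validate_partition(self) -> bool:
        seen: set[int] = set()
        for c in self.clusters:
            if not c or seen & c:
                return False
            seen |= c
        return seen == set(range(self.n_monomers))


def contact_pair_counts(
    frame: SystemState, cutoff: float
) -> tuple[dict[tuple[int, int], int], int]:
    """Count inter-monomer hydrophobic bead pairs within ``cutoff``.

    Returns ({(m_lo, m_hi): n_bead_pairs}, total contact count).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.mod(frame.coordinates, frame.box_length)
    mask = frame.hydrophobic_mask()
    idx = np.flatnonzero(mask)
    counts: dict[tuple[int, int], int] = {}
    if len(idx) == 0:
        return counts, 0
    # cKDTree with boxsize handles the periodic minimum image
    tree = cKDTree(pos[idx], boxsize=frame.box_length)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    total = 0
    if len(pairs):
        mi = frame.monomer_id[idx[pairs[:, 0]]]
        mj = frame.monomer_id[idx[pairs[:, 1]]]
        inter = mi != mj
        lo = np.minimum(mi[inter], mj[inter])
        hi = np.maximum(mi[inter], mj[inter])
        total = int(inter.sum())
        keys, cnt = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        counts = {(int(a), int(b)): int(c) for (a, b), c in zip(keys, cnt)}
    return counts, total


def detect_clusters(
    frame: SystemState,
    cutoff: float = DEFAULT_CUTOFF,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> ClusterSet:
    """Single-linkage aggregates of one frame.

    Monomers are linked when >= ``min_contacts`` inter-monomer
    hydrophobic bead pairs are within ``cutoff``; clusters are the
    connected components of the link graph.
    """
    if min_contacts < 1:
        raise ValueError("min_contacts must be >= 1")
    counts, total = contact_pair_counts(frame, cutoff)
    uf = UnionFind(frame.n_monomers)
    for (a, b), c in counts.items():
        if c >= min_contacts:
            uf.union(a, b)
    labels = uf.labels()
    clusters: dict[int, set[int]] = {}
    for m, lab in enumerate(labels):
        clusters.setdefault(int(lab), set()).add(m)
    return ClusterSet(
        time=frame.time,
        clusters=list(clusters.values()),
        n_monomers=frame.n_monomers,
        cutoff=cutoff,
        min_contacts=min_contacts,
        contact_pairs=counts,
        hh_contacts=total,
    )


def mean_aggregate_size(cs: ClusterSet, weighting: str = "number") -> float:
    """Mean monomers per aggregate, singletons included.

    number: arithmetic mean of cluster sizes; mass: sum(s^2)/sum(s),
    the size experienced by a randomly picked monomer.
    """
    sizes = cs.sizes
    if weighting == "number":
        return float(sizes.mean())
    if weighting == "mass":
        return float((sizes.astype(float) ** 2).sum() / sizes.sum())
    raise ValueError(f"unknown weighting {weighting!r}")


@dataclass
class KineticsSeries:
    """n_mol(t) and companions for one run or a replica average."""

    times: np.ndarray
    n_mol: np.ndarray
    n_clusters: np.ndarray
    largest_cluster: np.ndarray
    hh_contacts: np.ndarray
    weighting: str = "number"
    cutoff: float = DEFAULT_CUTOFF
    min_contacts: int = DEFAULT_MIN_CONTACTS
    n_replicas: int = 1
    n_mol_se: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "time": self.times,
            "n_mol": self.n_mol,
            "n_clusters": self.n_clusters,
            "largest_cluster": self.largest_cluster,
            "hh_contacts": self.hh_contacts,
        }
        if self.n_mol_se is not None:
            data["n_mol_se"] = self.n_mol_se
        return pd.DataFrame(data)

    def final_value(self, tail_fraction: float = 0.1) -> float:
        """Mean n_mol over the trailing ``tail_fraction`` of frames."""
        k = max(1, int(round(tail_fraction * len(self.times))))
        return float(np.mean(self.n_mol[-k:]))


def kinetics_series(
    traj: Trajectory,
    cutoff: float = DEFAULT_CUTOFF,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
    weighting: str = "number",
) -> KineticsSeries:
    """Apply cluster detection to every frame of a trajectory."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    n_mol = np.empty(traj.n_frames)
    n_clusters = np.empty(traj.n_frames, dtype=np.int64)
    largest = np.empty(traj.n_frames, dtype=np.int64)
    contacts = np.empty(traj.n_frames, dtype=np.int64)
    for fi in range(traj.n_frames):
        cs = detect_clusters(traj.frame(fi), cutoff, min_contacts)
        n_mol[fi] = mean_aggregate_size(cs, weighting)
        sizes = cs.sizes
        n_clusters[fi] = len(sizes)
        largest[fi] = sizes.max()
        contacts[fi] = cs.hh_contacts
    return KineticsSeries(
        times=traj.times.copy(),
        n_mol=n_mol,
        n_clusters=n_clusters,
        largest_cluster=largest,
        hh_contacts=contacts,
        weighting=weighting,
        cutoff=cutoff,
        min_contacts=min_contacts,
    )


def replica_average(series: list[KineticsSeries]) -> KineticsSeries:
    """Pointwise mean and standard error over replicas.

    Replica runs mirror the averaging protocol of the study: several
    independent seeds per condition, one mean curve with errors.
    """
    if not series:
        raise ValueError("no series to average")
    t0 = series[0].times
    for s in series[1:]:
        if len(s.times) != len(t0) or not np.allclose(s.times, t0):
            raise ValueError("replica time grids do not match")
    stack = np.stack([s.n_mol for s in series])
    n = len(series)
    se = (
        stack.std(axis=0, ddof=1) / np.sqrt(n)
        if n > 1
        else np.zeros_like(stack[0])
    )
    return KineticsSeries(
        times=t0.copy(),
        n_mol=stack.mean(axis=0),
        n_clusters=np.stack([s.n_clusters for s in series]).mean(axis=0),
        largest_cluster=np.stack([s.largest_cluster for s in series]).mean(axis=0),
        hh_contacts=np.stack([s.hh_contacts for s in series]).mean(axis=0),
        weighting=series[0].weighting,
        cutoff=series[0].cutoff,
        min_contacts=series[0].min_contacts,
        n_replicas=n,
        n_mol_se=se,
    )


@dataclass
class PhiSweepSummary:
    """Final aggregate size versus doped fraction, with crossover estimate."""

    table: pd.DataFrame
    crossover_phi: float | None
    factor: float
    tail_fraction: float


def phi_sweep_summary(
    final_series: dict[float, KineticsSeries],
    factor: float = 3.0,
    tail_fraction: float = 0.1,
) -> PhiSweepSummary:
    """Summarise a doped-fraction sweep.

    ``final_series`` maps phi to the (replica-averaged) kinetics of that
    condition; the grid must contain phi = 0 as the undoped baseline.
    The crossover estimate is the smallest phi whose final n_mol exceeds
    ``factor`` times the phi = 0 value; None when no phi qualifies.  The
    rule is a ratio, so it is invariant to rescaling all n_mol.
    """
    phis = sorted(final_series)
    if len(phis) < 3:
        raise ValueError("need at least 3 phi values")
    if 0.0 not in final_series:
        raise ValueError("sweep must include the undoped baseline phi = 0")
    rows = []
    for phi in phis:
        s = final_series[phi]
        k = max(1, int(round(tail_fraction * len(s.times))))
        final = float(np.mean(s.n_mol[-k:]))
        if s.n_mol_se is not None:
            final_se = float(np.mean(s.n_mol_se[-k:]))
        else:
            final_se = np.nan
        rows.append(
            {
                "phi": phi,
                "final_n_mol": final,
                "final_n_mol_se": final_se,
                "final_largest": float(np.mean(s.largest_cluster[-k:])),
            }
        )
    table = pd.DataFrame(rows)
    baseline = table.loc[table["phi"] == 0.0, "final_n_mol"].iloc[0]
    above = table[table["final_n_mol"] > factor * baseline]
    crossover = float(above["phi"].min()) if len(above) else None
    return PhiSweepSummary(
        table=table, crossover_phi=crossover, factor=factor,
        tail_fraction=tail_fraction,
    )
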