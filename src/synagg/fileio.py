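"""Configuration, trajectory and manifest plumbing.

Formats: TOML run configuration (flat keys, unknown keys rejected),
extended-XYZ for frames and trajectories (human-readable, one block per
frame, the comment line carrying time/box/column layout), CSV/JSON for
analysis output, and a JSON run manifest recording the configuration
hash, seeds and a checksum for every file a run wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cg_model import (
    BEAD_SPECIES,
    N_BEADS_PER_MONOMER,
    SEED,
    SPECIES_CODES,
    ForceFieldParams,
    SystemState,
)
from .dynamics import IntegratorParams, Trajectory

_FF_KEYS = {f.name for f in dataclasses.fields(ForceFieldParams)}
_IP_KEYS = {f.name for f in dataclasses.fields(IntegratorParams)} - {"rng_seed"}
_SYSTEM_KEYS = {"n_monomers", "phi", "box_length", "seed", "seeds", "output_dir"}
_ANALYSIS_KEYS = {"cutoff", "min_contacts", "weighting", "crossover_factor"}
KNOWN_KEYS = _FF_KEYS | _IP_KEYS | _SYSTEM_KEYS | _ANALYSIS_KEYS


@dataclass
class RunConfig:
    """Fully materialised run configuration with defaults applied."""

    n_monomers: int = 128
    phi: float = 0.0
    box_length: float | None = None
    seeds: tuple[int, ...] = (1, 2, 3)
    output_dir: str = "."
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    cutoff: float = 1.5
    min_contacts: int = 2
    weighting: str = "number"
    crossover_factor: float = 3.0

    def to_flat_dict(self) -> dict:
        out = {
            "n_monomers": self.n_monomers,
            "phi": self.phi,
            "seeds": list(self.seeds),
            "output_dir": self.output_dir,
            "cutoff": self.cutoff,
            "min_contacts": self.min_contacts,
            "weighting": self.weighting,
            "crossover_factor": self.crossover_factor,
        }
        if self.box_length is not None:
            out["box_length"] = self.box_length
        for k in sorted(_FF_KEYS):
            out[k] = getattr(self.forcefield, k)
        for k in sorted(_IP_KEYS):
            out[k] = getattr(self.integrator, k)
        return out

    def config_hash(self) -> str:
        payload = json.dumps(self.to_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat TOML run configuration; unknown keys are an error."""
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    ff_kwargs = {k: raw[k] for k in _FF_KEYS if k in raw}
    ip_kwargs = {k: raw[k] for k in _IP_KEYS if k in raw}
    seeds = raw.get("seeds")
    if seeds is None:
        seeds = (raw["seed"],) if "seed" in raw else (1, 2, 3)
    cfg = RunConfig(
        n_monomers=int(raw.get("n_monomers", 128)),
        phi=float(raw.get("phi", 0.0)),
        box_length=float(raw["box_length"]) if "box_length" in raw else None,
        seeds=tuple(int(s) for s in seeds),
        output_dir=str(raw.get("output_dir", ".")),
        forcefield=ForceFieldParams(**ff_kwargs),
        integrator=IntegratorParams(**ip_kwargs),
        cutoff=float(raw.get("cutoff", 1.5)),
        min_contacts=int(raw.get("min_contacts", 2)),
        weighting=str(raw.get("weighting", "number")),
        crossover_factor=float(raw.get("crossover_factor", 3.0)),
    )
    if not 0.0 <= cfg.phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if cfg.weighting not in ("number", "mass"):
        raise ValueError("weighting must be 'number' or 'mass'")
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialise a RunConfig back to flat TOML (read_config round-trips)."""
    lines = []
    for k, v in cfg.to_flat_dict().items():
        if isinstance(v, bool):
            lines.append(f"{k} = {'true' if v else 'false'}")
        elif isinstance(v, (int, float)):
            lines.append(f"{k} = {v}")
        elif isinstance(v, list):
            lines.append(f"{k} = {v}")
        else:
            lines.append(f'{k} = "{v}"')
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# extended XYZ
# --------------------------------------------------------------------------

_XYZ_PROPERTIES = "species:S:1:pos:R:3:monomer_id:I:1:doped:I:1"


def _frame_block(
    coords: np.ndarray,
    bead_types: np.ndarray,
    monomer_id: np.ndarray,
    box: float,
    time: float,
) -> str:
    n = coords.shape[0]
    doped_monomer = {
        int(monomer_id[i]): 1
        for i in range(n)
        if bead_types[i] == SEED
    }
    lines = [str(n)]
    lines.append(
        f'Lattice="{box} 0 0 0 {box} 0 0 0 {box}" '
        f"Properties={_XYZ_PROPERTIES} Time={time}"
    )
    for i in range(n):
        sp = BEAD_SPECIES[int(bead_types[i])]
        m = int(monomer_id[i])
        d = doped_monomer.get(m, 0)
        lines.append(
            f"{sp} {coords[i, 0]:.8f} {coords[i, 1]:.8f} {coords[i, 2]:.8f} {m} {d}"
        )
    return "\n".join(lines)


def write_state(state: SystemState, path: str | Path) -> None:
    """One extended-XYZ frame for a single system snapshot."""
    block = _frame_block(
        np.mod(state.coordinates, state.box_length),
        state.bead_types,
        state.monomer_id,
        state.box_length,
        state.time,
    )
    Path(path).write_text(block + "\n")


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Multi-frame extended-XYZ trajectory."""
    blocks = [
        _frame_block(
            traj.positions[fi],
            traj.bead_types,
            traj.monomer_id,
            traj.box_length,
            float(traj.times[fi]),
        )
        for fi in range(traj.n_frames)
    ]
    Path(path).write_text("\n".join(blocks) + "\n")


def _parse_comment(comment: str, frame_index: int) -> tuple[float, float]:
    box = None
    time = 0.0
    for token in comment.replace('"', " ").split():
        if token.startswith("Time="):
            time = float(token[5:])
    if "Lattice=" in comment:
        inside = comment.split("Lattice=")[1].split('"')[1]
        vals = [float(v) for v in inside.split()]
        box = vals[0]
    if box is None:
        raise ValueError(f"frame {frame_index}: comment line lacks Lattice")
    return box, time


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a (multi-frame) extended-XYZ file written by this package."""
    lines = Path(path).read_text().splitlines()
    pos_frames = []
    times = []
    bead_types = None
    monomer_id = None
    box = None
    cursor = 0
    frame_index = 0
    while cursor < len(lines):
        if not lines[cursor].strip():
            cursor += 1
            continue
        try:
            n = int(lines[cursor].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_index}: bad atom count line") from exc
        if cursor + 1 + n > len(lines):
            raise ValueError(f"frame {frame_index}: truncated frame")
        fbox, time = _parse_comment(lines[cursor + 1], frame_index)
        coords = np.empty((n, 3))
        types = np.empty(n, dtype=np.int8)
        mono = np.empty(n, dtype=np.int64)
        for i in range(n):
            parts = lines[cursor + 2 + i].split()
            if len(parts) < 6:
                raise ValueError(f"frame {frame_index}: malformed atom line {i}")
            types[i] = SPECIES_CODES[parts[0]]
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            mono[i] = int(parts[4])
        if bead_types is None:
            bead_types, monomer_id, box = types, mono, fbox
        elif n != len(bead_types) or fbox != box:
            raise ValueError(f"frame {frame_index}: inconsistent system size or box")
        pos_frames.append(coords)
        times.append(time)
        cursor += 2 + n
        frame_index += 1
    if not pos_frames:
        raise ValueError("no frames found")
    return Trajectory(
        times=np.array(times),
        positions=np.stack(pos_frames),
        bead_types=bead_types,
        monomer_id=monomer_id,
        box_length=box,
        n_monomers=len(bead_types) // N_BEADS_PER_MONOMER,
        provenance={"source": str(path)},
    )


def read_state(path: str | Path) -> SystemState:
    """Read a single extended-XYZ frame as a SystemState."""
    traj = read_trajectory(path)
    return traj.frame(0)


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    out_dir: str | Path,
    config_hash: str,
    seeds: list[int] | tuple[int, ...],
    outputs: list[str | Path],
    name: str = "manifest.json",
) -> Path:
    """Record what a run produced: config hash, seeds, file checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry = {}
    for p in outputs:
        p = Path(p)
        registry[p.name] = _sha256(p) if p.exists() else None
    manifest = {
        "config_hash": config_hash,
        "seeds": list(seeds),
        "package_version": __version__,
        "outputs": registry,
    }
    path = out_dir / name
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
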