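"""Trajectory/ensemble loading and boost-energy log parsing.

Replica trajectories are concatenated after a per-replica equilibration
exclusion (the production analyses drop the equilibration stretch of each
replica and keep the tail — e.g. three replicas × 7000 retained frames give
the 21,000-frame analysis ensemble).  Per-frame replica provenance is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np

from .amd import BoostRecord

__all__ = ["TrajectoryEnsemble", "load_ensemble", "parse_boost_log"]


@dataclass
class TrajectoryEnsemble:
    """Concatenated replicas with per-frame provenance."""

    traj: md.Trajectory
    replica: np.ndarray  # per-frame replica index
    sources: list[str] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.traj.n_frames

    def __len__(self) -> int:
        return self.traj.n_frames


def _load_one(item, topology):
    if isinstance(item, md.Trajectory):
        return item, "<in-memory>"
    path = str(item)
    if topology is None:
        t = md.load(path)
    else:
        t = md.load(path, top=str(topology))
    return t, path


def load_ensemble(
    trajectories,
    topology=None,
    exclude_frames: int = 0,
    keep_last: int | None = None,
    stride: int = 1,
) -> TrajectoryEnsemble:
    """Load and merge replica trajectories.

    Parameters
    ----------
    trajectories:
        Paths (DCD/XTC/...) or in-memory ``mdtraj.Trajectory`` objects.
    topology:
        PDB path, required for coordinate-only formats.
    exclude_frames:
        Equilibration frames dropped from the start of *each* replica
        (applied after ``stride``).
    keep_last:
        Alternative to ``exclude_frames``: retain only the last N frames of
        each replica.
    stride:
        Subsampling step applied per replica before the exclusion — the
        save interval of a production run rarely matches the analysis grid,
        so the stride is explicit rather than implied.
    """
    if exclude_frames and keep_last is not None:
        raise ValueError("give either exclude_frames or keep_last, not both")
    if isinstance(trajectories, (str, Path)) or isinstance(trajectories, md.Trajectory):
        trajectories = [trajectories]
    parts, replica, sources = [], [], []
    n_atoms = None
    for r, item in enumerate(trajectories):
        t, name = _load_one(item, topology)
        if n_atoms is None:
            n_atoms = t.n_atoms
        elif t.n_atoms != n_atoms:
            raise ValueError(
                f"atom count mismatch: '{name}' has {t.n_atoms} atoms, "
                f"'{sources[0]}' has {n_atoms}"
            )
        if stride > 1:
            t = t[::stride]
        if keep_last is not None:
            if keep_last > t.n_frames:
                raise ValueError(
                    f"keep_last={keep_last} exceeds the {t.n_frames} frames of '{name}'"
                )
            t = t[-keep_last:]
        elif exclude_frames:
            if exclude_frames >= t.n_frames:
                raise ValueError(
                    f"equilibration exclusion of {exclude_frames} frames leaves "
                    f"nothing of '{name}' ({t.n_frames} frames)"
                )
            t = t[exclude_frames:]
        parts.append(t)
        replica.append(np.full(t.n_frames, r, dtype=int))
        sources.append(name)
    merged = parts[0] if len(parts) == 1 else md.join(parts)
    return TrajectoryEnsemble(
        traj=merged, replica=np.concatenate(replica), sources=sources
    )


def parse_boost_log(
    path: str | Path,
    temperature: float = 300.0,
    dv_columns=None,
) -> BoostRecord:
    """Read per-frame total boost energies ΔV (kcal/mol) from a text log.

    Accepted dialects:

    * two whitespace-separated columns ``frame_or_time  delta_v`` — the
      second column is ΔV;
    * AMBER-style aMD logs (comment lines starting with ``#`` or ``@``,
      numeric rows whose last two columns are the potential and dihedral
      boost energies) — ΔV is their sum, matching a dual-boost run;
    * any layout via ``dv_columns``: an iterable of 0-based column indices
      summed into ΔV.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s[0] in "#@;":
            continue
        try:
            rows.append([float(tok) for tok in s.split()])
        except ValueError:
            continue  # stray text line
    if not rows:
        raise ValueError(f"no numeric rows found in boost log '{path}'")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows], float)
    if dv_columns is not None:
        dv = data[:, list(dv_columns)].sum(axis=1)
    elif ncol == 2:
        dv = data[:, 1]
    elif ncol >= 4:
        dv = data[:, -2] + data[:, -1]
    else:
        raise ValueError(
            f"boost log '{path}' has {ncol} columns; expected 2 (frame, dV) "
            "or an AMBER-style layout with boost energies in the last two"
        )
    return BoostRecord(delta_v=dv, temperature=temperature)
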