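"""GROMOS conformational clustering and essential dynamics.

GROMOS clustering: given the pairwise RMSD matrix, repeatedly take the
frame with the most neighbors within the cutoff as a cluster medoid, assign
it and its neighbors to that cluster, remove them from the pool, and stop
when the pool is empty or the cluster cap is reached (ties on neighbor
count go to the lower frame index).  Antibody matrices use Cα atoms
(cutoffs 0.75 nm for cMD, 0.65 nm for aMD; caps 15 and 10); glycan matrices
use the glycosidic oxygens (cutoff 0.1 nm, cap 10).

Essential dynamics: PCA of the 3N Cα coordinate covariance after
least-squares superposition onto the iterated mean structure.  Projections
on the leading eigenvectors describe the dominant collective motions; a
trajectory reconstructed from a single component isolates that motion for
downstream angle analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import mdtraj as md
import numpy as np

from .geometry import DeltaPhiSeries, FabAngles, compute_delta_phi, compute_fab_angles
from .groups import AtomGroupConfig
from .util import as_mdtraj

__all__ = [
    "RMSDMatrix",
    "ClusterResult",
    "EDResult",
    "rmsd_matrix",
    "gromos_cluster",
    "essential_dynamics",
    "reconstruct_component",
    "filtered_delta_phi",
]


@dataclass
class RMSDMatrix:
    """Symmetric pairwise minimal-RMSD matrix (nm) over trajectory frames."""

    values: np.ndarray
    selection: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("RMSD matrix must be square")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ClusterResult:
    """GROMOS assignments: −1 marks the unassigned remainder."""

    labels: np.ndarray  # per-frame cluster id, clusters ordered by size
    medoids: np.ndarray  # frame index per cluster
    populations: np.ndarray  # fraction of all frames per cluster
    cutoff: float
    max_clusters: int

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    @property
    def unassigned_fraction(self) -> float:
        return float(np.mean(self.labels < 0))


@dataclass
class EDResult:
    """Essential-dynamics decomposition of the superposed coordinates."""

    mean_xyz: np.ndarray  # (n_sel, 3) nm
    eigenvalues: np.ndarray  # descending, nm^2
    eigenvectors: np.ndarray  # (3*n_sel, n_modes), columns orthonormal
    projections: np.ndarray  # (n_frames, n_modes) nm
    selection: np.ndarray
    superposed_xyz: np.ndarray  # (n_frames, n_sel, 3), the analyzed coordinates

    @property
    def cumulative_variance(self) -> np.ndarray:
        ev = np.clip(self.eigenvalues, 0, None)
        total = ev.sum()
        if total == 0:
            return np.zeros_like(ev)
        return np.cumsum(ev) / total


def rmsd_matrix(traj, selection=None) -> RMSDMatrix:
    """All-against-all minimal RMSD after optimal superposition (nm)."""
    t = as_mdtraj(traj)
    if t.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = t.topology.select("name CA")
    sel = np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("selection must contain at least 3 atoms")
    n = t.n_frames
    m = np.empty((n, n))
    for i in range(n):
        m[i] = md.rmsd(t, t, frame=i, atom_indices=sel)
    m = 0.5 * (m + m.T)  # Kabsch RMSD is symmetric; average out float noise
    np.fill_diagonal(m, 0.0)
    return RMSDMatrix(values=m, selection=sel)


def gromos_cluster(
    matrix: RMSDMatrix | np.ndarray, cutoff: float, max_clusters: int = 15
) -> ClusterResult:
    """Neighbor-counting clustering on a pairwise RMSD matrix.

    Deterministic: when two frames have equal neighbor counts the lower
    frame index becomes the medoid.  Frames left over once *max_clusters*
    clusters have been emitted keep the label −1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if max_clusters < 1:
        raise ValueError("max_clusters must be >= 1")
    m = matrix.values if isinstance(matrix, RMSDMatrix) else np.asarray(matrix, float)
    n = m.shape[0]
    neighbor = m <= cutoff
    in_pool = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    medoids: list[int] = []
    sizes: list[int] = []
    while in_pool.any() and len(medoids) < max_clusters:
        counts = (neighbor & in_pool[None, :]).sum(axis=1)
        counts[~in_pool] = -1
        center = int(np.argmax(counts))  # argmax takes the first = lowest index
        members = np.nonzero(neighbor[center] & in_pool)[0]
        labels[members] = len(medoids)
        medoids.append(center)
        sizes.append(len(members))
        in_pool[members] = False

    # emit in decreasing size order (stable: earlier cluster wins ties)
    order = sorted(range(len(medoids)), key=lambda k: (-sizes[k], k))
    relabel = {old: new for new, old in enumerate(order)}
    new_labels = np.array([relabel[l] if l >= 0 else -1 for l in labels])
    return ClusterResult(
        labels=new_labels,
        medoids=np.array([medoids[k] for k in order], int),
        populations=np.array([sizes[k] for k in order], float) / n,
        cutoff=float(cutoff),
        max_clusters=int(max_clusters),
    )


def essential_dynamics(traj, selection=None, n_modes: int | None = None) -> EDResult:
    """PCA of the Cα coordinate covariance after iterated-mean superposition."""
    t = as_mdtraj(traj)
    if t.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if selection is None:
        selection = t.topology.select("name CA")
    sel = np.asarray(selection, int)
    if sel.size < 3:
        raise ValueError("selection must contain at least 3 atoms")

    sup = t[:]
    sup.superpose(t, frame=0, atom_indices=sel)
    mean0 = sup.xyz.mean(axis=0)
    ref = md.Trajectory(mean0[None], t.topology)
    sup.superpose(ref, frame=0, atom_indices=sel)

    x = sup.xyz[:, sel].astype(np.float64).reshape(t.n_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / t.n_frames
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if n_modes is not None:
        w, v = w[:n_modes], v[:, :n_modes]
    proj = xc @ v
    return EDResult(
        mean_xyz=mean.reshape(-1, 3),
        eigenvalues=w,
        eigenvectors=v,
        projections=proj,
        selection=sel,
        superposed_xyz=sup.xyz[:, sel].astype(np.float64),
    )


def reconstruct_component(ed: EDResult, components) -> np.ndarray:
    """Coordinates (n_frames, n_sel, 3) keeping only the chosen components.

    ``mean + Σ_c proj[:, c] · eigenvector_c`` — the filtered trajectory of
    the essential motion along those components.
    """
    comps = np.atleast_1d(np.asarray(components, int))
    if comps.min() < 0 or comps.max() >= ed.eigenvectors.shape[1]:
        raise IndexError("component index out of range")
    flat = ed.mean_xyz.reshape(1, -1) + ed.projections[:, comps] @ ed.eigenvectors[:, comps].T
    return flat.reshape(len(ed.projections), -1, 3)


def _remap_groups(groups: AtomGroupConfig, selection: np.ndarray) -> AtomGroupConfig:
    pos = {int(a): i for i, a in enumerate(selection)}
    mapped = {}
    for name, idx in groups.to_dict().items():
        try:
            mapped[name] = [pos[int(a)] for a in idx]
        except KeyError:
            raise ValueError(
                f"group '{name}' has atoms outside the ED selection; "
                "compute ED on a selection covering every geometry group"
            ) from None
    return AtomGroupConfig(**mapped)


def filtered_delta_phi(
    ed: EDResult,
    groups: AtomGroupConfig,
    components,
    min_energy_frames=None,
) -> DeltaPhiSeries:
    """Δϕ of the essential motion along chosen ED components.

    Rebuilds a trajectory containing only the selected components' motion,
    restricts it to the minimum-energy frames, and recomputes ϕ and Δϕ on
    it.  The geometry groups must be a subset of the ED selection.
    """
    xyz = reconstruct_component(ed, components)
    if min_energy_frames is not None:
        xyz = xyz[np.asarray(min_energy_frames, int)]
    sub_groups = _remap_groups(groups, ed.selection)
    angles = compute_fab_angles(xyz, sub_groups)
    return compute_delta_phi(angles)


def angles_on_frames(ed: EDResult, groups: AtomGroupConfig, frames=None) -> FabAngles:
    """Fab angles on the full superposed ED coordinates (all components)."""
    xyz = ed.superposed_xyz
    if frames is not None:
        xyz = xyz[np.asarray(frames, int)]
    return compute_fab_angles(xyz, _remap_groups(groups, ed.selection))
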