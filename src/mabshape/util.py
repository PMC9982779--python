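"""Small shared helpers: coordinate extraction and physical constants."""

from __future__ import annotations

import numpy as np

# Boltzmann constant in kcal/mol/K
KB_KCAL = 0.0019872041


def kt_kcal(temperature: float = 300.0) -> float:
    """k_B·T in kcal/mol (0.5962 at the 300 K simulation temperature)."""
    return KB_KCAL * float(temperature)


def as_xyz(traj) -> np.ndarray:
    """Coordinates (n_frames, n_atoms, 3) in nm from a trajectory-like input.

    Accepts an ``mdtraj.Trajectory``, a :class:`~mabshape.io.TrajectoryEnsemble`
    or a bare ndarray (a single (N, 3) frame is promoted to one frame).
    """
    if hasattr(traj, "traj"):  # TrajectoryEnsemble
        traj = traj.traj
    if hasattr(traj, "xyz"):
        return np.asarray(traj.xyz, dtype=float)
    arr = np.asarray(traj, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"cannot interpret shape {arr.shape} as coordinates")
    return arr


def as_mdtraj(traj):
    """Return the underlying ``mdtraj.Trajectory`` (unwrapping ensembles)."""
    if hasattr(traj, "traj"):
        traj = traj.traj
    if not hasattr(traj, "xyz") or not hasattr(traj, "topology"):
        raise TypeError("an mdtraj.Trajectory (or ensemble wrapping one) is required")
    return traj
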