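"""Accelerated-MD boost parameters and Maclaurin reweighting to a (θ1, θ2) FES.

In dual-boost aMD the sampled ensemble is biased by a per-frame boost energy
ΔV ≥ 0.  Unbiased statistics follow by weighting each frame with exp(βΔV);
because the exponential amplifies noise in the tail, the weight is
approximated by its Maclaurin (Taylor-at-zero) series truncated at order
k_max (10 by default):

    w_i = Σ_{k=0}^{k_max} (β ΔV_i)^k / k!

The weighted 2-D histogram of the two Fab latitude angles gives the
probability surface p(θ1, θ2) and the potential of mean force
PMF = −k_B·T ln p, shifted so the occupied-bin minimum is exactly 0.
Frames falling in bins below a PMF cutoff (0.5 kcal/mol by default) form
the minimum-energy set used by the downstream descriptor analyses.

The boost-parameter recipe maps average dihedral/total potential energies
to thresholds and smoothing widths:

    EthreshD = DIHED + 4 kcal/mol/residue · n_residues
    alphaD   = (1/5) · 4 kcal/mol/residue · n_residues
    EthreshP = EPTOT + 0.16 kcal/mol/atom · n_atoms
    alphaP   = 0.16 kcal/mol/atom · n_atoms
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import FabAngles
from .util import kt_kcal

__all__ = [
    "AMDParams",
    "BoostRecord",
    "FESGrid",
    "compute_amd_params",
    "maclaurin_weights",
    "reweight_fes",
    "select_min_energy_frames",
    "default_theta_edges",
]

DIHED_BOOST_PER_RESIDUE = 4.0  # kcal/mol per solute residue
POT_BOOST_PER_ATOM = 0.16  # kcal/mol per atom


@dataclass(frozen=True)
class AMDParams:
    """Dual-boost aMD input parameters (kcal/mol)."""

    dihed: float
    eptot: float
    solute_residues: int
    n_atoms: int
    ethresh_d: float
    alpha_d: float
    ethresh_p: float
    alpha_p: float


@dataclass
class BoostRecord:
    """Per-frame total boost energy ΔV (kcal/mol) at temperature T (K)."""

    delta_v: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.delta_v = np.asarray(self.delta_v, dtype=float).ravel()
        if not np.all(np.isfinite(self.delta_v)):
            raise ValueError("boost energies must be finite")
        if np.any(self.delta_v < 0):
            raise ValueError("boost energies must be non-negative")

    def __len__(self) -> int:
        return len(self.delta_v)


@dataclass
class FESGrid:
    """Reweighted probability and PMF on a (θ1, θ2) grid.

    ``pmf`` is +inf on unoccupied bins; over occupied bins the probabilities
    sum to 1 and the PMF minimum is exactly 0.
    """

    theta1_edges: np.ndarray
    theta2_edges: np.ndarray
    prob: np.ndarray
    pmf: np.ndarray
    k_max: int
    temperature: float
    counts: np.ndarray = field(repr=False, default=None)
    series_max_rel_err: float = 0.0

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.pmf)

    def bin_of(self, theta1, theta2) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices of per-frame angles; raises when outside the grid."""
        i = np.digitize(theta1, self.theta1_edges) - 1
        j = np.digitize(theta2, self.theta2_edges) - 1
        # a point sitting on the uppermost edge belongs to the last bin
        i = np.where(np.asarray(theta1) == self.theta1_edges[-1], len(self.theta1_edges) - 2, i)
        j = np.where(np.asarray(theta2) == self.theta2_edges[-1], len(self.theta2_edges) - 2, j)
        if np.any(i < 0) or np.any(i >= len(self.theta1_edges) - 1):
            raise ValueError("theta1 value outside the grid")
        if np.any(j < 0) or np.any(j >= len(self.theta2_edges) - 1):
            raise ValueError("theta2 value outside the grid")
        return i, j

    def minimum(self) -> tuple[float, float]:
        """(θ1, θ2) bin-center location of the PMF global minimum."""
        i, j = np.unravel_index(np.argmin(np.where(self.occupied, self.pmf, np.inf)), self.pmf.shape)
        c1 = 0.5 * (self.theta1_edges[i] + self.theta1_edges[i + 1])
        c2 = 0.5 * (self.theta2_edges[j] + self.theta2_edges[j + 1])
        return float(c1), float(c2)

    def to_frame(self) -> pd.DataFrame:
        c1 = 0.5 * (self.theta1_edges[:-1] + self.theta1_edges[1:])
        c2 = 0.5 * (self.theta2_edges[:-1] + self.theta2_edges[1:])
        g1, g2 = np.meshgrid(c1, c2, indexing="ij")
        return pd.DataFrame(
            {
                "theta1_bin": g1.ravel(),
                "theta2_bin": g2.ravel(),
                "prob": self.prob.ravel(),
                "pmf_kcalmol": self.pmf.ravel(),
            }
        )


def compute_amd_params(
    dihed: float, eptot: float, solute_residues: int, n_atoms: int
) -> AMDParams:
    """Boost thresholds/widths from average energies and system size."""
    if solute_residues <= 0 or n_atoms <= 0:
        raise ValueError("solute_residues and n_atoms must be positive")
    if not (math.isfinite(dihed) and math.isfinite(eptot)):
        raise ValueError("input energies must be finite")
    dihed_boost = DIHED_BOOST_PER_RESIDUE * solute_residues
    pot_boost = POT_BOOST_PER_ATOM * n_atoms
    return AMDParams(
        dihed=float(dihed),
        eptot=float(eptot),
        solute_residues=int(solute_residues),
        n_atoms=int(n_atoms),
        ethresh_d=float(dihed) + dihed_boost,
        alpha_d=dihed_boost / 5.0,
        ethresh_p=float(eptot) + pot_boost,
        alpha_p=pot_boost,
    )


def maclaurin_weights(beta_dv: np.ndarray, k_max: int = 10) -> np.ndarray:
    """Truncated-series approximation of exp(βΔV), term-by-term (stable)."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(beta_dv, dtype=float)
    w = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, k_max + 1):
        term = term * x / k
        w = w + term
    return w


def default_theta_edges(width: float = 2.5) -> np.ndarray:
    """Uniform bin edges covering θ ∈ [0, 180] degrees (2.5° bins)."""
    n = int(round(180.0 / width))
    return np.linspace(0.0, 180.0, n + 1)


def reweight_fes(
    angles: FabAngles,
    boost: BoostRecord,
    theta1_edges: np.ndarray | None = None,
    theta2_edges: np.ndarray | None = None,
    k_max: int = 10,
) -> FESGrid:
    """Reweight the boosted (θ1, θ2) sample onto a PMF grid.

    A diagnostic, ``series_max_rel_err``, records how far the truncated
    series deviates from the exact exponential at the largest βΔV seen; a
    value above 1% triggers a warning (the 10th-order series is accurate to
    ~0.03% at βΔV = 3 but degrades quickly beyond βΔV ≈ 5).
    """
    if len(angles) != len(boost):
        raise ValueError(
            f"angles ({len(angles)} frames) and boost ({len(boost)}) are not aligned"
        )
    if theta1_edges is None:
        theta1_edges = default_theta_edges()
    if theta2_edges is None:
        theta2_edges = default_theta_edges()
    theta1_edges = np.asarray(theta1_edges, float)
    theta2_edges = np.asarray(theta2_edges, float)

    kt = kt_kcal(boost.temperature)
    beta_dv = boost.delta_v / kt
    w = maclaurin_weights(beta_dv, k_max=k_max)

    x_max = float(beta_dv.max(initial=0.0))
    exact = math.exp(x_max)
    approx = float(maclaurin_weights(np.array([x_max]), k_max=k_max)[0])
    rel_err = abs(approx - exact) / exact
    if rel_err > 0.01:
        warnings.warn(
            f"Maclaurin series of order {k_max} deviates from exp by "
            f"{rel_err:.1%} at max(beta*dV) = {x_max:.2f}; "
            "the reweighted PMF may be biased",
            RuntimeWarning,
            stacklevel=2,
        )

    hist, _, _ = np.histogram2d(
        angles.theta1, angles.theta2, bins=(theta1_edges, theta2_edges), weights=w
    )
    counts, _, _ = np.histogram2d(
        angles.theta1, angles.theta2, bins=(theta1_edges, theta2_edges)
    )
    prob = hist / hist.sum()
    occupied = counts > 0
    pmf = np.full_like(prob, np.inf)
    pmf[occupied] = -kt * np.log(prob[occupied])
    pmf[occupied] -= pmf[occupied].min()
    return FESGrid(
        theta1_edges=theta1_edges,
        theta2_edges=theta2_edges,
        prob=prob,
        pmf=pmf,
        k_max=k_max,
        temperature=boost.temperature,
        counts=counts.astype(int),
        series_max_rel_err=rel_err,
    )


def select_min_energy_frames(
    grid: FESGrid, angles: FabAngles, cutoff: float = 0.5
) -> np.ndarray:
    """Frame indices whose (θ1, θ2) bin has PMF below *cutoff* (kcal/mol).

    Non-empty by construction: the global-minimum bin (PMF = 0) always
    qualifies for any positive cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive (kcal/mol)")
    i, j = grid.bin_of(angles.theta1, angles.theta2)
    mask = grid.pmf[i, j] < cutoff
    return np.nonzero(mask)[0]
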