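"""Fc-anchored reference frame and Fab orientation angles.

The hinge-linked IgG1 architecture leaves each Fab free to move on a sphere
around the hinge.  Its position is described by latitude/longitude angles
(θ, ϕ) in a body frame attached to the Fc:

* origin — centroid of the hinge atoms;
* z — dominant principal axis of the Fc atom cloud, sign-fixed so it points
  from the Fc toward the Fabs;
* x — vector joining the two CH2 domain centroids, orthogonalized against z;
* y — z × x (right-handed).

θ is the polar angle of the Fab centroid from +z (so θ = 90° puts the Fab in
the Fc equatorial plane: "T-shaped"; small θ folds it onto the Fc axis:
"Y-shaped"); ϕ is the longitude measured from +x.  The frame is rebuilt for
every trajectory frame, so all angles are internal coordinates, invariant
under rigid motion of the whole molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .groups import AtomGroupConfig
from .util import as_xyz

__all__ = [
    "FcFrame",
    "FabAngles",
    "ShapeCall",
    "DeltaPhiSeries",
    "DegenerateGeometryError",
    "build_fc_frame",
    "compute_fab_angles",
    "classify_shape",
    "compute_delta_phi",
    "wrap_degrees",
    "shape_fractions_from_theta",
]


class DegenerateGeometryError(ValueError):
    """Raised when the Fc frame cannot be constructed unambiguously."""


@dataclass(frozen=True)
class FcFrame:
    """Orthonormal right-handed frame anchored to the Fc (units: nm)."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix whose rows are (x, y, z): maps lab to frame coords."""
        return np.stack([self.x, self.y, self.z])


@dataclass
class FabAngles:
    """Per-frame Fab orientation angles in degrees.

    theta1/theta2 in [0, 180], phi1/phi2 in (-180, 180].
    """

    theta1: np.ndarray
    theta2: np.ndarray
    phi1: np.ndarray
    phi2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.theta1)
        for name in ("theta2", "phi1", "phi2"):
            if len(getattr(self, name)) != n:
                raise ValueError("angle series must have equal length")

    def __len__(self) -> int:
        return len(self.theta1)

    def take(self, indices) -> "FabAngles":
        idx = np.asarray(indices)
        return FabAngles(
            self.theta1[idx], self.theta2[idx], self.phi1[idx], self.phi2[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self)),
                "theta1": self.theta1,
                "theta2": self.theta2,
                "phi1": self.phi1,
                "phi2": self.phi2,
            }
        )


@dataclass
class ShapeCall:
    """Per-frame T/Y/asym labels plus ensemble fractions."""

    labels: np.ndarray  # array of 'T' | 'Y' | 'asym'
    fraction_t: float  # both Fabs theta >= threshold
    fraction_y: float  # both Fabs theta < threshold
    fraction_asym: float
    per_fab_fraction_t: tuple[float, float]  # fraction theta >= threshold, per Fab
    threshold: float


@dataclass
class DeltaPhiSeries:
    """Per-frame longitude shift Δϕ = ϕ_i − ϕ_ref per Fab, degrees.

    Wrapped to (−180, 180] by default; ``cumulative=True`` at construction
    unwraps the series so multi-turn rotations accumulate.
    """

    dphi1: np.ndarray
    dphi2: np.ndarray
    reference_frame: int
    cumulative: bool = False


def wrap_degrees(angle) -> np.ndarray:
    """Wrap angles (degrees) into (−180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.ceil((a - 180.0) / 360.0)
    return wrapped


def build_fc_frame(coords: np.ndarray, groups: AtomGroupConfig) -> FcFrame:
    """Construct the Fc-anchored frame from one coordinate set (N, 3) nm."""
    coords = np.asarray(coords, dtype=float)
    origin = coords[groups.hinge].mean(axis=0)

    fc = coords[groups.fc]
    fc_centroid = fc.mean(axis=0)
    centered = fc - fc_centroid
    # dominant principal axis of the Fc atom cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    z = vt[0]
    # sign: +z runs from the Fc body toward the hinge, i.e. toward the Fab
    # side of the molecule.  (Signing on the Fab midpoint itself is unstable:
    # with both Fabs past the equator, theta > 90 deg, the midpoint falls on
    # the Fc side and would flip the frame.)
    toward_hinge = origin - fc_centroid
    if np.linalg.norm(toward_hinge) > 1e-9:
        if float(z @ toward_hinge) < 0.0:
            z = -z
    else:
        fab_mid = 0.5 * (
            coords[groups.fab1].mean(axis=0) + coords[groups.fab2].mean(axis=0)
        )
        toward_fabs = fab_mid - origin
        if np.linalg.norm(toward_fabs) < 1e-9:
            raise DegenerateGeometryError(
                "hinge centroid coincides with both the Fc centroid and the "
                "Fab midpoint; z axis sign is undefined"
            )
        if float(z @ toward_fabs) < 0.0:
            z = -z

    ch2_vec = coords[groups.ch2_b].mean(axis=0) - coords[groups.ch2_a].mean(axis=0)
    x = ch2_vec - (ch2_vec @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-6:
        raise DegenerateGeometryError(
            "CH2_A -> CH2_B vector is parallel to the Fc axis; "
            "x axis of the Fc frame is undefined"
        )
    x = x / nx
    y = np.cross(z, x)
    return FcFrame(origin=origin, x=x, y=y, z=z)


def _fab_angles_one(coords: np.ndarray, groups: AtomGroupConfig, frame: FcFrame):
    out = []
    for sel in (groups.fab1, groups.fab2):
        v = coords[sel].mean(axis=0) - frame.origin
        r = np.linalg.norm(v)
        if r < 1e-6:
            raise DegenerateGeometryError("Fab centroid coincides with hinge centroid")
        local = frame.rotation @ v
        theta = np.degrees(np.arccos(np.clip(local[2] / r, -1.0, 1.0)))
        phi = np.degrees(np.arctan2(local[1], local[0]))
        out.append((theta, wrap_degrees(phi)))
    return out


def compute_fab_angles(traj, groups: AtomGroupConfig) -> FabAngles:
    """Per-frame (θ, ϕ) for both Fabs; the Fc frame is rebuilt every frame."""
    xyz = as_xyz(traj)
    n = xyz.shape[0]
    if n == 0:
        raise ValueError("empty trajectory")
    groups.validate(xyz.shape[1])
    th1 = np.empty(n)
    th2 = np.empty(n)
    ph1 = np.empty(n)
    ph2 = np.empty(n)
    for i in range(n):
        frame = build_fc_frame(xyz[i], groups)
        (th1[i], ph1[i]), (th2[i], ph2[i]) = _fab_angles_one(xyz[i], groups, frame)
    return FabAngles(theta1=th1, theta2=th2, phi1=ph1, phi2=ph2)


def classify_shape(angles: FabAngles, threshold: float = 85.0) -> ShapeCall:
    """Label every frame T (both θ ≥ threshold), Y (both <) or asym."""
    if not 0.0 < threshold < 180.0:
        raise ValueError("threshold must lie in (0, 180) degrees")
    if len(angles) == 0:
        raise ValueError("empty angle series")
    up1 = angles.theta1 >= threshold
    up2 = angles.theta2 >= threshold
    labels = np.where(up1 & up2, "T", np.where(~up1 & ~up2, "Y", "asym"))
    n = len(angles)
    return ShapeCall(
        labels=labels,
        fraction_t=float(np.count_nonzero(up1 & up2)) / n,
        fraction_y=float(np.count_nonzero(~up1 & ~up2)) / n,
        fraction_asym=float(np.count_nonzero(up1 ^ up2)) / n,
        per_fab_fraction_t=(
            float(np.count_nonzero(up1)) / n,
            float(np.count_nonzero(up2)) / n,
        ),
        threshold=float(threshold),
    )


def shape_fractions_from_theta(
    theta1, theta2, threshold: float = 85.0
) -> dict[str, float]:
    """Shape-fraction summary straight from per-frame θ columns.

    Convenience for externally produced per-frame tables (e.g. exported
    source data); equivalent to :func:`classify_shape` on the same angles.
    """
    angles = FabAngles(
        theta1=np.asarray(theta1, float),
        theta2=np.asarray(theta2, float),
        phi1=np.zeros(len(theta1)),
        phi2=np.zeros(len(theta1)),
    )
    call = classify_shape(angles, threshold=threshold)
    return {
        "fraction_t": call.fraction_t,
        "fraction_y": call.fraction_y,
        "fraction_asym": call.fraction_asym,
        "fab1_fraction_t": call.per_fab_fraction_t[0],
        "fab2_fraction_t": call.per_fab_fraction_t[1],
    }


def compute_delta_phi(
    angles: FabAngles,
    reference_frame_index: int = 0,
    cumulative: bool = False,
) -> DeltaPhiSeries:
    """Longitude shift of each Fab from its position at the reference frame.

    Values are wrapped into (−180, 180]; the reference frame is exactly 0.
    With ``cumulative=True`` successive differences are unwrapped first, so
    a slow full turn reads 360° rather than 0°.
    """
    n = len(angles)
    if not -n <= reference_frame_index < n:
        raise IndexError(f"reference frame {reference_frame_index} out of range")
    out = []
    for phi in (angles.phi1, angles.phi2):
        if cumulative:
            unwrapped = np.degrees(np.unwrap(np.radians(phi)))
            d = unwrapped - unwrapped[reference_frame_index]
        else:
            d = wrap_degrees(phi - phi[reference_frame_index])
        d[reference_frame_index] = 0.0
        out.append(d)
    return DeltaPhiSeries(
        dphi1=out[0],
        dphi2=out[1],
        reference_frame=int(reference_frame_index),
        cumulative=cumulative,
    )
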