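"""Toy-antibody generators with known ground truth.

A pseudo-atomic IgG1 stand-in: an elongated Fc slab, a hinge cluster at the
origin, two rigid Fab clouds placed at prescribed (θ, ϕ) on a sphere around
the hinge, two CH2 clusters flanking the Fc base (their Asn pseudo-residues
carry the CH2 opening distance), and two short glycan chains with named
glycosidic oxygens plus a detachable fucose pseudo-atom.  Every frame is
built from sampled internal coordinates and then (optionally) subjected to
a random global rotation + translation, so recovering the planted values
exercises the full rotation-equivariant analysis path.

Ground truth (per-frame θ/ϕ, shape labels, CH2 distances, glycan jitter) is
emitted alongside the coordinates for round-trip tests.  All randomness
flows from the mandatory seed.

A second generator draws (θ1, θ2) ensembles from a known unbiased density
biased by an analytic boost ΔV(θ1, θ2), by rejection sampling — the exact
reference for validating Maclaurin reweighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import mdtraj as md
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.stats import norm, truncnorm

from .amd import BoostRecord
from .geometry import FabAngles, wrap_degrees
from .groups import AtomGroupConfig
from .util import kt_kcal

__all__ = [
    "SyntheticSpec",
    "ToyMab",
    "BoostedSpec",
    "BoostedSample",
    "generate_toy_mab",
    "generate_boosted_samples",
    "generate_hbond_fixture",
]


# ---------------------------------------------------------------------------
# toy antibody


@dataclass
class SyntheticSpec:
    """Generative parameters of the toy antibody.

    The default condition mirrors the study systems: a (T, Y, asym) shape
    mixture of (0.3, 0.5, 0.2) with T latitudes near 100 deg and Y latitudes
    near 70 deg (5 deg spread, truncated at the 85 deg threshold so labels
    are exact), and a CH2 opening distance ~ Normal(4.8, 0.3) nm.
    Explicit per-frame ``theta``/``phi`` (n_frames, 2) arrays override the
    sampling laws when supplied.
    """

    seed: int
    n_frames: int = 2000
    shape_weights: tuple[float, float, float] = (0.3, 0.5, 0.2)  # T, Y, asym
    theta_threshold: float = 85.0
    theta_t_mean: float = 100.0
    theta_y_mean: float = 70.0
    theta_sd: float = 5.0
    phi_mean: tuple[float, float] = (90.0, -90.0)
    phi_sd: float = 20.0
    phi_ramp: float = 0.0  # deg/frame drift added to both Fabs
    fab_radius_nm: float = 4.0
    ch2_mean_nm: float = 4.8
    ch2_sd_nm: float = 0.3
    glycan_inside: bool = False
    glycan_jitter_nm: float = 0.05
    rigid_motion: bool = True
    theta: np.ndarray | None = None  # (n_frames, 2) explicit override, deg
    phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        w = np.asarray(self.shape_weights, float)
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("shape_weights must be non-negative and sum to 1")
        for name in ("theta_sd", "phi_sd", "fab_radius_nm", "ch2_sd_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for name in ("theta", "phi"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, float)
                if arr.shape != (self.n_frames, 2):
                    raise ValueError(f"{name} override must have shape (n_frames, 2)")
                setattr(self, name, arr)


@dataclass
class ToyMab:
    """Generated toy system: trajectory, selections and ground truth.

    ``traj`` holds single-precision coordinates (the trajectory-format
    convention); ``xyz`` keeps the exact double-precision coordinates the
    frames were built from, for strict round-trip checks.
    """

    traj: md.Trajectory
    xyz: np.ndarray
    groups: AtomGroupConfig
    truth: pd.DataFrame
    linkages: list[dict]
    spec: SyntheticSpec

    def save(self, outdir: str | Path) -> None:
        """Write topology.pdb, traj.dcd, groups.yml and truth/*.csv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traj[0].save_pdb(str(outdir / "topology.pdb"))
        self.traj.save_dcd(str(outdir / "traj.dcd"))
        self.groups.to_yaml(outdir / "groups.yml")
        tdir = outdir / "truth"
        tdir.mkdir(exist_ok=True)
        self.truth.to_csv(tdir / "per_frame.csv", index=False)


def _unit(theta_deg: float, phi_deg: float) -> np.ndarray:
    th, ph = np.radians(theta_deg), np.radians(phi_deg)
    return np.array(
        [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
    )


_FAB_OFFSETS = 0.3 * np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], float
)
_HINGE_OFFSETS = np.array(
    [[0.15, 0, 0.05], [-0.15, 0, 0.05], [0, 0.15, -0.05], [0, -0.15, -0.05], [0, 0, 0]]
)
_CH2_OFFSETS = 0.15 * np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)

# internal geometry of one glycan chain (relative to its base point):
# NAG1(C1, O5) - O4 linkage - NAG2(C4, C5) and a fucose pseudo-atom
_GLYCAN_ATOMS = [
    ("NAG", "C1", np.array([0.00, 0.00, 0.00])),
    ("NAG", "O5", np.array([0.10, 0.10, 0.05])),
    ("NAG", "O4", np.array([0.25, 0.00, 0.10])),
    ("NAG", "C4", np.array([0.40, 0.05, 0.15])),
    ("NAG", "C5", np.array([0.55, 0.00, 0.10])),
    ("FUC", "C1", np.array([0.10, -0.20, -0.10])),
]


def _truncated(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_angles(spec: SyntheticSpec, rng: np.random.Generator):
    n = spec.n_frames
    if spec.theta is not None:
        theta = np.asarray(spec.theta, float)
        labels = np.where(
            (theta[:, 0] >= spec.theta_threshold) & (theta[:, 1] >= spec.theta_threshold),
            "T",
            np.where(
                (theta[:, 0] < spec.theta_threshold) & (theta[:, 1] < spec.theta_threshold),
                "Y",
                "asym",
            ),
        )
    else:
        labels = rng.choice(["T", "Y", "asym"], size=n, p=list(spec.shape_weights))
        theta = np.empty((n, 2))
        thr = spec.theta_threshold
        for j in range(2):
            hi_mask = (labels == "T") | ((labels == "asym") & (j == 0))
            lo_mask = ~hi_mask
            theta[hi_mask, j] = _truncated(
                rng, spec.theta_t_mean, spec.theta_sd, thr, 180.0, hi_mask.sum()
            )
            theta[lo_mask, j] = _truncated(
                rng, spec.theta_y_mean, spec.theta_sd, 0.0, thr, lo_mask.sum()
            )
    if spec.phi is not None:
        phi = wrap_degrees(np.asarray(spec.phi, float))
    else:
        ramp = spec.phi_ramp * np.arange(n)
        phi = np.stack(
            [
                wrap_degrees(rng.normal(spec.phi_mean[0], spec.phi_sd, n) + ramp),
                wrap_degrees(rng.normal(spec.phi_mean[1], spec.phi_sd, n) + ramp),
            ],
            axis=1,
        )
    return theta, phi, labels


def _build_topology(n_fc: int) -> tuple[md.Topology, dict[str, list[int]]]:
    top = md.Topology()
    groups: dict[str, list[int]] = {k: [] for k in (
        "fc", "hinge", "fab1", "fab2", "ch2_a", "ch2_b",
        "glyco_asn_a", "glyco_asn_b", "glycan_a", "glycan_b", "lc_cterm",
    )}
    carbon = md.element.carbon
    oxygen = md.element.oxygen

    def add_chain_of_cas(chain_name, res_name, n, group):
        chain = top.add_chain()
        for _ in range(n):
            res = top.add_residue(res_name, chain)
            a = top.add_atom("CA", carbon, res)
            groups[group].append(a.index)
        return chain

    add_chain_of_cas("FC", "GLY", n_fc, "fc")
    add_chain_of_cas("H", "PRO", len(_HINGE_OFFSETS), "hinge")
    add_chain_of_cas("1", "ALA", len(_FAB_OFFSETS), "fab1")
    add_chain_of_cas("2", "ALA", len(_FAB_OFFSETS), "fab2")
    for side in "ab":
        chain = top.add_chain()
        for _ in range(len(_CH2_OFFSETS)):
            res = top.add_residue("LEU", chain)
            a = top.add_atom("CA", carbon, res)
            groups[f"ch2_{side}"].append(a.index)
        res = top.add_residue("ASN", chain)
        a = top.add_atom("CA", carbon, res)
        groups[f"glyco_asn_{side}"].append(a.index)
    for side in "ab":
        chain = top.add_chain()
        res_by_name: dict[str, object] = {}
        prev_name = None
        for res_name, atom_name, _ in _GLYCAN_ATOMS:
            if res_name != prev_name:
                res_by_name[res_name] = top.add_residue(res_name, chain)
                prev_name = res_name
            el = oxygen if atom_name.startswith("O") else carbon
            a = top.add_atom(atom_name, el, res_by_name[res_name])
            groups[f"glycan_{side}"].append(a.index)
    # the last Fab residues stand in for the LC C-terminal stretch
    groups["lc_cterm"] = groups["fab1"][-3:]
    return top, groups


def generate_toy_mab(spec: SyntheticSpec) -> ToyMab:
    """Build the toy antibody trajectory with per-frame ground truth."""
    rng = np.random.default_rng(spec.seed)
    theta, phi, labels = _sample_angles(spec, rng)
    ch2 = rng.normal(spec.ch2_mean_nm, spec.ch2_sd_nm, spec.n_frames)
    ch2 = np.abs(ch2)  # distances; the default law makes negatives vanishing

    # static lab-frame pieces: Fc slab elongated along z, below the hinge
    zs = np.linspace(-5.0, -1.4, 6)
    grid = [(x, y) for x in (-0.6, 0.0, 0.6) for y in (-0.6, 0.0, 0.6)]
    fc_xyz = np.array([[x, y, z] for z in zs for x, y in grid])
    top, group_idx = _build_topology(len(fc_xyz))
    groups = AtomGroupConfig(**group_idx)
    n_atoms = top.n_atoms

    ch2_base = {"a": np.array([-1.2, 0.0, -4.6]), "b": np.array([1.2, 0.0, -4.6])}
    glyc_x = 0.5 if spec.glycan_inside else 1.8
    glyc_base = {"a": np.array([-glyc_x, 0.0, -3.3]), "b": np.array([glyc_x, 0.0, -3.3])}
    glyc_local = np.array([off for _, _, off in _GLYCAN_ATOMS])

    xyz = np.empty((spec.n_frames, n_atoms, 3), dtype=float)
    glyc_jitter = {
        s: rng.normal(0.0, spec.glycan_jitter_nm, (spec.n_frames, 3)) for s in "ab"
    }
    for i in range(spec.n_frames):
        c = np.empty((n_atoms, 3))
        c[groups.fc] = fc_xyz
        c[groups.hinge] = _HINGE_OFFSETS  # centroid exactly at the origin
        for j, g in enumerate((groups.fab1, groups.fab2)):
            center = spec.fab_radius_nm * _unit(theta[i, j], phi[i, j])
            c[g] = center + _FAB_OFFSETS
        for side in "ab":
            c[getattr(groups, f"ch2_{side}")] = ch2_base[side] + _CH2_OFFSETS
            sign = -1.0 if side == "a" else 1.0
            c[getattr(groups, f"glyco_asn_{side}")] = np.array(
                [sign * ch2[i] / 2.0, 0.2, -4.2]
            )
            c[getattr(groups, f"glycan_{side}")] = (
                glyc_base[side]
                + glyc_jitter[side][i]
                + glyc_local * np.array([sign, 1.0, 1.0])
            )
        if spec.rigid_motion:
            rot = Rotation.random(random_state=rng).as_matrix()
            trans = rng.uniform(-2.0, 2.0, 3)
            c = c @ rot.T + trans
        xyz[i] = c

    traj = md.Trajectory(xyz.astype(np.float32), top)  # xyz kept in float64 below
    truth = pd.DataFrame(
        {
            "frame": np.arange(spec.n_frames),
            "label": labels,
            "theta1": theta[:, 0],
            "theta2": theta[:, 1],
            "phi1": phi[:, 0],
            "phi2": phi[:, 1],
            "ch2_distance": ch2,
        }
    )
    ga, gb = groups.glycan_a, groups.glycan_b
    linkages = [
        {
            "name": f"NAG1-NAG2_{side}",
            # Wormald convention: phi = O5-C1-O4-C4, psi = C1-O4-C4-C5
            "phi": [int(g[1]), int(g[0]), int(g[2]), int(g[3])],
            "psi": [int(g[0]), int(g[2]), int(g[3]), int(g[4])],
        }
        for side, g in (("A", ga), ("B", gb))
    ]
    return ToyMab(
        traj=traj, xyz=xyz, groups=groups, truth=truth, linkages=linkages, spec=spec
    )


# ---------------------------------------------------------------------------
# boosted ensembles with analytic reference


@dataclass
class BoostedSpec:
    """A known unbiased (θ1, θ2) density plus an analytic boost ΔV.

    The unbiased density is a Gaussian-mixture over wells
    ``(mu1, mu2, sd, weight)`` restricted to [0, 180]²; the boost is a
    single Gaussian bump of height ``dv_max`` kcal/mol.  Defaults plant one
    Y-like well at (70, 70) and one T-like well at (100, 100) whose weights
    differ by exp(−ΔG/kT) with ΔG = 1 kcal/mol, and a boost centred between
    them — the regime the 10th-order Maclaurin reweighting must recover.
    """

    seed: int
    n_samples: int = 50_000
    wells: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [(70.0, 70.0, 6.0, 1.0), (100.0, 100.0, 6.0, None)]
    )
    well_depth_gap: float = 1.0  # kcal/mol between first and second well
    dv_max: float = 1.5  # kcal/mol, keeps beta*dV <= ~2.5
    dv_center: tuple[float, float] = (85.0, 85.0)
    dv_width: float = 25.0
    temperature: float = 300.0

    def resolved_wells(self) -> np.ndarray:
        """Wells as (mu1, mu2, sd, weight) rows with weights normalized."""
        rows = []
        kt = kt_kcal(self.temperature)
        for mu1, mu2, sd, w in self.wells:
            if w is None:
                w = rows[0][3] * np.exp(-self.well_depth_gap / kt)
            rows.append([mu1, mu2, sd, w])
        arr = np.asarray(rows, float)
        arr[:, 3] /= arr[:, 3].sum()
        return arr

    def delta_v(self, theta1, theta2) -> np.ndarray:
        t1 = np.asarray(theta1, float)
        t2 = np.asarray(theta2, float)
        r2 = (t1 - self.dv_center[0]) ** 2 + (t2 - self.dv_center[1]) ** 2
        return self.dv_max * np.exp(-r2 / (2.0 * self.dv_width**2))

    def analytic_bin_probability(self, theta1_edges, theta2_edges) -> np.ndarray:
        """Exact unbiased bin probabilities of the mixture on the grid."""
        e1 = np.asarray(theta1_edges, float)
        e2 = np.asarray(theta2_edges, float)
        p = np.zeros((len(e1) - 1, len(e2) - 1))
        for mu1, mu2, sd, w in self.resolved_wells():
            c1 = np.diff(norm.cdf(e1, loc=mu1, scale=sd))
            c2 = np.diff(norm.cdf(e2, loc=mu2, scale=sd))
            p += w * np.outer(c1, c2)
        return p / p.sum()

    def analytic_pmf(self, theta1_edges, theta2_edges) -> np.ndarray:
        """Reference PMF (kcal/mol), zero at its occupied minimum."""
        p = self.analytic_bin_probability(theta1_edges, theta2_edges)
        kt = kt_kcal(self.temperature)
        pmf = np.full_like(p, np.inf)
        mask = p > 0
        pmf[mask] = -kt * np.log(p[mask])
        pmf[mask] -= pmf[mask].min()
        return pmf


@dataclass
class BoostedSample:
    """Rejection-sampled biased ensemble with its exact references."""

    angles: FabAngles
    boost: BoostRecord
    spec: BoostedSpec
    efficiency: float


def generate_boosted_samples(spec: BoostedSpec) -> BoostedSample:
    """Draw (θ1, θ2) from the boosted-ensemble density ∝ p₀ · exp(−βΔV).

    A system simulated on the boosted potential V + ΔV samples
    p ∝ exp(−β(V + ΔV)) = p₀ · exp(−βΔV); reweighting each frame with
    exp(+βΔV) recovers p₀.  Rejection sampling from the unbiased mixture
    with acceptance exp(−βΔV) is exact (ΔV ≥ 0 so acceptance ≤ 1); an
    efficiency below 1e-3 raises rather than silently looping.
    """
    rng = np.random.default_rng(spec.seed)
    wells = spec.resolved_wells()
    kt = kt_kcal(spec.temperature)
    beta = 1.0 / kt

    out = np.empty((0, 2))
    proposed = 0
    while len(out) < spec.n_samples:
        batch = max(4 * (spec.n_samples - len(out)), 1000)
        comp = rng.choice(len(wells), size=batch, p=wells[:, 3])
        draw = np.stack(
            [
                rng.normal(wells[comp, 0], wells[comp, 2]),
                rng.normal(wells[comp, 1], wells[comp, 2]),
            ],
            axis=1,
        )
        inside = np.all((draw >= 0.0) & (draw <= 180.0), axis=1)
        draw = draw[inside]
        accept_p = np.exp(-beta * spec.delta_v(draw[:, 0], draw[:, 1]))
        keep = rng.random(len(draw)) < accept_p
        out = np.vstack([out, draw[keep]])
        proposed += batch
        if proposed > 50_000 and len(out) / proposed < 1e-3:
            raise RuntimeError(
                f"rejection efficiency {len(out) / proposed:.2e} below 1e-3; "
                "lower dv_max or widen the boost"
            )
    efficiency = len(out) / proposed
    out = out[: spec.n_samples]
    dv = spec.delta_v(out[:, 0], out[:, 1])
    angles = FabAngles(
        theta1=out[:, 0],
        theta2=out[:, 1],
        phi1=np.zeros(spec.n_samples),
        phi2=np.zeros(spec.n_samples),
    )
    return BoostedSample(
        angles=angles,
        boost=BoostRecord(delta_v=dv, temperature=spec.temperature),
        spec=spec,
        efficiency=efficiency,
    )


# ---------------------------------------------------------------------------
# hydrogen-bond fixture


def generate_hbond_fixture(
    occupancy: float = 0.6, n_frames: int = 50, seed: int = 0
) -> md.Trajectory:
    """All-atom micro-fixture: one O–H donor facing one acceptor O.

    The bond geometry is ideal (linear, H···A = 0.20 nm) in exactly
    ``round(occupancy * n_frames)`` randomly placed frames and broken
    (acceptor displaced to 1 nm) in the rest, so the detected frequency has
    an exact expected value.
    """
    rng = np.random.default_rng(seed)
    top = md.Topology()
    chain = top.add_chain()
    don = top.add_residue("SER", chain)
    o_d = top.add_atom("OG", md.element.oxygen, don)
    h_d = top.add_atom("HG", md.element.hydrogen, don)
    acc = top.add_residue("HOH", chain)
    o_a = top.add_atom("O", md.element.oxygen, acc)
    top.add_bond(top.atom(o_d.index), top.atom(h_d.index))

    n_on = int(round(occupancy * n_frames))
    on = np.zeros(n_frames, bool)
    on[rng.permutation(n_frames)[:n_on]] = True
    xyz = np.zeros((n_frames, 3, 3), np.float32)
    xyz[:, h_d.index, 0] = 0.10  # O-H along +x
    xyz[:, o_a.index, 0] = np.where(on, 0.30, 1.00)  # H...A 0.20 nm when bonded
    return md.Trajectory(xyz, top)
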