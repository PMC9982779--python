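"""Scalar and tabular structural descriptors.

Everything here is a per-frame observable on the trajectory: global shape
statistics (RMSD / RMSF / radius of gyration on Cα atoms), the CH2 opening
distance measured between the two glycosylated Asn residues, glycan
chain-to-chain minimum distance and Fc-aligned center-of-mass displacement,
heavy-atom contact counts between the light-chain C-terminus and the hinge
(4 Å threshold), geometric hydrogen-bond frequencies, and glycosidic φ/ψ
torsions with occupancy of a reference (allowed) range.

Units are nm and degrees throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import mdtraj as md
import numpy as np
import pandas as pd

from .geometry import wrap_degrees
from .groups import AtomGroupConfig
from .util import as_mdtraj, as_xyz

__all__ = [
    "DistanceSeries",
    "ContactTable",
    "HBondTable",
    "DihedralSeries",
    "basic_descriptors",
    "ch2_distance",
    "glycan_min_distance",
    "glycan_com_displacement",
    "residue_contacts",
    "hydrogen_bonds",
    "glycosidic_dihedrals",
]


@dataclass
class DistanceSeries:
    """Named per-frame scalar distance (nm) with quartile summary."""

    name: str
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distance series must be 1-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and non-negative")

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def quartiles(self) -> tuple[float, float, float]:
        q1, q2, q3 = np.percentile(self.values, [25, 50, 75])
        return float(q1), float(q2), float(q3)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(len(self.values)), self.name: self.values})


@dataclass
class ContactTable:
    """Per-residue, per-frame heavy-atom contact-pair counts."""

    residue_labels: list[str]
    counts: np.ndarray  # (n_frames, n_residues), int
    cutoff_nm: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.residue_labels)
        df.insert(0, "frame", np.arange(len(df)))
        return df

    def mean_per_residue(self) -> pd.Series:
        return pd.Series(self.counts.mean(axis=0), index=self.residue_labels)


@dataclass
class HBondTable:
    """Unique donor/acceptor residue pairs with occurrence frequency."""

    table: pd.DataFrame  # donor_res, acceptor_res, chain_class, frequency
    n_frames: int
    distance_cutoff_nm: float
    angle_cutoff_deg: float


@dataclass
class DihedralSeries:
    """Per-linkage glycosidic φ/ψ series and in-range fractions."""

    linkage_names: list[str]
    phi: np.ndarray  # (n_frames, n_linkages) degrees
    psi: np.ndarray
    phi_in_range: np.ndarray  # fraction per linkage, nan when no range given
    psi_in_range: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frames = np.arange(self.phi.shape[0])
        parts = []
        for k, name in enumerate(self.linkage_names):
            parts.append(
                pd.DataFrame(
                    {
                        "frame": frames,
                        "linkage": name,
                        "phi": self.phi[:, k],
                        "psi": self.psi[:, k],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# global descriptors


def basic_descriptors(traj, selection=None):
    """RMSD (vs frame 0), per-residue RMSF (about the mean) and Rg, on Cα.

    *selection* defaults to all Cα atoms (``name CA``); pass explicit indices
    to override.  All three follow optimal least-squares superposition of the
    selection, so rigid-body motion does not contribute.
    Returns ``(rmsd, rmsf, rg)``: two per-frame arrays and one per-selected-atom
    array, all in nm.
    """
    t = as_mdtraj(traj)
    if selection is None:
        selection = t.topology.select("name CA")
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    rmsd = md.rmsd(t, t, frame=0, atom_indices=sel)
    sup = t[:]
    sup.superpose(t, frame=0, atom_indices=sel)
    mean_xyz = sup.xyz[:, sel].mean(axis=0)
    rmsf = np.sqrt(((sup.xyz[:, sel] - mean_xyz) ** 2).sum(axis=2).mean(axis=0))
    rg = md.compute_rg(t.atom_slice(sel))
    return rmsd.astype(float), rmsf.astype(float), rg.astype(float)


# ---------------------------------------------------------------------------
# distances


def _ca_or_sole_atom(topology, indices: np.ndarray, label: str) -> int:
    """The Cα atom of a residue selection, or the atom itself if single."""
    idx = np.asarray(indices, int)
    if idx.size == 0:
        raise ValueError(f"group '{label}' is empty")
    if idx.size == 1:
        return int(idx[0])
    if topology is not None:
        for a in idx:
            if topology.atom(int(a)).name == "CA":
                return int(a)
    raise ValueError(
        f"group '{label}' has several atoms and none named CA; "
        "point it at the Asn CA atom"
    )


def ch2_distance(traj, groups: AtomGroupConfig) -> DistanceSeries:
    """CH2 opening: Cα–Cα distance between the two glycosylated Asn (nm)."""
    if groups.glyco_asn_a.size == 0 or groups.glyco_asn_b.size == 0:
        raise ValueError("glyco_asn_a and glyco_asn_b groups are required")
    xyz = as_xyz(traj)
    top = getattr(getattr(traj, "traj", traj), "topology", None)
    a = _ca_or_sole_atom(top, groups.glyco_asn_a, "glyco_asn_a")
    b = _ca_or_sole_atom(top, groups.glyco_asn_b, "glyco_asn_b")
    d = np.linalg.norm(xyz[:, a] - xyz[:, b], axis=1)
    return DistanceSeries("ch2_distance_nm", d, meta={"atoms": (a, b)})


def _heavy(topology, indices: np.ndarray) -> np.ndarray:
    idx = np.asarray(indices, int)
    if topology is None:
        return idx
    keep = [
        i
        for i in idx
        if topology.atom(int(i)).element is None
        or topology.atom(int(i)).element.symbol != "H"
    ]
    return np.asarray(keep, dtype=int)


def glycan_min_distance(traj, groups: AtomGroupConfig) -> DistanceSeries:
    """Per-frame minimum heavy-atom distance between the two glycan chains."""
    if groups.glycan_a.size == 0 or groups.glycan_b.size == 0:
        raise ValueError("both glycan groups must be non-empty")
    xyz = as_xyz(traj)
    top = getattr(getattr(traj, "traj", traj), "topology", None)
    ga = _heavy(top, groups.glycan_a)
    gb = _heavy(top, groups.glycan_b)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("glycan groups contain no heavy atoms")
    diff = xyz[:, ga, None, :] - xyz[:, None, gb, :]
    d = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
    return DistanceSeries("glycan_min_distance_nm", d)


def glycan_com_displacement(
    traj, groups: AtomGroupConfig, chain: str = "a", reference_frame: int = 0
) -> DistanceSeries:
    """Glycan center-of-mass displacement from its reference position,
    after superposing every frame onto the reference frame using the Fc atoms.

    Isolates glycan motion relative to the Fc: rigid motion of the whole
    molecule is removed by the alignment.  Masses come from the topology
    elements when available, otherwise atoms are weighted equally.
    """
    sel = {"a": groups.glycan_a, "b": groups.glycan_b}[chain.lower()]
    if sel.size == 0:
        raise ValueError(f"glycan_{chain} group is empty")
    if groups.fc.size < 3:
        raise ValueError("Fc selection must contain at least 3 atoms for alignment")
    t = as_mdtraj(traj)[:]
    t.superpose(as_mdtraj(traj), frame=reference_frame, atom_indices=np.asarray(groups.fc, int))
    masses = np.ones(sel.size)
    top = t.topology
    if top is not None:
        m = np.array(
            [top.atom(int(i)).element.mass if top.atom(int(i)).element else 0.0 for i in sel]
        )
        if np.all(m > 0):
            masses = m
    com = (t.xyz[:, sel] * masses[None, :, None]).sum(axis=1) / masses.sum()
    d = np.linalg.norm(com - com[reference_frame], axis=1)
    return DistanceSeries(
        f"glycan_{chain}_com_displacement_nm",
        d,
        meta={"reference_frame": int(reference_frame), "aligned_on": "fc"},
    )


# ---------------------------------------------------------------------------
# contacts


def residue_contacts(
    traj, groups: AtomGroupConfig = None, group_a=None, group_b=None, cutoff: float = 0.4
) -> ContactTable:
    """Heavy-atom contact-pair counts between each residue of group A
    (default: the LC C-terminal residues) and group B (default: hinge).

    For every frame and every residue contributing atoms to group A, counts
    the number of heavy-atom pairs (a in residue, b in group B) with
    |a − b| ≤ cutoff (0.4 nm, i.e. the 4 Å contact threshold).
    """
    if group_a is None:
        group_a = groups.lc_cterm
    if group_b is None:
        group_b = groups.hinge
    ga = np.asarray(group_a, int)
    gb = np.asarray(group_b, int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both contact groups must be non-empty")
    t = as_mdtraj(traj)
    top = t.topology
    ga = _heavy(top, ga)
    gb = _heavy(top, gb)
    xyz = t.xyz

    by_res: dict[int, list[int]] = {}
    for a in ga:
        by_res.setdefault(top.atom(int(a)).residue.index, []).append(int(a))
    res_order = sorted(by_res)
    labels = []
    for r in res_order:
        res = top.residue(r)
        labels.append(f"{res.name}{res.resSeq}")

    counts = np.zeros((t.n_frames, len(res_order)), dtype=int)
    for k, r in enumerate(res_order):
        ra = np.asarray(by_res[r], int)
        diff = xyz[:, ra, None, :] - xyz[:, None, gb, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        counts[:, k] = (d <= cutoff).sum(axis=(1, 2))
    return ContactTable(residue_labels=labels, counts=counts, cutoff_nm=float(cutoff))


# ---------------------------------------------------------------------------
# hydrogen bonds


def _donors_acceptors(top):
    """(donor heavy atom, H) pairs and acceptor atoms from topology bonds."""
    donors = []
    for b in top.bonds:
        a1, a2 = b[0], b[1]
        for h, x in ((a1, a2), (a2, a1)):
            if (
                h.element is not None
                and h.element.symbol == "H"
                and x.element is not None
                and x.element.symbol in ("N", "O", "S")
            ):
                donors.append((x.index, h.index))
    acceptors = [
        a.index
        for a in top.atoms
        if a.element is not None and a.element.symbol in ("N", "O", "S")
    ]
    return donors, np.asarray(acceptors, int)


def hydrogen_bonds(
    traj,
    frames=None,
    distance_cutoff: float = 0.35,
    angle_cutoff: float = 120.0,
    chain_class=None,
) -> HBondTable:
    """Geometric hydrogen-bond frequencies over a frame subset.

    A bond is counted in a frame when the donor–acceptor heavy-atom distance
    is ≤ ``distance_cutoff`` (nm) and the D–H···A angle is ≥ ``angle_cutoff``
    (degrees).  Frequencies are per unique (donor residue, acceptor residue)
    pair over the analyzed frames; intra-residue pairs are ignored.

    *chain_class* optionally maps a chain index to a class label (e.g.
    HC1/HC2/LC) used to tag each pair by its donor chain.
    """
    t = as_mdtraj(traj)
    top = t.topology
    donors, acceptors = _donors_acceptors(top)
    if not donors:
        raise ValueError(
            "topology has no X-H bonds: hydrogen-bond analysis needs explicit "
            "hydrogens and bond information in the topology"
        )
    if frames is None:
        frames = np.arange(t.n_frames)
    frames = np.asarray(frames, int)
    xyz = t.xyz[frames]
    nfr = len(frames)

    pair_counts: dict[tuple[int, int], int] = {}
    d_idx = np.array([d for d, _ in donors], int)
    h_idx = np.array([h for _, h in donors], int)
    # angle at H between H->D and H->A; linear bond = 180 deg, so the
    # criterion "angle >= cutoff" reads cos(angle) <= cos(cutoff)
    cos_cut = np.cos(np.radians(angle_cutoff))
    for ai in acceptors:
        same = d_idx == ai
        dvec = xyz[:, ai][:, None, :] - xyz[:, d_idx]  # D -> A
        dist = np.linalg.norm(dvec, axis=-1)
        hvec_a = xyz[:, ai][:, None, :] - xyz[:, h_idx]  # H -> A
        hvec_d = xyz[:, d_idx] - xyz[:, h_idx]  # H -> D
        num = (hvec_a * hvec_d).sum(-1)
        den = np.linalg.norm(hvec_a, axis=-1) * np.linalg.norm(hvec_d, axis=-1)
        cos_dha = np.divide(num, den, out=np.ones_like(num), where=den > 0)
        # D-H...A angle >= cutoff <=> cos(angle at H) <= cos(cutoff)
        ok = (dist <= distance_cutoff) & (cos_dha <= cos_cut) & ~same[None, :]
        for j in range(len(d_idx)):
            n_hit = int(ok[:, j].sum())
            if n_hit == 0:
                continue
            dres = top.atom(int(d_idx[j])).residue.index
            ares = top.atom(int(ai)).residue.index
            if dres == ares:
                continue
            key = (dres, ares)
            pair_counts[key] = pair_counts.get(key, 0) + n_hit

    rows = []
    for (dres, ares), n_hit in sorted(pair_counts.items()):
        dr, ar = top.residue(dres), top.residue(ares)
        cls = ""
        if chain_class is not None:
            cls = chain_class.get(dr.chain.index, "")
        rows.append(
            {
                "donor_res": f"{dr.name}{dr.resSeq}",
                "acceptor_res": f"{ar.name}{ar.resSeq}",
                "chain_class": cls,
                "frequency": min(n_hit / nfr, 1.0),
            }
        )
    table = pd.DataFrame(rows, columns=["donor_res", "acceptor_res", "chain_class", "frequency"])
    return HBondTable(
        table=table,
        n_frames=nfr,
        distance_cutoff_nm=float(distance_cutoff),
        angle_cutoff_deg=float(angle_cutoff),
    )


# ---------------------------------------------------------------------------
# glycosidic torsions


def _resolve_quad(top, quad, linkage_name: str) -> list[int]:
    """Four atom indices from [(residue_index, atom_name), ...] or indices."""
    out = []
    for item in quad:
        if isinstance(item, (int, np.integer)):
            out.append(int(item))
            continue
        res_idx, atom_name = item
        res = top.residue(int(res_idx))
        match = [a.index for a in res.atoms if a.name == atom_name]
        if not match:
            raise KeyError(
                f"linkage '{linkage_name}': atom '{atom_name}' not found in "
                f"residue {res.name}{res.resSeq}"
            )
        out.append(match[0])
    if len(out) != 4:
        raise ValueError(f"linkage '{linkage_name}': a torsion needs 4 atoms")
    return out


def _fraction_in_range(values: np.ndarray, rng) -> float:
    if rng is None:
        return float("nan")
    lo, hi = float(rng[0]), float(rng[1])
    v = wrap_degrees(values)
    if lo <= hi:
        return float(np.mean((v >= lo) & (v <= hi)))
    return float(np.mean((v >= lo) | (v <= hi)))  # range wraps through 180


def glycosidic_dihedrals(traj, linkages) -> DihedralSeries:
    """φ/ψ torsions per glycosidic linkage, degrees in (−180, 180].

    *linkages* is a list of dicts with keys ``name``, ``phi`` and ``psi``
    (each four (residue_index, atom_name) pairs or plain atom indices,
    ordered O5–C1–Ox–Cx for φ and C1–Ox–Cx–C(x+1) for ψ) and optional
    ``phi_range`` / ``psi_range`` [lo, hi] reference windows; when a window
    wraps through ±180°, give lo > hi.  The per-linkage fraction of frames
    inside each window is reported alongside the series.
    """
    t = as_mdtraj(traj)
    top = t.topology
    names, quads, ranges = [], [], []
    for lk in linkages:
        name = lk.get("name", f"linkage{len(names)}")
        names.append(name)
        quads.append(_resolve_quad(top, lk["phi"], name))
        quads.append(_resolve_quad(top, lk["psi"], name))
        ranges.append((lk.get("phi_range"), lk.get("psi_range")))
    rad = md.compute_dihedrals(t, np.asarray(quads, int))
    deg = wrap_degrees(np.degrees(rad))
    phi = deg[:, 0::2]
    psi = deg[:, 1::2]
    phi_frac = np.array(
        [_fraction_in_range(phi[:, k], ranges[k][0]) for k in range(len(names))]
    )
    psi_frac = np.array(
        [_fraction_in_range(psi[:, k], ranges[k][1]) for k in range(len(names))]
    )
    return DihedralSeries(
        linkage_names=names, phi=phi, psi=psi, phi_in_range=phi_frac, psi_in_range=psi_frac
    )
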