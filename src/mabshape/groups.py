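"""Named atom selections for the antibody domains.

All analyses address atoms through an :class:`AtomGroupConfig`: named index
lists for the Fc slab, the two Fab arms, the hinge, the two CH2 domains, the
two glycan chains, the light-chain C-terminal stretch and the two
glycosylated Asn residues.  Indices are 0-based throughout (config files
included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

__all__ = ["AtomGroupConfig", "load_groups"]

_GROUP_FIELDS = (
    "fc",
    "fab1",
    "fab2",
    "hinge",
    "ch2_a",
    "ch2_b",
    "glycan_a",
    "glycan_b",
    "lc_cterm",
    "glyco_asn_a",
    "glyco_asn_b",
)

# groups an analysis can run without; the geometric core cannot
_OPTIONAL = ("glycan_a", "glycan_b", "lc_cterm", "glyco_asn_a", "glyco_asn_b")


def _as_index_array(value) -> np.ndarray:
    arr = np.asarray(value, dtype=np.intp).ravel()
    return arr


@dataclass
class AtomGroupConfig:
    """Atom-index selections (0-based) for every named antibody region."""

    fc: np.ndarray
    fab1: np.ndarray
    fab2: np.ndarray
    hinge: np.ndarray
    ch2_a: np.ndarray
    ch2_b: np.ndarray
    glycan_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    glycan_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    lc_cterm: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    glyco_asn_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    glyco_asn_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, _as_index_array(getattr(self, f.name)))
        if self.hinge.size == 0:
            raise ValueError("hinge selection must be non-empty")
        for name in ("fc", "fab1", "fab2", "ch2_a", "ch2_b"):
            if getattr(self, name).size == 0:
                raise ValueError(f"{name} selection must be non-empty")
        for a, b in (("fab1", "fab2"), ("fab1", "fc"), ("fab2", "fc")):
            if np.intersect1d(getattr(self, a), getattr(self, b)).size:
                raise ValueError(f"selections {a} and {b} must be disjoint")

    def validate(self, n_atoms: int) -> None:
        """Raise if any index is out of range for a topology of *n_atoms*."""
        for f in fields(self):
            idx = getattr(self, f.name)
            if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
                raise IndexError(
                    f"group '{f.name}' has indices outside [0, {n_atoms})"
                )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name).tolist() for f in fields(self)}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_groups(path: str | Path, topology=None) -> AtomGroupConfig:
    """Load an :class:`AtomGroupConfig` from a YAML mapping.

    Each group maps to either an explicit list of 0-based atom indices or,
    when *topology* (an ``mdtraj.Topology``) is given, an MDTraj selection
    string such as ``"chainid 0 and name CA"``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"group config {path} must be a mapping")
    resolved: dict[str, np.ndarray] = {}
    for name, value in raw.items():
        if name not in _GROUP_FIELDS:
            raise ValueError(f"unknown group '{name}' in {path}")
        if isinstance(value, str):
            if topology is None:
                raise ValueError(
                    f"group '{name}' is a selection string but no topology was given"
                )
            resolved[name] = topology.select(value)
        else:
            resolved[name] = _as_index_array(value)
    return AtomGroupConfig(**resolved)
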