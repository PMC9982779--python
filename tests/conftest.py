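import mdtraj as md
import numpy as np
import pytest

from mabshape import AtomGroupConfig, SyntheticSpec, generate_toy_mab


@pytest.fixture(scope="session")
def toy_small():
    """200-frame default-condition toy with global rigid motion per frame."""
    return generate_toy_mab(SyntheticSpec(seed=101, n_frames=200))


@pytest.fixture(scope="session")
def toy_static_frame():
    """A single hand-built axis-aligned frame: Fc along z below the hinge,
    CH2 domains on the x axis, Fabs above the equator."""
    coords = np.array(
        [
            # fc (0-4): elongated along z
            [0.0, 0.0, -1.0],
            [0.0, 0.0, -2.0],
            [0.0, 0.0, -3.0],
            [0.3, 0.0, -2.0],
            [-0.3, 0.0, -2.0],
            # hinge (5)
            [0.0, 0.0, 0.0],
            # ch2_a (6), ch2_b (7)
            [-1.0, 0.0, -2.5],
            [1.0, 0.0, -2.5],
            # fab1 (8), fab2 (9): above the hinge
            [2.0, 0.0, 2.0],
            [-2.0, 0.0, 2.0],
        ]
    )
    groups = AtomGroupConfig(
        fc=[0, 1, 2, 3, 4],
        fab1=[8],
        fab2=[9],
        hinge=[5],
        ch2_a=[6],
        ch2_b=[7],
    )
    return coords, groups


def make_single_chain_traj(xyz, atom_names=None, element=None):
    """Helper: wrap (n_frames, n_atoms, 3) coordinates in a one-residue-per-atom
    mdtraj trajectory."""
    xyz = np.asarray(xyz, dtype=np.float32)
    if xyz.ndim == 2:
        xyz = xyz[None]
    n_atoms = xyz.shape[1]
    top = md.Topology()
    chain = top.add_chain()
    el = element or md.element.carbon
    for i in range(n_atoms):
        res = top.add_residue("GLY", chain)
        name = atom_names[i] if atom_names else "CA"
        top.add_atom(name, el, res)
    return md.Trajectory(xyz, top)


@pytest.fixture
def chain_traj_factory():
    return make_single_chain_traj
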