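import numpy as np
import pytest

from spinpath.structures import Atom, StructureSnapshot


def make_snapshot(atom_specs, bonds=(), tags=None, temperature=290.0):
    """Compact snapshot builder for tests.

    ``atom_specs``: iterable of (atom_id, element, name, resname, resseq, xyz).
    """
    atoms = [
        Atom(atom_id=i, element=el, name=nm, residue_name=rn, residue_seq=rs,
             coords=np.asarray(xyz, dtype=float))
        for i, el, nm, rn, rs, xyz in atom_specs
    ]
    return StructureSnapshot(
        atoms=atoms,
        covalent_bonds=set(bonds),
        site_tags=dict(tags or {}),
        temperature=temperature,
    )


def random_rigid_transform(rng):
    """A uniformly random rotation + translation pair."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    shift = rng.normal(scale=10.0, size=3)
    return rot.as_matrix(), shift


@pytest.fixture()
def template():
    from spinpath.synthetic import toy_template

    return toy_template()
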