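"""Small builders shared across test modules."""

import numpy as np

from ifacewcn.structure_io import Atom, Residue


def single_atom_residue(coord, chain="A", number=1, name="GLY", element="C"):
    return Residue(
        chain_id=chain,
        seq_id=str(number),
        res_name=name,
        atoms=[Atom(name="CA", element=element, coord=np.asarray(coord, dtype=float))],
    )


def residues_from_coords(coords, chain="A"):
    return [single_atom_residue(c, chain=chain, number=i + 1) for i, c in enumerate(coords)]


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))
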