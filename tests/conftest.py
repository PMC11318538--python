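import numpy as np
import pytest

from cyclomimic import MatchParams, PeptideDatabase
from cyclomimic.fixtures import (
    FixtureSpec,
    make_cyclic_peptide,
    make_planted_target,
)
from cyclomimic.structure import Atom3D, MolecularModel, ResidueUnit


def make_residue(chain_id, number, res_name, atom_spec, seq_index=0):
    """atom_spec: list of (name, element, (x, y, z))."""
    atoms = [Atom3D(n, e, np.array(p, dtype=float)) for n, e, p in atom_spec]
    return ResidueUnit(chain_id, number, "", res_name, atoms, seq_index)


@pytest.fixture
def ring13():
    """13-residue head-to-tail ring with its database record."""
    return make_cyclic_peptide(FixtureSpec(13, "head_to_tail", seed=1))


@pytest.fixture
def disulfide18():
    return make_cyclic_peptide(FixtureSpec(18, "disulfide", seed=2))


@pytest.fixture
def planted_setup(ring13):
    """Small database plus a planted target built from the ring peptide."""
    model, record = ring13
    db = PeptideDatabase(motif_sizes=(5,))
    db.add_record(record, model)
    for i, (n, closure) in enumerate([(9, "disulfide"), (11, "head_to_tail")]):
        dm, dr = make_cyclic_peptide(FixtureSpec(n, closure, seed=40 + i))
        dr.pdb_id = f"decoy{i}"
        db.add_record(dr, dm)
    motif = (1, 3, 6, 8, 11)
    planted = make_planted_target(model, "P", motif, noise_sigma=0.0, seed=5)
    return model, record, db, motif, planted


@pytest.fixture
def default_params():
    return MatchParams(motif_size=5)


__all__ = ["make_residue", "MolecularModel"]
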