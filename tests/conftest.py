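import numpy as np
import pytest

from spasite.structure_io import Atom, ComplexStructure, ResidueRecord
from spasite.synthetic import FixtureSpec, make_bundle


def single_atom_residue(coord, chain_id="A", seq_index=0, kind="protein", element="C"):
    name = "CA" if kind == "protein" else "P"
    res_name = "ALA" if kind == "protein" else "U"
    return ResidueRecord(
        chain_id, seq_index, res_name, kind, [Atom(name, element, np.asarray(coord, dtype=float))]
    )


def line_structure(xs, kind="protein"):
    """Single-chain structure with one CA atom per residue at x positions ``xs``."""
    return ComplexStructure(
        [single_atom_residue((x, 0.0, 0.0), seq_index=i, kind=kind) for i, x in enumerate(xs)]
    )


def random_cloud_structure(rng, n_protein, n_rna, box=12.0, max_atoms=4):
    """Random atom-cloud complex for brute-force labeling oracles."""
    residues = []
    for i in range(n_protein):
        atoms = [
            Atom("CA" if j == 0 else f"C{j}", "C", rng.uniform(-box, box, 3))
            for j in range(rng.integers(1, max_atoms + 1))
        ]
        residues.append(ResidueRecord("A", i, "ALA", "protein", atoms))
    for i in range(n_rna):
        atoms = [
            Atom("P" if j == 0 else f"O{j}", "P" if j == 0 else "O", rng.uniform(-box, box, 3))
            for j in range(rng.integers(1, max_atoms + 1))
        ]
        residues.append(ResidueRecord("R", i, "U", "rna", atoms))
    return ComplexStructure(residues)


@pytest.fixture
def small_bundle():
    """30-residue helix with an RNA patch on residues 3-5 and strong signal."""
    return make_bundle(FixtureSpec(n_residues=30, rna_patch=(3, 5), rna_offset=4.0,
                                   profile_signal=3.0, seed=11))


@pytest.fixture
def ann_map(small_bundle):
    return {(r.chain_id, r.seq_index): r for r in small_bundle.annotations}
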