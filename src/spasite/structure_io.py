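"""Structure parsing, the residue/atom data model, distances and interface labeling.

A complex is represented as a flat ordered list of :class:`ResidueRecord`,
each tagged ``protein`` or ``rna``.  Interface residues are protein residues
whose closest heavy-atom distance to any RNA residue is strictly below a
cutoff (default 5.0 A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptyStructureError, MissingAtomsError, StructureParseError

logger = logging.getLogger(__name__)

#: 3-letter codes recognised as standard amino acids.
PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: residue names recognised as RNA nucleotides (PDB v3 single-letter plus
#: legacy one/two-letter variants).
RNA_RESNAMES = frozenset({"A", "C", "G", "U", "I", "RA", "RC", "RG", "RU", "RI"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_HYDROGEN_ELEMENTS = {"H", "D"}

DEFAULT_INTERFACE_CUTOFF = 5.0


@dataclass
class Atom:
    """A named heavy (or hydrogen) atom with Cartesian coordinates in A."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class ResidueRecord:
    """One polymer residue: chain label, position, kind and atoms.

    ``seq_index`` is the 0-based contiguous position within the chain;
    the author's residue number is kept in ``author_number`` as display
    metadata only.
    """

    chain_id: str
    seq_index: int
    res_name: str
    kind: str  # "protein" | "rna"
    atoms: list[Atom] = field(default_factory=list)
    author_number: int | None = None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.heavy_atoms()]
        if not coords:
            raise MissingAtomsError(
                f"residue {self.chain_id}/{self.seq_index} ({self.res_name}) has no heavy atoms"
            )
        return np.asarray(coords)

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        if self.kind == "protein":
            return THREE_TO_ONE.get(self.res_name, "X")
        return self.res_name[-1]


@dataclass
class ComplexStructure:
    """An ordered collection of protein and RNA residues."""

    residues: list[ResidueRecord]
    source_id: str = ""

    def protein_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.kind == "protein"]

    def rna_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.kind == "rna"]

    def protein_chains(self) -> dict[str, list[ResidueRecord]]:
        chains: dict[str, list[ResidueRecord]] = {}
        for r in self.protein_residues():
            chains.setdefault(r.chain_id, []).append(r)
        return chains

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.protein_chains()[chain_id])


def _classify_resname(name: str) -> str | None:
    name = name.strip().upper()
    if name in PROTEIN_RESNAMES:
        return "protein"
    if name in RNA_RESNAMES:
        return "rna"
    return None


def read_structure(path, format: str = "pdb") -> ComplexStructure:
    """Parse a PDB or mmCIF file into a :class:`ComplexStructure`.

    Waters, ions and other non-polymer hetero groups are dropped; hydrogens
    are kept on the record but excluded from every distance computation.
    Only the first model of multi-model files is read.  Alternate locations
    collapse to the highest-occupancy conformer.
    """
    from Bio.PDB import MMCIFParser, PDBParser

    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format: {format!r}")
    parser = PDBParser(QUIET=True) if format == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio_structure = parser.get_structure("s", str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio.PDB raises assorted concrete types
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    try:
        model = next(iter(bio_structure))
    except StopIteration:
        raise StructureParseError(f"{path}: file contains no model")

    residues: list[ResidueRecord] = []
    per_chain_counter: dict[tuple[str, str], int] = {}
    for chain in model:
        for res in chain:
            kind = _classify_resname(res.get_resname())
            if kind is None:
                continue  # water, ion, ligand
            atoms = []
            for atom in res.get_atoms():  # yields highest-occupancy altloc
                element = (atom.element or atom.get_name()[0]).strip()
                atoms.append(Atom(atom.get_name(), element, np.array(atom.get_coord(), dtype=float)))
            if not atoms:
                continue
            key = (chain.id, kind)
            idx = per_chain_counter.get(key, 0)
            per_chain_counter[key] = idx + 1
            residues.append(
                ResidueRecord(
                    chain_id=chain.id,
                    seq_index=idx,
                    res_name=res.get_resname().strip(),
                    kind=kind,
                    atoms=atoms,
                    author_number=res.get_id()[1],
                )
            )
    structure = ComplexStructure(residues, source_id=str(path))
    if not structure.protein_residues():
        raise EmptyStructureError(f"{path}: no protein residues after filtering")
    return structure


def min_heavy_atom_distance(a: ResidueRecord, b: ResidueRecord) -> float:
    """Minimum Euclidean distance over all heavy-atom pairs of two residues."""
    return float(cdist(a.heavy_coords(), b.heavy_coords()).min())


def label_interface_residues(
    s: ComplexStructure, cutoff: float = DEFAULT_INTERFACE_CUTOFF
) -> np.ndarray:
    """Binary interface labels for every protein residue, in structure order.

    A protein residue is labeled 1 iff its closest heavy-atom distance to
    any RNA residue is strictly less than ``cutoff``.  Structures without
    RNA yield all zeros.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    protein = s.protein_residues()
    if not protein:
        raise EmptyStructureError("structure has no protein residues")
    rna = s.rna_residues()
    labels = np.zeros(len(protein), dtype=int)
    if not rna:
        return labels
    rna_coords = np.vstack([r.heavy_coords() for r in rna])
    for i, res in enumerate(protein):
        if cdist(res.heavy_coords(), rna_coords).min() < cutoff:
            labels[i] = 1
    return labels


def _residue_centroid(r: ResidueRecord) -> np.ndarray:
    return r.heavy_coords().mean(axis=0)


def _residue_ca_coord(r: ResidueRecord) -> np.ndarray:
    ca = r.get_atom("CA")
    if ca is None or ca.is_hydrogen:
        logger.warning(
            "residue %s/%s lacks CA; falling back to heavy-atom centroid",
            r.chain_id, r.seq_index,
        )
        return _residue_centroid(r)
    return ca.coord


def residue_position(r: ResidueRecord, metric: str = "ca") -> np.ndarray:
    """Representative point of a residue under the ``ca``/``centroid`` metrics."""
    if metric == "ca":
        return _residue_ca_coord(r)
    if metric == "centroid":
        return _residue_centroid(r)
    raise ValueError(f"metric {metric!r} has no single representative point")


def residue_distance(s: ComplexStructure, i: int, j: int, metric: str = "ca") -> float:
    """Distance between protein residues ``i`` and ``j`` (indices into the
    protein-residue list) under one of three metrics: ``ca`` (Calpha-Calpha,
    centroid fallback for incomplete residues), ``min_heavy`` or ``centroid``.
    """
    protein = s.protein_residues()
    a, b = protein[i], protein[j]
    if metric == "min_heavy":
        return min_heavy_atom_distance(a, b)
    if metric in ("ca", "centroid"):
        return float(np.linalg.norm(residue_position(a, metric) - residue_position(b, metric)))
    raise ValueError(f"unknown distance metric: {metric!r}")
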