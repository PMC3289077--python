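"""Per-residue solvent accessibility and 3-state secondary structure.

Two sources are supported: classic DSSP output files, and a built-in
Shrake-Rupley accessible-surface-area fallback for structures without a
DSSP run.  DSSP 8-state codes collapse to 3 states as H,G,I -> H;
E,B -> E; everything else -> C.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    AnnotationParseError,
    EmptyAnnotationError,
    MissingAtomsError,
    UnknownElementError,
)
from .structure_io import ComplexStructure

logger = logging.getLogger(__name__)

#: van der Waals radii (A); documented constants, overridable per call.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

_SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def collapse_ss8(code: str) -> str:
    """Map one DSSP 8-state code to H/E/C."""
    return _SS8_TO_SS3.get(code.strip().upper(), "C")


@dataclass
class AnnotationRecord:
    """Solvent accessibility (A^2) and 3-state secondary structure of one residue."""

    chain_id: str
    seq_index: int
    asa: float
    ss3: str

    def __post_init__(self) -> None:
        if self.asa < 0:
            raise ValueError(f"asa must be non-negative, got {self.asa}")
        if self.ss3 not in ("H", "E", "C"):
            raise ValueError(f"ss3 must be one of H/E/C, got {self.ss3!r}")


def read_dssp(path) -> list[AnnotationRecord]:
    """Parse a classic fixed-column DSSP file.

    One record per residue line; chain-break lines (``!`` in the AA column)
    are skipped.  ``seq_index`` is assigned 0-based contiguously per chain.
    """
    with open(path) as fh:
        lines = fh.readlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise AnnotationParseError(f"{path}: no '#  RESIDUE' header line found")

    records: list[AnnotationRecord] = []
    counters: dict[str, int] = {}
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if len(line) < 38 or line[13] == "!":
            continue  # chain break
        chain_id = line[11].strip() or "A"
        ss3 = collapse_ss8(line[16])
        try:
            asa = float(line[34:38])
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: bad ACC field") from exc
        idx = counters.get(chain_id, 0)
        counters[chain_id] = idx + 1
        records.append(AnnotationRecord(chain_id, idx, asa, ss3))
    if not records:
        raise EmptyAnnotationError(f"{path}: zero residue lines")
    return records


def write_dssp(records: list[AnnotationRecord], path, sequence: str | None = None) -> None:
    """Write records in a minimal classic-DSSP column layout (round-trip aid)."""
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition (minimal writer) ====\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        for i, rec in enumerate(records):
            aa = sequence[i] if sequence else "A"
            # columns match read_dssp: chain at 11, aa at 13, ss at 16, ACC at 34:38
            line = f"{i + 1:5d}{rec.seq_index + 1:5d} {rec.chain_id}"
            line = line.ljust(13) + aa
            line = line.ljust(16) + rec.ss3
            line = line.ljust(34) + f"{rec.asa:4.0f}"
            fh.write(line + "\n")


def sphere_points(n: int) -> np.ndarray:
    """Deterministic spiral lattice of ``n`` near-uniform unit-sphere points."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k  # golden-angle spiral
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_asa(
    s: ComplexStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-residue accessible surface area (A^2) over all residues of ``s``.

    Each heavy atom's solvent-accessible sphere (radius r_vdw + probe) is
    sampled on a deterministic spiral lattice; a point is exposed when it
    lies outside every neighboring atom's accessible sphere.  Per-atom areas
    sum per residue.  Hydrogens are ignored.
    """
    radii = radii or VDW_RADII
    coords: list[np.ndarray] = []
    arad: list[float] = []
    owner: list[int] = []
    for ri, res in enumerate(s.residues):
        heavies = res.heavy_atoms()
        if not heavies:
            raise MissingAtomsError(f"residue {res.chain_id}/{res.seq_index} has no heavy atoms")
        for atom in heavies:
            el = atom.element.upper()
            if el not in radii:
                raise UnknownElementError(
                    f"no van der Waals radius for element {el!r} (atom {atom.name} "
                    f"in residue {res.chain_id}/{res.seq_index})"
                )
            coords.append(atom.coord)
            arad.append(radii[el] + probe_radius)
            owner.append(ri)

    xyz = np.asarray(coords)
    rad = np.asarray(arad)
    unit = sphere_points(n_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * rad.max()

    per_residue = np.zeros(len(s.residues))
    for i in range(len(xyz)):
        neighbors = [j for j in tree.query_ball_point(xyz[i], r=rad[i] + max_reach) if j != i]
        pts = xyz[i] + rad[i] * unit
        if neighbors:
            d2 = ((pts[:, None, :] - xyz[neighbors][None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (rad[neighbors] ** 2)[None, :], axis=1)
            n_exposed = int(exposed.sum())
        else:
            n_exposed = n_points
        per_residue[owner[i]] += 4.0 * math.pi * rad[i] ** 2 * n_exposed / n_points
    return per_residue


def annotations_from_structure(
    s: ComplexStructure,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> list[AnnotationRecord]:
    """Fallback annotations: Shrake-Rupley ASA on the protein residues alone,
    secondary structure all-C (no hydrogen-bond assignment is attempted)."""
    protein = s.protein_residues()
    protein_only = ComplexStructure(protein, source_id=s.source_id)
    asa = shrake_rupley_asa(protein_only, probe_radius, n_points)
    logger.warning("no DSSP available for %s: secondary structure set to all-C", s.source_id)
    return [
        AnnotationRecord(r.chain_id, r.seq_index, float(a), "C")
        for r, a in zip(protein, asa)
    ]


def write_annotation_tsv(records: list[AnnotationRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chain_id\tseq_index\tasa\tss3\n")
        for r in records:
            fh.write(f"{r.chain_id}\t{r.seq_index}\t{r.asa:.6g}\t{r.ss3}\n")


def read_annotation_tsv(path) -> list[AnnotationRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chain_id", "seq_index", "asa", "ss3"]:
            raise AnnotationParseError(f"{path}: unexpected header {header}")
        for line in fh:
            chain_id, seq_index, asa, ss3 = line.rstrip("\n").split("\t")
            records.append(AnnotationRecord(chain_id, int(seq_index), float(asa), ss3))
    if not records:
        raise EmptyAnnotationError(f"{path}: zero records")
    return records


def annotation_map(records: list[AnnotationRecord]) -> dict[tuple[str, int], AnnotationRecord]:
    """Index records by (chain_id, seq_index)."""
    return {(r.chain_id, r.seq_index): r for r in records}
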