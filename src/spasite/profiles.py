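"""Per-residue sequence profiles: PSI-BLAST PSSM ingestion and a BLOSUM62
pseudo-profile fallback, with optional sigmoid scaling.

All sources are converted to a fixed amino-acid column order
(``ARNDCQEGHILKMFPSTWYV``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import InvalidSequenceError, ProfileParseError, SequenceMismatchError

#: canonical column order for every profile row.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_SET = frozenset(AA_ORDER)


@dataclass
class ProfileMatrix:
    """Per-residue 20-column score rows for one protein chain."""

    chain_id: str
    rows: np.ndarray  # (n_residues, 20)
    residues: str = ""  # residue letters, for cross-checking; may be empty
    scaling: str = "raw"  # raw | sigmoid

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 20:
            raise ValueError(f"profile rows must be (n, 20), got {self.rows.shape}")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("profile rows must be finite")
        if self.residues and len(self.residues) != len(self.rows):
            raise ValueError("residue letters and rows disagree in length")

    def __len__(self) -> int:
        return len(self.rows)


def read_pssm(path, chain_id: str = "A") -> ProfileMatrix:
    """Parse PSI-BLAST ASCII PSSM output (the ``-Q`` checkpoint format).

    Captures the first 20 numeric columns (log-odds block) of each residue
    line; residue letters are preserved for sequence cross-checks.
    """
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # residue lines look like: <pos> <letter> <20 ints> [<20 pcts> <info> <weight>]
            if len(parts) < 22 or not parts[0].isdigit() or len(parts[1]) != 1:
                continue
            if not parts[1].isalpha():
                continue
            try:
                values = [float(v) for v in parts[2:22]]
            except ValueError as exc:
                raise ProfileParseError(
                    f"{path}:{lineno}: expected 20 numeric log-odds columns"
                ) from exc
            rows.append(values)
            letters.append(parts[1].upper())
    if not rows:
        raise ProfileParseError(f"{path}: no residue lines recognised")
    return ProfileMatrix(chain_id, np.asarray(rows), residues="".join(letters))


def write_pssm(p: ProfileMatrix, path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout readable by :func:`read_pssm`."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write(" " * 11 + "  ".join(AA_ORDER) + "\n")
        for i, row in enumerate(p.rows):
            letter = p.residues[i] if p.residues else "A"
            values = " ".join(f"{v:6.2f}" for v in row)
            # pad with a dummy percentage block so lines satisfy the >=22-token rule
            pct = " ".join("0" for _ in range(20))
            fh.write(f"{i + 1:5d} {letter} {values}  {pct}  0.00 0.00\n")


_BLOSUM62_CACHE: np.ndarray | None = None


def _blosum62_rows() -> np.ndarray:
    """BLOSUM62 rows indexed by AA_ORDER position, columns in AA_ORDER."""
    global _BLOSUM62_CACHE
    if _BLOSUM62_CACHE is None:
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        _BLOSUM62_CACHE = np.array(
            [[float(m[a, b]) for b in AA_ORDER] for a in AA_ORDER]
        )
    return _BLOSUM62_CACHE


def pseudo_profile(sequence: str, chain_id: str = "A", matrix_name: str = "blosum62") -> ProfileMatrix:
    """Substitution-matrix pseudo-profile: row i is the BLOSUM62 row of
    residue i; ``X`` maps to an all-zero row.  A deterministic, search-free
    stand-in for a database-derived profile."""
    if matrix_name.lower() != "blosum62":
        raise ValueError(f"unsupported substitution matrix: {matrix_name!r}")
    table = _blosum62_rows()
    index = {a: i for i, a in enumerate(AA_ORDER)}
    rows = np.zeros((len(sequence), 20))
    for i, letter in enumerate(sequence.upper()):
        if letter == "X":
            continue
        if letter not in _AA_SET:
            raise InvalidSequenceError(f"illegal amino-acid letter {letter!r} at position {i}")
        rows[i] = table[index[letter]]
    return ProfileMatrix(chain_id, rows, residues=sequence.upper())


def scale_profile(p: ProfileMatrix, mode: str = "sigmoid") -> ProfileMatrix:
    """Return a profile scaled per entry: ``sigmoid`` maps x to 1/(1+exp(-x)),
    ``raw`` returns the input unchanged."""
    if mode == "raw":
        return p
    if mode == "sigmoid":
        return ProfileMatrix(p.chain_id, expit(p.rows), residues=p.residues, scaling="sigmoid")
    raise ValueError(f"unknown scaling mode: {mode!r}")


def check_profile_sequence(p: ProfileMatrix, sequence: str, strict: bool = True) -> list[int]:
    """Compare the profile's residue letters against a structure sequence.

    Returns mismatching positions; raises :class:`SequenceMismatchError`
    when ``strict`` and any exist (positions where either side reads X are
    exempt).
    """
    if not p.residues:
        return []
    if len(p.residues) != len(sequence):
        raise SequenceMismatchError(
            f"profile has {len(p.residues)} rows but sequence has {len(sequence)} residues"
        )
    mismatches = [
        i
        for i, (a, b) in enumerate(zip(p.residues, sequence.upper()))
        if a != b and "X" not in (a, b)
    ]
    if mismatches and strict:
        raise SequenceMismatchError(f"profile/sequence mismatch at positions {mismatches}")
    return mismatches


def write_profile_tsv(p: ProfileMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scaling={p.scaling}\n")
        cols = "\t".join(f"s_{a}" for a in AA_ORDER)
        fh.write(f"chain_id\tseq_index\tresidue\t{cols}\n")
        for i, row in enumerate(p.rows):
            letter = p.residues[i] if p.residues else "X"
            values = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{p.chain_id}\t{i}\t{letter}\t{values}\n")


def read_profile_tsv(path) -> ProfileMatrix:
    scaling = "raw"
    rows: list[list[float]] = []
    letters: list[str] = []
    chain_id = "A"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# scaling="):
                scaling = line.split("=", 1)[1]
                continue
            if line.startswith("chain_id\t") or not line:
                continue
            parts = line.split("\t")
            if len(parts) != 23:
                raise ProfileParseError(f"{path}: expected 23 columns, got {len(parts)}")
            chain_id = parts[0]
            letters.append(parts[2])
            rows.append([float(v) for v in parts[3:]])
    if not rows:
        raise ProfileParseError(f"{path}: empty profile")
    return ProfileMatrix(chain_id, np.asarray(rows), residues="".join(letters), scaling=scaling)
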