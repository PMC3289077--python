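"""Feature encodings for interface-residue prediction.

Three spatial encodings built from a residue's 3D neighborhood —

* ``SpaPF``      profile rows of the target plus its w-1 nearest residues (20*w dims)
* ``SpawASA``    distance-weighted solvent accessibility of the window (w dims)
* ``SpaSecond``  H/E/C occurrence frequencies of the window (3 dims)

— plus two sequence-window baselines (``SeqProfile``, ``SeqASA``).  The
size-w spatial window is the target residue plus its w-1 nearest protein
residues of the same chain, in ascending 3D-distance order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, squareform

from .annotations import AnnotationRecord
from .errors import (
    EmptyTableError,
    InvalidWindowError,
    MissingAnnotationError,
    MissingProfileError,
    ShortChainError,
)
from .profiles import AA_ORDER, ProfileMatrix
from .structure_io import ComplexStructure, ResidueRecord, min_heavy_atom_distance, residue_position

logger = logging.getLogger(__name__)

ENCODINGS = ("SpaPF", "SpawASA", "SpaSecond", "SeqProfile", "SeqASA")

DEFAULT_D0 = 8.0


def encoding_dim(encoding: str, w: int) -> int:
    """Feature-vector length of an encoding at window width ``w``."""
    if encoding in ("SpaPF", "SeqProfile"):
        return 20 * w
    if encoding in ("SpawASA", "SeqASA"):
        return w
    if encoding == "SpaSecond":
        return 3
    raise ValueError(f"unknown encoding: {encoding!r}")


@dataclass
class FeatureTable:
    """Per-residue feature vectors with binary labels and provenance."""

    encoding: str
    window_w: int
    X: np.ndarray  # (n_rows, dim)
    labels: np.ndarray  # (n_rows,) in {0, 1}
    provenance: list[tuple[str, int]]  # (chain_id, seq_index) per row
    metric: str = "ca"
    d0: float = DEFAULT_D0
    scaling: str = "raw"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.X) != len(self.labels) or len(self.X) != len(self.provenance):
            raise ValueError("X, labels and provenance must align")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.X)


def chain_distance_matrix(chain: list[ResidueRecord], metric: str = "ca") -> np.ndarray:
    """Symmetric inter-residue distance matrix for one protein chain."""
    n = len(chain)
    if metric in ("ca", "centroid"):
        pos = np.array([residue_position(r, metric) for r in chain])
        return cdist(pos, pos)
    if metric == "min_heavy":
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = min_heavy_atom_distance(chain[i], chain[j])
        return d
    raise ValueError(f"unknown distance metric: {metric!r}")


def _neighbor_order_from_row(drow: np.ndarray, target: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Order (target first, then ascending distance, ties by index) and distances."""
    others = np.array([j for j in range(len(drow)) if j != target])
    # lexsort: primary key distance, secondary key seq_index (ascending)
    order = others[np.lexsort((others, drow[others]))][: max(w - 1, 0)]
    idx = np.concatenate([[target], order]).astype(int)
    dist = np.concatenate([[0.0], drow[order]])
    return idx, dist


def spatial_neighbor_order(
    s: ComplexStructure, target: int, w: int, metric: str = "ca"
) -> np.ndarray:
    """Within-chain indices of the size-w spatial window of ``target``.

    ``target`` indexes the structure's protein-residue list; the returned
    indices are 0-based positions within the target's chain (for a
    single-chain structure the two coincide).  Element 0 is the target
    itself; the rest are its w-1 nearest same-chain protein residues in
    ascending distance order, ties broken by ascending sequence index.
    """
    idx, _ = spatial_neighbors_with_distances(s, target, w, metric)
    return idx


def spatial_neighbors_with_distances(
    s: ComplexStructure, target: int, w: int, metric: str = "ca"
) -> tuple[np.ndarray, np.ndarray]:
    """As :func:`spatial_neighbor_order` but also returning the distances
    (0 for the target itself)."""
    if w < 1:
        raise InvalidWindowError(f"window width must be >= 1, got {w}")
    protein = s.protein_residues()
    tres = protein[target]
    chain = [r for r in protein if r.chain_id == tres.chain_id]
    if len(chain) < w:
        raise ShortChainError(
            f"chain {tres.chain_id} has {len(chain)} residues < window {w}"
        )
    d = chain_distance_matrix(chain, metric)
    return _neighbor_order_from_row(d[tres.seq_index], tres.seq_index, w)


def _pad_tail(vec: np.ndarray, dim: int) -> np.ndarray:
    if len(vec) == dim:
        return vec
    out = np.zeros(dim)
    out[: len(vec)] = vec
    return out


def _profile_row(p: ProfileMatrix, idx: int) -> np.ndarray:
    if idx < 0 or idx >= len(p):
        raise MissingProfileError(f"no profile row for residue index {idx}")
    return p.rows[idx]


def _ann_for(ann, chain_id: str, idx: int) -> AnnotationRecord:
    if isinstance(ann, dict):
        rec = ann.get((chain_id, idx))
    else:
        rec = next((r for r in ann if r.chain_id == chain_id and r.seq_index == idx), None)
    if rec is None:
        raise MissingAnnotationError(f"no annotation for residue {chain_id}/{idx}")
    return rec


def build_spapf(p: ProfileMatrix, order: np.ndarray, w: int) -> np.ndarray:
    """Concatenated profile rows in spatial-neighbor order (20*w entries).

    When ``order`` is shorter than ``w`` (short chain) the tail is zero-padded
    so the dimensionality stays fixed.
    """
    parts = [_profile_row(p, int(j)) for j in order]
    return _pad_tail(np.concatenate(parts), 20 * w)


def build_spawasa(
    ann, order: np.ndarray, distances: np.ndarray, w: int, d0: float = DEFAULT_D0,
    chain_id: str | None = None,
) -> np.ndarray:
    """Distance-weighted window ASA: entry j = ASA(order[j]) * exp(-d_j/d0).

    The target sits at distance 0 so entry 0 is its raw ASA; ``d0=inf``
    degenerates to the unweighted ASA window.  Zero-padded on short chains.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if len(order) != len(distances):
        raise ValueError("order and distances must align")
    if chain_id is None:
        chain_id = order_chain_id(ann)
    vec = np.array(
        [
            _ann_for(ann, chain_id, int(j)).asa * math.exp(-float(d) / d0)
            for j, d in zip(order, distances)
        ]
    )
    return _pad_tail(vec, w)


def order_chain_id(ann) -> str:
    """Single chain id of an annotation collection (helper for per-chain calls)."""
    if isinstance(ann, dict):
        chains = {c for c, _ in ann}
    else:
        chains = {r.chain_id for r in ann}
    if len(chains) != 1:
        raise ValueError("chain_id must be given explicitly for multi-chain annotations")
    return chains.pop()


def build_spasecond(ann, order: np.ndarray, w: int, chain_id: str | None = None) -> np.ndarray:
    """(f_H, f_E, f_C): class occurrence frequencies within the window."""
    if chain_id is None:
        chain_id = order_chain_id(ann)
    codes = [_ann_for(ann, chain_id, int(j)).ss3 for j in order]
    n = len(codes)
    return np.array([codes.count("H") / n, codes.count("E") / n, codes.count("C") / n])


def _seq_window_indices(target: int, w: int, n: int) -> list[int | None]:
    if w % 2 == 0:
        raise InvalidWindowError(f"sequence windows require odd w, got {w}")
    half = (w - 1) // 2
    return [i if 0 <= i < n else None for i in range(target - half, target + half + 1)]


def build_seqprofile(p: ProfileMatrix, target: int, w: int) -> np.ndarray:
    """Concatenated profile rows of the centered sequence window; positions
    past the chain termini contribute all-zero rows."""
    parts = [
        np.zeros(20) if i is None else _profile_row(p, i)
        for i in _seq_window_indices(target, w, len(p))
    ]
    return np.concatenate(parts)


def build_seqasa(ann, target: int, w: int, n: int | None = None, chain_id: str | None = None) -> np.ndarray:
    """Raw ASA values of the centered sequence window, zero-padded at termini."""
    if chain_id is None:
        chain_id = order_chain_id(ann)
    if n is None:
        n = (max(i for c, i in ann) if isinstance(ann, dict) else max(r.seq_index for r in ann)) + 1
    return np.array(
        [
            0.0 if i is None else _ann_for(ann, chain_id, i).asa
            for i in _seq_window_indices(target, w, n)
        ]
    )


def featurize_complex(
    s: ComplexStructure,
    profiles,
    ann,
    labels: np.ndarray,
    encoding: str,
    w: int,
    metric: str = "ca",
    d0: float = DEFAULT_D0,
) -> FeatureTable:
    """One feature row per protein residue of ``s``, in chain order.

    ``profiles`` is a :class:`ProfileMatrix` (single chain) or a dict
    ``chain_id -> ProfileMatrix``; ``ann`` a record list or a
    ``(chain_id, seq_index)`` dict.  Residues whose window cannot be built
    (short chain) get a reduced window with zero-padded tails, logged once
    per chain.
    """
    if encoding not in ENCODINGS:
        raise ValueError(f"unknown encoding: {encoding!r}")
    protein = s.protein_residues()
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(protein):
        raise ValueError("labels must align with the protein residues")
    if isinstance(profiles, ProfileMatrix):
        profiles = {profiles.chain_id: profiles}
    if not isinstance(ann, dict):
        ann = {(r.chain_id, r.seq_index): r for r in ann}

    dim = encoding_dim(encoding, w)
    chains = s.protein_chains()
    dmats = {}
    if encoding.startswith("Spa"):
        dmats = {cid: chain_distance_matrix(res, metric) for cid, res in chains.items()}

    rows, row_labels, provenance = [], [], []
    warned_short: set[str] = set()
    for gi, res in enumerate(protein):
        cid = res.chain_id
        chain = chains[cid]
        t = res.seq_index
        if encoding.startswith("Spa"):
            eff_w = min(w, len(chain))
            if eff_w < w and cid not in warned_short:
                logger.warning("chain %s shorter than window %d: padding", cid, w)
                warned_short.add(cid)
            order, dists = _neighbor_order_from_row(dmats[cid][t], t, eff_w)
            if encoding == "SpaPF":
                vec = build_spapf(profiles[cid], order, w)
            elif encoding == "SpawASA":
                vec = build_spawasa(ann, order, dists, w, d0, chain_id=cid)
            else:
                vec = build_spasecond(ann, order, w, chain_id=cid)
        elif encoding == "SeqProfile":
            vec = build_seqprofile(profiles[cid], t, w)
        else:  # SeqASA
            vec = build_seqasa(ann, t, w, n=len(chain), chain_id=cid)
        rows.append(vec)
        row_labels.append(labels[gi])
        provenance.append((cid, t))

    if not rows:
        raise EmptyTableError("featurization produced zero rows")
    scaling = next(iter(profiles.values())).scaling if profiles else "raw"
    return FeatureTable(
        encoding, w, np.vstack(rows), np.array(row_labels), provenance,
        metric=metric, d0=d0, scaling=scaling,
    )


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Stack feature tables of identical encoding/width (multi-complex dataset).

    Provenance chain ids are prefixed ``<k>:`` per source table so rows stay
    attributable and chain-level CV splitting keeps complexes apart.
    """
    if not tables:
        raise EmptyTableError("no tables to concatenate")
    head = tables[0]
    for t in tables[1:]:
        if (t.encoding, t.window_w) != (head.encoding, head.window_w):
            raise ValueError("tables disagree in encoding or window width")
    provenance = [
        (f"{k}:{cid}", idx)
        for k, t in enumerate(tables)
        for cid, idx in t.provenance
    ]
    return FeatureTable(
        head.encoding,
        head.window_w,
        np.vstack([t.X for t in tables]),
        np.concatenate([t.labels for t in tables]),
        provenance,
        metric=head.metric,
        d0=head.d0,
        scaling=head.scaling,
    )


def write_feature_tsv(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# encoding={table.encoding}\tw={table.window_w}\tmetric={table.metric}"
            f"\td0={table.d0}\tscaling={table.scaling}\n"
        )
        dim = table.X.shape[1]
        cols = "\t".join(f"f{i}" for i in range(dim))
        fh.write(f"chain_id\tseq_index\tlabel\t{cols}\n")
        for (cid, idx), y, row in zip(table.provenance, table.labels, table.X):
            values = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{cid}\t{idx}\t{int(y)}\t{values}\n")


def read_feature_tsv(path) -> FeatureTable:
    with open(path) as fh:
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith("# "):
            raise EmptyTableError(f"{path}: missing metadata header")
        meta = dict(kv.split("=", 1) for kv in meta_line[2:].split("\t"))
        fh.readline()  # column header
        provenance, labels, rows = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            provenance.append((parts[0], int(parts[1])))
            labels.append(int(parts[2]))
            rows.append([float(v) for v in parts[3:]])
    if not rows:
        raise EmptyTableError(f"{path}: zero feature rows")
    return FeatureTable(
        meta["encoding"], int(meta["w"]), np.asarray(rows), np.asarray(labels),
        provenance, metric=meta["metric"], d0=float(meta["d0"]), scaling=meta["scaling"],
    )
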